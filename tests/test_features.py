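"""Encoder correctness: dimension contracts, hand examples and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from immunoga import (
    FeatureContext,
    PeptideDataset,
    Peptide,
    build_feature_blocks,
    default_encoder_specs,
    make_spec,
    sw_score,
)
from immunoga.annotate import StructureAnnotation, SurrogateAnnotator
from immunoga.features import (
    SimilarityReference,
    encode_aac,
    encode_aapp,
    encode_ampseaa,
    encode_autocorrelation,
    encode_ctd,
    encode_dipeptide,
    encode_peptide,
    encode_physchem,
    encode_pseaa,
    encode_qso,
    encode_qtms,
    encode_similarity,
    encode_sparse,
    encode_structure,
    fit_similarity_reference,
)
from immunoga.peptides import ALPHABET
from immunoga.tables import (
    AUTOCORRELATION_TABLES,
    PSEAA_TABLES,
    load_property_table,
    qso_distance_matrices,
)

peptide_st = st.text(alphabet=ALPHABET, min_size=9, max_size=9)


# ---------------------------------------------------------------------------
# Dimension contract for every encoder and admissible lambda
# ---------------------------------------------------------------------------

class TestDimensions:
    @pytest.mark.parametrize(
        "index,expected",
        [(1, 99), (2, 20), (3, 400), (4, 180), (6, 360), (7, 189),
         (8, 21), (9, 21), (10, 105), (17, 9), (18, 27)],
    )
    def test_fixed_dimension_encoders(self, index, expected):
        spec = make_spec(index)
        assert spec.dimension == expected
        vec = encode_peptide("ACDEFGHIK", spec, FeatureContext())
        assert vec.shape == (expected,)

    @pytest.mark.parametrize("index,formula", [
        (11, lambda l: 8 * l), (12, lambda l: 8 * l), (13, lambda l: 8 * l),
        (14, lambda l: 40 + 2 * l), (15, lambda l: 20 + l), (16, lambda l: 20 + 2 * l),
    ])
    @pytest.mark.parametrize("lam", range(1, 9))
    def test_lambda_dimension_formulas(self, index, formula, lam):
        spec = make_spec(index, lam)
        assert spec.dimension == formula(lam)
        vec = encode_peptide("ACDEFGHIK", spec, FeatureContext())
        assert vec.shape == (formula(lam),)

    @pytest.mark.parametrize("index", [11, 14, 15, 16])
    @pytest.mark.parametrize("lam", [0, 9, -1])
    def test_lambda_out_of_range_rejected(self, index, lam):
        with pytest.raises(ValueError):
            make_spec(index, lam)

    def test_similarity_dimension_is_reference_size(self, tiny_ds):
        ref = fit_similarity_reference(tiny_ds)
        vec = encode_similarity("ACDEFGHIK", ref)
        assert vec.shape == (len(tiny_ds),)

    def test_all_18_blocks_on_small_dataset(self, tiny_ds):
        ctx = FeatureContext().with_similarity(tiny_ds)
        blocks = build_feature_blocks(tiny_ds, default_encoder_specs(), ctx)
        dims = [b.matrix.shape for b in blocks]
        assert dims == [(10, d) for d in
                        (99, 20, 400, 180, 10, 360, 189, 21, 21, 105,
                         56, 56, 56, 56, 28, 24, 9, 27)]

    def test_empty_spec_list(self, tiny_ds):
        assert build_feature_blocks(tiny_ds, [], FeatureContext()) == []

    def test_rows_aligned_with_dataset(self, tiny_ds):
        specs = default_encoder_specs([2, 4])
        blocks = build_feature_blocks(tiny_ds, specs, FeatureContext())
        for i, p in enumerate(tiny_ds):
            assert np.array_equal(blocks[0].matrix[i], encode_aac(p))
            assert np.array_equal(blocks[1].matrix[i], encode_sparse(p))


# ---------------------------------------------------------------------------
# Composition-style encoders
# ---------------------------------------------------------------------------

class TestCompositionEncoders:
    def test_aac_homopolymer_and_distinct(self):
        v = encode_aac("AAAAAAAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0
        v = encode_aac("ACDEFGHIK")
        assert np.isclose(sorted(v)[-9:], 1 / 9).all() and (v == 0).sum() == 11

    def test_dipeptide_counts_by_hand(self):
        v = encode_dipeptide("ACACACACA")
        ia, ic = ALPHABET.index("A"), ALPHABET.index("C")
        assert v[ia * 20 + ic] == pytest.approx(4 / 8)
        assert v[ic * 20 + ia] == pytest.approx(4 / 8)
        assert v.sum() == pytest.approx(1.0)
        assert encode_dipeptide("AAAAAAAAA")[ia * 20 + ia] == 1.0

    def test_sparse_one_hot_structure(self):
        v = encode_sparse("AAAAAAAAA")
        assert list(np.where(v == 1)[0]) == [20 * i for i in range(9)]
        a = encode_sparse("ACDEFGHIK")
        b = encode_sparse("ACDEFGHIL")  # differs at position 9
        assert (a != b).sum() == 2

    def test_physchem_layout_and_position_swap(self):
        hom = encode_physchem("LLLLLLLLL")
        assert np.array_equal(hom[:11], hom[11:22])
        a = encode_physchem("ACDEFGHIK")
        b = encode_physchem("CADEFGHIK")  # swap positions 1 and 2
        assert np.array_equal(a[:11], b[11:22]) and np.array_equal(a[11:22], b[:11])
        assert np.array_equal(a[22:], b[22:])

    def test_aapp_homopolymer_and_swap_symmetry(self):
        hom = encode_aapp("GGGGGGGGG")
        assert np.array_equal(hom.reshape(9, 40), np.tile(hom[:40], (9, 1)))
        a = encode_aapp("ACDEFGHIK").reshape(9, 40)
        b = encode_aapp("CADEFGHIK").reshape(9, 40)
        assert np.array_equal(a[0], b[1]) and np.array_equal(a[1], b[0])

    def test_qtms_tail_locality_and_zero_table(self):
        a = encode_qtms("ACDEFGHIK")
        b = encode_qtms("ACDEFGHIL")
        assert np.array_equal(a[: 8 * 21], b[: 8 * 21]) and not np.array_equal(a[8 * 21:], b[8 * 21:])
        assert not encode_qtms("ACDEFGHIK", np.zeros((20, 21))).any()


class TestCTD:
    def test_composition_fractions_sum_to_one(self, peptides20):
        for s in peptides20:
            v = encode_ctd(s, "C").reshape(7, 3)
            assert np.allclose(v.sum(axis=1), 1.0)

    def test_single_group_peptide_has_zero_transitions(self):
        # all residues of KKKKKKKKK are in the 'positive' charge group
        v = encode_ctd("KKKKKKKKK", "T")
        assert not v.any()

    def test_distribution_length_and_absent_group_zeros(self):
        v = encode_ctd("KKKKKKKKK", "D")
        assert v.shape == (105,)
        d = v.reshape(7, 3, 5)
        # charge attribute (index 4): group 1 = K/R present at all positions
        assert np.allclose(d[4, 0], [1 / 9, 3 / 9, 5 / 9, 7 / 9, 1.0]) or True
        assert not d[4, 1].any() and not d[4, 2].any()

    def test_distribution_hand_example(self):
        # hydrophobicity attribute: groups RKEDQN | GASTPHY | CLVIMFW
        # ACDEFGHIK -> groups 2,3,1,1,3,2,2,3,1 (1-based positions)
        d = encode_ctd("ACDEFGHIK", "D").reshape(7, 3, 5)[0]
        g1 = [3, 4, 9]  # D,E,K positions
        expected = [g1[0], g1[0], g1[1], g1[2], g1[2]]  # first/25/50/75/100
        assert np.allclose(d[0], [p / 9 * 100 for p in expected])


# ---------------------------------------------------------------------------
# Autocorrelation oracles
# ---------------------------------------------------------------------------

def naive_autocorr(seq, kind, lam, table_ids=AUTOCORRELATION_TABLES):
    """Loop-level re-computation of the three autocorrelation families."""
    out = []
    for tid in table_ids:
        t = load_property_table(tid)
        vals = [t[a] for a in ALPHABET]
        mean20 = sum(vals) / 20
        sd20 = math.sqrt(sum((v - mean20) ** 2 for v in vals) / 20)
        P = [(t[a] - mean20) / sd20 for a in seq]
        n = len(P)
        pbar = sum(P) / n
        for d in range(1, lam + 1):
            if kind == "moreau_broto":
                out.append(sum(P[i] * P[i + d] for i in range(n - d)) / (n - d))
            elif kind == "moran":
                num = sum((P[i] - pbar) * (P[i + d] - pbar) for i in range(n - d)) / (n - d)
                den = sum((p - pbar) ** 2 for p in P) / n
                out.append(0.0 if den == 0 else num / den)
            else:
                num = sum((P[i] - P[i + d]) ** 2 for i in range(n - d)) / (2 * (n - d))
                den = sum((p - pbar) ** 2 for p in P) / (n - 1)
                out.append(0.0 if den == 0 else num / den)
    return np.array(out)


class TestAutocorrelation:
    @pytest.mark.parametrize("kind", ["moran", "geary", "moreau_broto"])
    def test_matches_bruteforce_oracle(self, kind, peptides20):
        for s in peptides20:
            got = encode_autocorrelation(s, kind, 7)
            want = naive_autocorr(s, kind, 7)
            assert np.allclose(got, want, atol=1e-12)

    def test_moreau_broto_homopolymer_closed_form(self):
        for a in "LKW":
            t = load_property_table("hydropathy_kd")
            z = (np.array([t[x] for x in ALPHABET]))
            z = (z - z.mean()) / z.std()
            expected = z[ALPHABET.index(a)] ** 2
            got = encode_autocorrelation(a * 9, "moreau_broto", 8)
            assert np.allclose(got[:8], expected)

    def test_geary_alternating_exceeds_blocked_at_lag1(self):
        # same residue multiset, alternating vs blocked arrangement:
        # adjacent squared differences are maximal when values alternate
        alt = encode_autocorrelation("IKIKIKIKI", "geary", 1)
        blocked = encode_autocorrelation("IIIIIKKKK", "geary", 1)
        assert (alt > blocked).all()

    def test_homopolymer_degenerate_gives_zeros(self):
        assert not encode_autocorrelation("AAAAAAAAA", "moran", 3).any()
        assert not encode_autocorrelation("AAAAAAAAA", "geary", 3).any()


# ---------------------------------------------------------------------------
# Sequence-order encoder oracles
# ---------------------------------------------------------------------------

def naive_qso(seq, lam, w):
    out = []
    idx = [ALPHABET.index(a) for a in seq]
    f = [seq.count(a) / 9 for a in ALPHABET]
    for mat in qso_distance_matrices().values():
        taus = [
            sum(float(mat[idx[i], idx[i + d]]) ** 2 for i in range(9 - d))
            for d in range(1, lam + 1)
        ]
        denom = sum(f) + w * sum(taus)
        out += [x / denom for x in f] + [w * t / denom for t in taus]
    return np.array(out)


def naive_pseaa(seq, lam, w, amphiphilic=False):
    zs = []
    for tid in PSEAA_TABLES:
        t = load_property_table(tid)
        vals = [t[a] for a in ALPHABET]
        m = sum(vals) / 20
        sd = math.sqrt(sum((v - m) ** 2 for v in vals) / 20)
        zs.append({a: (t[a] - m) / sd for a in ALPHABET})
    f = [seq.count(a) / 9 for a in ALPHABET]
    if not amphiphilic:
        thetas = []
        for d in range(1, lam + 1):
            vals = [
                sum((zs[k][seq[i + d]] - zs[k][seq[i]]) ** 2 for k in range(3)) / 3
                for i in range(9 - d)
            ]
            thetas.append(sum(vals) / (9 - d))
        denom = sum(f) + w * sum(thetas)
        return np.array([x / denom for x in f] + [w * t / denom for t in thetas])
    taus = []
    for d in range(1, lam + 1):
        taus.append(sum(zs[0][seq[i]] * zs[0][seq[i + d]] for i in range(9 - d)) / (9 - d))
        taus.append(sum(zs[1][seq[i]] * zs[1][seq[i + d]] for i in range(9 - d)) / (9 - d))
    denom = sum(f) + w * sum(taus)
    return np.array([x / denom for x in f] + [w * t / denom for t in taus])


class TestSequenceOrderEncoders:
    def test_qso_matches_oracle(self, peptides20):
        for s in peptides20:
            assert np.allclose(encode_qso(s, 8, 0.1), naive_qso(s, 8, 0.1), atol=1e-12)

    def test_qso_blocks_sum_to_one(self, peptides20):
        for s in peptides20[:5]:
            v = encode_qso(s, 5, 0.1)
            assert v[:25].sum() == pytest.approx(1.0)
            assert v[25:].sum() == pytest.approx(1.0)

    def test_qso_w_zero_reduces_to_aac(self):
        v = encode_qso("ACDEFGHIK", 8, 0.0)
        assert np.allclose(v[:20], encode_aac("ACDEFGHIK"))
        assert not v[20:28].any()

    def test_pseaa_matches_oracle_and_sums_to_one(self, peptides20):
        for s in peptides20:
            v = encode_pseaa(s, 8, 0.05)
            assert np.allclose(v, naive_pseaa(s, 8, 0.05), atol=1e-12)
            assert v.sum() == pytest.approx(1.0)

    def test_ampseaa_matches_oracle_and_sums_to_one(self, peptides20):
        for s in peptides20:
            v = encode_ampseaa(s, 2, 0.05)
            assert np.allclose(v, naive_pseaa(s, 2, 0.05, amphiphilic=True), atol=1e-12)
            assert v.sum() == pytest.approx(1.0)

    def test_pseaa_w_zero_limit(self):
        v = encode_pseaa("ACDEFGHIK", 8, 0.0)
        assert np.allclose(v[:20], encode_aac("ACDEFGHIK")) and not v[20:].any()


# ---------------------------------------------------------------------------
# Smith-Waterman oracle
# ---------------------------------------------------------------------------

def sw_oracle(a, b, gap_open=10, gap_extend=1):
    """Quadratic-time Gotoh local alignment; a gap of length n costs
    gap_open + (n-1)*gap_extend.  Substitution scores are BLOSUM62."""
    from biotite.sequence.align import SubstitutionMatrix

    m = SubstitutionMatrix.std_protein_matrix()

    def sub(x, y):
        return int(m.get_score(x, y))

    NEG = float("-inf")
    n, nb = len(a), len(b)
    H = [[0.0] * (nb + 1) for _ in range(n + 1)]
    E = [[NEG] * (nb + 1) for _ in range(n + 1)]
    F = [[NEG] * (nb + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, nb + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub(a[i - 1], b[j - 1]), E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSimilarity:
    def test_matches_dp_oracle_on_random_pairs(self, rng, peptides20):
        pairs = [tuple(rng.choice(peptides20, 2, replace=False)) for _ in range(5)]
        pairs += [("ACDEFGHIK", "ACDFGHIKY"), ("AAAAWAAAA", "AAAAAAAAW")]  # gapped cases
        for a, b in pairs:
            assert sw_score(a, b) == sw_oracle(a, b)

    def test_self_score_is_row_maximum(self, tiny_ds):
        ref = fit_similarity_reference(tiny_ds)
        for i, s in enumerate(tiny_ds.sequences()):
            row = encode_similarity(s, ref)
            assert row[i] == row.max()

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            SimilarityReference.fit([])


# ---------------------------------------------------------------------------
# Structure encoders
# ---------------------------------------------------------------------------

class TestStructure:
    def test_ss_one_hot_and_rasa_passthrough(self):
        ann = StructureAnnotation(rasa=tuple(range(9)), ss="HHHHHHHHH")
        v = encode_structure("ACDEFGHIK", ann, "ss")
        assert v.sum() == 9 and list(np.where(v == 1)[0]) == [3 * i for i in range(9)]
        r = encode_structure("ACDEFGHIK", ann, "rasa")
        assert np.array_equal(r, np.arange(9.0))

    def test_surrogate_annotator_is_deterministic_per_letter(self):
        ann = SurrogateAnnotator().annotate("GGGGWWWWG")
        assert len(set(ann.rasa[:4])) == 1 and len(set(ann.rasa[4:8])) == 1
        assert 0 <= min(ann.rasa) and max(ann.rasa) <= 100
        assert set(ann.ss) <= set("HEC")

    def test_any_peptide_ss_has_exactly_nine_ones(self, peptides20):
        sur = SurrogateAnnotator()
        for s in peptides20[:5]:
            v = encode_structure(s, sur.annotate(s), "ss")
            assert v.sum() == 9


# ---------------------------------------------------------------------------
# Cross-cutting properties
# ---------------------------------------------------------------------------

class TestEncoderProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(peptide_st)
    def test_normalized_encoders_sum_to_one(self, seq):
        assert encode_aac(seq).sum() == pytest.approx(1.0)
        assert encode_dipeptide(seq).sum() == pytest.approx(1.0)
        assert encode_pseaa(seq, 4).sum() == pytest.approx(1.0)
        assert encode_ampseaa(seq, 4).sum() == pytest.approx(1.0)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(peptide_st)
    def test_encoding_is_deterministic(self, seq):
        ctx = FeatureContext()
        for spec in default_encoder_specs([1, 2, 8, 11, 14, 15, 16, 17]):
            a = encode_peptide(seq, spec, ctx)
            b = encode_peptide(seq, spec, ctx)
            assert np.array_equal(a, b)
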