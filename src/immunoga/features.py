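"""The 18 sequence-derived feature encoders behind one uniform interface.

Each encoder maps a 9-mer peptide (plus fitted context where needed) to a
fixed-length numeric vector:

====== ================================== =========== ==========
index  encoder                             dimension   parameter
====== ================================== =========== ==========
F1     position-wise physicochemical       99 (9x11)   —
F2     amino-acid composition (AAC)        20          —
F3     amino-acid pair profile             400         —
F4     sparse (one-hot) profile            180 (9x20)  —
F5     pairwise similarity profile         n (fitted)  —
F6     contact potentials (AAPP)           360 (9x40)  —
F7     QTMS descriptors                    189 (9x21)  —
F8     CTD composition                     21 (7x3)    —
F9     CTD transition                      21 (7x3)    —
F10    CTD distribution                    105 (7x3x5) —
F11    Moran autocorrelation               8xλ         λ in 1..8
F12    Geary autocorrelation               8xλ         λ in 1..8
F13    Moreau–Broto autocorrelation        8xλ         λ in 1..8
F14    quasi-sequence-order (QSO)          40+2λ       λ in 1..8
F15    pseudo amino-acid comp. (PseAA)     20+λ        λ in 1..8
F16    amphiphilic PseAA (AmPseAA)         20+2λ       λ in 1..8
F17    predicted RASA                      9           —
F18    predicted secondary structure       27 (9x3)    —
====== ================================== =========== ==========

The sparse profile is 9x20 = 180 wide: one 20-bit one-hot block per
position, which is what "merging the bit vectors for its amino acids"
yields for a 9-mer.

λ-parameterised encoders accept lags/order factors up to sequence
length − 1 = 8.  Default λ values (7, 7, 7, 8, 8, 2 for F11–F16) are
the per-feature optima found by the λ sweep on the IMMA2 benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np

from .annotate import StructureAnnotation, SurrogateAnnotator, SS_STATES
from .peptides import (
    ALPHABET,
    ALPHABET_INDEX,
    PEPTIDE_LENGTH,
    Peptide,
    PeptideDataset,
    ValidationError,
)
from .tables import (
    AUTOCORRELATION_TABLES,
    CTD_ATTRIBUTES,
    PHYSCHEM_PROPENSITY_TABLES,
    PSEAA_TABLES,
    PropertyTable,
    load_contact_potentials,
    load_property_table,
    load_qtms_table,
    qso_distance_matrices,
)

logger = logging.getLogger(__name__)

N = PEPTIDE_LENGTH
MAX_LAMBDA = N - 1

#: Default lag / sequence-order depth per λ-parameterised encoder.
DEFAULT_LAMBDAS: dict[int, int] = {11: 7, 12: 7, 13: 7, 14: 8, 15: 8, 16: 2}

QSO_WEIGHT = 0.1
PSEAA_WEIGHT = 0.05

SW_GAP_OPEN = 10
SW_GAP_EXTEND = 1


def _seq(p: Peptide | str) -> str:
    s = p.sequence if isinstance(p, Peptide) else str(p)
    if len(s) != N or set(s) - set(ALPHABET):
        raise ValidationError(f"not a valid 9-mer over the standard alphabet: {s!r}")
    return s


def _check_lambda(lam: int) -> int:
    lam = int(lam)
    if not 1 <= lam <= MAX_LAMBDA:
        raise ValueError(f"lambda must be in 1..{MAX_LAMBDA}, got {lam}")
    return lam


# ---------------------------------------------------------------------------
# Encoder specs and registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncoderSpec:
    """Identity, parameterisation and output width of one encoder."""

    index: int
    name: str
    lam: int | None = None
    dimension: int | None = None  # None for F5 until a reference is fitted
    requires_fit: bool = False
    requires_annotator: bool = False

    @property
    def code(self) -> str:
        return f"F{self.index}"


_FIXED_DIMS = {1: 99, 2: 20, 3: 400, 4: 180, 6: 360, 7: 189, 8: 21, 9: 21,
               10: 105, 17: 9, 18: 27}
_LAMBDA_DIMS: dict[int, Callable[[int], int]] = {
    11: lambda l: 8 * l,
    12: lambda l: 8 * l,
    13: lambda l: 8 * l,
    14: lambda l: 40 + 2 * l,
    15: lambda l: 20 + l,
    16: lambda l: 20 + 2 * l,
}
_NAMES = {
    1: "physicochemical propensities",
    2: "amino acid composition (AAC)",
    3: "amino acid pair profile",
    4: "sparse profile",
    5: "pairwise similarity profile",
    6: "contact potentials (AAPP)",
    7: "QTMS descriptors",
    8: "CTD composition",
    9: "CTD transition",
    10: "CTD distribution",
    11: "Moran autocorrelation",
    12: "Geary autocorrelation",
    13: "Moreau-Broto autocorrelation",
    14: "quasi-sequence-order (QSO)",
    15: "pseudo amino acid composition (PseAA)",
    16: "amphiphilic PseAA (AmPseAA)",
    17: "predicted RASA",
    18: "predicted secondary structure (SS)",
}
ALL_INDICES = tuple(range(1, 19))


def make_spec(index: int, lam: int | None = None, n_reference: int | None = None) -> EncoderSpec:
    """Build the :class:`EncoderSpec` for feature ``Findex``."""
    if index not in _NAMES:
        raise ValueError(f"feature index must be 1..18, got {index}")
    if index in _LAMBDA_DIMS:
        lam = _check_lambda(lam if lam is not None else DEFAULT_LAMBDAS[index])
        dim: int | None = _LAMBDA_DIMS[index](lam)
    else:
        if lam is not None:
            raise ValueError(f"F{index} takes no lambda parameter")
        dim = _FIXED_DIMS.get(index)  # None for F5
        if index == 5 and n_reference is not None:
            dim = int(n_reference)
    return EncoderSpec(
        index=index,
        name=_NAMES[index],
        lam=lam,
        dimension=dim,
        requires_fit=index == 5,
        requires_annotator=index in (17, 18),
    )


def default_encoder_specs(
    indices: Iterable[int] = ALL_INDICES, lambdas: dict[int, int] | None = None
) -> list[EncoderSpec]:
    """Specs for the requested features, with benchmark-optimal default λ."""
    lambdas = lambdas or {}
    return [
        make_spec(i, lambdas.get(i, DEFAULT_LAMBDAS.get(i)))
        for i in indices
    ]


# ---------------------------------------------------------------------------
# Smith-Waterman similarity (F5)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _blosum62():
    from biotite.sequence.align import SubstitutionMatrix

    return SubstitutionMatrix.std_protein_matrix()


@lru_cache(maxsize=500_000)
def _sw_cached(a: str, b: str) -> float:
    from biotite.sequence import ProteinSequence
    from biotite.sequence.align import align_optimal

    ali = align_optimal(
        ProteinSequence(a),
        ProteinSequence(b),
        _blosum62(),
        gap_penalty=(-SW_GAP_OPEN, -SW_GAP_EXTEND),
        local=True,
    )
    return float(ali[0].score)


def sw_score(a: str, b: str) -> float:
    """Smith–Waterman local-alignment score (BLOSUM62, gap open 10, extend 1).

    A gap of length ``n`` costs ``10 + (n-1)``.  Raw (unnormalised) scores.
    """
    a, b = _seq(a), _seq(b)
    if b < a:  # symmetric; canonicalise for the cache
        a, b = b, a
    return _sw_cached(a, b)


@dataclass(frozen=True)
class SimilarityReference:
    """The training-fold sequences a similarity profile is computed against."""

    sequences: tuple[str, ...]

    @classmethod
    def fit(cls, train: PeptideDataset | Sequence[str]) -> "SimilarityReference":
        seqs = train.sequences() if isinstance(train, PeptideDataset) else list(train)
        if not seqs:
            raise ValueError("cannot fit a similarity reference on an empty set")
        return cls(sequences=tuple(_seq(s) for s in seqs))

    def __len__(self) -> int:
        return len(self.sequences)


def fit_similarity_reference(train: PeptideDataset) -> SimilarityReference:
    return SimilarityReference.fit(train)


def encode_similarity(p: Peptide | str, ref: SimilarityReference) -> np.ndarray:
    """F5: local-alignment scores of ``p`` against every reference sequence."""
    s = _seq(p)
    return np.array([sw_score(s, r) for r in ref.sequences], dtype=float)


# ---------------------------------------------------------------------------
# Composition-style encoders (F1-F4, F6, F7)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _default_physchem() -> tuple[PropertyTable, ...]:
    return tuple(load_property_table(t) for t in PHYSCHEM_PROPENSITY_TABLES)


def encode_physchem(p: Peptide | str, tables: Sequence[PropertyTable] | None = None) -> np.ndarray:
    """F1: per-position values of 11 physicochemical scales (position-major)."""
    s = _seq(p)
    tables = tuple(tables) if tables is not None else _default_physchem()
    return np.array([t[a] for a in s for t in tables], dtype=float)


def encode_aac(p: Peptide | str) -> np.ndarray:
    """F2: fraction of each of the 20 residues (sums to 1)."""
    s = _seq(p)
    v = np.zeros(20)
    for a in s:
        v[ALPHABET_INDEX[a]] += 1.0
    return v / N


def encode_dipeptide(p: Peptide | str) -> np.ndarray:
    """F3: fraction of each ordered adjacent residue pair (400 entries)."""
    s = _seq(p)
    v = np.zeros(400)
    for a, b in zip(s, s[1:]):
        v[ALPHABET_INDEX[a] * 20 + ALPHABET_INDEX[b]] += 1.0
    return v / (N - 1)


def encode_sparse(p: Peptide | str) -> np.ndarray:
    """F4: nine concatenated 20-bit one-hot blocks (180 entries, nine ones)."""
    s = _seq(p)
    v = np.zeros(9 * 20)
    for i, a in enumerate(s):
        v[i * 20 + ALPHABET_INDEX[a]] = 1.0
    return v


def encode_aapp(p: Peptide | str, contact_tables: np.ndarray | None = None) -> np.ndarray:
    """F6: per-position values of 40 contact-potential scales (position-major)."""
    s = _seq(p)
    tables = load_contact_potentials() if contact_tables is None else np.asarray(contact_tables, float)
    if tables.shape != (40, 20):
        raise ValueError(f"contact-potential table set must be (40, 20), got {tables.shape}")
    idx = [ALPHABET_INDEX[a] for a in s]
    return tables[:, idx].T.reshape(-1)  # position-major: pos1 x 40, pos2 x 40, ...


def encode_qtms(p: Peptide | str, qtms_table: np.ndarray | None = None) -> np.ndarray:
    """F7: per-position 21 QTMS descriptor values (position-major, 189 entries)."""
    s = _seq(p)
    table = load_qtms_table() if qtms_table is None else np.asarray(qtms_table, float)
    if table.shape != (20, 21):
        raise ValueError(f"QTMS table must be (20, 21), got {table.shape}")
    idx = [ALPHABET_INDEX[a] for a in s]
    return table[idx].reshape(-1)


# ---------------------------------------------------------------------------
# CTD (F8-F10)
# ---------------------------------------------------------------------------

def _group_string(s: str, groups: tuple[str, str, str]) -> list[int]:
    lookup = {a: g for g, members in enumerate(groups) for a in members}
    return [lookup[a] for a in s]


def encode_ctd(p: Peptide | str, part: str) -> np.ndarray:
    """F8/F9/F10: composition / transition / distribution over the 7
    standard three-group attribute partitions.

    * C — per attribute, the fraction of residues in each group (7x3).
    * T — per attribute, transitions between distinct adjacent groups
      for the pairs (1,2), (1,3), (2,3), divided by 8 (7x3).
    * D — per attribute and group, the positions (% of length) of the
      first, 25%, 50%, 75% and last occurrence; 0 for absent groups
      (7x3x5).
    """
    s = _seq(p)
    if part not in ("C", "T", "D"):
        raise ValueError(f"part must be C, T or D, got {part!r}")
    out: list[float] = []
    for _, groups in CTD_ATTRIBUTES:
        g = _group_string(s, groups)
        if part == "C":
            for k in range(3):
                out.append(g.count(k) / N)
        elif part == "T":
            pairs = list(zip(g, g[1:]))
            for a, b in ((0, 1), (0, 2), (1, 2)):
                count = sum(1 for x, y in pairs if {x, y} == {a, b})
                out.append(count / (N - 1))
        else:
            for k in range(3):
                pos = [i + 1 for i, x in enumerate(g) if x == k]
                if not pos:
                    out.extend([0.0] * 5)
                    continue
                m = len(pos)
                for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                    rank = max(1, int(np.ceil(frac * m)))
                    out.append(pos[rank - 1] / N * 100.0)
    return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# Autocorrelation (F11-F13)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _default_autocorr() -> tuple[PropertyTable, ...]:
    return tuple(load_property_table(t).standardized() for t in AUTOCORRELATION_TABLES)


def encode_autocorrelation(
    p: Peptide | str,
    kind: str,
    lam: int,
    props: Sequence[PropertyTable] | None = None,
) -> np.ndarray:
    """F11/F12/F13: Moran / Geary / Moreau–Broto autocorrelation of 8
    standardized property scales at lags 1..λ (property-major layout).

    With residue property values ``P_1..P_N`` (N = 9, scales z-scored
    over the 20 letters) and lag ``d``:

    * Moreau–Broto: ``AC(d) = sum_i P_i P_{i+d} / (N-d)``
    * Moran: ``I(d) = [sum_i (P_i-Pbar)(P_{i+d}-Pbar)/(N-d)] /
      [sum_i (P_i-Pbar)^2 / N]``
    * Geary: ``C(d) = [sum_i (P_i-P_{i+d})^2 / (2(N-d))] /
      [sum_i (P_i-Pbar)^2 / (N-1)]``

    A homopolymer makes the Moran/Geary denominators vanish; the
    affected entries are emitted as 0 with a logged warning.
    """
    s = _seq(p)
    lam = _check_lambda(lam)
    if kind not in ("moran", "geary", "moreau_broto"):
        raise ValueError(f"unknown autocorrelation kind {kind!r}")
    if props is None:
        tables = _default_autocorr()
    else:
        tables = tuple(t.standardized() if not t.table_id.endswith(":z") else t for t in props)
    out: list[float] = []
    for t in tables:
        P = np.array([t[a] for a in s])
        mean = P.mean()
        centered = P - mean
        degenerate = np.ptp(P) == 0  # homopolymer: positional variance vanishes
        var_n = (centered**2).sum() / len(P)
        var_n1 = (centered**2).sum() / (len(P) - 1)
        for d in range(1, lam + 1):
            lead, lag_v = P[: len(P) - d], P[d:]
            if kind == "moreau_broto":
                out.append(float((lead * lag_v).sum() / (len(P) - d)))
            elif kind == "moran":
                if degenerate or var_n == 0:
                    logger.warning("zero-variance property %s on %s; Moran set to 0", t.table_id, s)
                    out.append(0.0)
                else:
                    num = ((lead - mean) * (lag_v - mean)).sum() / (len(P) - d)
                    out.append(float(num / var_n))
            else:
                if degenerate or var_n1 == 0:
                    logger.warning("zero-variance property %s on %s; Geary set to 0", t.table_id, s)
                    out.append(0.0)
                else:
                    num = ((lead - lag_v) ** 2).sum() / (2 * (len(P) - d))
                    out.append(float(num / var_n1))
    return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# Sequence-order encoders (F14-F16)
# ---------------------------------------------------------------------------

def encode_qso(
    p: Peptide | str,
    lam: int = 8,
    w: float = QSO_WEIGHT,
    dists: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """F14: quasi-sequence-order descriptors from two residue distance
    matrices, each contributing a self-normalised ``20 + λ`` block.

    Per matrix, the order-d coupling number is
    ``tau_d = sum_i d(r_i, r_{i+d})^2``; the block is
    ``[f_a / (sum f + w sum tau)]_a  ++  [w tau_d / (sum f + w sum tau)]_d``
    with ``f`` the residue fractions.
    """
    s = _seq(p)
    lam = _check_lambda(lam)
    dists = dists if dists is not None else qso_distance_matrices()
    if len(dists) != 2:
        raise ValueError(f"QSO needs exactly 2 distance matrices, got {len(dists)}")
    f = encode_aac(s)
    idx = [ALPHABET_INDEX[a] for a in s]
    out: list[float] = []
    for mat in dists.values():
        mat = np.asarray(mat, dtype=float)
        if mat.shape != (20, 20):
            raise ValueError(f"distance matrix must be 20x20, got {mat.shape}")
        taus = [
            float(sum(mat[idx[i], idx[i + d]] ** 2 for i in range(N - d)))
            for d in range(1, lam + 1)
        ]
        denom = f.sum() + w * sum(taus)
        out.extend((f / denom).tolist())
        out.extend((w * t / denom) for t in taus)
    return np.array(out, dtype=float)


@lru_cache(maxsize=1)
def _pseaa_scales() -> tuple[PropertyTable, ...]:
    return tuple(load_property_table(t).standardized() for t in PSEAA_TABLES)


def encode_pseaa(p: Peptide | str, lam: int = 8, w: float = PSEAA_WEIGHT) -> np.ndarray:
    """F15: pseudo amino-acid composition (20 + λ entries, sums to 1).

    ``theta_d`` averages ``Theta(r_i, r_{i+d})`` over the sequence, where
    ``Theta`` is the mean squared difference of the standardized
    hydrophobicity, hydrophilicity and side-chain-mass values.
    """
    s = _seq(p)
    lam = _check_lambda(lam)
    scales = _pseaa_scales()
    vals = np.stack([[t[a] for a in s] for t in scales])  # 3 x 9
    thetas = [
        float(((vals[:, d:] - vals[:, : N - d]) ** 2).mean(axis=0).sum() / (N - d))
        for d in range(1, lam + 1)
    ]
    f = encode_aac(s)
    denom = f.sum() + w * sum(thetas)
    return np.concatenate([f / denom, w * np.array(thetas) / denom])


def encode_ampseaa(p: Peptide | str, lam: int = 2, w: float = PSEAA_WEIGHT) -> np.ndarray:
    """F16: amphiphilic PseAA (20 + 2λ entries, sums to 1).

    Per lag d the hydrophobicity and hydrophilicity correlation factors
    ``tau_{2d-1}, tau_{2d}`` are mean products of the standardized scale
    values at distance d.
    """
    s = _seq(p)
    lam = _check_lambda(lam)
    h1, h2 = _pseaa_scales()[0], _pseaa_scales()[1]
    v1 = np.array([h1[a] for a in s])
    v2 = np.array([h2[a] for a in s])
    taus: list[float] = []
    for d in range(1, lam + 1):
        taus.append(float((v1[: N - d] * v1[d:]).sum() / (N - d)))
        taus.append(float((v2[: N - d] * v2[d:]).sum() / (N - d)))
    f = encode_aac(s)
    denom = f.sum() + w * sum(taus)
    return np.concatenate([f / denom, w * np.array(taus) / denom])


# ---------------------------------------------------------------------------
# Structure encoders (F17, F18)
# ---------------------------------------------------------------------------

def encode_structure(p: Peptide | str, ann: StructureAnnotation, part: str) -> np.ndarray:
    """F17/F18: the 9 RASA values, or 9 concatenated H/E/C one-hot triples."""
    _seq(p)
    if part == "rasa":
        return np.array(ann.rasa, dtype=float)
    if part == "ss":
        v = np.zeros(27)
        for i, state in enumerate(ann.ss):
            v[i * 3 + SS_STATES.index(state)] = 1.0
        return v
    raise ValueError(f"part must be 'rasa' or 'ss', got {part!r}")


# ---------------------------------------------------------------------------
# Feature blocks
# ---------------------------------------------------------------------------

@dataclass
class FeatureBlock:
    """One encoder's matrix over a dataset (rows aligned with the dataset)."""

    spec: EncoderSpec
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature block matrix must be 2-D")
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"{self.spec.code}: non-finite entries in feature block")
        if self.spec.dimension is not None and self.matrix.shape[1] != self.spec.dimension:
            raise ValueError(
                f"{self.spec.code}: got {self.matrix.shape[1]} columns, "
                f"spec says {self.spec.dimension}"
            )


@dataclass
class FeatureContext:
    """Fitted/bundled context shared by the encoders.

    Holds the property tables, distance matrices, λ-independent encoder
    parameters, the structure annotator and, once fitted, the
    similarity reference (F5's training-fold sequences).
    """

    physchem_tables: tuple[PropertyTable, ...] | None = None
    autocorr_tables: tuple[PropertyTable, ...] | None = None
    qso_matrices: dict[str, np.ndarray] | None = None
    qso_weight: float = QSO_WEIGHT
    pseaa_weight: float = PSEAA_WEIGHT
    contact_potentials: np.ndarray | None = None
    qtms_table: np.ndarray | None = None
    annotator: object | None = field(default_factory=SurrogateAnnotator)
    similarity: SimilarityReference | None = None

    def with_similarity(self, train: PeptideDataset | Sequence[str]) -> "FeatureContext":
        return replace(self, similarity=SimilarityReference.fit(train))

    def annotation(self, sequence: str) -> StructureAnnotation:
        if self.annotator is None:
            raise ValidationError("no structure annotator configured")
        return self.annotator.annotate(sequence)


def encode_peptide(p: Peptide | str, spec: EncoderSpec, context: FeatureContext | None = None) -> np.ndarray:
    """Encode one peptide under ``spec`` using ``context``."""
    context = context or FeatureContext()
    s = _seq(p)
    i = spec.index
    if i == 1:
        return encode_physchem(s, context.physchem_tables)
    if i == 2:
        return encode_aac(s)
    if i == 3:
        return encode_dipeptide(s)
    if i == 4:
        return encode_sparse(s)
    if i == 5:
        if context.similarity is None:
            raise ValidationError("F5 requires a fitted similarity reference")
        return encode_similarity(s, context.similarity)
    if i == 6:
        return encode_aapp(s, context.contact_potentials)
    if i == 7:
        return encode_qtms(s, context.qtms_table)
    if i in (8, 9, 10):
        return encode_ctd(s, {8: "C", 9: "T", 10: "D"}[i])
    if i in (11, 12, 13):
        kind = {11: "moran", 12: "geary", 13: "moreau_broto"}[i]
        return encode_autocorrelation(s, kind, spec.lam, context.autocorr_tables)
    if i == 14:
        return encode_qso(s, spec.lam, context.qso_weight, context.qso_matrices)
    if i == 15:
        return encode_pseaa(s, spec.lam, context.pseaa_weight)
    if i == 16:
        return encode_ampseaa(s, spec.lam, context.pseaa_weight)
    if i in (17, 18):
        ann = context.annotation(s)
        return encode_structure(s, ann, "rasa" if i == 17 else "ss")
    raise ValueError(f"unknown encoder index {i}")


def build_feature_blocks(
    ds: PeptideDataset,
    specs: Sequence[EncoderSpec],
    context: FeatureContext | None = None,
) -> list[FeatureBlock]:
    """One :class:`FeatureBlock` per spec, rows aligned across blocks."""
    context = context or FeatureContext()
    blocks: list[FeatureBlock] = []
    for spec in specs:
        try:
            rows = [encode_peptide(p, spec, context) for p in ds]
            matrix = np.vstack(rows) if rows else np.empty((0, spec.dimension or 0))
            eff_spec = spec
            if spec.index == 5 and spec.dimension is None and context.similarity is not None:
                eff_spec = replace(spec, dimension=len(context.similarity))
            blocks.append(FeatureBlock(spec=eff_spec, matrix=matrix))
        except Exception as exc:
            raise type(exc)(f"{spec.code} ({spec.name}): {exc}") from exc
    return blocks
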