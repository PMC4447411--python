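"""Synthetic labelled 9-mer datasets with a known, controllable signal.

Three generating mechanisms are supported, each parameterised by a
non-negative effect size with the null (exchangeable classes) at 0:

* ``composition-bias`` — positive-class residues are drawn from a
  multinomial exponentially tilted on a designated residue subset:
  ``P(a) ∝ exp(effect)`` for subset members, uniform otherwise.
  Detectable by composition-style encoders.
* ``positional-motif`` — with probability ``effect`` a designated
  residue is planted at a fixed position in positives, and at a
  uniformly random *other* position in negatives.  Both classes then
  share the same expected residue composition, so the signal is visible
  to position-aware encoders (the sparse profile) but not to bag-of-
  residue compositions — a recoverable planted truth for the subset GA.
* ``property-shift`` — positive-class residues are drawn with
  ``P(a) ∝ exp(effect · z(a))`` where ``z`` is a standardized property
  scale; negatives are uniform.  Spreads signal over many
  physicochemistry-driven encoders.

Backgrounds are uniform over the 20 letters; duplicate sequences are
resampled so datasets satisfy the no-duplicates invariant.  Generation
is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peptides import ALPHABET, PEPTIDE_LENGTH, Peptide, PeptideDataset
from .tables import load_property_table

MECHANISMS = ("composition-bias", "positional-motif", "property-shift")


@dataclass(frozen=True)
class SignalSpec:
    """Recipe for one synthetic dataset."""

    n_pos: int
    n_neg: int
    mechanism: str = "composition-bias"
    effect_size: float = 1.0
    seed: int = 0
    #: residues favoured by composition-bias
    residue_subset: str = "ILVF"
    #: planted residue and (0-based) position for positional-motif
    motif_residue: str = "L"
    motif_position: int = 4
    #: scale driving property-shift
    property_table: str = "hydropathy_kd"
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class counts must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.motif_position < PEPTIDE_LENGTH:
            raise ValueError("motif_position must be in 0..8")


def _composition_probs(spec: SignalSpec) -> np.ndarray:
    w = np.ones(20)
    for a in spec.residue_subset:
        w[ALPHABET.index(a)] = np.exp(spec.effect_size)
    return w / w.sum()


def _property_probs(spec: SignalSpec) -> np.ndarray:
    z = load_property_table(spec.property_table).standardized().vector()
    w = np.exp(spec.effect_size * z)
    return w / w.sum()


def generate(spec: SignalSpec) -> PeptideDataset:
    """Draw a duplicate-free labelled dataset according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(ALPHABET))
    uniform = np.full(20, 1 / 20)

    def draw(label: int) -> str:
        if spec.mechanism == "composition-bias" and label == 1:
            probs = _composition_probs(spec)
        elif spec.mechanism == "property-shift" and label == 1:
            probs = _property_probs(spec)
        else:
            probs = uniform
        seq = list(rng.choice(letters, size=PEPTIDE_LENGTH, p=probs))
        if spec.mechanism == "positional-motif":
            # plant at the fixed position for positives, at a random
            # *other* position for negatives: expected compositions match
            # (one planted residue either way) but the position differs
            if rng.random() < spec.effect_size:
                if label == 1:
                    pos = spec.motif_position
                else:
                    pos = int(rng.integers(PEPTIDE_LENGTH - 1))
                    if pos >= spec.motif_position:
                        pos += 1
                seq[pos] = spec.motif_residue
        return "".join(seq)

    seen: set[str] = set()
    peptides: list[Peptide] = []
    for label, count in ((1, spec.n_pos), (0, spec.n_neg)):
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 1000 * count:
                raise RuntimeError("cannot draw enough unique sequences; space exhausted?")
            s = draw(label)
            if s in seen:
                continue
            seen.add(s)
            peptides.append(Peptide(s, label))
            made += 1
    return PeptideDataset(name=f"{spec.name}-{spec.mechanism}", peptides=peptides)
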