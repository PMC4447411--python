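"""Per-residue structure annotations (RASA and secondary structure).

Two encoders consume, for each 9-mer, a predicted relative accessible
surface area (RASA, a percentage in [0, 100] per residue) and a
three-state secondary-structure string over {H, E, C}.  Such
predictions normally come from an external structure predictor; this
module provides

* a parser for section-based prediction reports (the SABLE-style text
  layout documented below) and a simple TSV dialect, and
* :class:`SurrogateAnnotator`, a bundled deterministic per-letter
  surrogate so the whole pipeline runs closed-box.  The surrogate is
  explicitly *not* a structure predictor: it maps each residue type to
  a fixed RASA propensity (rescaled Chothia accessible surface areas)
  and to the argmax of its Chou–Fasman helix/sheet/turn propensities.

Accepted report grammar (one block per peptide)::

    >name            (optional header line)
    SEQUENCE         (literal section keyword, case-insensitive)
    ACDEFGHIK
    SECONDARY STRUCTURE
    CCHHHHECC
    RELATIVE SOLVENT ACCESSIBILITY
    12 34 56 78 90 11 22 33 44

TSV dialect: header ``sequence<TAB>ss<TAB>rasa`` with ``rasa`` a
comma-separated list of nine values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .peptides import ALPHABET, PEPTIDE_LENGTH, ValidationError
from .tables import load_property_table

SS_STATES = "HEC"


@dataclass(frozen=True)
class StructureAnnotation:
    """Nine RASA percentages and a nine-state H/E/C string for one peptide."""

    rasa: tuple[float, ...]
    ss: str

    def __post_init__(self) -> None:
        rasa = tuple(float(v) for v in self.rasa)
        object.__setattr__(self, "rasa", rasa)
        if len(rasa) != PEPTIDE_LENGTH:
            raise ValidationError(f"RASA needs {PEPTIDE_LENGTH} values, got {len(rasa)}")
        if any(not (0.0 <= v <= 100.0) for v in rasa):
            raise ValidationError("RASA values must lie in [0, 100]")
        if len(self.ss) != PEPTIDE_LENGTH or set(self.ss) - set(SS_STATES):
            raise ValidationError(f"SS must be 9 letters over {SS_STATES}, got {self.ss!r}")


class SurrogateAnnotator:
    """Deterministic per-letter RASA/SS propensities (not a predictor).

    RASA is the Chothia tripeptide accessible surface area rescaled to
    [0, 100] over the 20 residues; SS is H, E or C according to which of
    the Chou–Fasman helix/sheet/turn propensities is largest for the
    residue (ties broken in H > E > C order).
    """

    name = "surrogate"

    def __init__(self) -> None:
        asa = load_property_table("asa_chothia").vector()
        lo, hi = asa.min(), asa.max()
        rasa = 100.0 * (asa - lo) / (hi - lo)
        self._rasa = dict(zip(ALPHABET, rasa.tolist()))
        props = np.stack(
            [load_property_table(s).vector() for s in ("helix_cf", "sheet_cf", "turn_cf")]
        )
        self._ss = {a: SS_STATES[int(np.argmax(props[:, i]))] for i, a in enumerate(ALPHABET)}

    def annotate(self, sequence: str) -> StructureAnnotation:
        return StructureAnnotation(
            rasa=tuple(self._rasa[a] for a in sequence),
            ss="".join(self._ss[a] for a in sequence),
        )


class AnnotationStore:
    """Annotator backed by a mapping ``sequence -> StructureAnnotation``."""

    name = "store"

    def __init__(self, annotations: Mapping[str, StructureAnnotation]):
        self._ann = dict(annotations)

    def annotate(self, sequence: str) -> StructureAnnotation:
        try:
            return self._ann[sequence]
        except KeyError:
            raise ValidationError(f"no structure annotation for {sequence!r}") from None

    def __len__(self) -> int:
        return len(self._ann)


_SEQ_RE = re.compile(rf"^[{ALPHABET}]{{{PEPTIDE_LENGTH}}}$")
_SS_RE = re.compile(rf"^[{SS_STATES}]{{{PEPTIDE_LENGTH}}}$")


def parse_structure_report(text: str) -> dict[str, StructureAnnotation]:
    """Parse a section-based prediction report (grammar in module docstring)."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    out: dict[str, StructureAnnotation] = {}
    i = 0
    while i < len(lines):
        ln = lines[i].upper()
        if ln.startswith("SEQUENCE"):
            seq = lines[i + 1].upper()
            if not _SEQ_RE.match(seq):
                raise ValidationError(f"bad sequence line {lines[i + 1]!r}")
            j = i + 2
            ss = rasa = None
            while j < len(lines) and not lines[j].upper().startswith("SEQUENCE"):
                up = lines[j].upper()
                if up.startswith("SECONDARY"):
                    ss = lines[j + 1].upper()
                    j += 2
                elif up.startswith("RELATIVE") or up.startswith("RSA"):
                    rasa = [float(v) for v in re.split(r"[,\s]+", lines[j + 1]) if v]
                    j += 2
                else:
                    j += 1
            if ss is None or rasa is None:
                raise ValidationError(f"incomplete report block for {seq}")
            if not _SS_RE.match(ss):
                raise ValidationError(f"bad secondary-structure line {ss!r}")
            out[seq] = StructureAnnotation(rasa=tuple(rasa), ss=ss)
            i = j
        else:
            i += 1
    if not out:
        raise ValidationError("no annotation blocks found in report")
    return out


def load_annotations(path: str | Path) -> AnnotationStore:
    """Load structure annotations from a report file or the TSV dialect."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".tsv":
        ann: dict[str, StructureAnnotation] = {}
        for ln in text.splitlines()[1:]:
            if not ln.strip():
                continue
            seq, ss, rasa = ln.split("\t")
            ann[seq.upper()] = StructureAnnotation(
                rasa=tuple(float(v) for v in rasa.split(",")), ss=ss.upper()
            )
        if not ann:
            raise ValidationError(f"{path}: no annotations")
        return AnnotationStore(ann)
    return AnnotationStore(parse_structure_report(text))


def save_annotations(annotations: Mapping[str, StructureAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tss\trasa\n")
        for seq, ann in annotations.items():
            fh.write(f"{seq}\t{ann.ss}\t{','.join(repr(v) for v in ann.rasa)}\n")
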