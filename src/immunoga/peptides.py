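"""Peptide records, labelled datasets and their on-disk formats.

The unit of data is a 9-mer peptide over the 20 standard amino-acid
letters, optionally carrying a binary immunogenicity label (1 =
immunogenic epitope, 0 = non-immunogenic).  Datasets are ordered,
duplicate-free collections of such peptides.

Two text dialects are supported:

* ``tabular`` — CSV/TSV with a header row ``sequence,label``; the label
  column holds ``1``/``0`` and may be empty for unlabelled peptides.
* ``fasta-label`` — standard FASTA where the label is the last
  ``|``-separated token of the record header, e.g. ``>pep_3|1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, in alphabetical order.
#: This order fixes the indexing of every composition-style feature.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: MHC class I epitopes handled by this package are 9-mers.
PEPTIDE_LENGTH = 9

_NONSTANDARD = set("BJOUXZ")


class ValidationError(ValueError):
    """A record violates the peptide invariants (length/alphabet/label)."""


class DuplicateSequenceError(ValueError):
    """A dataset contains the same sequence more than once."""


class DatasetIOError(IOError):
    """A dataset file is unreadable or yields zero valid records."""


@dataclass(frozen=True)
class Peptide:
    """A validated 9-mer with an optional binary immunogenicity label."""

    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        seq = str(self.sequence).strip().upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != PEPTIDE_LENGTH:
            raise ValidationError(
                f"peptide {seq!r} has length {len(seq)}, expected {PEPTIDE_LENGTH}"
            )
        bad = sorted(set(seq) - set(ALPHABET))
        if bad:
            raise ValidationError(
                f"peptide {seq!r} contains non-standard residue(s) {''.join(bad)}"
            )
        if self.label is not None:
            lab = int(self.label)
            if lab not in (0, 1):
                raise ValidationError(f"label must be 0 or 1, got {self.label!r}")
            object.__setattr__(self, "label", lab)


@dataclass
class PeptideDataset:
    """An ordered, duplicate-free collection of labelled peptides."""

    name: str
    peptides: list[Peptide] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.peptides:
            if p.sequence in seen:
                raise DuplicateSequenceError(
                    f"duplicate sequence {p.sequence!r} in dataset {self.name!r}"
                )
            seen.add(p.sequence)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    @property
    def n_positive(self) -> int:
        return sum(1 for p in self.peptides if p.label == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for p in self.peptides if p.label == 0)

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def labels(self) -> np.ndarray:
        """Label vector; raises if any peptide is unlabelled."""
        labs = [p.label for p in self.peptides]
        if any(l is None for l in labs):
            raise ValidationError(f"dataset {self.name!r} contains unlabelled peptides")
        return np.asarray(labs, dtype=int)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "PeptideDataset":
        return PeptideDataset(
            name=name or f"{self.name}[subset]",
            peptides=[self.peptides[i] for i in indices],
        )


def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fa", ".fasta", ".fna", ".faa"):
        return "fasta-label"
    if suffix in (".csv", ".tsv", ".txt"):
        return "tabular"
    raise DatasetIOError(
        f"cannot auto-detect dialect from extension {suffix!r}; pass dialect="
    )


def _records_from_fasta(path: Path) -> Iterator[tuple[str, str | None]]:
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split("|")
        label = tokens[-1].strip() if len(tokens) > 1 else None
        yield str(rec.seq), label


def _records_from_tabular(path: Path) -> Iterator[tuple[str, str | None]]:
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    if "sequence" not in cols:
        raise DatasetIOError(f"{path}: missing required 'sequence' column")
    df.columns = cols
    for _, row in df.iterrows():
        label = row.get("label", "")
        yield row["sequence"], (label if str(label).strip() != "" else None)


def load_dataset(
    path: str | Path,
    dialect: str | None = None,
    *,
    skip_invalid: bool = False,
    dedupe: bool = False,
    name: str | None = None,
) -> PeptideDataset:
    """Read a labelled peptide dataset from ``path``.

    Parameters
    ----------
    dialect
        ``"fasta-label"`` or ``"tabular"``; auto-detected from the file
        extension when omitted.
    skip_invalid
        Drop records failing the peptide invariants with a logged
        warning instead of raising.
    dedupe
        Keep the first occurrence of a repeated sequence instead of
        raising :class:`DuplicateSequenceError`.
    """
    path = Path(path)
    if not path.is_file():
        raise DatasetIOError(f"no such dataset file: {path}")
    dialect = dialect or _detect_dialect(path)
    if dialect == "fasta-label":
        records = _records_from_fasta(path)
    elif dialect == "tabular":
        records = _records_from_tabular(path)
    else:
        raise DatasetIOError(f"unknown dialect {dialect!r}")

    peptides: list[Peptide] = []
    seen: set[str] = set()
    for i, (seq, label) in enumerate(records):
        try:
            lab: int | None
            if label is None:
                lab = None
            else:
                lab = {"1": 1, "0": 0, "positive": 1, "negative": 0}.get(
                    str(label).strip().lower()
                )
                if lab is None:
                    raise ValidationError(f"unrecognised label {label!r}")
            pep = Peptide(seq, lab)
        except ValidationError as exc:
            if skip_invalid:
                logger.warning("skipping record %d of %s: %s", i, path.name, exc)
                continue
            raise ValidationError(f"{path.name}, record {i}: {exc}") from exc
        if pep.sequence in seen:
            if dedupe:
                logger.warning(
                    "dropping duplicate sequence %s (record %d of %s)",
                    pep.sequence, i, path.name,
                )
                continue
            raise DuplicateSequenceError(
                f"{path.name}: duplicate sequence {pep.sequence!r} (use dedupe=True)"
            )
        seen.add(pep.sequence)
        peptides.append(pep)

    if not peptides:
        raise DatasetIOError(f"{path}: zero valid records")
    return PeptideDataset(name=name or path.stem, peptides=peptides)


def save_dataset(ds: PeptideDataset, path: str | Path, dialect: str | None = None) -> None:
    """Write ``ds`` to ``path`` in the given (or extension-detected) dialect."""
    path = Path(path)
    dialect = dialect or _detect_dialect(path)
    if dialect == "tabular":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.DataFrame(
            {
                "sequence": ds.sequences(),
                "label": ["" if p.label is None else p.label for p in ds],
            }
        )
        df.to_csv(path, sep=sep, index=False)
    elif dialect == "fasta-label":
        records = [
            SeqRecord(
                Seq(p.sequence),
                id=f"{ds.name}_{i}",
                description=f"{ds.name}_{i}|{'' if p.label is None else p.label}",
            )
            for i, p in enumerate(ds)
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        raise DatasetIOError(f"unknown dialect {dialect!r}")
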