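"""Bundled per-residue property tables, group partitions and distance matrices.

All numeric lookup data used by the feature encoders ships with the
package as plain-text files under ``immunoga/data`` so that no network
access is ever required:

* ``aa_scales.tsv`` — published per-residue physicochemical scales
  (hydropathy, hydrophilicity, masses, Grantham polarity/volume, …).
* ``contact_potentials_synthetic.tsv`` — a *synthetic* reconstruction of
  the 40 pairwise-contact-potential scales used by the AAPP encoder.
* ``qtms_descriptors_synthetic.tsv`` — a *synthetic* reconstruction of
  the 21 per-residue QTMS descriptors.

The original feature set this package re-implements was built from 11
AAindex accessions whose numeric content is not redistributed here; the
accessions are accepted as aliases resolving to the bundled stand-in
scales (see :data:`AAINDEX_ALIASES`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .peptides import ALPHABET

_N = len(ALPHABET)


class TableError(KeyError):
    """Unknown table id or malformed/incomplete table."""


@dataclass(frozen=True)
class PropertyTable:
    """A 20-entry map from amino-acid letter to a real property value."""

    table_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = sorted(set(ALPHABET) - set(self.values))
        extra = sorted(set(self.values) - set(ALPHABET))
        if missing or extra:
            raise TableError(
                f"table {self.table_id!r}: missing letters {missing}, extra {extra}"
            )

    def vector(self) -> np.ndarray:
        """Values in alphabetical residue order."""
        return np.array([self.values[a] for a in ALPHABET], dtype=float)

    def standardized(self) -> "PropertyTable":
        """Zero-mean, unit-variance version over the 20 letters (population std)."""
        v = self.vector()
        sd = v.std()  # ddof=0 over the 20 letters
        if sd == 0:
            raise TableError(f"table {self.table_id!r} has zero variance")
        z = (v - v.mean()) / sd
        return PropertyTable(
            self.table_id + ":z", dict(zip(ALPHABET, z.tolist()))
        )

    def __getitem__(self, letter: str) -> float:
        return self.values[letter]


def _data_path(name: str):
    return resources.files("immunoga").joinpath("data", name)


def _read_tsv(name: str) -> list[list[str]]:
    text = _data_path(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.rstrip("\n").split("\t"))
    return rows


@lru_cache(maxsize=1)
def _scales() -> dict[str, PropertyTable]:
    rows = _read_tsv("aa_scales.tsv")
    header = rows[0]
    letters = header[1:]
    out: dict[str, PropertyTable] = {}
    for row in rows[1:]:
        sid = row[0]
        out[sid] = PropertyTable(sid, {a: float(v) for a, v in zip(letters, row[1:])})
    return out


#: Accessions named by the original feature set, resolved to bundled
#: stand-in scales (documented reconstructions, not AAindex data).
AAINDEX_ALIASES: dict[str, str] = {
    "MEEJ800102": "hydropathy_kd",
    "WOLS870102": "hydrophilicity_hw",
    "CASG920101": "side_chain_mass",
    "NAKH900110": "polarity_grantham",
    "FASG760105": "volume_grantham",
    "FAUJ880105": "composition_grantham",
    "CHAM830107": "charge_ph7",
    "QIAN880127": "isoelectric_point",
    "RACS820108": "asa_chothia",
    "DIGM050101": "helix_cf",
    "TANS770109": "sheet_cf",
}

#: The 11 scales behind the position-wise physicochemical encoder (F1).
PHYSCHEM_PROPENSITY_TABLES: tuple[str, ...] = tuple(AAINDEX_ALIASES.values())

#: The 8 property scales used by the three autocorrelation encoders.
AUTOCORRELATION_TABLES: tuple[str, ...] = (
    "hydropathy_kd",
    "hydrophilicity_hw",
    "side_chain_mass",
    "polarity_grantham",
    "volume_grantham",
    "isoelectric_point",
    "asa_chothia",
    "helix_cf",
)

#: Hydrophobicity / hydrophilicity / side-chain-mass triplet of the
#: pseudo amino-acid composition encoders.
PSEAA_TABLES: tuple[str, ...] = ("hydropathy_kd", "hydrophilicity_hw", "side_chain_mass")


def available_tables() -> list[str]:
    return sorted(_scales()) + sorted(AAINDEX_ALIASES)


def load_property_table(table_id: str) -> PropertyTable:
    """Return a bundled 20-letter property table by id or accession alias."""
    scales = _scales()
    sid = AAINDEX_ALIASES.get(table_id, table_id)
    if sid not in scales:
        raise TableError(f"unknown property table {table_id!r}")
    table = scales[sid]
    if sid != table_id:  # keep the requested id on the returned object
        table = PropertyTable(table_id, dict(table.values))
    return table


def save_property_table(table: PropertyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("letter\tvalue\n")
        for a in ALPHABET:
            fh.write(f"{a}\t{table.values[a]!r}\n")


def load_property_table_file(path: str | Path, table_id: str | None = None) -> PropertyTable:
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        a, v = line.split("\t")
        values[a] = float(v)
    return PropertyTable(table_id or Path(path).stem, values)


# ---------------------------------------------------------------------------
# CTD attribute partitions
# ---------------------------------------------------------------------------

#: The 7 conventional CTD attributes, each partitioning the alphabet
#: into three groups (order of attributes fixes the encoder layout).
CTD_ATTRIBUTES: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("hydrophobicity", ("RKEDQN", "GASTPHY", "CLVIMFW")),
    ("normalized_vdw_volume", ("GASCTPD", "NVEQIL", "MHKFRYW")),
    ("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    ("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    ("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    ("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    ("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MSPTHY")),
)

for _name, _groups in CTD_ATTRIBUTES:
    assert sorted("".join(_groups)) == sorted(ALPHABET), _name


# ---------------------------------------------------------------------------
# 20x20 residue distance matrices (quasi-sequence-order encoder)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def grantham_distance_matrix() -> np.ndarray:
    """Grantham's chemical distance, computed from his published formula.

    ``D(a,b) = rho * sqrt(alpha*dc^2 + beta*dp^2 + gamma*dv^2)`` with
    composition ``c``, polarity ``p`` and volume ``v``; ``rho`` scales the
    mean inter-residue distance to ~100.
    """
    c = _scales()["composition_grantham"].vector()
    p = _scales()["polarity_grantham"].vector()
    v = _scales()["volume_grantham"].vector()
    alpha, beta, gamma, rho = 1.833, 0.1018, 0.000399, 50.723
    d = np.sqrt(
        alpha * (c[:, None] - c[None, :]) ** 2
        + beta * (p[:, None] - p[None, :]) ** 2
        + gamma * (v[:, None] - v[None, :]) ** 2
    )
    return rho * d


@lru_cache(maxsize=1)
def physchem_distance_matrix() -> np.ndarray:
    """Synthetic physicochemical distance: Euclidean distance between
    residues in the z-scored (hydropathy, polarity, volume) space.

    This is a documented stand-in for a second published residue distance
    matrix; it is symmetric, non-negative and zero on the diagonal.
    """
    feats = np.stack(
        [
            _scales()[s].standardized().vector()
            for s in ("hydropathy_kd", "polarity_grantham", "volume_grantham")
        ],
        axis=1,
    )
    diff = feats[:, None, :] - feats[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def qso_distance_matrices() -> dict[str, np.ndarray]:
    """The two residue-pair distance matrices used by the QSO encoder."""
    return {
        "grantham": grantham_distance_matrix(),
        "physchem_synthetic": physchem_distance_matrix(),
    }


# ---------------------------------------------------------------------------
# AAPP contact potentials and QTMS descriptor tables (synthetic stand-ins)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def load_contact_potentials() -> np.ndarray:
    """40 per-residue contact-potential scales as a (40, 20) array.

    Bundled values are a seeded synthetic reconstruction (see the data
    file header); supply a real table via ``FeatureContext`` to use
    published potentials.
    """
    rows = _read_tsv("contact_potentials_synthetic.tsv")
    letters = rows[0][1:]
    order = [letters.index(a) for a in ALPHABET]
    mat = np.array([[float(v) for v in row[1:]] for row in rows[1:]], dtype=float)
    mat = mat[:, order]
    if mat.shape != (40, _N):
        raise TableError(f"contact-potential table has shape {mat.shape}, want (40, 20)")
    return mat


@lru_cache(maxsize=1)
def load_qtms_table() -> np.ndarray:
    """Per-residue QTMS descriptors as a (20, 21) array (synthetic stand-in)."""
    rows = _read_tsv("qtms_descriptors_synthetic.tsv")
    data = {row[0]: [float(v) for v in row[1:]] for row in rows[1:]}
    mat = np.array([data[a] for a in ALPHABET], dtype=float)
    if mat.shape != (_N, 21):
        raise TableError(f"QTMS table has shape {mat.shape}, want (20, 21)")
    return mat
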