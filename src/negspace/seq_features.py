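"""Classical sequence-based feature blocks for single amino-acid sequences.

Six descriptor families are computed from the primary sequence alone:

* AAC — amino-acid composition (20 dims),
* DPC — dipeptide composition (400 dims),
* ATC — atomic composition: fractions of C/H/N/O/S atoms over the chain (5 dims),
* PGC — property-group composition: fraction of residues in each named
  physicochemical group (11 dims by default),
* P2G — physicochemical 2-grams: fraction of adjacent residue pairs falling
  jointly inside each group (11 dims by default),
* PCP — physicochemical properties: per-scale mean over the sequence
  (7 dims by default).

Residue order is fixed alphabetically by one-letter code (ACDEFGHIKLMNPQRSTVWY)
throughout the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Ambiguity-code substitutions used by the ``map_to_nearest`` policy.
NEAREST_MAP = {"B": "N", "Z": "Q", "U": "C", "J": "L", "O": "K"}

ATOMS: str = "CHNOS"

# Peptide-bonded residue formulas: free amino acid minus one water.
# Counts are (C, H, N, O, S).
RESIDUE_ATOM_COUNTS: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 5, 1, 1, 0),
    "C": (3, 5, 1, 1, 1),
    "D": (4, 5, 1, 3, 0),
    "E": (5, 7, 1, 3, 0),
    "F": (9, 9, 1, 1, 0),
    "G": (2, 3, 1, 1, 0),
    "H": (6, 7, 3, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "K": (6, 12, 2, 1, 0),
    "L": (6, 11, 1, 1, 0),
    "M": (5, 9, 1, 1, 1),
    "N": (4, 6, 2, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "Q": (5, 8, 2, 2, 0),
    "R": (6, 12, 4, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "T": (4, 7, 1, 2, 0),
    "V": (5, 9, 1, 1, 0),
    "W": (11, 10, 2, 1, 0),
    "Y": (9, 9, 1, 2, 0),
}

# Default 11-group residue classification (overlapping groups are allowed).
DEFAULT_GROUPS: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ACFILMVW"),
    "hydrophilic": frozenset("DEHKNQRST"),
    "aromatic": frozenset("FHWY"),
    "aliphatic": frozenset("AILV"),
    "positively_charged": frozenset("HKR"),
    "negatively_charged": frozenset("DE"),
    "polar_uncharged": frozenset("CNQSTY"),
    "small": frozenset("ACDGNPSTV"),
    "tiny": frozenset("ACGS"),
    "sulfur_containing": frozenset("CM"),
    "amide": frozenset("NQ"),
}

# Default per-residue numeric scales for PCP.
DEFAULT_SCALES: dict[str, dict[str, float]] = {
    # Kyte-Doolittle hydropathy
    "hydrophobicity": {
        "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
        "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
        "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
        "W": -0.9, "Y": -1.3,
    },
    # Hopp-Woods hydrophilicity
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
        "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
        "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
        "W": -3.4, "Y": -2.3,
    },
    # Grantham polarity
    "polarity": {
        "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0,
        "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6,
        "P": 8.0, "Q": 10.5, "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9,
        "W": 5.4, "Y": 6.2,
    },
    # Charton-Charton polarizability
    "polarizability": {
        "A": 0.046, "C": 0.128, "D": 0.105, "E": 0.151, "F": 0.290,
        "G": 0.000, "H": 0.230, "I": 0.186, "K": 0.219, "L": 0.186,
        "M": 0.221, "N": 0.134, "P": 0.131, "Q": 0.180, "R": 0.291,
        "S": 0.062, "T": 0.108, "V": 0.140, "W": 0.409, "Y": 0.298,
    },
    # Formal side-chain charge at physiological pH
    "net_charge": {
        "A": 0.0, "C": 0.0, "D": -1.0, "E": -1.0, "F": 0.0, "G": 0.0,
        "H": 0.1, "I": 0.0, "K": 1.0, "L": 0.0, "M": 0.0, "N": 0.0,
        "P": 0.0, "Q": 0.0, "R": 1.0, "S": 0.0, "T": 0.0, "V": 0.0,
        "W": 0.0, "Y": 0.0,
    },
    # Average residue mass (Da, peptide-bonded)
    "molecular_mass": {
        "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
        "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
        "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
        "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
    },
    # Isoelectric point of the free amino acid
    "isoelectric_point": {
        "A": 6.00, "C": 5.07, "D": 2.77, "E": 3.22, "F": 5.48, "G": 5.97,
        "H": 7.59, "I": 6.02, "K": 9.74, "L": 5.98, "M": 5.74, "N": 5.41,
        "P": 6.30, "Q": 5.65, "R": 10.76, "S": 5.68, "T": 5.60, "V": 5.96,
        "W": 5.89, "Y": 5.66,
    },
}


class Role(str, enum.Enum):
    CYTOKINE = "cytokine"
    RECEPTOR = "receptor"


class Scheme(str, enum.Enum):
    AAC = "AAC"
    DPC = "DPC"
    PGC = "PGC"
    P2G = "P2G"
    ATC = "ATC"
    PCP = "PCP"
    AAC_PSSM = "AAC_PSSM"
    D_FPSSM = "D_FPSSM"
    COMBINED56 = "COMBINED56"


class SanitizePolicy(str, enum.Enum):
    DROP = "drop"
    MAP_TO_NEAREST = "map_to_nearest"
    ERROR = "error"


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with a cytokine/receptor role."""

    id: str
    role: Role
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} < 2"
            )
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical residues {sorted(bad)}; "
                "sanitize_sequence first"
            )


@dataclass(frozen=True)
class FeatureBlock:
    """An ordered, named vector of real-valued features under one scheme."""

    scheme: Scheme
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ValueError("names and values must align 1:1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ResiduePropertyTable:
    """Residue groupings, atom counts and numeric scales backing PGC/P2G/ATC/PCP.

    ``groups`` is an ordered mapping of group name -> residue subset (11 groups
    required for P2G); ``atom_counts`` maps each canonical residue to its
    (C, H, N, O, S) counts in peptide-bonded form; ``scales`` maps scale name
    -> per-residue value.
    """

    groups: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    atom_counts: dict[str, tuple[int, int, int, int, int]] = field(
        default_factory=lambda: dict(RESIDUE_ATOM_COUNTS)
    )
    scales: dict[str, dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALES)
    )

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name!r} is empty")
            if not members <= _ALPHABET_SET:
                raise ValueError(f"group {name!r} has non-canonical residues")


DEFAULT_TABLE = ResiduePropertyTable()


def sanitize_sequence(
    raw: str, policy: SanitizePolicy | str = SanitizePolicy.DROP
) -> str:
    """Uppercase ``raw`` and resolve non-canonical letters per ``policy``.

    ``drop`` removes X/B/Z/U/J/O (and anything else non-canonical);
    ``map_to_nearest`` substitutes B->N, Z->Q, U->C, J->L, O->K and drops X;
    ``error`` raises on the first non-canonical letter.
    """
    policy = SanitizePolicy(policy)
    if not raw:
        raise ValueError("empty input sequence")
    out: list[str] = []
    for ch in raw.upper():
        if ch in _ALPHABET_SET:
            out.append(ch)
        elif policy is SanitizePolicy.ERROR:
            raise ValueError(f"non-canonical residue {ch!r}")
        elif policy is SanitizePolicy.MAP_TO_NEAREST and ch in NEAREST_MAP:
            out.append(NEAREST_MAP[ch])
        # drop: skip silently (also drops X under map_to_nearest)
    if not out:
        raise ValueError("unusable sequence: empty after sanitization")
    return "".join(out)


def _check_seq(seq: str, min_len: int = 1) -> None:
    if len(seq) < min_len:
        raise ValueError(f"sequence length {len(seq)} < {min_len}")
    bad = set(seq) - _ALPHABET_SET
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)}")


def compute_aac(seq: str) -> FeatureBlock:
    """Amino-acid composition: residue frequencies in alphabetical order."""
    _check_seq(seq)
    counts = np.zeros(20)
    for ch in seq:
        counts[_RESIDUE_INDEX[ch]] += 1
    return FeatureBlock(
        Scheme.AAC,
        tuple(f"AAC_{aa}" for aa in ALPHABET),
        counts / len(seq),
    )


def compute_dpc(seq: str) -> FeatureBlock:
    """Dipeptide composition: adjacent-pair frequencies, row-major over the alphabet."""
    _check_seq(seq, min_len=2)
    counts = np.zeros((20, 20))
    for a, b in zip(seq, seq[1:]):
        counts[_RESIDUE_INDEX[a], _RESIDUE_INDEX[b]] += 1
    names = tuple(f"DPC_{a}{b}" for a in ALPHABET for b in ALPHABET)
    return FeatureBlock(Scheme.DPC, names, counts.ravel() / (len(seq) - 1))


def compute_atc(
    seq: str, table: ResiduePropertyTable = DEFAULT_TABLE
) -> FeatureBlock:
    """Atomic composition: C/H/N/O/S atom fractions over the peptide chain.

    Residues contribute their peptide-bonded formula (free amino acid minus
    one water); the terminal water is ignored, a choice whose effect vanishes
    with chain length.
    """
    _check_seq(seq)
    totals = np.zeros(5)
    for ch in seq:
        try:
            totals += table.atom_counts[ch]
        except KeyError:
            raise KeyError(f"residue {ch!r} missing from atom-count table")
    return FeatureBlock(
        Scheme.ATC,
        tuple(f"ATC_{a}" for a in ATOMS),
        totals / totals.sum(),
    )


def compute_pgc(
    seq: str, table: ResiduePropertyTable = DEFAULT_TABLE
) -> FeatureBlock:
    """Property-group composition: fraction of residues in each named group.

    Groups may overlap, so the values need not sum to 1.
    """
    _check_seq(seq)
    L = len(seq)
    values = [
        sum(1 for ch in seq if ch in members) / L
        for members in table.groups.values()
    ]
    return FeatureBlock(
        Scheme.PGC,
        tuple(f"PGC_{g}" for g in table.groups),
        np.array(values),
    )


def compute_p2g(
    seq: str, table: ResiduePropertyTable = DEFAULT_TABLE
) -> FeatureBlock:
    """Physicochemical 2-grams: per group, the fraction of adjacent residue
    pairs with both members in the group. Requires exactly 11 groups."""
    _check_seq(seq, min_len=2)
    if len(table.groups) != 11:
        raise ValueError(
            f"P2G requires exactly 11 groups, got {len(table.groups)}"
        )
    npairs = len(seq) - 1
    values = [
        sum(1 for a, b in zip(seq, seq[1:]) if a in members and b in members)
        / npairs
        for members in table.groups.values()
    ]
    return FeatureBlock(
        Scheme.P2G,
        tuple(f"P2G_{g}" for g in table.groups),
        np.array(values),
    )


def compute_pcp(
    seq: str, table: ResiduePropertyTable = DEFAULT_TABLE
) -> FeatureBlock:
    """Physicochemical properties: mean of each configured scale over the sequence."""
    _check_seq(seq)
    if not table.scales:
        raise ValueError("PCP requires at least one configured scale")
    values = []
    for name, scale in table.scales.items():
        try:
            values.append(sum(scale[ch] for ch in seq) / len(seq))
        except KeyError as exc:
            raise KeyError(f"scale {name!r} missing residue {exc.args[0]!r}")
    return FeatureBlock(
        Scheme.PCP,
        tuple(f"PCP_{s}" for s in table.scales),
        np.array(values),
    )
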