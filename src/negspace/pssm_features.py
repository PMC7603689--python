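"""PSI-BLAST ASCII PSSM parsing and the two evolutionary feature blocks.

Two descriptors are derived from a position-specific scoring matrix:

* AAC_PSSM — per-residue-column mean of the log-odds scores (20 dims),
* D-FPSSM  — column sums of the non-negatively clamped ("filtered") matrix,
  length-normalized by default (20 dims).

Only the log-odds block of the PSI-BLAST file is consumed; the weighted
percentage block is ignored. Columns are reordered from PSI-BLAST order
(ARNDCQEGHILKMFPSTWYV) to the package-wide alphabetical order at parse time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seq_features import (
    ALPHABET,
    DEFAULT_TABLE,
    FeatureBlock,
    ResiduePropertyTable,
    Scheme,
    compute_atc,
    compute_p2g,
    sanitize_sequence,
)

#: Residue column order used by PSI-BLAST ``-out_ascii_pssm`` output.
PSIBLAST_ORDER: str = "ARNDCQEGHILKMFPSTWYV"
_TO_ALPHABETICAL = [PSIBLAST_ORDER.index(aa) for aa in ALPHABET]
_TO_PSIBLAST = [ALPHABET.index(aa) for aa in PSIBLAST_ORDER]


class DFPSSMNorm(str, enum.Enum):
    LENGTH = "length"
    MAX = "max"
    NONE = "none"


@dataclass(frozen=True)
class PSSMatrix:
    """An L x 20 log-odds matrix aligned to a protein sequence.

    Columns follow the alphabetical residue order (ACDEFGHIKLMNPQRSTVWY).
    """

    protein_id: str
    residues: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape != (len(self.residues), 20):
            raise ValueError(
                f"{self.protein_id}: scores must be {len(self.residues)}x20, "
                f"got {scores.shape}"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"{self.protein_id}: non-finite PSSM entries")

    def __len__(self) -> int:
        return len(self.residues)


class PSSMParseError(ValueError):
    pass


def parse_pssm(path: str | Path, protein_id: str | None = None) -> PSSMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a :class:`PSSMatrix`.

    Data rows carry a position index, the query residue, 20 log-odds columns
    and (usually) 20 weighted-percentage columns plus two trailing statistics;
    only the log-odds block is kept.
    """
    path = Path(path)
    residues: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens or not tokens[0].isdigit():
            continue  # header, column-label or footer line
        if len(tokens) < 2 or len(tokens[1]) != 1 or not tokens[1].isalpha():
            continue
        body = tokens[2:]
        if len(body) not in (20, 40, 42):
            raise PSSMParseError(
                f"{path}:{lineno}: expected 20, 40 or 42 numeric columns, "
                f"got {len(body)}"
            )
        try:
            scores = [float(tok) for tok in body[:20]]
        except ValueError as exc:
            raise PSSMParseError(f"{path}:{lineno}: non-numeric score ({exc})")
        residues.append(tokens[1].upper())
        rows.append(scores)
    if not rows:
        raise PSSMParseError(f"{path}: no PSSM data rows found")
    scores = np.array(rows)[:, _TO_ALPHABETICAL]
    return PSSMatrix(protein_id or path.stem, "".join(residues), scores)


def write_pssm(pssm: PSSMatrix, path: str | Path) -> None:
    """Write a PSSMatrix in PSI-BLAST ASCII layout (log-odds block only).

    Exists to produce test fixtures and mock PSSMs; the percentage block is
    filled with zeros.
    """
    path = Path(path)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted "
        "observed percentages rounded down, information per position, "
        "and relative weight of gapless real matches to pseudocounts",
        "            " + "  ".join(PSIBLAST_ORDER) + "   "
        + "   ".join(PSIBLAST_ORDER),
    ]
    psiblast_scores = pssm.scores[:, _TO_PSIBLAST]
    for i, (aa, row) in enumerate(zip(pssm.residues, psiblast_scores), 1):
        cells = "".join(f"{v:7g}" for v in row)
        pct = "".join(f"{0:4d}" for _ in range(20))
        lines.append(f"{i:5d} {aa} {cells} {pct}  0.00 0.00")
    lines.append("")
    path.write_text("\n".join(lines))


def aac_pssm(pssm: PSSMatrix) -> FeatureBlock:
    """Column means of the log-odds matrix (20 dims)."""
    return FeatureBlock(
        Scheme.AAC_PSSM,
        tuple(f"AAC_PSSM_{aa}" for aa in ALPHABET),
        pssm.scores.mean(axis=0),
    )


def d_fpssm(
    pssm: PSSMatrix, normalization: DFPSSMNorm | str = DFPSSMNorm.LENGTH
) -> FeatureBlock:
    """Column sums of the clamped-at-zero (filtered) PSSM, normalized.

    ``length`` divides by L (default), ``max`` by the largest column sum
    (0 if all columns vanish), ``none`` returns plain sums. All outputs
    are non-negative.
    """
    normalization = DFPSSMNorm(normalization)
    sums = np.maximum(pssm.scores, 0.0).sum(axis=0)
    if normalization is DFPSSMNorm.LENGTH:
        values = sums / len(pssm)
    elif normalization is DFPSSMNorm.MAX:
        top = sums.max()
        values = sums / top if top > 0 else sums
    else:
        values = sums
    return FeatureBlock(
        Scheme.D_FPSSM,
        tuple(f"D_FPSSM_{aa}" for aa in ALPHABET),
        values,
    )


def combined56(
    seq: str,
    pssm: PSSMatrix,
    table: ResiduePropertyTable = DEFAULT_TABLE,
    normalization: DFPSSMNorm | str = DFPSSMNorm.LENGTH,
) -> FeatureBlock:
    """The 56-dim per-protein block: ATC (5) | P2G (11) | AAC_PSSM (20) | D-FPSSM (20)."""
    clean = sanitize_sequence(seq)
    if clean != pssm.residues.upper():
        raise ValueError(
            f"{pssm.protein_id}: sequence does not match PSSM residues"
        )
    blocks = [
        compute_atc(clean, table),
        compute_p2g(clean, table),
        aac_pssm(pssm),
        d_fpssm(pssm, normalization),
    ]
    names = tuple(n for b in blocks for n in b.names)
    values = np.concatenate([b.values for b in blocks])
    assert len(values) == 56
    return FeatureBlock(Scheme.COMBINED56, names, values)
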