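"""Closed-world pair enumeration, pair-vector assembly and dataset I/O.

Under the closed-world assumption every cytokine-receptor combination not in
the known-interaction list is a candidate negative. With 123 cytokines and
102 receptors there are 12,546 combinations; removing the 203 known positives
leaves a 12,343-pair negative pool.

Pair vectors concatenate the cytokine block first, then the receptor block
(112 dims for the 56-dim combined per-protein features). Datasets round-trip
through a minimal ARFF dialect (numeric attributes plus one trailing nominal
``class`` attribute with values interacting / non_interacting) and CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .seq_features import (
    FeatureBlock,
    ProteinRecord,
    Role,
    SanitizePolicy,
    sanitize_sequence,
)

POSITIVE_LABEL = "interacting"
NEGATIVE_LABEL = "non_interacting"
LABELS = (POSITIVE_LABEL, NEGATIVE_LABEL)


@dataclass(frozen=True)
class PairTable:
    """Labeled cytokine-receptor pairs with row-aligned feature vectors."""

    pairs: tuple[tuple[str, str], ...]
    labels: tuple[str, ...]
    vectors: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vectors)
        n = len(self.pairs)
        if len(self.labels) != n or vectors.shape != (n, len(self.feature_names)):
            raise ValueError("pairs, labels and vectors must align")
        if len(set(self.pairs)) != n:
            raise ValueError("duplicate (cytokine, receptor) pair")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, indices) -> "PairTable":
        idx = list(indices)
        return PairTable(
            tuple(self.pairs[i] for i in idx),
            tuple(self.labels[i] for i in idx),
            self.vectors[idx],
            self.feature_names,
        )


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column min and max observed on the fitting table."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)
        if np.any(maxs < mins):
            raise ValueError("max < min for some column")


def read_fasta(path: str | Path, role: Role | str,
               policy: SanitizePolicy | str = SanitizePolicy.DROP
               ) -> list[ProteinRecord]:
    """Read a protein roster from FASTA, assigning every record one role."""
    role = Role(role)
    records = [
        ProteinRecord(rec.id, role, sanitize_sequence(str(rec.seq), policy))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def read_positive_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read known interacting pairs from two-column delimited text."""
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        pairs.append((fields[0], fields[1]))
    return pairs


def enumerate_negative_pool(
    cytokines: list[str],
    receptors: list[str],
    positives: list[tuple[str, str]],
) -> list[tuple[str, str]]:
    """All (cytokine, receptor) combinations not in ``positives``, in
    lexicographic order — the closed-world candidate-negative pool."""
    cyt_set, rec_set = set(cytokines), set(receptors)
    pos_set = set(positives)
    if len(pos_set) != len(positives):
        raise ValueError("duplicate positive pair")
    for c, r in pos_set:
        if c not in cyt_set or r not in rec_set:
            raise ValueError(f"positive pair ({c}, {r}) references unknown ID")
    return [
        (c, r)
        for c in sorted(cyt_set)
        for r in sorted(rec_set)
        if (c, r) not in pos_set
    ]


def assemble_pair_vector(
    cyt_block: FeatureBlock, rec_block: FeatureBlock
) -> np.ndarray:
    """Concatenate cytokine-first: width = 2 x per-protein block width."""
    if cyt_block.scheme is not rec_block.scheme:
        raise ValueError(
            f"scheme mismatch: {cyt_block.scheme} vs {rec_block.scheme}"
        )
    return np.concatenate([cyt_block.values, rec_block.values])


def pair_feature_names(block: FeatureBlock) -> tuple[str, ...]:
    return tuple(f"cyt_{n}" for n in block.names) + tuple(
        f"rec_{n}" for n in block.names
    )


def build_pair_table(
    pairs: list[tuple[str, str]],
    labels: list[str],
    blocks: dict[str, FeatureBlock],
) -> PairTable:
    """Assemble a PairTable from per-protein feature blocks keyed by ID."""
    vectors = np.stack(
        [assemble_pair_vector(blocks[c], blocks[r]) for c, r in pairs]
    )
    names = pair_feature_names(blocks[pairs[0][0]])
    return PairTable(tuple(pairs), tuple(labels), vectors, names)


def fit_minmax(table: PairTable) -> NormalizationParams:
    if len(table) == 0:
        raise ValueError("cannot fit normalization on an empty table")
    return NormalizationParams(
        table.vectors.min(axis=0), table.vectors.max(axis=0)
    )


def apply_minmax(table: PairTable, params: NormalizationParams) -> PairTable:
    """Map each column by (x - min) / (max - min); constant columns map to 0.

    Applying params fitted on one table to another may yield values outside
    [0, 1]; callers wanting a guaranteed unit range must fit on the same table.
    """
    span = params.maxs - params.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (table.vectors - params.mins) / safe
    scaled[:, span == 0] = 0.0
    return replace(table, vectors=scaled)


# --- ARFF I/O (numeric attributes + one trailing nominal class) -------------

def write_arff(table: PairTable, path: str | Path,
               relation: str = "cri") -> None:
    lines = [f"@relation {relation}", ""]
    lines.append("@attribute cytokine_id string")
    lines.append("@attribute receptor_id string")
    for name in table.feature_names:
        lines.append(f"@attribute {name} numeric")
    lines.append(
        f"@attribute class {{{POSITIVE_LABEL},{NEGATIVE_LABEL}}}"
    )
    lines.append("")
    lines.append("@data")
    for (c, r), label, row in zip(table.pairs, table.labels, table.vectors):
        cells = ",".join(format(float(v), ".12g") for v in row)
        lines.append(f"{c},{r},{cells},{label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_arff(path: str | Path) -> PairTable:
    """Read a PairTable written by :func:`write_arff` (or an equivalent ARFF
    with numeric attributes and a final nominal ``class`` attribute)."""
    path = Path(path)
    attr_names: list[str] = []
    attr_kinds: list[str] = []
    class_values: tuple[str, ...] | None = None
    data_rows: list[str] = []
    in_data = False
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("%"):
            continue
        low = stripped.lower()
        if in_data:
            data_rows.append(stripped)
        elif low.startswith("@attribute"):
            parts = stripped.split(None, 2)
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed @attribute")
            name, kind = parts[1], parts[2].strip()
            if kind.startswith("{"):
                values = tuple(
                    v.strip() for v in kind.strip("{}").split(",")
                )
                if name != "class":
                    raise ValueError(
                        f"{path}:{lineno}: nominal attribute {name!r}; only "
                        "'class' may be nominal"
                    )
                class_values = values
                attr_kinds.append("class")
            elif kind.lower() in ("numeric", "real", "integer"):
                attr_kinds.append("numeric")
            elif kind.lower() == "string":
                attr_kinds.append("string")
            else:
                raise ValueError(
                    f"{path}:{lineno}: unknown attribute type {kind!r}"
                )
            attr_names.append(name)
        elif low.startswith("@data"):
            if class_values is None:
                raise ValueError(f"{path}: missing nominal class attribute")
            in_data = True
    if not in_data:
        raise ValueError(f"{path}: no @data section")

    class_idx = attr_kinds.index("class")
    string_idx = [i for i, k in enumerate(attr_kinds) if k == "string"]
    numeric_idx = [i for i, k in enumerate(attr_kinds) if k == "numeric"]
    pairs, labels, rows = [], [], []
    for rowno, row in enumerate(data_rows, 1):
        cells = [c.strip() for c in row.split(",")]
        if len(cells) != len(attr_names):
            raise ValueError(
                f"{path}: data row {rowno}: expected {len(attr_names)} "
                f"values, got {len(cells)}"
            )
        label = cells[class_idx]
        if label not in class_values:
            raise ValueError(
                f"{path}: data row {rowno}: class value {label!r} outside "
                f"declared set {class_values}"
            )
        if len(string_idx) == 2:
            pairs.append((cells[string_idx[0]], cells[string_idx[1]]))
        else:
            pairs.append((f"row{rowno}", ""))  # anonymous feature-only ARFF
        labels.append(label)
        rows.append([float(cells[i]) for i in numeric_idx])
    return PairTable(
        tuple(pairs),
        tuple(labels),
        np.array(rows, dtype=float),
        tuple(attr_names[i] for i in numeric_idx),
    )


def write_csv(table: PairTable, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(table.vectors, columns=list(table.feature_names))
    df.insert(0, "cytokine_id", [c for c, _ in table.pairs])
    df.insert(1, "receptor_id", [r for _, r in table.pairs])
    df["class"] = list(table.labels)
    df.to_csv(path, index=False)
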