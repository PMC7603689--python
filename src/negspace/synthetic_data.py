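"""Self-contained synthetic inputs: rosters, mock PSSMs and planted pairs.

The generator emulates the structure of the cytokine-receptor interaction
problem at its published scale — two rosters (123 cytokines, 102 receptors),
203 planted interacting pairs, and a 12,343-pair closed-world negative pool —
while remaining fully synthetic: sequences are random over the canonical
alphabet and PSSMs are random integer matrices with an own-residue bias.

Planted structure. Pair vectors are generated from a latent factor model:
each pair's concatenated per-protein features are projected to a small latent
space z and embedded as v = mu + W z + offset. Positive pairs receive a small
isotropic offset (they live on the manifold); candidate negatives are split
into three strata with increasing off-manifold offsets — "hard" negatives sit
nearly on the positive manifold, "mid" at an intermediate distance, and
"easy" far away. Stratum labels are ground truth for tests only and are never
exposed to classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pair_space import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    PairTable,
    enumerate_negative_pool,
)
from .pssm_features import PSSMatrix
from .seq_features import ALPHABET, ProteinRecord, Role

STRATA = ("hard", "mid", "easy")


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale defaults: 123 cytokines x 102 receptors, 203 positives."""

    n_cytokines: int = 123
    n_receptors: int = 102
    n_positives: int = 203
    length_range: tuple[int, int] = (50, 200)
    strata_fractions: tuple[float, float, float] = (0.1, 0.2, 0.7)
    signal_strength: float = 1.0
    latent_dim: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positives > self.n_cytokines * self.n_receptors:
            raise ValueError("more positives than possible pairs")
        if abs(sum(self.strata_fractions) - 1.0) > 1e-9:
            raise ValueError("strata_fractions must sum to 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")


#: Desk-scale configuration for tests: 24 x 18 roster, 40 positives,
#: 392-pair negative pool, short sequences.
TINY = SynthConfig(
    n_cytokines=24,
    n_receptors=18,
    n_positives=40,
    length_range=(30, 60),
)

PRESETS = {"paper-scale": SynthConfig(), "tiny": TINY}


def generate_rosters(
    cfg: SynthConfig,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Random canonical-alphabet sequences, lengths uniform in length_range."""
    rng = np.random.default_rng(cfg.seed)
    alphabet = np.array(list(ALPHABET))

    def make(prefix: str, role: Role, n: int) -> list[ProteinRecord]:
        records = []
        for i in range(n):
            L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            seq = "".join(rng.choice(alphabet, size=L))
            records.append(ProteinRecord(f"{prefix}{i:04d}", role, seq))
        return records

    return (
        make("CYT", Role.CYTOKINE, cfg.n_cytokines),
        make("REC", Role.RECEPTOR, cfg.n_receptors),
    )


def mock_pssm(record: ProteinRecord, seed: int = 0) -> PSSMatrix:
    """Random integer log-odds in [-8, 12] with the own-residue column biased
    upward, emulating the diagonal structure of real profiles."""
    rng = np.random.default_rng(seed)
    L = len(record.sequence)
    scores = rng.integers(-8, 5, size=(L, 20)).astype(float)
    idx = {aa: j for j, aa in enumerate(ALPHABET)}
    for i, aa in enumerate(record.sequence):
        scores[i, idx[aa]] = rng.integers(5, 13)
    return PSSMatrix(record.id, record.sequence, scores)


@dataclass(frozen=True)
class PlantedData:
    """Positives and stratified negative pool with test-only ground truth."""

    positives: PairTable
    pool: PairTable
    strata: tuple[str, ...] = field(default=())  # per pool row

    def stratum_indices(self, stratum: str) -> list[int]:
        return [i for i, s in enumerate(self.strata) if s == stratum]


def plant_interactions(
    cfg: SynthConfig,
    cytokine_features: dict[str, np.ndarray],
    receptor_features: dict[str, np.ndarray],
) -> PlantedData:
    """Plant positives on a latent manifold and stratify the negatives.

    ``*_features`` map protein ID to a per-protein feature vector (any common
    width). Pair vectors are built as v = mu + W z + offset with z a random
    projection of the concatenated per-protein features, so sequence features
    influence where a pair lands on the manifold. Offsets are isotropic
    Gaussian draws whose scale encodes the stratum: positives sigma_0, hard
    2*sigma_0, mid 6*sigma_0, easy 20*sigma_0, with the stratum separation
    scaled by ``signal_strength``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    cyt_ids = sorted(cytokine_features)
    rec_ids = sorted(receptor_features)
    if len(cyt_ids) != cfg.n_cytokines or len(rec_ids) != cfg.n_receptors:
        raise ValueError("feature dicts do not match configured roster sizes")

    width = len(next(iter(cytokine_features.values()))) + len(
        next(iter(receptor_features.values()))
    )
    all_pairs = [(c, r) for c in cyt_ids for r in rec_ids]
    pos_idx = rng.choice(len(all_pairs), size=cfg.n_positives, replace=False)
    positives = [all_pairs[i] for i in sorted(pos_idx)]
    pool_pairs = enumerate_negative_pool(cyt_ids, rec_ids, positives)

    # latent embedding shared by every pair
    q = cfg.latent_dim
    P = rng.normal(size=(width, q)) / np.sqrt(width)  # feature -> latent
    W = rng.normal(size=(q, width)) / np.sqrt(q)      # latent -> observed
    mu = rng.normal(size=width)

    # Manifold spread per coordinate is ~manifold_scale; stratum offsets grow
    # past it so distance-to-positives orders hard < mid < easy.
    sigma0 = 0.02
    manifold_scale = 0.1
    offset_scale = {
        "positive": sigma0,
        "hard": sigma0 * (1 + cfg.signal_strength),
        "mid": sigma0 * (1 + 5 * cfg.signal_strength),
        "easy": sigma0 * (1 + 19 * cfg.signal_strength),
    }

    def embed(pairs: list[tuple[str, str]], scales: list[float]) -> np.ndarray:
        base = np.stack([
            np.concatenate([cytokine_features[c], receptor_features[r]])
            for c, r in pairs
        ])
        z = base @ P
        z = (z - z.mean(axis=0)) / (z.std(axis=0) + 1e-12)
        noise = rng.normal(size=(len(pairs), width))
        return (
            mu
            + manifold_scale * (z @ W)
            + noise * np.asarray(scales)[:, None]
        )

    # assign strata by fraction, deterministically shuffled
    n_pool = len(pool_pairs)
    counts = [int(round(f * n_pool)) for f in cfg.strata_fractions[:2]]
    counts.append(n_pool - sum(counts))
    strata = np.array(
        ["hard"] * counts[0] + ["mid"] * counts[1] + ["easy"] * counts[2]
    )
    rng.shuffle(strata)

    pos_vectors = embed(positives, [offset_scale["positive"]] * len(positives))
    pool_vectors = embed(pool_pairs, [offset_scale[s] for s in strata])

    names = tuple(f"f{i}" for i in range(width))
    return PlantedData(
        PairTable(tuple(positives), (POSITIVE_LABEL,) * len(positives),
                  pos_vectors, names),
        PairTable(tuple(pool_pairs), (NEGATIVE_LABEL,) * len(pool_pairs),
                  pool_vectors, names),
        tuple(strata),
    )


def default_protein_features(
    records: list[ProteinRecord], rng: np.random.Generator, width: int = 16
) -> dict[str, np.ndarray]:
    """Cheap per-protein features for generator-internal use: residue-composition
    projections plus a random identity component."""
    from .seq_features import compute_aac

    out = {}
    proj = rng.normal(size=(20, width)) / np.sqrt(20)
    for rec in records:
        aac = compute_aac(rec.sequence).values
        out[rec.id] = aac @ proj + 0.1 * rng.normal(size=width)
    return out


def generate_dataset(cfg: SynthConfig) -> PlantedData:
    """One-call generator: rosters -> per-protein features -> planted pairs."""
    cyts, recs = generate_rosters(cfg)
    rng = np.random.default_rng(cfg.seed + 2)
    return plant_interactions(
        cfg,
        default_protein_features(cyts, rng),
        default_protein_features(recs, rng),
    )
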