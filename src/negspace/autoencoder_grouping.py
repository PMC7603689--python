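"""Autoencoder-based stratification of candidate negatives.

An autoencoder is trained on the positive (interacting) pair vectors only.
Every pair — positive or candidate negative — is then scored by its
reconstruction error

    delta_i = (1/n) * sum_j (X_ij - O_ij)^2,

where X is the input vector, O its reconstruction and n the feature count.
Candidate negatives that the positives-only model reconstructs well lie close
to the interacting-pair manifold and are hard to classify; high-error
negatives are easy. Rows are stratified into three bands by two cutoffs
(defaults 0.001 and 0.003, both upper bounds inclusive):

    A_hard: delta <= low;  B_mid: low < delta <= high;  C_easy: delta > high.

Two architecture presets ship: ``paper`` (hidden layers 1000-500-100, tanh,
1000 epochs, l2 = 1e-4) and ``small`` (32-16-8, tanh, 400 epochs), the latter
being the desk-scale default used by the test suite. The network is a
multilayer-perceptron regressor fit to reproduce its own input.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor


class Activation(str, enum.Enum):
    TANH = "tanh"
    RECTIFIER = "rectifier"


class Group(str, enum.Enum):
    A_HARD = "A_hard"
    B_MID = "B_mid"
    C_EASY = "C_easy"


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture and training hyperparameters for the autoencoder."""

    hidden_layers: tuple[int, ...] = (32, 16, 8)
    activation: Activation = Activation.TANH
    epochs: int = 400
    l2: float = 1e-4
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int | str = "auto"

    def __post_init__(self) -> None:
        if not self.hidden_layers:
            raise ValueError("at least one hidden layer required")
        if self.epochs < 1 or self.l2 < 0:
            raise ValueError("epochs >= 1 and l2 >= 0 required")


#: The architecture the study settled on after model selection.
PAPER_PRESET = AutoencoderSpec(
    hidden_layers=(1000, 500, 100),
    activation=Activation.TANH,
    epochs=1000,
    l2=1e-4,
)
#: Desk-scale preset; default for tests and synthetic work.
SMALL_PRESET = AutoencoderSpec()

PRESETS = {"paper": PAPER_PRESET, "small": SMALL_PRESET}


@dataclass(frozen=True)
class TrainedAutoencoder:
    """Opaque trained model; supports reconstruct(X) -> X_hat."""

    spec: AutoencoderSpec
    mse: float
    rmse: float
    _model: MLPRegressor = field(repr=False, compare=False, default=None)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self._model.n_features_in_:
            raise ValueError(
                f"width {X.shape[1]} != model width {self._model.n_features_in_}"
            )
        out = self._model.predict(X)
        return np.atleast_2d(out)


def train_autoencoder(
    positives: np.ndarray, spec: AutoencoderSpec = SMALL_PRESET
) -> TrainedAutoencoder:
    """Fit the autoencoder on positive pair vectors only.

    Returns the trained model with its training-set MSE and RMSE computed
    over all matrix entries. Deterministic for a fixed spec (seed included).
    """
    X = np.asarray(positives, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D array with >= 2 training rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training inputs")
    model = MLPRegressor(
        hidden_layer_sizes=spec.hidden_layers,
        activation="tanh" if spec.activation is Activation.TANH else "relu",
        alpha=spec.l2,
        max_iter=spec.epochs,
        learning_rate_init=spec.learning_rate,
        batch_size=spec.batch_size,
        solver="adam",
        random_state=spec.seed,
        shuffle=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, X)
    residual = X - np.atleast_2d(model.predict(X))
    mse = float(np.mean(residual**2))
    trained = TrainedAutoencoder(spec, mse, float(np.sqrt(mse)))
    object.__setattr__(trained, "_model", model)
    return trained


def reconstruction_error(
    model: TrainedAutoencoder, X: np.ndarray
) -> np.ndarray:
    """Per-row mean squared residual between input and reconstruction."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    O = model.reconstruct(X)
    return np.mean((X - O) ** 2, axis=1)


def group_by_error(
    errors: np.ndarray, low: float = 0.001, high: float = 0.003
) -> list[Group]:
    """Band each reconstruction error: hard (<= low), mid, easy (> high)."""
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    errors = np.asarray(errors, dtype=float)
    if np.any(errors < 0):
        raise ValueError("reconstruction errors must be >= 0")
    return [
        Group.A_HARD if e <= low else Group.B_MID if e <= high else Group.C_EASY
        for e in errors
    ]


def quantile_cutoffs(
    positive_errors: np.ndarray, q_low: float = 0.5, q_high: float = 0.95
) -> tuple[float, float]:
    """Data-driven cutoffs from positive-error quantiles, for inputs whose
    error scale differs from the defaults."""
    lo, hi = np.quantile(np.asarray(positive_errors, dtype=float), [q_low, q_high])
    if lo >= hi:
        hi = lo * (1 + 1e-9) + 1e-12
    return float(lo), float(hi)


def error_histogram(
    errors: np.ndarray, bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of reconstruction errors; counts sum to the number of rows."""
    if bins < 1:
        raise ValueError("bins >= 1")
    counts, edges = np.histogram(np.asarray(errors, dtype=float), bins=bins)
    return edges, counts


@dataclass(frozen=True)
class ReconstructionReport:
    """Per-row errors, band assignments and training diagnostics."""

    errors: np.ndarray
    groups: tuple[Group, ...]
    cutoffs: tuple[float, float]
    train_mse: float
    train_rmse: float

    def group_counts(self) -> dict[Group, int]:
        return {g: sum(1 for x in self.groups if x is g) for g in Group}


def score_and_group(
    model: TrainedAutoencoder,
    X: np.ndarray,
    low: float = 0.001,
    high: float = 0.003,
) -> ReconstructionReport:
    """Score all rows by reconstruction error and band them by the cutoffs."""
    errors = reconstruction_error(model, X)
    return ReconstructionReport(
        errors,
        tuple(group_by_error(errors, low, high)),
        (low, high),
        model.mse,
        model.rmse,
    )
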