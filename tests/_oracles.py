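"""Independent brute-force oracles shared by the test modules."""

import math

import numpy as np


def ks_oracle(X: np.ndarray, n: int) -> list[int]:
    """Brute-force max-min (Kennard-Stone) selection with plain loops."""
    mean = [sum(col) / len(X) for col in X.T]
    dist_to_mean = [math.dist(row, mean) for row in X]
    first = dist_to_mean.index(min(dist_to_mean))
    selected = [first]
    while len(selected) < n:
        best_idx, best_score = None, -1.0
        for i in range(len(X)):
            if i in selected:
                continue
            d = min(math.dist(X[i], X[j]) for j in selected)
            if d > best_score:
                best_idx, best_score = i, d
        selected.append(best_idx)
    return selected


def normalize_minmax(X: np.ndarray) -> np.ndarray:
    mins, maxs = X.min(axis=0), X.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    out = (X - mins) / span
    out[:, maxs == mins] = 0.0
    return out
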