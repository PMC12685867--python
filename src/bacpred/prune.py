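"""Correlation-based feature pruning on training data.

When two features are highly correlated (Pearson |r| >= 0.9 by default) one
of them is redundant; the greedy scan keeps the earlier feature in schema
order and drops the later one.  Zero-variance features have undefined
correlation and are dropped outright (reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schema import FeatureMatrix


@dataclass(frozen=True)
class PruneResult:
    kept: tuple[int, ...]                       # indices into the input schema
    dropped: tuple[tuple[int, int, float], ...]  # (dropped, retained partner, r)
    constant: tuple[int, ...]                    # zero-variance features dropped
    threshold: float
    kept_names: tuple[str, ...] = field(default=())

    def apply(self, matrix: FeatureMatrix) -> FeatureMatrix:
        """Project a matrix (train or test) onto the retained features."""
        return matrix.select(self.kept_names)


def pearson_prune(matrix: FeatureMatrix, threshold: float = 0.9) -> PruneResult:
    """Greedy keep-first correlation pruning.

    Scanning features in schema order, feature j is dropped iff
    |r(i, j)| >= threshold against some already-kept feature i < j.  The
    threshold is inclusive (a pair at exactly r = 0.9 triggers a drop).
    Deterministic: depends only on matrix content and column order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if matrix.n_samples < 3:
        raise ValueError("pruning needs at least 3 training samples")
    if matrix.n_features == 0:
        raise ValueError("empty feature matrix")

    X = matrix.values
    std = X.std(axis=0)
    constant = np.flatnonzero(std == 0.0)
    variable = np.flatnonzero(std > 0.0)

    # correlation over the variable columns only (r toward/among constants
    # is treated as 0, so constants never shadow a real feature)
    Z = (X[:, variable] - X[:, variable].mean(axis=0)) / std[variable]
    R = (Z.T @ Z) / X.shape[0]
    np.clip(R, -1.0, 1.0, out=R)
    # exact duplicates must hit |r| = 1 despite rounding, so the inclusive
    # threshold comparison stays meaningful at the top end
    R[R > 1.0 - 1e-12] = 1.0
    R[R < -1.0 + 1e-12] = -1.0

    kept_local: list[int] = []
    dropped: list[tuple[int, int, float]] = []
    for j in range(len(variable)):
        hit = None
        for i in kept_local:
            if abs(R[i, j]) >= threshold:
                hit = i
                break
        if hit is None:
            kept_local.append(j)
        else:
            dropped.append((int(variable[j]), int(variable[hit]), float(R[hit, j])))
    kept = tuple(int(variable[j]) for j in kept_local)
    names = matrix.schema.names
    return PruneResult(
        kept=kept,
        dropped=tuple(dropped),
        constant=tuple(int(c) for c in constant),
        threshold=threshold,
        kept_names=tuple(names[i] for i in kept),
    )
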