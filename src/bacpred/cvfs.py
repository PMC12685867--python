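"""Cross-validated consensus feature selection (CVFS).

The dataset is randomly split into ``c`` disjoint, label-stratified parts; a
gradient-boosted model is fit on each part and the features it actually uses
(nonzero gain importance) are ranked; the per-part top sets are intersected.
Repeating with ``e`` independent splits yields ``e`` intersection sets, and
a feature enters the final selection if it appears in at least
``ceil(p * e)`` of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .schema import FeatureMatrix

#: Fixed configuration for the per-subset importance models.  A single
#: moderate setting is used for every subset so that importance rankings are
#: comparable across parts and runs.
DEFAULT_SUBSET_PARAMS: dict = {
    "n_estimators": 200,
    "max_depth": 5,
    "learning_rate": 0.1,
    "subsample": 1.0,
    "tree_method": "hist",
    "n_jobs": 1,
}


@dataclass(frozen=True)
class CVFSConfig:
    c: int = 2          # disjoint sub-parts per run
    e: int = 5          # repeated runs
    p: float = 0.4      # fraction of runs a feature must survive
    seed: int = 0
    importance_rule: str = "nonzero_gain"
    xgb_params: Mapping = field(default_factory=lambda: dict(DEFAULT_SUBSET_PARAMS))

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("c must be >= 2")
        if self.e < 1:
            raise ValueError("e must be >= 1")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must be in (0, 1]")
        if self.importance_rule != "nonzero_gain":
            raise ValueError(f"unknown importance rule {self.importance_rule!r}")

    @property
    def consensus_threshold(self) -> int:
        """Minimum number of intersection sets a selected feature must hit."""
        return math.ceil(self.p * self.e)


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    per_run_intersections: tuple[frozenset[str], ...]
    support_counts: Mapping[str, int]
    provenance: dict

    def __post_init__(self) -> None:
        thr = self.provenance.get("consensus_threshold")
        if thr is not None:
            assert all(self.support_counts[f] >= thr for f in self.selected)


def _run_seeds(seed: int, e: int) -> list[int]:
    """Independent, replayable per-run RNG seeds derived from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(e)]


def split_disjoint(matrix: FeatureMatrix, c: int, seed: int) -> list[FeatureMatrix]:
    """Random label-stratified partition into c disjoint parts covering all rows."""
    y = matrix.require_labels()
    if matrix.n_samples < 2 * c:
        raise ValueError(f"need at least {2 * c} samples for c={c}")
    counts = np.bincount(y, minlength=2)
    if (counts < c).any():
        raise ValueError("too few samples in a class to form c stratified parts")
    skf = StratifiedKFold(n_splits=c, shuffle=True, random_state=seed)
    return [matrix.rows(test_idx) for _, test_idx in skf.split(matrix.values, y)]


def subset_top_features(part: FeatureMatrix, config: CVFSConfig, seed: int = 0) -> list[str]:
    """Features with nonzero gain importance in a model fit on one part.

    Returned in descending gain order, ties broken by ascending schema index.
    """
    y = part.require_labels()
    if len(np.unique(y)) < 2:
        raise ValueError("subset contains a single class; cannot rank features")
    clf = XGBClassifier(random_state=seed, **dict(config.xgb_params))
    clf.fit(part.values, y)
    gains = clf.get_booster().get_score(importance_type="gain")
    names = part.schema.names
    scored = []
    for key, gain in gains.items():
        col = int(key[1:])  # xgboost's default f<idx> naming
        if gain > 0:
            scored.append((-gain, col))
    scored.sort()
    return [names[col] for _, col in scored]


def run_cvfs(matrix: FeatureMatrix, config: CVFSConfig) -> SelectionResult:
    """Full CVFS: e runs of (split -> per-part top sets -> intersection),
    then consensus thresholding at ceil(p*e)."""
    run_seeds = _run_seeds(config.seed, config.e)
    intersections: list[frozenset[str]] = []
    for run, rs in enumerate(run_seeds):
        parts = split_disjoint(matrix, config.c, seed=rs)
        tops = [frozenset(subset_top_features(p, config, seed=rs)) for p in parts]
        inter = frozenset.intersection(*tops)
        intersections.append(inter)
    support: dict[str, int] = {}
    for inter in intersections:
        for f in inter:
            support[f] = support.get(f, 0) + 1
    thr = config.consensus_threshold
    order = {name: i for i, name in enumerate(matrix.schema.names)}
    selected = tuple(sorted((f for f, n in support.items() if n >= thr),
                            key=order.__getitem__))
    return SelectionResult(
        selected=selected,
        per_run_intersections=tuple(intersections),
        support_counts=support,
        provenance={
            "c": config.c,
            "e": config.e,
            "p": config.p,
            "seed": config.seed,
            "consensus_threshold": thr,
            "run_seeds": run_seeds,
            "importance_rule": config.importance_rule,
        },
    )
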