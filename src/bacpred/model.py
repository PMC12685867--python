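"""Gradient-boosted classification, evaluation and SHAP attribution.

Training runs a grid search over a committed XGBoost hyperparameter grid via
stratified 5-fold cross-validation on the training split only, refits the
best configuration on the full training data, and packages the booster into
a portable JSON bundle.  Evaluation thresholds predicted probabilities at
0.5 and reports the confusion-matrix metric suite plus rank-based AUC.
Feature attribution uses exact TreeSHAP values (computed natively by the
booster), aggregated per feature and per descriptor family.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .metrics import ConfusionMatrix, MetricsReport, metrics_from_confusion, rank_auc
from .schema import FAMILIES, SCHEMA_VERSION, FeatureMatrix, family_of

#: Committed hyperparameter grid (the per-axis values searched).
DEFAULT_GRID: dict[str, tuple] = {
    "max_depth": (3, 5, 7),
    "learning_rate": (0.05, 0.1, 0.3),
    "n_estimators": (100, 300),
    "subsample": (0.8, 1.0),
}

_FIXED_PARAMS = {"tree_method": "hist", "n_jobs": 1, "objective": "binary:logistic"}


class SchemaMismatchError(ValueError):
    """Model bundle and data disagree on features or schema version."""


def split_train_test(
    matrix: FeatureMatrix, test_frac: float = 0.2, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified train/test split with a per-class floor rule.

    Each class contributes floor(test_frac * n_class) samples to the test
    split, so 283/283 at 20% gives a 112-sample test set (56 per class).
    """
    y = matrix.require_labels()
    if not (0.0 < test_frac < 1.0):
        raise ValueError("test_frac must be in (0, 1)")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(y == c)
        n_test = int(np.floor(test_frac * len(members)))
        chosen = rng.choice(members, size=n_test, replace=False)
        test_idx.extend(int(i) for i in chosen)
    test_set = set(test_idx)
    train_idx = [i for i in range(matrix.n_samples) if i not in test_set]
    return matrix.rows(train_idx), matrix.rows(sorted(test_idx))


@dataclass
class ModelBundle:
    """A trained booster plus everything needed to reapply it."""

    booster_json: str
    feature_names: tuple[str, ...]
    best_params: dict
    cv_results: list  # (params, mean CV accuracy) in search order
    seed: int
    schema_version: str = SCHEMA_VERSION
    extra: dict = field(default_factory=dict)

    def booster(self) -> xgb.Booster:
        bst = xgb.Booster()
        bst.load_model(bytearray(self.booster_json, "utf-8"))
        return bst

    def _check(self, matrix: FeatureMatrix) -> None:
        if matrix.schema.names != self.feature_names:
            raise SchemaMismatchError(
                "feature matrix columns do not match the bundle's feature subset"
            )

    def predict_proba(self, matrix: FeatureMatrix) -> np.ndarray:
        self._check(matrix)
        dm = xgb.DMatrix(matrix.values, feature_names=list(self.feature_names))
        return self.booster().predict(dm)

    def predict(self, matrix: FeatureMatrix, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(matrix) >= threshold).astype(np.int64)

    # -- portable JSON artifact ---------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": self.schema_version,
                "feature_names": list(self.feature_names),
                "best_params": self.best_params,
                "cv_results": self.cv_results,
                "seed": self.seed,
                "extra": self.extra,
                "booster": self.booster_json,
            },
            sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path, expected_schema: str = SCHEMA_VERSION) -> "ModelBundle":
        d = json.loads(Path(path).read_text())
        if d.get("schema_version") != expected_schema:
            raise SchemaMismatchError(
                f"bundle schema version {d.get('schema_version')!r} "
                f"!= expected {expected_schema!r}"
            )
        return cls(
            booster_json=d["booster"],
            feature_names=tuple(d["feature_names"]),
            best_params=d["best_params"],
            cv_results=d["cv_results"],
            seed=d["seed"],
            schema_version=d["schema_version"],
            extra=d.get("extra", {}),
        )


def _grid_configs(grid: dict[str, tuple]) -> list[dict]:
    """Grid points ordered so that ties in CV accuracy resolve to the
    smaller model (fewer trees first, then shallower)."""
    keys = list(grid)
    configs = [dict(zip(keys, vals)) for vals in itertools.product(*grid.values())]
    configs.sort(key=lambda c: (c.get("n_estimators", 0), c.get("max_depth", 0),
                                c.get("learning_rate", 0), c.get("subsample", 0)))
    return configs


def train_model(
    train: FeatureMatrix,
    selected: list[str] | tuple[str, ...] | None = None,
    grid: dict[str, tuple] | None = None,
    seed: int = 0,
    cv_folds: int = 5,
) -> ModelBundle:
    """Grid-searched XGBoost training on the training split only.

    ``selected`` restricts to a feature subset (default: all columns).
    Model selection is by mean CV accuracy over stratified ``cv_folds``
    folds; ties go to the smaller model.  Fully deterministic given the
    seed (single-threaded histogram tree construction).
    """
    if selected is not None:
        if len(selected) == 0:
            raise ValueError("selected feature list is empty")
        unknown = [f for f in selected if f not in train.schema.names]
        if unknown:
            raise SchemaMismatchError(f"unknown feature name(s): {unknown[:5]}")
        train = train.select(list(selected))
    y = train.require_labels()
    counts = np.bincount(y, minlength=2)
    if (counts < 2).any():
        raise ValueError("need at least 2 samples per class to train")

    configs = _grid_configs(grid or DEFAULT_GRID)
    folds = min(cv_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(train.values, y))

    cv_results = []
    best_acc, best_cfg = -1.0, None
    for cfg in configs:
        accs = []
        for tr_idx, va_idx in splits:
            clf = xgb.XGBClassifier(random_state=seed, **_FIXED_PARAMS, **cfg)
            clf.fit(train.values[tr_idx], y[tr_idx])
            pred = clf.predict(train.values[va_idx])
            accs.append(float(np.mean(pred == y[va_idx])))
        mean_acc = float(np.mean(accs))
        cv_results.append([cfg, mean_acc])
        if mean_acc > best_acc:  # strict: earlier (smaller) config wins ties
            best_acc, best_cfg = mean_acc, cfg

    final = xgb.XGBClassifier(random_state=seed, **_FIXED_PARAMS, **best_cfg)
    final.fit(train.values, y)
    final.get_booster().feature_names = list(train.schema.names)
    booster_json = final.get_booster().save_raw(raw_format="json").decode()
    return ModelBundle(
        booster_json=booster_json,
        feature_names=train.schema.names,
        best_params=dict(best_cfg),
        cv_results=cv_results,
        seed=seed,
        extra={"cv_folds": folds, "best_cv_accuracy": best_acc,
               "n_train": train.n_samples},
    )


def evaluate(bundle: ModelBundle, test: FeatureMatrix) -> MetricsReport:
    """Threshold-0.5 confusion counts, metric suite, and rank AUC on a test set."""
    y = test.require_labels()
    proba = bundle.predict_proba(test)
    pred = (proba >= 0.5).astype(np.int64)
    cm = ConfusionMatrix.from_predictions(y, pred)
    auc = rank_auc(y, proba) if len(np.unique(y)) == 2 else None
    return metrics_from_confusion(cm, auc=auc)


@dataclass(frozen=True)
class ShapSummary:
    feature_names: tuple[str, ...]
    per_sample: np.ndarray          # n x m signed SHAP values (margin scale)
    base_value: float
    mean_abs: dict                  # feature -> mean |SHAP|
    ranking: tuple[str, ...]        # all features, descending mean |SHAP|
    top: tuple[tuple[str, float], ...]  # top_k (feature, mean |SHAP|)
    family_sums: dict               # family -> sum of member mean |SHAP|


def explain(bundle: ModelBundle, data: FeatureMatrix, top_k: int = 10) -> ShapSummary:
    """Exact TreeSHAP attribution on ``data`` (margin/log-odds scale).

    Per-feature importance is the mean absolute SHAP value over samples;
    family sums aggregate those means over the nine descriptor families
    (families with no surviving feature contribute 0).  The per-sample
    values satisfy local accuracy: base value + row sum = model margin.
    """
    bundle._check(data)
    bst = bundle.booster()
    dm = xgb.DMatrix(data.values, feature_names=list(bundle.feature_names))
    contribs = bst.predict(dm, pred_contribs=True)
    per_sample = contribs[:, :-1]
    base_value = float(contribs[0, -1])
    mean_abs = np.abs(per_sample).mean(axis=0)
    names = bundle.feature_names
    order = np.lexsort((np.arange(len(names)), -mean_abs))
    ranking = tuple(names[i] for i in order)
    family_sums = {fam: 0.0 for fam in FAMILIES}
    for i, name in enumerate(names):
        family_sums[family_of(name)] += float(mean_abs[i])
    return ShapSummary(
        feature_names=names,
        per_sample=per_sample,
        base_value=base_value,
        mean_abs={names[i]: float(mean_abs[i]) for i in range(len(names))},
        ranking=ranking,
        top=tuple((f, float(mean_abs[names.index(f)])) for f in ranking[:top_k]),
        family_sums=family_sums,
    )
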