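"""Feature schema and the labeled feature-matrix container.

The toolkit's full descriptor vocabulary is a fixed, ordered list of 1,103
named features grouped into nine descriptor families.  Selection stages work
on subsets of this vocabulary; the schema keeps name -> family resolution and
ordering stable across the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Version stamp written into every serialized artifact (feature tables,
#: model bundles, manifests).  Bumped on any change to the vocabulary.
SCHEMA_VERSION = "1.0"

#: (name prefix, family label, block size) in schema order.
FAMILY_BLOCKS: tuple[tuple[str, str, int], ...] = (
    ("aac", "AAC", 20),
    ("dipep", "DC", 400),
    ("pseudo", "PseAAC", 30),
    ("amphipseudo", "APseAAC", 40),
    ("comp", "CTD", 21),
    ("tran", "CTD", 21),
    ("dist", "CTD", 105),
    ("ss", "SS", 6),
    ("socn", "SOCN", 20),
    ("qso", "QSO", 40),
    ("pssm", "PSSM", 400),
)

#: The nine family labels used for SHAP aggregation (CTD spans three blocks).
FAMILIES: tuple[str, ...] = (
    "AAC", "DC", "PseAAC", "APseAAC", "CTD", "SS", "SOCN", "QSO", "PSSM",
)

_PREFIX_TO_FAMILY = {prefix: family for prefix, family, _ in FAMILY_BLOCKS}

TOTAL_FEATURES = sum(size for _, _, size in FAMILY_BLOCKS)


def full_feature_names() -> tuple[str, ...]:
    """The complete ordered 1,103-name vocabulary (``aac_1`` ... ``pssm_400``)."""
    names: list[str] = []
    for prefix, _, size in FAMILY_BLOCKS:
        names.extend(f"{prefix}_{i}" for i in range(1, size + 1))
    return tuple(names)


def family_of(name: str) -> str:
    """Resolve a feature name to its descriptor family label."""
    prefix = name.rsplit("_", 1)[0]
    try:
        return _PREFIX_TO_FAMILY[prefix]
    except KeyError:
        raise KeyError(f"unknown feature name {name!r}") from None


@dataclass(frozen=True)
class FeatureSchema:
    """An ordered, unique feature-name list (the full vocabulary or a subset)."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = {n for n in self.names if list(self.names).count(n) > 1}
            raise ValueError(f"duplicate feature names: {sorted(dupes)[:5]}")
        for n in self.names:
            family_of(n)  # raises on unknown prefix

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def families(self) -> tuple[str, ...]:
        return tuple(family_of(n) for n in self.names)

    @classmethod
    def full(cls) -> "FeatureSchema":
        return cls(full_feature_names())


@dataclass
class FeatureMatrix:
    """n-sample x m-feature table with sample ids and optional 0/1 labels."""

    ids: tuple[str, ...]
    values: np.ndarray
    schema: FeatureSchema
    labels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} rows")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate sample ids")
        if m != len(self.schema):
            raise ValueError(f"{m} columns vs schema of length {len(self.schema)}")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (n,):
                raise ValueError("labels must be one 0/1 value per sample")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the order given; names must exist in the schema."""
        idx = [self.schema.index(n) for n in names]
        return FeatureMatrix(
            ids=self.ids,
            values=self.values[:, idx],
            schema=FeatureSchema(tuple(names)),
            labels=None if self.labels is None else self.labels.copy(),
            metadata=dict(self.metadata),
        )

    def rows(self, indices: Iterable[int]) -> "FeatureMatrix":
        idx = np.asarray(list(indices), dtype=np.int64)
        return FeatureMatrix(
            ids=tuple(self.ids[i] for i in idx),
            values=self.values[idx],
            schema=self.schema,
            labels=None if self.labels is None else self.labels[idx],
            metadata=dict(self.metadata),
        )

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("this operation requires labels")
        return self.labels
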