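"""Hypergraph-based feature evaluation (HFE).

Samples are vertices; for every feature, each occupied uniform-width bin of
its discretized values is a hyperedge connecting the samples that fall in
that bin, and two extra hyperedges encode the class labels.  A lazy random
walk on this hypergraph (stay with probability alpha, otherwise pick an
incident hyperedge proportional to its weight and a vertex in it
proportional to vertex weight) leaks probability between classes through
mixed bins; class-pure bins have low cut conductance.  With uniform weights
the landing class distribution of a step through an edge is simply the edge's
class proportions, which gives closed-form per-edge ratings:

* ``R1 = n_minority / n`` — retention of the minority class,
* ``R2 = n_majority / n`` — retention of the majority class,
* ``R0 = |n_pos - n_neg| / n`` — class separation of the bin.

The per-feature score is the sample-weighted mean of R0 over the feature's
bins; the top ``z = round(beta * m)`` features by score are retained.
A seeded Monte-Carlo walk simulator is provided as an independent check of
the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .schema import FeatureMatrix


@dataclass(frozen=True)
class HFEConfig:
    bins: int = 10
    beta: float = 0.30
    stay_prob: float = 0.5   # lazy-walk alpha; cancels from closed-form scores
    seed: int = 0            # consumed only by the Monte-Carlo oracle

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must be in (0, 1]")
        if not (0.0 <= self.stay_prob < 1.0):
            raise ValueError("stay_prob must be in [0, 1)")


@dataclass(frozen=True)
class BinRating:
    n_pos: int
    n_neg: int
    r1: float  # minority-class retention
    r2: float  # majority-class retention
    r0: float  # class separation


@dataclass
class Hypergraph:
    """Vertices (samples), one hyperedge per occupied (feature, bin), plus
    two class hyperedges.  Uniform vertex and edge weights."""

    vertex_ids: tuple[str, ...]
    labels: np.ndarray
    bin_edges: dict[tuple[int, int], np.ndarray]  # (feature, bin) -> member rows
    class_edges: dict[int, np.ndarray]            # label -> member rows
    n_features: int
    n_bins: int

    def incident_edge_count(self, vertex: int) -> int:
        # one bin edge per feature + one class edge
        return self.n_features + 1


@dataclass(frozen=True)
class HFESelection:
    scores: Mapping[str, float]
    ranking: tuple[str, ...]
    z: int
    selected: tuple[str, ...]
    m: int
    provenance: dict


def discretize(matrix: FeatureMatrix, bins: int) -> np.ndarray:
    """Uniform-width binning of each feature over its training [min, max].

    Returns an n x m int array of bin ids in [0, bins).  Bins are
    left-closed/right-open with the final bin closed; a value exactly on an
    interior boundary joins the upper bin.  Constant features occupy a
    single bin.
    """
    X = matrix.values
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    ids = np.floor((X - lo) / safe * bins).astype(np.int64)
    np.clip(ids, 0, bins - 1, out=ids)
    ids[:, span == 0] = 0
    return ids


def assign_bins(values: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    """Bin ids for arbitrary values against a training range; out-of-range
    values clamp to the edge bins."""
    span = hi - lo
    if span <= 0:
        return np.zeros(len(values), dtype=np.int64)
    ids = np.floor((np.asarray(values) - lo) / span * bins).astype(np.int64)
    return np.clip(ids, 0, bins - 1)


def build_hypergraph(matrix: FeatureMatrix, bins: int) -> Hypergraph:
    y = matrix.require_labels()
    bin_ids = discretize(matrix, bins)
    bin_edges: dict[tuple[int, int], np.ndarray] = {}
    for f in range(matrix.n_features):
        col = bin_ids[:, f]
        for b in np.unique(col):
            bin_edges[(f, int(b))] = np.flatnonzero(col == b)
    class_edges = {int(c): np.flatnonzero(y == c) for c in np.unique(y)}
    return Hypergraph(
        vertex_ids=matrix.ids,
        labels=y,
        bin_edges=bin_edges,
        class_edges=class_edges,
        n_features=matrix.n_features,
        n_bins=bins,
    )


def _minority_class(labels: np.ndarray) -> int:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    # tie -> positive class designated minority
    return 1 if n_pos <= n_neg else 0


def rate_hyperedge(members_labels: np.ndarray, minority: int) -> BinRating:
    """Closed-form one-step ratings of a hyperedge from its member labels."""
    n = len(members_labels)
    if n == 0:
        raise ValueError("empty hyperedge")
    n_pos = int((members_labels == 1).sum())
    n_neg = n - n_pos
    n_min = n_pos if minority == 1 else n_neg
    return BinRating(
        n_pos=n_pos,
        n_neg=n_neg,
        r1=n_min / n,
        r2=(n - n_min) / n,
        r0=abs(n_pos - n_neg) / n,
    )


def score_features(graph: Hypergraph) -> np.ndarray:
    """Per-feature score S(f) = sum_b (n_b / N) * R0_b, in [0, 1].

    The sample-weighted mean class separation over the feature's bins: 1 when
    every bin is class-pure, 0 when every bin mirrors a 50/50 mixture.
    """
    N = len(graph.labels)
    minority = _minority_class(graph.labels)
    scores = np.zeros(graph.n_features)
    for (f, _), members in graph.bin_edges.items():
        rating = rate_hyperedge(graph.labels[members], minority)
        scores[f] += (len(members) / N) * rating.r0
    return scores


def feature_budget(beta: float, m: int) -> int:
    """z = round(beta * m), rounding half away from zero."""
    import math

    return int(math.floor(beta * m + 0.5))


def select_hfe(matrix: FeatureMatrix, config: HFEConfig) -> HFESelection:
    """Full HFE pipeline: discretize, build, rate, score, rank, retain top z.

    Ranking is by descending score with ties broken by ascending schema
    index, so results are deterministic.
    """
    if matrix.n_features < 1:
        raise ValueError("empty feature matrix")
    graph = build_hypergraph(matrix, config.bins)
    scores = score_features(graph)
    m = matrix.n_features
    order = np.lexsort((np.arange(m), -scores))
    names = matrix.schema.names
    ranking = tuple(names[i] for i in order)
    z = feature_budget(config.beta, m)
    return HFESelection(
        scores={names[i]: float(scores[i]) for i in range(m)},
        ranking=ranking,
        z=z,
        selected=ranking[:z],
        m=m,
        provenance={"bins": config.bins, "beta": config.beta,
                    "stay_prob": config.stay_prob},
    )


# -- Monte-Carlo oracle ------------------------------------------------------

def simulate_edge_landing(
    graph: Hypergraph,
    edge: tuple[int, int] | str,
    stay_prob: float,
    n_steps: int,
    seed: int,
) -> tuple[dict[int, float], int]:
    """Lazy-random-walk estimate of the landing-class distribution of an edge.

    Runs a lazy walk over the full hypergraph (stay with probability
    ``stay_prob``; otherwise choose an incident hyperedge uniformly — all
    weights are 1 — then a member vertex uniformly).  Every move that
    traverses the requested edge records the class of the landing vertex.
    Returns (class -> landing frequency, number of traversals).  Purely an
    oracle for the closed-form ratings; never used to compute scores.
    """
    rng = np.random.default_rng(seed)
    if isinstance(edge, str):
        target_members = graph.class_edges[{"pos": 1, "neg": 0}[edge]]
        target_key = ("class", edge)
    else:
        target_members = graph.bin_edges[edge]
        target_key = edge

    # per-vertex incident edges: one bin edge per feature + its class edge
    vertex_bin: dict[int, list[tuple[int, int]]] = {v: [] for v in range(len(graph.labels))}
    for key, members in graph.bin_edges.items():
        for v in members:
            vertex_bin[int(v)].append(key)

    counts = {0: 0, 1: 0}
    traversals = 0
    v = int(rng.integers(len(graph.labels)))
    for _ in range(n_steps):
        if stay_prob > 0 and rng.random() < stay_prob:
            continue
        incident = vertex_bin[v] + [("class", "pos" if graph.labels[v] == 1 else "neg")]
        choice = incident[int(rng.integers(len(incident)))]
        if choice[0] == "class":
            members = graph.class_edges[1 if choice[1] == "pos" else 0]
        else:
            members = graph.bin_edges[choice]
        v = int(members[int(rng.integers(len(members)))])
        if choice == target_key:
            traversals += 1
            counts[int(graph.labels[v])] += 1
    total = max(traversals, 1)
    return {c: counts[c] / total for c in (0, 1)}, traversals
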