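"""Edge ranking and selection: Fisher score, SVM-RFE, consensus edges.

The Fisher score ranks each connectivity edge by |mu+ - mu-| / (s+^2 + s-^2),
the absolute class-mean difference over the summed class variances (the
absolute value makes the ranking independent of which class happens to have
the larger mean; the raw signed score is kept alongside).

RFE (recursive feature elimination) iteratively refits a classifier and
removes the features whose deletion changes the squared margin quantity
W^2(alpha) = sum_{i,s} alpha_i alpha_s y_i y_s K(x_i, x_s) the least.  For a
linear kernel this criterion reduces exactly to w_j^2, so linear models are
scored by |w_j| directly — including the linear xi-SOCP model, whose RFE
combination is the novel selector this package provides.  The kernel
xi-SOCP criterion (sensitivity of s'Ks with s held fixed) is provided but
experimental.  Elimination proceeds in chunks down a decreasing schedule of
feature counts rather than one feature at a time.

The consensus procedure intersects the top-k edges of two rankings
(typically Fisher and linear-RFE), keeping the edges both selectors agree on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classifiers import SoftMarginSVM, TwinBoundedSVM, XiSOCPSVM, kernel_matrix

__all__ = ["FeatureRanking", "EdgeSet", "fisher_scores", "rfe_margin_criterion",
           "rfe_rank", "consensus_edges", "ranking_to_csv", "edge_set_to_csv",
           "edge_set_to_graphml", "DEFAULT_SCHEDULE"]

DEFAULT_SCHEDULE = (1830, 1000, 500, 250, 100, 50, 20, 10)


@dataclass
class FeatureRanking:
    """Feature columns ordered most- to least-relevant."""

    order: np.ndarray                 # permutation of 0..d-1
    scores: np.ndarray                # per-feature score (last round for RFE)
    method: str
    elimination_round: np.ndarray | None = None   # RFE round index per feature
    elimination_schedule: tuple[int, ...] | None = None
    signed_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        d = len(self.order)
        if sorted(self.order.tolist()) != list(range(d)):
            raise ValueError("order must be a permutation of the feature columns")

    @property
    def n_features(self) -> int:
        return len(self.order)

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


@dataclass
class EdgeSet:
    """Selected channel pairs with their best source-ranking positions."""

    edges: list[tuple[int, int]]
    positions: list[int] = field(default_factory=list)   # best rank per edge
    columns: list[int] = field(default_factory=list)     # feature columns

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in EdgeSet")


# ---------------------------------------------------------------------------
# Fisher score

def fisher_scores(X: np.ndarray, y: np.ndarray) -> FeatureRanking:
    """Per-feature class-separability ranking (descending score).

    Features constant in both classes score 0 (with a warning) and rank
    last; ties break toward the lower column index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    pos, neg = X[y == 1], X[y == -1]
    num_signed = pos.mean(axis=0) - neg.mean(axis=0)
    denom = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    zero = denom == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} feature(s) constant within both "
                      "classes; scored 0", stacklevel=2)
    scores = np.zeros(X.shape[1])
    scores[~zero] = np.abs(num_signed[~zero]) / denom[~zero]
    signed = np.zeros(X.shape[1])
    signed[~zero] = num_signed[~zero] / denom[~zero]
    order = np.lexsort((np.arange(X.shape[1]), -scores))
    return FeatureRanking(order=order, scores=scores, method="fisher",
                          signed_scores=signed)


# ---------------------------------------------------------------------------
# RFE criterion

def _w2_criteria(model) -> np.ndarray:
    """Per-feature |W^2 - W^2_(-j)| (or its |w_j| linear equivalent)."""
    if isinstance(model, SoftMarginSVM):
        if model.kernel == "linear":
            return np.abs(model.w_)
        ay = model.alpha_ * model.y_train_
        return _kernel_sensitivity(model.X_train_, ay, model.kernel, model.sigma)
    if isinstance(model, XiSOCPSVM):
        if model.w_ is not None:
            return np.abs(model.w_)
        # experimental: sensitivity of s'Ks with the dual-like s held fixed
        return _kernel_sensitivity(model.X_sorted_, model.s_, model.kernel,
                                   model.sigma)
    if isinstance(model, TwinBoundedSVM):
        if model.kernel != "linear":
            raise ValueError("RFE criterion not defined for the kernel twin model")
        return np.abs(model.u1_) + np.abs(model.u2_)
    raise TypeError(f"no RFE criterion for {type(model).__name__}")


def _kernel_sensitivity(X: np.ndarray, coeff: np.ndarray, kernel: str,
                        sigma: float) -> np.ndarray:
    """|c'Kc - c'K_(-j)c| for every feature j, K over the rows of X."""
    K = kernel_matrix(X, X, kernel, sigma)
    w2 = coeff @ K @ coeff
    d = X.shape[1]
    out = np.empty(d)
    for j in range(d):
        diff = X[:, j][:, None] - X[:, j][None, :]
        if kernel == "linear":
            Kj = K - np.outer(X[:, j], X[:, j])
        else:
            Kj = K * np.exp(diff ** 2 / (2 * sigma ** 2))
        out[j] = abs(w2 - coeff @ Kj @ coeff)
    return out


def rfe_margin_criterion(model, feature_j: int) -> float:
    """Margin-change criterion |W^2(alpha) - W^2_(-j)(alpha)| for one feature."""
    crit = _w2_criteria(model)
    if not (0 <= feature_j < len(crit)):
        raise IndexError(f"feature index {feature_j} out of range")
    return float(crit[feature_j])


# ---------------------------------------------------------------------------
# recursive elimination

def default_schedule(d: int) -> tuple[int, ...]:
    """Chunked schedule from d down through the evaluated grid."""
    tail = [k for k in DEFAULT_SCHEDULE if k < d]
    return tuple([d] + tail)


def rfe_rank(X: np.ndarray, y: np.ndarray,
             trainer: Callable[[np.ndarray, np.ndarray], object] | None = None,
             schedule: Sequence[int] | None = None) -> FeatureRanking:
    """Backward elimination down a decreasing feature-count schedule.

    ``trainer(X, y)`` must return a fitted model with an RFE criterion
    (default: linear soft-margin SVM, C = 1).  At each round the surviving
    features are scored; the lowest-scored are dropped to the next schedule
    point.  The ranking is the reverse elimination order; survivors of the
    final round lead, ordered by their last-round score.  Ties break toward
    the lower column index throughout.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    d = X.shape[1]
    if trainer is None:
        trainer = lambda Xs, ys: SoftMarginSVM(C=1.0, kernel="linear").fit(Xs, ys)
    if schedule is None:
        schedule = default_schedule(d)
    schedule = tuple(int(k) for k in schedule)
    if schedule[0] != d:
        raise ValueError(f"schedule must start at the full feature count {d}")
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must strictly decrease")
    if schedule[-1] < 1:
        raise ValueError("schedule floor must be >= 1")

    surviving = np.arange(d)
    last_score = np.zeros(d)
    elim_round = np.full(d, -1)
    ranking_tail: list[int] = []          # eliminated, least relevant first

    def fit_and_score(rnd: int) -> np.ndarray:
        try:
            model = trainer(X[:, surviving], y)
        except Exception as exc:
            raise RuntimeError(f"classifier failed in RFE round {rnd}: {exc}") from exc
        crit = np.asarray(_w2_criteria(model), dtype=float)
        last_score[surviving] = crit
        return crit

    for rnd, target in enumerate(schedule[1:]):
        crit = fit_and_score(rnd)
        # keep the target highest-scored; among the dropped, eliminate
        # lowest score first (higher column index first on ties, so the
        # lower index ends up ranked better)
        by_relevance = np.lexsort((surviving, -crit))
        dropped = by_relevance[target:]
        dropped_sorted = dropped[np.lexsort((-surviving[dropped], crit[dropped]))]
        for pos in dropped_sorted:
            ranking_tail.append(int(surviving[pos]))
            elim_round[surviving[pos]] = rnd
        surviving = np.sort(surviving[by_relevance[:target]])
    fit_and_score(len(schedule) - 1)      # final-round scores for survivors
    head_order = np.lexsort((surviving, -last_score[surviving]))
    head = [int(surviving[i]) for i in head_order]
    order = np.array(head + ranking_tail[::-1], dtype=int)
    elim_round[surviving] = len(schedule) - 1
    return FeatureRanking(order=order, scores=last_score, method="rfe",
                          elimination_round=elim_round,
                          elimination_schedule=schedule)


# ---------------------------------------------------------------------------
# consensus

def consensus_edges(ranking_a: FeatureRanking, ranking_b: FeatureRanking,
                    k: int, edge_index: list[tuple[int, int]]) -> EdgeSet:
    """Intersection of the top-k edges of two rankings over the same edges.

    Ordered by the better of the two rank positions, then column index.  A
    valid (possibly empty) set is returned when the top-k sets are disjoint.
    """
    if ranking_a.n_features != ranking_b.n_features:
        raise ValueError("rankings cover different feature sets")
    if len(edge_index) != ranking_a.n_features:
        raise ValueError("edge_index does not match the rankings")
    if not (0 < k <= ranking_a.n_features):
        raise ValueError("k must be in 1..d")
    top_a = ranking_a.top(k)
    top_b = set(ranking_b.top(k).tolist())
    pos_a = {int(c): p for p, c in enumerate(ranking_a.order)}
    pos_b = {int(c): p for p, c in enumerate(ranking_b.order)}
    common = [int(c) for c in top_a if int(c) in top_b]
    common.sort(key=lambda c: (min(pos_a[c], pos_b[c]), c))
    return EdgeSet(edges=[edge_index[c] for c in common],
                   positions=[min(pos_a[c], pos_b[c]) for c in common],
                   columns=common)


# ---------------------------------------------------------------------------
# exports

def ranking_to_csv(ranking: FeatureRanking,
                   edge_index: list[tuple[int, int]], path: str | Path) -> None:
    rows = [{"edge": f"{edge_index[c][0]}-{edge_index[c][1]}",
             "column": int(c), "rank": r,
             "score": float(ranking.scores[c])}
            for r, c in enumerate(ranking.order)]
    df = pd.DataFrame(rows)
    df["method"] = ranking.method
    df.to_csv(path, index=False)


def edge_set_to_csv(edges: EdgeSet, path: str | Path) -> None:
    pd.DataFrame({"edge": [f"{i}-{j}" for i, j in edges.edges],
                  "best_rank": edges.positions,
                  "column": edges.columns}).to_csv(path, index=False)


def edge_set_to_graphml(edges: EdgeSet, channel_labels: list[str],
                        path: str | Path) -> None:
    import networkx as nx
    g = nx.Graph()
    for idx, label in enumerate(channel_labels):
        g.add_node(idx, label=label)
    for (i, j), pos in zip(edges.edges, edges.positions or [0] * len(edges.edges)):
        g.add_edge(i, j, best_rank=int(pos))
    nx.write_graphml(g, str(path))
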