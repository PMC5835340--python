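"""Nested cross-validated model selection and reporting.

The protocol: a stratified outer 10-fold split yields held-out test sets;
within each outer training set, features are ranked (Fisher, RFE, or none)
and a stratified inner loop grid-searches the hyperparameters together with
the number of top-ranked features to keep.  The winning configuration is
refit on the full outer training set and scored once on the untouched outer
test fold; reported accuracy is the average over outer folds.  Outer test
data never reaches the ranking or tuning stages.

Plain accuracy is the headline metric (matching the usual tabulated form);
balanced accuracy is logged alongside because with imbalanced classes the
permutation-null of plain accuracy sits at the majority rate, not at 50%.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .classifiers import SoftMarginSVM, TwinBoundedSVM, XiSOCPSVM
from .connectivity import FeatureDataset
from .feature_selection import FeatureRanking, fisher_scores, rfe_rank

__all__ = ["HyperGrid", "ClassifierSpec", "CVReport", "nested_cv",
           "accuracy_curve", "report_tables", "SummaryTable"]

_POW2 = tuple(float(2.0 ** k) for k in range(-7, 8))


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter grids: powers of two for C/c_i/sigma, the four-point
    eta grid, and the evaluated feature counts."""

    C_values: tuple[float, ...] = _POW2
    c_values: tuple[float, ...] = _POW2          # twin c1=c2 and c3=c4
    sigma_values: tuple[float, ...] = _POW2
    eta_values: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    feature_counts: tuple[int, ...] = (10, 20, 50, 100, 250, 500, 1000, 1830)

    def __post_init__(self) -> None:
        for vals in (self.C_values, self.c_values, self.sigma_values):
            if any(v <= 0 for v in vals):
                raise ValueError("grid values must be positive")
        if any(not (0 < e < 1) for e in self.eta_values):
            raise ValueError("eta values must lie in (0, 1)")

    @classmethod
    def coarse(cls, counts: tuple[int, ...] | None = None) -> "HyperGrid":
        """A budget-capped grid for smoke runs: 5 log-spaced values."""
        five = tuple(float(2.0 ** k) for k in (-7, -3, 0, 3, 7))
        return cls(C_values=five, c_values=five, sigma_values=five,
                   feature_counts=counts or (10, 20, 50, 100, 250, 500, 1000, 1830))


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier family and kernel a CV run evaluates."""

    family: str = "svm"        # svm | tbsvm | socp
    kernel: str = "linear"     # linear | gaussian

    def __post_init__(self) -> None:
        if self.family not in ("svm", "tbsvm", "socp"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.kernel not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def name(self) -> str:
        kind = {"svm": "SVM", "tbsvm": "TB-SVM", "socp": "xi-SOCP"}[self.family]
        return f"{kind} ({self.kernel})"

    def configs(self, grid: HyperGrid) -> list[dict]:
        sigmas: Sequence = grid.sigma_values if self.kernel == "gaussian" else (None,)
        out = []
        if self.family == "svm":
            for C, s in product(grid.C_values, sigmas):
                out.append({"C": C, "sigma": s})
        elif self.family == "tbsvm":
            for c12, c34, s in product(grid.c_values, grid.c_values, sigmas):
                out.append({"c1": c12, "c2": c12, "c3": c34, "c4": c34, "sigma": s})
        else:
            for C, e1, e2, s in product(grid.C_values, grid.eta_values,
                                        grid.eta_values, sigmas):
                out.append({"C": C, "eta1": e1, "eta2": e2, "sigma": s})
        return out

    def build(self, config: dict):
        sigma = config.get("sigma") or 1.0
        if self.family == "svm":
            return SoftMarginSVM(C=config["C"], kernel=self.kernel, sigma=sigma)
        if self.family == "tbsvm":
            return TwinBoundedSVM(config["c1"], config["c2"], config["c3"],
                                  config["c4"], kernel=self.kernel, sigma=sigma)
        return XiSOCPSVM(C=config["C"], eta1=config["eta1"], eta2=config["eta2"],
                         kernel=self.kernel, sigma=sigma)


@dataclass
class CVReport:
    """Outcome of one nested-CV run."""

    method: str
    dataset: str
    accuracy: float                       # mean outer-test accuracy, percent
    balanced_accuracy: float              # percent
    per_count: dict[int, float] | None    # feature count -> mean accuracy (%)
    per_count_balanced: dict[int, float] | None
    optimal_count: int | None
    folds: list[dict]                     # per-fold chosen config and scores
    fold_test_indices: list[np.ndarray]
    seed: int
    runtime_s: float
    n_samples: int = 0

    def to_frame(self) -> pd.DataFrame:
        if not self.per_count:
            return pd.DataFrame({"n_features": [], "accuracy": []})
        counts = sorted(self.per_count)
        return pd.DataFrame({"n_features": counts,
                             "accuracy": [self.per_count[c] for c in counts]})


def _resolve_ranking(ranking, spec: ClassifierSpec
                     ) -> Callable[[np.ndarray, np.ndarray], FeatureRanking] | None:
    if ranking is None or ranking == "none":
        return None
    if callable(ranking):
        return ranking
    if ranking == "fisher":
        return fisher_scores
    if ranking == "rfe":
        # linear soft-margin trainer: the standard RFE backbone
        return lambda X, y: rfe_rank(X, y)
    if ranking == "rfe-socp":
        trainer = lambda X, y: XiSOCPSVM(C=1.0, eta1=0.5, eta2=0.5,
                                         kernel="linear").fit(X, y)
        return lambda X, y: rfe_rank(X, y, trainer=trainer)
    raise ValueError(f"unknown ranking {ranking!r}")


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(dataset, FeatureDataset):
        name = dataset.provenance.get("measure", "dataset")
        band = dataset.provenance.get("band")
        if band:
            name = f"{name}:{band}"
        return dataset.X, dataset.y, name
    X, y = dataset
    return np.asarray(X, float), np.asarray(y, int), "dataset"


def nested_cv(dataset, spec: ClassifierSpec, grid: HyperGrid,
              ranking=None, outer_k: int = 10, inner_k: int = 5,
              seed: int = 0, budget: int | None = None,
              dataset_name: str | None = None) -> CVReport:
    """Nested cross-validation; see the module docstring for the protocol.

    ``budget`` optionally caps the number of hyperparameter configurations
    (taken in enumeration order) for smoke runs.
    """
    return _nested_engine(dataset, spec, grid, ranking, outer_k, inner_k,
                          seed, budget, per_count=False,
                          dataset_name=dataset_name)


def accuracy_curve(dataset, spec: ClassifierSpec, grid: HyperGrid,
                   ranking=None, outer_k: int = 10, inner_k: int = 5,
                   seed: int = 0, budget: int | None = None,
                   dataset_name: str | None = None) -> CVReport:
    """Nested-CV accuracy at every feature count in the grid.

    The report's ``per_count`` maps each count to its mean outer-test
    accuracy (inner loop selects hyperparameters only); ``optimal_count`` is
    the argmax, ties resolved toward fewer features.
    """
    return _nested_engine(dataset, spec, grid, ranking, outer_k, inner_k,
                          seed, budget, per_count=True,
                          dataset_name=dataset_name)


def _nested_engine(dataset, spec, grid, ranking, outer_k, inner_k, seed,
                   budget, per_count, dataset_name=None) -> CVReport:
    t0 = time.perf_counter()
    X, y, auto_name = _as_xy(dataset)
    name = dataset_name or auto_name
    d = X.shape[1]
    rank_fn = _resolve_ranking(ranking, spec)
    if rank_fn is None:
        counts = [d]
    else:
        counts = sorted(c for c in grid.feature_counts if c <= d) or [d]
    configs = spec.configs(grid)
    if budget is not None:
        configs = configs[:budget]

    rng = np.random.default_rng(seed)
    outer_state = int(rng.integers(2 ** 31))
    inner_states = [int(rng.integers(2 ** 31)) for _ in range(outer_k)]
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True,
                            random_state=outer_state)

    fold_rows, test_indices = [], []
    outer_acc, outer_bal = [], []
    count_acc = {c: [] for c in counts}
    count_bal = {c: [] for c in counts}
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        ytr, yte = y[tr], y[te]
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            raise ValueError(f"outer fold {fold} contains a single class; "
                             "use stratification or more data per class")
        Xtr, Xte = X[tr], X[te]
        order = rank_fn(Xtr, ytr).order if rank_fn is not None else np.arange(d)

        inner = StratifiedKFold(n_splits=inner_k, shuffle=True,
                                random_state=inner_states[fold])
        table = np.zeros((len(counts), len(configs)))
        for itr, iva in inner.split(Xtr, ytr):
            if len(np.unique(ytr[itr])) < 2:
                raise ValueError(f"inner fold within outer fold {fold} has a "
                                 "single class")
            for ci, count in enumerate(counts):
                cols = order[:count]
                Xi, Xv = Xtr[itr][:, cols], Xtr[iva][:, cols]
                for gi, cfg in enumerate(configs):
                    model = spec.build(cfg).fit(Xi, ytr[itr])
                    table[ci, gi] += np.mean(model.predict(Xv) == ytr[iva])
        table /= inner_k

        def refit_score(count, gi):
            cols = order[:count]
            model = spec.build(configs[gi]).fit(Xtr[:, cols], ytr)
            pred = model.predict(Xte[:, cols])
            return (float(np.mean(pred == yte)),
                    float(balanced_accuracy_score(yte, pred)))

        # per-count winners (ties toward the earlier config)
        if per_count:
            for ci, count in enumerate(counts):
                gi = int(np.argmax(table[ci]))
                acc, bal = refit_score(count, gi)
                count_acc[count].append(acc)
                count_bal[count].append(bal)
        # global winner: best accuracy, ties toward fewer features
        best_ci, best_gi, best_val = 0, 0, -np.inf
        for ci, count in enumerate(counts):
            gi = int(np.argmax(table[ci]))
            if table[ci, gi] > best_val + 1e-12:
                best_ci, best_gi, best_val = ci, gi, table[ci, gi]
        if per_count:
            acc = count_acc[counts[best_ci]][-1]
            bal = count_bal[counts[best_ci]][-1]
        else:
            acc, bal = refit_score(counts[best_ci], best_gi)
        outer_acc.append(acc)
        outer_bal.append(bal)
        test_indices.append(te.copy())
        fold_rows.append({"fold": fold, "n_features": counts[best_ci],
                          "config": configs[best_gi], "test_accuracy": acc,
                          "test_balanced_accuracy": bal,
                          "inner_accuracy": float(best_val)})

    per_count_mean = None
    per_count_bal_mean = None
    optimal = None
    if per_count:
        per_count_mean = {c: 100 * float(np.mean(v)) for c, v in count_acc.items()}
        per_count_bal_mean = {c: 100 * float(np.mean(v)) for c, v in count_bal.items()}
        best = max(per_count_mean.values())
        optimal = min(c for c, v in per_count_mean.items() if v >= best - 1e-12)
    return CVReport(method=f"{spec.name}"
                           + (f" + {ranking}" if ranking not in (None, "none") and not callable(ranking) else ""),
                    dataset=name,
                    accuracy=100 * float(np.mean(outer_acc)),
                    balanced_accuracy=100 * float(np.mean(outer_bal)),
                    per_count=per_count_mean,
                    per_count_balanced=per_count_bal_mean,
                    optimal_count=optimal,
                    folds=fold_rows, fold_test_indices=test_indices,
                    seed=seed, runtime_s=time.perf_counter() - t0,
                    n_samples=len(y))


# ---------------------------------------------------------------------------
# summary tables

@dataclass
class SummaryTable:
    accuracy: pd.DataFrame          # methods x datasets, plus an Average row
    best: dict[str, list[str]]      # dataset -> best-two methods
    optimal_n: pd.DataFrame | None  # methods x datasets optimal feature count

    def to_csv(self, path) -> None:
        self.accuracy.to_csv(path)


def report_tables(reports: list[CVReport]) -> SummaryTable:
    """Methods x datasets accuracy grid in the shape of the usual tables.

    The two best methods per dataset are flagged; a tie in accuracy resolves
    toward the method using fewer selected attributes.
    """
    if not reports:
        raise ValueError("at least one report required")
    methods = list(dict.fromkeys(r.method for r in reports))
    datasets = list(dict.fromkeys(r.dataset for r in reports))
    acc = pd.DataFrame(index=methods, columns=datasets, dtype=float)
    nopt = pd.DataFrame(index=methods, columns=datasets, dtype="Int64")
    for r in reports:
        acc.loc[r.method, r.dataset] = r.accuracy
        if r.optimal_count is not None:
            nopt.loc[r.method, r.dataset] = r.optimal_count
    best: dict[str, list[str]] = {}
    for ds in datasets:
        col = acc[ds].dropna()

        def sort_key(m):
            n = nopt.loc[m, ds]
            return (-col[m], int(n) if pd.notna(n) else np.inf)

        ranked = sorted(col.index, key=sort_key)
        best[ds] = ranked[:2]
    acc.loc["Average"] = acc.mean(axis=0)
    return SummaryTable(accuracy=acc, best=best,
                        optimal_n=None if nopt.isna().all().all() else nopt)
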