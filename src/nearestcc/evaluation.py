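"""Evaluation protocol: repeated stratified holdout, confusion metrics,
Welch t-tests, a K sweep, and per-cluster Kaplan-Meier survival curves.

Every method in a comparison is fitted and scored on identical train/test
splits within a repeat, so paired differences between methods reflect the
methods and not the draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CohortTable
from .clustering import RngStream
from .classify import (
    NearestCCConfig,
    NearestCCModel,
    make_method,
    predict_with_cluster_tree,
)


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary confusion counts and the derived rates.

    A rate whose denominator is zero is reported as ``None`` (absent),
    never as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    recall = sensitivity

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def error_rate(self) -> float | None:
        acc = self.accuracy
        return None if acc is None else 1.0 - acc

    def __add__(self, other: "ConfusionMetrics") -> "ConfusionMetrics":
        return ConfusionMetrics(self.tp + other.tp, self.fp + other.fp,
                                self.tn + other.tn, self.fn + other.fn)

    def as_row(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "recall": self.recall,
            "accuracy": self.accuracy, "error_rate": self.error_rate,
        }


def confusion_metrics(y_true, y_pred, positive: str = "1") -> ConfusionMetrics:
    """Confusion counts for a binary problem; ``positive`` marks the class
    counted as an event (default "1" = event before threshold)."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = set(y_true.tolist()) | set(y_pred.tolist())
    if len(labels) > 2:
        raise ValueError(f"binary labels required, got {sorted(map(str, labels))}")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMetrics(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def stratified_split(
    y: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified random train/test indices.

    Each class contributes ``round(test_fraction * n_class)`` test rows
    (at least 1, at most n_class - 1 when the class has >= 2 rows).
    """
    y = np.asarray(y, dtype=object)
    test_idx = []
    for lab in sorted(set(y.tolist())):
        idx = np.flatnonzero(y == lab)
        perm = rng.permutation(idx)
        n_test = int(round(test_fraction * len(idx)))
        if len(idx) >= 2:
            n_test = min(max(n_test, 1), len(idx) - 1)
        test_idx.append(perm[:n_test])
    test = np.sort(np.concatenate(test_idx))
    mask = np.ones(len(y), dtype=bool)
    mask[test] = False
    return np.flatnonzero(mask), test


# ---------------------------------------------------------------------------
# Repeated holdout
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Per-method per-repeat error rates plus pooled confusion metrics."""

    errors: pd.DataFrame            # columns: method, repeat, error
    confusion: dict                 # method -> ConfusionMetrics (summed)
    seed: int
    config: dict = field(default_factory=dict)

    def error_vector(self, method: str) -> np.ndarray:
        sub = self.errors[self.errors["method"] == method]
        return sub.sort_values("repeat")["error"].to_numpy()

    def mean_errors(self) -> pd.Series:
        return self.errors.groupby("method")["error"].mean()

    def metrics_frame(self) -> pd.DataFrame:
        rows = [{"method": m, **cm.as_row()} for m, cm in self.confusion.items()]
        return pd.DataFrame(rows)

    def to_csv(self, errors_path, metrics_path=None) -> None:
        self.errors.to_csv(errors_path, index=False)
        if metrics_path is not None:
            self.metrics_frame().to_csv(metrics_path, index=False)


def repeated_holdout(
    table: CohortTable,
    methods: dict,
    repeats: int = 10,
    test_fraction: float = 0.2,
    rng: RngStream | int = 0,
    positive: str = "1",
    per_cluster: bool = True,
) -> ExperimentResult:
    """Repeated stratified 80/20 holdout over a method roster.

    ``methods`` maps a name to a ``(fit, predict)`` pair where
    ``fit(train, seed) -> model`` and ``predict(model, table) -> labels``.
    Within a repeat every method sees the same split. For models exposing
    consensus clusters, each cluster's tree is additionally scored alone on
    the full test set (entries named ``<method>:cluster<j>``).
    """
    if isinstance(rng, int):
        rng = RngStream(rng)
    if table.y is None:
        raise ValueError("labeled table required")
    y_all = np.asarray(table.y, dtype=object)

    rows, conf = [], {}
    for r in range(repeats):
        # re-draw if a class is missing from the training side
        for attempt in range(100):
            g = rng.generator(f"split-{r}-{attempt}")
            train_idx, test_idx = stratified_split(y_all, test_fraction, g)
            if set(y_all[train_idx]) == set(y_all.tolist()):
                break
        else:
            raise RuntimeError("could not draw a split containing every class")
        train, test = table.subset(train_idx), table.subset(test_idx)
        y_test = np.asarray(test.y, dtype=object)

        for name, (fit, predict) in methods.items():
            seed = rng.seed_int(f"fit-{r}-{name}")
            model = fit(train, seed)
            pred = predict(model, test)
            err = float(np.mean(pred != y_test))
            rows.append({"method": name, "repeat": r, "error": err})
            cm = confusion_metrics(y_test, pred, positive=positive)
            conf[name] = conf.get(name, ConfusionMetrics(0, 0, 0, 0)) + cm

            if per_cluster and isinstance(model, NearestCCModel) and len(model.clusters) > 1:
                for j, _c in enumerate(model.clusters):
                    if _c.tree is None:
                        continue  # deferred to fallback; not a cluster model
                    cpred = predict_with_cluster_tree(model, test, j)
                    cerr = float(np.mean(cpred != y_test))
                    cname = f"{name}:cluster{j}"
                    rows.append({"method": cname, "repeat": r, "error": cerr})
                    ccm = confusion_metrics(y_test, cpred, positive=positive)
                    conf[cname] = conf.get(cname, ConfusionMetrics(0, 0, 0, 0)) + ccm

    return ExperimentResult(
        errors=pd.DataFrame(rows), confusion=conf, seed=rng.master_seed,
        config={"repeats": repeats, "test_fraction": test_fraction},
    )


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------

def welch_t(a, b, paired: bool = False) -> tuple[float, float]:
    """Unequal-variance t-test (Welch-Satterthwaite df), two-sided.

    Set ``paired=True`` for a paired t-test on the differences instead.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.array_equal(a, b):
            return 0.0, 1.0
        raise ValueError("both samples are constant; t-test undefined")
    if paired:
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# K sweep
# ---------------------------------------------------------------------------

def sweep_k(
    table: CohortTable,
    k_values=(3, 4, 5, 7, 10),
    config: NearestCCConfig | None = None,
    rng: RngStream | int = 0,
    repeats: int = 10,
    test_fraction: float = 0.2,
    method: str = "nearest-cc",
) -> pd.DataFrame:
    """Error distribution of the classifier for each cluster count K.

    Returns a tidy (k, repeat, error) table, ready for a boxplot. A K
    larger than the training-side row count is skipped with a warning.
    """
    config = config or NearestCCConfig()
    if isinstance(rng, int):
        rng = RngStream(rng)
    n_train = table.n_rows - int(round(test_fraction * table.n_rows))
    frames = []
    for k in k_values:
        if k > n_train:
            warnings.warn(f"skipping k={k}: larger than training size {n_train}")
            continue
        cfg = dc_replace(config, k=int(k))
        res = repeated_holdout(
            table, {method: make_method(method, cfg)},
            repeats=repeats, test_fraction=test_fraction,
            rng=RngStream(rng.seed_int(f"sweep-k-{k}")), per_cluster=False,
        )
        sub = res.errors[res.errors["method"] == method].copy()
        sub.insert(0, "k", int(k))
        frames.append(sub[["k", "repeat", "error"]])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve over the distinct event times.

    ``survival[i]`` is S(t_i) = prod_{j<=i} (1 - d_j / n_j); S is 1 before
    the first event time. Censored observations shrink later risk sets but
    produce no step.
    """

    times: np.ndarray       # distinct event times, ascending
    at_risk: np.ndarray     # n_i just before each event time
    events: np.ndarray      # d_i events at each time
    survival: np.ndarray    # S(t_i)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (1.0 before the first event)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "n_risk": self.at_risk,
            "n_event": self.events, "survival": self.survival,
        })


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` is 1 where the event was observed, 0 where the observation
    is right-censored (the event is only known to lie beyond that time).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    if t.shape != e.shape:
        raise ValueError("times and events must align")
    if np.any(t < 0):
        raise ValueError("negative times")
    event_times = np.unique(t[e == 1])
    at_risk = np.empty(len(event_times))
    d = np.empty(len(event_times))
    surv = np.empty(len(event_times))
    s = 1.0
    for i, ti in enumerate(event_times):
        n_i = float(np.sum(t >= ti))
        d_i = float(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d_i / n_i
        at_risk[i], d[i], surv[i] = n_i, d_i, s
    return KMCurve(times=event_times, at_risk=at_risk, events=d, survival=surv)


def km_by_cluster(model: NearestCCModel, table: CohortTable) -> dict[int, KMCurve]:
    """One survival curve per consensus cluster.

    Every row of ``table`` (training or held-out) is routed to its
    linkage-nearest cluster; the product-limit curve is estimated within
    each resulting group.
    """
    from .classify import route
    from .core_data import apply_scaler

    if table.time is None or table.event is None:
        raise ValueError("time and event columns required")
    filled = model.imputer.apply(table)
    Xs = apply_scaler(model.scaler, filled.X)
    assign = np.array([route(x, model) for x in Xs])
    out = {}
    for j, c in enumerate(model.clusters):
        idx = np.flatnonzero(assign == j)
        if idx.size:
            out[c.label] = km_estimate(table.time[idx], table.event[idx])
    return out
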