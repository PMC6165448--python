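"""Gaussian-kernel probabilistic neural network (PNN) classification with
exact leave-one-out (LOO) evaluation and exhaustive feature-subset search.

The PNN scores a query x against each class c by the average Gaussian
kernel over that class's stored patterns,

    score_c(x) = (1/n_c) * sum_i exp(-||x - x_{c,i}||^2 / (2 sigma_k^2)),

and assigns the arg-max class (ties broken deterministically by lowest
class index).  As sigma_k -> 0 the rule converges to 1-nearest-neighbour.

Features are z-normalized (pooled mean/sd over all patterns of the
classes involved).  Inside LOO the normalization can either be recomputed
from each fold's n-1 training patterns (``norm="fold"``, the default --
no information leaks from the held-out pattern) or computed once over the
whole set (``norm="pooled"``, the literal single-pass procedure).

Kernel-width policies: a fixed float; ``"grid"`` (default for the subset
search) evaluating {0.05, 0.1, 0.2, 0.5, 1, 2} x sqrt(p) by the same LOO
accuracy that ranks subsets; or ``"nested"``, selecting sigma per fold by
an inner LOO on the n-1 training patterns only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TruthTable",
    "PNNModel",
    "normalize",
    "pnn_score",
    "pnn_classify",
    "loo_evaluate",
    "subset_search",
    "SIGMA_GRID",
]

SIGMA_GRID = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0)
_VAR_EPS = 1e-12


@dataclass
class TruthTable:
    """LOO confusion counts, true class (rows) x assigned class (columns)."""

    counts: np.ndarray
    classes: tuple

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def per_class_recall(self) -> dict:
        row = self.counts.sum(axis=1)
        return {
            c: float(self.counts[i, i] / row[i]) if row[i] else float("nan")
            for i, c in enumerate(self.classes)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def normalize(X: np.ndarray, warn: bool = True):
    """Pooled z-normalization; constant features are dropped with a warning.

    Returns (X_normalized, mean, sd, kept_index).
    """
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > _VAR_EPS)
    dropped = np.flatnonzero(sd <= _VAR_EPS)
    if dropped.size and warn:
        warnings.warn(f"dropping zero-variance features at indices {dropped.tolist()}", stacklevel=2)
    Xn = (X[:, kept] - mu[kept]) / sd[kept]
    return Xn, mu, sd, kept


@dataclass
class PNNModel:
    """Stored training patterns per class with a Gaussian kernel width."""

    patterns: dict  # class label -> (n_c, p) array
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("kernel width must be positive")
        for c, X in self.patterns.items():
            if len(X) == 0:
                raise ValueError(f"class {c!r} has no stored patterns")


def pnn_score(model: PNNModel, query: np.ndarray) -> dict:
    """Per-class average-Gaussian-kernel scores (plain, not log-domain)."""
    q = np.asarray(query, dtype=np.float64)
    if np.isnan(q).any():
        raise ValueError("query has missing features; pattern rejected")
    out = {}
    for c, X in model.patterns.items():
        d2 = ((np.asarray(X, dtype=np.float64) - q) ** 2).sum(axis=1)
        out[c] = float(np.exp(-d2 / (2.0 * model.sigma**2)).mean())
    return out


def pnn_classify(model: PNNModel, query: np.ndarray):
    """Arg-max class; computed stably in the shifted domain so that the
    sigma -> 0 limit reduces to 1-nearest-neighbour, ties to the first
    registered class."""
    q = np.asarray(query, dtype=np.float64)
    if np.isnan(q).any():
        raise ValueError("query has missing features; pattern rejected")
    labels = list(model.patterns)
    d2 = [((np.asarray(model.patterns[c], dtype=np.float64) - q) ** 2).sum(axis=1) for c in labels]
    shift = min(float(d.min()) for d in d2)
    scores = [float(np.exp(-(d - shift) / (2.0 * model.sigma**2)).mean()) for d in d2]
    return labels[int(np.argmax(scores))]


# ---------------------------------------------------------------------------
# vectorized exact-LOO core


def _fold_weights(X: np.ndarray, norm: str) -> np.ndarray:
    """Per-fold inverse-variance feature weights, shape (n, p).

    Row i holds 1/var computed over all patterns but i (norm="fold") or
    over all patterns (norm="pooled").  Features with (near-)zero fold
    variance get weight 0, i.e. are ignored in that fold.
    """
    n = X.shape[0]
    if norm == "pooled":
        var = X.var(axis=0)
        w = np.where(var > _VAR_EPS, 1.0 / np.maximum(var, _VAR_EPS), 0.0)
        return np.broadcast_to(w, X.shape).copy()
    if norm != "fold":
        raise ValueError("norm must be 'fold' or 'pooled'")
    mu = X.mean(axis=0)
    m2 = (X**2).mean(axis=0)
    mu_i = (n * mu - X) / (n - 1)
    ex2_i = (n * m2 - X**2) / (n - 1)
    var_i = ex2_i - mu_i**2
    return np.where(var_i > _VAR_EPS, 1.0 / np.maximum(var_i, _VAR_EPS), 0.0)


def _loo_assignments(diff2, w, y_idx, n_classes, sigma):
    """Assigned class index for every pattern under exact LOO.

    diff2: (n, n, p) squared per-feature differences of the raw patterns;
    w: (n, p) per-fold inverse variances (normalization is affine, so the
    fold's normalized squared distance is the w-weighted raw distance).
    """
    n = diff2.shape[0]
    D = np.einsum("ijf,if->ij", diff2, w)
    np.fill_diagonal(D, np.inf)
    # subtract the row-min before exponentiating: a per-query constant
    # factor that prevents underflow and preserves the arg-max
    Dmin = D.min(axis=1, keepdims=True)
    E = np.exp(-(D - Dmin) / (2.0 * sigma**2))
    E[~np.isfinite(D)] = 0.0
    Y = np.zeros((n, n_classes))
    Y[np.arange(n), y_idx] = 1.0
    counts = Y.sum(axis=0)
    denom = counts[None, :] - Y  # own class excludes the held-out pattern
    S = (E @ Y) / denom
    return np.argmax(S, axis=1)


def _sigma_list(policy, p):
    scale = np.sqrt(p)
    if isinstance(policy, (int, float)):
        return [float(policy)]
    if policy in ("grid", "auto"):
        return [s * scale for s in SIGMA_GRID]
    raise ValueError(f"unknown sigma policy {policy!r}")


def loo_evaluate(
    X: np.ndarray,
    y,
    subset=None,
    sigma="grid",
    norm: str = "fold",
    classes: tuple | None = None,
):
    """Exact leave-one-out evaluation of the PNN on a feature subset.

    Returns (TruthTable, sigma_used).  ``sigma`` may be a float, "grid"
    (sigma chosen by LOO accuracy over the default grid), or "nested"
    (sigma chosen per fold by inner LOO on the training patterns only).
    Every class must hold at least 2 patterns.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if classes is None:
        classes = tuple(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("discrimination needs at least 2 classes")
    y_idx = np.array([list(classes).index(c) for c in y])
    counts = np.bincount(y_idx, minlength=len(classes))
    if (counts < 2).any():
        raise ValueError("leave-one-out needs at least 2 patterns per class")
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("feature subset must be nonempty")
        X = X[:, subset]
    if np.isnan(X).any():
        raise ValueError("patterns with missing features must be removed before LOO")

    n, p = X.shape
    if sigma == "nested":
        assigned = _nested_loo(X, y_idx, len(classes), norm)
        sigma_used = float("nan")
    else:
        diff2 = (X[:, None, :] - X[None, :, :]) ** 2
        w = _fold_weights(X, norm)
        best = None
        for s in _sigma_list(sigma, p):
            a = _loo_assignments(diff2, w, y_idx, len(classes), s)
            acc = float((a == y_idx).mean())
            if best is None or acc > best[0]:
                best = (acc, s, a)
        _, sigma_used, assigned = best

    tt = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(tt, (y_idx, assigned), 1)
    return TruthTable(tt, tuple(classes)), sigma_used


def _nested_loo(X, y_idx, n_classes, norm):
    """Per-fold sigma selection by inner LOO on the n-1 training patterns."""
    n, p = X.shape
    assigned = np.empty(n, dtype=np.int64)
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        Xt, yt = X[keep], y_idx[keep]
        diff2 = (Xt[:, None, :] - Xt[None, :, :]) ** 2
        w = _fold_weights(Xt, norm)
        best = None
        for s in _sigma_list("grid", p):
            a = _loo_assignments(diff2, w, yt, n_classes, s)
            acc = float((a == yt).mean())
            if best is None or acc > best[0]:
                best = (acc, s)
        sigma_i = best[1]
        # classify the held-out pattern with training-set normalization
        mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
        wf = np.where(sd > _VAR_EPS, 1.0 / np.maximum(sd, _VAR_EPS), 0.0)
        Xn = (Xt - mu) * wf
        qn = (X[i] - mu) * wf
        model = PNNModel(
            {c: Xn[yt == c] for c in range(n_classes) if (yt == c).any()}, sigma_i
        )
        assigned[i] = pnn_classify(model, qn)
    return assigned


@dataclass
class SearchResult:
    subset: tuple
    truth_table: TruthTable
    sigma: float
    ranked: pd.DataFrame


def subset_search(
    X: np.ndarray,
    y,
    max_size: int = 3,
    sigma="grid",
    norm: str = "fold",
    feature_names=None,
    force: bool = False,
    top_k: int = 20,
) -> SearchResult:
    """Exhaustively evaluate every feature subset of size 1..max_size.

    Returns the subset with maximal LOO accuracy; ties go to fewer
    features, then lexicographic feature order (both implicit in the
    ascending-size, lexicographic enumeration with strict improvement).
    Sizes above 6 require ``force=True`` (combinatorial guard).
    """
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if not 1 <= max_size <= p:
        raise ValueError("max_size must be in [1, n_features]")
    if max_size > 6 and not force:
        raise ValueError("max_size > 6 enumerates >376k subsets; pass force=True")
    if feature_names is None:
        feature_names = [str(i) for i in range(p)]

    y = np.asarray(y)
    classes = tuple(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("discrimination needs at least 2 classes")
    y_idx = np.array([list(classes).index(c) for c in y])
    n_classes = len(classes)

    # shared precomputation: raw squared per-feature differences and the
    # per-fold inverse variances (both independent of the subset)
    diff2_full = (X[:, None, :] - X[None, :, :]) ** 2
    w_full = _fold_weights(X, norm)

    records = []
    best = None  # (accuracy, subset, sigma, assignments)
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(range(p), size):
            idx = list(subset)
            diff2 = diff2_full[:, :, idx]
            w = w_full[:, idx]
            sub_best = None
            for s in _sigma_list(sigma, size):
                a = _loo_assignments(diff2, w, y_idx, n_classes, s)
                acc = float((a == y_idx).mean())
                if sub_best is None or acc > sub_best[0]:
                    sub_best = (acc, s, a)
            acc, s_used, a = sub_best
            records.append((subset, acc, s_used))
            if best is None or acc > best[0]:
                best = (acc, subset, s_used, a)

    acc, subset, s_used, a = best
    tt = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(tt, (y_idx, a), 1)
    ranked = pd.DataFrame(records, columns=["subset", "accuracy", "sigma"])
    ranked["features"] = ranked["subset"].map(lambda t: tuple(feature_names[i] for i in t))
    ranked = ranked.sort_values(
        ["accuracy", "subset"], ascending=[False, True], kind="stable"
    ).head(top_k).reset_index(drop=True)
    return SearchResult(subset, TruthTable(tt, classes), s_used, ranked)
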