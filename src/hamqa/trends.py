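"""Storage-time trend modelling and group-mean comparison.

Two tools used throughout the shelf-life analysis:

* ``fit_trend`` -- least-squares second-order polynomial of a feature
  against storage day, with Spearman rank correlation between observed
  and fitted values as the goodness-of-fit statistic; a fit is accepted
  when |r| exceeds the threshold (default 0.2).
* ``compare_groups`` -- one-way ANOVA followed by Tukey HSD at alpha
  0.05, with a compact letter display: groups sharing no letter differ
  significantly.
"""

from __future__ import annotations

from dataclasses import dataclass

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendFit",
    "GroupComparison",
    "spearman",
    "fit_trend",
    "compare_groups",
    "day_effect_scan",
]


@dataclass(frozen=True)
class TrendFit:
    """value = c0 + c1*day + c2*day^2 with Spearman goodness of fit."""

    c0: float
    c1: float
    c2: float
    spearman_r: float
    accepted: bool

    def predict(self, day):
        day = np.asarray(day, dtype=float)
        return self.c0 + self.c1 * day + self.c2 * day**2


def spearman(x, y) -> float:
    """Spearman rank correlation (midranks for ties); NaN when either
    variable has zero rank variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length series with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def fit_trend(days, values, threshold: float = 0.2, against: str = "fitted") -> TrendFit:
    """Quadratic least-squares trend of ``values`` over storage ``days``.

    Goodness of fit is the Spearman correlation of observed values with
    the fitted curve (``against="fitted"``, default) or with the days
    themselves (``against="day"``).  Accepted iff |r| > threshold.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size != values.size or days.size < 4:
        raise ValueError("need at least 4 (day, value) points")
    if np.unique(days).size < 3:
        raise ValueError("need at least 3 distinct days for a quadratic fit")
    c2, c1, c0 = np.polyfit(days, values, 2)
    fitted = c0 + c1 * days + c2 * days**2
    if against == "fitted":
        r = spearman(values, fitted) if np.unique(np.round(fitted, 12)).size > 1 else float("nan")
    elif against == "day":
        r = spearman(days, values)
    else:
        raise ValueError("against must be 'fitted' or 'day'")
    accepted = bool(np.isfinite(r) and abs(r) > threshold)
    return TrendFit(float(c0), float(c1), float(c2), r, accepted)


@dataclass
class GroupComparison:
    """Per-group mean +/- sd with compact letter display at alpha 0.05."""

    groups: tuple
    means: dict
    sds: dict
    ns: dict
    letters: dict
    anova_p: float
    significant_pairs: set


def compare_groups(values_by_group: dict, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA + Tukey HSD with a compact letter display.

    Groups sharing no letter differ significantly (p < alpha).  If every
    group has zero internal variance the comparison degenerates to exact
    equality of the group constants.
    """
    groups = tuple(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    means = {g: float(a.mean()) for g, a in arrays.items()}
    sds = {g: float(a.std(ddof=1)) for g, a in arrays.items()}
    ns = {g: int(a.size) for g, a in arrays.items()}

    if all(a.std() == 0 for a in arrays.values()):
        # degenerate: group by exact equality of the constants
        sig = {
            frozenset((g1, g2))
            for i, g1 in enumerate(groups)
            for g2 in groups[i + 1 :]
            if means[g1] != means[g2]
        }
        anova_p = float("nan")
    else:
        anova_p = float(stats.f_oneway(*arrays.values()).pvalue)
        sig = _tukey_significant_pairs(arrays, alpha)

    letters = _letter_display(groups, means, sig)
    return GroupComparison(groups, means, sds, ns, letters, anova_p, sig)


@lru_cache(maxsize=256)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def _tukey_significant_pairs(arrays: dict, alpha: float) -> set:
    """Tukey-Kramer HSD decisions via the studentized-range distribution.

    The critical value is cached per (alpha, k, df); decisions agree with
    statsmodels' pairwise_tukeyhsd (p-values are not computed here).
    """
    groups = list(arrays)
    k = len(groups)
    ns = {g: a.size for g, a in arrays.items()}
    means = {g: a.mean() for g, a in arrays.items()}
    N = sum(ns.values())
    df = N - k
    mse = sum(((a - means[g]) ** 2).sum() for g, a in arrays.items()) / df
    if mse <= 0:  # identical within-group values but unequal means
        return {
            frozenset((g1, g2))
            for i, g1 in enumerate(groups)
            for g2 in groups[i + 1 :]
            if means[g1] != means[g2]
        }
    q = _q_crit(alpha, k, df)
    sig = set()
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            if abs(means[g1] - means[g2]) > q * se:
                sig.add(frozenset((g1, g2)))
    return sig


def _letter_display(groups, means, significant_pairs):
    """Greedy insert-and-absorb compact letter display.

    Start from one letter covering all groups; for each significant pair
    sharing a letter, split that letter; absorb letters that became
    subsets of others.  Letters are named a, b, c... over groups sorted
    by descending mean; deterministic throughout.
    """
    order = sorted(groups, key=lambda g: (-means[g], str(g)))
    sets = [set(order)]
    for g1, g2 in sorted(significant_pairs, key=lambda p: sorted(map(str, p))):
        g1, g2 = sorted(p_ := (g1, g2), key=str)
        for s in list(sets):
            if g1 in s and g2 in s:
                sets.remove(s)
                sets.extend([s - {g1}, s - {g2}])
        sets = [s for s in sets if s]
        # absorb subsets
        sets = [s for s in sets if not any(s < t for t in sets)]
        # deduplicate
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    # order letters by the best-ranked group they contain
    rank = {g: i for i, g in enumerate(order)}
    sets.sort(key=lambda s: min(rank[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for li, s in enumerate(sets):
        for g in order:
            if g in s:
                letters[g] += alphabet[li % 26]
    return letters


def day_effect_scan(
    data: pd.DataFrame,
    variables: list[str],
    day_col: str = "day",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable comparison of group means across storage days.

    A variable is ``flagged`` when its one-way ANOVA across days has
    p < alpha.  ``direction`` is the sign of (last-day mean - first-day
    mean); ``first_last_significant`` reports whether the Tukey pair
    (first day, last day) rejects.
    """
    days = sorted(data[day_col].unique())
    if len(days) < 2:
        raise ValueError("need at least 2 sampling days")
    rows = []
    for var in variables:
        by_day = {d: data.loc[data[day_col] == d, var].to_numpy() for d in days}
        if any(len(v) < 2 for v in by_day.values()):
            raise ValueError(f"variable {var!r}: every day needs >= 2 replicates")
        cmp = compare_groups(by_day, alpha=alpha)
        delta = cmp.means[days[-1]] - cmp.means[days[0]]
        rows.append(
            {
                "variable": var,
                "anova_p": cmp.anova_p,
                "flagged": bool(np.isfinite(cmp.anova_p) and cmp.anova_p < alpha),
                "direction": int(np.sign(delta)),
                "first_last_significant": frozenset((days[0], days[-1])) in cmp.significant_pairs,
                "first_mean": cmp.means[days[0]],
                "last_mean": cmp.means[days[-1]],
            }
        )
    return pd.DataFrame(rows)
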