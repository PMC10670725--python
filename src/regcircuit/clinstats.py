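"""Clinicopathological association statistics for hub features.

Per-hub analyses mirror the standard oncology toolkit: ROC/AUC for
tumor-versus-normal discrimination, Kruskal-Wallis plus pairwise
Mann-Whitney across pathologic T stages, Kaplan-Meier overall-survival
curves compared by log-rank between the lower and upper expression
quartiles, and Pearson correlation for regulator-target pairs with the
inverse-significance gate p <= 0.05 and r <= -0.3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import floor

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)

T_STAGES = ("T1", "T2", "T3", "T4")

AUC_BANDS = (
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "fair"),
    (0.6, "poor"),
    (0.5, "failure"),
)


@dataclass(frozen=True)
class RocResult:
    auc: float
    orientation: str  # "as-is" or "flipped"
    n_pos: int
    n_neg: int
    band: str


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve as a right-continuous step function."""

    times: np.ndarray  # sorted distinct drop times
    survival: np.ndarray  # S(t) just after each drop time

    def __call__(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass(frozen=True)
class SurvivalComparison:
    km_low: KMCurve
    km_high: KMCurve
    logrank_stat: float
    p_value: float
    n_low: int
    n_high: int
    valid: bool = True


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    inverse_significant: bool


def auc_band(auc: float) -> str:
    for cut, name in AUC_BANDS:
        if auc >= cut:
            return name
    return "failure"


def roc_auc(values, labels) -> RocResult:
    """AUC via the rank (Mann-Whitney) statistic, ties getting half credit.

    ``labels`` marks the positive class: booleans, or "tumor"/"normal"
    strings.  Equals the probability that a random positive value exceeds
    a random negative one; orientation is flipped (and recorded) when the
    raw AUC falls below 0.5, matching the convention that a marker's
    discriminative power is reported irrespective of its direction.
    """
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind == "b":
        pos = lab
    elif lab.dtype.kind in "iuf":
        pos = lab.astype(bool)
    else:
        s = lab.astype(str)
        if not np.isin(s, ["tumor", "normal"]).all():
            raise ValueError("labels must be tumor/normal or boolean")
        pos = s == "tumor"
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(x)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    orientation = "as-is"
    if auc < 0.5:
        auc, orientation = 1.0 - auc, "flipped"
    return RocResult(float(auc), orientation, n_pos, n_neg, auc_band(auc))


def quartile_stratify(expression: pd.Series) -> tuple[list, list]:
    """Lower- and upper-quartile sample groups, each of size floor(n/4).

    Samples are ordered by expression with a deterministic lexicographic
    tie-break on sample ID at the boundaries; the groups are disjoint.
    """
    n = len(expression)
    if n < 4:
        raise ValueError("quartile stratification needs >=4 samples")
    m = floor(n / 4)
    order = sorted(expression.index, key=lambda s: (expression[s], str(s)))
    return order[:m], order[-m:]


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(0) = 1; the curve drops only at event times; censored subjects leave
    the risk set after their time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("survival times must be nonnegative")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_.iloc[:, 0]
    drop_times = sf.index.values.astype(float)
    keep = drop_times > 0
    return KMCurve(times=drop_times[keep], survival=sf.values[keep])


def logrank_test(group_a, group_b) -> SurvivalComparison:
    """Two-group log-rank test; ``group_a``/``group_b`` are (times, events).

    Statistic is (sum O - E)^2 / sum Var over distinct event times, with p
    from a 1-df chi-square.  By convention group_a is the low-expression
    group in quartile comparisons.  If neither group has any event the
    statistic is undefined and the result is flagged ``valid=False``.
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    km_a, km_b = km_estimate(ta, ea), km_estimate(tb, eb)
    if ea.sum() + eb.sum() == 0:
        return SurvivalComparison(km_a, km_b, float("nan"), float("nan"),
                                  len(ta), len(tb), valid=False)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return SurvivalComparison(
        km_a, km_b, float(res.test_statistic), float(res.p_value),
        len(ta), len(tb), valid=True,
    )


def kruskal_wallis(values, group_labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (g-1 df).

    The degenerate all-tied configuration is defined as H = 0, p = 1.
    """
    v = np.asarray(values, dtype=float)
    labs = np.asarray(group_labels)
    groups = [v[labs == g] for g in pd.unique(labs)]
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("each group must be nonempty")
    if np.all(v == v[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for sample a).

    Exact enumeration when n_a + n_b <= 12 and there are no ties;
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_inverse(x, y) -> CorrelationResult:
    """Pearson r with two-sided t-test p (n-2 df) and the inverse gate.

    ``inverse_significant`` is true iff p <= 0.05 and r <= -0.3.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv):
        raise ValueError("x and y must have equal length")
    if len(xv) < 3:
        raise ValueError("need n >= 3")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(xv, yv)
    return CorrelationResult(float(r), float(p), bool(p <= 0.05 and r <= -0.3))


def t_stage_association(
    expression: pd.Series, t_stage: pd.Series, adjust_pairwise: bool = False
) -> dict:
    """Kruskal-Wallis across T1-T4 plus all pairwise Mann-Whitney tests.

    Samples missing a T-stage annotation are dropped (logged).  Pairwise
    p-values are reported unadjusted by default; ``adjust_pairwise``
    applies BH over the pairwise family.
    """
    common = expression.index.intersection(t_stage.index)
    stage = t_stage.loc[common]
    keep = stage.notna()
    if (~keep).sum():
        log.info("dropping %d samples without T stage", int((~keep).sum()))
    stage = stage[keep]
    expr = expression.loc[stage.index]
    present = [s for s in T_STAGES if (stage == s).any()]
    if len(present) < 2:
        raise ValueError("need >=2 T-stage groups with samples")
    h, p = kruskal_wallis(expr.values, stage.values)
    pairs, pvals = [], []
    for s1, s2 in combinations(present, 2):
        _, mp = mann_whitney(expr[stage == s1].values, expr[stage == s2].values)
        pairs.append(f"{s1}v{s2}")
        pvals.append(mp)
    if adjust_pairwise and pvals:
        pvals = list(bh_adjust(pvals))
    return {
        "kw_stat": h,
        "kw_p": p,
        "pairwise": dict(zip(pairs, pvals)),
        "n": int(len(stage)),
    }
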