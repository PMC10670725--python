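"""Differential expression of tumor versus normal count matrices.

The statistical model is a negative-binomial (NB) Wald test in the DESeq2
style: median-of-ratios size factors, a per-feature method-of-moments
dispersion estimate (``var = mu + alpha * mu**2``), and an unshrunk log2
fold change (tumor over normal) tested against a standard-normal
reference.  The shrinkage and outlier-replacement machinery of dedicated
DE packages is deliberately not reproduced; the simplifications are
documented in docs/methods.md.

Directional calls follow the usual two-threshold convention: genes need
``p_adj <= alpha`` and ``|log2FC| >= 1`` while miRNAs need only
``p_adj <= alpha`` and a nonzero fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TUMOR = "tumor"
NORMAL = "normal"

#: pseudo-count added to group means before taking log2 ratios
DEFAULT_EPSILON = 0.5

RESULT_COLUMNS = ["base_mean", "log2fc", "se", "wald_stat", "p_value", "p_adj", "call"]


@dataclass
class CountMatrix:
    """Integer feature x sample counts with tumor/normal labels.

    Parameters
    ----------
    counts
        DataFrame indexed by feature ID, one column per sample.
    condition
        Series mapping sample ID to ``"tumor"`` or ``"normal"``.
    kind
        ``"mRNA"`` or ``"miRNA"``; controls downstream call thresholds.
    """

    counts: pd.DataFrame
    condition: pd.Series
    kind: str = "mRNA"

    def __post_init__(self) -> None:
        if self.kind not in ("mRNA", "miRNA"):
            raise ValueError(f"kind must be 'mRNA' or 'miRNA', got {self.kind!r}")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()].tolist()
            raise ValueError(f"samples without condition label: {missing[:5]}")
        bad = set(self.condition.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"condition labels must be tumor/normal, got {sorted(bad)}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        for grp in (TUMOR, NORMAL):
            if (self.condition == grp).sum() == 0:
                raise ValueError(f"no {grp} samples present")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, group: str) -> pd.Index:
        return self.condition.index[self.condition == group]


@dataclass(frozen=True)
class DirectionalSets:
    """Up/down feature sets produced by :func:`call_differential`."""

    up: frozenset = field(default_factory=frozenset)
    down: frozenset = field(default_factory=frozenset)
    kind: str = "mRNA"

    @property
    def all(self) -> frozenset:
        return self.up | self.down

    def direction_of(self, feature: str) -> str | None:
        if feature in self.up:
            return "up"
        if feature in self.down:
            return "down"
        return None


def estimate_size_factors(cm: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    Each sample's factor is the median over reference features of
    ``count / geometric_mean(feature)``.  By default only features with
    strictly positive counts in every sample form the reference; with
    ``pseudo_reference=True`` the geometric mean is taken over positive
    entries only, which rescues sparse matrices at the cost of a less
    standard reference.
    """
    counts = cm.counts.values.astype(float)
    if pseudo_reference:
        logs = np.where(counts > 0, np.log(np.where(counts > 0, counts, 1.0)), 0.0)
        n_pos = (counts > 0).sum(axis=1)
        usable = n_pos > 0
        log_geo = np.where(usable, logs.sum(axis=1) / np.maximum(n_pos, 1), np.nan)
        if not usable.any():
            raise ValueError("no feature with any positive count; cannot normalize")
        ratios = np.where(counts > 0, counts / np.exp(log_geo)[:, None], np.nan)
        ratios = ratios[usable]
        factors = np.nanmedian(ratios, axis=0)
    else:
        all_pos = (counts > 0).all(axis=1)
        if not all_pos.any():
            raise ValueError(
                "no feature has positive counts in every sample; "
                "retry with pseudo_reference=True"
            )
        ref = counts[all_pos]
        log_geo = np.mean(np.log(ref), axis=1)
        factors = np.median(ref / np.exp(log_geo)[:, None], axis=0)
    if (factors <= 0).any() or np.isnan(factors).any():
        raise ValueError("degenerate size factors; inspect input counts")
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(
    cm: CountMatrix, sf: pd.Series, epsilon: float = DEFAULT_EPSILON
) -> pd.DataFrame:
    """Per-feature NB Wald test of tumor versus normal.

    Returns a DataFrame indexed by feature with columns ``base_mean``
    (mean normalized count over all samples), ``log2fc`` (tumor over
    normal with pseudo-count ``epsilon``), ``se``, ``wald_stat``,
    ``p_value`` and BH-adjusted ``p_adj``.  Features with zero counts in
    every sample are not tested (NaN p-values, excluded from the BH
    denominator) and are pre-filled with ``call='ns'``.
    """
    for grp in (TUMOR, NORMAL):
        if (cm.condition == grp).sum() < 2:
            raise ValueError(f"need >=2 {grp} samples for a Wald test")
    sf = sf.reindex(cm.sample_ids)
    if sf.isna().any():
        raise ValueError("size factors missing for some samples")
    norm = cm.counts.values / sf.values
    is_t = (cm.condition == TUMOR).values

    t, n = norm[:, is_t], norm[:, ~is_t]
    n_t, n_n = t.shape[1], n.shape[1]
    mean_t, mean_n = t.mean(axis=1), n.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion, pooled across groups, floored at 0
    var_t, var_n = t.var(axis=1, ddof=1), n.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        exc_t = np.where(mean_t > 0, (var_t - mean_t) / mean_t**2, 0.0)
        exc_n = np.where(mean_n > 0, (var_n - mean_n) / mean_n**2, 0.0)
    alpha = np.maximum(((n_t - 1) * exc_t + (n_n - 1) * exc_n) / (n_t + n_n - 2), 0.0)

    # delta-method SE of log2 of each (group mean + epsilon); the Poisson
    # part of the NB variance picks up the 1/sf scaling of normalization
    inv_sf = 1.0 / sf.values
    m_inv_t, m_inv_n = inv_sf[is_t].mean(), inv_sf[~is_t].mean()
    var_mean_t = (mean_t * m_inv_t + alpha * mean_t**2) / n_t
    var_mean_n = (mean_n * m_inv_n + alpha * mean_n**2) / n_n
    ln2sq = np.log(2.0) ** 2
    var_log = var_mean_t / ((mean_t + epsilon) ** 2 * ln2sq) + var_mean_n / (
        (mean_n + epsilon) ** 2 * ln2sq
    )
    se = np.sqrt(var_log)

    log2fc = np.log2((mean_t + epsilon) / (mean_n + epsilon))
    tested = cm.counts.values.sum(axis=1) > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(tested, p, np.nan)
    z = np.where(tested, z, np.nan)

    p_adj = np.full_like(p, np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(p[tested])

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_stat": z,
            "p_value": p,
            "p_adj": p_adj,
            "call": "ns",
        },
        index=cm.feature_ids,
    )


def call_differential(
    result: pd.DataFrame,
    kind: str,
    lfc_threshold: float | None = None,
    alpha: float = 0.05,
) -> DirectionalSets:
    """Directional DE calls; annotates ``result['call']`` in place.

    Genes: up iff ``log2fc >= lfc_threshold`` (default 1) and
    ``p_adj <= alpha``; down symmetric.  miRNAs: up iff ``log2fc > 0``
    and ``p_adj <= alpha``; down symmetric (threshold strict at 0).
    """
    if kind not in ("mRNA", "miRNA"):
        raise ValueError(f"kind must be 'mRNA' or 'miRNA', got {kind!r}")
    if lfc_threshold is None:
        lfc_threshold = 1.0 if kind == "mRNA" else 0.0
    sig = result["p_adj"].values <= alpha
    sig = np.where(np.isnan(result["p_adj"].values), False, sig)
    lfc = result["log2fc"].values
    if kind == "mRNA":
        up = sig & (lfc >= lfc_threshold)
        down = sig & (lfc <= -lfc_threshold)
    else:
        up = sig & (lfc > lfc_threshold)
        down = sig & (lfc < -lfc_threshold)
    result["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    idx = result.index
    return DirectionalSets(
        up=frozenset(idx[up]), down=frozenset(idx[down]), kind=kind
    )


def vst_like_transform(cm: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    """``log2(normalized count + 1)`` expression matrix.

    A monotone variance-stabilizing surrogate; its only downstream uses
    (quartile stratification, rank tests, correlation) depend on ranks
    or near-linear trends, not on the exact transform.
    """
    sf = sf.reindex(cm.sample_ids)
    return pd.DataFrame(
        np.log2(cm.counts.values / sf.values + 1.0),
        index=cm.feature_ids,
        columns=cm.sample_ids,
    )
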