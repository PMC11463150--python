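"""Stratified nonparametric association battery.

Group comparisons are rank-based (Mann-Whitney U, Kruskal-Wallis),
descriptives are reported as mean ± SD, correlations default to Spearman,
and the food-addiction 2x2 comparison uses Fisher's exact test by
default.  All tests are two-sided; no multiple-testing correction is
applied, but reports carry the number of tests performed.

The test statistics themselves are delegated to scipy.stats; this module
fixes the conventions (exact vs normal approximation, continuity and tie
corrections, degenerate-input handling) used throughout the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mlgs import SignalingGroup

__all__ = [
    "MannWhitneyResult",
    "KruskalWallisResult",
    "CorrelationResult",
    "PrevalenceComparison",
    "GroupComparison",
    "mann_whitney_u",
    "kruskal_wallis",
    "spearman",
    "prevalence_test",
    "compare_groups_stratified",
]

logger = logging.getLogger(__name__)

#: pooled sample size at or below which a tie-free Mann-Whitney test is exact
EXACT_MW_LIMIT = 16


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str          # "exact" | "asymptotic"
    n_x: int
    n_y: int


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    continuity: bool = True,
    method: str = "auto",
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration is used for tie-free pooled samples of at most
    16 observations; otherwise the normal approximation with tie
    correction (and, by default, continuity correction) applies.
    A pooled sample that is entirely constant yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # no rank information at all
        return MannWhitneyResult(x.size * y.size / 2.0, 1.0, "degenerate", x.size, y.size)
    if method == "auto":
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (tie_free and pooled.size <= EXACT_MW_LIMIT) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=continuity
    )
    return MannWhitneyResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), method, x.size, y.size
    )


@dataclass(frozen=True)
class KruskalWallisResult:
    h: float
    p_value: float
    df: int
    group_sizes: tuple[int, ...]


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> KruskalWallisResult:
    """Kruskal-Wallis H test with tie correction, chi-square reference.

    All-constant pooled input yields H = 0, p = 1 by convention.
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("Kruskal-Wallis requires at least two non-empty groups")
    sizes = tuple(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return KruskalWallisResult(0.0, 1.0, len(arrays) - 1, sizes)
    h, p = stats.kruskal(*arrays)
    return KruskalWallisResult(float(h), float(p), len(arrays) - 1, sizes)


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    method: str
    r: Optional[float]
    p_value: Optional[float]
    n: int
    stratum: Optional[str] = None
    defined: bool = True


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
    stratum: Optional[str] = None,
    method: str = "spearman",
) -> CorrelationResult:
    """Rank (or optionally Pearson) correlation with an undefined flag.

    Zero variance in either variable makes the coefficient undefined;
    the result is flagged rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(x_name, y_name, method, None, None, x.size, stratum, False)
    if method == "spearman":
        res = stats.spearmanr(x, y)
    elif method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        x_name, y_name, method, float(res.statistic), float(res.pvalue), x.size, stratum
    )


@dataclass(frozen=True)
class PrevalenceComparison:
    """2x2 comparison of a binary outcome between signaling groups.

    ``counts`` rows are (LOW group, HIGH group), columns (outcome yes,
    outcome no); prevalences are percentages within each group.
    """

    counts: tuple[tuple[int, int], tuple[int, int]]
    prevalence_low: float
    prevalence_high: float
    test: str
    p_value: float

    @property
    def n_low(self) -> int:
        return sum(self.counts[0])

    @property
    def n_high(self) -> int:
        return sum(self.counts[1])


def prevalence_test(
    counts: Sequence[Sequence[int]], test: str = "fisher"
) -> PrevalenceComparison:
    """Compare outcome prevalence between two groups on a 2x2 table.

    ``counts = [[yes_low, no_low], [yes_high, no_high]]``.  Fisher's
    exact test by default; ``test="chi2"`` selects the plain Pearson
    chi-square (no continuity correction).
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("both groups must contain subjects")
    prev_low = 100.0 * table[0, 0] / table[0].sum()
    prev_high = 100.0 * table[1, 0] / table[1].sum()
    if test == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    elif test == "chi2":
        if (table.sum(axis=0) == 0).any():
            p = 1.0  # outcome constant in both groups
        else:
            p = stats.chi2_contingency(table, correction=False).pvalue
    else:
        raise ValueError(f"unknown prevalence test {test!r}")
    return PrevalenceComparison(
        tuple(map(tuple, table.tolist())), prev_low, prev_high, test, float(p)
    )


@dataclass(frozen=True)
class GroupComparison:
    """Descriptives and rank-test result for one variable in one stratum."""

    variable: str
    stratum: str
    n_high: int
    mean_high: float
    sd_high: float
    n_low: int
    mean_low: float
    sd_low: float
    test: str
    statistic: float
    p_value: float


ALL_STRATUM = "all"


def compare_groups_stratified(
    data: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "mlgs_group",
    stratum_col: str = "weight_status",
    sex_col: Optional[str] = None,
    continuity: bool = True,
    strata_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Mann-Whitney battery per variable, overall and within strata.

    ``data`` must carry the signaling group (:class:`SignalingGroup`
    values or their strings) and a stratum label per subject.  Rows where
    the group is undefined are excluded.  For each stratum (plus an
    overall ``"all"`` row set, and per-sex row sets when ``sex_col`` is
    given) the HIGH (< threshold) and LOW (>= threshold) groups are
    described as mean ± SD and compared by Mann-Whitney; a stratum where
    either group is empty is skipped with a warning.

    Returns a tidy frame, one row per (stratum, variable).
    """
    df = data.copy()
    group = df[group_col].map(lambda g: getattr(g, "value", g))
    df = df[group.isin([SignalingGroup.LOW.value, SignalingGroup.HIGH.value])]
    group = group.loc[df.index]

    strata: list[tuple[str, pd.DataFrame]] = [(ALL_STRATUM, df)]
    stratum_labels = df[stratum_col].map(lambda s: getattr(s, "value", s))
    if strata_order is None:
        strata_order = sorted(stratum_labels.dropna().unique())
    for label in strata_order:
        strata.append((str(label), df[stratum_labels == label]))
    if sex_col is not None:
        sex_labels = df[sex_col].map(lambda s: getattr(s, "value", s))
        for label in sorted(sex_labels.dropna().unique()):
            strata.append((f"sex:{label}", df[sex_labels == label]))

    rows = []
    for stratum_name, sub in strata:
        sub_group = sub[group_col].map(lambda g: getattr(g, "value", g))
        for var in variables:
            if var not in sub.columns:
                raise KeyError(f"variable {var!r} not present in the cohort")
            values = pd.to_numeric(sub[var], errors="coerce")
            mask = values.notna()
            hi = values[mask & (sub_group == SignalingGroup.HIGH.value)]
            lo = values[mask & (sub_group == SignalingGroup.LOW.value)]
            if hi.empty or lo.empty:
                logger.warning(
                    "stratum %r: variable %r skipped (empty signaling group)",
                    stratum_name,
                    var,
                )
                continue
            mw = mann_whitney_u(hi.to_numpy(), lo.to_numpy(), continuity=continuity)
            rows.append(
                GroupComparison(
                    var,
                    stratum_name,
                    int(hi.size),
                    float(hi.mean()),
                    float(hi.std(ddof=1)) if hi.size > 1 else 0.0,
                    int(lo.size),
                    float(lo.mean()),
                    float(lo.std(ddof=1)) if lo.size > 1 else 0.0,
                    "mann-whitney",
                    mw.u,
                    mw.p_value,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
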