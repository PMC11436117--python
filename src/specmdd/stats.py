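"""Group-comparison battery and clinical statistics.

The battery runs a Wilcoxon rank-sum test and a Hedge's g effect size for
every designed feature — by default the 50-test family
[2 conditions (PSD, periodic) x 2 spaces (electrode, source) x 5 regions x
2 bands (theta, alpha)] + [aperiodic x 2 spaces x 5 regions] — with
Bonferroni adjustment over the full designed family.  Demographic helpers
(one-way ANOVA from summary statistics, Pearson chi-square on a 2x2 table)
and Spearman correlations with clinical scores round out the module.

Sign convention: Hedge's g is computed as HC minus MDD, so reduced activity
in the depressed group yields positive g.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import ANALYSIS_BANDS, REGIONS, SPACES, feature_key

EXACT_MAX_N = 12  # exact rank-sum enumeration up to this combined sample size


@dataclass
class ComparisonResult:
    """One battery row."""

    condition: str
    space: str
    region: str
    band: str | None
    n_hc: int
    n_mdd: int
    median_hc: float
    median_mdd: float
    hedges_g: float
    p_raw: float
    p_adjusted: float
    degenerate: bool = False

    @property
    def key(self) -> str:
        return feature_key(self.space, self.condition, self.region, self.band)


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by full enumeration of rank assignments.

    Uses midranks, so ties are handled; p = 2 * min(P(W <= w), P(W >= w)),
    capped at 1, where W is the rank sum of the first sample.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    total = 0
    n_le = 0
    n_ge = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return float(w_obs), float(min(p, 1.0))


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (rank sum of ``x`` with midranks, two-sided p).  For combined
    samples of 12 or fewer, p comes from exact enumeration; otherwise from
    the normal approximation with tie-corrected variance and a continuity
    correction.  Identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if np.ptp(pooled) == 0:
        return w, 1.0
    if n1 + n2 <= EXACT_MAX_N:
        return _rank_sum_exact(x, y)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / float(n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    diff = w - mu
    z = (abs(diff) - 0.5) / np.sqrt(var)  # continuity correction
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return w, float(min(p, 1.0))


def hedges_g(x, y) -> float:
    """Hedge's g: bias-corrected standardized mean difference of x vs y.

    g = J * (mean(x) - mean(y)) / s_pooled, with the pooled SD weighted by
    degrees of freedom and the small-sample correction
    J = 1 - 3 / (4(n1 + n2) - 9).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        if x.mean() == y.mean():
            return 0.0
        raise ValueError("pooled variance is zero")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * (x.mean() - y.mean()) / np.sqrt(s2))


def bonferroni_adjust(p_values, family_size: int) -> np.ndarray:
    """p_adj = min(1, p * family_size)."""
    p = np.asarray(p_values, dtype=float)
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if family_size < p.size:
        raise ValueError("family_size must be >= number of p values")
    return np.minimum(1.0, p * family_size)


@dataclass(frozen=True)
class BatteryDesign:
    """Which (condition, space, region, band) cells the battery tests."""

    spaces: tuple[str, ...] = SPACES
    regions: tuple[str, ...] = REGIONS
    bands: tuple[str, ...] = ANALYSIS_BANDS

    def cells(self) -> list[tuple[str, str, str, str | None]]:
        out = []
        for condition in ("psd", "periodic"):
            for space in self.spaces:
                for region in self.regions:
                    for band in self.bands:
                        out.append((condition, space, region, band))
        for space in self.spaces:
            for region in self.regions:
                out.append(("aperiodic", space, region, None))
        return out

    @property
    def family_size(self) -> int:
        return len(self.cells())


def run_battery(table: pd.DataFrame,
                design: BatteryDesign | None = None,
                alpha: float = 0.05) -> list[ComparisonResult]:
    """Run the Wilcoxon + Hedge's g battery over the designed feature cells.

    The Bonferroni family size is the number of *designed* tests (50 by
    default), regardless of missing data; subjects with a missing value are
    dropped pairwise per feature.
    """
    design = design or BatteryDesign()
    cells = design.cells()
    m = design.family_size
    hc_mask = table["group"] == "HC"
    mdd_mask = table["group"] == "MDD"
    if not hc_mask.any() or not mdd_mask.any():
        raise ValueError("both groups must be present")
    results = []
    for condition, space, region, band in cells:
        key = feature_key(space, condition, region, band)
        col = table[key] if key in table.columns else pd.Series(np.nan, index=table.index)
        x = col[hc_mask].dropna().to_numpy()
        y = col[mdd_mask].dropna().to_numpy()
        if x.size < 2 or y.size < 2:
            results.append(ComparisonResult(condition, space, region, band,
                                            x.size, y.size, np.nan, np.nan,
                                            np.nan, np.nan, np.nan,
                                            degenerate=True))
            continue
        _, p = wilcoxon_ranksum(x, y)
        degenerate = np.ptp(np.concatenate([x, y])) == 0
        g = 0.0 if degenerate else hedges_g(x, y)
        results.append(ComparisonResult(
            condition, space, region, band, x.size, y.size,
            float(np.median(x)), float(np.median(y)), g, p,
            float(bonferroni_adjust([p], m)[0]), degenerate=degenerate))
    return results


def battery_frame(results: list[ComparisonResult], alpha: float = 0.05) -> pd.DataFrame:
    """Battery results as the output table."""
    rows = [{
        "feature": r.key, "condition": r.condition, "space": r.space,
        "region": r.region, "band": r.band if r.band else "",
        "n_hc": r.n_hc, "n_mdd": r.n_mdd,
        "median_hc": r.median_hc, "median_mdd": r.median_mdd,
        "hedges_g": r.hedges_g, "p_raw": r.p_raw,
        "p_bonferroni": r.p_adjusted,
        "significant_at_0.05": bool(r.p_adjusted < alpha)
        if np.isfinite(r.p_adjusted) else False,
    } for r in results]
    return pd.DataFrame(rows)


def anova_oneway_summary(n1: int, mean1: float, sd1: float,
                         n2: int, mean2: float, sd2: float):
    """One-way two-group ANOVA computed from summary statistics.

    Returns (F, df_between, df_within, p).  Zero within-group variance with
    unequal means gives F = inf.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    n = n1 + n2
    grand = (n1 * mean1 + n2 * mean2) / n
    ss_between = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    ss_within = (n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2
    df_b, df_w = 1, n - 2
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
        return f, df_b, df_w, 0.0 if ss_between > 0 else 1.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def chi_square_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], no continuity
    correction: chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(mg == 0 for mg in margins):
        raise ValueError("all table margins must be positive")
    chi2 = n * (a * d - b * c) ** 2 / float(np.prod(margins, dtype=float))
    p = float(sps.chi2.sf(chi2, 1))
    return float(chi2), 1, p


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks; two-sided p from the
    t-approximation.  Constant input yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def correlation_table(table: pd.DataFrame, features: list[str],
                      scores=("bdi", "bdi_anh", "bdi_mel")) -> pd.DataFrame:
    """Spearman correlations of selected features with clinical scores."""
    rows = []
    for feat in features:
        for score in scores:
            sub = table[[feat, score]].dropna()
            rho, p = spearman_corr(sub[feat], sub[score])
            rows.append({"feature": feat, "score": score, "n": len(sub),
                         "rho": rho, "p": p})
    return pd.DataFrame(rows)
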