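"""Agreement and comparison statistics for morphometric outputs.

Implements the statistical layer used to validate automated area readouts
against manual mean linear intercept: z-scoring (sample SD, n−1), Pearson
correlation with a Shapiro–Wilk normality check, Bland–Altman analysis of
the standardized pairs, and two-group comparisons with an F-test-gated
Welch correction.

Because both series are z-scored before the Bland–Altman step, the bias is
identically zero and the upper 95% limit of agreement reduces to the
closed form

    loa_high = 1.96 · sqrt(2·(1 − r))

with r the sample Pearson correlation — a useful identity for checking
implementations, and the reason the limits of agreement are symmetric
(±) for standardized measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StandardizedSeries",
    "PearsonReport",
    "BlandAltmanResult",
    "GroupComparison",
    "zscore",
    "pearson_with_gate",
    "bland_altman_z",
    "compare_groups",
]

LOA_MULTIPLIER = 1.96


@dataclass
class StandardizedSeries:
    """A series together with its z-scored values: z = (x − µ)/σ, σ with n−1."""

    values: np.ndarray
    mean: float
    sd: float
    z: np.ndarray


@dataclass
class PearsonReport:
    r: float
    p: float
    n: int
    shapiro_x: tuple[float, float]  # (W, p)
    shapiro_y: tuple[float, float]
    normal_x: bool
    normal_y: bool
    alpha_normality: float


@dataclass
class BlandAltmanResult:
    """Bland–Altman analysis of z-scored pairs (method minus reference)."""

    differences: np.ndarray
    means: np.ndarray
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    outside_loa: np.ndarray  # indices of pairs beyond the limits
    r: float
    proportional_bias_slope: float
    proportional_bias_p: float


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    f_stat: float
    f_p: float
    welch: bool
    t_stat: float
    p: float


def zscore(values) -> StandardizedSeries:
    """Standardize a series: z = (x − µ)/σ with the sample (n−1) SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to z-score")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance: cannot z-score a constant series")
    return StandardizedSeries(values=x, mean=mu, sd=sd, z=(x - mu) / sd)


def pearson_r_p(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided p via the t transform with n−2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    if n < 3 or abs(r) >= 1.0:
        return r, float("nan") if n < 3 else 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p, n


def pearson_with_gate(x, y, alpha_normality: float = 0.05) -> PearsonReport:
    """Pearson correlation preceded by a Shapiro–Wilk normality check.

    Non-normal inputs are flagged, not rejected: the correlation is still
    returned, and the normality report travels with it so the analyst can
    judge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    sw_x = sps.shapiro(x)
    sw_y = sps.shapiro(y)
    r, p, n = pearson_r_p(x, y)
    return PearsonReport(
        r=r,
        p=p,
        n=n,
        shapiro_x=(float(sw_x.statistic), float(sw_x.pvalue)),
        shapiro_y=(float(sw_y.statistic), float(sw_y.pvalue)),
        normal_x=bool(sw_x.pvalue >= alpha_normality),
        normal_y=bool(sw_y.pvalue >= alpha_normality),
        alpha_normality=alpha_normality,
    )


def bland_altman_z(x, y) -> BlandAltmanResult:
    """Bland–Altman agreement of z-scored pairs (x = method, y = reference).

    Both series are standardized, differences are z_x − z_y, and the 95%
    limits of agreement are bias ± 1.96·SD of the differences. For
    standardized inputs the bias is 0 by construction and the limits are
    ±1.96·sqrt(2(1−r)). A proportional-bias slope (regression of
    differences on pair means) is reported alongside; note that for
    z-scored pairs this linear slope vanishes identically
    (cov(z_x − z_y, z_x + z_y) = var z_x − var z_y = 0), so any remaining
    proportional bias is curvature, judged from the plot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    zx = zscore(x).z
    zy = zscore(y).z
    d = zx - zy
    m = (zx + zy) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - LOA_MULTIPLIER * sd
    loa_high = bias + LOA_MULTIPLIER * sd
    outside = np.flatnonzero((d < loa_low) | (d > loa_high))
    r = float(np.corrcoef(x, y)[0, 1])
    if np.std(m) > 0:
        reg = sps.linregress(m, d)
        slope, slope_p = float(reg.slope), float(reg.pvalue)
    else:
        slope, slope_p = 0.0, float("nan")
    return BlandAltmanResult(
        differences=d,
        means=m,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        outside_loa=outside,
        r=r,
        proportional_bias_slope=slope,
        proportional_bias_p=slope_p,
    )


def compare_groups(a, b, variance_alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison: F-test for variance equality, then Student's
    t (pooled) or Welch's t if the variances differ at ``variance_alpha``.

    Two-sided throughout. The F-test p is two-tailed:
    p = 2·min(P(F ≤ f), P(F ≥ f)) with f = s_a²/s_b².
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        f_stat, f_p = 1.0, 1.0
    else:
        f_stat = float(va / vb) if vb > 0 else float("inf")
        cdf = sps.f.cdf(f_stat, a.size - 1, b.size - 1)
        f_p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    welch = f_p < variance_alpha
    t_res = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        f_stat=f_stat,
        f_p=f_p,
        welch=welch,
        t_stat=float(t_res.statistic),
        p=float(t_res.pvalue),
    )
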