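"""Reliability and validity statistics for paired measurements.

Implements the agreement battery used to evaluate a two-occasion or
two-method measurement design on continuous outcomes:

* single-measure two-way intraclass correlations — absolute agreement
  ICC(A,1) and consistency ICC(C,1) — with F-based 95% confidence
  intervals, following McGraw & Wong (1996);
* Spearman rank correlation with a percentile bootstrap CI (paired case
  resampling);
* Bland–Altman analysis: mean difference with t-based CI, 1.96-SD limits
  of agreement with CIs, and proportional bias as the OLS slope of
  differences on pair means;
* Bonett's closed-form sample size for a target ICC CI width.

All estimators operate on a :class:`PairedMeasurements` of two equal-length
vectors (occasion 1 vs occasion 2, or questionnaire vs device).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "CIValue",
    "AgreementResult",
    "BlandAltmanResult",
    "icc_two_way_mixed",
    "spearman_bootstrap",
    "bland_altman",
    "sample_size_bonett",
    "agreement_battery",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Two pairwise-complete measurement vectors for the same participants."""

    ids: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray

    @classmethod
    def from_arrays(cls, x, y, ids=None) -> "PairedMeasurements":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-d vectors")
        if len(x) < 2:
            raise ValueError("need at least 2 pairs")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("pairs must be complete; drop missing pairs upstream")
        if ids is None:
            ids = tuple(str(i) for i in range(len(x)))
        return cls(tuple(ids), x, y)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class CIValue:
    estimate: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (self.lower <= self.estimate + 1e-12 and self.estimate <= self.upper + 1e-12):
            raise ValueError(
                f"CI must bracket estimate: {self.lower} <= {self.estimate} <= {self.upper}"
            )


@dataclass(frozen=True)
class AgreementResult:
    icc_a1: CIValue
    icc_c1: CIValue
    spearman_rho: CIValue
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: CIValue
    sd_diff: float
    loa_lower: CIValue
    loa_upper: CIValue
    prop_bias_beta: float
    prop_bias_p: float
    n: int


def _anova_mean_squares(x: np.ndarray, y: np.ndarray):
    """Two-way (participants x occasions) ANOVA mean squares for k=2.

    Returns (MS_R rows/participants, MS_C columns/occasions, MS_E residual, n, k).
    """
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return ms_r, ms_c, ms_e, n, k


def icc_two_way_mixed(
    p: PairedMeasurements, alpha: float = 0.05
) -> tuple[CIValue, CIValue]:
    """Single-measure two-way mixed-model ICCs with F-based CIs.

    ICC(C,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)
    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    CI for ICC(C,1): F_obs = MS_R/MS_E with (n-1, (n-1)(k-1)) df;
      bounds (F_L - 1)/(F_L + k - 1) with F_L = F_obs / F_{1-a/2} and
      F_U = F_obs * F_{1-a/2} with swapped df (McGraw & Wong, Table 7).
    CI for ICC(A,1): Satterthwaite df for the denominator
      a*MS_C + b*MS_E with a = k*r/(n(1-r)), b = 1 + k*r(n-1)/(n(1-r)).
    """
    ms_r, ms_c, ms_e, n, k = _anova_mean_squares(p.x, p.y)
    denom_c = ms_r + (k - 1) * ms_e
    denom_a = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom_c <= 0 or denom_a <= 0:
        raise ValueError("zero total variance: ICC undefined")
    icc_c = (ms_r - ms_e) / denom_c
    icc_a = (ms_r - ms_e) / denom_a

    df1 = n - 1
    df2 = (n - 1) * (k - 1)

    # Consistency CI
    if ms_e > 0:
        f_obs = ms_r / ms_e
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        c_lo = (fl - 1) / (fl + k - 1)
        c_hi = (fu - 1) / (fu + k - 1)
    else:
        c_lo, c_hi = icc_c, icc_c
    ci_c = CIValue(icc_c, min(c_lo, icc_c), max(c_hi, icc_c))

    # Absolute-agreement CI (Satterthwaite approximation)
    r = icc_a
    if ms_e > 0 and abs(1 - r) > 1e-12:
        a = (k * r) / (n * (1 - r))
        b = 1 + (k * r * (n - 1)) / (n * (1 - r))
        num = (a * ms_c + b * ms_e) ** 2
        den = (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else df2
        f_l = stats.f.ppf(1 - alpha / 2, df1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, df1)
        a_lo = (n * (ms_r - f_l * ms_e)) / (
            f_l * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r
        )
        a_hi = (n * (f_u * ms_r - ms_e)) / (
            k * ms_c + (k * n - k - n) * ms_e + n * f_u * ms_r
        )
    else:
        a_lo, a_hi = icc_a, icc_a
    ci_a = CIValue(icc_a, min(a_lo, icc_a), max(a_hi, icc_a))
    return ci_a, ci_c


def spearman_bootstrap(
    p: PairedMeasurements,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> CIValue:
    """Spearman's rho with a percentile bootstrap CI (paired resampling).

    Ranks use the mid-rank (average) convention for ties. Deterministic for
    a given seed. Bootstrap replicates where one resampled vector is
    constant contribute NaN and are dropped from the percentile interval.
    """
    if p.n < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.ptp(p.x) == 0 or np.ptp(p.y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = float(stats.spearmanr(p.x, p.y).statistic)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, p.n, size=(n_boot, p.n))
    rx = stats.rankdata(p.x[idx], axis=1)
    ry = stats.rankdata(p.y[idx], axis=1)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        reps = (rx * ry).sum(axis=1) / den
    reps = reps[den > 0]
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return CIValue(rho, min(float(lo), rho), max(float(hi), rho))


def bland_altman(p: PairedMeasurements, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland–Altman agreement of two methods on the same scale.

    Differences are d_i = x_i - y_i (method 1 minus method 2). The mean
    difference carries a t-based CI; the limits of agreement are
    mean ± 1.96 SD with CIs from SE(LoA) = SD * sqrt(3/n) (t multiplier).
    Proportional bias is the OLS slope of d_i on the pair means
    a_i = (x_i + y_i)/2, with its t-test p-value.
    """
    if p.n < 3:
        raise ValueError("need at least 3 pairs")
    d = p.x - p.y
    a = (p.x + p.y) / 2.0
    n = p.n
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    t_crit = stats.t.ppf(1 - alpha / 2, n - 1)
    se_mean = sd_d / math.sqrt(n)
    ci_mean = CIValue(mean_d, mean_d - t_crit * se_mean, mean_d + t_crit * se_mean)
    loa_lo = mean_d - 1.96 * sd_d
    loa_hi = mean_d + 1.96 * sd_d
    se_loa = sd_d * math.sqrt(3.0 / n)
    ci_lo = CIValue(loa_lo, loa_lo - t_crit * se_loa, loa_lo + t_crit * se_loa)
    ci_hi = CIValue(loa_hi, loa_hi - t_crit * se_loa, loa_hi + t_crit * se_loa)

    if np.ptp(a) == 0 or sd_d == 0:
        beta, pval = 0.0, 1.0
    else:
        fit = stats.linregress(a, d)
        beta, pval = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(ci_mean, sd_d, ci_lo, ci_hi, beta, pval, n)


def sample_size_bonett(
    rho0: float, half_width: float, k: int = 2, alpha: float = 0.05
) -> int:
    """Minimum n so the ICC CI has the planned width, by Bonett's formula.

    n = ceil( 8 z^2 (1-rho0)^2 (1+(k-1)rho0)^2 / (k(k-1) w^2) + 1 ),
    with w the full CI width (twice the half-width).
    """
    if not 0 < rho0 < 1:
        raise ValueError("rho0 must be in (0, 1)")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if k < 2:
        raise ValueError("k must be at least 2")
    z = stats.norm.ppf(1 - alpha / 2)
    w = 2.0 * half_width
    n = 8 * z**2 * (1 - rho0) ** 2 * (1 + (k - 1) * rho0) ** 2 / (k * (k - 1) * w**2) + 1
    return math.ceil(n)


def agreement_battery(
    p: PairedMeasurements,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> AgreementResult:
    """ICC(A,1), ICC(C,1) and bootstrap Spearman rho for one behaviour."""
    icc_a, icc_c = icc_two_way_mixed(p, alpha=alpha)
    rho = spearman_bootstrap(p, n_boot=n_boot, seed=seed, alpha=alpha)
    return AgreementResult(icc_a, icc_c, rho, p.n)
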