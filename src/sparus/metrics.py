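"""Image-quality metrics and agreement/power statistics.

SSIM is the whole-image (global) formula built from full-frame means,
variances and covariance; a windowed mean-SSIM is available as an explicit
non-default option.  PSNR uses ``20 log10(i_max / sqrt(MSE))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity as _windowed_ssim

__all__ = [
    "SSIMParams",
    "MetricReport",
    "AgreementResult",
    "ssim",
    "mse",
    "psnr",
    "fwhm",
    "iou",
    "bland_altman",
    "ttest_power",
    "evaluate_pair",
]


@dataclass(frozen=True)
class SSIMParams:
    """Stabilizers for the SSIM denominator.

    ``k1``/``k2`` are the additive constants themselves; when left None
    they default to ``(0.01 L)^2`` and ``(0.03 L)^2``.
    """

    L: float = 255.0
    k1: float | None = None
    k2: float | None = None

    def resolved(self) -> tuple[float, float]:
        k1 = (0.01 * self.L) ** 2 if self.k1 is None else self.k1
        k2 = (0.03 * self.L) ** 2 if self.k2 is None else self.k2
        if k1 <= 0 or k2 <= 0:
            raise ValueError("SSIM stabilizers must be positive")
        return float(k1), float(k2)


def _as_float_pair(gt, x) -> tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt, dtype=float)
    x = np.asarray(x, dtype=float)
    if gt.shape != x.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {x.shape}")
    return gt, x


def ssim(gt, x, params: SSIMParams = SSIMParams(), windowed: bool = False) -> float:
    """Structural similarity between two images.

    Default is the global single-number formula over whole-image statistics

        (2 mu_a mu_b + k1)(2 cov + k2)
        ------------------------------------------
        (mu_a^2 + mu_b^2 + k1)(var_a + var_b + k2)

    symmetric in its arguments.  ``windowed=True`` instead returns the
    common sliding-window mean SSIM.
    """
    gt, x = _as_float_pair(gt, x)
    if gt.size < 2:
        raise ValueError("need at least 2 pixels")
    k1, k2 = params.resolved()
    if windowed:
        return float(
            _windowed_ssim(gt, x, data_range=params.L, K1=math.sqrt(k1) / params.L,
                           K2=math.sqrt(k2) / params.L)
        )
    mu_a, mu_b = gt.mean(), x.mean()
    var_a, var_b = gt.var(), x.var()
    cov = ((gt - mu_a) * (x - mu_b)).mean()
    num = (2.0 * mu_a * mu_b + k1) * (2.0 * cov + k2)
    den = (mu_a**2 + mu_b**2 + k1) * (var_a + var_b + k2)
    return float(num / den)


def mse(gt, x) -> float:
    """Mean squared pixel difference."""
    gt, x = _as_float_pair(gt, x)
    return float(np.mean((gt - x) ** 2))


def psnr(gt, x, i_max: float = 255.0) -> float:
    """Peak signal-to-noise ratio, ``20 log10(i_max / sqrt(MSE))`` in dB.

    A perfect match (MSE = 0) returns ``math.inf``.
    """
    if i_max <= 0:
        raise ValueError("i_max must be positive")
    err = mse(gt, x)
    if err == 0.0:
        return math.inf
    return float(20.0 * np.log10(i_max / np.sqrt(err)))


def fwhm(profile, spacing: float) -> float:
    """Full width at half maximum of a 1-D profile, in units of ``spacing``.

    The half-maximum crossings nearest the unique global peak are located
    by linear interpolation.  Raises if the peak touches the boundary or a
    crossing is missing on either side.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    peak_val = profile.max()
    if peak_val <= 0:
        raise ValueError("profile peak must be positive")
    peaks = np.flatnonzero(profile == peak_val)
    if peaks.size > 1 and (peaks[-1] - peaks[0]) != (peaks.size - 1):
        raise ValueError("profile has multiple separated global maxima")
    half = peak_val / 2.0

    def _cross(idx_range, reverse: bool) -> float:
        prev = None
        for i in idx_range:
            if profile[i] < half:
                j = i + 1 if reverse else i - 1
                # interpolate between sample i (below) and its peak-side neighbor
                frac = (half - profile[i]) / (profile[j] - profile[i])
                return i + frac * (j - i)
            prev = i
        raise ValueError("half-maximum crossing not found (peak at boundary)")

    left = _cross(range(peaks[0] - 1, -1, -1), reverse=True)
    right = _cross(range(peaks[-1] + 1, profile.size), reverse=False)
    return float((right - left) * spacing)


def iou(a, b) -> float:
    """Intersection over union of two congruent binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("union of masks is empty")
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class AgreementResult:
    """Bland-Altman bias/limits plus Pearson r and paired t-test p-value."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    pearson_r: float | None
    pearson_defined: bool
    t_statistic: float | None
    t_p_value: float | None
    n: int


def bland_altman(x, y) -> AgreementResult:
    """Agreement between paired measurement series ``x`` and ``y``.

    bias = mean(y - x); limits of agreement = bias +/- 1.96 SD(y - x)
    (sample SD).  Pearson r is flagged undefined when either series is
    constant; the paired t-test p-value is None when all differences are
    identical (zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 2:
        raise ValueError("need at least 2 paired measurements")
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    r: float | None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r, r_defined = None, False
    else:
        r = float(stats.pearsonr(x, y).statistic)
        r_defined = True
    if sd == 0:
        t_stat, p = None, None
    else:
        res = stats.ttest_rel(y, x)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return AgreementResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        pearson_r=r,
        pearson_defined=r_defined,
        t_statistic=t_stat,
        t_p_value=p,
        n=int(x.size),
    )


def ttest_power(
    delta: float,
    sd1: float,
    sd2: float,
    n_per_group: int,
    alpha: float = 0.05,
    paired: bool = False,
) -> float:
    """Power of a two-tailed t-test via the noncentral t distribution.

    Default models two independent groups of ``n_per_group`` with pooled
    SD ``sqrt((sd1^2 + sd2^2)/2)``: noncentrality ``d sqrt(n/2)`` with
    ``d = delta / pooled_sd`` and ``df = 2n - 2``.  ``paired=True`` treats
    ``sd1`` as the SD of differences (``sd2`` ignored, df = n - 1,
    noncentrality ``delta/sd1 * sqrt(n)``).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sd1 <= 0 or (not paired and sd2 <= 0):
        raise ValueError("standard deviations must be positive")
    if paired:
        df = n_per_group - 1
        nc = (delta / sd1) * math.sqrt(n_per_group)
    else:
        pooled = math.sqrt((sd1**2 + sd2**2) / 2.0)
        df = 2 * n_per_group - 2
        nc = (delta / pooled) * math.sqrt(n_per_group / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    # P(T < -t_crit) = P(T' > t_crit) with noncentrality -nc; this form is
    # numerically stable where nct.cdf underflows to NaN in the far tail
    power = stats.nct.sf(t_crit, df, nc) + stats.nct.sf(t_crit, df, -nc)
    return float(np.clip(np.nan_to_num(power), 0.0, 1.0))


@dataclass
class MetricReport:
    """Per-pair quality metrics, optionally with resolution/overlap extras."""

    ssim: float
    mse: float
    psnr: float
    fwhm_mm: float | None = None
    iou: float | None = None
    extras: dict = field(default_factory=dict)


def evaluate_pair(gt, x, params: SSIMParams = SSIMParams()) -> MetricReport:
    """SSIM/MSE/PSNR of one image pair (ground truth first)."""
    return MetricReport(
        ssim=ssim(gt, x, params),
        mse=mse(gt, x),
        psnr=psnr(gt, x, i_max=params.L),
    )
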