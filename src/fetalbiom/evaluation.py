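"""Agreement and performance statistics for method comparison.

These are the statistics used to compare automated measurements with a
human operator's: mean absolute error, Bland-Altman bias and 95% limits
of agreement (optionally as a percentage of the pair mean), the one-way
intraclass correlation coefficient, the paired Wilcoxon signed-rank
test, sensitivity/specificity for categorical calls, and Dice/IoU for
mask overlap.

The 1.96 multiplier in the limits of agreement is the conventional 95%
normal quantile and is deliberately not configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .imaging_io import LabelMask

__all__ = [
    "PairedSeries",
    "AgreementStats",
    "mae",
    "bland_altman",
    "icc",
    "paired_wilcoxon",
    "WilcoxonResult",
    "sens_spec",
    "SensSpecResult",
    "dice_iou",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class PairedSeries:
    """Two equal-length measurement series on the same subjects."""

    a: np.ndarray  # e.g. model
    b: np.ndarray  # e.g. operator
    subject_ids: tuple = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired series must be equal-length 1-D sequences")
        if len(a) < 2:
            raise ValueError("paired series needs at least 2 pairs")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("paired series must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if self.subject_ids and len(self.subject_ids) != len(a):
            raise ValueError("subject_ids length mismatch")

    def __len__(self) -> int:
        return len(self.a)

    @property
    def ids(self) -> tuple:
        return self.subject_ids or tuple(range(len(self)))


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary plus MAE and ICC for one parameter."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    percentage_mode: bool
    mae: float
    icc: Optional[float]
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low - 1e-12 <= self.bias <= self.loa_high + 1e-12):
            raise ValueError("limits of agreement must bracket the bias")


def mae(series: PairedSeries) -> tuple[float, float]:
    """Mean absolute error and its standard deviation (ddof=1)."""
    abs_err = np.abs(series.a - series.b)
    sd = float(abs_err.std(ddof=1)) if len(abs_err) > 1 else 0.0
    return float(abs_err.mean()), sd


def bland_altman(series: PairedSeries, percentage: bool = False) -> AgreementStats:
    """Bland-Altman bias and 95% limits of agreement.

    In percentage mode each difference is expressed relative to the pair
    mean: ``100 * (a - b) / ((a + b) / 2)``; pairs with zero mean are a
    domain error.
    """
    d = series.a - series.b
    if percentage:
        means = (series.a + series.b) / 2.0
        zero = np.nonzero(means == 0)[0]
        if len(zero):
            bad = [series.ids[i] for i in zero]
            raise ValueError(f"zero pair mean for subjects {bad}; percentage undefined")
        d = 100.0 * d / means
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    m, _ = mae(series)
    try:
        icc_val: Optional[float] = icc(series)
    except ValueError:
        icc_val = None
    if icc_val is not None and math.isnan(icc_val):
        icc_val = None
    return AgreementStats(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        percentage_mode=percentage,
        mae=m,
        icc=icc_val,
        n=len(series),
    )


def icc(series: PairedSeries, model: str = "one-way") -> float:
    """Intraclass correlation coefficient for two raters.

    ``one-way`` (default) is the random-effects ICC(1,1) from the one-way
    ANOVA mean squares, ``(MSB - MSW) / (MSB + (k-1) MSW)`` with k = 2
    raters; it can be negative.  ``two-way`` is the two-way
    absolute-agreement single-measure estimator ICC(2,1).

    Returns NaN (with a warning) when the total variance is zero.
    """
    n = len(series)
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    data = np.stack([series.a, series.b], axis=1)  # n subjects x k raters
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    msb = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    msw = ((data - subj_means[:, None]) ** 2).sum() / (n * (k - 1))
    if model == "one-way":
        denom = msb + (k - 1) * msw
        if denom == 0:
            warnings.warn("ICC undefined: zero total variance")
            return math.nan
        return float((msb - msw) / denom)
    if model == "two-way":
        rater_means = data.mean(axis=0)
        msc = n * ((rater_means - grand) ** 2).sum() / (k - 1)
        sse = ((data - subj_means[:, None] - rater_means[None, :] + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        denom = msb + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            warnings.warn("ICC undefined: zero total variance")
            return math.nan
        return float((msb - mse) / denom)
    raise ValueError(f"unknown ICC model {model!r}")


class WilcoxonResult(NamedTuple):
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    method: str  # "exact" | "normal" | "degenerate"


def paired_wilcoxon(series: PairedSeries) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped (Wilcoxon's original procedure); ties
    get mid-ranks.  The null distribution is exact (all 2^n sign
    assignments, computed by convolution) for n <= 25 nonzero
    differences, and a normal approximation with tie correction and
    continuity correction beyond.
    """
    d = series.a - series.b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, "degenerate")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))  # mid-ranks; multiples of 0.5
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, "exact")
    mean = n * (n + 1) / 4.0
    tie_term = 0.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    from scipy.stats import norm

    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, "normal")


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p via the distribution of W+ over all sign flips.

    Mid-ranks are multiples of 1/2, so doubling them gives integers and
    the null distribution is a polynomial product."""
    doubled = np.rint(2.0 * ranks).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


@dataclass(frozen=True)
class SensSpecResult:
    sensitivity: Optional[float]
    specificity: Optional[float]
    tp: int
    fn: int
    tn: int
    fp: int
    reason: Optional[str] = None


def sens_spec(pred: Sequence[bool], truth: Sequence[bool]) -> SensSpecResult:
    """Sensitivity and specificity with the full 2x2 table.

    A metric whose denominator class is absent from ``truth`` is reported
    as ``None`` with the reason."""
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("pred and truth must have equal length")
    tp = int((p & t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    reasons = []
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    if sens is None:
        reasons.append("no positives in truth: sensitivity undefined")
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    if spec is None:
        reasons.append("no negatives in truth: specificity undefined")
    return SensSpecResult(
        sensitivity=sens, specificity=spec, tp=tp, fn=fn, tn=tn, fp=fp,
        reason="; ".join(reasons) or None,
    )


def dice_iou(mask_a: LabelMask, mask_b: LabelMask) -> tuple[float, float]:
    """Dice coefficient and intersection-over-union of two masks.

    Both are 1.0 when both masks are empty (perfect agreement on
    absence); this convention is the one used for per-image averages.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share dimensions")
    inter = int((mask_a.grid & mask_b.grid).sum())
    union = int((mask_a.grid | mask_b.grid).sum())
    size_sum = mask_a.count + mask_b.count
    if union == 0:
        return 1.0, 1.0
    return 2.0 * inter / size_sum, inter / union


def bland_altman_plot(series: PairedSeries, percentage: bool = False, ax=None):
    """Mean-vs-difference plot with bias and limits-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    stats = bland_altman(series, percentage=percentage)
    means = (series.a + series.b) / 2.0
    diffs = series.a - series.b
    if percentage:
        diffs = 100.0 * diffs / means
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(means, diffs, s=12)
    for y, style in ((stats.bias, "-"), (stats.loa_low, "--"), (stats.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("pair mean")
    ax.set_ylabel("difference (%)" if percentage else "difference")
    return ax, stats
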