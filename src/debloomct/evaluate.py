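"""Agreement, diagnostic-performance, plaque-change and image-quality stats.

Conventions
-----------
* Bland-Altman limits of agreement use the sample SD (``ddof=1``) and the
  1.96 multiplier, so the limits are exactly symmetric about the bias.
* Binomial confidence intervals are Clopper-Pearson exact (beta quantiles).
* Detection thresholds are inclusive on both prediction and condition
  (a measurement *at* the threshold counts as positive).
* Group-level reduction statistics are the mean +/- SD of per-plaque
  fractional reductions, not the ratio of group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .quantify import PlaqueQuant


@dataclass
class BlandAltmanResult:
    bias: float  # mean of (measured - reference)
    sd: float  # sample SD of the differences
    loa_low: float  # bias - 1.96 * sd
    loa_high: float  # bias + 1.96 * sd
    n: int


def bland_altman(measured, reference) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements.

    Raises
    ------
    ValueError
        If the inputs differ in length or hold fewer than two pairs.
    """
    m = np.asarray(measured, dtype=np.float64)
    r = np.asarray(reference, dtype=np.float64)
    if m.shape != r.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {r.shape}")
    if m.size < 2:
        raise ValueError("need at least two pairs")
    diff = m - r
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=m.size
    )


def bias_from_limits(loa_low: float, loa_high: float) -> float:
    """Bias implied by limits of agreement (symmetry: their midpoint)."""
    return (loa_low + loa_high) / 2.0


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval, in percent.

    ``low`` is 0 when ``k == 0`` and ``high`` is 100 when ``k == n``.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, n >= 1; got k={k}, n={n}")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1)) * 100.0
    high = 100.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k)) * 100.0
    return low, high


@dataclass
class DiagnosticPerformance:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None = None  # percent; None when denominator is 0
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    ppv_ci: tuple[float, float] | None = None
    npv_ci: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def diagnostic_performance(measured, truth, threshold: float, conf: float = 0.95) -> DiagnosticPerformance:
    """Sensitivity/specificity/PPV/NPV for detecting stenosis >= threshold.

    Undefined metrics (zero denominator) are left as ``None`` rather than
    propagating NaN.
    """
    m = np.asarray(measured, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if m.shape != t.shape or m.size < 1:
        raise ValueError("measured and truth must be equal-length, non-empty")
    if not 0.0 < threshold < 100.0:
        raise ValueError(f"threshold must be in (0, 100), got {threshold}")
    pred = m >= threshold
    cond = t >= threshold
    tp = int(np.count_nonzero(pred & cond))
    fp = int(np.count_nonzero(pred & ~cond))
    tn = int(np.count_nonzero(~pred & ~cond))
    fn = int(np.count_nonzero(~pred & cond))
    result = DiagnosticPerformance(tp=tp, fp=fp, tn=tn, fn=fn)

    for name, k, n in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        if n > 0:
            setattr(result, name, 100.0 * k / n)
            setattr(result, f"{name}_ci", clopper_pearson(k, n, conf))
    return result


@dataclass
class PlaqueChange:
    """Fractional reductions after de-blooming, reported in percent."""

    rcv: float | None  # calcium-volume reduction
    rds: float | None  # diameter-stenosis reduction
    ras: float | None  # area-stenosis reduction


def _reduction(before: float, after: float) -> float | None:
    if before <= 0:
        return None
    return (before - after) / before * 100.0


def plaque_change(before: PlaqueQuant, after: PlaqueQuant) -> PlaqueChange:
    """Per-plaque reductions; a metric is ``None`` when its 'before' is 0."""
    return PlaqueChange(
        rcv=_reduction(before.calcium_volume, after.calcium_volume),
        rds=_reduction(before.diameter_stenosis_pct, after.diameter_stenosis_pct),
        ras=_reduction(before.area_stenosis_pct, after.area_stenosis_pct),
    )


@dataclass
class IQSummary:
    """Tally of 4-point image-quality scores (1 best, 4 non-diagnostic)."""

    counts: dict[int, int]
    percents: dict[int, float]  # one decimal
    percent_diagnostic: float  # scores 1-3, one decimal
    n: int

    @property
    def percent_excellent(self) -> float:
        return self.percents[1]


def iq_summary(scores) -> IQSummary:
    """Summarize image-quality scores on the 4-point scale."""
    scores = list(scores)
    if not scores:
        raise ValueError("scores must be non-empty")
    if any(int(s) not in (1, 2, 3, 4) for s in scores):
        raise ValueError("scores must all be in {1, 2, 3, 4}")
    n = len(scores)
    counts = {s: sum(1 for x in scores if int(x) == s) for s in (1, 2, 3, 4)}
    percents = {s: round(100.0 * counts[s] / n, 1) for s in (1, 2, 3, 4)}
    diagnostic = round(100.0 * (counts[1] + counts[2] + counts[3]) / n, 1)
    return IQSummary(counts=counts, percents=percents, percent_diagnostic=diagnostic, n=n)


def compare_groups(a, b) -> tuple[float, float]:
    """Two-sided two-sample t-test; returns ``(t, p)``."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def bland_altman_plot(measured, reference, path, title: str = "") -> None:
    """Save a Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(measured, reference)
    m = np.asarray(measured, float)
    r = np.asarray(reference, float)
    mean = (m + r) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, m - r, s=18)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of methods (%)")
    ax.set_ylabel("difference (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
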