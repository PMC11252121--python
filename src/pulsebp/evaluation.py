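"""Agreement metrics and device-grading standards.

Implements Pearson's r, mean difference (MD), mean absolute error (MAE),
the population standard deviation of the error (SD), and cumulative error
percentages (CP) at 5/10/15 mmHg, plus the BHS letter grade, the AAMI
pass/fail recommendation (|MD| ≤ 5 and SD ≤ 8 mmHg) and the IEEE MAE-band
letter grade, and a Bland–Altman agreement summary.

Conventions: errors are predicted − true; SD uses divisor m (population
form, not m − 1); all threshold comparisons are inclusive; the AAMI mean
difference is taken in absolute value so that a negative bias of equal
magnitude grades identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MetricReport:
    r: float
    md: float
    mae: float
    sd: float
    cp5: float
    cp10: float
    cp15: float
    m: int
    r_defined: bool = True


@dataclass
class GradeReport:
    bhs: str
    aami: str  # "Pass" | "Fail"
    ieee: str


@dataclass
class BlandAltmanSummary:
    mean_diff: float
    loa_low: float
    loa_high: float
    pct_within_5: float
    pct_within_10: float
    pct_within_15: float
    ci95_low: float
    ci95_high: float


def _pair(y, yhat, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} pairs, got {y.size}")
    return y, yhat


def pearson_r(y, yhat) -> float:
    """Pearson correlation between true and predicted values."""
    y, yhat = _pair(y, yhat, min_len=2)
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    denom = np.sqrt(np.sum(yc**2)) * np.sqrt(np.sum(pc**2))
    if denom == 0.0:
        raise ValueError("Pearson r undefined: zero variance in an input")
    return float(np.sum(yc * pc) / denom)


def mean_difference(y, yhat) -> float:
    """MD = mean(ŷ − y); sign convention: positive = over-prediction."""
    y, yhat = _pair(y, yhat)
    return float(np.mean(yhat - y))


def mae(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(yhat - y)))


def sd_error(y, yhat) -> float:
    """Population standard deviation (divisor m) of the error about MD."""
    y, yhat = _pair(y, yhat, min_len=2)
    err = yhat - y
    return float(np.sqrt(np.mean((err - err.mean()) ** 2)))


def cumulative_percent(
    y, yhat, thresholds: tuple[float, ...] = (5.0, 10.0, 15.0)
) -> tuple[float, ...]:
    """Percent of absolute errors ≤ each threshold (inclusive)."""
    y, yhat = _pair(y, yhat)
    err = np.abs(yhat - y)
    return tuple(float(100.0 * np.mean(err <= t)) for t in thresholds)


# ---------------------------------------------------------------------------
# grading

#: BHS letter thresholds: (cp5, cp10, cp15) minima, best first
_BHS_LEVELS = [("A", (60.0, 85.0, 95.0)), ("B", (50.0, 75.0, 90.0)), ("C", (40.0, 65.0, 85.0))]


def grade_bhs(cp5: float, cp10: float, cp15: float) -> str:
    """Best BHS letter whose three cumulative-percentage minima are all met."""
    for letter, (t5, t10, t15) in _BHS_LEVELS:
        if cp5 >= t5 and cp10 >= t10 and cp15 >= t15:
            return letter
    return "D"


def grade_aami(md: float, sd: float) -> str:
    """AAMI recommendation: Pass iff |MD| ≤ 5 mmHg and SD ≤ 8 mmHg."""
    return "Pass" if abs(md) <= 5.0 and sd <= 8.0 else "Fail"


def grade_ieee(mae_value: float) -> str:
    """IEEE MAE bands: A ≤ 5 < B ≤ 6 < C ≤ 7 < D."""
    if mae_value < 0:
        raise ValueError("MAE cannot be negative")
    if mae_value <= 5.0:
        return "A"
    if mae_value <= 6.0:
        return "B"
    if mae_value <= 7.0:
        return "C"
    return "D"


def bland_altman(y, yhat) -> BlandAltmanSummary:
    """Limits of agreement MD ± 1.96 SD and the 95% CI of the mean difference."""
    y, yhat = _pair(y, yhat, min_len=2)
    md = mean_difference(y, yhat)
    sd = sd_error(y, yhat)
    cp5, cp10, cp15 = cumulative_percent(y, yhat)
    half_ci = 1.96 * sd / np.sqrt(y.size)
    return BlandAltmanSummary(
        mean_diff=md,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        pct_within_5=cp5,
        pct_within_10=cp10,
        pct_within_15=cp15,
        ci95_low=md - half_ci,
        ci95_high=md + half_ci,
    )


def compute_metrics(y, yhat) -> MetricReport:
    """All agreement metrics for one prediction set.

    If either input has zero variance, Pearson's r is reported as NaN with
    ``r_defined=False`` rather than aborting the whole report.
    """
    y, yhat = _pair(y, yhat, min_len=2)
    try:
        r = pearson_r(y, yhat)
        r_defined = True
    except ValueError:
        r, r_defined = float("nan"), False
    cp5, cp10, cp15 = cumulative_percent(y, yhat)
    return MetricReport(
        r=r,
        md=mean_difference(y, yhat),
        mae=mae(y, yhat),
        sd=sd_error(y, yhat),
        cp5=cp5,
        cp10=cp10,
        cp15=cp15,
        m=int(y.size),
        r_defined=r_defined,
    )


def grade(report: MetricReport) -> GradeReport:
    return GradeReport(
        bhs=grade_bhs(report.cp5, report.cp10, report.cp15),
        aami=grade_aami(report.md, report.sd),
        ieee=grade_ieee(report.mae),
    )


def evaluate(model, test_segments) -> tuple[MetricReport, GradeReport, BlandAltmanSummary]:
    """Run a trained model on a test set and compute the full report."""
    if not test_segments:
        raise ValueError("empty test set")
    y = np.array([s.sbp for s in test_segments], dtype=float)
    target = getattr(model, "target", "sbp")
    if target == "dbp":
        y = np.array([s.dbp for s in test_segments], dtype=float)
    yhat = model.predict_segments(test_segments)
    report = compute_metrics(y, yhat)
    return report, grade(report), bland_altman(y, yhat)


def plot_report(y, yhat, out_prefix: str) -> list[str]:
    """Optional error-histogram / Bland–Altman / scatter plots (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    err = yhat - y
    ba = bland_altman(y, yhat)
    paths = []

    fig, ax = plt.subplots()
    ax.hist(err, bins=60)
    for ref in (-15, -10, -5, 5, 10, 15):
        ax.axvline(ref, color="grey", linestyle="--", linewidth=0.6)
    ax.axvline(float(err.mean()), color="k", linestyle="--")
    ax.set_xlabel("prediction error (mmHg)")
    ax.set_ylabel("count")
    p = f"{out_prefix}_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots()
    ax.scatter((y + yhat) / 2, err, s=2, alpha=0.4)
    for level in (ba.mean_diff, ba.loa_low, ba.loa_high):
        ax.axhline(level, color="k", linestyle="--", linewidth=0.8)
    ax.set_xlabel("mean of true and predicted (mmHg)")
    ax.set_ylabel("difference (mmHg)")
    p = f"{out_prefix}_bland_altman.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots()
    ax.scatter(y, yhat, s=2, alpha=0.4)
    lim = [min(y.min(), yhat.min()), max(y.max(), yhat.max())]
    ax.plot(lim, lim, "k--", linewidth=0.8)
    slope, intercept = np.polyfit(y, yhat, 1)
    ax.plot(lim, [slope * v + intercept for v in lim], color="tab:orange")
    ax.set_xlabel("true pressure (mmHg)")
    ax.set_ylabel("predicted pressure (mmHg)")
    p = f"{out_prefix}_scatter.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
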