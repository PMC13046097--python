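"""Night-scale sleep quantity measures and paired agreement statistics.

For one harmonized hypnogram: total sleep time (TST), time in each stage
(TI), proportion of the analysis window in each stage (PI), number of
episodes per stage (NE) and the count of stage changes. For a cohort of
paired (device, reference) values: mean absolute error, Bland-Altman
bias with 95% limits of agreement, proportional-bias regression, and a
seeded RANSAC robust regression of device on reference.

PI convention: the denominator is the full analysis window (so the four
PI values sum to 100%), with a total-sleep-time denominator available as
an option; the window convention is what the reported sleep-quantity
tables are arithmetically consistent with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .errors import FitError, SampleSizeError, VocabularyError
from .hypnogram import Hypnogram, extract_episodes, stage_changes
from .epoch_metrics import STAGE_ORDER

__all__ = [
    "SleepMeasures",
    "PairedMeasureStats",
    "RansacFit",
    "compute_measures",
    "paired_stats",
    "ransac_regression",
    "MEASURE_NAMES",
]

#: The per-night scalar measures compared between device and reference.
MEASURE_NAMES: tuple[str, ...] = (
    "tst_min",
    "ti_rem_min", "ti_light_min", "ti_deep_min", "ti_wake_min",
    "pi_rem_pct", "pi_light_pct", "pi_deep_pct", "pi_wake_pct",
    "ne_rem", "ne_light", "ne_deep", "ne_wake",
    "stage_changes",
)


@dataclass(frozen=True)
class SleepMeasures:
    """Night-scale summaries of one hypnogram (minutes / percent / counts)."""

    tst_min: float
    ti_min: dict[str, float]
    pi_pct: dict[str, float]
    ne: dict[str, int]
    stage_changes: int
    window_min: float

    def flat(self) -> dict[str, float]:
        out = {"tst_min": self.tst_min}
        for s in STAGE_ORDER:
            if s == "WAKE":
                continue
            out[f"ti_{s.lower()}_min"] = self.ti_min[s]
        out["ti_wake_min"] = self.ti_min["WAKE"]
        for s in ("REM", "LIGHT", "DEEP", "WAKE"):
            out[f"pi_{s.lower()}_pct"] = self.pi_pct[s]
        for s in ("REM", "LIGHT", "DEEP", "WAKE"):
            out[f"ne_{s.lower()}"] = self.ne[s]
        out["stage_changes"] = self.stage_changes
        out["window_min"] = self.window_min
        return out


@dataclass(frozen=True)
class PairedMeasureStats:
    """Device-vs-reference agreement for one measure across nights."""

    mae: float
    mae_ci95: tuple[float, float]
    bias: float
    bias_ci95: tuple[float, float]
    loa_low: float
    loa_high: float
    prop_bias_slope: float
    prop_bias_p: float
    n_nights: int


@dataclass(frozen=True)
class RansacFit:
    slope: float
    intercept: float
    r2: float
    inlier_fraction: float
    slope_p: float
    seed: int


def compute_measures(h: Hypnogram, pi_denominator: str = "window") -> SleepMeasures:
    """Sleep quantity measures of a HARMONIZED4 hypnogram.

    TI is epoch count times epoch duration; TST is the analysis window
    minus wake time; PI is TI over the window (default) or over TST;
    NE counts maximal same-stage runs; stage changes count adjacent
    differing epoch pairs at the hypnogram's native resolution.
    """
    if h.vocabulary.name != "HARMONIZED4":
        raise VocabularyError("measures are defined on HARMONIZED4 hypnograms")
    window_min = h.duration_s / 60.0
    ti = {s: 0.0 for s in STAGE_ORDER}
    for s in h.stages:
        ti[s] += h.epoch_s / 60.0
    tst = window_min - ti["WAKE"]
    if pi_denominator == "window":
        denom = window_min
    elif pi_denominator == "tst":
        denom = tst
    else:
        raise ValueError(f"unknown pi_denominator {pi_denominator!r}")
    pi = {s: (100.0 * ti[s] / denom if denom > 0 else float("nan")) for s in STAGE_ORDER}
    ne = {s: 0 for s in STAGE_ORDER}
    for ep in extract_episodes(h):
        ne[ep.stage] += 1
    return SleepMeasures(
        tst_min=tst,
        ti_min=ti,
        pi_pct=pi,
        ne=ne,
        stage_changes=stage_changes(h),
        window_min=window_min,
    )


def paired_stats(
    device_vals,
    ref_vals,
    ci_method: str = "normal",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> PairedMeasureStats:
    """MAE, Bland-Altman bias and limits of agreement for paired nights.

    Differences are device minus reference. Limits of agreement are
    ``bias +/- 1.96 * SD(diff)``; CIs for the MAE and the bias use the
    normal approximation (``1.96 * SD / sqrt(n)``) by default or a
    seeded percentile bootstrap. Proportional bias is the least-squares
    slope of the differences on the pairwise means, with its two-sided
    p value.
    """
    dev = np.asarray(device_vals, dtype=float)
    ref = np.asarray(ref_vals, dtype=float)
    if dev.shape != ref.shape or dev.ndim != 1:
        raise SampleSizeError("device and reference value arrays must match")
    n = dev.size
    if n < 2:
        raise SampleSizeError("need at least 2 paired nights")
    diff = dev - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    mae = float(np.abs(diff).mean())
    if ci_method == "normal":
        mae_half = 1.96 * float(np.abs(diff).std(ddof=1)) / np.sqrt(n)
        bias_half = 1.96 * sd / np.sqrt(n)
        mae_ci = (mae - mae_half, mae + mae_half)
        bias_ci = (bias - bias_half, bias + bias_half)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = diff[idx]
        mae_ci = tuple(float(q) for q in np.percentile(np.abs(boot).mean(axis=1), [2.5, 97.5]))
        bias_ci = tuple(float(q) for q in np.percentile(boot.mean(axis=1), [2.5, 97.5]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    means = (dev + ref) / 2.0
    if np.ptp(means) > 0 and np.ptp(diff) > 0:
        fit = stats.linregress(means, diff)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
    else:
        slope, slope_p = 0.0, 1.0
    return PairedMeasureStats(
        mae=mae,
        mae_ci95=mae_ci,
        bias=bias,
        bias_ci95=bias_ci,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        prop_bias_slope=slope,
        prop_bias_p=slope_p,
        n_nights=int(n),
    )


def ransac_regression(
    device_vals,
    ref_vals,
    seed: int,
    residual_threshold: float | None = None,
    n_iter: int = 1000,
) -> RansacFit:
    """Seeded RANSAC line of device values on reference values.

    The default residual threshold is the median absolute deviation of
    the residuals of an initial least-squares fit. R^2 and the slope's
    t-test p value are computed on the inlier set.
    """
    dev = np.asarray(device_vals, dtype=float)
    ref = np.asarray(ref_vals, dtype=float)
    if dev.size != ref.size or dev.size < 3:
        raise SampleSizeError("need at least 3 paired nights for a robust fit")
    if np.ptp(ref) == 0:
        raise FitError("reference values are constant; line undefined")
    X = ref.reshape(-1, 1)
    if residual_threshold is None:
        ls = LinearRegression().fit(X, dev)
        resid = dev - ls.predict(X)
        residual_threshold = float(np.median(np.abs(resid - np.median(resid))))
        if residual_threshold == 0:
            residual_threshold = max(1e-9, float(np.std(resid)))
    try:
        model = RANSACRegressor(
            estimator=LinearRegression(),
            residual_threshold=residual_threshold,
            max_trials=n_iter,
            random_state=seed,
        ).fit(X, dev)
    except ValueError as exc:
        raise FitError(f"RANSAC fit failed: {exc}") from exc
    inliers = model.inlier_mask_
    if inliers.sum() < 2 or np.ptp(ref[inliers]) == 0:
        raise FitError("degenerate inlier set")
    fit = stats.linregress(ref[inliers], dev[inliers])
    return RansacFit(
        slope=float(model.estimator_.coef_[0]),
        intercept=float(model.estimator_.intercept_),
        r2=float(fit.rvalue**2),
        inlier_fraction=float(inliers.mean()),
        slope_p=float(fit.pvalue),
        seed=int(seed),
    )
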