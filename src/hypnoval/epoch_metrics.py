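"""Epoch-by-epoch classification statistics.

Confusion matrices over the canonical four-stage vocabulary (rows =
reference, columns = device, order WAKE, REM, LIGHT, DEEP), one-vs-rest
sensitivity and specificity per stage, overall accuracy and Cohen kappa
for both the 4-stage and the sleep-wake task, per-night aggregation
with normal-approximation 95% CIs, pooled matrices, and the stratified
(agreement vs disagreement) comparison with two-proportion z tests.

Reporting convention: per-night metrics are averaged across nights
("mean of results per night"); pooled-epoch variants are emitted
separately and labeled as such. Nights with zero reference support for
a stage carry NaN for that stage's sensitivity and are excluded from
its average rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyNightError, HypnovalError, StratumError
from .hypnogram import AlignedPair

__all__ = [
    "STAGE_ORDER",
    "ConfusionMatrix4",
    "NightClassificationMetrics",
    "confusion",
    "night_metrics",
    "aggregate_nights",
    "pooled_confusion",
    "two_proportion_z",
    "compare_strata",
]

STAGE_ORDER: tuple[str, ...] = ("WAKE", "REM", "LIGHT", "DEEP")
_IDX = {s: i for i, s in enumerate(STAGE_ORDER)}


@dataclass(frozen=True)
class ConfusionMatrix4:
    """4x4 stage-by-stage epoch counts; rows reference, columns device."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (4, 4) or (c < 0).any():
            raise HypnovalError("confusion counts must be a non-negative 4x4 matrix")
        object.__setattr__(self, "counts", c)

    @property
    def n_epochs(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self, decimals: int = 1) -> pd.DataFrame:
        """Row percentages (rows sum to 100 up to rounding); all-zero rows stay 0."""
        c = self.counts.astype(float)
        sums = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, 100.0 * c / sums, 0.0)
        return pd.DataFrame(np.round(pct, decimals), index=STAGE_ORDER, columns=STAGE_ORDER)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=STAGE_ORDER, columns=STAGE_ORDER)

    def collapse_sleep_wake(self) -> np.ndarray:
        """2x2 counts [[wake,sleep],[wake,sleep]] with SLEEP = REM+LIGHT+DEEP."""
        c = self.counts
        w = _IDX["WAKE"]
        s = [i for i in range(4) if i != w]
        return np.array(
            [
                [c[w, w], c[w, s].sum()],
                [c[s, w].sum(), c[np.ix_(s, s)].sum()],
            ],
            dtype=np.int64,
        )


@dataclass(frozen=True)
class NightClassificationMetrics:
    """One night's agreement statistics. NaN marks an undefined metric."""

    kappa4: float
    accuracy4: float
    se: dict[str, float]
    sp: dict[str, float]
    kappa2: float
    accuracy2: float
    se_sleep: float
    sp_sleep: float
    support: dict[str, int]

    def flat(self) -> dict[str, float]:
        out = {"kappa4": self.kappa4, "accuracy4": self.accuracy4}
        for s in STAGE_ORDER:
            out[f"se_{s.lower()}"] = self.se[s]
        for s in STAGE_ORDER:
            out[f"sp_{s.lower()}"] = self.sp[s]
        out.update(
            kappa2=self.kappa2,
            accuracy2=self.accuracy2,
            se_sleep=self.se_sleep,
            sp_sleep=self.sp_sleep,
        )
        return out


def confusion(pair: AlignedPair) -> ConfusionMatrix4:
    """Count valid epochs of an aligned pair into the canonical 4x4 matrix."""
    ref, dev = pair.valid_arrays()
    if ref.size == 0:
        raise EmptyNightError(f"night {pair.subject_id}: zero valid epochs")
    counts = np.zeros((4, 4), dtype=np.int64)
    ri = np.array([_IDX[s] for s in ref])
    di = np.array([_IDX[s] for s in dev])
    np.add.at(counts, (ri, di), 1)
    return ConfusionMatrix4(counts)


def _kappa_from_counts(cm: np.ndarray) -> float:
    total = cm.sum()
    po = np.trace(cm) / total
    pe = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0)) / total**2)
    if abs(1.0 - pe) < 1e-12:
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def night_metrics(cm: ConfusionMatrix4) -> NightClassificationMetrics:
    """One-vs-rest Se/Sp per stage, accuracy and kappa for both tasks.

    By construction ``se_wake == sp_sleep`` and ``sp_wake == se_sleep``
    exactly: wake is the negative class of the sleep-wake task.
    """
    c = cm.counts.astype(float)
    n = c.sum()
    if n == 0:
        raise EmptyNightError("empty confusion matrix")
    se: dict[str, float] = {}
    sp: dict[str, float] = {}
    support: dict[str, int] = {}
    for s, i in _IDX.items():
        tp = c[i, i]
        fn = c[i, :].sum() - tp
        fp = c[:, i].sum() - tp
        tn = n - tp - fn - fp
        support[s] = int(tp + fn)
        se[s] = float(tp / (tp + fn)) if (tp + fn) > 0 else float("nan")
        sp[s] = float(tn / (tn + fp)) if (tn + fp) > 0 else float("nan")
    c2 = cm.collapse_sleep_wake().astype(float)
    # rows/cols: 0 = WAKE, 1 = SLEEP
    se_sleep = float(c2[1, 1] / c2[1, :].sum()) if c2[1, :].sum() > 0 else float("nan")
    sp_sleep = float(c2[0, 0] / c2[0, :].sum()) if c2[0, :].sum() > 0 else float("nan")
    return NightClassificationMetrics(
        kappa4=_kappa_from_counts(c),
        accuracy4=float(np.trace(c) / n),
        se=se,
        sp=sp,
        kappa2=_kappa_from_counts(c2),
        accuracy2=float(np.trace(c2) / n),
        se_sleep=se_sleep,
        sp_sleep=sp_sleep,
        support=support,
    )


def aggregate_nights(
    metrics: Sequence[NightClassificationMetrics],
    ci_method: str = "normal",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cohort summary: per-metric mean, SD and 95% CI across nights.

    Nights where a metric is undefined (NaN) are excluded from that
    metric's average and its ``n``. The default CI is the normal
    approximation ``mean +/- 1.96 * SD / sqrt(n)``; ``ci_method=
    'bootstrap'`` uses a seeded percentile bootstrap instead.
    """
    if len(metrics) < 2:
        raise HypnovalError("need >= 2 nights to aggregate")
    table = pd.DataFrame([m.flat() for m in metrics])
    rows = []
    rng = np.random.default_rng(seed)
    for name in table.columns:
        vals = table[name].dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"metric {name} undefined on every night; omitted", stacklevel=2)
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        if ci_method == "normal":
            half = 1.96 * sd / np.sqrt(vals.size)
            lo, hi = mean - half, mean + half
        elif ci_method == "bootstrap":
            idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
            means = vals[idx].mean(axis=1)
            lo, hi = (float(q) for q in np.percentile(means, [2.5, 97.5]))
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        rows.append(
            {
                "metric": name,
                "mean": mean,
                "sd": sd,
                "ci95_low": float(lo),
                "ci95_high": float(hi),
                "n_nights_used": int(vals.size),
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def pooled_confusion(cms: Sequence[ConfusionMatrix4]) -> tuple[ConfusionMatrix4, pd.DataFrame]:
    """Element-wise sum of per-night matrices plus the row-normalized form."""
    if not cms:
        raise HypnovalError("need at least one matrix")
    total = ConfusionMatrix4(np.sum([cm.counts for cm in cms], axis=0))
    return total, total.row_normalized()


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z test; returns (z, two-sided p).

    z = (p1 - p2) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2)) with the
    pooled proportion p_hat. Degenerate pooling (p_hat 0 or 1) yields
    (nan, nan).
    """
    if n1 <= 0 or n2 <= 0 or not (0 <= x1 <= n1) or not (0 <= x2 <= n2):
        raise HypnovalError("invalid success/trial counts")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return float("nan"), float("nan")
    z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_strata(
    agreement_pairs: Sequence[AlignedPair],
    disagreement_pairs: Sequence[AlignedPair],
    ci_method: str = "normal",
) -> pd.DataFrame:
    """Performance on reviewer-agreement vs -disagreement epochs.

    Reports, per metric and per stratum, the across-night mean with its
    95% CI (NaN-aware), plus pooled epoch counts and a z score from the
    pooled-proportion two-sample z test. For kappa — not a proportion —
    the z score is computed on the pooled observed-agreement proportion.
    """
    sides = {}
    for label, pairs in (("agreement", agreement_pairs), ("disagreement", disagreement_pairs)):
        cms = []
        mets = []
        for p in pairs:
            try:
                cm = confusion(p)
            except EmptyNightError:
                continue
            cms.append(cm)
            mets.append(night_metrics(cm))
        if not cms:
            raise StratumError(f"{label} stratum has no valid epochs")
        pooled, _ = pooled_confusion(cms)
        sides[label] = {
            "pooled": pooled,
            "summary": aggregate_nights(mets, ci_method=ci_method) if len(mets) > 1 else None,
            "metrics": mets,
        }

    n_a = sides["agreement"]["pooled"].n_epochs
    n_d = sides["disagreement"]["pooled"].n_epochs
    total = n_a + n_d

    rows = []
    for metric in [
        "kappa4", "accuracy4",
        *(f"se_{s.lower()}" for s in STAGE_ORDER),
        *(f"sp_{s.lower()}" for s in STAGE_ORDER),
        "kappa2", "accuracy2", "se_sleep", "sp_sleep",
    ]:
        row: dict[str, float | str] = {"metric": metric}
        for label in ("agreement", "disagreement"):
            summary = sides[label]["summary"]
            if summary is not None and metric in summary.index:
                row[f"{label}_mean"] = summary.loc[metric, "mean"]
                row[f"{label}_ci95_low"] = summary.loc[metric, "ci95_low"]
                row[f"{label}_ci95_high"] = summary.loc[metric, "ci95_high"]
            else:
                vals = [m.flat()[metric] for m in sides[label]["metrics"]]
                vals = [v for v in vals if not np.isnan(v)]
                row[f"{label}_mean"] = float(np.mean(vals)) if vals else float("nan")
                row[f"{label}_ci95_low"] = float("nan")
                row[f"{label}_ci95_high"] = float("nan")
        xa, na = _pooled_counts(sides["agreement"]["pooled"], metric)
        xd, nd = _pooled_counts(sides["disagreement"]["pooled"], metric)
        if na > 0 and nd > 0:
            z, _ = two_proportion_z(xa, na, xd, nd)
        else:
            z = float("nan")
        row["z"] = z
        rows.append(row)

    out = pd.DataFrame(rows).set_index("metric")
    out.attrs["epochs"] = {
        "agreement": {"n": n_a, "pct": round(100.0 * n_a / total, 1)},
        "disagreement": {"n": n_d, "pct": round(100.0 * n_d / total, 1)},
    }
    return out


def _pooled_counts(cm: ConfusionMatrix4, metric: str) -> tuple[int, int]:
    """(successes, trials) of a metric as a pooled-epoch proportion."""
    c = cm.counts
    n = c.sum()
    c2 = cm.collapse_sleep_wake()
    if metric in ("accuracy4", "kappa4"):
        return int(np.trace(c)), int(n)
    if metric in ("accuracy2", "kappa2"):
        return int(np.trace(c2)), int(n)
    if metric == "se_sleep":
        return int(c2[1, 1]), int(c2[1, :].sum())
    if metric == "sp_sleep":
        return int(c2[0, 0]), int(c2[0, :].sum())
    kind, _, stage = metric.partition("_")
    i = _IDX[stage.upper()]
    if kind == "se":
        return int(c[i, i]), int(c[i, :].sum())
    if kind == "sp":
        tn = n - c[i, :].sum() - c[:, i].sum() + c[i, i]
        return int(tn), int(n - c[i, :].sum())
    raise KeyError(metric)
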