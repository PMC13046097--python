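"""Inter-device clock synchronization from respiratory traces.

The reference recorder and the under-mattress device keep independent
clocks. Both observe the same breathing motion, so the clock offset is
estimated by maximizing the Pearson correlation between the two
respiratory traces over a grid of candidate lags. The estimated offset
is then applied to the device hypnogram, snapping to the reference's
30-s epoch grid, and a shift-sensitivity analysis quantifies how much
the epoch-by-epoch classification metrics depend on residual
misalignment.

Conventions: ``offset_s`` is device-clock minus reference-clock; an
event at reference time ``t`` appears at device time ``t + offset_s``.
Correlation is computed only on the overlapping support of the two
series at each lag (no zero padding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateSignalError, WindowError
from .hypnogram import AlignedPair, Hypnogram

__all__ = [
    "RespiratorySeries",
    "OffsetEstimate",
    "estimate_offset",
    "apply_offset",
    "shift_sensitivity",
]


@dataclass(frozen=True)
class RespiratorySeries:
    """A uniformly sampled respiratory trace (arbitrary units)."""

    source: str
    rate_hz: float
    t0_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise DataError("respiratory series needs >= 2 samples")

    @property
    def duration_s(self) -> float:
        return (self.values.size - 1) / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.rate_hz


@dataclass(frozen=True)
class OffsetEstimate:
    """Result of the lag search: the arg-max lag and the whole curve."""

    offset_s: float
    peak_r: float
    curve: pd.DataFrame  # columns: lag_s, r
    low_confidence: bool = False


def read_respiratory(path, source: str | None = None) -> RespiratorySeries:
    """Read a respiratory CSV (header ``t_s,value``, ``# key=value`` comments)."""
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
        else:
            data_lines.append(line)
    if not data_lines or data_lines[0].replace(" ", "") != "t_s,value":
        raise DataError(f"{path}: expected header 't_s,value'")
    arr = np.loadtxt(data_lines[1:], delimiter=",", ndmin=2)
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    mean_dt = (t[-1] - t[0]) / (t.size - 1)
    if not np.allclose(dt, mean_dt, rtol=0, atol=max(1e-5, 1e-4 * mean_dt)):
        raise DataError(f"{path}: non-uniform sampling")
    return RespiratorySeries(
        source=source or meta.get("source", "unknown"),
        rate_hz=1.0 / mean_dt,
        t0_s=float(t[0]),
        values=v,
    )


def write_respiratory(series: RespiratorySeries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# source={series.source}\n")
        fh.write("t_s,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.6f},{v:.6f}\n")


def _resample(series: RespiratorySeries, rate_hz: float) -> np.ndarray:
    """Linear resampling of the series onto its own span at ``rate_hz``."""
    n = int(np.floor(series.duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    return np.interp(t, series.times - series.t0_s, series.values)


def estimate_offset(
    ref: RespiratorySeries,
    dev: RespiratorySeries,
    max_lag_s: float = 300.0,
    step_s: float = 0.5,
    low_confidence_r: float = 0.3,
) -> OffsetEstimate:
    """Estimate the device clock offset by exhaustive lag search.

    Both series are linearly resampled to the higher of the two rates
    (at least ``1/step_s``), and the Pearson correlation between the
    reference at time ``t`` and the device at time ``t + lag`` is
    evaluated for every lag on the grid ``-max_lag_s .. max_lag_s`` with
    spacing ``step_s``. The offset estimate is the arg-max lag.

    A peak correlation below ``low_confidence_r`` triggers a warning and
    a fallback to offset 0 with the ``low_confidence`` flag set.
    """
    rate = max(ref.rate_hz, dev.rate_hz, 1.0 / step_s)
    x = _resample(ref, rate)
    y = _resample(dev, rate)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSignalError("flat respiratory signal cannot be correlated")

    base = (ref.t0_s - dev.t0_s) * rate  # device index of ref sample 0 at lag 0
    lag_samples = np.unique(np.round(np.arange(-max_lag_s, max_lag_s + step_s / 2, step_s) * rate).astype(int))

    lags_out: list[float] = []
    rs: list[float] = []
    min_overlap = max(int(2 * rate), 8)
    for k in lag_samples:
        shift = int(round(base + k))
        lo = max(0, -shift)
        hi = min(x.size, y.size - shift)
        if hi - lo < min_overlap:
            continue
        xs = x[lo:hi]
        ys = y[lo + shift : hi + shift]
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            r = 0.0
        else:
            r = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))
        lags_out.append(k / rate)
        rs.append(r)
    if not lags_out:
        raise DataError("series overlap insufficient for the requested lag range")

    curve = pd.DataFrame({"lag_s": lags_out, "r": rs})
    i = int(np.argmax(curve["r"].to_numpy()))
    peak_r = float(curve["r"].iloc[i])
    offset = float(curve["lag_s"].iloc[i])
    low = peak_r < low_confidence_r
    if low:
        warnings.warn(
            f"peak breathing correlation {peak_r:.3f} below {low_confidence_r}; "
            "falling back to offset 0",
            stacklevel=2,
        )
        offset = 0.0
    return OffsetEstimate(offset_s=offset, peak_r=peak_r, curve=curve, low_confidence=low)


def snap_offset_epochs(offset_s: float, grid_s: float = 30.0) -> int:
    """Whole-epoch shift nearest to ``offset_s``; half-grid ties round toward 0."""
    q = offset_s / grid_s
    frac = abs(q) - np.floor(abs(q))
    if abs(frac - 0.5) < 1e-9:
        return int(np.sign(q) * np.floor(abs(q)))
    return int(round(q))


def apply_offset(h: Hypnogram, offset_s: float, grid_s: float = 30.0) -> Hypnogram:
    """Correct a device hypnogram onto the reference clock.

    The onset is shifted by ``-offset_s`` and the result re-snapped to
    the nearest ``grid_s`` boundary of the reference grid; ties at
    exactly half a grid step round toward zero net shift, so an offset
    of 14 s leaves a grid-aligned hypnogram unshifted while 16 s moves
    it one epoch.
    """
    corrected = h.onset_s - offset_s
    k = snap_offset_epochs(h.onset_s - corrected, grid_s)  # = snap(offset)
    snapped = h.onset_s - k * grid_s
    # If the original onset was off-grid (a real-valued clock offset was
    # simulated or measured), snap the corrected onset itself.
    if abs(snapped / grid_s - round(snapped / grid_s)) > 1e-6:
        q = corrected / grid_s
        frac = abs(q) - np.floor(abs(q))
        if abs(frac - 0.5) < 1e-9:
            snapped = np.sign(q) * np.floor(abs(q)) * grid_s
        else:
            snapped = round(q) * grid_s
    return replace(h, onset_s=float(snapped))


def shift_sensitivity(
    pairs: Sequence[AlignedPair],
    shifts_s: Iterable[float] = tuple(range(-90, 91, 30)),
) -> pd.DataFrame:
    """Per-stage Se/Sp of the cohort under deliberate temporal shifts.

    For each shift the device sequence of every pair is displaced by the
    corresponding number of 30-s epochs (edge epochs invalidated) and the
    cohort-mean one-vs-rest sensitivity and specificity of every stage
    are recomputed. Returns a table with one row per metric, one column
    per shift, and an ``sd`` column holding the sample SD across shifts.
    """
    from .epoch_metrics import confusion, night_metrics  # cyclic at import time

    shifts = [float(s) for s in shifts_s]
    span = min(p.n_epochs for p in pairs) * 30.0
    if any(abs(s) >= span for s in shifts):
        raise WindowError("shift exceeds the shortest recording span")

    rows: dict[str, list[float]] = {}
    for s in shifts:
        k = snap_offset_epochs(s)
        per_night: list[dict[str, float]] = []
        for p in pairs:
            per_night.append(_shifted_metrics(p, k))
        for metric in per_night[0]:
            vals = [m[metric] for m in per_night if not np.isnan(m[metric])]
            rows.setdefault(metric, []).append(float(np.mean(vals)) if vals else np.nan)

    table = pd.DataFrame(rows, index=[f"{int(s):+d}s" for s in shifts]).T
    sds = table.std(axis=1, ddof=1) if len(shifts) > 1 else pd.Series(0.0, index=table.index)
    table["sd"] = sds.fillna(0.0) if len(shifts) > 1 else 0.0
    return table


def _shifted_metrics(pair: AlignedPair, k: int) -> dict[str, float]:
    from .epoch_metrics import confusion, night_metrics

    n = pair.n_epochs
    dev = np.roll(np.asarray(pair.device, dtype=object), k)
    mask = np.asarray(pair.valid_mask, dtype=bool) & np.roll(np.asarray(pair.valid_mask, dtype=bool), k)
    if k > 0:
        mask[:k] = False
    elif k < 0:
        mask[k:] = False
    shifted = replace(pair, device=tuple(dev), valid_mask=tuple(bool(b) for b in mask))
    m = night_metrics(confusion(shifted))
    out: dict[str, float] = {}
    for stage in ("WAKE", "REM", "LIGHT", "DEEP"):
        out[f"se_{stage.lower()}"] = m.se[stage]
        out[f"sp_{stage.lower()}"] = m.sp[stage]
    return out
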