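"""Seeded generators for everything the validation pipeline consumes.

The generator emulates the structure of a home validation cohort:

* ground-truth sleep architecture as a first-order Markov chain over the
  five AASM stages on 30-s epochs, padded with quiet pre- and post-sleep
  wake, sized so a night spans roughly 9-11 hours with about 30% wake
  and a mean total sleep time near 7 1/4 h;
* two imperfect reviewers drawn epoch-wise from per-reviewer confusion
  matrices whose off-diagonal mass concentrates where human scorers
  actually disagree (N2 vs N3, N1 vs wake/REM), plus an adjudicator;
* the device: the truth mapped to the four-stage vocabulary, majority
  smoothed to 6-min windows, passed through a 4x4 emission matrix whose
  default sends most misclassification into LIGHT, with bed-absence
  head/tail windows and a configurable clock offset;
* paired respiratory traces (shared latent sinusoid with a slowly
  drifting rate, independent noise, the device copy delayed by the
  clock offset) for the synchronization stage;
* a participant metadata table with the demographic, questionnaire and
  environment columns the subgroup analyses consume.

All randomness flows from ``numpy.random.SeedSequence``; per-subject
child seeds are keyed by subject index so a cohort is stable under
subject-count changes, and regenerating from the manifest reproduces
byte-identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .hypnogram import (
    Hypnogram,
    broadcast,
    map_stages,
    smooth_majority,
    write_hypnogram,
)
from .stages import DEVICE5, HARMONIZED4, PSG5
from .sync import RespiratorySeries, write_respiratory

__all__ = [
    "ArchitectureModel",
    "ReviewerModel",
    "DeviceModel",
    "RespirationModel",
    "CohortConfig",
    "SubjectRecord",
    "SyntheticBundle",
    "simulate_truth",
    "simulate_reviewers",
    "simulate_device",
    "simulate_breathing",
    "simulate_metadata",
    "simulate_cohort",
    "write_bundle",
]

_PSG5_ORDER = PSG5.stages  # (WAKE, N1, N2, N3, REM)
_H4_ORDER = HARMONIZED4.stages  # (WAKE, REM, LIGHT, DEEP)


def _default_transition() -> np.ndarray:
    """Rank-one switching chain: stay with prob 1-a, else redraw from pi.

    The stationary distribution is exactly ``pi``; with a = 0.06 per
    30-s step the mean dwell time is ~10-13 min per stage. ``pi`` is set
    so the harmonized occupancy lands near wake 25% (30% once quiet-wake
    padding is added), light 30%, deep 27%, REM 18%.
    """
    pi = np.array([0.25, 0.07, 0.23, 0.27, 0.18])
    a = 0.06
    return (1 - a) * np.eye(5) + a * np.tile(pi, (5, 1))


def _default_reviewer_confusion() -> np.ndarray:
    # rows/cols in PSG5 order WAKE, N1, N2, N3, REM; off-diagonal mass
    # concentrated N2<->N3 and N1<->WAKE/REM.
    return np.array(
        [
            [0.88, 0.06, 0.03, 0.01, 0.02],
            [0.12, 0.70, 0.10, 0.01, 0.07],
            [0.01, 0.02, 0.86, 0.08, 0.03],
            [0.01, 0.01, 0.13, 0.85, 0.00],
            [0.03, 0.05, 0.04, 0.00, 0.88],
        ]
    )


def _default_emission() -> np.ndarray:
    # rows truth, cols device, HARMONIZED4 order WAKE, REM, LIGHT, DEEP.
    # Misclassification flows predominantly into LIGHT.
    return np.array(
        [
            [0.73, 0.035, 0.20, 0.035],
            [0.05, 0.53, 0.37, 0.05],
            [0.107, 0.107, 0.68, 0.106],
            [0.02, 0.02, 0.40, 0.56],
        ]
    )


def _check_stochastic(m: np.ndarray, name: str, n: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n, n) or (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigError(f"{name} must be a {n}x{n} row-stochastic matrix")
    return m


@dataclass(frozen=True)
class ArchitectureModel:
    """Markov-chain sleep architecture plus quiet-wake padding."""

    initial_dist: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0, 0]))
    transition: np.ndarray = field(default_factory=_default_transition)
    night_epochs: tuple[int, int] = (1100, 1300)  # total, uniform inclusive
    pre_sleep_wake_epochs: tuple[int, int] = (20, 60)
    post_sleep_wake_epochs: tuple[int, int] = (20, 60)

    def __post_init__(self) -> None:
        object.__setattr__(self, "transition", _check_stochastic(self.transition, "transition", 5))
        init = np.asarray(self.initial_dist, dtype=float)
        if init.shape != (5,) or (init < 0).any() or abs(init.sum() - 1) > 1e-9:
            raise ConfigError("initial_dist must be a probability vector over the 5 stages")
        object.__setattr__(self, "initial_dist", init)
        if self.night_epochs[0] < 120:
            raise ConfigError("nights shorter than 120 epochs (1 h) are not supported")

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the chain by eigen-decomposition."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, i])
        return v / v.sum()


@dataclass(frozen=True)
class ReviewerModel:
    """Per-reviewer stage-emission (confusion) matrices and adjudication."""

    confusion_r1: np.ndarray = field(default_factory=_default_reviewer_confusion)
    confusion_r2: np.ndarray = field(default_factory=_default_reviewer_confusion)
    adjudicator_policy: str | np.ndarray = "truth"

    def __post_init__(self) -> None:
        object.__setattr__(self, "confusion_r1", _check_stochastic(self.confusion_r1, "confusion_r1", 5))
        object.__setattr__(self, "confusion_r2", _check_stochastic(self.confusion_r2, "confusion_r2", 5))
        if isinstance(self.adjudicator_policy, str):
            if self.adjudicator_policy != "truth":
                raise ConfigError("adjudicator_policy must be 'truth' or a 5x5 matrix")
        else:
            object.__setattr__(
                self,
                "adjudicator_policy",
                _check_stochastic(self.adjudicator_policy, "adjudicator_policy", 5),
            )


@dataclass(frozen=True)
class DeviceModel:
    """Device staging as an emission matrix over the smoothed truth."""

    emission: np.ndarray = field(default_factory=_default_emission)
    clock_offset_s: float = 0.0
    absence_head_windows: tuple[int, int] = (0, 3)
    absence_tail_windows: tuple[int, int] = (0, 3)
    window_s: float = 360.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "emission", _check_stochastic(self.emission, "emission", 4))
        if abs(self.clock_offset_s) > 300:
            raise ConfigError("|clock_offset_s| must be <= 300 s")


@dataclass(frozen=True)
class RespirationModel:
    """Shared latent breathing sinusoid with a random-walk rate."""

    base_rate_bpm: tuple[float, float] = (12.0, 18.0)
    rate_rw_sd: float = 0.5  # bpm random-walk step per minute
    amplitude: float = 1.0
    noise_sd: float = 0.1414  # amplitude RMS / noise_sd ~ SNR 5
    rate_ref_hz: float = 4.0
    rate_dev_hz: float = 3.5

    def __post_init__(self) -> None:
        if min(self.base_rate_bpm) <= 0 or self.rate_ref_hz <= 0 or self.rate_dev_hz <= 0:
            raise ConfigError("rates must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def scale_emission_error(emission: np.ndarray, multiplier: float, floor: float = 0.02) -> np.ndarray:
    """Scale a device emission matrix's off-diagonal (error) mass.

    Each row's off-diagonal probabilities are multiplied by
    ``multiplier`` and the diagonal absorbs the difference, floored at
    ``floor`` (the row's errors are rescaled if the floor binds).
    """
    e = np.asarray(emission, dtype=float).copy()
    for i in range(e.shape[0]):
        off = e[i].sum() - e[i, i]
        new_off = off * multiplier
        if new_off > 1 - floor:
            new_off = 1 - floor
        scale = new_off / off if off > 0 else 0.0
        row = e[i] * scale
        row[i] = 1.0 - new_off
        e[i] = row
    return e


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _uniform_int(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    if hi < lo:
        raise ConfigError(f"invalid count bounds {bounds}")
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_truth(model: ArchitectureModel, seed, subject_id: str = "synthetic") -> Hypnogram:
    """Sample one night's ground-truth hypnogram (PSG5, 30 s, onset 0)."""
    rng = _rng(seed)
    total = _uniform_int(rng, model.night_epochs)
    pre = _uniform_int(rng, model.pre_sleep_wake_epochs)
    post = _uniform_int(rng, model.post_sleep_wake_epochs)
    core = total - pre - post
    if core < 1:
        raise ConfigError("padding leaves no core sleep epochs")

    t = model.transition
    if t[0, 0] >= 1.0 - 1e-12 and model.initial_dist[0] >= 1.0 - 1e-12:
        warnings.warn("absorbing-wake transition matrix: the night never sleeps", stacklevel=2)
    cum = np.cumsum(t, axis=1)
    cum_init = np.cumsum(model.initial_dist)
    u = rng.random(core)
    states = np.empty(core, dtype=np.intp)
    states[0] = int(np.searchsorted(cum_init, u[0], side="right"))
    for i in range(1, core):
        states[i] = int(np.searchsorted(cum[states[i - 1]], u[i], side="right"))
    states = np.minimum(states, 4)

    stages = (
        ("WAKE",) * pre
        + tuple(_PSG5_ORDER[s] for s in states)
        + ("WAKE",) * post
    )
    return Hypnogram(subject_id, "truth", 0.0, 30.0, stages, PSG5)


def _emit(codes: np.ndarray, matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized per-element categorical draw: row ``codes[i]`` of ``matrix``."""
    cum = np.cumsum(matrix, axis=1)[codes]
    u = rng.random(codes.size)
    return np.minimum((u[:, None] > cum).sum(axis=1), matrix.shape[1] - 1)


def simulate_reviewers(
    truth: Hypnogram, model: ReviewerModel, seed
) -> tuple[Hypnogram, Hypnogram, Hypnogram]:
    """Draw two reviewers' annotations and the adjudicator's reading."""
    rng = _rng(seed)
    codes = truth.codes()
    out = []
    for source, matrix in (("reviewer1", model.confusion_r1), ("reviewer2", model.confusion_r2)):
        drawn = _emit(codes, matrix, rng)
        out.append(
            dc_replace(truth, source=source, stages=tuple(_PSG5_ORDER[i] for i in drawn))
        )
    if isinstance(model.adjudicator_policy, str):
        adj = dc_replace(truth, source="adjudicator")
    else:
        drawn = _emit(codes, model.adjudicator_policy, rng)
        adj = dc_replace(
            truth, source="adjudicator", stages=tuple(_PSG5_ORDER[i] for i in drawn)
        )
    return out[0], out[1], adj


def simulate_device(truth: Hypnogram, model: DeviceModel, seed) -> Hypnogram:
    """Generate the device hypnogram (DEVICE5, 6-min windows).

    The truth is harmonized and majority-smoothed to the device's
    window so the emission error is conditioned on the device's actual
    decision granularity; ABSENT windows are prepended/appended and the
    onset is displaced by the device clock offset.
    """
    rng = _rng(seed)
    window_epochs = int(round(model.window_s / truth.epoch_s))
    smoothed = smooth_majority(map_stages(truth), window_epochs)
    codes = smoothed.codes()  # HARMONIZED4 codes
    drawn = _emit(codes, model.emission, rng)
    emitted = tuple(_H4_ORDER[i] for i in drawn)
    head = _uniform_int(rng, model.absence_head_windows)
    tail = _uniform_int(rng, model.absence_tail_windows)
    stages = ("ABSENT",) * head + emitted + ("ABSENT",) * tail
    return Hypnogram(
        subject_id=truth.subject_id,
        source="device",
        onset_s=smoothed.onset_s - head * model.window_s + model.clock_offset_s,
        epoch_s=model.window_s,
        stages=stages,
        vocabulary=DEVICE5,
    )


def simulate_breathing(
    truth: Hypnogram, model: RespirationModel, offset_s: float, seed
) -> tuple[RespiratorySeries, RespiratorySeries]:
    """Paired respiratory traces; the device copy is delayed by ``offset_s``.

    Both devices observe the same latent sinusoid whose instantaneous
    rate follows a clipped per-minute random walk; each trace gets its
    own sampling rate and an independent noise stream.
    """
    rng = _rng(seed)
    duration = truth.duration_s
    margin = abs(offset_s) + 5.0
    fine = max(model.rate_ref_hz, model.rate_dev_hz, 8.0)
    t_fine = np.arange(-margin, duration + margin, 1.0 / fine)

    n_min = int(np.ceil((duration + 2 * margin) / 60.0)) + 2
    lo, hi = model.base_rate_bpm
    rates = np.empty(n_min)
    rates[0] = rng.uniform(lo, hi)
    steps = rng.normal(0.0, model.rate_rw_sd, size=n_min - 1)
    for i in range(1, n_min):
        rates[i] = np.clip(rates[i - 1] + steps[i - 1], lo - 2, hi + 2)
    t_min = -margin + 60.0 * np.arange(n_min)
    rate_fine = np.interp(t_fine, t_min, rates)
    phase = 2 * np.pi * np.cumsum(rate_fine / 60.0) / fine
    latent = model.amplitude * np.sin(phase)

    t_ref = np.arange(0.0, duration, 1.0 / model.rate_ref_hz)
    ref_vals = np.interp(t_ref, t_fine, latent) + rng.normal(0, model.noise_sd, t_ref.size)
    t_dev = np.arange(0.0, duration, 1.0 / model.rate_dev_hz) + offset_s
    dev_vals = np.interp(t_dev - offset_s, t_fine, latent) + rng.normal(0, model.noise_sd, t_dev.size)

    ref = RespiratorySeries("reference", model.rate_ref_hz, 0.0, ref_vals)
    dev = RespiratorySeries("device", model.rate_dev_hz, float(offset_s), dev_vals)
    return ref, dev


# ---------------------------------------------------------------------------
# Metadata and the cohort
# ---------------------------------------------------------------------------

_MATTRESS_TYPES = ("foam", "spring", "latex", "memory_foam", "other", "unknown")
_MATTRESS_PROBS = (0.35, 0.25, 0.21, 0.10, 0.06, 0.03)
_QUALITY_WITH_PSG_PROBS = (0.054, 0.349, 0.403, 0.172, 0.022)
_PSQI_COMPONENT_MEANS = (1.2, 1.3, 0.8, 0.4, 1.3, 0.2, 0.9)
from .subgroup_stats import QUALITY_LEVELS  # noqa: E402  (fixed ordinal scale)


def simulate_metadata(n_subjects: int, seed) -> pd.DataFrame:
    """Participant table matching the cohort's demographic distributions."""
    rng = _rng(seed)
    sid = [f"S{i:03d}" for i in range(n_subjects)]
    age = np.clip(rng.normal(39.9, 11.4, n_subjects), 19, 69).round(1)
    bmi = np.clip(rng.normal(23.9, 3.3, n_subjects), 17.9, 30.9).round(1)
    sex = rng.choice(["F", "M"], n_subjects, p=[69 / 117, 48 / 117])
    bed_partner = rng.choice(["yes", "no"], n_subjects, p=[0.55, 0.45])
    mattress = rng.choice(_MATTRESS_TYPES, n_subjects, p=_MATTRESS_PROBS)
    thickness = rng.choice(["thin", "medium", "thick"], n_subjects, p=[0.3, 0.5, 0.2])

    comps = {}
    for j, mean in enumerate(_PSQI_COMPONENT_MEANS, start=1):
        top = 2 if j == 3 else 3  # sleep-duration component spans 0-2 in this cohort
        comps[f"psqi_c{j}"] = rng.binomial(top, mean / top, n_subjects)
    psqi_total = np.sum([comps[f"psqi_c{j}"] for j in range(1, 8)], axis=0)

    q_with_idx = rng.choice(5, n_subjects, p=_QUALITY_WITH_PSG_PROBS)
    shift = rng.choice([-1, 0, 1, 2], n_subjects, p=[0.08, 0.40, 0.35, 0.17])
    q_without_idx = np.clip(q_with_idx + shift, 0, 4)

    meta = pd.DataFrame(
        {
            "subject_id": sid,
            "sex": sex,
            "age_years": age,
            "bmi": bmi,
            "bed_partner": bed_partner,
            "mattress_type": mattress,
            "mattress_thickness_group": thickness,
            **comps,
            "psqi_total": psqi_total,
            "sleep_duration_group": np.where(comps["psqi_c3"] >= 2, "bad", "good"),
            "quality_with_psg": [QUALITY_LEVELS[i] for i in q_with_idx],
            "quality_without_psg": [QUALITY_LEVELS[i] for i in q_without_idx],
            "self_reported_quality": [QUALITY_LEVELS[i] for i in q_with_idx],
            "woke_during_night": rng.choice(["yes", "no"], n_subjects, p=[0.5, 0.5]),
            "disturbance_with_psg": rng.random(n_subjects) < 0.414,
            "disturbance_without_psg": np.zeros(n_subjects, dtype=bool),
        }
    )
    meta["sensor_disturbance"] = np.where(meta["disturbance_with_psg"], "yes", "no")
    return meta


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to regenerate a cohort deterministically."""

    n_subjects: int = 117
    architecture: ArchitectureModel = field(default_factory=ArchitectureModel)
    reviewer: ReviewerModel = field(default_factory=ReviewerModel)
    device: DeviceModel = field(default_factory=DeviceModel)
    respiration: RespirationModel = field(default_factory=RespirationModel)
    with_breathing: bool = False
    clock_offsets_s: tuple[float, ...] | None = None  # cycled over subjects
    group_effects: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    truth: Hypnogram
    reviewer1: Hypnogram
    reviewer2: Hypnogram
    adjudicator: Hypnogram
    device: Hypnogram
    clock_offset_s: float
    emission: np.ndarray
    breathing_ref: RespiratorySeries | None = None
    breathing_dev: RespiratorySeries | None = None


@dataclass(frozen=True)
class SyntheticBundle:
    subjects: tuple[SubjectRecord, ...]
    metadata: pd.DataFrame
    manifest: dict


def _child_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))


def simulate_cohort(config: CohortConfig, seed: int) -> SyntheticBundle:
    """Generate a full synthetic cohort.

    Subject ``i`` derives its truth / reviewer / device / breathing
    seeds from ``SeedSequence(seed, spawn_key=(i+1, stage))`` so the
    cohort is reproducible and stable when ``n_subjects`` changes.
    Per-group device-error multipliers (``group_effects``) rescale the
    emission matrix's off-diagonal mass for subjects in that group.
    """
    metadata = simulate_metadata(config.n_subjects, _child_seed(seed, 0, 0))
    subjects = []
    for i in range(config.n_subjects):
        sid = metadata.loc[i, "subject_id"]
        truth = simulate_truth(config.architecture, _child_seed(seed, i + 1, 0), sid)
        r1, r2, adj = simulate_reviewers(truth, config.reviewer, _child_seed(seed, i + 1, 1))

        offset = (
            config.clock_offsets_s[i % len(config.clock_offsets_s)]
            if config.clock_offsets_s
            else config.device.clock_offset_s
        )
        emission = np.asarray(config.device.emission, dtype=float)
        if config.group_effects:
            for column, effects in config.group_effects.items():
                value = str(metadata.loc[i, column])
                if value in effects:
                    emission = scale_emission_error(emission, float(effects[value]))
        dev_model = dc_replace(config.device, emission=emission, clock_offset_s=float(offset))
        device = simulate_device(truth, dev_model, _child_seed(seed, i + 1, 2))

        b_ref = b_dev = None
        if config.with_breathing:
            b_ref, b_dev = simulate_breathing(
                truth, config.respiration, float(offset), _child_seed(seed, i + 1, 3)
            )
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                truth=truth,
                reviewer1=r1,
                reviewer2=r2,
                adjudicator=adj,
                device=device,
                clock_offset_s=float(offset),
                emission=emission,
                breathing_ref=b_ref,
                breathing_dev=b_dev,
            )
        )

    manifest = {
        "seed": int(seed),
        "n_subjects": config.n_subjects,
        "with_breathing": config.with_breathing,
        "clock_offsets_s": list(config.clock_offsets_s) if config.clock_offsets_s else None,
        "group_effects": {k: dict(v) for k, v in (config.group_effects or {}).items()} or None,
        "architecture": {
            "initial_dist": config.architecture.initial_dist.tolist(),
            "transition": config.architecture.transition.tolist(),
            "night_epochs": list(config.architecture.night_epochs),
            "pre_sleep_wake_epochs": list(config.architecture.pre_sleep_wake_epochs),
            "post_sleep_wake_epochs": list(config.architecture.post_sleep_wake_epochs),
        },
        "reviewer": {
            "confusion_r1": config.reviewer.confusion_r1.tolist(),
            "confusion_r2": config.reviewer.confusion_r2.tolist(),
            "adjudicator_policy": (
                config.reviewer.adjudicator_policy
                if isinstance(config.reviewer.adjudicator_policy, str)
                else config.reviewer.adjudicator_policy.tolist()
            ),
        },
        "device": {
            "emission": config.device.emission.tolist(),
            "clock_offset_s": config.device.clock_offset_s,
            "absence_head_windows": list(config.device.absence_head_windows),
            "absence_tail_windows": list(config.device.absence_tail_windows),
            "window_s": config.device.window_s,
        },
        "respiration": {
            "base_rate_bpm": list(config.respiration.base_rate_bpm),
            "rate_rw_sd": config.respiration.rate_rw_sd,
            "amplitude": config.respiration.amplitude,
            "noise_sd": config.respiration.noise_sd,
            "rate_ref_hz": config.respiration.rate_ref_hz,
            "rate_dev_hz": config.respiration.rate_dev_hz,
        },
    }
    return SyntheticBundle(tuple(subjects), metadata, manifest)


def config_from_manifest(manifest: Mapping) -> CohortConfig:
    """Rebuild a :class:`CohortConfig` from a manifest dictionary."""
    arch = manifest["architecture"]
    rev = manifest["reviewer"]
    dev = manifest["device"]
    resp = manifest["respiration"]
    adj = rev["adjudicator_policy"]
    return CohortConfig(
        n_subjects=int(manifest["n_subjects"]),
        architecture=ArchitectureModel(
            initial_dist=np.array(arch["initial_dist"]),
            transition=np.array(arch["transition"]),
            night_epochs=tuple(arch["night_epochs"]),
            pre_sleep_wake_epochs=tuple(arch["pre_sleep_wake_epochs"]),
            post_sleep_wake_epochs=tuple(arch["post_sleep_wake_epochs"]),
        ),
        reviewer=ReviewerModel(
            confusion_r1=np.array(rev["confusion_r1"]),
            confusion_r2=np.array(rev["confusion_r2"]),
            adjudicator_policy=adj if isinstance(adj, str) else np.array(adj),
        ),
        device=DeviceModel(
            emission=np.array(dev["emission"]),
            clock_offset_s=float(dev["clock_offset_s"]),
            absence_head_windows=tuple(dev["absence_head_windows"]),
            absence_tail_windows=tuple(dev["absence_tail_windows"]),
            window_s=float(dev["window_s"]),
        ),
        respiration=RespirationModel(
            base_rate_bpm=tuple(resp["base_rate_bpm"]),
            rate_rw_sd=float(resp["rate_rw_sd"]),
            amplitude=float(resp["amplitude"]),
            noise_sd=float(resp["noise_sd"]),
            rate_ref_hz=float(resp["rate_ref_hz"]),
            rate_dev_hz=float(resp["rate_dev_hz"]),
        ),
        with_breathing=bool(manifest["with_breathing"]),
        clock_offsets_s=tuple(manifest["clock_offsets_s"]) if manifest.get("clock_offsets_s") else None,
        group_effects=manifest.get("group_effects"),
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write a bundle to disk: hypnogram/respiratory CSVs, metadata, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in bundle.subjects:
        for name, h in (
            ("truth", rec.truth),
            ("reviewer1", rec.reviewer1),
            ("reviewer2", rec.reviewer2),
            ("adjudicator", rec.adjudicator),
            ("device", rec.device),
        ):
            write_hypnogram(h, outdir / f"{rec.subject_id}_{name}.csv")
        if rec.breathing_ref is not None:
            write_respiratory(rec.breathing_ref, outdir / f"{rec.subject_id}_breath_ref.csv")
            write_respiratory(rec.breathing_dev, outdir / f"{rec.subject_id}_breath_dev.csv")
    bundle.metadata.to_csv(outdir / "metadata.csv", index=False)
    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(bundle.manifest, fh, sort_keys=True)
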