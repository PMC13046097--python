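"""Hypnogram data model, harmonization operations and file I/O.

A :class:`Hypnogram` is a contiguous, gap-free sequence of staged epochs
on a uniform grid. Epoch ``i`` occupies the half-open interval
``[onset_s + i*epoch_s, onset_s + (i+1)*epoch_s)``; times are seconds
from a per-night clock origin and indices are 0-based.

The harmonization chain that puts a reference annotation and a device
hypnogram on a common comparison grid is:

reference (PSG5, 30 s)
    -> :func:`map_stages` (N1/N2 pooled into LIGHT, N3 into DEEP)
    -> :func:`smooth_majority` (6-min majority vote, matching the
       device's decision granularity)
    -> :func:`broadcast` back to 30-s epochs

device (DEVICE5, 6 min)
    -> ABSENT policy (mask out or recode as WAKE)
    -> :func:`broadcast` to 30-s epochs

:func:`align_pair` performs the whole chain and intersects the two
timelines into an :class:`AlignedPair` with a validity mask.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    ContiguityError,
    FormatError,
    GridError,
    MappingError,
    VocabularyError,
    WindowError,
)
from .stages import (
    DEVICE5,
    HARMONIZED4,
    PSG5,
    PSG5_TO_HARMONIZED4,
    StageVocabulary,
    VOCABULARIES,
    tie_priority,
)

__all__ = [
    "Hypnogram",
    "Episode",
    "AlignedPair",
    "read_hypnogram",
    "write_hypnogram",
    "map_stages",
    "smooth_majority",
    "broadcast",
    "restrict_window",
    "extract_episodes",
    "align_pair",
]

CSV_HEADER = "onset_s,duration_s,stage"


@dataclass(frozen=True)
class Hypnogram:
    """A staged, contiguous epoch sequence for one night and one source."""

    subject_id: str
    source: str
    onset_s: float
    epoch_s: float
    stages: tuple[str, ...]
    vocabulary: StageVocabulary

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise GridError(f"epoch_s must be positive, got {self.epoch_s}")
        if len(self.stages) == 0:
            raise FormatError("hypnogram must contain at least one epoch")
        bad = [s for s in self.stages if s not in self.vocabulary]
        if bad:
            raise VocabularyError(
                f"stages {sorted(set(bad))} not in vocabulary {self.vocabulary.name}"
            )
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def end_s(self) -> float:
        return self.onset_s + self.n_epochs * self.epoch_s

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def codes(self) -> np.ndarray:
        """Integer stage codes in vocabulary order."""
        lut = {s: i for i, s in enumerate(self.vocabulary.stages)}
        return np.array([lut[s] for s in self.stages], dtype=np.intp)

    def with_stages(self, stages: Sequence[str], vocabulary: StageVocabulary | None = None) -> "Hypnogram":
        return replace(
            self,
            stages=tuple(stages),
            vocabulary=vocabulary if vocabulary is not None else self.vocabulary,
        )


@dataclass(frozen=True)
class Episode:
    """A maximal run of consecutive epochs in one stage."""

    stage: str
    start_epoch: int
    length_epochs: int

    def __post_init__(self) -> None:
        if self.length_epochs < 1:
            raise ValueError("episode length must be >= 1")


@dataclass(frozen=True)
class AlignedPair:
    """Reference and device stage sequences on a common 30-s grid.

    Epochs where ``valid_mask`` is False are excluded from every
    downstream count.
    """

    subject_id: str
    reference: tuple[str, ...]
    device: tuple[str, ...]
    valid_mask: tuple[bool, ...]
    window_origin_s: float
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        if not (len(self.reference) == len(self.device) == len(self.valid_mask)):
            raise AlignmentError("reference, device and mask must have equal length")
        for name, seq in (("reference", self.reference), ("device", self.device)):
            bad = [s for s in seq if s not in HARMONIZED4]
            if bad:
                raise VocabularyError(f"{name} stages {sorted(set(bad))} not HARMONIZED4")

    @property
    def n_epochs(self) -> int:
        return len(self.reference)

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid_mask))

    def valid_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(reference, device) label arrays restricted to valid epochs."""
        mask = np.asarray(self.valid_mask, dtype=bool)
        ref = np.asarray(self.reference, dtype=object)[mask]
        dev = np.asarray(self.device, dtype=object)[mask]
        return ref, dev

    def with_mask(self, mask: Sequence[bool]) -> "AlignedPair":
        if len(mask) != self.n_epochs:
            raise AlignmentError("mask length mismatch")
        return replace(self, valid_mask=tuple(bool(m) for m in mask))


# ---------------------------------------------------------------------------
# File I/O — CSV dialect: header `onset_s,duration_s,stage`, one row per
# epoch, `# key=value` comment lines carry metadata.
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path, vocabulary: StageVocabulary | None = None) -> Hypnogram:
    """Read a hypnogram CSV.

    Parameters
    ----------
    path
        CSV file in the package dialect.
    vocabulary
        Expected vocabulary. If None, the file's ``# vocabulary=`` metadata
        line selects a built-in vocabulary.

    Rows with identical consecutive stages are preserved as distinct
    epochs, never merged.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, str, int]] = []
    header_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != CSV_HEADER:
                    raise FormatError(f"{path}: line {lineno}: expected header {CSV_HEADER!r}")
                header_seen = True
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            try:
                onset, duration = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric time") from exc
            rows.append((onset, duration, parts[2], lineno))
    if not header_seen or not rows:
        raise FormatError(f"{path}: no epochs found")

    if vocabulary is None:
        name = meta.get("vocabulary")
        if name is None or name not in VOCABULARIES:
            raise FormatError(f"{path}: no usable '# vocabulary=' metadata line")
        vocabulary = VOCABULARIES[name]

    durations = {d for _, d, _, _ in rows}
    if len(durations) != 1:
        raise GridError(f"{path}: non-uniform duration_s values {sorted(durations)}")
    epoch_s = rows[0][1]
    stages = []
    for i, (onset, _, stage, lineno) in enumerate(rows):
        if stage not in vocabulary:
            raise FormatError(
                f"{path}: line {lineno}: unknown stage {stage!r} for vocabulary {vocabulary.name}"
            )
        expected = rows[0][0] + i * epoch_s
        if abs(onset - expected) > 1e-6:
            raise ContiguityError(
                f"{path}: line {lineno}: onset {onset} breaks contiguity (expected {expected})"
            )
        stages.append(stage)

    return Hypnogram(
        subject_id=meta.get("subject_id", path.stem),
        source=meta.get("source", "unknown"),
        onset_s=rows[0][0],
        epoch_s=epoch_s,
        stages=tuple(stages),
        vocabulary=vocabulary,
    )


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram in the CSV dialect (lossless round-trip)."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# subject_id={h.subject_id}\n")
    buf.write(f"# source={h.source}\n")
    buf.write(f"# vocabulary={h.vocabulary.name}\n")
    buf.write(CSV_HEADER + "\n")
    for i, stage in enumerate(h.stages):
        onset = h.onset_s + i * h.epoch_s
        buf.write(f"{_fmt(onset)},{_fmt(h.epoch_s)},{stage}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# Harmonization operations
# ---------------------------------------------------------------------------

def map_stages(
    h: Hypnogram,
    mapping: Mapping[str, str] | None = None,
    target: StageVocabulary | None = None,
) -> Hypnogram:
    """Element-wise stage relabeling; timing unchanged.

    Default mapping pools the AASM non-REM depth levels: N1, N2 -> LIGHT
    and N3 -> DEEP, producing a HARMONIZED4 hypnogram from a PSG5 one.
    """
    if mapping is None:
        if h.vocabulary.name != "PSG5":
            raise MappingError("default mapping applies to PSG5 hypnograms only")
        mapping = PSG5_TO_HARMONIZED4
        target = HARMONIZED4
    missing = set(h.stages) - set(mapping)
    if missing:
        raise MappingError(f"mapping missing source stages {sorted(missing)}")
    new_stages = tuple(mapping[s] for s in h.stages)
    if target is None:
        targets = [v for v in VOCABULARIES.values() if all(s in v for s in set(mapping.values()))]
        if not targets:
            raise MappingError("no built-in vocabulary covers the mapping's targets")
        target = min(targets, key=len)
    return h.with_stages(new_stages, vocabulary=target)


def smooth_majority(
    h: Hypnogram,
    window_epochs: int = 12,
    priority: Sequence[str] | None = None,
) -> Hypnogram:
    """Majority-vote smoothing onto coarse windows.

    Each window of ``window_epochs`` consecutive epochs is replaced by
    the stage with the highest occurrence; a trailing partial window is
    scored by majority over its available epochs. Ties are broken by a
    fixed priority (default WAKE > REM > DEEP > LIGHT for HARMONIZED4).
    """
    if window_epochs < 1:
        raise GridError("window_epochs must be >= 1")
    if priority is None:
        priority = tie_priority(h.vocabulary)
    missing = set(h.stages) - set(priority)
    if missing:
        raise VocabularyError(f"tie priority does not cover stages {sorted(missing)}")
    rank = {s: i for i, s in enumerate(priority)}

    out: list[str] = []
    for start in range(0, h.n_epochs, window_epochs):
        window = h.stages[start : start + window_epochs]
        counts: dict[str, int] = {}
        for s in window:
            counts[s] = counts.get(s, 0) + 1
        # highest count wins; ties -> lowest priority rank (most preferred)
        out.append(min(counts, key=lambda s: (-counts[s], rank[s])))
    return replace(h, epoch_s=h.epoch_s * window_epochs, stages=tuple(out))


def broadcast(h: Hypnogram, target_epoch_s: float = 30.0) -> Hypnogram:
    """Replicate each epoch onto a finer grid (e.g. 6-min -> 30-s)."""
    ratio = h.epoch_s / target_epoch_s
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise GridError(
            f"epoch_s {h.epoch_s} not divisible by target_epoch_s {target_epoch_s}"
        )
    k = int(round(ratio))
    stages = tuple(s for s in h.stages for _ in range(k))
    return replace(h, epoch_s=float(target_epoch_s), stages=stages)


def restrict_window(h: Hypnogram, start_s: float, end_s: float) -> Hypnogram:
    """Keep epochs fully inside ``[start_s, end_s)``; partial edge epochs drop."""
    if start_s >= end_s:
        raise WindowError(f"empty window [{start_s}, {end_s})")
    first = int(np.ceil((start_s - h.onset_s) / h.epoch_s - 1e-9))
    last = int(np.floor((end_s - h.onset_s) / h.epoch_s + 1e-9))  # exclusive
    first = max(first, 0)
    last = min(last, h.n_epochs)
    if first >= last:
        raise WindowError(
            f"window [{start_s}, {end_s}) contains no complete epoch of {h.subject_id}"
        )
    return replace(
        h,
        onset_s=h.onset_s + first * h.epoch_s,
        stages=h.stages[first:last],
    )


def extract_episodes(h: Hypnogram) -> list[Episode]:
    """Maximal runs of consecutive identical stages, in order."""
    episodes: list[Episode] = []
    start = 0
    for i in range(1, h.n_epochs + 1):
        if i == h.n_epochs or h.stages[i] != h.stages[start]:
            episodes.append(Episode(h.stages[start], start, i - start))
            start = i
    return episodes


def stage_changes(h: Hypnogram) -> int:
    """Number of adjacent epoch pairs with differing stages."""
    return sum(a != b for a, b in zip(h.stages, h.stages[1:]))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def harmonize_reference(h: Hypnogram, window_epochs: int = 12) -> Hypnogram:
    """Map a reference annotation to HARMONIZED4 on the 30-s comparison grid.

    A 30-s PSG5 hypnogram is relabeled, majority-smoothed to the device's
    6-min granularity, and broadcast back to 30-s epochs, so that both
    sources are compared at the device's effective resolution.
    """
    if h.vocabulary.name == "PSG5":
        h = map_stages(h)
    elif h.vocabulary.name != "HARMONIZED4":
        raise VocabularyError(f"cannot harmonize vocabulary {h.vocabulary.name}")
    if abs(h.epoch_s - 30.0) < 1e-9:
        h = smooth_majority(h, window_epochs)
    return broadcast(h, 30.0)


def harmonize_device(h: Hypnogram, absent_policy: str = "exclude") -> tuple[Hypnogram, np.ndarray]:
    """Map a device hypnogram to HARMONIZED4 at 30 s plus an absence mask.

    Returns the broadcast hypnogram and a boolean array that is False on
    30-s epochs covered by ABSENT windows under the ``exclude`` policy
    (all-True under ``as_wake``, where ABSENT is recoded WAKE).
    """
    if absent_policy not in ("exclude", "as_wake"):
        raise ValueError(f"unknown absent_policy {absent_policy!r}")
    if h.vocabulary.name == "DEVICE5":
        absent = np.array([s == "ABSENT" for s in h.stages], dtype=bool)
        mapping = {"WAKE": "WAKE", "LIGHT": "LIGHT", "DEEP": "DEEP", "REM": "REM", "ABSENT": "WAKE"}
        h = map_stages(h, mapping, HARMONIZED4)
    elif h.vocabulary.name == "HARMONIZED4":
        absent = np.zeros(h.n_epochs, dtype=bool)
    else:
        raise VocabularyError(f"cannot harmonize device vocabulary {h.vocabulary.name}")
    h30 = broadcast(h, 30.0)
    k = h30.n_epochs // len(absent)
    mask = ~np.repeat(absent, k) if absent_policy == "exclude" else np.ones(h30.n_epochs, dtype=bool)
    return h30, mask


def align_pair(
    reference: Hypnogram,
    device: Hypnogram,
    absent_policy: str = "exclude",
    window_epochs: int = 12,
) -> AlignedPair:
    """Intersect reference and device onto a common 30-s comparison grid.

    The reference's 30-s grid is authoritative; the device onset must
    fall on it (synchronize with :func:`hypnoval.sync.apply_offset`
    first). Device ABSENT windows are masked out (``exclude``, default)
    or recoded WAKE (``as_wake``).
    """
    ref = harmonize_reference(reference, window_epochs)
    dev, dev_mask = harmonize_device(device, absent_policy)

    shift = (dev.onset_s - ref.onset_s) / 30.0
    if abs(shift - round(shift)) > 1e-6:
        raise GridError(
            f"device onset {dev.onset_s} off the reference 30-s grid (origin {ref.onset_s})"
        )
    start = max(ref.onset_s, dev.onset_s)
    end = min(ref.end_s, dev.end_s)
    if start >= end:
        raise AlignmentError(
            f"no temporal overlap between reference [{ref.onset_s}, {ref.end_s}) "
            f"and device [{dev.onset_s}, {dev.end_s})"
        )
    n = int(round((end - start) / 30.0))
    ri = int(round((start - ref.onset_s) / 30.0))
    di = int(round((start - dev.onset_s) / 30.0))
    return AlignedPair(
        subject_id=reference.subject_id,
        reference=ref.stages[ri : ri + n],
        device=dev.stages[di : di + n],
        valid_mask=tuple(bool(b) for b in dev_mask[di : di + n]),
        window_origin_s=start,
    )
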