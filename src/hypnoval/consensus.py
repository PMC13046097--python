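"""Reference construction from two reviewers plus an adjudicator.

Two certified scorers annotate each night independently on 30-s AASM
epochs; wherever they disagree, a third scorer's reading decides. The
module also quantifies inter-rater reliability (Cohen kappa on the five
stages and on the sleep-wake collapse) and splits an aligned pair into
the complementary agreement / disagreement epoch strata used to ask
whether the device fails preferentially where the human experts do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, HypnovalError, VocabularyError
from .hypnogram import AlignedPair, Hypnogram
from .stages import PSG5_TO_BINARY

__all__ = ["ConsensusResult", "build_consensus", "cohen_kappa", "stratify_epochs"]


@dataclass(frozen=True)
class ConsensusResult:
    consensus: Hypnogram
    agreement_mask: tuple[bool, ...]
    kappa_stages: float
    kappa_sw: float


def build_consensus(r1: Hypnogram, r2: Hypnogram, adjudicator: Hypnogram) -> ConsensusResult:
    """Epoch-wise consensus: the shared stage where reviewers agree, the
    adjudicator's stage where they disagree.

    All three hypnograms must share the 30-s grid and the PSG5
    vocabulary. The adjudicator is consulted only at disagreements.
    """
    for h in (r2, adjudicator):
        if (
            abs(h.onset_s - r1.onset_s) > 1e-9
            or abs(h.epoch_s - r1.epoch_s) > 1e-9
            or h.n_epochs != r1.n_epochs
        ):
            raise AlignmentError("reviewer/adjudicator grids differ")
        if h.vocabulary.name != r1.vocabulary.name:
            raise VocabularyError("reviewer vocabularies differ")

    a1 = np.asarray(r1.stages, dtype=object)
    a2 = np.asarray(r2.stages, dtype=object)
    adj = np.asarray(adjudicator.stages, dtype=object)
    agree = a1 == a2
    stages = np.where(agree, a1, adj)

    consensus = Hypnogram(
        subject_id=r1.subject_id,
        source="consensus",
        onset_s=r1.onset_s,
        epoch_s=r1.epoch_s,
        stages=tuple(stages.tolist()),
        vocabulary=r1.vocabulary,
    )
    sw1 = [PSG5_TO_BINARY[s] for s in r1.stages]
    sw2 = [PSG5_TO_BINARY[s] for s in r2.stages]
    return ConsensusResult(
        consensus=consensus,
        agreement_mask=tuple(bool(b) for b in agree),
        kappa_stages=cohen_kappa(r1.stages, r2.stages),
        kappa_sw=cohen_kappa(sw1, sw2),
    )


def cohen_kappa(a: Sequence[str], b: Sequence[str]) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``p_e`` comes from the product of the two marginal label
    distributions. Returns NaN (the undefined flag) when ``p_e = 1``,
    i.e. both sequences are constant and equal.
    """
    if len(a) != len(b) or len(a) == 0:
        raise HypnovalError("sequences must have equal nonzero length")
    aa = np.asarray(a, dtype=object)
    bb = np.asarray(b, dtype=object)
    labels = sorted(set(aa.tolist()) | set(bb.tolist()))
    lut = {s: i for i, s in enumerate(labels)}
    ai = np.array([lut[s] for s in aa])
    bi = np.array([lut[s] for s in bb])
    n = len(labels)
    cm = np.zeros((n, n))
    np.add.at(cm, (ai, bi), 1)
    total = cm.sum()
    po = np.trace(cm) / total
    pe = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0)) / total**2)
    if abs(1.0 - pe) < 1e-12:
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def stratify_epochs(
    pair: AlignedPair, agreement_mask: Sequence[bool]
) -> tuple[AlignedPair, AlignedPair]:
    """Split an aligned pair into reviewer-agreement and -disagreement strata.

    The mask lives on the same 30-s grid as the pair (the reviewers'
    grid), so each underlying 30-s epoch carries its own stratum even
    though device decisions span 6 minutes. Returns complementary
    masked pairs whose valid epoch counts sum to the original's.
    """
    if len(agreement_mask) != pair.n_epochs:
        raise AlignmentError(
            f"mask length {len(agreement_mask)} != pair length {pair.n_epochs}"
        )
    mask = np.asarray(agreement_mask, dtype=bool)
    valid = np.asarray(pair.valid_mask, dtype=bool)
    return pair.with_mask(valid & mask), pair.with_mask(valid & ~mask)


def crop_mask_to_pair(
    mask: Sequence[bool], mask_origin_s: float, pair: AlignedPair
) -> tuple[tuple[bool, ...], tuple[bool, ...]]:
    """Crop a 30-s mask defined from ``mask_origin_s`` onto a pair's window.

    Returns ``(values, covered)``: the mask values on the pair's grid
    and a coverage flag that is False where the pair extends beyond the
    mask's span (e.g. epochs contributed by a trailing partial smoothing
    window); uncovered epochs belong to neither stratum.
    """
    start = int(round((pair.window_origin_s - mask_origin_s) / pair.epoch_s))
    values, covered = [], []
    for i in range(pair.n_epochs):
        j = start + i
        inside = 0 <= j < len(mask)
        covered.append(inside)
        values.append(bool(mask[j]) if inside else False)
    return tuple(values), tuple(covered)
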