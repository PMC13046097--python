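"""Stage vocabularies and the canonical relabeling tables.

The pipeline compares annotations drawn from different label sets:

* ``PSG5`` — AASM manual scoring (WAKE, N1, N2, N3, REM) on 30-s epochs;
* ``DEVICE5`` — the tracker's output (WAKE, LIGHT, DEEP, REM) on 6-min
  windows plus an ABSENT mark for bed absence;
* ``HARMONIZED4`` — the common four-stage vocabulary all comparisons are
  made in: N1 and N2 are pooled into LIGHT, N3 becomes DEEP;
* ``BINARY`` — sleep-wake collapse (all non-wake stages are SLEEP).

The HARMONIZED4 stage order (WAKE, REM, LIGHT, DEEP) is canonical for
every confusion matrix in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "StageVocabulary",
    "PSG5",
    "DEVICE5",
    "HARMONIZED4",
    "BINARY",
    "VOCABULARIES",
    "PSG5_TO_HARMONIZED4",
    "HARMONIZED4_TO_BINARY",
    "PSG5_TO_BINARY",
    "DEFAULT_TIE_PRIORITY",
]


@dataclass(frozen=True)
class StageVocabulary:
    """An ordered set of stage labels with a name.

    The order is meaningful: it fixes row/column order of confusion
    matrices and the integer codes used internally.
    """

    name: str
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValueError(f"duplicate stage labels in vocabulary {self.name!r}")
        if not self.stages:
            raise ValueError("vocabulary needs at least one stage")

    def __contains__(self, stage: object) -> bool:
        return stage in self.stages

    def __len__(self) -> int:
        return len(self.stages)

    def index(self, stage: str) -> int:
        return self.stages.index(stage)


PSG5 = StageVocabulary("PSG5", ("WAKE", "N1", "N2", "N3", "REM"))
DEVICE5 = StageVocabulary("DEVICE5", ("WAKE", "LIGHT", "DEEP", "REM", "ABSENT"))
HARMONIZED4 = StageVocabulary("HARMONIZED4", ("WAKE", "REM", "LIGHT", "DEEP"))
BINARY = StageVocabulary("BINARY", ("WAKE", "SLEEP"))

VOCABULARIES: dict[str, StageVocabulary] = {
    v.name: v for v in (PSG5, DEVICE5, HARMONIZED4, BINARY)
}

#: N1 and N2 are pooled into the light category; N3 is compared with deep.
PSG5_TO_HARMONIZED4: dict[str, str] = {
    "WAKE": "WAKE",
    "N1": "LIGHT",
    "N2": "LIGHT",
    "N3": "DEEP",
    "REM": "REM",
}

HARMONIZED4_TO_BINARY: dict[str, str] = {
    "WAKE": "WAKE",
    "REM": "SLEEP",
    "LIGHT": "SLEEP",
    "DEEP": "SLEEP",
}

PSG5_TO_BINARY: dict[str, str] = {
    "WAKE": "WAKE",
    "N1": "SLEEP",
    "N2": "SLEEP",
    "N3": "SLEEP",
    "REM": "SLEEP",
}

#: Majority-smoothing tie-break order, most preferred first. Conservative:
#: a tie never invents sleep (WAKE wins), and within sleep never invents
#: depth (REM > DEEP > LIGHT mirrors decreasing one-vs-rest specificity).
DEFAULT_TIE_PRIORITY: dict[str, tuple[str, ...]] = {
    "HARMONIZED4": ("WAKE", "REM", "DEEP", "LIGHT"),
    "PSG5": ("WAKE", "REM", "N3", "N2", "N1"),
    "DEVICE5": ("ABSENT", "WAKE", "REM", "DEEP", "LIGHT"),
    "BINARY": ("WAKE", "SLEEP"),
}


def tie_priority(vocabulary: StageVocabulary) -> tuple[str, ...]:
    """Default tie-break priority for a vocabulary (most preferred first)."""
    try:
        return DEFAULT_TIE_PRIORITY[vocabulary.name]
    except KeyError:
        return vocabulary.stages
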