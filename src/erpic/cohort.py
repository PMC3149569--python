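"""In-memory container for per-subject averaged ERPs.

An :class:`ERPCohort` holds one channels x samples matrix per subject and
task condition (go, nogo, ignore, novel), all on a common montage and time
grid.  The time grid is 250 samples at 250 Hz covering [0, 996] ms after the
second stimulus, i.e. sample ``k`` sits at ``k * 4`` ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .montage import Montage

#: Canonical task-condition order.
CONDITIONS: tuple[str, ...] = ("go", "nogo", "ignore", "novel")

#: Preparatory sets: first-stimulus animal (prepare to respond) vs plant.
SET_CONDITIONS: dict[str, tuple[str, str]] = {
    "continue": ("go", "nogo"),
    "discontinue": ("ignore", "novel"),
}

GROUPS: tuple[str, str] = ("control", "case")

N_SAMPLES = 250
SAMPLING_RATE = 250.0
SAMPLE_STEP_MS = 1000.0 / SAMPLING_RATE


def times_ms(n_samples: int = N_SAMPLES) -> np.ndarray:
    """Sample times in ms after second-stimulus onset (0, 4, ..., 996)."""
    return np.arange(n_samples) * SAMPLE_STEP_MS


@dataclass(frozen=True)
class Subject:
    id: str
    group: str  # "case" or "control"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidInputError(
                f"subject {self.id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )


@dataclass
class ERPCohort:
    """Per-subject, per-condition averaged ERPs with group labels.

    ``data`` has shape ``(n_subjects, n_conditions, n_channels, n_samples)``
    in µV, with conditions ordered as :data:`CONDITIONS`.
    """

    subjects: list[Subject]
    data: np.ndarray = field(repr=False)
    montage: Montage
    sampling_rate: float = SAMPLING_RATE
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = (
            len(self.subjects),
            len(self.conditions),
            self.montage.n_channels,
        )
        if self.data.ndim != 4 or self.data.shape[:3] != expected:
            raise InvalidInputError(
                f"data shape {self.data.shape} inconsistent with "
                f"{expected} (subjects, conditions, channels)"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            subj = self.subjects[bad[0]].id
            cond = self.conditions[bad[1]]
            raise InvalidInputError(
                f"non-finite value in ERP of subject {subj!r}, condition {cond!r}"
            )
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("subject ids must be unique")

    # -- accessors ---------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def subject_ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def condition_index(self, condition: str) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise InvalidInputError(f"unknown condition {condition!r}") from None

    def get(self, subject_id: str, condition: str) -> np.ndarray:
        """ERP matrix (channels x samples) for one subject and condition."""
        try:
            i = self.subject_ids.index(subject_id)
        except ValueError:
            raise InvalidInputError(f"unknown subject {subject_id!r}") from None
        return self.data[i, self.condition_index(condition)]

    def subset(self, group: str) -> "ERPCohort":
        """Sub-cohort restricted to one group ('case' or 'control')."""
        mask = self.groups == group
        if not mask.any():
            raise InvalidInputError(f"no subjects in group {group!r}")
        return ERPCohort(
            [s for s, m in zip(self.subjects, mask) if m],
            self.data[mask],
            self.montage,
            self.sampling_rate,
            self.conditions,
        )
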