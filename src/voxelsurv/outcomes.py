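"""Outcome containers for the three supported model families.

The primary use case is a right-censored time-to-event outcome (months to
relapse, administratively censored); continuous and binary labels are carried
for the benchmark experiments that tune imaging parameters on age or
diagnosis prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import as_bool_events

FAMILIES = ("survival", "gaussian", "binomial")


@dataclass
class Outcome:
    family: str
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    y: np.ndarray | None = None
    subject_ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown outcome family {self.family!r}")
        if self.family == "survival":
            if self.time is None or self.event is None:
                raise ValueError("survival outcome requires time and event")
            self.time = np.asarray(self.time, dtype=float)
            self.event = as_bool_events(self.event)
            if (self.time <= 0).any():
                raise ValueError("survival times must be positive")
            if self.time.shape != self.event.shape:
                raise ValueError("time/event shape mismatch")
        else:
            if self.y is None:
                raise ValueError(f"{self.family} outcome requires y")
            self.y = np.asarray(self.y, dtype=float)
            if self.family == "binomial" and not np.isin(self.y, [0.0, 1.0]).all():
                raise ValueError("binomial outcome must be 0/1")

    @classmethod
    def survival(cls, time, event, subject_ids=None) -> "Outcome":
        return cls("survival", time=time, event=event, subject_ids=subject_ids)

    @classmethod
    def gaussian(cls, y, subject_ids=None) -> "Outcome":
        return cls("gaussian", y=np.asarray(y, float), subject_ids=subject_ids)

    @classmethod
    def binomial(cls, y, subject_ids=None) -> "Outcome":
        return cls("binomial", y=np.asarray(y, float), subject_ids=subject_ids)

    @property
    def n(self) -> int:
        return len(self.time) if self.family == "survival" else len(self.y)

    @property
    def n_events(self) -> int:
        if self.family != "survival":
            raise AttributeError("n_events only defined for survival outcomes")
        return int(self.event.sum())

    def subset(self, idx) -> "Outcome":
        take = lambda a: None if a is None else np.asarray(a)[idx]
        return Outcome(
            self.family,
            time=take(self.time),
            event=take(self.event),
            y=take(self.y),
            subject_ids=take(self.subject_ids),
        )


def make_folds(outcome: Outcome, k: int = 10, seed: int = 0) -> np.ndarray:
    """Event-stratified k-fold assignment.

    Subjects with an observed event are shuffled and dealt round-robin to the
    k folds, then censored (or non-survival) subjects likewise, so per-fold
    event counts differ by at most one. Returns the per-subject fold index.
    """
    n = outcome.n
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.int64)
    if outcome.family == "survival":
        groups = [np.flatnonzero(outcome.event), np.flatnonzero(~outcome.event)]
    elif outcome.family == "binomial":
        y = outcome.y.astype(bool)
        groups = [np.flatnonzero(y), np.flatnonzero(~y)]
    else:
        groups = [np.arange(n)]
    offset = 0
    for g in groups:
        g = rng.permutation(g)
        folds[g] = (np.arange(len(g)) + offset) % k
        offset += len(g)  # continue dealing where the last group stopped
    return folds
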