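"""Per-fragment 4C count profiles anchored to a viewpoint.

A :class:`Profile` is the observable the signal model is fitted to: one
count per restriction fragment, with the fragment midpoint as the genomic
coordinate ``x`` and the viewpoint coordinate ``xv`` as the anchor.  The
``stage`` field tracks the preprocessing state (raw → filtered →
normalized) so that pipeline steps can enforce their preconditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

STAGES = ("raw", "filtered", "normalized")


@dataclass
class Profile:
    chrom: str
    xv: float
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray
    stage: str = "raw"

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.stage not in STAGES:
            raise ValidationError(f"unknown profile stage {self.stage!r}")
        n = self.starts.size
        if not (self.ends.size == n and self.counts.size == n):
            raise ValidationError("profile arrays must have equal length")
        if n == 0:
            return
        if np.any(self.ends <= self.starts):
            raise ValidationError("profile contains inverted or empty fragments")
        mids = self.midpoints
        if np.any(np.diff(mids) <= 0):
            raise ValidationError("fragment midpoints must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("profile counts must be non-negative")
        if not (self.starts[0] <= self.xv <= self.ends[-1]):
            raise ValidationError(
                f"viewpoint {self.xv} lies outside the profile span "
                f"[{self.starts[0]}, {self.ends[-1]}]"
            )

    def __len__(self) -> int:
        return self.starts.size

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def distances(self) -> np.ndarray:
        """Absolute genomic distance of each fragment midpoint from xv."""
        return np.abs(self.midpoints - self.xv)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def subset(self, mask: np.ndarray, stage: str | None = None) -> "Profile":
        return Profile(
            self.chrom,
            self.xv,
            self.starts[mask],
            self.ends[mask],
            self.counts[mask],
            stage or self.stage,
        )

    def with_counts(self, counts: np.ndarray, stage: str | None = None) -> "Profile":
        return replace(self, counts=np.asarray(counts, dtype=np.float64), stage=stage or self.stage)
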