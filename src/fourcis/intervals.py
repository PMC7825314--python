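"""Genomic intervals and labelled annotation tracks.

All coordinates are 0-based, half-open (BED convention) throughout the
package; files are read and written in the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlap(self, other: "GenomicInterval") -> int:
        """Base pairs of overlap with ``other`` (0 if disjoint or trans)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class AnnotationTrack:
    """An ordered set of labelled intervals (enhancers, promoters, genes...).

    Features are kept sorted by (chrom, start); labels must be non-empty.
    """

    name: str
    features: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    def __post_init__(self):
        for iv, label in self.features:
            if not label:
                raise ValidationError(f"empty feature label in track {self.name!r}")
        self.features = sorted(self.features, key=lambda f: (f[0].chrom, f[0].start, f[0].end))

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)
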