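"""Intersect called interaction peaks with regulatory-element tracks.

Each peak is given a genomic footprint of ±k·sigma around its center
(k = 2 by default, covering ~95% of the Gaussian mass) and intersected
with a BED annotation track (enhancers, promoters, genes) by a sweep over
the start-sorted intervals, producing one row per overlapping
(peak, feature) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

from .decompose import ModelFit, Peak
from .errors import ValidationError
from .intervals import AnnotationTrack, GenomicInterval


@dataclass
class PeakAnnotation:
    peak: Peak
    feature_label: str
    feature: GenomicInterval
    overlap: int  # bp of overlap, >= 1 for reported rows
    distance_to_viewpoint: float  # |center - xv|


def peak_extent(peak: Peak, sigma: float, k: float = 2.0, chrom: str = ".") -> GenomicInterval:
    """Half-open footprint ``[center - k*sigma, center + k*sigma)``."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if k <= 0:
        raise ValidationError("extent multiplier k must be positive")
    half = k * sigma
    start = int(round(peak.center - half))
    end = int(round(peak.center + half))
    return GenomicInterval(chrom, max(start, 0), end)


def overlap_peaks(
    fit: ModelFit,
    track: AnnotationTrack,
    significant_only: bool = True,
    k: float = 2.0,
) -> list[PeakAnnotation]:
    """All (peak, feature) pairs whose half-open intervals intersect.

    Runs a two-pointer sweep over start-sorted peaks and features on the
    fit's chromosome.  Rows are sorted by peak center then feature start;
    overlaps are exact base-pair counts (>= 1 by construction of the
    half-open intersection).
    """
    peaks = fit.significant_peaks if significant_only else fit.peaks
    peaks = sorted(peaks, key=lambda p: p.center)
    extents = [peak_extent(p, fit.sigma, k=k, chrom=fit.chrom) for p in peaks]
    feats = [(iv, label) for iv, label in track if iv.chrom == fit.chrom]
    # track is already sorted by (chrom, start); chrom-restricted slice stays sorted

    out: list[PeakAnnotation] = []
    j = 0
    for peak, ext in zip(peaks, extents):
        # skip features that end at or before this extent's start; because
        # peaks are start-sorted they cannot overlap any later peak's extent
        # only if they also precede it -- so advance a *local* pointer
        while j < len(feats) and feats[j][0].end <= ext.start:
            j += 1
        i = j
        while i < len(feats) and feats[i][0].start < ext.end:
            iv, label = feats[i]
            ov = ext.overlap(iv)
            if ov >= 1:
                out.append(
                    PeakAnnotation(
                        peak=peak,
                        feature_label=label,
                        feature=iv,
                        overlap=ov,
                        distance_to_viewpoint=abs(peak.center - fit.xv),
                    )
                )
            i += 1
    out.sort(key=lambda a: (a.peak.center, a.feature.start))
    return out


def annotations_to_rows(annotations: list[PeakAnnotation]) -> list[dict]:
    """Flatten annotations to plain dicts for TSV/DataFrame export."""
    return [
        {
            "peak_center": a.peak.center,
            "peak_amplitude": a.peak.amplitude,
            "peak_p": a.peak.p,
            "feature": a.feature_label,
            "feature_start": a.feature.start,
            "feature_end": a.feature.end,
            "overlap_bp": a.overlap,
            "distance_to_viewpoint": a.distance_to_viewpoint,
        }
        for a in annotations
    ]
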