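"""Readers and writers for the text formats the pipeline touches.

Formats: 4-column bedGraph (per-fragment counts), BED3/BED4 annotation
tracks, TSV peak tables, JSON model fits and simulation-truth files, plus a
flat YAML config.  Coordinates are 0-based half-open everywhere, matching
the in-memory convention.  Every writer produces a file its paired reader
accepts unchanged.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import yaml

from .errors import ParseError, ValidationError
from .intervals import AnnotationTrack, GenomicInterval
from .profile import Profile

logger = logging.getLogger("fourcis")


def setup_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; ``verbose`` switches INFO → DEBUG."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# bedGraph profiles
# ---------------------------------------------------------------------------

def read_profile_bedgraph(path, viewpoint: GenomicInterval) -> Profile:
    """Read a 4-column bedGraph of per-fragment counts into a :class:`Profile`.

    The profile's anchor ``xv`` is the midpoint of ``viewpoint``.  Intervals
    must be sorted and non-overlapping with non-negative values; violations
    raise :class:`ValidationError`, malformed lines a :class:`ParseError`
    naming the line number.
    """
    starts, ends, counts = [], [], []
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}")
            try:
                c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if e <= s:
                raise ValidationError(f"{path}:{lineno}: interval end {e} <= start {s}")
            if v < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {v}")
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ValidationError(
                    f"{path}:{lineno}: near-cis profile must be single-chromosome "
                    f"({c!r} after {chrom!r})"
                )
            if starts and s < ends[-1]:
                raise ValidationError(f"{path}:{lineno}: intervals overlap or are unsorted")
            starts.append(s)
            ends.append(e)
            counts.append(v)
    xv = viewpoint.midpoint
    return Profile(chrom or viewpoint.chrom, xv, np.array(starts, dtype=np.int64),
                   np.array(ends, dtype=np.int64), np.array(counts), stage="raw")


def write_profile_bedgraph(profile: Profile, path) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(profile.starts, profile.ends, profile.counts):
            fh.write(f"{profile.chrom}\t{s}\t{e}\t{v:.17g}\n")


# ---------------------------------------------------------------------------
# BED tracks
# ---------------------------------------------------------------------------

def read_intervals_bed(path, name: str | None = None) -> AnnotationTrack:
    """Read BED3/BED4+ into a sorted :class:`AnnotationTrack`.

    BED3 records are auto-labelled ``feature_<index>`` in input order.
    """
    features = []
    with open(path) as fh:
        idx = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, s, e = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if e <= s:
                raise ValidationError(f"{path}:{lineno}: interval end {e} <= start {s}")
            label = fields[3] if len(fields) >= 4 else f"feature_{idx}"
            features.append((GenomicInterval(chrom, s, e), label))
            idx += 1
    return AnnotationTrack(name or Path(path).stem, features)


def write_intervals_bed(track: AnnotationTrack, path) -> None:
    with open(path, "w") as fh:
        for iv, label in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def write_fragment_map_bed(fmap, path) -> None:
    """Export a fragment map as BED4, flanks encoded as ``left:right``."""
    from .fragments import FLANK_NAMES

    with open(path, "w") as fh:
        for s, e, l, r in zip(fmap.starts, fmap.ends, fmap.left_codes, fmap.right_codes):
            fh.write(f"{fmap.chrom}\t{s}\t{e}\t{FLANK_NAMES[int(l)]}:{FLANK_NAMES[int(r)]}\n")


def read_fragment_map_bed(path):
    from .fragments import FLANK_CODES, FragmentMap

    starts, ends, lefts, rights = [], [], [], []
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 4 or ":" not in fields[3]:
                raise ParseError(f"{path}:{lineno}: expected BED4 with left:right flank name")
            chrom = chrom or fields[0]
            starts.append(int(fields[1]))
            ends.append(int(fields[2]))
            l, r = fields[3].split(":", 1)
            try:
                lefts.append(FLANK_CODES[l])
                rights.append(FLANK_CODES[r])
            except KeyError as exc:
                raise ParseError(f"{path}:{lineno}: unknown flank label {exc}") from exc
    region = GenomicInterval(chrom, starts[0], ends[-1])
    return FragmentMap(chrom, region, np.array(starts), np.array(ends),
                       np.array(lefts), np.array(rights))


# ---------------------------------------------------------------------------
# Peak tables and model fits
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = ("center", "amplitude", "z", "p", "significant")


def write_peaks_tsv(fit, path) -> None:
    """One row per fitted peak, ordered by center; header always present."""
    peaks = sorted(fit.peaks, key=lambda p: p.center)
    with open(path, "w") as fh:
        fh.write("\t".join(_PEAK_COLUMNS) + "\n")
        for pk in peaks:
            fh.write(
                f"{pk.center:.9g}\t{pk.amplitude:.9g}\t{pk.z:.9g}\t{pk.p:.9g}\t"
                f"{int(pk.significant)}\n"
            )


def read_peaks_tsv(path) -> list:
    from .decompose import Peak

    peaks = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if tuple(header) != _PEAK_COLUMNS:
            raise ParseError(f"{path}:1: unexpected peak-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            peaks.append(
                Peak(
                    center=float(fields[0]),
                    amplitude=float(fields[1]),
                    z=float(fields[2]),
                    p=float(fields[3]),
                    significant=bool(int(fields[4])),
                )
            )
    return peaks


def write_fit_json(fit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
        fh.write("\n")


def read_fit_json(path):
    from .decompose import ModelFit

    with open(path) as fh:
        return ModelFit.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Simulation truth
# ---------------------------------------------------------------------------

def write_truth_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
        fh.write("\n")


def read_truth_json(path):
    from .simulate import SimulationTruth

    with open(path) as fh:
        return SimulationTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Flat key-value YAML mirroring the CLI flags; CLI values override it."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a flat mapping")
    return cfg
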