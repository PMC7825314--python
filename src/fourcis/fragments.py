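"""Restriction fragment maps from in-silico digestion.

4C libraries are built with two 4-bp cutters: a primary enzyme (DpnII,
``GATC``) that defines the viewpoint fragment ends, and a secondary enzyme
(Csp6I, ``G^TAC``) used for the second circularisation step.  Digesting a
sequence with both enzymes yields an ordered map of fragments tiling the
region, each end labelled with the enzyme that produced the cut.  Fragments
flanked on both sides by sites of the *same* enzyme ("blind" fragments)
carry no usable ligation information and are filtered before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .intervals import GenomicInterval

# flank codes
BOUNDARY = 0
PRIMARY = 1
SECONDARY = 2
FLANK_NAMES = {BOUNDARY: "boundary", PRIMARY: "primary", SECONDARY: "secondary"}
FLANK_CODES = {v: k for k, v in FLANK_NAMES.items()}

_MOTIF_LEN = 4
_ALPHABET = set(b"ACGT")


@dataclass(frozen=True)
class EnzymeSpec:
    """A 4-bp cutter: recognition motif and cut offset within it."""

    name: str
    motif: str
    cut_offset: int
    role: str  # "primary" | "secondary"

    def __post_init__(self):
        motif = self.motif.upper()
        if len(motif) != _MOTIF_LEN or not set(motif.encode()) <= _ALPHABET:
            raise ValidationError(
                f"enzyme motif must be 4 letters over ACGT, got {self.motif!r}"
            )
        object.__setattr__(self, "motif", motif)
        if not 0 <= self.cut_offset <= _MOTIF_LEN:
            raise ValidationError(f"cut_offset must be in [0, 4], got {self.cut_offset}")
        if self.role not in ("primary", "secondary"):
            raise ValidationError(f"role must be primary|secondary, got {self.role!r}")


# catalog chemistry: DpnII cuts 5' of GATC; Csp6I cuts G^TAC
DPNII = EnzymeSpec("DpnII", "GATC", 0, "primary")
CSP6I = EnzymeSpec("Csp6I", "GTAC", 1, "secondary")


@dataclass(frozen=True)
class Fragment:
    interval: GenomicInterval
    left_flank: str
    right_flank: str

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def midpoint(self) -> float:
        return self.interval.midpoint


@dataclass
class FragmentMap:
    """Ordered restriction fragments exactly tiling ``region``.

    Stored columnar (numpy arrays) for vectorised filtering; ``fragments``
    materialises :class:`Fragment` objects on demand.
    """

    chrom: str
    region: GenomicInterval
    starts: np.ndarray
    ends: np.ndarray
    left_codes: np.ndarray
    right_codes: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.left_codes = np.asarray(self.left_codes, dtype=np.int8)
        self.right_codes = np.asarray(self.right_codes, dtype=np.int8)
        n = self.starts.size
        if not (self.ends.size == self.left_codes.size == self.right_codes.size == n):
            raise ValidationError("fragment map arrays must have equal length")
        if n:
            if np.any(self.ends <= self.starts):
                raise ValidationError("fragment map contains empty or inverted fragments")
            if self.starts[0] != self.region.start or self.ends[-1] != self.region.end:
                raise ValidationError("fragments do not span the declared region")
            if np.any(self.starts[1:] != self.ends[:-1]):
                raise ValidationError("fragments must be contiguous and sorted")

    def __len__(self) -> int:
        return self.starts.size

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def fragments(self) -> list[Fragment]:
        return [
            Fragment(
                GenomicInterval(self.chrom, int(s), int(e)),
                FLANK_NAMES[int(l)],
                FLANK_NAMES[int(r)],
            )
            for s, e, l, r in zip(self.starts, self.ends, self.left_codes, self.right_codes)
        ]


def find_motif_sites(sequence: str, motif: str) -> np.ndarray:
    """All 0-based start positions of ``motif`` in ``sequence``.

    Overlapping occurrences are included; matching is case-insensitive and
    any position overlapping an ``N`` never matches.
    """
    if len(motif) != _MOTIF_LEN:
        raise ValidationError(f"motif must be 4 bp, got {len(motif)}")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    m = np.frombuffer(motif.upper().encode("ascii"), dtype=np.uint8)
    n = arr.size - _MOTIF_LEN + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    hits = arr[0:n] == m[0]
    for k in range(1, _MOTIF_LEN):
        hits &= arr[k : n + k] == m[k]
    return np.flatnonzero(hits).astype(np.int64)


def digest(
    sequence: str,
    primary: EnzymeSpec = DPNII,
    secondary: EnzymeSpec = CSP6I,
    chrom: str = "chr_sim",
    offset: int = 0,
) -> FragmentMap:
    """Digest ``sequence`` with both enzymes into a :class:`FragmentMap`.

    Cut positions are motif starts plus the enzyme's cut offset, pooled over
    both enzymes, plus the region boundaries.  Each internal flank is
    labelled with the enzyme that produced the cut; region ends are labelled
    ``boundary``.  ``offset`` shifts coordinates to place the map on a
    genome (default 0 → sequence-local coordinates).
    """
    L = len(sequence)
    if L < 1:
        raise ValidationError("cannot digest a zero-length sequence")
    if primary.motif == secondary.motif:
        raise ValidationError("primary and secondary motifs must differ")

    pos_list, code_list = [], []
    for enz, code in ((primary, PRIMARY), (secondary, SECONDARY)):
        sites = find_motif_sites(sequence, enz.motif) + enz.cut_offset
        pos_list.append(sites)
        code_list.append(np.full(sites.size, code, dtype=np.int8))
    pos = np.concatenate(pos_list)
    codes = np.concatenate(code_list)

    # interior cuts only; a cut at 0 or L coincides with the region boundary
    keep = (pos > 0) & (pos < L)
    pos, codes = pos[keep], codes[keep]
    # sort by position; on a positional tie the primary enzyme takes precedence
    order = np.lexsort((codes, pos))
    pos, codes = pos[order], codes[order]
    uniq = np.ones(pos.size, dtype=bool)
    uniq[1:] = pos[1:] != pos[:-1]
    pos, codes = pos[uniq], codes[uniq]

    starts = np.concatenate(([0], pos)) + offset
    ends = np.concatenate((pos, [L])) + offset
    left = np.concatenate(([BOUNDARY], codes)).astype(np.int8)
    right = np.concatenate((codes, [BOUNDARY])).astype(np.int8)
    region = GenomicInterval(chrom, offset, offset + L)
    return FragmentMap(chrom, region, starts, ends, left, right)


def blind_mask(fmap: FragmentMap) -> np.ndarray:
    """Boolean mask of blind fragments (both flanks cut by the same enzyme).

    Region-boundary flanks never qualify: they are windowing artifacts, not
    restriction sites.
    """
    return (fmap.left_codes == fmap.right_codes) & (fmap.left_codes != BOUNDARY)


def blind_fragments(fmap: FragmentMap) -> list[Fragment]:
    """The blind subset of ``fmap`` as :class:`Fragment` objects."""
    mask = blind_mask(fmap)
    return [f for f, m in zip(fmap.fragments, mask) if m]
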