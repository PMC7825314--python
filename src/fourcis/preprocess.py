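"""Fragment filtering, depth normalization and left-right symmetrization.

Standard 4C preprocessing before model fitting:

* drop blind fragments (both flanks cut by the same enzyme), fragments
  shorter than 40 bp, and fragments inside a 10-kb window centred on the
  viewpoint (self-ligation and re-ligation artifacts dominate there);
* scale counts so that the total within ±2 Mb of the viewpoint equals a
  fixed value (10^6 by default, i.e. reads-per-million within the near-cis
  window), making profiles comparable across sequencing depths;
* average the left and right arms as a function of distance from the
  viewpoint, assuming a symmetric decay trend, to stabilise the decay fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .fragments import FragmentMap, blind_mask
from .profile import Profile


@dataclass
class SymmetrizedProfile:
    """Distance-binned left-right averaged signal.

    ``d`` is the mean fragment distance within each bin (bp), ``m`` the mean
    signal over contributing fragments from both arms, ``w`` the number of
    contributing fragments.  Empty bins are omitted.
    """

    d: np.ndarray
    m: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        self.m = np.asarray(self.m, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.d.size and (np.any(np.diff(self.d) <= 0) or np.any(self.d < 0)):
            raise ValidationError("bin distances must be non-negative and strictly increasing")
        if np.any(self.w < 1):
            raise ValidationError("each bin must have at least one contributing fragment")

    def __len__(self) -> int:
        return self.d.size


def _match_map(profile: Profile, fmap: FragmentMap) -> np.ndarray:
    """Indices into ``fmap`` of each profile fragment; errors if unmatched."""
    idx = np.searchsorted(fmap.starts, profile.starts)
    ok = (idx < len(fmap)) if len(fmap) else np.zeros(len(profile), dtype=bool)
    if len(fmap):
        idx_c = np.clip(idx, 0, len(fmap) - 1)
        ok &= (fmap.starts[idx_c] == profile.starts) & (fmap.ends[idx_c] == profile.ends)
    if not np.all(ok):
        bad = int(np.flatnonzero(~ok)[0])
        raise ValidationError(
            f"profile fragment [{profile.starts[bad]}, {profile.ends[bad]}) "
            "is not present in the fragment map"
        )
    return idx


def filter_fragments(
    profile: Profile,
    fmap: FragmentMap,
    min_len: int = 40,
    viewpoint_window: float = 10_000,
    drop_blind: bool = True,
) -> Profile:
    """Apply the three fragment filters; counts are never altered.

    Removes (a) blind fragments, (b) fragments with length < ``min_len``
    (strict: length exactly ``min_len`` is kept), and (c) fragments whose
    midpoint lies within the exclusion window of *total* width
    ``viewpoint_window`` centred on the viewpoint (|x - xv| <
    viewpoint_window / 2).  Rules are independent masks, so the result does
    not depend on application order; individual rules can be disabled
    (``min_len=0``, ``viewpoint_window=0``, ``drop_blind=False``) which also
    makes single-rule passes composable on an already-filtered profile.
    """
    if profile.stage not in ("raw", "filtered"):
        raise ValidationError(f"filter_fragments expects a raw profile, got stage {profile.stage!r}")
    idx = _match_map(profile, fmap)
    keep = np.ones(len(profile), dtype=bool)
    if drop_blind:
        keep &= ~blind_mask(fmap)[idx]
    keep &= profile.lengths >= min_len
    keep &= profile.distances >= viewpoint_window / 2.0
    if not keep.any():
        raise ValidationError("no fragments survive filtering; profile unusable")
    return profile.subset(keep, stage="filtered")


def normalize(
    profile: Profile,
    window: float = 2_000_000,
    scale: float = 1_000_000,
) -> Profile:
    """Scale counts so the total within ±``window`` of the viewpoint is ``scale``.

    Window membership is by fragment midpoint, bounds inclusive.  Applying
    normalize twice equals applying it once (idempotent at a fixed scale).
    """
    if profile.stage not in ("filtered", "normalized"):
        raise ValidationError(
            f"normalize expects a filtered profile, got stage {profile.stage!r}"
        )
    in_window = profile.distances <= window
    total = profile.counts[in_window].sum()
    if total <= 0:
        raise ValidationError("no reads within the normalization window")
    return profile.with_counts(profile.counts * (scale / total), stage="normalized")


def symmetrize(profile: Profile, bin_width: float = 2_000) -> SymmetrizedProfile:
    """Left-right averaged profile, binned by distance from the viewpoint.

    Fragments from both arms are pooled into consecutive distance bins of
    ``bin_width``; each bin reports the mean signal, the mean fragment
    distance and the number of contributing fragments.  Empty bins are
    omitted.  The output depends on fragment distances only, so it is
    invariant under mirroring the profile about the viewpoint.
    """
    if profile.stage != "normalized":
        raise ValidationError(f"symmetrize expects a normalized profile, got {profile.stage!r}")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    d = profile.distances
    bins = np.floor(d / bin_width).astype(np.int64)
    order = np.argsort(bins, kind="stable")
    bins_s, d_s, c_s = bins[order], d[order], profile.counts[order]
    uniq, start_idx = np.unique(bins_s, return_index=True)
    w = np.diff(np.append(start_idx, bins_s.size)).astype(np.float64)
    m = np.add.reduceat(c_s, start_idx) / w
    dmean = np.add.reduceat(d_s, start_idx) / w
    return SymmetrizedProfile(dmean, m, w)


def running_mean(values: np.ndarray, k: int) -> np.ndarray:
    """Centred running mean over ``k`` samples with edge replication."""
    from scipy.ndimage import uniform_filter1d

    if k <= 1:
        return np.asarray(values, dtype=np.float64)
    return uniform_filter1d(np.asarray(values, dtype=np.float64), size=k, mode="nearest")
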