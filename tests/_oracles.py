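"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive algorithms (per-position string scans,
all-pairs interval intersection) that share no code with the package.
"""

from __future__ import annotations

import numpy as np


def brute_force_digest(sequence: str, primary, secondary):
    """Scan every 4-mer, cut, and tile; returns (starts, ends, left, right).

    Flank codes: 0 boundary, 1 primary, 2 secondary.  On a positional tie
    the primary enzyme takes precedence.
    """
    seq = sequence.upper()
    L = len(seq)
    labels: dict[int, int] = {}
    for enz, code in ((primary, 1), (secondary, 2)):
        motif = enz.motif.upper()
        for i in range(L - 3):
            if seq[i : i + 4] == motif:
                pos = i + enz.cut_offset
                if 0 < pos < L:
                    labels.setdefault(pos, code)
    cuts = sorted(labels)
    bounds = [0] + cuts + [L]
    starts, ends, lefts, rights = [], [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        starts.append(a)
        ends.append(b)
        lefts.append(labels.get(a, 0) if a != 0 else 0)
        rights.append(labels.get(b, 0) if b != L else 0)
    return (np.array(starts), np.array(ends), np.array(lefts), np.array(rights))


def brute_force_overlaps(peak_extents, features):
    """All-pairs half-open interval intersection.

    ``peak_extents``: list of (peak_id, start, end); ``features``: list of
    (label, start, end).  Returns the set of (peak_id, label, overlap_bp)
    with overlap >= 1.
    """
    out = set()
    for pid, ps, pe in peak_extents:
        for label, fs, fe in features:
            ov = min(pe, fe) - max(ps, fs)
            if ov >= 1:
                out.add((pid, label, ov))
    return out
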