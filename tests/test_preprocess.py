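import itertools

import numpy as np
import pytest

from fourcis import (
    Profile,
    ValidationError,
    filter_fragments,
    normalize,
    symmetrize,
)
from conftest import mirror_dataset


class TestFilterFragments:
    def test_toy_map_one_violation_per_rule(self, toy_profile, toy_map):
        """Exactly one blind, one short and one viewpoint-proximal fragment drop."""
        out = filter_fragments(toy_profile, toy_map)
        assert len(out) == 3
        assert list(out.starts) == [0, 24_000, 32_000]
        assert out.stage == "filtered"

    def test_counts_never_altered(self, toy_profile, toy_map):
        out = filter_fragments(toy_profile, toy_map)
        assert list(out.counts) == [10.0, 50.0, 60.0]

    def test_length_boundary_is_strict(self, toy_map):
        # a fragment of exactly min_len survives; one bp shorter does not
        prof = Profile("chr_toy", 20_000.0, toy_map.starts, toy_map.ends,
                       np.ones(6), stage="raw")
        kept40 = filter_fragments(prof, toy_map, min_len=39, viewpoint_window=0,
                                  drop_blind=False)
        assert 8_000 in kept40.starts  # the 39-bp fragment kept at min_len=39
        kept = filter_fragments(prof, toy_map, min_len=40, viewpoint_window=0,
                                drop_blind=False)
        assert 8_000 not in kept.starts

    def test_blind_fragment_removed(self, toy_profile, toy_map):
        out = filter_fragments(toy_profile, toy_map, min_len=0, viewpoint_window=0)
        assert 8_039 not in out.starts

    def test_viewpoint_window_is_total_width(self, toy_profile, toy_map):
        # total width 10 kb = ±5 kb: only f4 (midpoint at xv) is dropped
        out = filter_fragments(toy_profile, toy_map, min_len=0, drop_blind=False,
                               viewpoint_window=10_000)
        assert 16_000 not in out.starts and 24_000 in out.starts
        # widening to ±8.5 kb additionally drops f5 (midpoint 8 kb away)
        out2 = filter_fragments(toy_profile, toy_map, min_len=0, drop_blind=False,
                                viewpoint_window=17_000)
        assert 24_000 not in out2.starts and 0 in out2.starts

    def test_order_independent(self, toy_profile, toy_map):
        """Applying the three rules one at a time, in any order, matches."""
        joint = filter_fragments(toy_profile, toy_map)
        passes = {
            "blind": dict(min_len=0, viewpoint_window=0, drop_blind=True),
            "len": dict(min_len=40, viewpoint_window=0, drop_blind=False),
            "vp": dict(min_len=0, viewpoint_window=10_000, drop_blind=False),
        }
        for order in itertools.permutations(passes):
            prof = toy_profile
            for rule in order:
                prof = filter_fragments(prof, toy_map, **passes[rule])
            assert list(prof.starts) == list(joint.starts)

    def test_empty_result_is_an_error(self, toy_profile, toy_map):
        with pytest.raises(ValidationError, match="unusable"):
            filter_fragments(toy_profile, toy_map, min_len=100_000)

    def test_unknown_fragment_rejected(self, toy_map):
        prof = Profile("chr_toy", 20_000.0, [0, 16_000], [8_000, 24_100],
                       [1.0, 1.0], stage="raw")
        with pytest.raises(ValidationError, match="not present"):
            filter_fragments(prof, toy_map)


def _flat_profile(xv=50_000.0, n=9, spacing=10_000, counts=None):
    starts = np.arange(n) * spacing
    ends = starts + spacing
    counts = np.full(n, 50.0) if counts is None else np.asarray(counts, float)
    return Profile("chrA", xv, starts, ends, counts, stage="filtered")


class TestNormalize:
    def test_in_window_total_equals_scale(self):
        prof = _flat_profile(n=4, counts=[50, 50, 50, 50], xv=20_000.0)
        out = normalize(prof)
        assert np.allclose(out.counts, 250_000.0)
        assert out.counts.sum() == pytest.approx(1e6, rel=1e-12)
        assert out.stage == "normalized"

    def test_distal_counts_do_not_affect_scaling(self):
        # one fragment far beyond the window contributes nothing to the factor
        starts = np.array([0, 10_000, 5_000_000])
        ends = starts + 10_000
        prof = Profile("chrA", 10_000.0, starts, ends, [50.0, 50.0, 1e9],
                       stage="filtered")
        out = normalize(prof, window=2_000_000)
        assert out.counts[0] == pytest.approx(5e5)

    def test_idempotent_at_fixed_scale(self, small_profile, small_map):
        filtered = filter_fragments(small_profile, small_map)
        once = normalize(filtered)
        twice = normalize(once)
        assert np.allclose(once.counts, twice.counts, rtol=1e-12)

    def test_zero_in_window_total_is_an_error(self):
        prof = _flat_profile(counts=np.zeros(9))
        with pytest.raises(ValidationError):
            normalize(prof)

    def test_requires_filtered_stage(self, toy_profile):
        with pytest.raises(ValidationError, match="filtered"):
            normalize(toy_profile)


class TestSymmetrize:
    def test_two_mirrored_fragments_pool_into_one_bin(self):
        starts = np.array([38_000, 58_000])
        ends = starts + 4_000
        prof = Profile("chrA", 50_000.0, starts, ends, [4.0, 8.0], stage="normalized")
        sym = symmetrize(prof, bin_width=2_000)
        assert len(sym) == 1
        assert sym.m[0] == pytest.approx(6.0)
        assert sym.w[0] == 2
        assert sym.d[0] == pytest.approx(10_000.0)

    def test_signal_mass_conserved(self, small_profile, small_map):
        prof = normalize(filter_fragments(small_profile, small_map))
        sym = symmetrize(prof)
        assert np.sum(sym.m * sym.w) == pytest.approx(prof.counts.sum(), rel=1e-12)
        assert np.sum(sym.w) == len(prof)

    def test_mirror_invariance(self, small_profile, small_map):
        prof = normalize(filter_fragments(small_profile, small_map))
        m_map, m_raw = mirror_dataset(small_map, small_profile)
        m_prof = normalize(filter_fragments(m_raw, m_map))
        a, b = symmetrize(prof), symmetrize(m_prof)
        assert np.allclose(a.d, b.d) and np.allclose(a.m, b.m) and np.array_equal(a.w, b.w)

    def test_exactly_symmetric_profile_equals_one_sided_binning(self):
        # mirror-symmetric counts: pooled bins equal the one-sided bins
        d_half = np.array([5_000, 9_000, 13_000])
        starts = np.concatenate([50_000 - d_half[::-1] - 500, 50_000 + d_half - 500])
        ends = starts + 1_000
        counts = np.array([3.0, 2.0, 1.0, 1.0, 2.0, 3.0])
        prof = Profile("chrA", 50_000.0, starts, ends, counts, stage="normalized")
        sym = symmetrize(prof, bin_width=2_000)
        # pooled bins equal the one-sided values, each with both arms pooled
        assert np.allclose(sym.d, d_half)
        assert np.allclose(sym.m, [1.0, 2.0, 3.0])
        assert np.array_equal(sym.w, [2, 2, 2])

    def test_requires_normalized_stage(self, toy_profile):
        with pytest.raises(ValidationError):
            symmetrize(toy_profile)
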