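import numpy as np
import pytest

from fourcis import (
    DecayParams,
    FragmentMap,
    GenomicInterval,
    Profile,
    SimulationTruth,
    digest,
    simulate_genome,
    simulate_profile,
)


@pytest.fixture(scope="session")
def toy_map():
    """Six contiguous fragments with exactly one filter violation each.

    With the viewpoint at 20 kb: f2 is 39 bp long, f3 is blind
    (secondary/secondary), f4 straddles the viewpoint; f1, f5, f6 are clean.
    """
    starts = [0, 8_000, 8_039, 16_000, 24_000, 32_000]
    ends = [8_000, 8_039, 16_000, 24_000, 32_000, 40_000]
    left = [0, 1, 2, 2, 1, 2]  # boundary, primary, secondary, ...
    right = [1, 2, 2, 1, 2, 0]
    region = GenomicInterval("chr_toy", 0, 40_000)
    return FragmentMap("chr_toy", region, np.array(starts), np.array(ends),
                       np.array(left), np.array(right))


@pytest.fixture
def toy_profile(toy_map):
    counts = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
    return Profile("chr_toy", 20_000.0, toy_map.starts, toy_map.ends, counts, stage="raw")


@pytest.fixture(scope="session")
def small_map():
    """A 1-Mb simulated genome digested with the default enzymes."""
    genome = simulate_genome(1_000_000, gc=0.41, seed=42)
    return digest(genome, chrom="chr_small")


@pytest.fixture(scope="session")
def small_truth():
    xv = 500_000.0
    return SimulationTruth(
        decay=DecayParams(B=5.0, I=500.0, lam=50_000.0),
        peaks=[(xv + 60_000.0, 150.0), (xv - 150_000.0, 80.0)],
        sigma=3_000.0,
        depth=300_000.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_profile(small_map, small_truth):
    return simulate_profile(small_map, 500_000.0, small_truth)


@pytest.fixture(scope="session")
def small_noise_free_profile(small_map, small_truth):
    return simulate_profile(small_map, 500_000.0, small_truth, noise_free=True)


def mirror_dataset(fmap: FragmentMap, profile: Profile):
    """Reflect a map and raw profile about the viewpoint (2*xv must be int)."""
    pivot = int(round(2 * profile.xv))
    starts = pivot - fmap.ends[::-1]
    ends = pivot - fmap.starts[::-1]
    region = GenomicInterval(fmap.chrom, int(starts[0]), int(ends[-1]))
    m_map = FragmentMap(fmap.chrom, region, starts, ends,
                        fmap.right_codes[::-1], fmap.left_codes[::-1])
    m_prof = Profile(profile.chrom, profile.xv, pivot - profile.ends[::-1],
                     pivot - profile.starts[::-1], profile.counts[::-1], stage=profile.stage)
    return m_map, m_prof


def shift_dataset(fmap: FragmentMap, profile: Profile, delta: int):
    region = GenomicInterval(fmap.chrom, int(fmap.region.start + delta),
                             int(fmap.region.end + delta))
    s_map = FragmentMap(fmap.chrom, region, fmap.starts + delta, fmap.ends + delta,
                        fmap.left_codes, fmap.right_codes)
    s_prof = Profile(profile.chrom, profile.xv + delta, profile.starts + delta,
                     profile.ends + delta, profile.counts, stage=profile.stage)
    return s_map, s_prof
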