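"""Self-contained validation studies on simulated data.

These runners generate data with the synthetic-data module, run the full
pipeline and measure recovery of the known truth.  They back both the
acceptance test suite and ``scripts/acceptance.py``.  Study sizes (region
4 Mb, depth 10^6, 20 recovery seeds, 100 null simulations, 1000 reporter
runs) are the package's reference conditions for a strong near-cis
profile; one restriction map (drawn from the base seed) is shared across
the seeds of a study, emulating repeated libraries on a fixed genome.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .fragments import CSP6I, DPNII, digest
from .model import FourCPeakCaller
from .reporter import allele_comparison_from_table
from .simulate import (
    SimulationTruth,
    default_truth,
    expected_signal,
    simulate_genome,
    simulate_profile,
    simulate_reporter_assay,
)

REGION_LENGTH = 4_000_000


def _child_seeds(base_seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(base_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def make_reference_map(seed: int = 0, region_length: int = REGION_LENGTH):
    """Digest a simulated genome into the reference fragment map."""
    genome = simulate_genome(region_length, gc=0.41, seed=seed)
    return digest(genome, DPNII, CSP6I, chrom="chr_sim")


def truth_scale(fmap, truth: SimulationTruth, viewpoint: float, caller=None) -> float:
    """Factor relating truth model units to fitted (normalized) amplitudes.

    The fitted profile is depth-scaled at simulation time and re-scaled by
    the preprocessing normalization (computed on the *filtered* in-window
    fragments), so truth amplitudes map to fitted ones through a single
    constant.  It is measured by pushing the exact expectations through the
    same preprocessing and comparing them to the truth model pointwise.
    """
    from .decompose import evaluate_model
    from .preprocess import filter_fragments, normalize
    from .profile import Profile

    caller = caller or FourCPeakCaller()
    mu = expected_signal(fmap, viewpoint, truth)
    prof = Profile(fmap.chrom, viewpoint, fmap.starts, fmap.ends, mu, stage="raw")
    prof = filter_fragments(
        prof, fmap, min_len=caller.min_fragment_len, viewpoint_window=caller.viewpoint_window
    )
    prof = normalize(prof, window=caller.norm_window, scale=caller.scale)
    s = evaluate_model(truth.decay, truth.peaks, truth.sigma, viewpoint, prof.midpoints)
    nz = s > 0
    return float(np.median(prof.counts[nz] / s[nz]))


def noise_free_recovery(seed: int = 0) -> dict:
    """Fit the pipeline to an exact (noise-free) model profile.

    Counts are set to the model expectation exactly; after depth
    normalization the profile equals c * S(x) with c the depth-matching
    factor, so fitted amplitudes are compared against c-scaled truth while
    lam, sigma and centers are compared directly.  Returns per-parameter
    relative errors and their maximum.
    """
    fmap = make_reference_map(seed)
    truth = default_truth(REGION_LENGTH, seed=seed)
    xv = REGION_LENGTH / 2.0
    profile = simulate_profile(fmap, xv, truth, noise_free=True)
    c = truth_scale(fmap, truth, xv)

    caller = FourCPeakCaller().fit(profile, fmap)
    fit = caller.model_fit_

    errors = {
        "B": abs(fit.decay.B - c * truth.decay.B) / (c * truth.decay.B),
        "I": abs(fit.decay.I - c * truth.decay.I) / (c * truth.decay.I),
        "lam": abs(fit.decay.lam - truth.decay.lam) / truth.decay.lam,
        "sigma": abs(fit.sigma - truth.sigma) / truth.sigma,
    }
    centers = np.array([p.center for p in fit.peaks])
    for i, (tc, ta) in enumerate(sorted(truth.peaks)):
        if centers.size == 0:
            errors[f"peak{i}_amplitude"] = np.inf
            errors[f"peak{i}_center"] = np.inf
            continue
        j = int(np.argmin(np.abs(centers - tc)))
        pk = fit.peaks[j]
        errors[f"peak{i}_amplitude"] = abs(pk.amplitude - c * ta) / (c * ta)
        errors[f"peak{i}_center"] = abs(pk.center - tc) / abs(tc)
    errors["n_peaks_called"] = len(fit.peaks)
    errors["max_rel_error"] = max(
        v for k, v in errors.items() if k != "n_peaks_called"
    )
    return errors


def parameter_recovery_study(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Noisy recovery at reference depth: lambda error, recall, center error.

    For each seed a Poisson profile is drawn from the default truth and the
    pipeline is run end to end.  A true peak counts as recovered when a
    significant called peak lies within ±2 kb of it.
    """
    fmap = make_reference_map(base_seed)
    xv = REGION_LENGTH / 2.0
    base_truth = default_truth(REGION_LENGTH)
    seeds = _child_seeds(base_seed, n_seeds)

    lam_errors, all_called, center_errors = [], [], []
    for seed in seeds:
        truth = replace(base_truth, seed=int(seed))
        profile = simulate_profile(fmap, xv, truth)
        fit = FourCPeakCaller().fit(profile, fmap).model_fit_
        lam_errors.append(abs(fit.decay.lam - truth.decay.lam) / truth.decay.lam)
        sig_centers = np.array([p.center for p in fit.significant_peaks])
        called = []
        for tc, _ in truth.peaks:
            if sig_centers.size:
                err = float(np.min(np.abs(sig_centers - tc)))
                called.append(err <= 2_000.0)
                if err <= 2_000.0:
                    center_errors.append(err)
            else:
                called.append(False)
        all_called.append(all(called))

    return {
        "n_seeds": n_seeds,
        "lambda_rel_errors": lam_errors,
        "lambda_median_rel_error": float(np.median(lam_errors)),
        "seeds_all_peaks_called": int(np.sum(all_called)),
        "center_errors_bp": center_errors,
        "median_center_error_bp": float(np.median(center_errors)) if center_errors else np.nan,
        "max_center_error_bp": float(np.max(center_errors)) if center_errors else np.nan,
    }


def null_specificity_study(n_sims: int = 100, base_seed: int = 0) -> dict:
    """Significant-peak counts on profiles simulated with zero true peaks."""
    fmap = make_reference_map(base_seed)
    xv = REGION_LENGTH / 2.0
    base_truth = default_truth(REGION_LENGTH)
    null_truth = replace(base_truth, peaks=[])
    seeds = _child_seeds(base_seed + 1, n_sims)

    counts = []
    for seed in seeds:
        truth = replace(null_truth, seed=int(seed))
        profile = simulate_profile(fmap, xv, truth)
        fit = FourCPeakCaller().fit(profile, fmap).model_fit_
        counts.append(len(fit.significant_peaks))
    return {
        "n_sims": n_sims,
        "significant_counts": counts,
        "median_significant": float(np.median(counts)),
        "mean_significant": float(np.mean(counts)),
    }


def reporter_power_study(
    n_runs: int = 1_000,
    base_seed: int = 0,
    effect_ratio: float = 0.75,
    cv: float = 0.10,
) -> dict:
    """Welch-test power for a 25% allelic reduction in the 4x3 design."""
    seeds = _child_seeds(base_seed + 2, n_runs)
    hits = 0
    for seed in seeds:
        table = simulate_reporter_assay(
            effect_ratio=effect_ratio, cv=cv, seed=int(seed)
        )
        result = allele_comparison_from_table(table)
        hits += result.welch_p < 0.05
    return {"n_runs": n_runs, "power": hits / n_runs}
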