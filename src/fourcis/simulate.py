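"""Synthetic data with known ground truth.

Three generators: random genomes (i.i.d. bases at a target GC content),
near-cis 4C count profiles over a restriction fragment map (constant
background + exponential decay + Gaussian peaks, Poisson count noise), and
dual-luciferase reporter replicate tables (log-normal multiplicative noise
around construct-specific fold changes).  Everything is bit-reproducible
under a fixed seed, and profile truth parameters can be written alongside
the simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decompose import DecayParams, evaluate_model
from .errors import ValidationError
from .fragments import FragmentMap
from .profile import Profile

NEAR_CIS_WINDOW = 2_000_000  # ±2 Mb normalization / depth window


@dataclass
class SimulationTruth:
    """Generative parameters of a simulated 4C profile.

    ``depth`` is the expected total read count within ±2 Mb of the
    viewpoint; ``peaks`` are (center, amplitude) pairs in model-signal
    units; ``sigma`` is the shared Gaussian width in bp.
    """

    decay: DecayParams
    peaks: list[tuple[float, float]] = field(default_factory=list)
    sigma: float = 3_000.0
    depth: float = 1_000_000.0
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if any(a < 0 for _, a in self.peaks):
            raise ValidationError("peak amplitudes must be non-negative")

    def to_dict(self) -> dict:
        return {
            "decay": {"B": self.decay.B, "I": self.decay.I, "lam": self.decay.lam},
            "peaks": [[float(c), float(a)] for c, a in self.peaks],
            "sigma": self.sigma,
            "depth": self.depth,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(
            decay=DecayParams(**d["decay"]),
            peaks=[(c, a) for c, a in d["peaks"]],
            sigma=d["sigma"],
            depth=d["depth"],
            seed=d["seed"],
        )


def default_truth(region_length: int = 4_000_000, seed: int = 0) -> SimulationTruth:
    """A strong near-cis profile: B=5, I=500, lam=50 kb, three peaks.

    The viewpoint sits at the region centre; peaks are placed at
    enhancer-like distances (+32 kb, mirroring a known distal bone enhancer,
    -150 kb and +600 kb) with amplitudes 150/100/50 and shared width 3 kb.
    """
    xv = region_length / 2.0
    return SimulationTruth(
        decay=DecayParams(B=5.0, I=500.0, lam=50_000.0),
        peaks=[(xv + 32_000.0, 150.0), (xv - 150_000.0, 100.0), (xv + 600_000.0, 50.0)],
        sigma=3_000.0,
        depth=1_000_000.0,
        seed=seed,
    )


def simulate_genome(length: int, gc: float = 0.41, seed: int = 0) -> str:
    """An i.i.d. random DNA string with P(G) + P(C) = ``gc``."""
    if length < 1:
        raise ValidationError("genome length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValidationError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(bases, size=length, p=p).tobytes().decode("ascii")


def expected_signal(
    fmap: FragmentMap, viewpoint: float, truth: SimulationTruth,
    window: float = NEAR_CIS_WINDOW,
) -> np.ndarray:
    """Per-fragment expected counts mu_j = c * S(x_j).

    The model is evaluated at fragment midpoints and globally scaled by c
    so that the expected total within ±``window`` of the viewpoint equals
    ``truth.depth``.  If the model is identically zero the expectation is
    all zeros (no scaling is possible or needed).
    """
    mids = fmap.midpoints
    s = evaluate_model(truth.decay, truth.peaks, truth.sigma, viewpoint, mids)
    in_window = np.abs(mids - viewpoint) <= window
    total = s[in_window].sum()
    if total <= 0:
        if np.any(s > 0):
            raise ValidationError("no expected signal within the depth window")
        return np.zeros_like(s)
    return s * (truth.depth / total)


def simulate_profile(
    fmap: FragmentMap,
    viewpoint: float,
    truth: SimulationTruth,
    noise_free: bool = False,
    dispersion: float | None = None,
    window: float = NEAR_CIS_WINDOW,
) -> Profile:
    """Draw a per-fragment count profile from the three-component model.

    Counts are independent Poisson(mu_j) draws (``noise_free=True`` returns
    the expectations exactly; ``dispersion`` switches to a gamma-Poisson
    i.e. negative-binomial scheme with Var = mu + dispersion * mu^2).
    Deterministic given ``truth.seed``.
    """
    if not (fmap.region.start <= viewpoint <= fmap.region.end):
        raise ValidationError("viewpoint must lie inside the fragment map region")
    for c, _ in truth.peaks:
        if not (fmap.region.start <= c <= fmap.region.end):
            raise ValidationError(f"peak center {c} lies outside the simulated region")
    mu = expected_signal(fmap, viewpoint, truth, window=window)
    if noise_free:
        counts = mu
    else:
        rng = np.random.default_rng(truth.seed)
        if dispersion is None:
            counts = rng.poisson(mu).astype(float)
        else:
            if dispersion <= 0:
                raise ValidationError("dispersion must be positive")
            shape = 1.0 / dispersion
            lam = rng.gamma(shape, scale=np.maximum(mu, 0) * dispersion)
            counts = rng.poisson(lam).astype(float)
    return Profile(fmap.chrom, float(viewpoint), fmap.starts, fmap.ends, counts, stage="raw")


REPORTER_CONSTRUCTS = ("empty", "major_allele", "minor_allele", "positive_control")


def simulate_reporter_assay(
    effect_ratio: float = 0.75,
    cv: float = 0.10,
    n_experiments: int = 4,
    n_replicates: int = 3,
    baseline_fold: float = 20.0,
    control_fold: float = 31.6,
    seed: int = 0,
    renilla_level: float = 100_000.0,
) -> pd.DataFrame:
    """Simulated dual-luciferase replicate table.

    One firefly/renilla pair per well for the four constructs (empty
    vector, major allele, minor allele, positive control) across
    ``n_experiments`` independent experiments of ``n_replicates`` wells.
    Expected RLU (firefly/renilla, normalised to the empty vector) is 1,
    ``baseline_fold``, ``baseline_fold * effect_ratio`` and
    ``control_fold`` respectively.  Noise is multiplicative log-normal with
    coefficient of variation ``cv`` on both channels, mean-corrected so
    the RLU expectation is exact.  Deterministic given ``seed``.
    """
    if effect_ratio <= 0:
        raise ValidationError("effect_ratio must be positive")
    if cv < 0:
        raise ValidationError("cv must be non-negative")
    if n_replicates < 1 or n_experiments < 1:
        raise ValidationError("need at least one experiment and one replicate")

    folds = {
        "empty": 1.0,
        "major_allele": baseline_fold,
        "minor_allele": baseline_fold * effect_ratio,
        "positive_control": control_fold,
    }
    sigma = np.sqrt(np.log1p(cv**2))
    rng = np.random.default_rng(seed)
    rows = []
    for construct in REPORTER_CONSTRUCTS:
        for exp in range(1, n_experiments + 1):
            for rep in range(1, n_replicates + 1):
                noise_r = np.exp(sigma * rng.standard_normal() - sigma**2 / 2)
                noise_f = np.exp(sigma * rng.standard_normal() - sigma**2 / 2)
                renilla = renilla_level * noise_r
                firefly = renilla * folds[construct] * noise_f
                rows.append((construct, exp, rep, firefly, renilla))
    return pd.DataFrame(rows, columns=["construct", "experiment", "replicate", "firefly", "renilla"])
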