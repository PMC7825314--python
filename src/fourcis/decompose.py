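"""Three-component decomposition of a near-cis 4C profile and peak calling.

The signal at genomic coordinate ``x``, relative to a viewpoint at ``xv``,
is modelled as the sum of three independent contributions: a constant
background ``B``, a negative exponential ``I * exp(-|x - xv| / lam)``
describing the monotonic decay of contact frequency with genomic distance,
and ``N`` Gaussians of shared width ``sigma`` representing specific
interaction peaks::

    S(x) = B + I * exp(-|x - xv| / lam)
             + sum_i P_i * exp(-(x - x_i)^2 / (2 * sigma^2))

Fitting proceeds in stages: (1) the decay (B, I, lam) is estimated by
weighted nonlinear least squares on the left-right averaged profile;
(2) a robust per-distance-band noise scale is estimated from the decay
residuals (median absolute deviation, scaled for normal consistency);
(3) candidate peaks are local maxima of the smoothed residual z-score;
(4) candidates are added greedily, each addition followed by a joint
refit of all parameters over the full (unbinned) profile; a candidate is
retained only while its Wald amplitude test stays below the significance
threshold (p < 5e-4 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .errors import FitError, ValidationError
from .preprocess import SymmetrizedProfile, running_mean
from .profile import Profile

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class DecayParams:
    """Background level B, viewpoint intensity I and decay length lam (bp)."""

    B: float
    I: float
    lam: float

    def __post_init__(self):
        if self.B < 0 or self.I < 0:
            raise ValidationError("background and intensity must be non-negative")
        if self.lam <= 0:
            raise ValidationError("decay length must be positive")

    def __call__(self, x, xv: float) -> np.ndarray:
        return self.B + self.I * np.exp(-np.abs(np.asarray(x, dtype=float) - xv) / self.lam)


@dataclass
class Peak:
    """A fitted interaction peak with its Wald amplitude test."""

    center: float
    amplitude: float
    z: float = np.nan
    p: float = np.nan
    significant: bool = False

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValidationError("peak amplitude must be non-negative")
        if np.isfinite(self.p) and not 0 <= self.p <= 1:
            raise ValidationError("peak p-value must lie in [0, 1]")


@dataclass
class NoiseBands:
    """Robust residual scales in log-spaced distance bands around xv."""

    edges: np.ndarray  # n_bands + 1 distance edges
    scales: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.float64)
        self.scales = np.asarray(self.scales, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def degenerate(self) -> bool:
        return bool(np.all(self.scales == 0))

    def scale_at(self, d) -> np.ndarray:
        """Noise scale for distance(s) ``d`` (nearest band outside the range)."""
        idx = np.clip(np.searchsorted(self.edges, d, side="right") - 1, 0, self.scales.size - 1)
        return self.scales[idx]


@dataclass
class ModelFit:
    """Fitted decomposition: decay, shared-width peaks and diagnostics."""

    decay: DecayParams
    peaks: list[Peak]
    sigma: float
    xv: float
    chrom: str = "."
    noise_bands: NoiseBands | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.peaks and self.sigma <= 0:
            raise ValidationError("sigma must be positive when peaks are present")
        self.peaks = sorted(self.peaks, key=lambda p: p.center)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def significant_peaks(self) -> list[Peak]:
        return [p for p in self.peaks if p.significant]

    def predict(self, x) -> np.ndarray:
        return evaluate_model(self.decay, self.peaks, self.sigma, self.xv, x)

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "xv": self.xv,
            "decay": {"B": self.decay.B, "I": self.decay.I, "lam": self.decay.lam},
            "sigma": self.sigma,
            "peaks": [
                {
                    "center": p.center,
                    "amplitude": p.amplitude,
                    "z": None if not np.isfinite(p.z) else p.z,
                    "p": None if not np.isfinite(p.p) else p.p,
                    "significant": bool(p.significant),
                }
                for p in self.peaks
            ],
            "diagnostics": {
                k: v for k, v in self.diagnostics.items()
                if isinstance(v, (int, float, bool, str, list))
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        peaks = [
            Peak(
                center=p["center"],
                amplitude=p["amplitude"],
                z=np.nan if p.get("z") is None else p["z"],
                p=np.nan if p.get("p") is None else p["p"],
                significant=bool(p.get("significant", False)),
            )
            for p in d["peaks"]
        ]
        return cls(
            decay=DecayParams(**d["decay"]),
            peaks=peaks,
            sigma=d["sigma"],
            xv=d["xv"],
            chrom=d.get("chrom", "."),
            diagnostics=d.get("diagnostics", {}),
        )


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def _peak_arrays(peaks) -> tuple[np.ndarray, np.ndarray]:
    centers, amps = [], []
    for p in peaks:
        if isinstance(p, Peak):
            centers.append(p.center)
            amps.append(p.amplitude)
        else:  # (center, amplitude) pair
            centers.append(p[0])
            amps.append(p[1])
    return np.asarray(centers, dtype=float), np.asarray(amps, dtype=float)


def evaluate_model(decay: DecayParams, peaks, sigma: float, xv: float, x) -> np.ndarray:
    """Evaluate S(x) = B + I e^(-|x-xv|/lam) + sum_i P_i e^(-(x-x_i)^2/(2 sigma^2))."""
    x = np.asarray(x, dtype=float)
    s = decay(x, xv)
    centers, amps = _peak_arrays(peaks)
    if centers.size:
        if sigma <= 0:
            raise ValidationError("sigma must be positive when peaks are present")
        for c, a in zip(centers, amps):
            s = s + a * np.exp(-((x - c) ** 2) / (2.0 * sigma**2))
    return s


# ---------------------------------------------------------------------------
# Decay fit on the symmetrized profile
# ---------------------------------------------------------------------------

def fit_decay(
    sym: SymmetrizedProfile,
    max_nfev: int = 500,
    tol: float = 1e-10,
) -> tuple[DecayParams, np.ndarray]:
    """Weighted NLS fit of (B, I, lam) to the left-right averaged profile.

    Minimises ``sum_b w_b (m_b - B - I exp(-d_b/lam))^2`` with non-negative
    B, I and positive lam, via a trust-region reflective solver.
    Initialisation: B0 from the median of far bins (d beyond half the
    span), I0 from the profile maximum above B0, lam0 from the first bin
    dropping below B0 + I0/e (fallback 50 kb).  Returns the parameters and
    the 3x3 covariance from the Jacobian at the optimum.
    """
    if len(sym) < 5:
        raise ValidationError(f"decay fit requires >= 5 bins, got {len(sym)}")
    d, m, w = sym.d, sym.m, sym.w
    sw = np.sqrt(w)

    far = m[d > d.max() / 2.0]
    B0 = float(np.median(far)) if far.size else float(np.median(m))
    B0 = max(B0, 0.0)
    I0 = max(float(m.max()) - B0, np.finfo(float).eps)
    below = d[m <= B0 + I0 / np.e]
    lam0 = float(below.min()) if below.size else 50_000.0
    lam0 = max(lam0, 1.0)

    def resid(theta):
        B, I, lam = theta
        return sw * (m - B - I * np.exp(-d / lam))

    res = optimize.least_squares(
        resid,
        x0=[B0, I0, lam0],
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        method="trf",
        x_scale="jac",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_nfev,
    )
    if not res.success:
        raise FitError(
            f"decay fit did not converge: {res.message}",
            diagnostics={"status": res.status, "nfev": res.nfev, "cost": res.cost},
        )
    B, I, lam = res.x
    if I <= 1e-9 * max(B, 1.0):
        warnings.warn(
            "decay fit is degenerate (flat profile): intensity ~ 0, "
            "decay length unidentified",
            stacklevel=2,
        )
    dof = max(len(sym) - 3, 1)
    s2 = 2.0 * res.cost / dof
    cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
    return DecayParams(float(B), float(I), float(lam)), cov


# ---------------------------------------------------------------------------
# Noise estimation
# ---------------------------------------------------------------------------

def _mad_scale(r: np.ndarray) -> float:
    # 1.4826 * MAD is a consistent estimator of the normal standard deviation
    return float(1.4826 * np.median(np.abs(r - np.median(r))))


def estimate_noise(
    profile: Profile,
    decay: DecayParams,
    n_bands: int = 4,
    min_per_band: int = 20,
) -> NoiseBands:
    """Robust residual scale in log-spaced distance bands around the viewpoint.

    Residuals are taken against the decay-only model; each band's scale is
    1.4826 x the median absolute deviation (robust to the very interaction
    peaks still present in the residuals).  Bands with fewer than
    ``min_per_band`` fragments are merged with a neighbour.
    """
    if len(profile) < min_per_band:
        raise ValidationError(
            f"noise estimation requires >= {min_per_band} fragments, got {len(profile)}"
        )
    d = profile.distances
    r = profile.counts - decay(profile.midpoints, profile.xv)

    lo = max(float(d.min()), 1.0)
    hi = float(d.max())
    if hi <= lo:
        edges = [float(d.min()), hi + 1.0]
    else:
        edges = list(np.geomspace(lo, hi, n_bands + 1))
        edges[0] = min(edges[0], float(d.min()))
        edges[-1] = np.nextafter(hi, np.inf)

    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1).tolist()

    # merge undersized bands into their smaller neighbour
    while len(counts) > 1 and min(counts) < min_per_band:
        i = int(np.argmin(counts))
        if i == 0:
            j = 1
        elif i == len(counts) - 1:
            j = i - 1
        else:
            j = i - 1 if counts[i - 1] <= counts[i + 1] else i + 1
        lo_i, hi_i = min(i, j), max(i, j)
        counts[lo_i] += counts[hi_i]
        del counts[hi_i]
        del edges[hi_i]

    edges_arr = np.asarray(edges)
    idx = np.clip(np.searchsorted(edges_arr, d, side="right") - 1, 0, len(counts) - 1)
    scales = np.array([_mad_scale(r[idx == b]) for b in range(len(counts))])
    nb = NoiseBands(edges_arr, scales, np.asarray(counts))
    if nb.degenerate:
        warnings.warn("all noise bands have zero scale (degenerate residuals)", stacklevel=2)
    return nb


# ---------------------------------------------------------------------------
# Candidate detection
# ---------------------------------------------------------------------------

def detect_candidates(
    profile: Profile,
    decay: DecayParams,
    noise_bands: NoiseBands,
    z_min: float = 3.0,
    smooth_k: int = 5,
    sigma_init: float = 3_000.0,
) -> np.ndarray:
    """Candidate peak centers: local maxima of the smoothed residual z-score.

    z_j = residual_j / band-scale(d_j); a centred running mean over
    ``smooth_k`` fragments suppresses single-fragment spikes.  Local maxima
    with smoothed z >= ``z_min`` are accepted greedily in descending order,
    enforcing a separation of at least 2 * ``sigma_init``.  Returns centers
    ordered by descending smoothed z.
    """
    if len(profile) == 0:
        return np.empty(0)
    x = profile.midpoints
    r = profile.counts - decay(x, profile.xv)
    scale = noise_bands.scale_at(profile.distances)
    positive = noise_bands.scales[noise_bands.scales > 0]
    floor = positive.min() if positive.size else max(float(np.abs(r).max()), 1.0) * 1e-12
    scale = np.where(scale > 0, scale, floor)
    z = r / scale
    sz = running_mean(z, smooth_k)

    n = sz.size
    if n == 1:
        is_max = np.array([True])
    else:
        is_max = np.ones(n, dtype=bool)
        is_max[1:] &= sz[1:] >= sz[:-1]
        is_max[:-1] &= sz[:-1] >= sz[1:]
    cand = np.flatnonzero(is_max & (sz >= z_min))
    if cand.size == 0:
        return np.empty(0)

    order = cand[np.argsort(sz[cand])[::-1]]
    accepted: list[float] = []
    for i in order:
        xi = float(x[i])
        if all(abs(xi - a) >= 2.0 * sigma_init for a in accepted):
            accepted.append(xi)
    return np.asarray(accepted)


# ---------------------------------------------------------------------------
# Joint peak fitting
# ---------------------------------------------------------------------------

def peak_pvalue(amplitude: float, se: float) -> float:
    """One-sided upper-tail Wald p-value for a fitted peak amplitude.

    p = 1 - Phi(P / SE) with the amplitude standard error taken from the
    joint nonlinear-least-squares covariance.
    """
    if se <= 0 or not np.isfinite(se):
        raise ValidationError(f"amplitude standard error must be positive, got {se}")
    return float(norm.sf(amplitude / se))


def _pack(B, I, lam, sigma, amps, centers):
    return np.concatenate(([B, I, lam, sigma], amps, centers))


def _unpack(theta, k):
    return theta[0], theta[1], theta[2], theta[3], theta[4 : 4 + k], theta[4 + k : 4 + 2 * k]


def _joint_residual(theta, x, y, xv, k):
    B, I, lam, sigma, amps, centers = _unpack(theta, k)
    s = B + I * np.exp(-np.abs(x - xv) / lam)
    for a, c in zip(amps, centers):
        s = s + a * np.exp(-((x - c) ** 2) / (2.0 * sigma**2))
    return y - s


def _joint_fit(x, y, xv, theta0, lower, upper, max_nfev):
    return optimize.least_squares(
        _joint_residual,
        x0=theta0,
        args=(x, y, xv, (theta0.size - 4) // 2),
        bounds=(lower, upper),
        method="trf",
        x_scale="jac",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )


def _wald(res, n, k):
    """Amplitude SEs (and full covariance) from the NLS Jacobian."""
    p = res.x.size
    dof = max(n - p, 1)
    s2 = max(2.0 * res.cost / dof, _TINY)
    cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
    se = np.sqrt(np.maximum(np.diag(cov)[4 : 4 + k], 0.0))
    return se, cov


def fit_peaks(
    profile: Profile,
    decay: DecayParams,
    candidates,
    sigma_init: float = 3_000.0,
    alpha: float = 0.0005,
    noise_bands: NoiseBands | None = None,
    chrom: str | None = None,
    max_nfev: int = 4_000,
) -> ModelFit:
    """Greedy forward selection of Gaussian peaks with full joint refits.

    Candidates are added in the order supplied (descending detection
    z-score).  After each addition all parameters — (B, I, lam), the shared
    width sigma, and every (P_i, x_i) — are refit jointly over the full
    unbinned profile, with P_i >= 0, x_i within ±3 sigma_init of its
    candidate and sigma in [min fragment spacing, 10 sigma_init].
    Selection stops at the first candidate whose Wald amplitude p-value
    fails ``alpha``; that candidate is dropped.  A solver failure on a
    candidate skips it with a warning.
    """
    x = profile.midpoints.astype(float)
    y = profile.counts.astype(float)
    xv = float(profile.xv)
    n = x.size
    candidates = np.atleast_1d(np.asarray(candidates, dtype=float))
    chrom = chrom or profile.chrom

    min_spacing = float(np.diff(x).min()) if n > 1 else 1.0
    sigma_lo = max(min_spacing, 1e-6)
    sigma_hi = 10.0 * sigma_init

    cur = {
        "B": decay.B,
        "I": decay.I,
        "lam": decay.lam,
        "sigma": float(np.clip(sigma_init, sigma_lo, sigma_hi)),
        "amps": np.empty(0),
        "centers": np.empty(0),
        "anchors": np.empty(0),
    }

    def rmse_of(theta, k):
        r = _joint_residual(theta, x, y, xv, k)
        return float(np.sqrt(np.mean(r**2)))

    theta_decay = _pack(cur["B"], cur["I"], cur["lam"], cur["sigma"], [], [])
    rmse_path = [rmse_of(theta_decay, 0)]
    total_nfev = 0
    last_res = None

    for cand in candidates:
        model_now = evaluate_model(
            DecayParams(cur["B"], cur["I"], cur["lam"]),
            list(zip(cur["centers"], cur["amps"])),
            cur["sigma"] if cur["amps"].size else sigma_init,
            xv,
            x,
        )
        j = int(np.argmin(np.abs(x - cand)))
        p0 = max(float(y[j] - model_now[j]), 1e-6)

        amps0 = np.append(cur["amps"], p0)
        centers0 = np.append(cur["centers"], cand)
        anchors0 = np.append(cur["anchors"], cand)
        k = amps0.size
        theta0 = _pack(cur["B"], cur["I"], cur["lam"], cur["sigma"], amps0, centers0)
        lower = np.concatenate(
            ([0.0, 0.0, 1e-9, sigma_lo], np.zeros(k), anchors0 - 3.0 * sigma_init)
        )
        upper = np.concatenate(
            ([np.inf, np.inf, np.inf, sigma_hi], np.full(k, np.inf), anchors0 + 3.0 * sigma_init)
        )
        theta0 = np.clip(theta0, lower, upper)

        try:
            res = _joint_fit(x, y, xv, theta0, lower, upper, max_nfev)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"joint fit raised for candidate at {cand:.0f}: {exc}", stacklevel=2)
            continue
        total_nfev += res.nfev
        if not res.success:
            warnings.warn(
                f"joint fit did not converge for candidate at {cand:.0f}; skipped",
                stacklevel=2,
            )
            continue

        se, _ = _wald(res, n, k)
        amp_new = res.x[4 + k - 1]
        se_new = se[-1]
        p_new = peak_pvalue(amp_new, se_new) if se_new > 0 else 0.0
        if not p_new < alpha:
            break  # newest peak not supported: drop it and stop

        B, I, lam, sigma, amps, centers = _unpack(res.x, k)
        cur.update(
            B=float(B), I=float(I), lam=float(lam), sigma=float(sigma),
            amps=amps.copy(), centers=centers.copy(), anchors=anchors0,
        )
        last_res = res
        rmse_path.append(rmse_of(res.x, k))

    k = cur["amps"].size
    peaks: list[Peak] = []
    if k and last_res is not None:
        se, _ = _wald(last_res, n, k)
        for a, c, s in zip(cur["amps"], cur["centers"], se):
            if s > 0:
                pz = a / s
                pv = peak_pvalue(a, s)
            else:  # exactly-zero residuals: amplitude formally certain
                pz, pv = np.inf, 0.0
            peaks.append(Peak(center=float(c), amplitude=float(a), z=float(pz), p=float(pv)))

    final_theta = _pack(cur["B"], cur["I"], cur["lam"], cur["sigma"], cur["amps"], cur["centers"])
    diagnostics = {
        "rmse": rmse_of(final_theta, k),
        "rmse_path": rmse_path,
        "nfev": total_nfev,
        "converged": True,
        "n_candidates": int(candidates.size),
    }
    return ModelFit(
        decay=DecayParams(cur["B"], cur["I"], cur["lam"]),
        peaks=peaks,
        sigma=cur["sigma"],
        xv=xv,
        chrom=chrom,
        noise_bands=noise_bands,
        diagnostics=diagnostics,
    )


def call_significant(fit: ModelFit, alpha: float = 0.0005, fdr: str | None = None) -> ModelFit:
    """Flag peaks with p strictly below ``alpha``; all peaks are retained.

    The default compares raw p-values against the threshold (a single raw
    cutoff, no multiplicity correction).  ``fdr='bh'`` instead applies the
    threshold to Benjamini-Hochberg adjusted p-values.
    """
    pvals = np.array([p.p for p in fit.peaks], dtype=float)
    if fdr is None:
        adjusted = pvals
    elif fdr == "bh":
        from scipy.stats import false_discovery_control

        adjusted = false_discovery_control(np.clip(pvals, 0.0, 1.0)) if pvals.size else pvals
    else:
        raise ValidationError(f"unknown fdr method {fdr!r}")
    peaks = [replace(p, significant=bool(q < alpha)) for p, q in zip(fit.peaks, adjusted)]
    return replace(fit, peaks=peaks, diagnostics={**fit.diagnostics, "alpha": alpha})
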