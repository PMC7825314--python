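"""Scikit-learn-style estimator running the full peak-calling pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .decompose import (
    ModelFit,
    call_significant,
    detect_candidates,
    estimate_noise,
    fit_decay,
    fit_peaks,
)
from .fragments import FragmentMap
from .preprocess import filter_fragments, normalize, symmetrize
from .profile import Profile


class FourCPeakCaller(BaseEstimator):
    """Fit the background + decay + Gaussian-peaks model to a raw 4C profile.

    The estimator chains fragment filtering, near-cis normalization,
    left-right symmetrized decay fitting, robust noise estimation,
    candidate detection and greedy joint peak fitting, then flags peaks
    significant at ``alpha`` (one-sided Wald test on the amplitude).

    Parameters
    ----------
    min_fragment_len : minimum fragment length kept, bp (strict: equal kept).
    viewpoint_window : total width of the viewpoint exclusion window, bp.
    norm_window : half-width of the normalization window around xv, bp.
    scale : post-normalization in-window total (reads-per-million-like).
    bin_width : distance bin width for the symmetrized decay fit, bp.
    n_noise_bands : number of log-spaced distance bands for noise scales.
    z_min : smoothed residual z-score threshold for candidate peaks.
    smooth_k : running-mean width (fragments) for candidate detection.
    sigma_init : initial shared Gaussian width, bp.
    alpha : peak significance threshold (strict p < alpha).

    Attributes (after ``fit``)
    --------------------------
    model_fit_ : the full :class:`ModelFit` (decay, peaks, diagnostics).
    decay_, sigma_, peaks_ : convenience views of the fitted parameters.
    profile_ : the filtered, normalized profile the model was fit to.
    """

    def __init__(
        self,
        min_fragment_len: int = 40,
        viewpoint_window: float = 10_000,
        norm_window: float = 2_000_000,
        scale: float = 1_000_000,
        bin_width: float = 2_000,
        n_noise_bands: int = 4,
        z_min: float = 3.0,
        smooth_k: int = 5,
        sigma_init: float = 3_000.0,
        alpha: float = 0.0005,
    ):
        self.min_fragment_len = min_fragment_len
        self.viewpoint_window = viewpoint_window
        self.norm_window = norm_window
        self.scale = scale
        self.bin_width = bin_width
        self.n_noise_bands = n_noise_bands
        self.z_min = z_min
        self.smooth_k = smooth_k
        self.sigma_init = sigma_init
        self.alpha = alpha

    def fit(self, profile: Profile, fragment_map: FragmentMap) -> "FourCPeakCaller":
        if not isinstance(profile, Profile):
            raise TypeError("fit expects a Profile")
        if not isinstance(fragment_map, FragmentMap):
            raise TypeError("fit expects a FragmentMap")

        prof = profile
        if prof.stage == "raw":
            prof = filter_fragments(
                prof, fragment_map,
                min_len=self.min_fragment_len,
                viewpoint_window=self.viewpoint_window,
            )
        if prof.stage == "filtered":
            prof = normalize(prof, window=self.norm_window, scale=self.scale)

        sym = symmetrize(prof, bin_width=self.bin_width)
        decay0, decay_cov = fit_decay(sym)
        bands = estimate_noise(prof, decay0, n_bands=self.n_noise_bands)
        candidates = detect_candidates(
            prof, decay0, bands,
            z_min=self.z_min, smooth_k=self.smooth_k, sigma_init=self.sigma_init,
        )
        fit = fit_peaks(
            prof, decay0, candidates,
            sigma_init=self.sigma_init, alpha=self.alpha, noise_bands=bands,
        )
        fit = call_significant(fit, alpha=self.alpha)

        self.profile_ = prof
        self.symmetrized_ = sym
        self.decay_cov_ = decay_cov
        self.candidates_ = candidates
        self.model_fit_ = fit
        self.decay_ = fit.decay
        self.sigma_ = fit.sigma
        self.peaks_ = fit.peaks
        return self

    def predict(self, x) -> np.ndarray:
        """Model signal at genomic coordinates ``x``."""
        if not hasattr(self, "model_fit_"):
            raise NotFittedError("FourCPeakCaller is not fitted yet; call fit first")
        return self.model_fit_.predict(np.asarray(x, dtype=float))


def call_peaks(profile: Profile, fragment_map: FragmentMap, **params) -> ModelFit:
    """Functional wrapper: run :class:`FourCPeakCaller` and return the fit."""
    return FourCPeakCaller(**params).fit(profile, fragment_map).model_fit_
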