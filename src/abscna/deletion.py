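"""Deletion typing: noise-model estimation, the Y summary statistic, and
Bayesian homo- vs hemi-deletion classification.

Model. At a heterozygous locus both alleles carry additive Gaussian noise
with variance sigma^2 and inter-allele correlation rho, so the allele
difference D_i = X_A,i - X_B,i has variance sigma_d^2 = 2 sigma^2 (1 - rho).
Over a length-L deletion segment define

    Y = sqrt( sum_i D_i^2 / sigma_d^2 ).

Under a homo-deletion both alleles are lost in the tumor, D_i is pure noise,
and Y follows a central chi distribution with L degrees of freedom. Under a
hemi-deletion exactly one allele is lost, |E[D_i]| = 1 - alpha (in
absolutely normalized units, with alpha the normal-cell fraction), and Y
follows a noncentral chi distribution with L degrees of freedom and
noncentrality

    lambda = sqrt(L) (1 - alpha) / sigma_d.

The call is the posterior argmax under configurable priors. Accuracy hinges
on sigma_d: estimating rho over loci contaminated by allelic imbalance or
copy-neutral LOH drives it spuriously negative, inflates sigma_d, shrinks Y,
and flips hemi calls to homo — which is why the noise model is estimated
only on balanced, normal-copy loci.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import AllelicTrack, DeletionCall, NoiseModel, Segment
from .errors import InsufficientDataError, NotADeletionError, ParameterError

__all__ = [
    "estimate_noise_model",
    "y_statistic",
    "deletion_likelihoods",
    "classify_deletion",
]

DEFAULT_CN_WINDOW = (1.8, 2.2)
DELETION_THRESHOLD = 1.8


def estimate_noise_model(
    track: AllelicTrack,
    mask: Optional[np.ndarray],
    segments: Sequence[Segment],
    cn_window: tuple[float, float] = DEFAULT_CN_WINDOW,
    min_loci: int = 100,
) -> NoiseModel:
    """Estimate (sigma^2, rho, sigma_d^2) from balanced normal-copy loci.

    Qualifying loci are heterozygous, masked-in (``mask=None`` accepts all —
    the legacy behaviour), and lie in segments whose normalized mean total is
    inside ``cn_window``. rho is the Pearson correlation of the (A, B)
    signals over those loci; sigma^2 the mean of the two allele sample
    variances.
    """
    lo, hi = cn_window
    select = np.zeros(len(track), dtype=bool)
    for seg in segments:
        if lo <= seg.mean_total <= hi:
            select[seg.indices] = True
    select &= track.het
    if mask is not None:
        select &= np.asarray(mask, dtype=bool)
    n = int(select.sum())
    if n < min_loci:
        raise InsufficientDataError(
            f"only {n} balanced normal-copy loci (< {min_loci}); widen the "
            "copy-number window or supply rho manually"
        )
    a = track.a_signal[select]
    b = track.b_signal[select]
    rho = float(np.corrcoef(a, b)[0, 1])
    sigma2 = float(0.5 * (a.var(ddof=1) + b.var(ddof=1)))
    return NoiseModel(sigma2=sigma2, rho=rho, n_loci=n)


def y_statistic(a_signal: np.ndarray, b_signal: np.ndarray,
                noise: NoiseModel, min_loci: int = 10) -> tuple[float, int]:
    """Y = sqrt(sum (X_A - X_B)^2 / sigma_d^2) over the given loci."""
    if noise.sigma_d2 <= 0:
        raise ParameterError("sigma_d^2 must be positive")
    a = np.asarray(a_signal, dtype=float)
    b = np.asarray(b_signal, dtype=float)
    L = len(a)
    if L < min_loci:
        raise InsufficientDataError(f"need >= {min_loci} het loci, got {L}")
    Y = float(np.sqrt(np.sum((a - b) ** 2) / noise.sigma_d2))
    return Y, L


def _log_chi_pdf(y: float, L: int) -> float:
    return float(stats.chi.logpdf(y, df=L))


def _log_noncentral_chi_pdf(y: float, L: int, lam: float) -> float:
    """Density of Y = sqrt(Q), Q ~ noncentral chi-square(L, lam^2):
    f_Y(y) = 2 y f_Q(y^2)."""
    if y <= 0:
        return -np.inf
    if lam <= 0:
        return _log_chi_pdf(y, L)
    return float(np.log(2.0 * y) + stats.ncx2.logpdf(y * y, df=L, nc=lam * lam))


def deletion_likelihoods(Y: float, L: int, lam: float) -> tuple[float, float]:
    """(central, noncentral) chi density values at Y.

    The central chi(L) density is the homo-deletion model; the noncentral
    chi(L, lambda) density is the hemi-deletion model. At lambda = 0 the two
    coincide. Both vanish for invalid (negative) Y.
    """
    if L < 1:
        raise ParameterError("L must be >= 1")
    if lam < 0:
        raise ParameterError("lambda must be >= 0")
    if Y < 0:
        return 0.0, 0.0
    f_homo = float(np.exp(_log_chi_pdf(Y, L))) if Y > 0 else (
        float(stats.chi.pdf(Y, df=L))
    )
    f_hemi = float(np.exp(_log_noncentral_chi_pdf(Y, L, lam)))
    return f_homo, f_hemi


def classify_deletion(
    track: AllelicTrack,
    segment: Segment,
    noise: NoiseModel,
    priors: tuple[float, float] = (0.5, 0.5),
    deletion_threshold: float = DELETION_THRESHOLD,
) -> DeletionCall:
    """Bayesian homo-vs-hemi call for one candidate deletion segment.

    The hemi-candidate normal fraction is the segment's own
    ``mean_total - 1`` (clamped to [0, 1)); the global alpha is unknown at
    this stage. ``priors`` are (P(homo), P(hemi)).
    """
    if not segment.mean_total < deletion_threshold:
        raise NotADeletionError(
            f"segment mean {segment.mean_total:.3f} is not below the deletion "
            f"threshold {deletion_threshold}"
        )
    p_homo, p_hemi = priors
    if p_homo < 0 or p_hemi < 0 or p_homo + p_hemi <= 0:
        raise ParameterError("priors must be non-negative and not both zero")
    sl = segment.indices
    het = track.het[sl]
    Y, L = y_statistic(track.a_signal[sl][het], track.b_signal[sl][het], noise)
    alpha_cand = float(np.clip(segment.mean_total - 1.0, 0.0, 1.0 - 1e-9))
    lam = float(np.sqrt(L) * (1.0 - alpha_cand) / noise.sigma_d)
    if Y <= 0 or not np.isfinite(_log_chi_pdf(Y, L)):
        # y -> 0+ limit: both densities ~ y^(L-1), ratio hemi/homo -> exp(-lam^2/2)
        log_ratio = -0.5 * lam * lam
        llr = log_ratio + np.log(max(p_hemi, 1e-300)) - np.log(max(p_homo, 1e-300))
        posterior_homo = float(1.0 / (1.0 + np.exp(llr)))
    else:
        log_post_homo = (
            np.log(p_homo) + _log_chi_pdf(Y, L) if p_homo > 0 else -np.inf
        )
        log_post_hemi = (
            np.log(p_hemi) + _log_noncentral_chi_pdf(Y, L, lam)
            if p_hemi > 0 else -np.inf
        )
        m = max(log_post_homo, log_post_hemi)
        w_homo = np.exp(log_post_homo - m)
        w_hemi = np.exp(log_post_hemi - m)
        posterior_homo = float(w_homo / (w_homo + w_hemi))
    return DeletionCall(
        type="homo" if posterior_homo >= 0.5 else "hemi",
        Y=Y, L=L, lam=lam, posterior_homo=posterior_homo,
    )
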