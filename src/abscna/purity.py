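"""Normal-cell fraction (tumor purity), tumor-specific profile recovery and
average ploidy.

With absolutely normalized signals the two-population mixture gives, for a
deletion segment, E[X] = 2 alpha under homo-deletion and E[X] = 1 + alpha
under hemi-deletion, so each called segment yields its own alpha estimate.
Intratumor heterogeneity can only inflate a segment's estimate (a subclonal
deletion leaves part of the tumor diploid, raising the segment mean), so the
genome-wide aggregate uses a low percentile — the 9th — of the per-segment
distribution rather than its mean.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import NoDeletionsError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "segment_alpha",
    "aggregate_alpha",
    "recover_tumor_profile",
    "average_ploidy",
]

ALPHA_PERCENTILE = 9.0


def _censored_mean(mu: float, sigma: float) -> float:
    """Mean of max(N(mu, sigma^2), 0): mu*Phi(mu/sigma) + sigma*phi(mu/sigma)."""
    z = mu / sigma
    return mu * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def _invert_censored_mean(target: float, sigma: float) -> float:
    """Latent mean whose zero-censored expectation equals ``target``
    (0 when the target is at/below the censoring floor sigma*phi(0))."""
    if target <= _censored_mean(0.0, sigma):
        return 0.0
    hi = target + 5.0 * sigma
    return float(optimize.brentq(
        lambda m: _censored_mean(m, sigma) - target, 0.0, hi, xtol=1e-10,
    ))


def segment_alpha(mean_total: float, call_type: str,
                  sigma: Optional[float] = None) -> float:
    """Per-segment normal-fraction estimate from the normalized mean.

    homo: alpha = mean/2; hemi: alpha = mean - 1; clamped to [0, 1]. A hemi
    segment at mean 2 clamps to 1.0 (non-informative) with a warning.

    When ``sigma`` (the per-allele noise sd) is given, the zero floor of the
    measurement is accounted for: a deleted allele's observed mean is the
    zero-censored Gaussian mean g(alpha) = alpha*Phi(alpha/sigma) +
    sigma*phi(alpha/sigma), which exceeds alpha when alpha is within a few
    sigma of zero. The estimate inverts g instead of the naive linear map
    (homo: 2 g(alpha) = mean; hemi: g(alpha) = mean - g(1)), removing the
    upward bias at low tumor-signal levels.
    """
    if call_type == "homo":
        if sigma is not None:
            alpha = _invert_censored_mean(mean_total / 2.0, sigma)
        else:
            alpha = mean_total / 2.0
    elif call_type == "hemi":
        if sigma is not None:
            alpha = _invert_censored_mean(
                mean_total - _censored_mean(1.0, sigma), sigma
            )
        else:
            alpha = mean_total - 1.0
    else:
        raise ParameterError(f"unknown call type '{call_type}'")
    if alpha < 0.0:
        logger.warning(
            "%s segment mean %.3f implies alpha < 0; clamped to 0",
            call_type, mean_total,
        )
        return 0.0
    if alpha >= 1.0:
        logger.warning(
            "%s segment mean %.3f implies alpha >= 1; clamped (non-informative)",
            call_type, mean_total,
        )
        return 1.0
    return float(alpha)


def aggregate_alpha(alphas: Sequence[float], percentile: float = ALPHA_PERCENTILE) -> float:
    """Genome-wide normal fraction: a low percentile of per-segment estimates.

    Uses linear interpolation between order statistics with inclusive
    endpoints (numpy's default quantile definition); every segment counts
    equally regardless of length. Raises :class:`NoDeletionsError` when no
    informative deletion segment exists.
    """
    alphas = np.asarray(list(alphas), dtype=float)
    if len(alphas) == 0:
        raise NoDeletionsError("no deletions found; purity not estimable")
    if not 0.0 <= percentile <= 100.0:
        raise ParameterError("percentile must lie in [0, 100]")
    return float(np.percentile(alphas, percentile))


def recover_tumor_profile(values: np.ndarray, alpha: float) -> np.ndarray:
    """Invert the normal/tumor mixture: X_tumor = (X - 2 alpha)/(1 - alpha).

    Applies elementwise to normalized totals (or segment means); values are
    clipped at zero. alpha >= 0.99 leaves the profile unidentifiable.
    """
    if not 0.0 <= alpha < 0.99:
        raise ParameterError(
            f"alpha must lie in [0, 0.99) for profile recovery, got {alpha}"
        )
    values = np.asarray(values, dtype=float)
    return np.clip((values - 2.0 * alpha) / (1.0 - alpha), 0.0, None)


def average_ploidy(tumor_means: Sequence[float], n_loci: Sequence[int]) -> float:
    """Locus-weighted mean tumor copy number over segments (not rounded —
    under subclonality the restored values need not be integers)."""
    tumor_means = np.asarray(list(tumor_means), dtype=float)
    weights = np.asarray(list(n_loci), dtype=float)
    if len(tumor_means) != len(weights):
        raise ParameterError("tumor_means and n_loci must have equal length")
    total = weights.sum()
    if total <= 0:
        raise ParameterError("zero total loci; ploidy undefined")
    return float(np.sum(weights * tumor_means) / total)
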