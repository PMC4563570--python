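"""Smoothing, sliding-window inter-allele correlation, and removal of
allelic-imbalanced / copy-neutral-LOH loci.

The detection signal: inside an allelic-imbalanced segment the identity of
the deviating allele alternates randomly across loci, so within a window the
A and B signals move in opposite directions and their Pearson correlation is
driven strongly negative, far below the small genuine noise correlation at
balanced loci. Thresholding the windowed correlation therefore separates
balanced loci (retained) from imbalanced / copy-neutral-LOH loci (removed)
before any baseline fitting or noise estimation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import AllelicTrack
from .errors import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "BalanceProfile",
    "moving_average_total",
    "sliding_allelic_correlation",
    "auto_balance_threshold",
    "balanced_mask",
    "correct_crosstalk",
]

#: Threshold returned when the correlation values show no imbalanced cluster
#: (or too few values to decide); retains everything except strong outliers.
FLOOR_THRESHOLD = -0.5


@dataclass
class BalanceProfile:
    """Windowed inter-allele correlation per locus with the derived mask.

    ``r`` is NaN where undefined (non-heterozygous loci and window-truncated
    chromosome edges); undefined loci are excluded from the mask.
    """

    r: np.ndarray
    threshold: Optional[float] = None
    mask: Optional[np.ndarray] = None

    def finalize(self, threshold: float) -> "BalanceProfile":
        self.threshold = float(threshold)
        self.mask = balanced_mask(self.r, threshold)
        return self


def moving_average_total(track: AllelicTrack, window: int = 51) -> np.ndarray:
    """Centered moving average of total signal, per chromosome.

    Edges use truncated windows, so the output is defined at every locus.
    ``window`` must be odd so the window is symmetric around the locus.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer, got {window}")
    totals = track.totals
    out = np.empty_like(totals)
    for _, sl in track.chromosomes():
        s = pd.Series(totals[sl])
        out[sl] = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return out


def sliding_allelic_correlation(track: AllelicTrack, window: int = 200) -> BalanceProfile:
    """Pearson correlation of (A, B) signals over a centered window of
    heterozygous loci, within one chromosome.

    Only heterozygous loci enter the windows and only they receive a value;
    everywhere else (and at edges where the full window does not fit) ``r``
    is NaN. A chromosome with fewer het loci than ``window`` gets no values
    and a warning.
    """
    if window < 10:
        raise ParameterError("correlation window must be >= 10 loci")
    n = len(track)
    r = np.full(n, np.nan)
    for chrom, sl in track.chromosomes():
        idx = np.flatnonzero(track.het[sl]) + sl.start
        if len(idx) < window:
            logger.warning(
                "chromosome %s: %d het loci < window %d; correlation undefined",
                chrom, len(idx), window,
            )
            continue
        a = pd.Series(track.a_signal[idx])
        b = pd.Series(track.b_signal[idx])
        rv = a.rolling(window, center=True, min_periods=window).corr(b)
        r[idx] = rv.to_numpy()
    return BalanceProfile(r=r)


def _two_means_1d(values: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Deterministic 1-D 2-means: centers start at the 10th/90th percentiles."""
    c_lo, c_hi = np.percentile(values, [10.0, 90.0])
    if c_lo == c_hi:
        return float(c_lo), float(c_hi)
    for _ in range(max_iter):
        mid = 0.5 * (c_lo + c_hi)
        lo = values[values <= mid]
        hi = values[values > mid]
        if len(lo) == 0 or len(hi) == 0:
            break
        new_lo, new_hi = lo.mean(), hi.mean()
        if abs(new_lo - c_lo) < 1e-12 and abs(new_hi - c_hi) < 1e-12:
            break
        c_lo, c_hi = new_lo, new_hi
    return float(c_lo), float(c_hi)


def auto_balance_threshold(r_values: np.ndarray, min_values: int = 100,
                           separation: float = 0.2, n_sd: float = 3.0) -> float:
    """Automatic threshold between imbalanced and balanced correlation values.

    Fits a two-cluster split (1-D 2-means) to the defined windowed
    correlations. The threshold is the midpoint of the cluster centers or,
    when higher, the balanced (upper) cluster's center minus ``n_sd`` robust
    standard deviations — a locus is removed when its correlation is
    inconsistent with the balanced population. The midpoint alone fails when
    the imbalance is weak (high normal fraction pushes the imbalanced
    cluster toward zero, past the midpoint). When the centers sit closer
    than ``separation`` (no imbalanced population present) — or with too few
    values to decide — the floor value −0.5 is returned, which retains all
    plausible loci.
    """
    r_values = np.asarray(r_values, dtype=float)
    r_values = r_values[np.isfinite(r_values)]
    if len(r_values) == 0:
        raise InsufficientDataError("no defined correlation values")
    if len(r_values) < min_values:
        logger.warning(
            "only %d correlation values (<%d); using floor threshold %.2f",
            len(r_values), min_values, FLOOR_THRESHOLD,
        )
        return FLOOR_THRESHOLD
    # Peel imbalanced clusters off from below until the remainder is
    # unimodal. A genuine imbalanced cluster comes from a genomic segment and
    # carries mass; thin continuum tails from windows straddling segment
    # borders must not trigger further peeling.
    vals = r_values
    threshold = None
    min_mass = max(int(0.05 * len(r_values)), min_values)
    for _ in range(10):
        c_lo, c_hi = _two_means_1d(vals)
        if c_hi - c_lo < separation:
            break
        if c_lo > -separation:
            # imbalance is a negative-correlation phenomenon; a lower
            # cluster near/above zero is not an imbalanced population
            break
        mid = 0.5 * (c_lo + c_hi)
        below = int(np.sum(vals <= mid))
        if below < min_mass or below == len(vals):
            break
        threshold = mid
        vals = vals[vals > mid]
    if threshold is None:
        return FLOOR_THRESHOLD
    # final guard: drop loci inconsistent with the balanced population
    s_hi = 1.4826 * np.median(np.abs(vals - np.median(vals)))
    return max(threshold, float(np.median(vals)) - n_sd * max(s_hi, 1e-3))


def balanced_mask(r_values: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask: True where the windowed correlation is defined and at or
    above the threshold (allelic-balanced, retained)."""
    r_values = np.asarray(r_values, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.isfinite(r_values) & (r_values >= threshold)


def correct_crosstalk(track: AllelicTrack, c: float,
                      M: Optional[float] = None) -> AllelicTrack:
    """Invert the saturation and linear-crosstalk distortions.

    Saturation ``s(x) = M(1 - exp(-x/M))`` is inverted exactly by
    ``x = -M ln(1 - s/M)`` (observed values at or above M are clipped just
    below it, with a warning); crosstalk ``a' = a + c b`` by solving the 2x2
    linear system. No blind estimation: ``c`` and ``M`` are inputs.
    """
    if c < 0 or c >= 1:
        raise ParameterError("crosstalk coefficient must lie in [0, 1)")
    if M is not None and M <= 0:
        raise ParameterError("saturation level must be positive")
    a, b = track.a_signal.copy(), track.b_signal.copy()
    if M is not None:
        cap = M * (1.0 - 1e-6)
        n_clip = int(np.sum((a >= M) | (b >= M)))
        if n_clip:
            logger.warning("%d signal(s) at/above saturation level; clipped", n_clip)
        a = -M * np.log1p(-np.minimum(a, cap) / M)
        b = -M * np.log1p(-np.minimum(b, cap) / M)
    if c > 0:
        det = 1.0 - c * c
        a, b = (a - c * b) / det, (b - c * a) / det
    return track.with_signals(np.clip(a, 0.0, None), np.clip(b, 0.0, None))
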