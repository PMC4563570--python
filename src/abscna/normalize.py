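"""Absolute normalization: Gaussian-mixture fit of balanced-locus totals,
baseline (copy-2) component selection, and rescaling of the allele signals.

Median- or mean-centering assumes the typical locus is diploid; in aneuploid
tumors it is not, and the dominant mixture component of the raw signal
histogram often sits at an aberrant copy state. Fitting the mixture only on
allelic-balanced loci (the "revised" histogram) restores the diploid peak as
the dominant component in most samples; the track is then rescaled so that
this baseline lands exactly at copy number 2. The scale is applied to the
allele signals, not just the totals, so that downstream allele-difference
statistics operate on absolutely normalized signals.

The expectation-maximization fit is implemented here directly (univariate,
with k-means++-style restarts, BIC model selection across K, degenerate
component pruning and a recorded per-iteration log-likelihood trace).
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .datamodel import AllelicTrack, MixtureModel, NormalizationReport
from .errors import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "fit_gaussian_mixture",
    "select_baseline",
    "absolute_normalize",
]

_MIN_VALUES = 50


def _kmeanspp_means(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding of component means."""
    means = [values[rng.integers(len(values))]]
    for _ in range(1, k):
        d2 = np.min((values[:, None] - np.asarray(means)) ** 2, axis=1)
        tot = d2.sum()
        if tot <= 0:
            means.append(values[rng.integers(len(values))])
            continue
        means.append(values[rng.choice(len(values), p=d2 / tot)])
    return np.asarray(means, dtype=float)


def _em_single(values: np.ndarray, means0: np.ndarray, tol: float,
               max_iter: int, var_floor: float) -> Optional[MixtureModel]:
    """One EM run from given initial means; prunes degenerate components."""
    n = len(values)
    k = len(means0)
    means = means0.copy()
    variances = np.full(k, values.var())
    weights = np.full(k, 1.0 / k)
    ll_trace: list[float] = []
    prev_ll = -np.inf
    it = 0
    while it < max_iter:
        it += 1
        # E-step in log space
        log_comp = (
            np.log(weights)
            - 0.5 * np.log(2 * np.pi * variances)
            - 0.5 * (values[:, None] - means) ** 2 / variances
        )
        m = log_comp.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        ll = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm[:, None])
        ll_trace.append(ll)
        # tol is a per-observation log-likelihood gain
        if ll - prev_ll < tol * n and it > 1:
            break
        prev_ll = ll
        # M-step
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * values[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        variances = (resp * (values[:, None] - means) ** 2).sum(axis=0) / np.maximum(
            nk, 1e-300
        )
        # prune collapsed components and continue with the survivors
        bad = (variances < var_floor) | (nk < 1.0)
        if bad.any():
            keep = ~bad
            if not keep.any():
                return None
            means, variances, weights = means[keep], variances[keep], weights[keep]
            variances = np.maximum(variances, var_floor)
            weights = weights / weights.sum()
            k = len(means)
            prev_ll = -np.inf
            continue
    weights = weights / weights.sum()
    return MixtureModel(
        weights=weights, means=means, variances=variances,
        log_likelihood=ll_trace[-1], n_iter=it, ll_trace=ll_trace,
    )


def fit_gaussian_mixture(
    values: np.ndarray,
    k_max: int = 6,
    n_starts: int = 3,
    tol: float = 1e-5,
    max_iter: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> MixtureModel:
    """Fit univariate Gaussian mixtures for K = 1..k_max and return the
    BIC-best model.

    Each K is fitted from ``n_starts`` k-means++-style initializations (the
    first start uses evenly spaced quantiles for reproducibility); EM stops
    when the mean per-observation log-likelihood gain drops below ``tol``.
    Components whose
    variance collapses below 1e-6 times the data variance are pruned and the
    fit continues with the survivors.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < _MIN_VALUES:
        raise InsufficientDataError(
            f"need >= {_MIN_VALUES} values to fit a mixture, got {len(values)}"
        )
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    data_var = values.var()
    if data_var <= 1e-20 * max(1.0, abs(float(values.mean()))) ** 2:
        raise InsufficientDataError("all values identical; zero variance")
    var_floor = 1e-6 * data_var
    rng = rng if rng is not None else np.random.default_rng(0)

    best: Optional[MixtureModel] = None
    best_bic = np.inf
    stall = 0
    for k in range(1, k_max + 1):
        improved = False
        for start in range(n_starts):
            if start == 0:
                qs = (np.arange(k) + 0.5) / k
                means0 = np.quantile(values, qs)
            else:
                means0 = _kmeanspp_means(values, k, rng)
            model = _em_single(values, means0, tol, max_iter, var_floor)
            if model is None:
                continue
            bic = model.bic(len(values))
            if bic < best_bic - 1e-9:
                best, best_bic = model, bic
                improved = True
        # larger K stops paying once BIC worsens twice in a row
        stall = 0 if improved else stall + 1
        if stall >= 2:
            break
    if best is None:
        raise InsufficientDataError("no mixture fit converged")
    return best


def _coalesce_peaks(model: MixtureModel, merge_frac: float = 0.10):
    """Group mean-sorted components into peaks: EM routinely splits a heavy
    copy state into near-identical sub-components, while distinct copy
    states sit a full copy apart. A component joins the current peak when
    its mean is within ``merge_frac`` (relative) of the peak's
    weight-averaged mean — anchoring on the peak mean prevents chaining
    through thin boundary-blend components.

    Returns (peak_weights, peak_means, groups).
    """
    groups: list[list[int]] = [[0]]
    for i in range(1, model.k):
        g = groups[-1]
        anchor = np.average(model.means[g], weights=model.weights[g])
        if model.means[i] - anchor < merge_frac * model.means[i]:
            groups[-1].append(i)
        else:
            groups.append([i])
    weights = np.array([model.weights[g].sum() for g in groups])
    means = np.array([
        np.average(model.means[g], weights=model.weights[g]) for g in groups
    ])
    return weights, means, groups


def select_baseline(
    model: MixtureModel,
    policy: str = "auto",
    pi_min: float = 0.05,
    dominance_ratio: float = 1.5,
) -> tuple[float, int]:
    """Choose the copy-2 baseline peak of a fitted mixture.

    Components are first coalesced into peaks (see :func:`_coalesce_peaks`).
    Policies:

    - ``dominant``: peak with the largest total weight (its mean is its mode).
    - ``lowest_mean``: smallest mean among peaks with weight >= pi_min
      (for samples where everything above copy 2 dominates).
    - ``auto``: dominant, unless the dominant mean exceeds ``dominance_ratio``
      times the lowest admissible mean — the signature of a copy-4 (or higher)
      dominant peak — in which case the lowest admissible mean is used.

    Returns (baseline_mean, component_index); the index is the heaviest
    original component of the chosen peak, in mean-sorted order.
    """
    if model.k == 0:
        raise ParameterError("empty mixture model")
    if policy not in ("dominant", "lowest_mean", "auto"):
        raise ParameterError(f"unknown baseline policy '{policy}'")
    weights, means, groups = _coalesce_peaks(model)
    dom = int(np.argmax(weights))
    admissible = np.flatnonzero(weights >= pi_min)
    if len(admissible) == 0:
        admissible = np.array([dom])
    low = int(admissible[np.argmin(means[admissible])])
    if policy == "dominant":
        idx = dom
    elif policy == "lowest_mean":
        idx = low
    else:
        idx = low if means[dom] > dominance_ratio * means[low] else dom
    g = groups[idx]
    comp_idx = int(g[int(np.argmax(model.weights[g]))])
    return float(means[idx]), comp_idx


def absolute_normalize(
    track: AllelicTrack,
    mask: np.ndarray,
    smoothed_totals: np.ndarray,
    scope: str = "auto",
    policy: str = "auto",
    k_max: int = 6,
    n_starts: int = 3,
    rng: Optional[np.random.Generator] = None,
    chrom_tolerance: float = 0.15,
    pi_min: float = 0.05,
    max_fit_values: int = 5000,
) -> tuple[AllelicTrack, NormalizationReport]:
    """Rescale the track so the balanced-locus baseline sits at copy 2.

    The mixture is fitted on the smoothed totals of masked-in (balanced)
    loci. With ``scope='auto'`` both genome-wide and per-chromosome baselines
    are computed; a chromosome whose baseline deviates from the genome
    baseline by more than ``chrom_tolerance`` (relative) is rescaled with its
    own baseline and the report is flagged inconsistent.

    Raises :class:`InsufficientDataError` when fewer than 50 balanced loci
    are available in a fitting scope — the acknowledged failure mode for
    highly aneuploid samples.
    """
    if scope not in ("auto", "genome", "chromosome"):
        raise ParameterError(f"unknown scope '{scope}'")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(track),):
        raise ParameterError("mask length must match the track")
    rng = rng if rng is not None else np.random.default_rng(0)

    def _fit(values: np.ndarray, label: str) -> tuple[MixtureModel, float, int]:
        if len(values) < _MIN_VALUES:
            raise InsufficientDataError(
                f"insufficient balanced loci ({len(values)}) for {label} baseline"
            )
        if len(values) > max_fit_values:
            # deterministic even-stride thinning; the baseline mean gains
            # nothing from >5k points
            idx = np.linspace(0, len(values) - 1, max_fit_values).astype(int)
            values = values[idx]
        model = fit_gaussian_mixture(values, k_max=k_max, n_starts=n_starts, rng=rng)
        mean, idx = select_baseline(model, policy=policy, pi_min=pi_min)
        return model, mean, idx

    genome_model = genome_baseline = genome_idx = None
    if scope in ("auto", "genome"):
        genome_model, genome_baseline, genome_idx = _fit(
            smoothed_totals[mask], "genome"
        )

    chroms = track.chromosomes()
    per_chrom: dict[str, float] = {}
    if scope == "auto" and len(chroms) == 1 and genome_baseline is not None:
        # one chromosome: its baseline IS the genome baseline
        per_chrom[chroms[0][0]] = genome_baseline
    elif scope in ("auto", "chromosome"):
        for chrom, sl in chroms:
            vals = smoothed_totals[sl][mask[sl]]
            if len(vals) < _MIN_VALUES:
                if scope == "chromosome":
                    raise InsufficientDataError(
                        f"insufficient balanced loci on {chrom}"
                    )
                logger.warning(
                    "chromosome %s: too few balanced loci for its own baseline",
                    chrom,
                )
                continue
            _, mean_c, _ = _fit(vals, f"chromosome {chrom}")
            per_chrom[chrom] = mean_c

    scale = np.empty(len(track))
    if scope == "genome":
        used_scope, baseline, idx = "genome", genome_baseline, genome_idx
        scale[:] = 2.0 / baseline
        consistent = True
    elif scope == "chromosome":
        used_scope = "chromosome"
        for chrom, sl in track.chromosomes():
            scale[sl] = 2.0 / per_chrom[chrom]
        # report the locus-weighted baseline for the record
        baseline = float(
            np.average(list(per_chrom.values()))
        )
        idx, consistent = -1, True
    else:  # auto: genome baseline unless a chromosome disagrees
        used_scope, baseline, idx = "genome", genome_baseline, genome_idx
        consistent = True
        scale[:] = 2.0 / genome_baseline
        for chrom, sl in track.chromosomes():
            if chrom not in per_chrom:
                continue
            rel = abs(per_chrom[chrom] - genome_baseline) / genome_baseline
            if rel > chrom_tolerance:
                consistent = False
                used_scope = "chromosome"
                scale[sl] = 2.0 / per_chrom[chrom]
                logger.warning(
                    "chromosome %s baseline %.3f deviates %.0f%% from genome "
                    "baseline %.3f; using chromosome-wide scale",
                    chrom, per_chrom[chrom], 100 * rel, genome_baseline,
                )

    normalized = track.scaled(scale)
    report = NormalizationReport(
        scope=used_scope,
        baseline_mean=float(baseline),
        baseline_component_index=int(idx),
        scale_factor=float(2.0 / baseline),
        per_chromosome=per_chrom,
        consistent=consistent,
    )
    return normalized, report
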