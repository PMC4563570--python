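"""End-to-end pipeline: read -> smooth -> balance-filter -> absolutely
normalize -> segment -> noise model -> deletion typing -> purity -> tumor
profile -> ploidy.

``run_pipeline`` is the full method; ``run_legacy`` reproduces the classic
behaviour it replaces — median-centering normalization, no balance
filtering, noise parameters estimated over all loci, and mean aggregation of
per-segment alpha — and exists to demonstrate that method's failure modes on
imbalanced/aneuploid samples.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .datamodel import AllelicTrack, SampleResult, Segment
from .deletion import classify_deletion, estimate_noise_model
from .errors import (
    AbscnaError,
    InsufficientDataError,
    NoDeletionsError,
    StageError,
)
from .normalize import absolute_normalize
from .preprocess import (
    auto_balance_threshold,
    balanced_mask,
    correct_crosstalk,
    moving_average_total,
    sliding_allelic_correlation,
)
from .purity import aggregate_alpha, average_ploidy, recover_tumor_profile, segment_alpha
from .segmentation import annotate_segments, segment_track

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_legacy"]


@dataclass
class PipelineConfig:
    """All tunable stage parameters in one place (YAML-serializable)."""

    ma_window: int = 51
    rho_window: int = 200
    balance_threshold: Optional[float] = None  # None = automatic
    scope: str = "auto"
    baseline_policy: str = "auto"
    k_max: int = 6
    n_starts: int = 3
    min_seg_len: int = 50
    z_threshold: float = 5.0
    deletion_threshold: float = 1.8
    cn_window: tuple = (1.8, 2.2)
    alpha_percentile: float = 9.0
    priors: tuple = (0.5, 0.5)
    crosstalk: float = 0.0
    saturation_level: Optional[float] = None
    seed: int = 0
    best_effort: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cn_window"] = list(self.cn_window)
        d["priors"] = list(self.priors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cn_window" in d:
            d["cn_window"] = tuple(d["cn_window"])
        if "priors" in d:
            d["priors"] = tuple(d["priors"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _call_and_aggregate(
    track_norm: AllelicTrack,
    segments: list[Segment],
    noise,
    config: PipelineConfig,
    aggregate: str,
) -> tuple[Optional[float], list[tuple]]:
    """Classify candidate deletion segments and aggregate their alphas."""
    seg_calls: list[tuple] = []
    alphas: list[float] = []
    for seg in segments:
        call, a_seg = None, None
        if seg.mean_total < config.deletion_threshold:
            try:
                call = classify_deletion(
                    track_norm, seg, noise, priors=config.priors,
                    deletion_threshold=config.deletion_threshold,
                )
                a_seg = segment_alpha(seg.mean_total, call.type,
                                      sigma=float(np.sqrt(noise.sigma2)))
                if 0.0 <= a_seg < 1.0:
                    alphas.append(a_seg)
            except InsufficientDataError:
                logger.warning(
                    "segment %s:%d-%d too short for deletion typing; skipped",
                    seg.chrom, seg.start, seg.end,
                )
        seg_calls.append((seg, call, a_seg))
    if not alphas:
        return None, seg_calls
    if aggregate == "percentile":
        alpha_hat = aggregate_alpha(alphas, percentile=config.alpha_percentile)
    else:
        alpha_hat = float(np.mean(alphas))
    return alpha_hat, seg_calls


def _finish(
    track_norm: AllelicTrack,
    segments: list[Segment],
    seg_calls: list[tuple],
    alpha_hat: Optional[float],
    scale_factor: float,
    qc: dict,
    config: PipelineConfig,
) -> SampleResult:
    if alpha_hat is None:
        if not config.best_effort:
            raise NoDeletionsError("no deletions found; purity not estimable")
        logger.warning("no informative deletion segments; reporting ploidy "
                       "of the normalized profile (alpha undefined)")
        ploidy_alpha = 0.0
    else:
        ploidy_alpha = min(alpha_hat, 0.98)
    tumor_means = recover_tumor_profile(
        np.array([s.mean_total for s in segments]), ploidy_alpha
    )
    ploidy = average_ploidy(tumor_means, [s.n_loci for s in segments])
    qc = dict(qc)
    qc["n_deletion_segments"] = sum(1 for _, c, _ in seg_calls if c is not None)
    qc["alpha_distribution"] = [a for _, _, a in seg_calls if a is not None]
    qc["tumor_segment_means"] = tumor_means.tolist()
    return SampleResult(
        sample_id=track_norm.sample_id,
        alpha=alpha_hat,
        scale_factor=scale_factor,
        ploidy=ploidy,
        segments_with_calls=seg_calls,
        qc=qc,
        seed=config.seed,
        config_hash=config.config_hash(),
    )


def run_pipeline(track: AllelicTrack, config: Optional[PipelineConfig] = None) -> SampleResult:
    """Full analysis of one allelic signal track.

    Deterministic given ``config.seed`` (the only stochastic stage is the
    mixture EM restart initialization).
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    try:
        if config.crosstalk > 0 or config.saturation_level is not None:
            track = correct_crosstalk(track, config.crosstalk,
                                      config.saturation_level)
        smoothed = moving_average_total(track, window=config.ma_window)
        profile = sliding_allelic_correlation(track, window=config.rho_window)
        threshold = (
            config.balance_threshold
            if config.balance_threshold is not None
            else auto_balance_threshold(profile.r)
        )
        profile.finalize(threshold)
        mask = profile.mask
    except AbscnaError as exc:
        raise StageError("preprocess", str(exc)) from exc

    try:
        track_norm, report = absolute_normalize(
            track, mask, smoothed,
            scope=config.scope, policy=config.baseline_policy,
            k_max=config.k_max, n_starts=config.n_starts, rng=rng,
        )
    except InsufficientDataError as exc:
        if not config.best_effort:
            raise StageError("normalize", str(exc)) from exc
        logger.warning("normalization failed (%s); proceeding unscaled", exc)
        track_norm, report = track, None

    try:
        totals_norm = track_norm.totals
        segments = segment_track(track_norm, totals_norm,
                                 min_len=config.min_seg_len,
                                 z_threshold=config.z_threshold)
        annotate_segments(segments, track_norm, mask, totals_norm)
    except AbscnaError as exc:
        raise StageError("segmentation", str(exc)) from exc

    try:
        noise = estimate_noise_model(track_norm, mask, segments,
                                     cn_window=config.cn_window)
    except InsufficientDataError as exc:
        raise StageError("noise_model", str(exc)) from exc

    alpha_hat, seg_calls = _call_and_aggregate(
        track_norm, segments, noise, config, aggregate="percentile"
    )
    qc = {
        "mode": "full",
        "eta_hat": float(np.mean(~mask)),  # fraction of loci removed as LOH-like
        "balance_threshold": float(threshold),
        "rho_hat": noise.rho,
        "sigma_hat": float(np.sqrt(noise.sigma2)),
        "sigma_d2": noise.sigma_d2,
        "n_noise_loci": noise.n_loci,
        "n_masked_in": int(mask.sum()),
        "normalization": None if report is None else {
            "scope": report.scope,
            "baseline_mean": report.baseline_mean,
            "scale_factor": report.scale_factor,
            "consistent": report.consistent,
            "per_chromosome": report.per_chromosome,
        },
    }
    scale = report.scale_factor if report is not None else 1.0
    return _finish(track_norm, segments, seg_calls, alpha_hat, scale, qc, config)


def run_legacy(track: AllelicTrack, config: Optional[PipelineConfig] = None) -> SampleResult:
    """Classic pipeline: median-centering, no balance filtering, noise model
    over all loci, mean alpha aggregation.

    Provided as a contrast/diagnostic; on samples where the median locus is
    not diploid-balanced it misnormalizes, misclassifies deletions, and
    overestimates the normal fraction.
    """
    config = config or PipelineConfig()
    try:
        if config.crosstalk > 0 or config.saturation_level is not None:
            track = correct_crosstalk(track, config.crosstalk,
                                      config.saturation_level)
        median = float(np.median(track.totals))
        if median <= 0:
            raise InsufficientDataError("non-positive median total signal")
        scale = 2.0 / median
        track_norm = track.scaled(scale)
    except AbscnaError as exc:
        raise StageError("legacy_normalize", str(exc)) from exc

    try:
        totals_norm = track_norm.totals
        segments = segment_track(track_norm, totals_norm,
                                 min_len=config.min_seg_len,
                                 z_threshold=config.z_threshold)
        annotate_segments(segments, track_norm, None, totals_norm)
    except AbscnaError as exc:
        raise StageError("segmentation", str(exc)) from exc

    try:
        # no mask, no copy-number window: all het loci enter the estimate
        noise = estimate_noise_model(track_norm, None, segments,
                                     cn_window=(-np.inf, np.inf))
    except InsufficientDataError as exc:
        raise StageError("noise_model", str(exc)) from exc

    alpha_hat, seg_calls = _call_and_aggregate(
        track_norm, segments, noise, config, aggregate="mean"
    )
    qc = {
        "mode": "legacy",
        "rho_hat": noise.rho,
        "sigma_hat": float(np.sqrt(noise.sigma2)),
        "sigma_d2": noise.sigma_d2,
        "median_total": median,
    }
    return _finish(track_norm, segments, seg_calls, alpha_hat, scale, qc, config)
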