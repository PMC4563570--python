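"""Core containers for allele-specific copy-number analysis.

The central object is the :class:`AllelicTrack`: per-locus A/B allele copy
number signals with genomic coordinates and heterozygosity flags, stored as
numpy arrays (a track routinely holds 10^4--10^6 loci). Individual loci can
still be addressed as lightweight :class:`Locus` records.

Coordinates are 1-based in files (input tables, SEG output) and 0-based
half-open locus-index ranges internally (:class:`Segment.start`/``end`` index
into the track, not into the genome).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "Locus",
    "AllelicTrack",
    "Segment",
    "MixtureModel",
    "NoiseModel",
    "DeletionCall",
    "NormalizationReport",
    "SampleResult",
    "chrom_sort_key",
]


def chrom_sort_key(chrom: str):
    """Natural ordering key for chromosome labels (chr2 < chr10 < chrX)."""
    s = str(chrom)
    if s.lower().startswith("chr"):
        s = s[3:]
    m = re.match(r"^(\d+)$", s)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, s)


@dataclass(frozen=True)
class Locus:
    """One SNP locus with allele-specific copy number signals."""

    chrom: str
    pos: int
    a_signal: float
    b_signal: float
    het: bool = True

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.a_signal < 0 or self.b_signal < 0:
            raise ValidationError("allele signals must be non-negative")

    @property
    def total(self) -> float:
        return self.a_signal + self.b_signal


class AllelicTrack:
    """Ordered per-locus allele-specific signal profile for one sample.

    Loci are sorted by (chromosome, position) with no duplicate coordinates.
    Arrays are validated and made read-only at construction.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        a_signal: np.ndarray,
        b_signal: np.ndarray,
        het: Optional[np.ndarray] = None,
        sample_id: str = "sample",
    ):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.a_signal = np.asarray(a_signal, dtype=float)
        self.b_signal = np.asarray(b_signal, dtype=float)
        n = len(self.pos)
        if het is None:
            het = np.ones(n, dtype=bool)
        self.het = np.asarray(het, dtype=bool)
        self.sample_id = str(sample_id)
        self._validate()
        for arr in (self.chrom, self.pos, self.a_signal, self.b_signal, self.het):
            arr.flags.writeable = False

    # -- construction/validation -------------------------------------------
    def _validate(self):
        n = len(self.pos)
        for name, arr in (
            ("chrom", self.chrom),
            ("a_signal", self.a_signal),
            ("b_signal", self.b_signal),
            ("het", self.het),
        ):
            if len(arr) != n:
                raise ValidationError(f"column '{name}' has length {len(arr)} != {n}")
        if n == 0:
            return
        if np.any(self.pos < 1):
            raise ValidationError("positions must be >= 1")
        if np.any(~np.isfinite(self.a_signal)) or np.any(~np.isfinite(self.b_signal)):
            raise ValidationError("allele signals must be finite")
        if np.any(self.a_signal < 0) or np.any(self.b_signal < 0):
            raise ValidationError("allele signals must be non-negative")
        keys = [(chrom_sort_key(c), p) for c, p in zip(self.chrom, self.pos)]
        if any(keys[i] >= keys[i + 1] for i in range(n - 1)):
            if any(keys[i] == keys[i + 1] for i in range(n - 1)):
                raise ValidationError("duplicate (chrom, pos) loci")
            raise ValidationError("loci are not sorted by (chrom, pos)")

    @classmethod
    def from_arrays(cls, chrom, pos, a_signal, b_signal, het=None,
                    sample_id: str = "sample", sort: bool = True) -> "AllelicTrack":
        """Build a track, sorting rows by (chrom, pos) if requested."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        a_signal = np.asarray(a_signal, dtype=float)
        b_signal = np.asarray(b_signal, dtype=float)
        het = (np.ones(len(pos), dtype=bool) if het is None
               else np.asarray(het, dtype=bool))
        if sort and len(pos) > 1:
            order = sorted(range(len(pos)),
                           key=lambda i: (chrom_sort_key(chrom[i]), pos[i]))
            order = np.asarray(order)
            chrom, pos = chrom[order], pos[order]
            a_signal, b_signal, het = a_signal[order], b_signal[order], het[order]
        dup = [
            i for i in range(len(pos) - 1)
            if chrom[i] == chrom[i + 1] and pos[i] == pos[i + 1]
        ]
        if dup:
            raise ValidationError(
                f"duplicate (chrom, pos) at {chrom[dup[0]]}:{pos[dup[0]]}"
            )
        return cls(chrom, pos, a_signal, b_signal, het, sample_id)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.pos)

    def __getitem__(self, i: int) -> Locus:
        return Locus(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            a_signal=float(self.a_signal[i]),
            b_signal=float(self.b_signal[i]),
            het=bool(self.het[i]),
        )

    def __iter__(self) -> Iterator[Locus]:
        for i in range(len(self)):
            yield self[i]

    @property
    def totals(self) -> np.ndarray:
        """Per-locus total signal X_i = X_A,i + X_B,i."""
        return self.a_signal + self.b_signal

    def chromosomes(self) -> list[tuple[str, slice]]:
        """Contiguous (label, index-slice) runs in track order."""
        out: list[tuple[str, slice]] = []
        if len(self) == 0:
            return out
        start = 0
        for i in range(1, len(self)):
            if self.chrom[i] != self.chrom[start]:
                out.append((str(self.chrom[start]), slice(start, i)))
                start = i
        out.append((str(self.chrom[start]), slice(start, len(self))))
        return out

    def with_signals(self, a_signal, b_signal) -> "AllelicTrack":
        """New track with replaced signals (same loci/metadata)."""
        return AllelicTrack(self.chrom, self.pos, a_signal, b_signal,
                            self.het, self.sample_id)

    def scaled(self, factor) -> "AllelicTrack":
        """Multiply both allele signals by ``factor`` (scalar or per-locus)."""
        factor = np.asarray(factor, dtype=float)
        return self.with_signals(self.a_signal * factor, self.b_signal * factor)


@dataclass
class Segment:
    """Contiguous constant-copy region as a 0-based half-open index range."""

    chrom: str
    start: int
    end: int
    mean_total: float = float("nan")
    balanced_fraction: float = float("nan")
    pos_start: Optional[int] = None  # 1-based genomic coords, filled at annotation
    pos_end: Optional[int] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"segment end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def n_loci(self) -> int:
        return self.end - self.start

    @property
    def indices(self) -> slice:
        return slice(self.start, self.end)


@dataclass
class MixtureModel:
    """K-component univariate Gaussian mixture (components sorted by mean)."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    n_iter: int = 0
    ll_trace: list = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.variances)):
            raise ValidationError("mixture parameter arrays must share a length")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValidationError("mixture variances must be positive")
        order = np.argsort(self.means)
        self.weights = self.weights[order]
        self.means = self.means[order]
        self.variances = self.variances[order]

    @property
    def k(self) -> int:
        return len(self.weights)

    def pdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        comp = (
            self.weights
            / np.sqrt(2 * np.pi * self.variances)
            * np.exp(-0.5 * (x[:, None] - self.means) ** 2 / self.variances)
        )
        return comp.sum(axis=1)

    def bic(self, n: int) -> float:
        p = 3 * self.k - 1
        return -2.0 * self.log_likelihood + p * np.log(n)


@dataclass
class NoiseModel:
    """Per-allele noise variance, inter-allele correlation and the implied
    variance of the allele difference X_A - X_B."""

    sigma2: float
    rho: float
    sigma_d2: float = None  # type: ignore[assignment]
    n_loci: int = 0  # loci the estimate was based on (0 = constructed)

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValidationError("sigma2 must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValidationError("rho must lie in (-1, 1)")
        implied = 2.0 * self.sigma2 * (1.0 - self.rho)
        if self.sigma_d2 is None:
            self.sigma_d2 = implied
        elif abs(self.sigma_d2 - implied) > 1e-9:
            raise ValidationError("sigma_d2 must equal 2*sigma2*(1-rho)")
        if self.sigma_d2 <= 0:
            raise ValidationError("sigma_d2 must be positive")

    @property
    def sigma_d(self) -> float:
        return float(np.sqrt(self.sigma_d2))


@dataclass
class DeletionCall:
    """Homo/hemi deletion call for one segment."""

    type: str  # "homo" | "hemi"
    Y: float
    L: int
    lam: float
    posterior_homo: float

    def __post_init__(self):
        if self.type not in ("homo", "hemi"):
            raise ValidationError(f"unknown deletion type '{self.type}'")
        if self.Y < 0 or self.lam < 0:
            raise ValidationError("Y and lambda must be non-negative")
        if not 0.0 <= self.posterior_homo <= 1.0:
            raise ValidationError("posterior must lie in [0, 1]")

    @property
    def posterior_hemi(self) -> float:
        return 1.0 - self.posterior_homo


@dataclass
class NormalizationReport:
    """Where the copy-2 baseline came from and how the track was rescaled."""

    scope: str  # "genome" | "chromosome"
    baseline_mean: float
    baseline_component_index: int
    scale_factor: float
    per_chromosome: dict = field(default_factory=dict)  # chrom -> baseline mean
    consistent: bool = True

    def __post_init__(self):
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")


@dataclass
class SampleResult:
    """Final per-sample output of the pipeline.

    ``alpha`` is the normal-cell fraction; ``purity = 1 - alpha``. ``alpha``
    is None when no informative deletion segment existed (best-effort mode).
    """

    sample_id: str
    alpha: Optional[float]
    scale_factor: float
    ploidy: float
    segments_with_calls: Sequence[tuple] = field(default_factory=list)
    qc: dict = field(default_factory=dict)
    seed: Optional[int] = None
    config_hash: Optional[str] = None

    def __post_init__(self):
        if self.alpha is not None and not 0.0 <= self.alpha < 1.0:
            raise ValidationError("alpha must lie in [0, 1)")
        if self.ploidy <= 0:
            raise ValidationError("ploidy must be positive")
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")

    @property
    def purity(self) -> Optional[float]:
        return None if self.alpha is None else 1.0 - self.alpha
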