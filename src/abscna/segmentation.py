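"""Recursive binary segmentation of the normalized total-signal profile.

At each node the split maximizing the two-sample z statistic of segment
means is taken, with the noise scale estimated robustly from the median
absolute deviation of first differences; a split is accepted when |z|
exceeds the threshold and both children respect the minimum length. The
procedure is applied to the unsmoothed normalized totals: the MAD-of-first-
differences noise estimate is only consistent on serially uncorrelated
signals, and a moving-averaged profile would inflate z roughly by the
smoothing window.

Users who prefer an external segmenter (e.g. CBS) can ingest a SEG file and
bypass this stage entirely.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datamodel import AllelicTrack, Segment
from .errors import ParameterError

__all__ = ["segment_signal", "segment_track", "annotate_segments", "segments_from_seg"]


def _robust_sigma(values: np.ndarray) -> float:
    """Noise sd from the MAD of first differences (diff variance is 2*sigma^2)."""
    d = np.diff(values)
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _best_split(prefix: np.ndarray, i: int, j: int, min_len: int,
                sigma: float) -> tuple[Optional[int], float]:
    """Best split index t (i < t < j) of the half-open node [i, j) by the
    two-sample z statistic of means; returns (t, |z|)."""
    lo, hi = i + min_len, j - min_len
    if hi < lo:
        return None, 0.0
    t = np.arange(lo, hi + 1)
    n_l = t - i
    n_r = j - t
    mean_l = (prefix[t] - prefix[i]) / n_l
    mean_r = (prefix[j] - prefix[t]) / n_r
    se = sigma * np.sqrt(1.0 / n_l + 1.0 / n_r)
    z = np.abs(mean_l - mean_r) / np.maximum(se, 1e-300)
    k = int(np.argmax(z))
    return int(t[k]), float(z[k])


def segment_signal(values: np.ndarray, min_len: int = 50,
                   z_threshold: float = 5.0,
                   sigma: Optional[float] = None) -> list[tuple[int, int]]:
    """Partition one chromosome's totals into constant-mean index ranges.

    Returns ordered, non-overlapping, covering half-open (start, end) pairs.
    A track shorter than ``2 * min_len`` is returned as a single segment.
    """
    if min_len < 10:
        raise ParameterError("min_len must be >= 10")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return []
    if sigma is None:
        sigma = _robust_sigma(values)
    sigma = max(sigma, 1e-12)
    prefix = np.concatenate([[0.0], np.cumsum(values)])

    out: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        t, z = _best_split(prefix, i, j, min_len, sigma)
        if t is None or z <= z_threshold:
            out.append((i, j))
        else:
            stack.append((t, j))
            stack.append((i, t))
    out.sort()
    return out


def segment_track(track: AllelicTrack, totals: np.ndarray, min_len: int = 50,
                  z_threshold: float = 5.0) -> list[Segment]:
    """Run binary segmentation per chromosome over a whole track."""
    segments: list[Segment] = []
    for chrom, sl in track.chromosomes():
        for i, j in segment_signal(totals[sl], min_len=min_len,
                                   z_threshold=z_threshold):
            segments.append(Segment(chrom=chrom, start=sl.start + i,
                                    end=sl.start + j))
    return segments


def annotate_segments(segments: Sequence[Segment], track: AllelicTrack,
                      mask: Optional[np.ndarray],
                      totals: Optional[np.ndarray] = None) -> list[Segment]:
    """Fill mean_total, balanced_fraction and genomic coordinates in place.

    ``totals`` defaults to the track's own totals (pass the normalized
    profile when annotating after normalization).
    """
    totals = track.totals if totals is None else np.asarray(totals, dtype=float)
    for seg in segments:
        sl = seg.indices
        seg.mean_total = float(np.mean(totals[sl]))
        if mask is None:
            seg.balanced_fraction = 1.0
        else:
            seg.balanced_fraction = float(np.mean(np.asarray(mask[sl], dtype=float)))
        seg.pos_start = int(track.pos[seg.start])
        seg.pos_end = int(track.pos[seg.end - 1])
    return list(segments)


def segments_from_seg(df, track: AllelicTrack) -> list[Segment]:
    """Convert an external SEG table (1-based inclusive genomic coordinates)
    into index-range segments over ``track``."""
    segments = []
    for _, row in df.iterrows():
        on_chrom = track.chrom == row["chrom"]
        inside = on_chrom & (track.pos >= row["loc.start"]) & (
            track.pos <= row["loc.end"]
        )
        idx = np.flatnonzero(inside)
        if len(idx) == 0:
            continue
        segments.append(
            Segment(chrom=str(row["chrom"]), start=int(idx[0]), end=int(idx[-1]) + 1)
        )
    segments.sort(key=lambda s: s.start)
    return segments
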