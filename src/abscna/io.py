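"""Readers and writers: allelic signal tables (TSV), IGV SEG files, and the
JSON result report.

Input table layout (tab-separated, with header)::

    chrom  pos  a_signal  b_signal  [genotype]

``genotype`` holds the matched-normal call; ``AB`` (case-insensitive) marks a
heterozygous locus. File coordinates are 1-based; SEG rows are written with
1-based inclusive coordinates per the IGV convention.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import AllelicTrack, DeletionCall, SampleResult, Segment
from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

_REQUIRED = ["chrom", "pos", "a_signal", "b_signal"]
_SEG_HEADER = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def read_allelic_table(path, has_genotype_column: Optional[bool] = None,
                       sample_id: Optional[str] = None) -> AllelicTrack:
    """Read a per-locus allelic signal table.

    Parameters
    ----------
    path
        TSV file with columns ``chrom pos a_signal b_signal [genotype]``.
    has_genotype_column
        If None, the genotype column is used when present. If True, it is
        required; if False, it is ignored even if present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if has_genotype_column is True and "genotype" not in df.columns:
        raise FormatError(f"{path}: genotype column required but absent")
    use_gt = (
        "genotype" in df.columns
        if has_genotype_column is None
        else has_genotype_column
    )

    def _numeric(col: str, as_int: bool = False) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if df[col].isna().any():
            bad |= df[col].isna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(
                f"{path}: non-numeric value in column '{col}' at line {line}"
            )
        return vals.to_numpy(dtype=np.int64 if as_int else float)

    pos = _numeric("pos", as_int=True)
    a = _numeric("a_signal")
    b = _numeric("b_signal")
    chrom = df["chrom"].to_numpy(dtype=object)

    if use_gt:
        gt = df["genotype"].astype(str).str.strip().str.upper()
        het = (gt == "AB").to_numpy()
        known = gt.isin(["AA", "AB", "BB"])
        if not known.all():
            n_bad = int((~known).sum())
            logger.warning(
                "%s: %d genotype value(s) outside {AA,AB,BB}; flagged het=False",
                path, n_bad,
            )
    else:
        het = np.ones(len(pos), dtype=bool)

    from .datamodel import chrom_sort_key

    keys = [(chrom_sort_key(c), p) for c, p in zip(chrom, pos)]
    if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
        logger.warning("%s: rows out of (chrom, pos) order; sorting", path)
    return AllelicTrack.from_arrays(
        chrom, pos, a, b, het,
        sample_id=sample_id or path.stem, sort=True,
    )


def write_allelic_table(track: AllelicTrack, path,
                        include_genotype: bool = True) -> None:
    """Write a track back to the TSV dialect read by :func:`read_allelic_table`."""
    cols = {
        "chrom": track.chrom,
        "pos": track.pos,
        "a_signal": np.round(track.a_signal, 6),
        "b_signal": np.round(track.b_signal, 6),
    }
    if include_genotype:
        cols["genotype"] = np.where(track.het, "AB", "AA")
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_segments_seg(
    segments: Sequence[Segment],
    calls: Optional[Sequence[Optional[DeletionCall]]],
    sample_id: str,
    path,
) -> None:
    """Write segments as an IGV SEG file (1-based inclusive coordinates).

    ``calls`` may be None or a parallel sequence; where a call is present the
    extra columns ``call`` and ``posterior_homo`` are appended (IGV ignores
    trailing columns).
    """
    if not segments:
        logger.warning("write_segments_seg: empty segment list; writing header only")
    rows = []
    with_calls = calls is not None and any(c is not None for c in calls)
    for i, seg in enumerate(segments):
        if seg.pos_start is None or seg.pos_end is None:
            raise ValidationError(
                "segments must carry genomic coordinates (annotate first)"
            )
        row = {
            "ID": sample_id,
            "chrom": seg.chrom,
            "loc.start": int(seg.pos_start),
            "loc.end": int(seg.pos_end),
            "num.mark": seg.n_loci,
            "seg.mean": round(float(seg.mean_total), 6),
        }
        if with_calls:
            call = calls[i] if calls is not None else None
            row["call"] = call.type if call else "."
            row["posterior_homo"] = (
                round(call.posterior_homo, 6) if call else ""
            )
        rows.append(row)
    header = _SEG_HEADER + (["call", "posterior_homo"] if with_calls else [])
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


def read_segments_seg(path) -> pd.DataFrame:
    """Read an IGV SEG file; returns the table with canonical column names."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SEG_HEADER if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: not an IGV SEG file; missing {missing}")
    return df


def _segment_to_dict(seg: Segment, call: Optional[DeletionCall],
                     alpha_seg: Optional[float]) -> dict:
    d = {
        "chrom": seg.chrom,
        "start": seg.start,
        "end": seg.end,
        "pos_start": seg.pos_start,
        "pos_end": seg.pos_end,
        "n_loci": seg.n_loci,
        "mean_total": float(seg.mean_total),
        "balanced_fraction": float(seg.balanced_fraction),
        "call": None,
        "alpha_segment": alpha_seg,
    }
    if call is not None:
        d["call"] = {
            "type": call.type,
            "Y": call.Y,
            "L": call.L,
            "lambda": call.lam,
            "posterior_homo": call.posterior_homo,
        }
    return d


def write_result(result: SampleResult, path) -> None:
    """Write a machine-readable JSON report of a :class:`SampleResult`."""
    doc = {
        "sample_id": result.sample_id,
        "alpha": result.alpha,
        "purity": result.purity,
        "scale_factor": result.scale_factor,
        "ploidy": result.ploidy,
        "segments": [
            _segment_to_dict(seg, call, a)
            for seg, call, a in result.segments_with_calls
        ],
        "qc": result.qc,
        "seed": result.seed,
        "config_hash": result.config_hash,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_result(path) -> SampleResult:
    """Re-read a JSON report into a :class:`SampleResult`.

    Segment calls are reconstructed; QC diagnostics come back as plain dicts.
    """
    with open(path) as fh:
        doc = json.load(fh)
    segs = []
    for sd in doc.get("segments", []):
        seg = Segment(
            chrom=sd["chrom"], start=sd["start"], end=sd["end"],
            mean_total=sd["mean_total"],
            balanced_fraction=sd["balanced_fraction"],
            pos_start=sd["pos_start"], pos_end=sd["pos_end"],
        )
        call = None
        if sd.get("call"):
            c = sd["call"]
            call = DeletionCall(
                type=c["type"], Y=c["Y"], L=c["L"], lam=c["lambda"],
                posterior_homo=c["posterior_homo"],
            )
        segs.append((seg, call, sd.get("alpha_segment")))
    return SampleResult(
        sample_id=doc["sample_id"],
        alpha=doc["alpha"],
        scale_factor=doc["scale_factor"],
        ploidy=doc["ploidy"],
        segments_with_calls=segs,
        qc=doc.get("qc", {}),
        seed=doc.get("seed"),
        config_hash=doc.get("config_hash"),
    )
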