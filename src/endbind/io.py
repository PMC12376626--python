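"""Readers and writers for the flat genomic formats the pipeline consumes.

Everything on disk follows the usual public conventions (BED dialects are
0-based half-open; GTF is 1-based closed).  Everything returned to, or
accepted from, the rest of the package is 1-based closed.  The conversion
happens here and nowhere else.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import pandas as pd

NARROWPEAK_COLUMNS = [
    "chrom",
    "chromStart",
    "chromEnd",
    "name",
    "score",
    "strand",
    "signalValue",
    "pValue",
    "qValue",
    "peak",
]


def read_narrowpeak(path, factor: str | None = None, sample: str = "") -> pd.DataFrame:
    """Read an ENCODE narrowPeak (BED6+4) file into the internal peak table.

    Returns a DataFrame with columns ``peak_id, factor, sample, chrom,
    start, end, summit, signal`` (1-based closed coordinates).  A summit
    offset of -1 in column 10 means "unknown" and is replaced by the
    interval midpoint.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=NARROWPEAK_COLUMNS,
        comment="#",
        dtype={"chrom": str},
    )
    start = df["chromStart"].astype(int) + 1
    end = df["chromEnd"].astype(int)
    summit = df["chromStart"].astype(int) + df["peak"].astype(int) + 1
    mid = (start + end) // 2
    summit = summit.where(df["peak"].astype(int) >= 0, mid)
    out = pd.DataFrame(
        {
            "peak_id": df["name"].astype(str),
            "factor": factor if factor is not None else df["name"].astype(str).str.split("_").str[0],
            "sample": sample,
            "chrom": df["chrom"],
            "start": start,
            "end": end,
            "summit": summit,
            "signal": df["signalValue"].astype(float),
        }
    )
    if (out["signal"] < 0).any():
        raise ValueError("negative signalValue in %s" % path)
    bad = (out["summit"] < out["start"]) | (out["summit"] > out["end"])
    if bad.any():
        raise ValueError("summit outside peak interval for %d records in %s" % (bad.sum(), path))
    return out


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    """Write the internal peak table back out as narrowPeak."""
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "chromStart": peaks["start"].astype(int) - 1,
            "chromEnd": peaks["end"].astype(int),
            "name": peaks["peak_id"],
            "score": 0,
            "strand": ".",
            "signalValue": peaks["signal"],
            "pValue": -1,
            "qValue": -1,
            "peak": peaks["summit"].astype(int) - peaks["start"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph into ``chrom, start, end, value`` (1-based closed)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
        skiprows=_count_track_lines(path),
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    df["value"] = df["value"].astype(float)
    return df


def _count_track_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_bedgraph(cov: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": cov["chrom"],
            "start": cov["start"].astype(int) - 1,
            "end": cov["end"].astype(int),
            "value": cov["value"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%g")


def read_bedpe(path) -> pd.DataFrame:
    """Read a BEDPE loop file (10+ column dialects tolerated).

    Returns ``loop_id, chrom1, start1, end1, chrom2, start2, end2, score``
    with 1-based closed anchor intervals, ordered so that anchor1 is the
    leftmost on intra-chromosomal loops.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    if df.shape[1] < 6:
        raise ValueError("BEDPE needs at least 6 columns, got %d" % df.shape[1])
    out = pd.DataFrame(
        {
            "chrom1": df[0].astype(str),
            "start1": df[1].astype(int) + 1,
            "end1": df[2].astype(int),
            "chrom2": df[3].astype(str),
            "start2": df[4].astype(int) + 1,
            "end2": df[5].astype(int),
        }
    )
    out["loop_id"] = (
        df[6].astype(str) if df.shape[1] >= 7 else ["loop%06d" % i for i in range(len(df))]
    )
    out["score"] = df[7].astype(float) if df.shape[1] >= 8 else float("nan")
    # canonical anchor order for intra-chromosomal loops
    flip = (out["chrom1"] == out["chrom2"]) & (out["start2"] < out["start1"])
    for a, b in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2")):
        va, vb = out[a].copy(), out[b].copy()
        out.loc[flip, a] = vb[flip]
        out.loc[flip, b] = va[flip]
    return out[["loop_id", "chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"]]


def write_bedpe(loops: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom1": loops["chrom1"],
            "start1": loops["start1"].astype(int) - 1,
            "end1": loops["end1"].astype(int),
            "chrom2": loops["chrom2"],
            "start2": loops["start2"].astype(int) - 1,
            "end2": loops["end2"].astype(int),
            "name": loops["loop_id"],
            "score": loops.get("score", 0),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%g")


def write_table(df: pd.DataFrame, path, header_fields: dict | None = None) -> None:
    """Write a TSV with a provenance header (all coordinates 1-based closed)."""
    buf = _io.StringIO()
    buf.write("# endbind table; coordinates 1-based closed\n")
    for k, v in (header_fields or {}).items():
        buf.write("# %s=%s\n" % (k, v))
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def file_sha1(path) -> str:
    return hashlib.sha1(Path(path).read_bytes()).hexdigest()
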