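"""Factor co-occupancy z-score profiles over factor-A-bound region classes.

Regions are windows around bound positions of a reference factor
(typically MYC), split into four disjoint classes — TSS, TES, intragenic
enhancer and distal enhancer (class precedence TSS > TES > intragenic >
distal).  For every queried factor, the percentage of regions whose
signed-distance bin is overlapped by at least one of its peaks is
computed per bin and z-scored across all bins of the row, yielding a
profile in which each non-degenerate row has mean 0 and unit standard
deviation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from endbind.signal_metrics import classify_peak_regions

logger = logging.getLogger(__name__)

REGION_CLASSES = ("TSS", "TES", "intragenic", "distal")
DEFAULT_HALFWIDTH = 2500
NARROW_HALFWIDTH = 500
DEFAULT_BIN = 250


def build_region_sets(
    ref_peaks: pd.DataFrame,
    ref_assignments: pd.DataFrame,
    genes,
    enhancer_annotation: pd.DataFrame | None = None,
    halfwidth: int = DEFAULT_HALFWIDTH,
    radius: int = 2500,
) -> dict:
    """Four disjoint region sets centred on reference-factor summits.

    Classes come from the position rules (end-window membership, then
    inside/outside gene spans); when an enhancer interval table (chrom,
    start, end) is given, intragenic/distal candidates are additionally
    required to overlap it.  Returns class -> DataFrame (chrom, center,
    start, end).
    """
    classified = classify_peak_regions(ref_peaks, ref_assignments, genes, radius)
    cls_by_pid = classified.set_index("peak_id")["region_class"]
    out = {}
    for cls in REGION_CLASSES:
        pids = cls_by_pid[cls_by_pid == cls].index
        sub = ref_peaks[ref_peaks["peak_id"].isin(pids)]
        if enhancer_annotation is not None and cls in ("intragenic", "distal"):
            keep = []
            for r in sub.itertuples():
                enh = enhancer_annotation[
                    (enhancer_annotation["chrom"] == r.chrom)
                    & (enhancer_annotation["start"] <= r.summit)
                    & (enhancer_annotation["end"] >= r.summit)
                ]
                keep.append(len(enh) > 0)
            sub = sub[np.array(keep, dtype=bool)] if len(sub) else sub
        out[cls] = pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "center": sub["summit"].to_numpy(),
                "start": sub["summit"].to_numpy() - halfwidth,
                "end": sub["summit"].to_numpy() + halfwidth,
            }
        ).reset_index(drop=True)
    return out


def _overlap_fraction(regions: pd.DataFrame, peaks: pd.DataFrame, lo: int, hi: int) -> float:
    """Fraction of regions whose [center+lo, center+hi] bin touches a peak."""
    if regions.empty:
        return np.nan
    n_hit = 0
    for chrom, reg in regions.groupby("chrom"):
        pk = peaks[peaks["chrom"] == chrom]
        if pk.empty:
            continue
        starts = pk["start"].to_numpy()
        ends = pk["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        run_max_end = np.maximum.accumulate(ends)
        q_lo = reg["center"].to_numpy() + lo
        q_hi = reg["center"].to_numpy() + hi
        idx = np.searchsorted(starts, q_hi, side="right")
        hit = (idx > 0) & (run_max_end[np.maximum(idx - 1, 0)] >= q_lo)
        n_hit += int(hit.sum())
    return n_hit / len(regions)


def occupancy_zscores(
    region_sets: dict,
    factor_peaks: dict,
    halfwidth: int = DEFAULT_HALFWIDTH,
    bin_width: int = DEFAULT_BIN,
) -> pd.DataFrame:
    """Per-factor z-scored occupancy percentages over class x distance bins.

    Columns are a (region_class, bin_center_offset) MultiIndex; rows are
    factors.  Percent occupancy is computed per bin, then z-scored per
    factor across every bin of every class.  Factors with zero variance
    across bins get a zero row and are flagged via the ``degenerate``
    attribute column set alongside (returned DataFrame attrs).
    """
    edges = np.arange(-halfwidth, halfwidth + 1, bin_width)
    if len(edges) < 3:
        raise ValueError("need >= 2 bins per class")
    cols, col_keys = [], []
    for cls in REGION_CLASSES:
        if cls not in region_sets:
            continue
        for lo, hi in zip(edges[:-1], edges[1:]):
            cols.append((cls, int((lo + hi) // 2)))
            col_keys.append((cls, int(lo), int(hi - 1)))
    rows = {}
    degenerate = []
    for factor in sorted(factor_peaks):
        pct = []
        for (cls, _), (_, lo, hi) in zip(cols, col_keys):
            pct.append(100.0 * _overlap_fraction(region_sets[cls], factor_peaks[factor], lo, hi))
        pct = np.asarray(pct, dtype=float)
        sd = np.nanstd(pct, ddof=0)
        if not np.isfinite(sd) or sd == 0:
            rows[factor] = np.zeros(len(pct))
            degenerate.append(factor)
            logger.warning("factor %s has zero variance across bins; z-row set to 0", factor)
        else:
            rows[factor] = (pct - np.nanmean(pct)) / sd
    mat = pd.DataFrame.from_dict(rows, orient="index")
    mat.columns = pd.MultiIndex.from_tuples(cols, names=["region_class", "bin_center"])
    mat.attrs["degenerate_factors"] = degenerate
    return mat
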