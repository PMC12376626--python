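"""Assignment of ChIP peaks to TSS/TES anchor windows.

A peak belongs to a gene end when its summit lies within ``radius`` bp
(default 2500; a 1000-bp preset suits compact genomes) of one of that
end's anchors.  A peak within the windows of two genes is assigned to
both.  Peaks that could be read as TES binding of one gene *or* TSS
binding of its closely spaced head-to-tail partner are flagged ambiguous
so that signal-level analyses can drop them; category classification
keeps them by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSIGNMENT_COLUMNS = [
    "peak_id",
    "factor",
    "sample",
    "gene_id",
    "end_kind",
    "anchor",
    "offset",
    "signal",
    "summit",
    "chrom",
    "ambiguous",
    "same_gene_both_ends",
]


def _anchor_table(genes) -> pd.DataFrame:
    rows = []
    for g in genes:
        for kind in ("TSS", "TES"):
            for a in g.anchors(kind):
                rows.append((g.chrom, int(a), g.gene_id, kind, 1 if g.strand == "+" else -1))
    return pd.DataFrame(rows, columns=["chrom", "anchor", "gene_id", "end_kind", "orient"])


def assign_peaks(peaks: pd.DataFrame, genes, radius: int = 2500, mode: str = "summit") -> pd.DataFrame:
    """Assign peaks to every gene end whose anchor lies within ``radius``.

    ``mode='summit'`` (default) tests the summit position against the
    anchor window; ``mode='overlap'`` tests the whole peak interval.
    Offsets are gene-oriented: positive means downstream of the anchor in
    the gene's reading direction.  When several anchors of the *same*
    (gene, end) hit, only the nearest is kept.  Peaks on chromosomes
    absent from the annotation are logged and left unassigned.
    """
    if radius <= 0:
        raise ValueError("radius must be positive, got %r" % radius)
    if mode not in ("summit", "overlap"):
        raise ValueError("mode must be 'summit' or 'overlap'")
    anchors = _anchor_table(genes)
    known = set(anchors["chrom"])
    missing = set(peaks["chrom"]) - known
    if missing:
        n = int(peaks["chrom"].isin(missing).sum())
        logger.warning("%d peaks on chromosomes absent from annotation: %s", n, sorted(missing))

    out_rows = []
    for chrom, pk in peaks.groupby("chrom", sort=True):
        an = anchors[anchors["chrom"] == chrom]
        if an.empty:
            continue
        apos = an["anchor"].to_numpy()
        order = np.argsort(apos, kind="stable")
        apos_sorted = apos[order]
        an_sorted = an.iloc[order].reset_index(drop=True)
        summits = pk["summit"].to_numpy()
        if mode == "summit":
            lo = np.searchsorted(apos_sorted, summits - radius, side="left")
            hi = np.searchsorted(apos_sorted, summits + radius, side="right")
        else:
            lo = np.searchsorted(apos_sorted, pk["start"].to_numpy() - radius, side="left")
            hi = np.searchsorted(apos_sorted, pk["end"].to_numpy() + radius, side="right")
        for (_, prow), l, h in zip(pk.iterrows(), lo, hi):
            if l == h:
                continue
            hits = an_sorted.iloc[l:h]
            # nearest anchor per (gene, end_kind)
            dist = (hits["anchor"] - prow["summit"]).abs()
            nearest = hits.assign(_d=dist).sort_values(["_d", "anchor"]).drop_duplicates(
                ["gene_id", "end_kind"], keep="first"
            )
            for _, arow in nearest.iterrows():
                offset = int((prow["summit"] - arow["anchor"]) * arow["orient"])
                out_rows.append(
                    (
                        prow["peak_id"],
                        prow["factor"],
                        prow.get("sample", ""),
                        arow["gene_id"],
                        arow["end_kind"],
                        int(arow["anchor"]),
                        offset,
                        float(prow["signal"]),
                        int(prow["summit"]),
                        chrom,
                    )
                )
    out = pd.DataFrame(out_rows, columns=ASSIGNMENT_COLUMNS[:10])
    out["ambiguous"] = False
    # same-gene note: one peak hitting both end kinds of a single short gene
    if len(out):
        both = out.groupby(["peak_id", "gene_id"])["end_kind"].transform("nunique") > 1
        out["same_gene_both_ends"] = both.to_numpy()
    else:
        out["same_gene_both_ends"] = pd.Series(dtype=bool)
    out = out.sort_values(["chrom", "summit", "peak_id", "gene_id", "end_kind"]).reset_index(drop=True)
    return out


def flag_ambiguous(assignments: pd.DataFrame, relations) -> pd.DataFrame:
    """Set the ambiguous flag on TES/TSS cross-assignments in head-to-tail pairs.

    A peak assigned both to the TES of one member of a head-to-tail pair
    and to the TSS of the other has *both* assignment rows flagged.  No
    other configuration (tail-to-tail shared TES peaks, isolated genes)
    is touched.  The assignment set itself is never reduced.
    """
    out = assignments.copy()
    out["ambiguous"] = False
    if out.empty:
        return out
    key = pd.MultiIndex.from_frame(out[["peak_id", "gene_id", "end_kind"]])
    flag = np.zeros(len(out), dtype=bool)
    for rel in relations:
        if rel.orientation != "head_to_tail":
            continue
        tes_peaks = set(out.loc[(out["gene_id"] == rel.tes_gene) & (out["end_kind"] == "TES"), "peak_id"])
        tss_peaks = set(out.loc[(out["gene_id"] == rel.tss_gene) & (out["end_kind"] == "TSS"), "peak_id"])
        shared = tes_peaks & tss_peaks
        if not shared:
            continue
        for pid in shared:
            flag |= np.asarray(
                key.isin([(pid, rel.tes_gene, "TES"), (pid, rel.tss_gene, "TSS")])
            )
    out["ambiguous"] = flag
    return out


def drop_ambiguous(assignments: pd.DataFrame) -> pd.DataFrame:
    """The ambiguity filter: remove flagged rows (used by signal analyses)."""
    return assignments[~assignments["ambiguous"]].reset_index(drop=True)


def site_counts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Distinct-peak counts per (gene, end_kind, factor).

    Multiplicities are preserved for reporting; the category classifier
    downstream uses presence/absence only.
    """
    if assignments.empty:
        return pd.DataFrame(columns=["gene_id", "end_kind", "factor", "n_peaks"])
    counts = (
        assignments.groupby(["gene_id", "end_kind", "factor"])["peak_id"]
        .nunique()
        .rename("n_peaks")
        .reset_index()
        .sort_values(["gene_id", "end_kind", "factor"])
        .reset_index(drop=True)
    )
    return counts
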