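"""Head-to-tail dyads with solitary intergenic binding, and their responses.

A dyad is an adjacent head-to-tail gene pair whose *only* factor binding
(at any timepoint of a time course) lies in the shared intergenic
window: a single site whose summit falls within the assignment radius of
both the upstream gene's TES anchor and the downstream gene's TSS
anchor.  Sites already occupied at baseline are high-affinity; sites
appearing only after induction are low-affinity.  Each flank's
expression response versus baseline is classed positive / none /
negative at a fold-change threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DyadRecord:
    upstream_gene: str  # TES side of the shared site
    downstream_gene: str  # TSS side
    site_affinity: str  # high (bound at baseline) | low (post-induction only)
    peak_ids: tuple
    response_up: str | None = None
    response_down: str | None = None


def _pooled(assignments_by_timepoint: dict, factor: str) -> pd.DataFrame:
    frames = [df[df["factor"] == factor] for df in assignments_by_timepoint.values()]
    frames = [f for f in frames if len(f)]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["peak_id", "gene_id", "end_kind"]
    )


def find_dyads(
    relations,
    assignments_by_timepoint: dict,
    genes,
    peaks_by_timepoint: dict,
    baseline: str,
    factor: str = "MYC",
    radius: int = 2500,
    vicinity: str = "span_plus_radius",
):
    """Dyads among head-to-tail relations (responses left unset).

    ``assignments_by_timepoint`` and ``peaks_by_timepoint`` map timepoint
    labels to assignment and peak tables for the same peak sets.  The
    exclusivity rule uses ``vicinity``: with the default
    ``span_plus_radius`` any factor peak whose summit falls inside either
    gene's span extended by ``radius`` — other than the shared intergenic
    site itself — disqualifies the pair; ``windows`` restricts the scan
    to the four end windows (i.e. to the assignment table).
    """
    if baseline not in assignments_by_timepoint:
        raise ValueError("baseline timepoint %r missing" % baseline)
    if len(assignments_by_timepoint) < 2:
        raise ValueError("need >= 2 timepoints for affinity calls")
    gene_by_id = {g.gene_id: g for g in genes}
    pooled = _pooled(assignments_by_timepoint, factor)
    base_peaks = set(
        peaks_by_timepoint[baseline].loc[
            peaks_by_timepoint[baseline]["factor"] == factor, "peak_id"
        ]
    )
    peak_frames = [df[df["factor"] == factor] for df in peaks_by_timepoint.values()]
    peak_frames = [f for f in peak_frames if len(f)]
    all_peaks = (
        pd.concat(peak_frames, ignore_index=True).drop_duplicates("peak_id")
        if peak_frames
        else pd.DataFrame(columns=["peak_id", "chrom", "summit"])
    )

    dyads = []
    for rel in relations:
        if rel.orientation != "head_to_tail":
            continue
        up, down = gene_by_id[rel.tes_gene], gene_by_id[rel.tss_gene]
        up_tes = pooled[
            (pooled["gene_id"] == up.gene_id) & (pooled["end_kind"] == "TES")
        ]
        down_tss = pooled[
            (pooled["gene_id"] == down.gene_id) & (pooled["end_kind"] == "TSS")
        ]
        shared = set(up_tes["peak_id"]) & set(down_tss["peak_id"])
        if not shared:
            continue
        # exclusivity: no other binding for either gene, at any timepoint
        if vicinity == "span_plus_radius":
            extra = False
            for g in (up, down):
                lo, hi = g.start - radius, g.end + radius
                near = all_peaks[
                    (all_peaks["chrom"] == g.chrom)
                    & (all_peaks["summit"] >= lo)
                    & (all_peaks["summit"] <= hi)
                ]
                if not set(near["peak_id"]) <= shared:
                    extra = True
                    break
        else:  # windows mode: only assignments count
            own = pooled[pooled["gene_id"].isin([up.gene_id, down.gene_id])]
            extra = not set(own["peak_id"]) <= shared
        if extra:
            continue
        affinity = "high" if shared & base_peaks else "low"
        dyads.append(
            DyadRecord(
                upstream_gene=up.gene_id,
                downstream_gene=down.gene_id,
                site_affinity=affinity,
                peak_ids=tuple(sorted(shared)),
            )
        )
    # flag genes participating in two dyads (gene genuinely between partners)
    seen: dict[str, int] = {}
    for d in dyads:
        for gid in (d.upstream_gene, d.downstream_gene):
            seen[gid] = seen.get(gid, 0) + 1
    multi = [g for g, n in seen.items() if n > 1]
    if multi:
        logger.info("genes in more than one dyad: %s", multi)
    return dyads


def classify_responses(
    dyads,
    expression: pd.DataFrame,
    baseline: str,
    fold_threshold: float = 1.5,
):
    """Fill each dyad's flank responses from a gene x timepoint expression table.

    Per gene: log2 fold change versus baseline at every later timepoint;
    the summary timepoint is the one with maximal absolute change.  The
    response is positive (negative) when that change exceeds
    log2(fold_threshold) with the matching sign, otherwise none.  Returns
    the completed records, the per-gene log2FC matrix and quadrant counts
    (affinity x flank x response).
    """
    if baseline not in expression.columns:
        raise ValueError("baseline column %r missing from expression table" % baseline)
    later = [c for c in expression.columns if c != baseline]
    thresh = np.log2(fold_threshold)
    lfc = np.log2(expression[later].div(expression[baseline], axis=0))

    def call(gid: str) -> str:
        v = lfc.loc[gid]
        peak = v.iloc[np.argmax(np.abs(v.to_numpy()))]
        if abs(peak) < thresh:
            return "none"
        return "positive" if peak > 0 else "negative"

    completed, dropped = [], []
    for d in dyads:
        if d.upstream_gene not in expression.index or d.downstream_gene not in expression.index:
            dropped.append((d.upstream_gene, d.downstream_gene))
            continue
        d.response_up = call(d.upstream_gene)
        d.response_down = call(d.downstream_gene)
        completed.append(d)
    if dropped:
        logger.warning("dyads dropped for missing expression: %s", dropped)
    counts = (
        pd.DataFrame(
            [
                dict(affinity=d.site_affinity, flank=flank, response=resp)
                for d in completed
                for flank, resp in (("upstream", d.response_up), ("downstream", d.response_down))
            ]
        )
        .groupby(["affinity", "flank", "response"])
        .size()
        .rename("n")
        .reset_index()
        if completed
        else pd.DataFrame(columns=["affinity", "flank", "response", "n"])
    )
    return completed, lfc, counts


def dyads_to_frame(dyads) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "upstream_gene": [d.upstream_gene for d in dyads],
            "downstream_gene": [d.downstream_gene for d in dyads],
            "site_affinity": [d.site_affinity for d in dyads],
            "response_up": [d.response_up for d in dyads],
            "response_down": [d.response_down for d in dyads],
            "peak_ids": [",".join(d.peak_ids) for d in dyads],
        }
    )
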