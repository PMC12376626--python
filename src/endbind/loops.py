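"""Chromatin-loop anchors at gene ends and the A-H contact groups.

Loop anchors are assigned to TSS/TES windows by their midpoints, with
the same ±radius convention as peak assignment.  Each gene then gets a
contact profile — does a loop join its own TSS and TES windows, and do
its TSS or TES contact any *other* locus — and the eight groups are the
cells of that three-flag table: A-D have the direct TSS-TES loop
(A: other contacts at both ends, B: TSS only, C: TES only, D: neither),
E-H mirror A-D without it.  The B-versus-C orientation is a package
convention, overridable via ``group_flag_order``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from endbind.peaks import assign_peaks

logger = logging.getLogger(__name__)

GROUPS = ("A", "B", "C", "D", "E", "F", "G", "H")


def _anchor_midpoints(loops: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in loops.itertuples():
        if r.chrom1 != r.chrom2:
            continue
        rows.append((r.loop_id, 1, r.chrom1, (r.start1 + r.end1) // 2))
        rows.append((r.loop_id, 2, r.chrom2, (r.start2 + r.end2) // 2))
    return pd.DataFrame(rows, columns=["loop_id", "anchor_idx", "chrom", "midpoint"])


def assign_loop_ends(loops: pd.DataFrame, genes, radius: int = 2500) -> pd.DataFrame:
    """Assign each intra-chromosomal loop anchor to gene ends by midpoint.

    Returns one row per (loop, anchor, gene, end) hit.  Inter-chromosomal
    loops are excluded with a logged count.
    """
    inter = int((loops["chrom1"] != loops["chrom2"]).sum())
    if inter:
        logger.info("excluded %d inter-chromosomal loops", inter)
    mids = _anchor_midpoints(loops)
    if mids.empty:
        return pd.DataFrame(columns=["loop_id", "anchor_idx", "gene_id", "end_kind", "anchor", "offset"])
    # reuse the summit-based window machinery: an anchor midpoint is a "summit"
    pseudo = pd.DataFrame(
        {
            "peak_id": mids["loop_id"] + ":" + mids["anchor_idx"].astype(str),
            "factor": "loop",
            "sample": "",
            "chrom": mids["chrom"],
            "start": mids["midpoint"],
            "end": mids["midpoint"],
            "summit": mids["midpoint"],
            "signal": 0.0,
        }
    )
    asn = assign_peaks(pseudo, genes, radius=radius, mode="summit")
    if asn.empty:
        return pd.DataFrame(columns=["loop_id", "anchor_idx", "gene_id", "end_kind", "anchor", "offset"])
    split = asn["peak_id"].str.rsplit(":", n=1, expand=True)
    out = pd.DataFrame(
        {
            "loop_id": split[0],
            "anchor_idx": split[1].astype(int),
            "gene_id": asn["gene_id"],
            "end_kind": asn["end_kind"],
            "anchor": asn["anchor"],
            "offset": asn["offset"],
        }
    )
    return out.sort_values(["loop_id", "anchor_idx", "gene_id"]).reset_index(drop=True)


def contact_profiles(loop_assignments: pd.DataFrame, genes) -> pd.DataFrame:
    """Per-gene flags: direct TSS-TES loop, TSS-other and TES-other contacts.

    An "other" contact requires the partner anchor of the loop to lie
    outside the same gene's opposite end window; loops with both anchors
    in one window (self-loops) are discarded.
    """
    hits: dict[tuple, set] = {}
    for r in loop_assignments.itertuples():
        hits.setdefault((r.loop_id, r.anchor_idx), set()).add((r.gene_id, r.end_kind))
    by_loop: dict[str, dict] = {}
    for (lid, idx), ends in hits.items():
        by_loop.setdefault(lid, {1: set(), 2: set()})[idx] = ends
    flags = {g.gene_id: dict(tss_tes_loop=False, tss_other=False, tes_other=False) for g in genes}
    for lid, sides in by_loop.items():
        s1, s2 = sides.get(1, set()), sides.get(2, set())
        for gid in {g for g, _ in s1 | s2}:
            e1 = {k for g, k in s1 if g == gid}
            e2 = {k for g, k in s2 if g == gid}
            if gid not in flags:
                continue
            f = flags[gid]
            if e1 and e2:
                if e1 == e2:
                    continue  # self-loop within one window
                f["tss_tes_loop"] = True  # one anchor at each end of the gene
                continue
            own, partner = (e1, s2) if e1 else (e2, s1)
            partner_ends_of_gene = {k for g, k in partner if g == gid}
            if partner_ends_of_gene:
                continue  # partner anchor sits in this gene's other window
            if "TSS" in own:
                f["tss_other"] = True
            if "TES" in own:
                f["tes_other"] = True
    out = pd.DataFrame(
        [
            dict(gene_id=gid, **f)
            for gid, f in flags.items()
        ]
    )
    return out.sort_values("gene_id").reset_index(drop=True)


def classify_groups(profiles: pd.DataFrame) -> pd.DataFrame:
    """Map the three contact flags to groups A-H (total over the universe)."""
    def grp(r):
        if r.tss_tes_loop:
            if r.tss_other and r.tes_other:
                return "A"
            if r.tss_other:
                return "B"
            if r.tes_other:
                return "C"
            return "D"
        if r.tss_other and r.tes_other:
            return "E"
        if r.tss_other:
            return "F"
        if r.tes_other:
            return "G"
        return "H"

    out = profiles.copy()
    out["group"] = [grp(r) for r in profiles.itertuples()]
    return out


def category_by_group_matrix(
    calls, profiles: pd.DataFrame, expression=None, min_cell: int = 5
):
    """16x8 gene-count matrix (and mean expression where n >= min_cell).

    Gene universes are intersected; counts sum to the intersection size.
    Returns ``(counts, mean_expression)`` DataFrames indexed by category.
    """
    from endbind.categories import calls_to_frame

    cdf = calls_to_frame(calls) if not isinstance(calls, pd.DataFrame) else calls
    merged = cdf.merge(profiles[["gene_id", "group"]], on="gene_id", how="inner")
    counts = (
        merged.groupby(["category", "group"]).size().unstack(fill_value=0)
        .reindex(index=range(1, 17), columns=list(GROUPS), fill_value=0)
    )
    mean_expr = pd.DataFrame(np.nan, index=counts.index, columns=counts.columns)
    if expression is not None:
        expr = pd.Series(expression)
        merged["expr"] = merged["gene_id"].map(expr)
        for (cat, g), grp_df in merged.groupby(["category", "group"]):
            vals = grp_df["expr"].dropna()
            if len(vals) >= min_cell:
                mean_expr.loc[cat, g] = float(vals.mean())
    return counts, mean_expr


def looping_frequency(calls, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-category fraction of genes with a direct TSS-TES loop.

    Reports both natural denominators: genes with >= 1 TSS-TES loop over
    all genes of the category, and over genes with any contact at all.
    """
    from endbind.categories import calls_to_frame

    cdf = calls_to_frame(calls) if not isinstance(calls, pd.DataFrame) else calls
    merged = cdf.merge(classify_groups(profiles), on="gene_id", how="inner")
    rows = []
    for cat, grp in merged.groupby("category"):
        n = len(grp)
        n_loop = int(grp["tss_tes_loop"].sum())
        n_any = int((grp["group"] != "H").sum())
        rows.append(
            dict(category=cat, n_genes=n, n_tss_tes=n_loop,
                 freq_of_all=n_loop / n if n else np.nan,
                 freq_of_contacted=n_loop / n_any if n_any else np.nan)
        )
    return pd.DataFrame(rows)


def rnapii_gate(
    genes,
    rnapii_assignments: pd.DataFrame,
    tes_assignments: pd.DataFrame | None = None,
    factor_a: str = "MYC",
    factor_b: str = "MAX",
    rnapii_factor: str = "POLR2A",
):
    """Restrict the universe to genes with RNAPII at both ends.

    Returns ``(universe, tes_groups)`` where ``tes_groups`` maps each
    retained gene to its TES-binding split — both factors, A only, B only
    or neither — for frequency comparisons across the four groups.
    """
    pol = rnapii_assignments[rnapii_assignments["factor"] == rnapii_factor]
    ends = pol.groupby("gene_id")["end_kind"].agg(set)
    universe = sorted(gid for gid, ks in ends.items() if {"TSS", "TES"} <= ks)
    groups = {}
    if tes_assignments is not None:
        tes = tes_assignments[
            (tes_assignments["end_kind"] == "TES")
            & (tes_assignments["factor"].isin([factor_a, factor_b]))
        ]
        by_gene = tes.groupby("gene_id")["factor"].agg(set)
        for gid in universe:
            fs = by_gene.get(gid, set())
            if factor_a in fs and factor_b in fs:
                groups[gid] = "A_and_B"
            elif factor_a in fs:
                groups[gid] = "A_only"
            elif factor_b in fs:
                groups[gid] = "B_only"
            else:
                groups[gid] = "neither"
    return universe, pd.Series(groups, dtype=object)
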