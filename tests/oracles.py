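"""Independent brute-force oracles used to cross-check the fast paths.

Everything here is deliberately naive: nested loops over every pair,
no sorting tricks, no shared code with the package internals beyond the
data containers.
"""

import pandas as pd


def brute_assignments(peaks: pd.DataFrame, genes, radius: int):
    """Exhaustive (peak x gene-end) scan; returns a set of tuples
    (peak_id, gene_id, end_kind, nearest_anchor, offset)."""
    out = set()
    for p in peaks.itertuples():
        for g in genes:
            if g.chrom != p.chrom:
                continue
            orient = 1 if g.strand == "+" else -1
            for kind in ("TSS", "TES"):
                hits = [a for a in g.anchors(kind) if abs(p.summit - a) <= radius]
                if not hits:
                    continue
                nearest = min(hits, key=lambda a: (abs(p.summit - a), a))
                out.add((p.peak_id, g.gene_id, kind, nearest, (p.summit - nearest) * orient))
    return out


def brute_ambiguous(assignment_set, relations):
    """Set of (peak_id, gene_id, end_kind) that the head-to-tail rule flags."""
    flagged = set()
    for rel in relations:
        if rel.orientation != "head_to_tail":
            continue
        tes = {a[0] for a in assignment_set if a[1] == rel.tes_gene and a[2] == "TES"}
        tss = {a[0] for a in assignment_set if a[1] == rel.tss_gene and a[2] == "TSS"}
        for pid in tes & tss:
            flagged.add((pid, rel.tes_gene, "TES"))
            flagged.add((pid, rel.tss_gene, "TSS"))
    return flagged


def brute_relations(genes, max_gap: int):
    """All-pairs adjacency scan; returns {(gene_a, gene_b): orientation}."""
    rels = {}
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    for i, a in enumerate(ordered):
        for j, b in enumerate(ordered):
            if a.chrom != b.chrom or j <= i:
                continue
            if any(
                a.chrom == c.chrom and i < k < j
                for k, c in enumerate(ordered)
            ):
                continue  # not adjacent: someone sits between
            if a.strand == "-" and b.strand == "+":
                orient = "head_to_head"
            elif a.strand == "+" and b.strand == "-":
                orient = "tail_to_tail"
            else:
                orient = "head_to_tail"
            right_kind = "TES" if a.strand == "+" else "TSS"
            left_kind = "TSS" if b.strand == "+" else "TES"
            gap = min(b.anchors(left_kind)) - max(a.anchors(right_kind))
            if gap <= max_gap:
                rels[(a.gene_id, b.gene_id)] = (orient, gap)
    return rels


def brute_region_class(peaks: pd.DataFrame, genes, radius: int):
    """Rule-by-rule region classification per peak (TSS > TES > intragenic > distal)."""
    out = {}
    for p in peaks.itertuples():
        cls = "distal"
        near_tss = near_tes = False
        for g in genes:
            if g.chrom != p.chrom:
                continue
            near_tss |= any(abs(p.summit - a) <= radius for a in g.tss_anchors)
            near_tes |= any(abs(p.summit - a) <= radius for a in g.tes_anchors)
        if near_tss:
            cls = "TSS"
        elif near_tes:
            cls = "TES"
        else:
            for g in genes:
                if g.chrom == p.chrom and g.start <= p.summit <= g.end:
                    cls = "intragenic"
                    break
        out[p.peak_id] = cls
    return out


def brute_loop_assignments(loops: pd.DataFrame, genes, radius: int):
    """Midpoint x gene-end scan; set of (loop_id, anchor_idx, gene_id, end_kind)."""
    out = set()
    for r in loops.itertuples():
        if r.chrom1 != r.chrom2:
            continue
        for idx, (chrom, s, e) in enumerate(
            [(r.chrom1, r.start1, r.end1), (r.chrom2, r.start2, r.end2)], start=1
        ):
            mid = (s + e) // 2
            for g in genes:
                if g.chrom != chrom:
                    continue
                for kind in ("TSS", "TES"):
                    if any(abs(mid - a) <= radius for a in g.anchors(kind)):
                        out.add((r.loop_id, idx, g.gene_id, kind))
    return out
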