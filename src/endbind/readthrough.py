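"""Downstream-of-gene (DoG) read-through quantification.

The read count in the 500-bp window just past a gene's TES (on the
gene's own strand) measures read-through; the 500-bp window just before
the TES measures the gene's expression.  Because the windows are equal
length, their count ratio equals the density ratio and is invariant to
global depth scaling.  Genes whose upstream window is below a minimum
count, or whose downstream window overlaps another annotated gene on the
same strand, have no defined fraction and are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WINDOW = 500
DEFAULT_MIN_UPSTREAM = 10.0
DEFAULT_PSEUDOCOUNT = 0.5


def _window_mass(cov: pd.DataFrame, chrom: str, lo: int, hi: int) -> float:
    """Coverage mass over [lo, hi], prorating intervals by overlap length."""
    sub = cov[(cov["chrom"] == chrom) & (cov["end"] >= lo) & (cov["start"] <= hi)]
    if sub.empty:
        return 0.0
    ov = (
        np.minimum(sub["end"].to_numpy(), hi)
        - np.maximum(sub["start"].to_numpy(), lo)
        + 1
    )
    length = sub["end"].to_numpy() - sub["start"].to_numpy() + 1
    return float(np.sum(sub["value"].to_numpy() * ov / length))


def _primary_tes(gene) -> int:
    """Most-downstream TES anchor in the gene's reading direction."""
    return max(gene.tes_anchors) if gene.strand == "+" else min(gene.tes_anchors)


def count_windows(
    coverage: dict,
    genes,
    window: int = DEFAULT_WINDOW,
    min_upstream: float = DEFAULT_MIN_UPSTREAM,
    mask_same_strand_overlap: bool = True,
) -> pd.DataFrame:
    """Per-gene DoG record: downstream/upstream window counts and fraction.

    ``coverage`` maps strand ('+'/'-') to a coverage table (chrom, start,
    end, value; 1-based closed).  Both strands must be present — for
    unstranded data build a single table and pass it under both keys
    explicitly (a separate, wider gene-boundary convention applies there
    and is the caller's choice).
    """
    for s in ("+", "-"):
        if s not in coverage:
            raise ValueError(
                "coverage lacks strand %r; read-through needs strand-resolved "
                "input (for unstranded data pass the same table under both "
                "strands and use unstranded gene boundaries)" % s
            )
    if window <= 0:
        raise ValueError("window must be positive")
    spans_by_strand: dict[str, list] = {"+": [], "-": []}
    for g in genes:
        spans_by_strand[g.strand].append((g.chrom, g.start, g.end, g.gene_id))
    rows = []
    for g in genes:
        tes = _primary_tes(g)
        if g.strand == "+":
            up_lo, up_hi = tes - window + 1, tes
            dn_lo, dn_hi = tes + 1, tes + window
        else:
            up_lo, up_hi = tes, tes + window - 1
            dn_lo, dn_hi = tes - window, tes - 1
        cov = coverage[g.strand]
        up = _window_mass(cov, g.chrom, up_lo, up_hi)
        dn = _window_mass(cov, g.chrom, dn_lo, dn_hi)
        flags = []
        if mask_same_strand_overlap:
            for chrom, s, e, gid in spans_by_strand[g.strand]:
                if gid == g.gene_id or chrom != g.chrom:
                    continue
                if s <= dn_hi and e >= dn_lo:
                    flags.append("masked_overlap")
                    break
        if up < min_upstream:
            flags.append("low_expression")
        frac = dn / up if not flags else np.nan
        rows.append(
            dict(gene_id=g.gene_id, downstream_count=dn, upstream_count=up,
                 fraction=frac, flags=";".join(flags))
        )
    return pd.DataFrame(rows)


def compare_groups(records: pd.DataFrame, group_labels) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of DoG fractions between groups.

    ``group_labels`` maps gene_id to ``TES_bound`` / ``TES_unbound`` (a
    dict or Series).  Requires at least two genes with defined fractions
    per group.
    """
    labels = pd.Series(group_labels)
    df = records.dropna(subset=["fraction"]).copy()
    df["group"] = df["gene_id"].map(labels)
    df = df.dropna(subset=["group"])
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two non-empty groups, got %r" % groups)
    a = df.loc[df["group"] == groups[0], "fraction"].to_numpy()
    b = df.loc[df["group"] == groups[1], "fraction"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 genes with defined fractions")
    stat, p = stats.ranksums(a, b)
    med = {g: float(np.median(df.loc[df["group"] == g, "fraction"])) for g in groups}
    return {
        "group_a": groups[0],
        "group_b": groups[1],
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "statistic": float(stat),
        "p_value": float(p),
        "median_a": med[groups[0]],
        "median_b": med[groups[1]],
        "direction": groups[0] if med[groups[0]] > med[groups[1]] else groups[1],
        "test": "wilcoxon_ranksum",
    }


def condition_delta(
    records_by_condition: dict,
    baseline: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene log2 change of the read-through fraction versus baseline.

    Fractions are recomputed with a pseudocount on both window counts so
    zero-count genes stay finite; genes flagged in either condition are
    excluded (flag recorded).
    """
    if baseline not in records_by_condition:
        raise ValueError("baseline condition %r missing" % baseline)
    base = records_by_condition[baseline].set_index("gene_id")
    rows = []
    for cond, rec in records_by_condition.items():
        if cond == baseline:
            continue
        cur = rec.set_index("gene_id")
        shared = base.index.intersection(cur.index)
        for gid in shared:
            b, c = base.loc[gid], cur.loc[gid]
            flags = ";".join(x for x in (b["flags"], c["flags"]) if x)
            if flags:
                rows.append(dict(condition=cond, gene_id=gid, log2_delta=np.nan, flags=flags))
                continue
            fb = (b["downstream_count"] + pseudocount) / (b["upstream_count"] + pseudocount)
            fc = (c["downstream_count"] + pseudocount) / (c["upstream_count"] + pseudocount)
            rows.append(
                dict(condition=cond, gene_id=gid, log2_delta=float(np.log2(fc / fb)), flags="")
            )
    return pd.DataFrame(rows)
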