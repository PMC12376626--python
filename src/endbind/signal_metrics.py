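"""Binding-signal summaries by region class and distance, and retention kinetics.

Region classes partition peaks: TSS window, TES window, intragenic
(inside a gene body but more than the window radius downstream of every
TSS anchor and upstream of every TES anchor of that gene) and distal
(outside all gene spans and all end windows).  Retention kinetics track,
across a treatment time course, the fraction of baseline-bound sites
still peak-positive and the signal at retained sites relative to
baseline, split into high/low affinity tiers at a baseline-signal
quantile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from endbind.peaks import drop_ambiguous

REGION_CLASSES = ("TSS", "TES", "intragenic", "distal")


def classify_peak_regions(peaks: pd.DataFrame, assignments: pd.DataFrame, genes,
                          radius: int = 2500) -> pd.DataFrame:
    """One region class per peak (precedence TSS > TES > intragenic > distal).

    `assignments` should already have the ambiguity filter applied where
    the analysis calls for it; flagged rows are dropped here regardless.
    Peaks on chromosomes absent from the annotation stay unclassified
    (class ``NA``).
    """
    asn = drop_ambiguous(assignments) if len(assignments) else assignments
    cls = pd.Series("distal", index=peaks["peak_id"].to_numpy(), dtype=object)

    if len(asn):
        tes_peaks = set(asn.loc[asn["end_kind"] == "TES", "peak_id"])
        tss_peaks = set(asn.loc[asn["end_kind"] == "TSS", "peak_id"])
    else:
        tes_peaks, tss_peaks = set(), set()

    gene_index: dict[str, list] = {}
    for g in genes:
        gene_index.setdefault(g.chrom, []).append(g)
    known_chroms = set(gene_index)

    for _, p in peaks.iterrows():
        pid = p["peak_id"]
        if p["chrom"] not in known_chroms:
            cls[pid] = "NA"
            continue
        if pid in tss_peaks:
            cls[pid] = "TSS"
            continue
        if pid in tes_peaks:
            cls[pid] = "TES"
            continue
        s = p["summit"]
        intragenic = False
        for g in gene_index[p["chrom"]]:
            if not (g.start <= s <= g.end):
                continue
            # gene-oriented distances from every anchor
            orient = 1 if g.strand == "+" else -1
            down_of_all_tss = all((s - a) * orient > radius for a in g.tss_anchors)
            up_of_all_tes = all((a - s) * orient > radius for a in g.tes_anchors)
            if down_of_all_tss and up_of_all_tes:
                intragenic = True
                break
        if intragenic:
            cls[pid] = "intragenic"
        else:
            # inside a span but within an unassigned window margin counts with
            # the nearer end window; with summit-mode assignment this cannot
            # happen, so anything left outside spans is distal
            in_span = any(
                g.start <= s <= g.end for g in gene_index[p["chrom"]]
            )
            cls[pid] = "intragenic" if in_span else "distal"
    out = peaks[["peak_id", "factor", "signal"]].copy()
    out["region_class"] = cls.loc[out["peak_id"]].to_numpy()
    return out


def stratify_signal(assignments: pd.DataFrame, peaks: pd.DataFrame, genes,
                    radius: int = 2500) -> pd.DataFrame:
    """Mean signal ± s.e. per (region class, factor); every peak in one class."""
    classified = classify_peak_regions(peaks, assignments, genes, radius)
    rows = []
    for (cls, factor), grp in classified.groupby(["region_class", "factor"]):
        sig = grp["signal"].to_numpy(dtype=float)
        n = len(sig)
        rows.append(
            dict(region_class=cls, factor=factor, n=n,
                 mean=float(sig.mean()) if n else np.nan,
                 sem=float(sig.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan)
        )
    for cls in REGION_CLASSES:  # report empty classes with n=0
        for factor in classified["factor"].unique():
            if not any(r["region_class"] == cls and r["factor"] == factor for r in rows):
                rows.append(dict(region_class=cls, factor=factor, n=0, mean=np.nan, sem=np.nan))
    return (
        pd.DataFrame(rows)
        .sort_values(["region_class", "factor"])
        .reset_index(drop=True)
    )


def distance_strata(assignments: pd.DataFrame, overlap_halfwidth: int = 100) -> pd.DataFrame:
    """Signal summaries per (end_kind, factor, upstream/overlapping/downstream).

    The stratum comes from the gene-oriented offset sign; ``overlapping``
    means the summit lies within ``overlap_halfwidth`` of the anchor.
    """
    asn = assignments.copy()
    off = asn["offset"].to_numpy()
    stratum = np.where(
        np.abs(off) <= overlap_halfwidth, "overlapping",
        np.where(off < 0, "upstream", "downstream"),
    )
    asn["stratum"] = stratum
    rows = []
    for (kind, factor, strat), grp in asn.groupby(["end_kind", "factor", "stratum"]):
        sig = grp["signal"].to_numpy(dtype=float)
        rows.append(
            dict(end_kind=kind, factor=factor, stratum=strat, n=len(sig),
                 mean=float(sig.mean()),
                 sem=float(sig.std(ddof=1) / np.sqrt(len(sig))) if len(sig) > 1 else np.nan)
        )
    return pd.DataFrame(rows).sort_values(["end_kind", "factor", "stratum"]).reset_index(drop=True)


def _site_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Collapse assignments to sites keyed by (gene, end, anchor, factor).

    The site signal is the strongest peak signal at that key; interval
    identity is deliberately not used, so summit jitter between
    timepoints does not break the matching.
    """
    return (
        assignments.groupby(["gene_id", "end_kind", "anchor", "factor"])["signal"]
        .max()
        .reset_index()
    )


def retention_kinetics(
    timecourse: dict,
    baseline: str,
    order: list | None = None,
    tier_quantile: float = 0.5,
) -> pd.DataFrame:
    """Fraction of baseline sites still bound, and relative signal, per timepoint.

    ``timecourse`` maps timepoint label to an assignment table.  Sites are
    matched across timepoints by (gene, end, anchor, factor).  Baseline
    sites are split into high/low affinity tiers at the ``tier_quantile``
    of baseline signal within each (factor, end_kind).  ``frac_bound`` is
    presence/absence; ``rel_signal`` is the mean signal over retained
    sites divided by the mean baseline signal over all baseline sites.
    Both are exactly 1 at the baseline timepoint.
    """
    if baseline not in timecourse:
        raise ValueError("baseline timepoint %r missing from timecourse" % baseline)
    labels = order if order is not None else list(timecourse)
    base = _site_table(timecourse[baseline])
    if base.empty:
        raise ValueError("baseline timepoint has no assignments")
    tiers = []
    for (factor, kind), grp in base.groupby(["factor", "end_kind"]):
        cut = grp["signal"].quantile(tier_quantile)
        t = grp.copy()
        t["tier"] = np.where(t["signal"] >= cut, "high", "low")
        tiers.append(t)
    base = pd.concat(tiers, ignore_index=True)
    key_cols = ["gene_id", "end_kind", "anchor", "factor"]
    rows = []
    for label in labels:
        sites = _site_table(timecourse[label])
        merged = base.merge(sites, on=key_cols, how="left", suffixes=("_base", ""))
        merged["bound"] = merged["signal"].notna()
        for (factor, kind, tier), grp in merged.groupby(["factor", "end_kind", "tier"]):
            n = len(grp)
            frac = float(grp["bound"].mean())
            retained = grp.loc[grp["bound"], "signal"]
            rel = float(retained.mean() / grp["signal_base"].mean()) if len(retained) else 0.0
            rows.append(
                dict(timepoint=label, factor=factor, end_kind=kind, tier=tier,
                     n_baseline=n, frac_bound=frac, rel_signal=rel)
            )
        # pooled row across factors/ends/tiers
        n = len(merged)
        retained = merged.loc[merged["bound"], "signal"]
        rows.append(
            dict(timepoint=label, factor="all", end_kind="all", tier="all",
                 n_baseline=n, frac_bound=float(merged["bound"].mean()),
                 rel_signal=float(retained.mean() / merged["signal_base"].mean())
                 if len(retained) else 0.0)
        )
    return pd.DataFrame(rows)
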