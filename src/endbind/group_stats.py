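"""Expression comparisons across binding categories, strata and loop groups.

Expression values are summarised on a log2 scale with a pseudocount of 1
before testing.  Unpaired t-tests, Wilcoxon rank-sum tests and
chi-squared tests are available per comparison, with Benjamini-Hochberg
FDR columns emitted alongside the raw p-values.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TESTS = ("t_unpaired", "wilcoxon_ranksum", "chi_squared")


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def compare_expression(
    expression,
    grouping,
    test: str = "t_unpaired",
    pairs: list | None = None,
    pseudocount: float = 1.0,
    min_group: int = 2,
) -> pd.DataFrame:
    """Pairwise group comparisons of log2(expression + pseudocount).

    ``expression`` maps gene_id to a value (Series/dict); ``grouping``
    maps gene_id to a label.  All unordered label pairs are compared
    unless ``pairs`` restricts them.  Groups below ``min_group`` defined
    values are skipped with a log message.
    """
    if test not in ("t_unpaired", "wilcoxon_ranksum"):
        raise ValueError("test must be t_unpaired or wilcoxon_ranksum, got %r" % test)
    expr = pd.Series(expression, dtype=float)
    grp = pd.Series(grouping)
    df = pd.DataFrame({"value": np.log2(expr + pseudocount), "group": grp}).dropna()
    by_group = {g: s["value"].to_numpy() for g, s in df.groupby("group")}
    labels = sorted(by_group)
    todo = pairs if pairs is not None else list(itertools.combinations(labels, 2))
    rows = []
    for a, b in todo:
        xa, xb = by_group.get(a, np.array([])), by_group.get(b, np.array([]))
        if len(xa) < min_group or len(xb) < min_group:
            logger.info("skipping degenerate comparison %s vs %s (n=%d, %d)", a, b, len(xa), len(xb))
            continue
        if test == "t_unpaired":
            stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        else:
            stat, p = stats.ranksums(xa, xb)
        rows.append(
            dict(group_a=a, group_b=b, n_a=len(xa), n_b=len(xb),
                 mean_a=float(xa.mean()), mean_b=float(xb.mean()),
                 statistic=float(stat), p_value=float(p), test=test)
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = _bh_fdr(out["p_value"].to_numpy())
    return out


def quantile_summary(expression, grouping, qs=(0.1, 0.25, 0.5, 0.75, 0.9),
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-group log2-expression quantiles (tabular stand-in for ridge plots)."""
    expr = pd.Series(expression, dtype=float)
    grp = pd.Series(grouping)
    df = pd.DataFrame({"value": np.log2(expr + pseudocount), "group": grp}).dropna()
    rows = []
    for g, s in df.groupby("group"):
        row = {"group": g, "n": len(s)}
        for q in qs:
            row["q%02d" % int(q * 100)] = float(s["value"].quantile(q))
        rows.append(row)
    return pd.DataFrame(rows)


def _two_by_two(n1_yes: int, n1: int, n2_yes: int, n2: int) -> dict:
    table = np.array([[n1_yes, n1 - n1_yes], [n2_yes, n2 - n2_yes]])
    flagged = False
    if (table == 0).any():
        _, p = stats.fisher_exact(table)
        chi2 = np.nan
        flagged = True
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return dict(statistic=float(chi2) if np.isfinite(chi2) else np.nan,
                p_value=float(p), exact_fallback=flagged)


def biotype_binding_fractions(calls, genes) -> pd.DataFrame:
    """Per-biotype fractions of genes bound at the 5' and 3' ends.

    For every biotype, the TES fraction is compared with the TSS fraction
    by a 2x2 chi-squared test (Fisher's exact fallback for zero cells,
    flagged).  Genes with an unrecognised biotype fall into ``other``.
    """
    from endbind.categories import calls_to_frame

    cdf = calls_to_frame(calls) if not isinstance(calls, pd.DataFrame) else calls
    biotype = {
        g.gene_id: (g.biotype if g.biotype in ("protein_coding", "lncRNA") else "other")
        for g in genes
    }
    cdf = cdf.copy()
    cdf["biotype"] = cdf["gene_id"].map(biotype)
    rows = []
    for bt, grp in cdf.groupby("biotype"):
        n = len(grp)
        n5 = int((grp["state_5p"] != "none").sum())
        n3 = int((grp["state_3p"] != "none").sum())
        res = _two_by_two(n3, n, n5, n)
        rows.append(
            dict(biotype=bt, n_genes=n, frac_tss=n5 / n, frac_tes=n3 / n,
                 chi2=res["statistic"], p_value=res["p_value"],
                 exact_fallback=res["exact_fallback"])
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = _bh_fdr(out["p_value"].to_numpy())
    return out


def compare_binding_fraction(calls_a, calls_b, end: str = "3p") -> dict:
    """Chi-squared comparison of end-binding fractions between two gene sets."""
    from endbind.categories import calls_to_frame

    col = "state_%s" % end
    a = calls_to_frame(calls_a) if not isinstance(calls_a, pd.DataFrame) else calls_a
    b = calls_to_frame(calls_b) if not isinstance(calls_b, pd.DataFrame) else calls_b
    res = _two_by_two(
        int((a[col] != "none").sum()), len(a), int((b[col] != "none").sum()), len(b)
    )
    res.update(n_a=len(a), n_b=len(b), test="chi_squared")
    return res
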