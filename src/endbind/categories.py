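"""The 16-category two-factor end-binding classification.

Each gene's 5' and 3' ends are summarised as one of four states — no
binding, factor A only, factor B only, or both factors — giving sixteen
(5' state, 3' state) configurations, numbered 1-16 with 16 the fully
unbound cell.  Factor names default to MYC (A) and MAX (B) but are
parameters, so the same scheme applies to MYCN or MXD-family factors.

Only some of the category numbers are pinned down by published usage
(e.g. 9 = A/B at 5' only, 7 = B-only at both ends, 10/11/12 all have
both factors at the 5' end, 2/6/13 are the TES-only cells, 16 = unbound);
the remaining cells of the default numbering complete the bijection and
can be overridden — downstream code keys on the state pair, never the
integer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd


class EndState(str, enum.Enum):
    NONE = "none"
    A_ONLY = "A_only"
    B_ONLY = "B_only"
    BOTH = "A_and_B"

    @classmethod
    def from_presence(cls, has_a: bool, has_b: bool) -> "EndState":
        if has_a and has_b:
            return cls.BOTH
        if has_a:
            return cls.A_ONLY
        if has_b:
            return cls.B_ONLY
        return cls.NONE


#: default (state_5p, state_3p) -> category number bijection
DEFAULT_CATEGORY_MAP = {
    (EndState.A_ONLY, EndState.NONE): 1,
    (EndState.NONE, EndState.A_ONLY): 2,
    (EndState.A_ONLY, EndState.A_ONLY): 3,
    (EndState.A_ONLY, EndState.B_ONLY): 4,
    (EndState.B_ONLY, EndState.NONE): 5,
    (EndState.NONE, EndState.B_ONLY): 6,
    (EndState.B_ONLY, EndState.B_ONLY): 7,
    (EndState.B_ONLY, EndState.A_ONLY): 8,
    (EndState.BOTH, EndState.NONE): 9,
    (EndState.BOTH, EndState.B_ONLY): 10,
    (EndState.BOTH, EndState.A_ONLY): 11,
    (EndState.BOTH, EndState.BOTH): 12,
    (EndState.NONE, EndState.BOTH): 13,
    (EndState.A_ONLY, EndState.BOTH): 14,
    (EndState.B_ONLY, EndState.BOTH): 15,
    (EndState.NONE, EndState.NONE): 16,
}

#: constraints any admissible numbering must satisfy (name -> predicate input)
_MAP_CONSTRAINTS = [
    ("cat 3 = (A_only, A_only)", lambda m: m[(EndState.A_ONLY, EndState.A_ONLY)] == 3),
    ("cat 4 = (A_only, B_only)", lambda m: m[(EndState.A_ONLY, EndState.B_ONLY)] == 4),
    ("cat 7 = (B_only, B_only)", lambda m: m[(EndState.B_ONLY, EndState.B_ONLY)] == 7),
    ("cat 9 = (both, none)", lambda m: m[(EndState.BOTH, EndState.NONE)] == 9),
    ("cat 10 = (both, B_only)", lambda m: m[(EndState.BOTH, EndState.B_ONLY)] == 10),
    ("cat 12 = (both, both)", lambda m: m[(EndState.BOTH, EndState.BOTH)] == 12),
    (
        "cats 10,11,12 all have 5' state = both",
        lambda m: all(
            s5 == EndState.BOTH for (s5, _s3), c in m.items() if c in (10, 11, 12)
        ),
    ),
    (
        "cats 2,6,13 are TES-only (5' none, 3' bound)",
        lambda m: all(
            s5 == EndState.NONE and s3 != EndState.NONE
            for (s5, s3), c in m.items()
            if c in (2, 6, 13)
        ),
    ),
    ("cat 16 = (none, none)", lambda m: m[(EndState.NONE, EndState.NONE)] == 16),
]


def validate_category_map(category_map: dict) -> None:
    """Check bijectivity and every published-usage constraint.

    Raises ``ValueError`` naming the violated constraint.
    """
    pairs = [(a, b) for a in EndState for b in EndState]
    if sorted(category_map.keys()) != sorted(pairs):
        raise ValueError("category map must cover all 16 (state_5p, state_3p) pairs")
    if sorted(category_map.values()) != list(range(1, 17)):
        raise ValueError("category map values must be a bijection onto 1..16")
    for name, ok in _MAP_CONSTRAINTS:
        if not ok(category_map):
            raise ValueError("category map violates constraint: %s" % name)


@dataclass
class CategoryCall:
    gene_id: str
    state_5p: EndState
    state_3p: EndState
    category: int


def end_states(assignments: pd.DataFrame, genes, factor_a: str = "MYC", factor_b: str = "MAX") -> pd.DataFrame:
    """Per-gene (5' state, 3' state) from assignment presence/absence."""
    present: dict[tuple, set] = {}
    if len(assignments):
        sub = assignments[assignments["factor"].isin([factor_a, factor_b])]
        for (gid, kind), grp in sub.groupby(["gene_id", "end_kind"]):
            present[(gid, kind)] = set(grp["factor"])
    rows = []
    for g in genes:
        s5 = EndState.from_presence(
            factor_a in present.get((g.gene_id, "TSS"), ()),
            factor_b in present.get((g.gene_id, "TSS"), ()),
        )
        s3 = EndState.from_presence(
            factor_a in present.get((g.gene_id, "TES"), ()),
            factor_b in present.get((g.gene_id, "TES"), ()),
        )
        rows.append((g.gene_id, s5, s3))
    return pd.DataFrame(rows, columns=["gene_id", "state_5p", "state_3p"])


def classify(
    assignments: pd.DataFrame,
    genes,
    factor_a: str = "MYC",
    factor_b: str = "MAX",
    category_map: dict | None = None,
):
    """One :class:`CategoryCall` per annotated gene.

    Peak multiplicity is ignored: a gene with three factor-A peaks in its
    TSS window is classified identically to one with a single peak.
    """
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    validate_category_map(cmap)
    states = end_states(assignments, genes, factor_a, factor_b)
    return [
        CategoryCall(r.gene_id, r.state_5p, r.state_3p, cmap[(r.state_5p, r.state_3p)])
        for r in states.itertuples()
    ]


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "state_5p": [c.state_5p.value for c in calls],
            "state_3p": [c.state_3p.value for c in calls],
            "category": [c.category for c in calls],
        }
    )


def category_summary(calls) -> pd.DataFrame:
    """Gene counts and fractions per category (all 16 rows, zeros kept)."""
    df = calls_to_frame(calls)
    counts = df["category"].value_counts().reindex(range(1, 17), fill_value=0)
    total = len(df)
    out = pd.DataFrame(
        {
            "category": counts.index,
            "n_genes": counts.to_numpy(),
            "fraction": counts.to_numpy() / total if total else 0.0,
        }
    )
    return out.reset_index(drop=True)
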