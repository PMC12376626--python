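"""Gene models: per-transcript TSS/TES anchors, biotypes and neighbour relations.

A gene's 5' and 3' ends are defined by the start and end sites of each of
its annotated transcripts, so a gene carries a *set* of TSS anchors and a
set of TES anchors.  Adjacent genes on a chromosome stand in one of three
orientations — head-to-head (5' ends facing), head-to-tail (3' end of one
facing the 5' end of the next) or tail-to-tail (3' ends facing) — which
downstream modules use for dual assignment, ambiguity filtering and dyad
discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd

#: source-annotation biotype strings folded into the three-way scheme
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
}

ANCHOR_DEDUP_BP = 10


class AnnotationError(ValueError):
    """Raised for malformed annotation records; carries offending line numbers."""


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "other"
    tss_anchors: tuple = ()
    tes_anchors: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -, got %r" % self.strand)
        if self.start > self.end:
            raise ValueError("gene %s: start > end" % self.gene_id)
        self.tss_anchors = tuple(sorted(set(int(a) for a in self.tss_anchors)))
        self.tes_anchors = tuple(sorted(set(int(a) for a in self.tes_anchors)))
        if not self.tss_anchors or not self.tes_anchors:
            raise ValueError("gene %s: empty anchor set" % self.gene_id)
        for a in self.tss_anchors + self.tes_anchors:
            if not (self.start <= a <= self.end):
                raise ValueError("gene %s: anchor %d outside span" % (self.gene_id, a))

    def anchors(self, end_kind: str) -> tuple:
        return self.tss_anchors if end_kind == "TSS" else self.tes_anchors


@dataclass
class GenePairRelation:
    gene_a: str  # leftmost by coordinate
    gene_b: str
    chrom: str
    orientation: str  # head_to_head | head_to_tail | tail_to_tail
    end_gap: int  # signed distance between nearest facing anchors (<=0: overlap)
    overlapping: bool = False
    # for head_to_tail pairs: which member contributes the facing TES / TSS
    tes_gene: str | None = None
    tss_gene: str | None = None


def _orientation(strand_left: str, strand_right: str) -> str:
    if strand_left == "-" and strand_right == "+":
        return "head_to_head"
    if strand_left == "+" and strand_right == "-":
        return "tail_to_tail"
    return "head_to_tail"


def _dedup_anchors(anchors, strand: str, end_kind: str, tol: int = ANCHOR_DEDUP_BP):
    """Collapse anchors within `tol` bp of each other on one gene end.

    Keeps the most upstream survivor for TSS clusters and the most
    downstream one for TES clusters, in the gene's reading direction.
    """
    if not anchors:
        return ()
    ordered = sorted(set(anchors), reverse=(strand == "-"))  # reading-direction order
    clusters, current = [], [ordered[0]]
    for a in ordered[1:]:
        if abs(a - current[-1]) <= tol:
            current.append(a)
        else:
            clusters.append(current)
            current = [a]
    clusters.append(current)
    keep = [c[0] if end_kind == "TSS" else c[-1] for c in clusters]
    return tuple(sorted(keep))


def load_annotation(path, biotype_map: dict | None = None, dedup_bp: int = ANCHOR_DEDUP_BP):
    """Parse a GTF/GFF file into a coordinate-sorted list of :class:`GeneModel`.

    Each transcript contributes one TSS and one TES anchor (by strand);
    gene-level anchor sets are the deduplicated unions.  Records with a
    start greater than their end raise :class:`AnnotationError` naming the
    line numbers; records without a usable strand are rejected.
    """
    biotype_map = dict(DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map)
    kept_lines, bad_lines, rejected = [], [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                bad_lines.append((lineno, "fewer than 9 fields"))
                continue
            try:
                s, e = int(parts[3]), int(parts[4])
            except ValueError:
                bad_lines.append((lineno, "non-integer coordinates"))
                continue
            if s > e:
                bad_lines.append((lineno, "start > end"))
                continue
            if parts[6] not in ("+", "-"):
                rejected += 1
                continue
            kept_lines.append(line)
    if bad_lines:
        raise AnnotationError(
            "malformed annotation records: "
            + "; ".join("line %d (%s)" % (n, why) for n, why in bad_lines[:20])
        )
    db = gffutils.create_db(
        "".join(kept_lines),
        ":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    spans: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "transcript", "mRNA"):
            continue
        gid = (feat.attributes.get("gene_id") or [None])[0]
        if gid is None:
            continue
        info = spans.setdefault(
            gid,
            {"chrom": feat.seqid, "strand": feat.strand, "start": feat.start,
             "end": feat.end, "biotype_src": None, "tss": [], "tes": []},
        )
        info["start"] = min(info["start"], feat.start)
        info["end"] = max(info["end"], feat.end)
        src = (feat.attributes.get("gene_type") or feat.attributes.get("gene_biotype") or [None])[0]
        if src is not None:
            info["biotype_src"] = src
        if feat.featuretype in ("transcript", "mRNA"):
            if feat.strand == "+":
                info["tss"].append(feat.start)
                info["tes"].append(feat.end)
            else:
                info["tss"].append(feat.end)
                info["tes"].append(feat.start)

    genes = []
    for gid, info in spans.items():
        tss, tes = info["tss"], info["tes"]
        if not tss:  # gene record without transcripts: the span defines one
            if info["strand"] == "+":
                tss, tes = [info["start"]], [info["end"]]
            else:
                tss, tes = [info["end"]], [info["start"]]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=info["chrom"],
                strand=info["strand"],
                start=info["start"],
                end=info["end"],
                biotype=biotype_map.get(info["biotype_src"], "other"),
                tss_anchors=_dedup_anchors(tss, info["strand"], "TSS", dedup_bp),
                tes_anchors=_dedup_anchors(tes, info["strand"], "TES", dedup_bp),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _facing(gene: GeneModel, side: str):
    """(end_kind, anchor) of a gene's left or right extremity."""
    if side == "right":
        kind = "TES" if gene.strand == "+" else "TSS"
        return kind, max(gene.anchors(kind))
    kind = "TSS" if gene.strand == "+" else "TES"
    return kind, min(gene.anchors(kind))


def pair_relations(genes, max_gap: int = 5000):
    """Orientation relations between coordinate-adjacent genes.

    A relation is emitted for each pair of genes that are consecutive in
    the coordinate sort on a chromosome and whose nearest facing anchors
    lie at most ``max_gap`` bp apart.  Overlapping genes yield a relation
    with ``end_gap <= 0`` and the ``overlapping`` flag set.
    """
    rels = []
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    for left, right in zip(ordered, ordered[1:]):
        if left.chrom != right.chrom:
            continue
        kind_l, anchor_l = _facing(left, "right")
        kind_r, anchor_r = _facing(right, "left")
        gap = anchor_r - anchor_l
        if gap > max_gap:
            continue
        orient = _orientation(left.strand, right.strand)
        tes_gene = tss_gene = None
        if orient == "head_to_tail":
            tes_gene = left.gene_id if kind_l == "TES" else right.gene_id
            tss_gene = right.gene_id if kind_l == "TES" else left.gene_id
        rels.append(
            GenePairRelation(
                gene_a=left.gene_id,
                gene_b=right.gene_id,
                chrom=left.chrom,
                orientation=orient,
                end_gap=int(gap),
                overlapping=bool(gap <= 0 or left.end >= right.start),
                tes_gene=tes_gene,
                tss_gene=tss_gene,
            )
        )
    return rels


def genes_to_frame(genes) -> pd.DataFrame:
    """Flat gene-model table (anchor sets comma-joined) for reporting."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "biotype": [g.biotype for g in genes],
            "tss_anchors": [",".join(map(str, g.tss_anchors)) for g in genes],
            "tes_anchors": [",".join(map(str, g.tes_anchors)) for g in genes],
        }
    )


def mirror_genes(genes, axis: int):
    """Mirror gene models around coordinate `axis` and flip strands.

    Anchor derivation commutes with this transform (an involution used in
    the test suite): a mirrored '+' gene's TSS set is the mirrored TES set
    of the original.
    """
    out = []
    for g in genes:
        out.append(
            replace(
                g,
                strand="-" if g.strand == "+" else "+",
                start=axis - g.end,
                end=axis - g.start,
                tss_anchors=tuple(axis - a for a in g.tss_anchors),
                tes_anchors=tuple(axis - a for a in g.tes_anchors),
            )
        )
    return sorted(out, key=lambda g: (g.chrom, g.start, g.gene_id))
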