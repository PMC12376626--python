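"""Synthetic fixture generator with recorded ground truth.

Builds an internally consistent bundle — gene annotation, per-factor
ChIP peak sets, strand-specific coverage, chromatin loops and an
expression table — on one synthetic chromosome, together with a ground
truth record sufficient to score every downstream module exactly:

* genes are laid out as isolated singletons or adjacent pairs in
  head-to-head, head-to-tail or tail-to-tail orientation with variable
  intergenic spacing;
* each gene is planted with one of the 16 two-factor end-binding
  configurations; peaks carry lognormal signal in two affinity tiers and
  normally jittered summits kept inside the assignment window;
* a configurable fraction of head-to-tail pairs become *dyads*: the two
  genes share a single solitary intergenic factor-A site (optionally
  co-bound by factor B) and carry planted expression responses;
* stranded coverage is Poisson per 50-bp tile, with read-through past
  the TES at a planted per-gene fraction of the gene's depth over an
  exponential-length tail;
* loops place anchors at gene ends according to a planted A-H contact
  group; twenty stand-in co-factors are planted with class-specific
  preferences for co-occupancy profiling.

All randomness flows through one seeded generator, so a seed fully
determines every output byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from endbind import io as ebio
from endbind.annotation import GeneModel
from endbind.categories import DEFAULT_CATEGORY_MAP, EndState

STATE_KEYS = {s.value: s for s in EndState}

#: default category mix, set to the reported marginal structure of the
#: human/mouse ChIP compendia: roughly half of genes bound at either end,
#: about 17.5% with 3'-end binding, promoter-only co-binding (category 9)
#: the modal bound configuration, the MYC-5'/MYC-3' and MYC-5'/MAX-3'
#: cells (3 and 4) collectively <0.5% of bound genes, and solitary MYC
#: several-fold rarer than solitary MAX.
DEFAULT_CATEGORY_PROBS = {
    1: 0.030, 2: 0.010, 3: 0.001, 4: 0.001, 5: 0.100, 6: 0.025,
    7: 0.020, 8: 0.003, 9: 0.220, 10: 0.025, 11: 0.010, 12: 0.040,
    13: 0.030, 14: 0.005, 15: 0.005, 16: 0.475,
}

DEFAULT_ORIENTATION_MIX = {
    "isolated": 0.40,
    "head_to_head": 0.15,
    "head_to_tail": 0.30,
    "tail_to_tail": 0.15,
}

DEFAULT_LOOP_GROUP_PROBS = {
    "A": 0.10, "B": 0.08, "C": 0.07, "D": 0.10,
    "E": 0.10, "F": 0.10, "G": 0.10, "H": 0.35,
}

RESPONSES = ("positive", "none", "negative")
RESPONSE_FOLD = {"positive": 4.0, "none": 1.0, "negative": 0.25}


@dataclass
class SimulationConfig:
    seed: int = 42
    n_genes: int = 500
    chrom: str = "chrS"
    chrom_length: int | None = None  # computed from packing when None
    radius: int = 2500
    orientation_mix: dict = field(default_factory=lambda: dict(DEFAULT_ORIENTATION_MIX))
    category_probs: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS))
    factor_a: str = "MYC"
    factor_b: str = "MAX"
    # lognormal binding-signal law per affinity tier: (mu, sigma) of log signal
    signal_law: dict = field(
        default_factory=lambda: {"high": (3.4, 0.5), "low": (2.1, 0.5)}
    )
    p_high_affinity: float = 0.5
    summit_jitter_sd: float = 300.0
    # gene/intergenic geometry (bp)
    gene_length_range: tuple = (8000, 30000)
    pair_gap_range: tuple = (6000, 12000)
    dyad_gap_range: tuple = (1200, 3800)
    unit_gap_range: tuple = (25000, 40000)
    p_second_transcript: float = 0.25
    # read-through
    dog_fraction_law: dict = field(
        default_factory=lambda: {"TES_bound": (3.0, 7.0), "TES_unbound": (1.0, 9.0)}
    )
    dog_fraction_values: tuple | None = None  # fixed fractions cycled over genes
    dog_tail_mean: float = 2000.0
    dog_tail_max: float = 15000.0
    depth: float = 100.0  # mean reads per 500-bp window
    tile: int = 50
    # loops / contacts
    loop_group_probs: dict = field(default_factory=lambda: dict(DEFAULT_LOOP_GROUP_PROBS))
    anchor_width: int = 400
    anchor_jitter: int = 500
    # dyads
    dyad_fraction: float = 0.5  # fraction of head-to-tail pairs made dyads
    dyad_cobind_prob: float = 0.5
    # RNAPII planting
    rnapii_probs: dict = field(
        default_factory=lambda: {"both": 0.70, "tss_only": 0.15, "none": 0.15}
    )
    # biotypes; lncRNA genes draw TES-bound categories at a higher rate
    biotype_probs: dict = field(
        default_factory=lambda: {"protein_coding": 0.70, "lncRNA": 0.20, "other": 0.10}
    )
    lncRNA_tes_multiplier: float = 1.5
    # expression: log2 mean structure + noise
    expression_law: dict = field(
        default_factory=lambda: {
            "base_log2": 3.0,
            "tss_both": 2.0,
            "tss_single": 1.0,
            "tes_any": 0.5,
            "sigma_log2": 0.8,
            "timepoint_sigma_log2": 0.3,
            "dyad_sigma_log2": 0.05,
        }
    )
    timepoints: tuple = ("0h", "4h")
    # co-occupancy stand-ins
    n_cofactors: int = 20
    cofactor_plant_prob: float = 0.8
    cofactor_background: int = 5
    p_intragenic_site: float = 0.15
    n_distal_sites: int | None = None  # default n_genes // 10

    def __post_init__(self):
        for name in ("orientation_mix", "category_probs", "loop_group_probs",
                     "rnapii_probs", "biotype_probs"):
            probs = getattr(self, name)
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError("%s must sum to 1 (got %.6f)" % (name, total))
        if not 0 <= self.dyad_fraction <= 1:
            raise ValueError("dyad_fraction must lie in [0, 1]")


@dataclass
class Bundle:
    config: SimulationConfig
    genes: list
    transcripts: dict  # gene_id -> list of (start, end) transcript spans
    peaks: pd.DataFrame  # steady-state (post-induction) peak set, all factors
    peaks_by_timepoint: dict  # timepoint -> peak DataFrame
    coverage: dict  # strand -> bedGraph-style DataFrame
    loops: pd.DataFrame
    expression: pd.DataFrame  # index gene_id, columns timepoints
    cofactor_peaks: dict  # factor name -> peak DataFrame
    truth: dict
    chrom_length: int = 0

    def write(self, outdir) -> dict:
        """Write every fixture file; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["annotation"] = outdir / "annotation.gtf"
        write_gtf(self.genes, self.transcripts, paths["annotation"])
        for factor in sorted(self.peaks["factor"].unique()):
            p = outdir / ("peaks_%s.narrowPeak" % factor)
            ebio.write_narrowpeak(self.peaks[self.peaks["factor"] == factor], p)
            paths["peaks_%s" % factor] = p
        for tp, df in self.peaks_by_timepoint.items():
            p = outdir / ("peaks_%s_%s.narrowPeak" % (self.config.factor_a, tp))
            ebio.write_narrowpeak(df[df["factor"] == self.config.factor_a], p)
            paths["peaks_%s_%s" % (self.config.factor_a, tp)] = p
        for strand, tag in (("+", "plus"), ("-", "minus")):
            p = outdir / ("coverage_%s.bedGraph" % tag)
            ebio.write_bedgraph(self.coverage[strand], p)
            paths["coverage_%s" % tag] = p
        paths["loops"] = outdir / "loops.bedpe"
        ebio.write_bedpe(self.loops, paths["loops"])
        paths["expression"] = outdir / "expression.tsv"
        self.expression.rename_axis("gene_id").reset_index().to_csv(
            paths["expression"], sep="\t", index=False, float_format="%.6g"
        )
        cof_dir = outdir / "cofactors"
        cof_dir.mkdir(exist_ok=True)
        for name in sorted(self.cofactor_peaks):
            p = cof_dir / ("%s.narrowPeak" % name)
            ebio.write_narrowpeak(self.cofactor_peaks[name], p)
            paths["cofactor_%s" % name] = p
        paths["truth"] = outdir / "truth.json"
        Path(paths["truth"]).write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


def write_gtf(genes, transcripts, path) -> None:
    lines = []
    for g in genes:
        attrs = 'gene_id "%s"; gene_type "%s";' % (g.gene_id, _biotype_src(g.biotype))
        lines.append(
            "\t".join(
                [g.chrom, "endbind_sim", "gene", str(g.start), str(g.end), ".", g.strand, ".", attrs]
            )
        )
        for i, (ts, te) in enumerate(transcripts[g.gene_id], start=1):
            tattrs = 'gene_id "%s"; transcript_id "%s.T%d"; gene_type "%s";' % (
                g.gene_id, g.gene_id, i, _biotype_src(g.biotype)
            )
            lines.append(
                "\t".join(
                    [g.chrom, "endbind_sim", "transcript", str(ts), str(te), ".", g.strand, ".", tattrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _biotype_src(biotype: str) -> str:
    return {"protein_coding": "protein_coding", "lncRNA": "lncRNA"}.get(biotype, "misc_RNA")


def _category_states(cmap=DEFAULT_CATEGORY_MAP):
    return {cat: pair for pair, cat in cmap.items()}


def draw_dog_fractions(rng, law: dict, group: str, n: int) -> np.ndarray:
    """Per-gene read-through fractions from the per-group beta law."""
    a, b = law[group]
    return rng.beta(a, b, size=n)


def _sample_category(rng, probs_items, tes_multiplier, is_lnc, states_by_cat):
    cats = [c for c, _ in probs_items]
    w = np.array([p for _, p in probs_items], dtype=float)
    if is_lnc and tes_multiplier != 1.0:
        for i, c in enumerate(cats):
            if states_by_cat[c][1] != EndState.NONE:
                w[i] *= tes_multiplier
    w = w / w.sum()
    return cats[rng.choice(len(cats), p=w)]


def simulate(config: SimulationConfig | None = None) -> Bundle:
    """Generate the full fixture bundle for the given configuration."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    states_by_cat = _category_states()
    probs_items = sorted(cfg.category_probs.items())
    orient_items = sorted(cfg.orientation_mix.items())
    loop_items = sorted(cfg.loop_group_probs.items())
    rnapii_items = sorted(cfg.rnapii_probs.items())
    biotype_items = sorted(cfg.biotype_probs.items())

    # ---- 1. lay out genes -------------------------------------------------
    cursor = 100_000
    gene_rows = []  # dicts
    pair_dyads = []  # (upstream_gene_idx, downstream_gene_idx) raw indices
    gi = 0
    while gi < cfg.n_genes:
        unit = orient_items[rng.choice(len(orient_items), p=[p for _, p in orient_items])][0]
        if unit == "isolated" or gi == cfg.n_genes - 1:
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(*cfg.gene_length_range))
            gene_rows.append(dict(start=cursor, end=cursor + length - 1, strand=strand, unit=unit))
            cursor += length - 1 + int(rng.integers(*cfg.unit_gap_range))
            gi += 1
            continue
        # pair unit
        is_dyad = unit == "head_to_tail" and rng.random() < cfg.dyad_fraction
        gap_range = cfg.dyad_gap_range if is_dyad else cfg.pair_gap_range
        gap = int(rng.integers(*gap_range))
        if unit == "head_to_head":
            s_left, s_right = "-", "+"
        elif unit == "tail_to_tail":
            s_left, s_right = "+", "-"
        else:
            s = "+" if rng.random() < 0.5 else "-"
            s_left = s_right = s
        len_l = int(rng.integers(*cfg.gene_length_range))
        len_r = int(rng.integers(*cfg.gene_length_range))
        left = dict(start=cursor, end=cursor + len_l - 1, strand=s_left, unit=unit)
        rstart = left["end"] + gap
        right = dict(start=rstart, end=rstart + len_r - 1, strand=s_right, unit=unit)
        gene_rows.append(left)
        gene_rows.append(right)
        if is_dyad:
            if s_left == "+":  # left TES faces right TSS
                pair_dyads.append((gi, gi + 1))
            else:  # right gene reads leftward: right TES faces left TSS
                pair_dyads.append((gi + 1, gi))
        cursor = right["end"] + int(rng.integers(*cfg.unit_gap_range))
        gi += 2
    gene_rows = gene_rows[: cfg.n_genes]
    pair_dyads = [(u, d) for u, d in pair_dyads if u < cfg.n_genes and d < cfg.n_genes]
    last_end = max(r["end"] for r in gene_rows)
    if cfg.chrom_length is not None and last_end + 200_000 > cfg.chrom_length:
        raise ValueError(
            "infeasible packing: %d genes need %d bp, chrom_length=%d"
            % (cfg.n_genes, last_end + 200_000, cfg.chrom_length)
        )

    dyad_members = {i for pair in pair_dyads for i in pair}

    # ---- 2. transcripts / anchors ----------------------------------------
    genes, transcripts = [], {}
    for i, row in enumerate(gene_rows):
        gid = "G%04d" % i
        row["gene_id"] = gid
        spans = [(row["start"], row["end"])]
        if rng.random() < cfg.p_second_transcript:
            if row["strand"] == "+":
                spans.append((row["start"] + 400, row["end"] - 800))
            else:
                spans.append((row["start"] + 800, row["end"] - 400))
        biotype = biotype_items[rng.choice(len(biotype_items), p=[p for _, p in biotype_items])][0]
        tss = [s if row["strand"] == "+" else e for s, e in spans]
        tes = [e if row["strand"] == "+" else s for s, e in spans]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=cfg.chrom,
                strand=row["strand"],
                start=row["start"],
                end=row["end"],
                biotype=biotype,
                tss_anchors=tuple(tss),
                tes_anchors=tuple(tes),
            )
        )
        transcripts[gid] = spans

    def primary_anchor(g: GeneModel, kind: str) -> int:
        # most-upstream TSS / most-downstream TES, in reading direction
        anchors = g.anchors(kind)
        if kind == "TSS":
            return min(anchors) if g.strand == "+" else max(anchors)
        return max(anchors) if g.strand == "+" else min(anchors)

    # ---- 3. categories ----------------------------------------------------
    gene_truth = {}
    for i, g in enumerate(genes):
        if i in dyad_members:
            cat = None  # decided by the shared intergenic site below
        else:
            cat = _sample_category(
                rng, probs_items, cfg.lncRNA_tes_multiplier, g.biotype == "lncRNA", states_by_cat
            )
        gene_truth[g.gene_id] = dict(
            biotype=g.biotype, strand=g.strand, unit=gene_rows[i]["unit"],
            is_dyad_member=i in dyad_members, category=cat,
        )

    # ---- 4. peaks ----------------------------------------------------------
    jitter_cap = cfg.radius - 100
    peak_rows, peak_truth = [], []
    counter = [0]

    def add_peak(factor, summit, signal, note):
        counter[0] += 1
        pid = "%s_p%05d" % (factor, counter[0])
        start = max(1, int(summit) - 150)
        end = int(summit) + 150
        peak_rows.append(
            dict(peak_id=pid, factor=factor, sample="", chrom=cfg.chrom,
                 start=start, end=end, summit=int(summit), signal=float(signal))
        )
        peak_truth.append(dict(peak_id=pid, factor=factor, **note))
        return pid

    def draw_signal(tier):
        mu, sigma = cfg.signal_law[tier]
        return float(np.exp(rng.normal(mu, sigma)))

    def jitter():
        return float(np.clip(rng.normal(0.0, cfg.summit_jitter_sd), -jitter_cap, jitter_cap))

    state_has = {
        EndState.NONE: (False, False),
        EndState.A_ONLY: (True, False),
        EndState.B_ONLY: (False, True),
        EndState.BOTH: (True, True),
    }

    for i, g in enumerate(genes):
        t = gene_truth[g.gene_id]
        if t["is_dyad_member"]:
            continue
        s5, s3 = states_by_cat[t["category"]]
        t["state_5p"], t["state_3p"] = s5.value, s3.value
        for kind, state in (("TSS", s5), ("TES", s3)):
            anchor = primary_anchor(g, kind)
            for factor, present in zip((cfg.factor_a, cfg.factor_b), state_has[state]):
                if not present:
                    continue
                tier = "high" if rng.random() < cfg.p_high_affinity else "low"
                add_peak(
                    factor, anchor + jitter(), draw_signal(tier),
                    dict(gene_id=g.gene_id, end_kind=kind, tier=tier, region_class=kind,
                         dyad_site=False),
                )

    # dyad sites: one solitary intergenic factor-A peak per pair
    dyad_truth = []
    dyad_peak_ids_low = []
    for u_idx, d_idx in pair_dyads:
        up, down = genes[u_idx], genes[d_idx]
        tes_a = primary_anchor(up, "TES")
        tss_a = primary_anchor(down, "TSS")
        mid = (tes_a + tss_a) // 2
        affinity = "high" if rng.random() < cfg.p_high_affinity else "low"
        cobound = rng.random() < cfg.dyad_cobind_prob
        sig = draw_signal(affinity)
        pid_a = add_peak(
            cfg.factor_a, mid, sig,
            dict(gene_id=None, end_kind="intergenic", tier=affinity,
                 region_class="intergenic", dyad_site=True,
                 upstream_gene=up.gene_id, downstream_gene=down.gene_id),
        )
        if affinity == "low":
            dyad_peak_ids_low.append(pid_a)
        if cobound:
            add_peak(
                cfg.factor_b, mid, draw_signal(affinity),
                dict(gene_id=None, end_kind="intergenic", tier=affinity,
                     region_class="intergenic", dyad_site=True,
                     upstream_gene=up.gene_id, downstream_gene=down.gene_id),
            )
        resp_up = RESPONSES[rng.choice(3)]
        resp_down = RESPONSES[rng.choice(3)]
        dyad_truth.append(
            dict(upstream_gene=up.gene_id, downstream_gene=down.gene_id,
                 site_affinity=affinity, cobound=bool(cobound),
                 response_up=resp_up, response_down=resp_down)
        )
        bound = EndState.BOTH if cobound else EndState.A_ONLY
        tu, td = gene_truth[up.gene_id], gene_truth[down.gene_id]
        tu["state_5p"], tu["state_3p"] = EndState.NONE.value, bound.value
        td["state_5p"], td["state_3p"] = bound.value, EndState.NONE.value
        tu["category"] = DEFAULT_CATEGORY_MAP[(EndState.NONE, bound)]
        td["category"] = DEFAULT_CATEGORY_MAP[(bound, EndState.NONE)]

    # RNAPII at gene ends
    for i, g in enumerate(genes):
        mode = rnapii_items[rng.choice(len(rnapii_items), p=[p for _, p in rnapii_items])][0]
        if i in dyad_members:
            mode = "none"  # keep dyad vicinities clean of extra structure
        gene_truth[g.gene_id]["rnapii"] = mode
        kinds = {"both": ("TSS", "TES"), "tss_only": ("TSS",), "none": ()}[mode]
        for kind in kinds:
            add_peak(
                "POLR2A", primary_anchor(g, kind) + jitter(), draw_signal("high"),
                dict(gene_id=g.gene_id, end_kind=kind, tier="high", region_class=kind,
                     dyad_site=False),
            )

    # intragenic and distal factor-A sites (enhancer-like classes)
    for i, g in enumerate(genes):
        if i in dyad_members:
            continue
        if rng.random() < cfg.p_intragenic_site:
            mid = (g.start + g.end) // 2 + int(rng.integers(-200, 201))
            tier = "high" if rng.random() < cfg.p_high_affinity else "low"
            add_peak(
                cfg.factor_a, mid, draw_signal(tier),
                dict(gene_id=g.gene_id, end_kind="intragenic", tier=tier,
                     region_class="intragenic", dyad_site=False),
            )
    desert_start = last_end + 50_000
    n_distal = cfg.n_distal_sites if cfg.n_distal_sites is not None else max(2, cfg.n_genes // 10)
    distal_positions = [desert_start + 10_000 * k for k in range(n_distal)]
    for pos in distal_positions:
        tier = "high" if rng.random() < cfg.p_high_affinity else "low"
        add_peak(
            cfg.factor_a, pos, draw_signal(tier),
            dict(gene_id=None, end_kind="distal", tier=tier, region_class="distal",
                 dyad_site=False),
        )

    peaks = pd.DataFrame(peak_rows)
    peaks = peaks[["peak_id", "factor", "sample", "chrom", "start", "end", "summit", "signal"]]
    # timepoints: low-affinity dyad sites appear only after induction
    low_set = set(dyad_peak_ids_low)
    tp0, tp1 = cfg.timepoints[0], cfg.timepoints[-1]
    peaks_by_timepoint = {
        tp0: peaks[~peaks["peak_id"].isin(low_set)].reset_index(drop=True),
        tp1: peaks.copy(),
    }

    # ---- 5. read-through fractions & coverage ------------------------------
    chrom_length = cfg.chrom_length or (desert_start + 10_000 * (n_distal + 4) + 400_000)
    if cfg.dog_fraction_values is not None:
        fractions = [
            float(cfg.dog_fraction_values[i % len(cfg.dog_fraction_values)])
            for i in range(len(genes))
        ]
    else:
        fractions = []
        for g in genes:
            bound = gene_truth[g.gene_id]["state_3p"] != EndState.NONE.value
            group = "TES_bound" if bound else "TES_unbound"
            fractions.append(float(draw_dog_fractions(rng, cfg.dog_fraction_law, group, 1)[0]))
    cov_rows = {"+": [], "-": []}
    tile = cfg.tile
    rate_per_bp = cfg.depth / 500.0

    def emit_tiles(strand, lo, hi, rate_bp):
        """Poisson tiles anchored at `lo`, last tile truncated at `hi`."""
        if hi < lo or rate_bp <= 0:
            return
        starts = np.arange(lo, hi + 1, tile)
        ends = np.minimum(starts + tile - 1, hi)
        lam = rate_bp * (ends - starts + 1)
        vals = rng.poisson(lam)
        for s, e, v in zip(starts, ends, vals):
            if v > 0:
                cov_rows[strand].append((cfg.chrom, int(s), int(e), float(v)))

    for g, frac in zip(genes, fractions):
        gene_truth[g.gene_id]["dog_fraction"] = frac
        tes = primary_anchor(g, "TES")
        # tail always spans at least the measurement window plus a margin, so
        # the 500-bp downstream window carries the planted fraction in full
        tail_len = int(min(600 + rng.exponential(cfg.dog_tail_mean), cfg.dog_tail_max))
        if g.strand == "+":
            emit_tiles("+", g.start, tes, rate_per_bp)
            emit_tiles("+", tes + 1, tes + tail_len, rate_per_bp * frac)
        else:
            emit_tiles("-", tes, g.end, rate_per_bp)
            emit_tiles("-", max(1, tes - tail_len), tes - 1, rate_per_bp * frac)
    coverage = {
        s: pd.DataFrame(cov_rows[s], columns=["chrom", "start", "end", "value"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
        for s in ("+", "-")
    }

    # ---- 6. loops -----------------------------------------------------------
    loop_rows = []
    other_cursor = [desert_start + 10_000 * (n_distal + 2)]
    lcount = [0]

    def anchor_interval(center):
        c = int(center + rng.integers(-cfg.anchor_jitter, cfg.anchor_jitter + 1))
        return c - cfg.anchor_width // 2, c + cfg.anchor_width // 2

    def add_loop(c1, c2):
        lcount[0] += 1
        s1, e1 = anchor_interval(c1)
        s2, e2 = anchor_interval(c2)
        if s2 < s1:
            (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
        loop_rows.append(
            dict(loop_id="loop%05d" % lcount[0], chrom1=cfg.chrom, start1=s1, end1=e1,
                 chrom2=cfg.chrom, start2=s2, end2=e2, score=1.0)
        )

    def next_other_locus():
        other_cursor[0] += 5000
        return other_cursor[0]

    group_flags = {
        "A": (True, True, True), "B": (True, True, False), "C": (True, False, True),
        "D": (True, False, False), "E": (False, True, True), "F": (False, True, False),
        "G": (False, False, True), "H": (False, False, False),
    }
    for i, g in enumerate(genes):
        if i in dyad_members:
            grp = "H"  # keep close-spaced dyad neighbourhoods loop-free
        else:
            grp = loop_items[rng.choice(len(loop_items), p=[p for _, p in loop_items])][0]
        gene_truth[g.gene_id]["loop_group"] = grp
        tss_tes, tss_other, tes_other = group_flags[grp]
        tss_a, tes_a = primary_anchor(g, "TSS"), primary_anchor(g, "TES")
        if tss_tes:
            add_loop(tss_a, tes_a)
        if tss_other:
            add_loop(tss_a, next_other_locus())
        if tes_other:
            add_loop(tes_a, next_other_locus())
    loops = pd.DataFrame(
        loop_rows,
        columns=["loop_id", "chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"],
    )

    # ---- 7. expression -------------------------------------------------------
    elaw = cfg.expression_law
    dyad_resp = {}
    for d in dyad_truth:
        dyad_resp[d["upstream_gene"]] = d["response_up"]
        dyad_resp[d["downstream_gene"]] = d["response_down"]
    expr = {}
    for g in genes:
        t = gene_truth[g.gene_id]
        mu = elaw["base_log2"]
        s5 = t["state_5p"]
        if s5 == EndState.BOTH.value:
            mu += elaw["tss_both"]
        elif s5 != EndState.NONE.value:
            mu += elaw["tss_single"]
        if t["state_3p"] != EndState.NONE.value:
            mu += elaw["tes_any"]
        base = 2.0 ** (mu + elaw["sigma_log2"] * rng.normal())
        row = {cfg.timepoints[0]: base}
        for tp in cfg.timepoints[1:]:
            if g.gene_id in dyad_resp:
                fold = RESPONSE_FOLD[dyad_resp[g.gene_id]]
                noise = elaw["dyad_sigma_log2"]
            else:
                fold, noise = 1.0, elaw["timepoint_sigma_log2"]
            row[tp] = base * fold * 2.0 ** (noise * rng.normal())
        expr[g.gene_id] = row
    expression = pd.DataFrame.from_dict(expr, orient="index")[list(cfg.timepoints)]
    expression.index.name = "gene_id"

    # ---- 8. co-occupancy stand-in factors ------------------------------------
    classes = ("TSS", "TES", "intragenic", "distal")
    region_centers = {c: [] for c in classes}
    summit_by_pid = {p["peak_id"]: p["summit"] for p in peak_rows}
    for pt in peak_truth:
        if pt["factor"] == cfg.factor_a and pt["region_class"] in classes:
            region_centers[pt["region_class"]].append(summit_by_pid[pt["peak_id"]])
    cofactor_peaks = {}
    cof_home = {}
    for k in range(cfg.n_cofactors):
        name = "TF%02d" % (k + 1)
        home = classes[k % len(classes)]
        cof_home[name] = home
        rows = []
        for c in region_centers[home]:
            if rng.random() < cfg.cofactor_plant_prob:
                s = int(c + rng.normal(0, 100))
                rows.append(
                    dict(peak_id="%s_p%05d" % (name, len(rows) + 1), factor=name, sample="",
                         chrom=cfg.chrom, start=max(1, s - 150), end=s + 150, summit=s,
                         signal=float(np.exp(rng.normal(2.5, 0.4))))
                )
        for _ in range(cfg.cofactor_background):
            s = int(rng.integers(1000, chrom_length - 1000))
            rows.append(
                dict(peak_id="%s_p%05d" % (name, len(rows) + 1), factor=name, sample="",
                     chrom=cfg.chrom, start=max(1, s - 150), end=s + 150, summit=s,
                     signal=float(np.exp(rng.normal(2.0, 0.4))))
            )
        cofactor_peaks[name] = pd.DataFrame(
            rows, columns=["peak_id", "factor", "sample", "chrom", "start", "end", "summit", "signal"]
        )

    truth = {
        "genes": gene_truth,
        "peaks": peak_truth,
        "dyads": dyad_truth,
        "cofactor_home": cof_home,
        "chrom_length": int(chrom_length),
        "timepoints": list(cfg.timepoints),
    }
    return Bundle(
        config=cfg,
        genes=genes,
        transcripts=transcripts,
        peaks=peaks,
        peaks_by_timepoint=peaks_by_timepoint,
        coverage=coverage,
        loops=loops,
        expression=expression,
        cofactor_peaks=cofactor_peaks,
        truth=truth,
        chrom_length=int(chrom_length),
    )


def perturb(
    bundle: Bundle,
    drop_peaks: float = 0.0,
    signal_decay: float = 1.0,
    add_noise_loops: int = 0,
    seed: int = 0,
):
    """Derive a perturbed bundle (for retention-kinetics and robustness tests).

    ``drop_peaks`` removes each peak independently with that probability;
    ``signal_decay`` scales every surviving signal; ``add_noise_loops``
    appends loops with uniformly random anchors.  Returns the new bundle
    and a truth delta recording exactly what changed.
    """
    if not 0.0 <= drop_peaks <= 1.0:
        raise ValueError("drop_peaks must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(bundle.peaks)) >= drop_peaks
    new_peaks = bundle.peaks[keep].copy().reset_index(drop=True)
    new_peaks["signal"] = new_peaks["signal"] * signal_decay
    dropped = bundle.peaks.loc[~keep, "peak_id"].tolist()
    new_loops = bundle.loops.copy()
    added = []
    rows = []
    for k in range(add_noise_loops):
        c1 = int(rng.integers(1000, bundle.chrom_length - 1000))
        c2 = int(rng.integers(1000, bundle.chrom_length - 1000))
        s1, s2 = sorted((c1, c2))
        lid = "noise%05d" % (k + 1)
        rows.append(
            dict(loop_id=lid, chrom1=bundle.config.chrom, start1=s1 - 200, end1=s1 + 200,
                 chrom2=bundle.config.chrom, start2=s2 - 200, end2=s2 + 200, score=0.0)
        )
        added.append(lid)
    if rows:
        new_loops = pd.concat([new_loops, pd.DataFrame(rows)], ignore_index=True)
    new_tp = {
        tp: df[~df["peak_id"].isin(set(dropped))].assign(signal=lambda d: d["signal"] * signal_decay)
        for tp, df in bundle.peaks_by_timepoint.items()
    }
    delta = {
        "dropped_peak_ids": dropped,
        "signal_decay": signal_decay,
        "added_loop_ids": added,
    }
    new_bundle = dataclasses.replace(
        bundle, peaks=new_peaks, loops=new_loops, peaks_by_timepoint=new_tp
    )
    return new_bundle, delta
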