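"""Pipeline stages tying the modules together over a fixture directory.

Each stage reads the flat fixture files (annotation, narrowPeak sets,
bedGraph coverage, BEDPE loops, expression TSV) from ``<outdir>/fixtures``
and writes result tables to ``<outdir>``, every one with a provenance
header carrying the configuration hash.  Outputs contain no timestamps,
so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from endbind import io as ebio
from endbind.annotation import load_annotation, pair_relations
from endbind.categories import calls_to_frame, category_summary, classify
from endbind.cooccupancy import build_region_sets, occupancy_zscores
from endbind.dyads import classify_responses, dyads_to_frame, find_dyads
from endbind.group_stats import biotype_binding_fractions, compare_expression
from endbind.loops import (
    assign_loop_ends,
    category_by_group_matrix,
    classify_groups,
    contact_profiles,
    looping_frequency,
)
from endbind.peaks import assign_peaks, drop_ambiguous, flag_ambiguous, site_counts
from endbind.readthrough import compare_groups, count_windows
from endbind.signal_metrics import distance_strata, stratify_signal
from endbind.simulate import SimulationConfig, simulate

logger = logging.getLogger(__name__)

SUBCOMMANDS = (
    "simulate", "assign", "classify", "signal", "dog",
    "loops", "cooccupy", "dyads", "stats", "all",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "endbind_run"
    seed: int = 42
    n_genes: int = 500
    radius: int = 2500
    window: int = 500
    min_upstream: float = 10.0
    overlap_halfwidth: int = 100
    fold_threshold: float = 1.5
    ambiguity_filter: bool = True
    factor_a: str = "MYC"
    factor_b: str = "MAX"
    baseline: str = "0h"
    induced: str = "4h"
    timepoints: tuple = ("0h", "4h")

    def config_hash(self) -> str:
        # the output path is not part of the scientific configuration
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def header(self) -> dict:
        return {"config": self.config_hash(), "version": "0.1.0"}


def _fixtures(cfg: PipelineConfig) -> Path:
    return Path(cfg.outdir) / "fixtures"


def _require(path: Path) -> Path:
    if not path.exists():
        raise PipelineError("missing input: %s" % path)
    return path


def stage_simulate(cfg: PipelineConfig):
    bundle = simulate(SimulationConfig(seed=cfg.seed, n_genes=cfg.n_genes, radius=cfg.radius,
                                       factor_a=cfg.factor_a, factor_b=cfg.factor_b,
                                       timepoints=tuple(cfg.timepoints)))
    paths = bundle.write(_fixtures(cfg))
    logger.info("simulate: genes=%d peaks=%d loops=%d", len(bundle.genes), len(bundle.peaks),
                len(bundle.loops))
    return paths


class _Inputs:
    """Lazy loader over the fixture directory."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.fix = _fixtures(cfg)
        self._genes = None
        self._peaks = None

    @property
    def genes(self):
        if self._genes is None:
            self._genes = load_annotation(_require(self.fix / "annotation.gtf"))
        return self._genes

    @property
    def peaks(self) -> pd.DataFrame:
        if self._peaks is None:
            frames = []
            for factor in (self.cfg.factor_a, self.cfg.factor_b, "POLR2A"):
                p = _require(self.fix / ("peaks_%s.narrowPeak" % factor))
                frames.append(ebio.read_narrowpeak(p, factor=factor))
            self._peaks = pd.concat(frames, ignore_index=True)
        return self._peaks

    def peaks_at(self, timepoint: str) -> pd.DataFrame:
        p = _require(self.fix / ("peaks_%s_%s.narrowPeak" % (self.cfg.factor_a, timepoint)))
        return ebio.read_narrowpeak(p, factor=self.cfg.factor_a)

    @property
    def coverage(self) -> dict:
        return {
            "+": ebio.read_bedgraph(_require(self.fix / "coverage_plus.bedGraph")),
            "-": ebio.read_bedgraph(_require(self.fix / "coverage_minus.bedGraph")),
        }

    @property
    def loops(self) -> pd.DataFrame:
        return ebio.read_bedpe(_require(self.fix / "loops.bedpe"))

    @property
    def expression(self) -> pd.DataFrame:
        df = pd.read_csv(_require(self.fix / "expression.tsv"), sep="\t")
        return df.set_index("gene_id")

    @property
    def cofactors(self) -> dict:
        cdir = _require(self.fix / "cofactors")
        return {
            p.stem: ebio.read_narrowpeak(p, factor=p.stem)
            for p in sorted(cdir.glob("*.narrowPeak"))
        }


def _assignments(cfg: PipelineConfig, inp: _Inputs, filtered: bool):
    asn = assign_peaks(inp.peaks, inp.genes, radius=cfg.radius)
    rels = pair_relations(inp.genes, max_gap=2 * cfg.radius)
    asn = flag_ambiguous(asn, rels)
    logger.info("assign: peaks=%d assignments=%d ambiguous=%d",
                len(inp.peaks), len(asn), int(asn["ambiguous"].sum()))
    if filtered:
        asn = drop_ambiguous(asn)
    return asn, rels


def stage_assign(cfg: PipelineConfig, inp: _Inputs):
    asn, _ = _assignments(cfg, inp, filtered=False)
    out = Path(cfg.outdir) / "assignments.tsv"
    ebio.write_table(asn, out, cfg.header())
    ebio.write_table(site_counts(asn), Path(cfg.outdir) / "site_counts.tsv", cfg.header())
    return out


def stage_classify(cfg: PipelineConfig, inp: _Inputs):
    # classification keeps ambiguous peaks (no 5'/3' distinction is drawn there)
    asn, _ = _assignments(cfg, inp, filtered=False)
    calls = classify(asn, inp.genes, cfg.factor_a, cfg.factor_b)
    ebio.write_table(calls_to_frame(calls), Path(cfg.outdir) / "categories.tsv", cfg.header())
    summary = category_summary(calls)
    ebio.write_table(summary, Path(cfg.outdir) / "category_summary.tsv", cfg.header())
    logger.info("classify: genes=%d bound=%d",
                len(calls), int(summary.loc[summary["category"] != 16, "n_genes"].sum()))
    return calls


def stage_signal(cfg: PipelineConfig, inp: _Inputs):
    asn, _ = _assignments(cfg, inp, filtered=cfg.ambiguity_filter)
    strat = stratify_signal(asn, inp.peaks, inp.genes, radius=cfg.radius)
    dist = distance_strata(asn, overlap_halfwidth=cfg.overlap_halfwidth)
    ebio.write_table(strat, Path(cfg.outdir) / "signal_by_region.tsv", cfg.header())
    ebio.write_table(dist, Path(cfg.outdir) / "signal_by_distance.tsv", cfg.header())
    return strat, dist


def stage_dog(cfg: PipelineConfig, inp: _Inputs):
    records = count_windows(inp.coverage, inp.genes, window=cfg.window,
                            min_upstream=cfg.min_upstream)
    asn, _ = _assignments(cfg, inp, filtered=False)
    calls = calls_to_frame(classify(asn, inp.genes, cfg.factor_a, cfg.factor_b))
    labels = {
        r.gene_id: ("TES_bound" if r.state_3p != "none" else "TES_unbound")
        for r in calls.itertuples()
    }
    result = compare_groups(records, labels)
    ebio.write_table(records, Path(cfg.outdir) / "dog_records.tsv", cfg.header())
    ebio.write_table(pd.DataFrame([result]), Path(cfg.outdir) / "dog_group_test.tsv", cfg.header())
    logger.info("dog: defined=%d p=%.3g", int(records["fraction"].notna().sum()),
                result["p_value"])
    return records, result


def stage_loops(cfg: PipelineConfig, inp: _Inputs):
    la = assign_loop_ends(inp.loops, inp.genes, radius=cfg.radius)
    profiles = classify_groups(contact_profiles(la, inp.genes))
    asn, _ = _assignments(cfg, inp, filtered=False)
    calls = classify(asn, inp.genes, cfg.factor_a, cfg.factor_b)
    expr = inp.expression[cfg.induced]
    counts, mean_expr = category_by_group_matrix(calls, profiles, expr)
    freq = looping_frequency(calls, profiles)
    ebio.write_table(profiles, Path(cfg.outdir) / "loop_profiles.tsv", cfg.header())
    ebio.write_table(counts.reset_index(), Path(cfg.outdir) / "category_by_group_counts.tsv",
                     cfg.header())
    ebio.write_table(mean_expr.reset_index(), Path(cfg.outdir) / "category_by_group_expr.tsv",
                     cfg.header())
    ebio.write_table(freq, Path(cfg.outdir) / "looping_frequency.tsv", cfg.header())
    return profiles, counts


def stage_cooccupy(cfg: PipelineConfig, inp: _Inputs):
    asn, _ = _assignments(cfg, inp, filtered=False)
    ref = inp.peaks[inp.peaks["factor"] == cfg.factor_a]
    ref_asn = asn[asn["factor"] == cfg.factor_a]
    regions = build_region_sets(ref, ref_asn, inp.genes, halfwidth=cfg.radius,
                                radius=cfg.radius)
    mat = occupancy_zscores(regions, inp.cofactors, halfwidth=cfg.radius)
    flat = mat.copy()
    flat.columns = ["%s:%d" % c for c in mat.columns]
    ebio.write_table(flat.rename_axis("factor").reset_index(),
                     Path(cfg.outdir) / "cooccupancy_zscores.tsv", cfg.header())
    return mat


def stage_dyads(cfg: PipelineConfig, inp: _Inputs):
    rels = pair_relations(inp.genes, max_gap=2 * cfg.radius)
    peaks_tp = {tp: inp.peaks_at(tp) for tp in cfg.timepoints}
    asn_tp = {tp: assign_peaks(df, inp.genes, radius=cfg.radius) for tp, df in peaks_tp.items()}
    found = find_dyads(rels, asn_tp, inp.genes, peaks_tp, baseline=cfg.baseline,
                       factor=cfg.factor_a, radius=cfg.radius)
    completed, lfc, counts = classify_responses(found, inp.expression, cfg.baseline,
                                                cfg.fold_threshold)
    ebio.write_table(dyads_to_frame(completed), Path(cfg.outdir) / "dyads.tsv", cfg.header())
    ebio.write_table(counts, Path(cfg.outdir) / "dyad_quadrants.tsv", cfg.header())
    logger.info("dyads: found=%d", len(completed))
    return completed, counts


def stage_stats(cfg: PipelineConfig, inp: _Inputs):
    asn, _ = _assignments(cfg, inp, filtered=False)
    calls = classify(asn, inp.genes, cfg.factor_a, cfg.factor_b)
    cdf = calls_to_frame(calls)
    expr = inp.expression[cfg.induced]
    grouping = cdf.set_index("gene_id")["category"].map(lambda c: "cat%02d" % c)
    comparisons = compare_expression(expr, grouping, test="t_unpaired")
    biotab = biotype_binding_fractions(calls, inp.genes)
    ebio.write_table(comparisons, Path(cfg.outdir) / "expression_comparisons.tsv", cfg.header())
    ebio.write_table(biotab, Path(cfg.outdir) / "biotype_fractions.tsv", cfg.header())
    return comparisons, biotab


_STAGES = {
    "assign": stage_assign,
    "classify": stage_classify,
    "signal": stage_signal,
    "dog": stage_dog,
    "loops": stage_loops,
    "cooccupy": stage_cooccupy,
    "dyads": stage_dyads,
    "stats": stage_stats,
}


def run_subcommand(name: str, cfg: PipelineConfig) -> int:
    """Run one stage (or ``all``); returns 0 on success.

    Raises :class:`PipelineError` on unknown subcommands or missing
    inputs; partially written outputs of the failing stage are removed.
    """
    if name not in SUBCOMMANDS:
        raise PipelineError("unknown subcommand: %s (choose from %s)" % (name, ", ".join(SUBCOMMANDS)))
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    before = set(Path(cfg.outdir).glob("*.tsv"))
    try:
        if name == "simulate":
            stage_simulate(cfg)
            return 0
        if name == "all":
            stage_simulate(cfg)
            inp = _Inputs(cfg)
            for stage in ("assign", "classify", "signal", "dog", "loops",
                          "cooccupy", "dyads", "stats"):
                _STAGES[stage](cfg, inp)
            return 0
        inp = _Inputs(cfg)
        _STAGES[name](cfg, inp)
        return 0
    except Exception:
        for p in set(Path(cfg.outdir).glob("*.tsv")) - before:
            p.unlink(missing_ok=True)
        raise


def output_checksums(cfg: PipelineConfig) -> dict:
    """SHA-1 of every output and fixture file (for determinism checks)."""
    root = Path(cfg.outdir)
    return {
        str(p.relative_to(root)): ebio.file_sha1(p)
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }
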