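import numpy as np
import pandas as pd
import pytest

from endbind.annotation import mirror_genes
from endbind.readthrough import compare_groups, condition_delta, count_windows
from endbind.simulate import SimulationConfig, simulate
from conftest import make_gene


def tiles(chrom, lo, hi, value, tile=50):
    starts = np.arange(lo, hi + 1, tile)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + tile - 1,
                         "value": float(value)})


def cov_pair(plus=None, minus=None):
    empty = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return {"+": plus if plus is not None else empty,
            "-": minus if minus is not None else empty}


class TestCountWindows:
    def test_no_coverage_past_tes_gives_fraction_zero(self):
        g = make_gene("A", "chr1", "+", 10_000, 29_999)
        cov = cov_pair(plus=tiles("chr1", 10_000, 29_999, 10))
        rec = count_windows(cov, [g]).iloc[0]
        assert rec["fraction"] == 0.0
        assert rec["upstream_count"] == pytest.approx(100.0)  # 10 reads x 10 tiles

    def test_equal_depth_past_tes_gives_fraction_one(self):
        g = make_gene("A", "chr1", "+", 10_000, 29_999)
        cov = cov_pair(plus=tiles("chr1", 10_000, 35_000, 10))
        assert count_windows(cov, [g]).iloc[0]["fraction"] == pytest.approx(1.0)

    def test_minus_strand_windows_face_the_other_way(self):
        g = make_gene("A", "chr1", "-", 10_000, 30_000)
        # body plus 500 bp of read-through below the '-' TES at half depth
        body = tiles("chr1", 10_000, 29_999, 10)
        tail = tiles("chr1", 9_500, 9_999, 5)
        cov = cov_pair(minus=pd.concat([body, tail], ignore_index=True))
        assert count_windows(cov, [g]).iloc[0]["fraction"] == pytest.approx(0.5)

    def test_depth_scaling_invariance(self):
        g = make_gene("A", "chr1", "+", 10_000, 29_999)
        base = pd.concat([tiles("chr1", 10_000, 29_999, 7), tiles("chr1", 30_000, 30_499, 3)],
                         ignore_index=True)
        f1 = count_windows(cov_pair(plus=base), [g]).iloc[0]["fraction"]
        # power-of-two scaling is exact in binary floating point
        f2 = count_windows(cov_pair(plus=base.assign(value=base["value"] * 8.0)), [g]).iloc[0]["fraction"]
        f3 = count_windows(cov_pair(plus=base.assign(value=base["value"] * 13.0)), [g]).iloc[0]["fraction"]
        assert f1 == f2
        assert f3 == pytest.approx(f1, rel=1e-12)

    def test_strand_flip_of_annotation_and_coverage_preserves_fractions(self):
        g = make_gene("A", "chr1", "+", 10_000, 30_000)
        plus = pd.concat([tiles("chr1", 10_000, 29_999, 8), tiles("chr1", 30_000, 31_000, 2)],
                         ignore_index=True)
        f_orig = count_windows(cov_pair(plus=plus), [g]).iloc[0]["fraction"]
        axis = 1_000_000
        (gm,) = mirror_genes([g], axis)
        minus = plus.assign(start=axis - plus["end"], end=axis - plus["start"])
        f_mirror = count_windows(cov_pair(minus=minus), [gm]).iloc[0]["fraction"]
        assert f_orig == pytest.approx(f_mirror)

    def test_low_expression_flagged_and_fraction_undefined(self):
        g = make_gene("A", "chr1", "+", 10_000, 30_000)
        cov = cov_pair(plus=tiles("chr1", 10_000, 29_999, 0.5))
        rec = count_windows(cov, [g], min_upstream=10).iloc[0]
        assert np.isnan(rec["fraction"]) and "low_expression" in rec["flags"]

    def test_downstream_overlap_with_same_strand_gene_masked(self):
        a = make_gene("A", "chr1", "+", 10_000, 30_000)
        b = make_gene("B", "chr1", "+", 30_200, 50_000)
        cov = cov_pair(plus=tiles("chr1", 10_000, 50_000, 10))
        recs = count_windows(cov, [a, b]).set_index("gene_id")
        assert "masked_overlap" in recs.loc["A", "flags"]
        assert recs.loc["B", "flags"] == ""

    def test_missing_strand_raises_with_unstranded_hint(self):
        g = make_gene("A", "chr1", "+", 10_000, 30_000)
        with pytest.raises(ValueError, match="unstranded"):
            count_windows({"+": tiles("chr1", 10_000, 30_000, 10)}, [g])

    def test_poisson_estimator_unbiased_at_planted_fractions(self):
        cfg = SimulationConfig(
            seed=7, n_genes=150,
            orientation_mix={"isolated": 1.0, "head_to_head": 0.0,
                             "head_to_tail": 0.0, "tail_to_tail": 0.0},
            dog_fraction_values=(0.05, 0.2, 0.5), dyad_fraction=0.0,
        )
        b = simulate(cfg)
        recs = count_windows(b.coverage, b.genes).set_index("gene_id")
        planted = pd.Series({g: t["dog_fraction"] for g, t in b.truth["genes"].items()})
        for target in (0.05, 0.2, 0.5):
            sel = planted[np.isclose(planted, target)].index
            est = recs.loc[sel, "fraction"].dropna()
            assert abs(est.mean() - target) / target < 0.10


class TestCompareGroups:
    def test_requires_two_genes_per_group(self):
        recs = pd.DataFrame({"gene_id": ["a", "b", "c"], "downstream_count": 1,
                             "upstream_count": 10, "fraction": [0.1, 0.2, 0.3],
                             "flags": ""})
        with pytest.raises(ValueError):
            compare_groups(recs, {"a": "TES_bound", "b": "TES_unbound", "c": "TES_unbound"})

    def test_shifted_groups_rejected_and_direction_reported(self, rng):
        n = 100
        fr = np.concatenate([rng.beta(3, 7, n), rng.beta(1, 9, n)])
        recs = pd.DataFrame({"gene_id": ["g%d" % i for i in range(2 * n)],
                             "downstream_count": 1.0, "upstream_count": 10.0,
                             "fraction": fr, "flags": ""})
        labels = {("g%d" % i): ("TES_bound" if i < n else "TES_unbound") for i in range(2 * n)}
        res = compare_groups(recs, labels)
        assert res["p_value"] < 1e-6
        assert res["direction"] == "TES_bound"

    def test_null_rejection_rate_nominal(self, rng):
        n, reps, rej = 60, 200, 0
        for _ in range(reps):
            fr = rng.beta(2, 8, 2 * n)
            recs = pd.DataFrame({"gene_id": ["g%d" % i for i in range(2 * n)],
                                 "downstream_count": 1.0, "upstream_count": 10.0,
                                 "fraction": fr, "flags": ""})
            labels = {("g%d" % i): ("TES_bound" if i < n else "TES_unbound")
                      for i in range(2 * n)}
            if compare_groups(recs, labels)["p_value"] < 0.05:
                rej += 1
        assert 0.01 <= rej / reps <= 0.10


class TestConditionDelta:
    def _recs(self, fracs, up=1000.0):
        return pd.DataFrame({
            "gene_id": ["g%d" % i for i in range(len(fracs))],
            "downstream_count": [f * up for f in fracs],
            "upstream_count": up, "fraction": fracs, "flags": "",
        })

    def test_identical_conditions_give_zero_delta(self):
        base = self._recs([0.1, 0.2, 0.4])
        out = condition_delta({"ctrl": base, "heat": base.copy()}, baseline="ctrl")
        assert np.allclose(out["log2_delta"], 0.0)

    def test_planted_doubling_gives_one_log2_unit(self):
        base = self._recs([0.1, 0.2])
        doubled = self._recs([0.2, 0.4])
        out = condition_delta({"ctrl": base, "kcl": doubled}, baseline="ctrl")
        assert np.allclose(out["log2_delta"], 1.0, atol=0.01)

    def test_flagged_genes_excluded(self):
        base = self._recs([0.1, 0.2])
        cond = self._recs([0.1, 0.2])
        cond.loc[1, "flags"] = "low_expression"
        out = condition_delta({"ctrl": base, "x": cond}, baseline="ctrl").set_index("gene_id")
        assert np.isnan(out.loc["g1", "log2_delta"])
        assert out.loc["g1", "flags"] == "low_expression"

    def test_missing_baseline_raises(self):
        with pytest.raises(ValueError, match="baseline"):
            condition_delta({"x": self._recs([0.1])}, baseline="ctrl")
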