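import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endbind.peaks import assign_peaks
from endbind.signal_metrics import (
    classify_peak_regions,
    distance_strata,
    retention_kinetics,
    stratify_signal,
)
from conftest import make_gene, make_peaks


class TestRegionStratification:
    def test_all_tss_peaks_leave_other_classes_empty(self):
        genes = [make_gene("A", "chr1", "+", 10_000, 40_000)]
        peaks = make_peaks([("p%d" % i, "MYC", "chr1", 10_000 + 100 * i, 5.0) for i in range(4)])
        asn = assign_peaks(peaks, genes)
        out = stratify_signal(asn, peaks, genes)
        assert out.loc[out["region_class"] == "TSS", "n"].iloc[0] == 4
        for cls in ("TES", "intragenic", "distal"):
            assert (out.loc[out["region_class"] == cls, "n"] == 0).all()

    def test_peak_3kb_inside_20kb_gene_is_intragenic(self):
        genes = [make_gene("A", "chr1", "+", 10_000, 30_000)]
        peaks = make_peaks([("p1", "MYC", "chr1", 13_000, 5.0)])
        asn = assign_peaks(peaks, genes)
        cls = classify_peak_regions(peaks, asn, genes)
        assert cls.iloc[0]["region_class"] == "intragenic"

    def test_peak_outside_all_spans_and_windows_is_distal(self):
        genes = [make_gene("A", "chr1", "+", 10_000, 30_000)]
        peaks = make_peaks([("p1", "MYC", "chr1", 100_000, 5.0)])
        asn = assign_peaks(peaks, genes)
        assert classify_peak_regions(peaks, asn, genes).iloc[0]["region_class"] == "distal"

    def test_classes_partition_peaks(self, bundle):
        asn = assign_peaks(bundle.peaks, bundle.genes, radius=2500)
        myc = bundle.peaks[bundle.peaks["factor"] == "MYC"]
        cls = classify_peak_regions(myc, asn, bundle.genes)
        assert len(cls) == len(myc)
        assert set(cls["region_class"]) <= {"TSS", "TES", "intragenic", "distal"}
        # and it agrees with the generator's planted site classes
        planted = {p["peak_id"]: p["region_class"] for p in bundle.truth["peaks"]
                   if p["factor"] == "MYC" and not p["dyad_site"]}
        got = cls.set_index("peak_id")["region_class"]
        for pid, expect in planted.items():
            assert got[pid] == expect, pid

    def test_planted_class_means_recovered_within_two_sem(self, rng):
        genes = [make_gene("G%d" % i, "chr1", "+", 50_000 * i + 10_000, 50_000 * i + 40_000)
                 for i in range(40)]
        rows, mus = [], {"TSS": 3.5, "TES": 2.5}
        for i, g in enumerate(genes):
            for kind, anchor in (("TSS", 50_000 * i + 10_000), ("TES", 50_000 * i + 40_000)):
                rows.append(("p%s%d" % (kind, i), "MYC", "chr1", anchor,
                             float(rng.lognormal(mus[kind], 0.4))))
        peaks = make_peaks(rows)
        out = stratify_signal(assign_peaks(peaks, genes), peaks, genes)
        for kind in ("TSS", "TES"):
            row = out[(out["region_class"] == kind) & (out["factor"] == "MYC")].iloc[0]
            expected = np.exp(mus[kind] + 0.4 ** 2 / 2)
            assert abs(row["mean"] - expected) < 2 * row["sem"] + 0.05 * expected


class TestDistanceStrata:
    def test_stratum_from_offset_sign(self):
        genes = [make_gene("A", "chr1", "+", 10_000, 30_000)]
        peaks = make_peaks([("up", "MYC", "chr1", 9_200, 5.0),
                            ("ov", "MYC", "chr1", 10_050, 5.0),
                            ("dn", "MYC", "chr1", 11_500, 5.0)])
        out = distance_strata(assign_peaks(peaks, genes))
        got = out.set_index("stratum")["n"]
        assert got["upstream"] == 1 and got["overlapping"] == 1 and got["downstream"] == 1

    def test_planted_stratum_shift_detected_by_t_test(self, rng):
        genes = [make_gene("G%d" % i, "chr1", "+", 60_000 * i + 10_000, 60_000 * i + 40_000)
                 for i in range(60)]
        rows = []
        for i in range(60):
            tss = 60_000 * i + 10_000
            rows.append(("u%d" % i, "MYC", "chr1", tss - 800, float(rng.lognormal(3.5, 0.3))))
            rows.append(("d%d" % i, "MYC", "chr1", tss + 800, float(rng.lognormal(2.5, 0.3))))
        asn = assign_peaks(make_peaks(rows), genes)
        asn_tss = asn[asn["end_kind"] == "TSS"]
        up = asn_tss.loc[asn_tss["offset"] < 0, "signal"]
        dn = asn_tss.loc[asn_tss["offset"] > 0, "signal"]
        _, p = stats.ttest_ind(np.log(up), np.log(dn))
        assert p < 1e-6
        out = distance_strata(asn)
        sub = out[out["end_kind"] == "TSS"].set_index("stratum")
        assert sub.loc["upstream", "mean"] > sub.loc["downstream", "mean"]


class TestRetentionKinetics:
    def _course(self, rng, n=200, drop=0.0, decay=1.0):
        genes = [make_gene("G%d" % i, "chr1", "+", 60_000 * i + 10_000, 60_000 * i + 40_000)
                 for i in range(n)]
        rows = [("p%d" % i, "MYC", "chr1", 60_000 * i + 10_000, float(rng.lognormal(3, 0.5)))
                for i in range(n)]
        peaks = make_peaks(rows)
        base = assign_peaks(peaks, genes)
        keep = rng.random(len(peaks)) >= drop
        later_peaks = peaks[keep].copy()
        later_peaks["signal"] *= decay
        later = assign_peaks(later_peaks, genes)
        return {"t0": base, "t1": later}

    def test_identical_timepoints_stay_at_unity(self, rng):
        course = self._course(rng)
        out = retention_kinetics(course, baseline="t0", order=["t0", "t1"])
        assert np.allclose(out["frac_bound"], 1.0)
        assert np.allclose(out["rel_signal"], 1.0)

    def test_dropping_half_halves_frac_bound(self, rng):
        course = self._course(rng, drop=0.5)
        out = retention_kinetics(course, baseline="t0", order=["t0", "t1"])
        pooled = out[(out["timepoint"] == "t1") & (out["factor"] == "all")].iloc[0]
        n = pooled["n_baseline"]
        se = np.sqrt(0.25 / n)
        assert abs(pooled["frac_bound"] - 0.5) < 3 * se

    def test_missing_baseline_raises(self, rng):
        with pytest.raises(ValueError, match="baseline"):
            retention_kinetics(self._course(rng), baseline="nope")

    def test_tiered_exponential_loss_keeps_high_tier_above_low(self, rng):
        n = 300
        genes = [make_gene("G%d" % i, "chr1", "+", 60_000 * i + 10_000, 60_000 * i + 40_000)
                 for i in range(n)]
        sig = np.where(np.arange(n) < n // 2, rng.lognormal(4.0, 0.2, n), rng.lognormal(2.0, 0.2, n))
        peaks = make_peaks([("p%d" % i, "MYC", "chr1", 60_000 * i + 10_000, float(sig[i]))
                            for i in range(n)])
        course = {"t0": assign_peaks(peaks, genes)}
        # high-signal sites decay slowly, low-signal sites quickly
        p_keep = np.where(sig > np.median(sig), 0.9, 0.4)
        for j, label in enumerate(["t1", "t2"], start=1):
            keep = rng.random(n) < p_keep ** j
            course[label] = assign_peaks(peaks[keep], genes)
        out = retention_kinetics(course, baseline="t0", order=["t0", "t1", "t2"])
        sub = out[(out["factor"] == "MYC") & (out["end_kind"] == "TSS")]
        for label in ("t1", "t2"):
            hi = sub[(sub["timepoint"] == label) & (sub["tier"] == "high")]["frac_bound"].iloc[0]
            lo = sub[(sub["timepoint"] == label) & (sub["tier"] == "low")]["frac_bound"].iloc[0]
            assert hi > lo

    def test_frac_bound_non_increasing_under_removal(self, rng):
        course = self._course(rng, drop=0.3)
        # remove further peaks from t1: frac_bound can only fall
        t1 = course["t1"]
        smaller = t1.iloc[: len(t1) // 2]
        out_full = retention_kinetics({"t0": course["t0"], "t1": t1}, baseline="t0")
        out_small = retention_kinetics({"t0": course["t0"], "t1": smaller}, baseline="t0")
        f_full = out_full[(out_full["timepoint"] == "t1") & (out_full["factor"] == "all")]["frac_bound"].iloc[0]
        f_small = out_small[(out_small["timepoint"] == "t1") & (out_small["factor"] == "all")]["frac_bound"].iloc[0]
        assert f_small <= f_full
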