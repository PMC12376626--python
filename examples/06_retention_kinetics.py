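"""Binding-site retention across a depletion time course.

Simulates a baseline peak set, then a later timepoint in which half the
peaks are lost and surviving signals are halved (mimicking inhibitor-
driven factor depletion), and tracks the fraction of baseline sites
still bound and their relative signal, split by affinity tier.
"""

from endbind.peaks import assign_peaks
from endbind.signal_metrics import retention_kinetics
from endbind.simulate import SimulationConfig, perturb, simulate

bundle = simulate(SimulationConfig(seed=1, n_genes=200))
depleted, delta = perturb(bundle, drop_peaks=0.5, signal_decay=0.5, seed=2)

course = {
    "0h": assign_peaks(bundle.peaks, bundle.genes, radius=2500),
    "24h": assign_peaks(depleted.peaks, bundle.genes, radius=2500),
}
out = retention_kinetics(course, baseline="0h", order=["0h", "24h"])
cols = ["timepoint", "factor", "end_kind", "tier", "n_baseline", "frac_bound", "rel_signal"]
print(out[out["factor"] == "MYC"][cols].to_string(index=False))
pooled = out[(out["factor"] == "all") & (out["timepoint"] == "24h")].iloc[0]
print("\npooled at 24h: %.1f%% of sites still bound, relative signal %.2f"
      % (100 * pooled["frac_bound"], pooled["rel_signal"]))
# With a 50% random drop and 50% signal decay the pooled curve lands at
# ~0.5 on both axes; the per-tier rows show how high- and low-affinity
# sites are tracked separately once a real depletion series is supplied.
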