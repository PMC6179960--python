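"""Quantify TF-knockdown effects on active chromatin and expression.

Simulates depletion of a remodeling TF (Tfea1) and a non-remodeling TF
(Tfla1), measures the per-site change in H3K27ac enrichment at their motif
sites, calls deregulated genes, and tests the two-TF co-regulation overlap.
"""
import numpy as np

from epiprime import SimulationConfig, generate_dataset
from epiprime.motifs import calibrate_threshold, scan_regions
from epiprime.perturbation import TargetSiteSet, coregulation_overlap, kd_chromatin_effect, kd_deregulated_genes
from epiprime.intervals import PeakSet

ds = generate_dataset(SimulationConfig(seed=1))
pwms = {p.motif_id: p for p in ds.pwm_library}

for tf, cls in (("Tfea1", "eA_unique"), ("Tfla1", "lA_unique")):
    info = ds.truth.tfs[tf]
    exp = ds.knockdown(tf)
    stage_peaks = ds.truth.class_peaks(cls)
    thr = calibrate_threshold(pwms[info["motif_id"]], 1e-4)
    hits = scan_regions(pwms[info["motif_id"]], stage_peaks, ds.genome, thr)
    sites = TargetSiteSet(
        tf=tf,
        stage=info["stage"],
        sites=PeakSet([iv for iv, h in zip(stage_peaks, hits.to_numpy()) if h]),
    )
    eff = kd_chromatin_effect(exp, sites, ds.input_track)
    dereg = kd_deregulated_genes(exp)
    kind = "remodeling" if info["remodeling"] else "non-remodeling"
    print(
        f"{tf} ({kind}): {len(sites.sites)} motif sites, "
        f"median delta log2 K27ac = {np.median(eff.delta):+.2f} (p = {eff.p:.2e}); "
        f"{len(dereg['down'])} genes down, {len(dereg['up'])} up"
    )

a = set(ds.truth.tfs["Tfea1"]["target_genes"])
b = set(ds.truth.tfs["Tfea2"]["target_genes"])
co = coregulation_overlap(a, b, universe=ds.cfg.n_genes, genes_with_both_motifs=a & b)
print(
    f"\nTfea1/Tfea2 shared targets: {co['overlap']} genes "
    f"(hypergeometric p = {co['p']:.2e}), {co['co_bound']} bound by both motifs"
)

# Only the remodeling TF loses acetylation at its sites (delta near
# log2(0.4) = -1.32); the non-remodeling TF changes expression without a
# chromatin footprint, and the planted 47-gene co-regulation overlap is
# recovered exactly from the truth tables.
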