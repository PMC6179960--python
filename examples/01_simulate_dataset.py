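"""Generate the synthetic two-lineage differentiation study and look inside.

Builds the default dataset (toy genome, planted enhancers with known
chromatin-state trajectories, ChIP tracks, expression counts) and prints
what was planted. The truth tables are the reference every downstream
example scores against.
"""
from epiprime import SimulationConfig, generate_dataset

cfg = SimulationConfig(seed=1)
ds = generate_dataset(cfg)

print(f"genome: {len(ds.genome)} chromosomes x {cfg.chrom_len/1e6:.1f} Mb")
print(f"genes:  {len(ds.genes)}")
print("enhancer classes:")
for cls, n in ds.truth.enhancers["class"].value_counts().sort_index().items():
    print(f"  {cls:<14} {n}")
print(f"ChIP tracks: {len(ds.tracks)} (2 marks x 3 stages x 2 lineages)")
print(f"expression: {ds.expression.counts.shape[0]} genes x {ds.expression.counts.shape[1]} samples")
print("planted TFs:")
for tf, info in ds.truth.tfs.items():
    kind = "remodeling" if info["remodeling"] else "non-remodeling"
    print(f"  {tf}: {kind}, stage {info['stage']}, {len(info['target_genes'])} target genes")

# Each stage-unique enhancer is primed one stage before it activates, so the
# class counts above are also the ground truth for the trajectory analyses.
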