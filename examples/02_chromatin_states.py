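"""Call peaks, classify chromatin states, and find stage-unique elements.

Runs the input-free Poisson peak caller on every H3K27ac track, partitions
each astro stage's peaks into stage-unique vs shared, and checks the
recovered unique sets against the planted enhancer classes.
"""
from epiprime import SimulationConfig, call_peaks, generate_dataset, stage_unique_sets
from epiprime.pipeline import recovery_metrics

ds = generate_dataset(SimulationConfig(seed=1))

called = {
    stage: call_peaks(ds.tracks[("K27ac", stage, "astro")])
    for stage in ("aNPC", "eA", "lA")
}
print("H3K27ac peaks per astro stage:", {s: len(p) for s, p in called.items()})

part = stage_unique_sets(called)
for stage in ("aNPC", "eA", "lA"):
    unique = part[stage]["unique"]
    truth = ds.truth.class_peaks(f"{stage}_unique")
    m = recovery_metrics(unique, truth)
    print(
        f"{stage}: {len(unique)} unique peaks; "
        f"precision {m['precision']:.2f}, recall {m['recall']:.2f} vs planted"
    )

# A stage-unique peak overlaps no other stage's peaks; precision/recall of 1.0
# means the caller plus the set algebra recovered exactly the planted
# stage-specific enhancers.
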