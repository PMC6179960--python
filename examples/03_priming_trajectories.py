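"""Build primed-to-active chromatin-state trajectories across both lineages.

Quantifies log2-over-input enrichment of both marks at the planted
enhancers, applies the two-mark state logic (K4me1 alone = primed, plus
K27ac = active), and counts when elements become primed-then-activated.
"""
import pandas as pd

from epiprime import SimulationConfig, generate_dataset, marked_status
from epiprime.signal import enrichment_matrix
from epiprime.states import build_trajectories

ds = generate_dataset(SimulationConfig(seed=1))
regions = ds.truth.all_peaks()

status = {"K4me1": {}, "K27ac": {}}
for lineage, stages in (("astro", ("aNPC", "eA", "lA")), ("neuro", ("nNPC", "eN", "lN"))):
    for mark in ("K4me1", "K27ac"):
        tracks = {s: ds.tracks[(mark, s, lineage)] for s in stages}
        sig = enrichment_matrix(tracks, ds.input_track, regions)
        status[mark][lineage] = marked_status(sig, threshold=1.0)

trajectories = build_trajectories(status["K4me1"], status["K27ac"], regions)

counts = pd.Series(
    [t.astro_activation_stage or "-" for t in trajectories]
).value_counts()
print("astro-lineage primed-then-activated stage counts:")
print(counts.to_string())

gfap_like = next(t for t in trajectories if t.astro_activation_stage == "eA")
print("\nan eA-activated element:", gfap_like.region_id)
print("  astro states:", [s.value for s in gfap_like.astro_states])
print("  neuro states:", [s.value for s in gfap_like.neuro_states])

# Elements activated at eA were primed at aNPC; elements activated at lA were
# primed at eA — priming precedes activation by one stage in this design, and
# the state caller reads that back from the simulated tracks alone.
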