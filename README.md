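# epiprime

Chromatin-state trajectories of enhancer priming and activation across
branching differentiation lineages.

## What this is for

During the differentiation of a shared neural progenitor into astrocytes
(aNPC → eA → lA) or neurons (nNPC → eN → lN), distal regulatory elements do
not switch on abruptly: they are first *primed* — marked by H3K4me1 without
H3K27ac — one stage before they become *active* (H3K4me1 + H3K27ac) and
their nearby genes are induced. `epiprime` is a Python toolkit for the
integrative analysis built around that observation:

* per-stage chromatin-state classification of regulatory elements
  (none / primed / active / acetyl-only) from two-mark ChIP-seq signal;
* discovery of stage- and lineage-specific H3K27ac elements by peak-set
  algebra, genomic annotation, and peak-to-gene assignment within 50 kb of
  the nearest TSS;
* construction and clustering of primed→active state trajectories across
  both lineages, and a test that genes near stage-unique active elements
  are expressed highest at their own stage;
* PWM motif enrichment at stage-unique elements against a GC- and
  length-matched background, with exactly calibrated per-motif score
  thresholds, and nomination of stage-specific transcription factors;
* negative-binomial differential expression (median-of-ratios
  normalisation, common-dispersion Wald test, BH-FDR at 0.1), temporal
  clustering and PCA of stage transcriptomes;
* quantification of TF-knockdown consequences: the per-site change in
  H3K27ac at a TF's motif-bearing target elements (Δlog2 over input, paired
  Wilcoxon), deregulated-gene calling, linkage of deregulated genes to
  regulatory sites, and two-TF co-regulation overlap with a hypergeometric
  test.

The state logic at the core is the exhaustive two-mark table: for element
*i* at stage *s*,

    state(i, s) = active       if K4me1(i,s) ∧ K27ac(i,s)
                  primed       if K4me1(i,s) ∧ ¬K27ac(i,s)
                  acetyl_only  if ¬K4me1(i,s) ∧ K27ac(i,s)
                  none         otherwise,

where marked means log2 enrichment over genomic input ≥ 1, and an element
is *primed-then-activated at stage s* iff it is primed at the stage before
*s* and active at *s*.

Because the package is developed against a fully specified synthetic study
— a toy genome with planted enhancer trajectories, motifs, expression
coupling and knockdowns, shipped as the first-class `epiprime.simulate`
module with complete truth tables — every analysis is scored against known
ground truth. See `docs/methods.md` for the models, defaults, and what the
synthetic benchmark does and does not demonstrate.

## Worked example

Recover stage-specific enhancers from simulated tracks and measure a
remodeling-TF knockdown (condensed from `examples/02`, `06`; every
`examples/*.py` script is a short narrative of one capability):

```python
from epiprime import SimulationConfig, call_peaks, generate_dataset, stage_unique_sets

ds = generate_dataset(SimulationConfig(seed=1))
called = {s: call_peaks(ds.tracks[("K27ac", s, "astro")]) for s in ("aNPC", "eA", "lA")}
part = stage_unique_sets(called)
```

prints, via `examples/02_chromatin_states.py`:

```
H3K27ac peaks per astro stage: {'aNPC': 300, 'eA': 300, 'lA': 300}
aNPC: 150 unique peaks; precision 1.00, recall 1.00 vs planted
eA: 150 unique peaks; precision 1.00, recall 1.00 vs planted
lA: 150 unique peaks; precision 1.00, recall 1.00 vs planted
```

Each stage yields 300 called acetylation peaks (150 stage-specific
enhancers + 150 constitutive elements); the 150 peaks unique to each stage
are exactly the planted stage-specific class. The knockdown analysis
(`examples/06_knockdown_analysis.py`) then prints:

```
Tfea1 (remodeling): 100 motif sites, median delta log2 K27ac = -1.25 (p = 1.95e-18); 75 genes down, 30 up
Tfla1 (non-remodeling): 100 motif sites, median delta log2 K27ac = -0.01 (p = 2.43e-01); 91 genes down, 36 up

Tfea1/Tfea2 shared targets: 47 genes (hypergeometric p = 4.53e-26), 47 bound by both motifs
```

Depleting the chromatin-remodeling TF halves-and-more the acetylation at
its motif-bearing sites (median Δ ≈ log2 0.4 = −1.32, attenuated slightly
by library renormalisation), while the non-remodeling TF deregulates genes
without any chromatin footprint — the two regulatory modes the knockdown
module is built to distinguish.

The whole analysis also runs behind one command:

```bash
epiprime run --seed 1 --out results/run1      # simulate → peaks → states →
                                              # DE → motifs → knockdowns → report.json
```

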