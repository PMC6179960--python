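"""Synthetic multi-stage, two-lineage regulatory genomics dataset generator.

The generator emulates the structure of a progenitor-derived differentiation
study: one shared toy genome; three astroglial stages (aNPC, eA, lA) and three
neuronal stages (nNPC, eN, lN); enhancers planted with known chromatin-state
trajectories (none -> primed -> active, stage- and lineage-specific); TF
motifs embedded in stage-specific active enhancers; expression counts coupled
to nearby enhancer activation; and knockdown experiments in which depleting a
"remodeling" TF attenuates H3K27ac and expression at its motif-bearing
targets while a "non-remodeling" TF only affects expression.

Everything is a pure function of (config, seed): named substreams derived
from the root seed make each product independently reproducible. Truth
tables are returned (and written) alongside every dataset so downstream
recovery metrics can be scored against them.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, write_gene_table
from .de import CountMatrix, write_counts
from .intervals import GenomicInterval, PeakSet, write_bed
from .motifs import PWM, calibrate_threshold, write_pwms
from .perturbation import KnockdownExperiment
from .signal import BinnedTrack, write_track

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "SimulatedDataset",
    "simulate_genome",
    "plant_enhancers",
    "simulate_chip",
    "simulate_expression",
    "simulate_knockdown",
    "generate_dataset",
    "CLASS_MARKS",
    "STAGE_UNIQUE_CLASSES",
]

ASTRO_STAGES = ("aNPC", "eA", "lA")
NEURO_STAGES = ("nNPC", "eN", "lN")
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

STAGE_UNIQUE_CLASSES = (
    "aNPC_unique",
    "eA_unique",
    "lA_unique",
    "nNPC_unique",
    "eN_unique",
    "lN_unique",
)
ALL_CLASSES = STAGE_UNIQUE_CLASSES + ("constitutive", "never_active")

# Mark presence per class: {class: {lineage: {mark: presence over the three
# stages}}}. K4me1 alone = primed, K4me1 + K27ac = active. Stage-unique
# classes are primed at the stage preceding activation (priming precedes
# activation); both lineages share the progenitor-stage K4me1 of classes that
# activate early, so clustering the progenitor-primed regions yields one
# archetype per class.
CLASS_MARKS: dict[str, dict[str, dict[str, tuple[int, int, int]]]] = {
    "aNPC_unique": {
        "astro": {"K4me1": (1, 1, 1), "K27ac": (1, 0, 0)},
        "neuro": {"K4me1": (1, 0, 0), "K27ac": (0, 0, 0)},
    },
    "eA_unique": {
        "astro": {"K4me1": (1, 1, 1), "K27ac": (0, 1, 0)},
        "neuro": {"K4me1": (1, 0, 0), "K27ac": (0, 0, 0)},
    },
    "lA_unique": {
        "astro": {"K4me1": (0, 1, 1), "K27ac": (0, 0, 1)},
        "neuro": {"K4me1": (0, 0, 0), "K27ac": (0, 0, 0)},
    },
    "nNPC_unique": {
        "astro": {"K4me1": (1, 0, 0), "K27ac": (0, 0, 0)},
        "neuro": {"K4me1": (1, 1, 1), "K27ac": (1, 0, 0)},
    },
    "eN_unique": {
        "astro": {"K4me1": (1, 0, 0), "K27ac": (0, 0, 0)},
        "neuro": {"K4me1": (1, 1, 1), "K27ac": (0, 1, 0)},
    },
    "lN_unique": {
        "astro": {"K4me1": (0, 0, 0), "K27ac": (0, 0, 0)},
        "neuro": {"K4me1": (0, 1, 1), "K27ac": (0, 0, 1)},
    },
    "constitutive": {
        "astro": {"K4me1": (1, 1, 1), "K27ac": (1, 1, 1)},
        "neuro": {"K4me1": (1, 1, 1), "K27ac": (1, 1, 1)},
    },
    "never_active": {
        "astro": {"K4me1": (1, 1, 1), "K27ac": (0, 0, 0)},
        "neuro": {"K4me1": (1, 1, 1), "K27ac": (0, 0, 0)},
    },
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset; defaults define the study design."""

    seed: int = 0
    n_chroms: int = 4
    chrom_len: int = 2_500_000
    n_genes: int = 1000
    n_enh_per_class: int = 150
    enhancer_width: int = 600
    bin_size: int = 200
    chip_depth: float = 2e6
    enrichment_fold_active: float = 8.0  # K27ac at active elements
    enrichment_fold_primed: float = 6.0  # K4me1 at primed/active elements
    nb_dispersion: float = 0.1
    expr_baseline_log_mean: float = float(np.log(200.0))
    expr_baseline_log_sd: float = 0.5
    expr_boost: float = 2.5
    kd_effect: float = 0.4  # fraction of H3K27ac retained at targets
    kd_up_fold: float = 2.0  # planted indirect upregulation upon knockdown
    kd_n_up: int = 40
    n_replicates: int = 3
    size_factor_jitter: float = 0.2
    motif_width: int = 10
    motif_consensus_prob: float = 0.88
    n_decoy_pwms: int = 20
    coreg_overlap: int = 47  # planted size of the two-TF shared-target set

    def __post_init__(self) -> None:
        if self.enrichment_fold_active <= 1 or self.enrichment_fold_primed <= 1:
            raise ValueError("enrichment folds must exceed 1")
        if self.chip_depth <= 0:
            raise ValueError("chip_depth must be positive")
        if self.n_genes % self.n_chroms:
            raise ValueError("n_genes must divide evenly across chromosomes")

    @property
    def genes_per_chrom(self) -> int:
        return self.n_genes // self.n_chroms

    @property
    def gene_slot(self) -> int:
        return self.chrom_len // self.genes_per_chrom

    def rng(self, name: str) -> np.random.Generator:
        """Named deterministic substream of the root seed."""
        return np.random.default_rng([self.seed, zlib.crc32(name.encode())])


@dataclass
class TruthTables:
    enhancers: pd.DataFrame  # id-indexed: chrom,start,end,class,linked_gene,motifs
    genes: pd.DataFrame  # id-indexed: chrom,strand,tss,baseline,archetype
    tfs: dict[str, dict]  # tf name -> properties and target lists

    def class_peaks(self, cls: str) -> PeakSet:
        sub = self.enhancers[self.enhancers["class"] == cls]
        return PeakSet(
            [
                GenomicInterval(r.chrom, int(r.start), int(r.end), name=i)
                for i, r in sub.iterrows()
            ],
            label=cls,
        )

    def all_peaks(self) -> PeakSet:
        return PeakSet(
            [
                GenomicInterval(r.chrom, int(r.start), int(r.end), name=i)
                for i, r in self.enhancers.iterrows()
            ],
            label="enhancers",
        )

    def mark_presence(self, mark: str, stage: str, lineage: str) -> pd.Series:
        si = (ASTRO_STAGES if lineage == "astro" else NEURO_STAGES).index(stage)
        return self.enhancers["class"].map(
            lambda c: bool(CLASS_MARKS[c][lineage][mark][si])
        )


def simulate_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], list[GeneModel]]:
    """I.i.d. uniform-base genome plus regularly slotted two-exon genes.

    Each chromosome is divided into equal gene slots; the gene occupies
    [slot+1000, slot+3000) with a random strand, leaving the downstream slot
    interior free for planted enhancers. Returns mutable byte arrays so motif
    instances can be written in before the FASTA is finalised.
    """
    rng = rng or cfg.rng("genome")
    if cfg.gene_slot < 9000:
        raise ValueError(
            "gene slots below 8 kb cannot hold a gene plus an intergenic "
            "enhancer; enlarge chrom_len or reduce n_genes"
        )
    genome: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    g = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        genome[chrom] = BASES[rng.integers(0, 4, size=cfg.chrom_len)]
        for k in range(cfg.genes_per_chrom):
            slot = k * cfg.gene_slot
            strand = "+" if rng.random() < 0.5 else "-"
            span = GenomicInterval(chrom, slot + 1000, slot + 3000)
            exons = (
                GenomicInterval(chrom, slot + 1000, slot + 1600),
                GenomicInterval(chrom, slot + 2400, slot + 3000),
            )
            genes.append(
                GeneModel(
                    gene_id=f"gene{g:04d}",
                    chrom=chrom,
                    strand=strand,
                    span=span,
                    exons=exons,
                )
            )
            g += 1
    return genome, genes


def _make_pwm(
    motif_id: str, tf_name: str, cfg: SimulationConfig, rng: np.random.Generator
) -> PWM:
    w = cfg.motif_width
    consensus = rng.integers(0, 4, size=w)
    m = np.full((w, 4), (1.0 - cfg.motif_consensus_prob) / 3.0)
    m[np.arange(w), consensus] = cfg.motif_consensus_prob
    return PWM(motif_id=motif_id, matrix=m, tf_name=tf_name)


def build_pwm_library(cfg: SimulationConfig) -> tuple[list[PWM], dict[str, str]]:
    """Three planted TF motifs plus shuffled/random decoys, and the TF map."""
    rng = cfg.rng("pwms")
    planted = [
        _make_pwm("M_EA1", "Tfea1", cfg, rng),
        _make_pwm("M_EA2", "Tfea2", cfg, rng),
        _make_pwm("M_LA1", "Tfla1", cfg, rng),
    ]
    decoys = [
        _make_pwm(f"M_DEC{i:02d}", f"Dtf{i:02d}", cfg, rng)
        for i in range(cfg.n_decoy_pwms)
    ]
    motif_to_gene = {
        "M_EA1": "Tfea1",
        "M_EA2": "Tfea2",
        "M_LA1": "Tfla1",
    }
    return planted + decoys, motif_to_gene


def _sample_instance(
    pwm: PWM, threshold: float, rng: np.random.Generator, max_tries: int = 50
) -> str:
    """Sample a motif instance that scores above the calibrated threshold."""
    lod = pwm.log_odds()
    for _ in range(max_tries):
        draw = np.array(
            [rng.choice(4, p=pwm.matrix[j]) for j in range(pwm.width)]
        )
        if lod[np.arange(pwm.width), draw].sum() >= threshold:
            return "".join("ACGT"[b] for b in draw)
    return pwm.consensus()


def plant_enhancers(
    cfg: SimulationConfig,
    genome: dict[str, np.ndarray],
    genes: list[GeneModel],
    pwm_library: list[PWM] | None = None,
) -> TruthTables:
    """Place enhancers, link them to genes, embed motif instances, build truth.

    Stage-unique enhancers occupy the intergenic interior of their linked
    gene's slot (midpoint 4.5-5.5 kb into the slot) so the planted link is
    exactly what the <50 kb nearest-TSS rule recovers. Constitutive and
    never-active enhancers sit in the far interior (around 8 kb) of the first
    slots. Motif instances sampled from the class PWM (rejection-sampled to
    score above the calibrated threshold) are written into the genome at
    enhancer centers.
    """
    rng = cfg.rng("enhancers")
    if pwm_library is None:
        pwm_library, _ = build_pwm_library(cfg)
    pwm_by_id = {p.motif_id: p for p in pwm_library}
    thresholds = {m: calibrate_threshold(pwm_by_id[m], 1e-4) for m in ("M_EA1", "M_EA2", "M_LA1")}

    n_linked = 6 * cfg.n_enh_per_class
    if n_linked > len(genes):
        raise ValueError("not enough genes to link every stage-unique enhancer")
    half_w = cfg.enhancer_width // 2
    slot = cfg.gene_slot

    # planted motif targets within the eA/lA classes (indices within class);
    # the two eA TFs share exactly ``coreg_overlap`` targets by construction:
    # TF1 takes the first two thirds, TF2 the last third plus the overlap
    n = cfg.n_enh_per_class
    cut = (2 * n) // 3
    if cfg.coreg_overlap > cut:
        raise ValueError("coreg_overlap too large for the eA class size")
    if cfg.kd_n_up > n - cut - 5:
        raise ValueError("kd_n_up leaves fewer than 5 unchanged-linked genes")
    ea1_idx = set(range(cut))
    ea2_idx = set(range(cut - cfg.coreg_overlap, n))
    la1_idx = set(range(cut))

    enh_rows = {}
    gi = 0
    for ci, cls in enumerate(STAGE_UNIQUE_CLASSES):
        for j in range(n):
            gene = genes[gi]
            slot_start = (gene.span.start - 1000)
            # bin-aligned so each enhancer covers whole track bins
            start = slot_start + 4400 + cfg.bin_size * int(rng.integers(0, 6))
            end = start + cfg.enhancer_width
            mid = start + half_w
            eid = f"enh_{cls}_{j:03d}"
            motifs = []
            if cls == "eA_unique":
                if j in ea1_idx:
                    motifs.append("M_EA1")
                if j in ea2_idx:
                    motifs.append("M_EA2")
            elif cls == "lA_unique" and j in la1_idx:
                motifs.append("M_LA1")
            for mi, m in enumerate(motifs):
                inst = _sample_instance(pwm_by_id[m], thresholds[m], rng)
                off = mid - 15 + 20 * mi  # non-overlapping slots near center
                genome[gene.chrom][off : off + len(inst)] = np.frombuffer(
                    inst.encode(), dtype=np.uint8
                )
            enh_rows[eid] = {
                "chrom": gene.chrom,
                "start": start,
                "end": end,
                "class": cls,
                "linked_gene": gene.gene_id,
                "motifs": ",".join(motifs),
            }
            gi += 1

    # unlinked classes in the far slot interior of the earliest slots
    for ci, cls in enumerate(("constitutive", "never_active")):
        for j in range(n):
            gene = genes[ci * n + j]  # reuse slots; region is disjoint
            slot_start = gene.span.start - 1000
            start = slot_start + 7600 + cfg.bin_size * int(rng.integers(0, 3))
            eid = f"enh_{cls}_{j:03d}"
            enh_rows[eid] = {
                "chrom": gene.chrom,
                "start": start,
                "end": start + cfg.enhancer_width,
                "class": cls,
                "linked_gene": "",
                "motifs": "",
            }

    enhancers = pd.DataFrame.from_dict(enh_rows, orient="index")
    enhancers.index.name = "enhancer_id"

    grng = cfg.rng("gene_baselines")
    baseline = np.exp(
        grng.normal(cfg.expr_baseline_log_mean, cfg.expr_baseline_log_sd, len(genes))
    )
    linked_class = {r.linked_gene: r["class"] for _, r in enhancers.iterrows() if r.linked_gene}
    gene_rows = {
        g.gene_id: {
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "baseline": baseline[i],
            "archetype": linked_class.get(g.gene_id, "flat"),
        }
        for i, g in enumerate(genes)
    }
    genes_df = pd.DataFrame.from_dict(gene_rows, orient="index")
    genes_df.index.name = "gene_id"
    # TF genes: highly expressed unlinked genes so the expression filter
    # passes; rename them in both the truth table and the gene models
    tf_names = ["Tfea1", "Tfea2", "Tfla1"]
    tf_gene_ids = [genes[n_linked + i].gene_id for i in range(3)]
    genes_df.loc[tf_gene_ids, "baseline"] = 500.0
    genes_df = genes_df.rename(index=dict(zip(tf_gene_ids, tf_names)))
    genes_df.loc[tf_names, "archetype"] = "tf"
    from dataclasses import replace as _dc_replace

    for i, name in enumerate(tf_names):
        genes[n_linked + i] = _dc_replace(genes[n_linked + i], gene_id=name)

    def class_ids(cls: str, idx: set[int]) -> list[str]:
        return [f"enh_{cls}_{j:03d}" for j in sorted(idx)]

    def linked(eids: list[str]) -> list[str]:
        out = []
        for e in eids:
            g = enhancers.loc[e, "linked_gene"]
            out.append(g)
        return out

    tfs = {
        "Tfea1": {
            "remodeling": True,
            "stage": "eA",
            "lineage": "astro",
            "motif_id": "M_EA1",
            "gene": "Tfea1",
            "target_enhancers": class_ids("eA_unique", ea1_idx),
            "target_genes": linked(class_ids("eA_unique", ea1_idx)),
            "up_genes": linked(class_ids("eA_unique", set(range(cut, cut + cfg.kd_n_up)))),
        },
        "Tfea2": {
            "remodeling": True,
            "stage": "eA",
            "lineage": "astro",
            "motif_id": "M_EA2",
            "gene": "Tfea2",
            "target_enhancers": class_ids("eA_unique", ea2_idx),
            "target_genes": linked(class_ids("eA_unique", ea2_idx)),
            "up_genes": linked(class_ids("eA_unique", set(range(0, cfg.kd_n_up)))),
        },
        "Tfla1": {
            "remodeling": False,
            "stage": "lA",
            "lineage": "astro",
            "motif_id": "M_LA1",
            "gene": "Tfla1",
            "target_enhancers": class_ids("lA_unique", la1_idx),
            "target_genes": linked(class_ids("lA_unique", la1_idx)),
            "up_genes": linked(class_ids("lA_unique", set(range(cut, cut + cfg.kd_n_up)))),
        },
    }
    # planted genes are renamed where they are TF genes (they are not linked)
    truth = TruthTables(enhancers=enhancers, genes=genes_df, tfs=tfs)
    return truth


def _enhancer_rate_multiplier(
    cfg: SimulationConfig,
    truth: TruthTables,
    chrom: str,
    n_bins: int,
    marked: pd.Series,
    fold: float,
    scale: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-bin Poisson rate multiplier from marked enhancers on one chromosome."""
    mult = np.ones(n_bins)
    sub = truth.enhancers[(truth.enhancers["chrom"] == chrom) & marked]
    bs = cfg.bin_size
    for eid, r in sub.iterrows():
        f = fold * (scale.get(eid, 1.0) if scale else 1.0)
        first, last = int(r.start) // bs, (int(r.end) - 1) // bs
        for b in range(first, last + 1):
            frac = (min(int(r.end), (b + 1) * bs) - max(int(r.start), b * bs)) / bs
            mult[b] += (f - 1.0) * frac
    return mult


def simulate_chip(
    cfg: SimulationConfig,
    truth: TruthTables,
    mark: str,
    stage: str,
    lineage: str,
    rng: np.random.Generator | None = None,
    kd_scale: dict[str, float] | None = None,
) -> BinnedTrack:
    """Poisson-binned ChIP track for one mark x stage x lineage condition.

    Background bins draw Poisson(lambda_bg); bins inside enhancers whose truth
    state implies the mark draw an elevated rate (enrichment fold for K27ac at
    active elements, the primed fold for K4me1). lambda_bg is set so the
    expected library size equals ``chip_depth``. ``kd_scale`` rescales the
    signal fold of selected enhancers (knockdown arms).
    """
    if rng is None:
        rng = cfg.rng(f"chip/{mark}/{stage}/{lineage}")
    fold = (
        cfg.enrichment_fold_active if mark == "K27ac" else cfg.enrichment_fold_primed
    )
    marked = truth.mark_presence(mark, stage, lineage)
    bins_per_chrom = cfg.chrom_len // cfg.bin_size
    total_bins = cfg.n_chroms * bins_per_chrom
    sub = truth.enhancers[np.asarray(marked)]
    extra = 0.0
    for eid, r in sub.iterrows():
        f = fold * (kd_scale.get(eid, 1.0) if kd_scale else 1.0)
        extra += (f - 1.0) * (int(r.end) - int(r.start)) / cfg.bin_size
    lam_bg = cfg.chip_depth / (total_bins + extra)
    counts = {}
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        mult = _enhancer_rate_multiplier(
            cfg, truth, chrom, bins_per_chrom, marked, fold, kd_scale
        )
        counts[chrom] = rng.poisson(lam_bg * mult).astype(float)
    return BinnedTrack(
        condition=f"{mark}/{stage}/{lineage}", bin_size=cfg.bin_size, counts=counts
    )


def simulate_input(cfg: SimulationConfig) -> BinnedTrack:
    """Genomic input: pure background at the same depth."""
    rng = cfg.rng("chip/input")
    bins_per_chrom = cfg.chrom_len // cfg.bin_size
    lam = cfg.chip_depth / (cfg.n_chroms * bins_per_chrom)
    counts = {
        f"chr{c + 1}": rng.poisson(lam, size=bins_per_chrom).astype(float)
        for c in range(cfg.n_chroms)
    }
    return BinnedTrack(condition="input", bin_size=cfg.bin_size, counts=counts)


def _stage_mu(cfg: SimulationConfig, truth: TruthTables, stage: str, lineage: str) -> np.ndarray:
    """Expected expression of every gene at one stage of one lineage."""
    si = (ASTRO_STAGES if lineage == "astro" else NEURO_STAGES).index(stage)
    active_classes = {
        cls
        for cls in ALL_CLASSES
        if CLASS_MARKS[cls][lineage]["K4me1"][si]
        and CLASS_MARKS[cls][lineage]["K27ac"][si]
    }
    linked_active = {
        r.linked_gene
        for _, r in truth.enhancers.iterrows()
        if r.linked_gene and r["class"] in active_classes
    }
    mu = truth.genes["baseline"].to_numpy(dtype=float).copy()
    boost = truth.genes.index.isin(linked_active)
    mu[boost] *= cfg.expr_boost
    return mu


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, alpha: float
) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2 via gamma-Poisson mixing."""
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mu * alpha)
    return rng.poisson(lam)


def simulate_expression(cfg: SimulationConfig, truth: TruthTables) -> CountMatrix:
    """NB expression counts over all stages x lineages x replicates.

    Gene means follow the baseline, multiplied by ``expr_boost`` at stages
    where a linked enhancer is active in that lineage; per-sample size factors
    jitter by +-``size_factor_jitter``.
    """
    rng = cfg.rng("expression")
    cols, design = {}, {}
    for lineage, stages in (("astro", ASTRO_STAGES), ("neuro", NEURO_STAGES)):
        for stage in stages:
            mu = _stage_mu(cfg, truth, stage, lineage)
            for rep in range(1, cfg.n_replicates + 1):
                sf = 1.0 + rng.uniform(-cfg.size_factor_jitter, cfg.size_factor_jitter)
                sample = f"{stage}_rep{rep}"
                cols[sample] = _nb_draw(rng, mu * sf, cfg.nb_dispersion)
                design[sample] = {
                    "stage": stage,
                    "lineage": lineage,
                    "replicate": rep,
                    "condition": "differentiation",
                }
    counts = pd.DataFrame(cols, index=truth.genes.index)
    return CountMatrix(counts=counts, design=pd.DataFrame.from_dict(design, orient="index"))


def simulate_knockdown(
    cfg: SimulationConfig, truth: TruthTables, tf: str
) -> KnockdownExperiment:
    """Control/kd arms for one TF at its stage.

    Remodeling TFs: the kd H3K27ac rate at motif-bearing target enhancers is
    scaled by ``kd_effect`` and target-gene means by 1/``expr_boost``.
    Non-remodeling TFs: chromatin is untouched; only direct target-gene means
    drop. A small planted set of indirectly upregulated genes (x``kd_up_fold``,
    chromatin untouched) gives the deregulated-gene linkage an up class.
    """
    if tf not in truth.tfs:
        raise KeyError(f"unknown TF {tf!r}")
    info = truth.tfs[tf]
    stage, lineage = info["stage"], info["lineage"]

    ctrl_track = simulate_chip(
        cfg, truth, "K27ac", stage, lineage, rng=cfg.rng(f"kd/{tf}/control_track")
    )
    kd_scale = (
        {e: cfg.kd_effect for e in info["target_enhancers"]}
        if info["remodeling"]
        else None
    )
    kd_track = simulate_chip(
        cfg,
        truth,
        "K27ac",
        stage,
        lineage,
        rng=cfg.rng(f"kd/{tf}/kd_track"),
        kd_scale=kd_scale,
    )

    rng = cfg.rng(f"kd/{tf}/expression")
    mu_ctrl = _stage_mu(cfg, truth, stage, lineage)
    mu_kd = mu_ctrl.copy()
    gidx = truth.genes.index
    mu_kd[gidx.isin(info["target_genes"])] /= cfg.expr_boost
    mu_kd[gidx.isin(info["up_genes"])] *= cfg.kd_up_fold
    mu_kd[gidx == info["gene"]] /= 4.0  # the depleted TF itself drops

    cols, design = {}, {}
    for cond, mu in (("control", mu_ctrl), ("kd", mu_kd)):
        for rep in range(1, cfg.n_replicates + 1):
            sf = 1.0 + rng.uniform(-cfg.size_factor_jitter, cfg.size_factor_jitter)
            sample = f"{tf}_{cond}_rep{rep}"
            cols[sample] = _nb_draw(rng, mu * sf, cfg.nb_dispersion)
            design[sample] = {
                "stage": stage,
                "lineage": lineage,
                "replicate": rep,
                "condition": cond,
            }
    counts = CountMatrix(
        counts=pd.DataFrame(cols, index=gidx),
        design=pd.DataFrame.from_dict(design, orient="index"),
    )
    return KnockdownExperiment(
        tf=tf, stage=stage, control_track=ctrl_track, kd_track=kd_track, counts=counts
    )


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the truth to score against."""

    cfg: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: TruthTables
    pwm_library: list[PWM]
    motif_to_gene: dict[str, str]
    tracks: dict[tuple[str, str, str], BinnedTrack]  # (mark, stage, lineage)
    input_track: BinnedTrack
    expression: CountMatrix
    annotation: GenomeAnnotation = field(init=False)

    def __post_init__(self) -> None:
        self.annotation = GenomeAnnotation(self.genes)

    def knockdown(self, tf: str) -> KnockdownExperiment:
        return simulate_knockdown(self.cfg, self.truth, tf)

    def stage_tracks(self, mark: str, lineage: str) -> dict[str, BinnedTrack]:
        stages = ASTRO_STAGES if lineage == "astro" else NEURO_STAGES
        return {s: self.tracks[(mark, s, lineage)] for s in stages}

    def write_all(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_gene_table(self.genes, out / "genes.tsv")
        write_bed(self.truth.all_peaks(), out / "enhancers.bed")
        self.truth.enhancers.to_csv(out / "enhancer_truth.tsv", sep="\t")
        self.truth.genes.to_csv(out / "gene_truth.tsv", sep="\t")
        write_pwms(self.pwm_library, out / "pwms.txt")
        with open(out / "motif_to_gene.tsv", "w") as fh:
            for m, g in self.motif_to_gene.items():
                fh.write(f"{m}\t{g}\n")
        for (mark, stage, lineage), tr in self.tracks.items():
            write_track(tr, out / f"track_{mark}_{stage}_{lineage}.bedgraph")
        write_track(self.input_track, out / "track_input.bedgraph")
        write_counts(self.expression, out / "counts.tsv", out / "design.tsv")
        import yaml

        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.cfg), fh, sort_keys=True)


def generate_dataset(cfg: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate the complete synthetic study from one config."""
    cfg = cfg or SimulationConfig()
    genome_arr, genes = simulate_genome(cfg)
    pwm_library, motif_to_gene = build_pwm_library(cfg)
    truth = plant_enhancers(cfg, genome_arr, genes, pwm_library)
    genome = {c: v.tobytes().decode("ascii") for c, v in genome_arr.items()}
    tracks = {}
    for lineage, stages in (("astro", ASTRO_STAGES), ("neuro", NEURO_STAGES)):
        for stage in stages:
            for mark in ("K4me1", "K27ac"):
                tracks[(mark, stage, lineage)] = simulate_chip(
                    cfg, truth, mark, stage, lineage
                )
    return SimulatedDataset(
        cfg=cfg,
        genome=genome,
        genes=genes,
        truth=truth,
        pwm_library=pwm_library,
        motif_to_gene=motif_to_gene,
        tracks=tracks,
        input_track=simulate_input(cfg),
        expression=simulate_expression(cfg, truth),
    )
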