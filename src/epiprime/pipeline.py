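"""End-to-end orchestration: simulate -> peaks -> states -> DE -> motifs -> KD.

`run_pipeline` executes the full analysis on a simulated dataset and writes a
machine-readable JSON report plus TSV artifacts. Every analysis number in the
report is computed by the library modules; when truth tables are present the
report gains a recovery-metrics section (precision/recall of stage-unique
element discovery, trajectory-label accuracy, clustering ARI).
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import de as de_mod
from . import states as states_mod
from .annotation import annotate_region
from .intervals import GenomicInterval, PeakSet, overlap_pairs, stage_unique_sets
from .motifs import (
    calibrate_threshold,
    gc_matched_background,
    motif_enrichment,
    motif_set_comparison,
    nominate_tfs,
    scan_regions,
)
from .perturbation import (
    TargetSiteSet,
    coregulation_overlap,
    kd_chromatin_effect,
    kd_deregulated_genes,
    link_deregulated_to_sites,
)
from .signal import call_peaks, enrichment_matrix, marked_status
from .simulate import (
    ASTRO_STAGES,
    NEURO_STAGES,
    STAGE_UNIQUE_CLASSES,
    SimulatedDataset,
    SimulationConfig,
    generate_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "random_pool"]


@dataclass
class PipelineConfig:
    """Analysis knobs on top of a simulation config."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    mark_threshold: float = 1.0
    min_overlap_bp: int = 1
    peak_fdr: float = 0.05
    peak_min_log2fc: float = 1.0
    max_tss_dist: int = 50_000
    k_trajectory: int = 6
    k_temporal: int = 5
    de_fdr_cut: float = 0.1
    motif_threshold_pvalue: float = 1e-4
    motif_fdr_cut: float = 0.05
    min_tf_expr: float = 1.0
    gc_ratio: int = 2
    gc_bins: int = 10

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig(**self.simulate)
        self.simulate.seed = self.seed


_RANGES = {
    "mark_threshold": (-10.0, 10.0),
    "min_overlap_bp": (1, 10_000),
    "peak_fdr": (0.0, 1.0),
    "max_tss_dist": (1, 10_000_000),
    "k_trajectory": (2, 100),
    "k_temporal": (2, 100),
    "de_fdr_cut": (0.0, 1.0),
    "motif_threshold_pvalue": (0.0, 1.0),
    "motif_fdr_cut": (0.0, 1.0),
    "gc_ratio": (1, 100),
    "gc_bins": (1, 100),
}


def validate_config(data: dict) -> list[str]:
    """Return a list of violations (empty = valid). Unknown keys are rejected."""
    violations = []
    known = {f.name for f in fields(PipelineConfig)}
    sim_known = {f.name for f in fields(SimulationConfig)}
    for key in data:
        if key not in known:
            violations.append(f"unknown key {key!r}")
    for key, val in (data.get("simulate") or {}).items():
        if key not in sim_known:
            violations.append(f"unknown key simulate.{key!r}")
    for key, (lo, hi) in _RANGES.items():
        if key in data and not (lo <= data[key] <= hi):
            violations.append(f"{key} must be in [{lo}, {hi}], got {data[key]}")
    if data.get("k_trajectory", 2) < 2:
        violations.append("k_trajectory must be >= 2")
    if violations:
        return violations
    try:
        PipelineConfig(**data)
    except (TypeError, ValueError) as exc:
        violations.append(str(exc))
    return violations


def merge_peaks(peak_sets: list[PeakSet], label: str = "merged") -> PeakSet:
    """Union of several peak sets with overlapping intervals merged."""
    ivs = sorted(iv for ps in peak_sets for iv in ps)
    merged = []
    for iv in ivs:
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end:
            last = merged.pop()
            merged.append(
                GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
            )
        else:
            merged.append(iv)
    named = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"region{n:05d}")
        for n, iv in enumerate(merged)
    ]
    return PeakSet(named, label=label)


def random_pool(
    cfg: SimulationConfig,
    exclude: PeakSet,
    n: int = 3000,
    seed: int = 1,
    widths: list[int] | None = None,
) -> PeakSet:
    """Random genomic windows avoiding an exclusion set.

    Window widths are sampled from ``widths`` (e.g. the target peak widths, so
    the background is length-matched and per-region hit probabilities are
    comparable); defaults to the configured enhancer width.
    """
    rng = np.random.default_rng([seed, 0xB6])
    widths = list(widths) if widths else [cfg.enhancer_width]
    excl = exclude.by_chrom()
    out = []
    tries = 0
    while len(out) < n and tries < 50 * n:
        tries += 1
        width = int(widths[int(rng.integers(0, len(widths)))])
        chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        start = int(rng.integers(0, cfg.chrom_len - width))
        iv = GenomicInterval(chrom, start, start + width, name=f"pool{len(out):05d}")
        if any(
            iv.start < e.end and e.start < iv.end for e in excl.get(chrom, [])
        ):
            continue
        out.append(iv)
    return PeakSet(out, label="pool")


def recovery_metrics(called: PeakSet, truth: PeakSet, min_bp: int = 1) -> dict:
    """Precision/recall of a called set against a truth set by >=min_bp overlap."""
    pairs = overlap_pairs(called, truth, min_bp=min_bp) if len(called) and len(truth) else []
    called_hit = {(a.chrom, a.start, a.end) for a, _ in pairs}
    truth_hit = {(b.chrom, b.start, b.end) for _, b in pairs}
    precision = len(called_hit) / len(called) if len(called) else float("nan")
    recall = len(truth_hit) / len(truth) if len(truth) else float("nan")
    return {
        "n_called": len(called),
        "n_truth": len(truth),
        "precision": precision,
        "recall": recall,
    }


def _stage_label(lineage: str, i: int) -> str:
    return (ASTRO_STAGES if lineage == "astro" else NEURO_STAGES)[i]


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run the full analysis; returns the report dict (and writes artifacts)."""
    t0 = time.time()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": {"seed": config.seed}}
    ds = generate_dataset(config.simulate)
    truth = ds.truth
    ann = ds.annotation

    # --- peak calling per condition ------------------------------------
    called: dict[tuple[str, str, str], PeakSet] = {}
    for key, track in ds.tracks.items():
        called[key] = call_peaks(
            track, fdr=config.peak_fdr, min_log2fc=config.peak_min_log2fc
        )
    report["peak_counts"] = {
        "/".join(k): len(v) for k, v in sorted(called.items())
    }

    # --- stage-unique K27ac sets per lineage (Venn logic) ---------------
    unique_sets: dict[str, dict[str, PeakSet]] = {}
    for lineage, stages in (("astro", ASTRO_STAGES), ("neuro", NEURO_STAGES)):
        per_stage = {s: called[("K27ac", s, lineage)] for s in stages}
        part = stage_unique_sets(per_stage, min_bp=config.min_overlap_bp)
        unique_sets[lineage] = {s: part[s]["unique"] for s in stages}
    report["stage_unique_counts"] = {
        lin: {s: len(ps) for s, ps in d.items()} for lin, d in unique_sets.items()
    }

    # --- genomic annotation breakdown of eA K27ac peaks -----------------
    breakdown: dict[str, int] = {"promoter": 0, "exon": 0, "intron": 0, "intergenic": 0}
    for iv in called[("K27ac", "eA", "astro")]:
        breakdown[annotate_region(iv, ann)] += 1
    report["annotation_breakdown_eA_K27ac"] = breakdown

    # --- chromatin states over merged regions ---------------------------
    regions = merge_peaks(list(called.values()), label="all_regions")
    sig = {}
    status = {"K4me1": {}, "K27ac": {}}
    for lineage, stages in (("astro", ASTRO_STAGES), ("neuro", NEURO_STAGES)):
        for mark in ("K4me1", "K27ac"):
            tracks = {s: ds.tracks[(mark, s, lineage)] for s in stages}
            mat = enrichment_matrix(tracks, ds.input_track, regions)
            sig[(mark, lineage)] = mat
            status[mark][lineage] = marked_status(mat, config.mark_threshold)
    trajectories = states_mod.build_trajectories(
        status["K4me1"], status["K27ac"], regions
    )
    report["n_regions"] = len(regions)
    report["primed_then_activated"] = {
        s: sum(1 for t in trajectories if t.astro_activation_stage == s)
        for s in ASTRO_STAGES[1:]
    }

    # --- trajectory clustering of progenitor-primed regions -------------
    primed_idx = [
        t.region_id
        for t in trajectories
        if t.astro_states[0]
        in (states_mod.ChromatinState.PRIMED, states_mod.ChromatinState.ACTIVE)
    ]
    feat = pd.concat(
        [
            sig[(mark, lineage)].values.add_prefix(f"{mark}/{lineage}/")
            for mark in ("K4me1", "K27ac")
            for lineage in ("astro", "neuro")
        ],
        axis=1,
    ).loc[primed_idx]
    clustering = states_mod.cluster_trajectories(
        feat, k=config.k_trajectory, seed=config.seed
    )
    report["trajectory_clusters"] = (
        clustering.assignments.value_counts().sort_index().to_dict()
    )

    # --- expression analyses --------------------------------------------
    cm = ds.expression
    astro_samples = list(cm.design.index[cm.design["lineage"] == "astro"])
    astro_cm = cm.subset_samples(astro_samples)
    coords, varexp = de_mod.pca_samples(astro_cm)
    report["pca_variance_explained"] = [float(v) for v in varexp]

    de_union: set[str] = set()
    de_summary = {}
    for a, b in zip(ASTRO_STAGES[:-1], ASTRO_STAGES[1:]):
        ga = list(cm.design.index[cm.design["stage"] == a])
        gb = list(cm.design.index[cm.design["stage"] == b])
        res = de_mod.de_test(cm, ga, gb, fdr_cut=config.de_fdr_cut)
        de_summary[f"{a}_vs_{b}"] = {
            "n_de": int(res.table["de"].sum()),
            "n_up": len(res.direction_sets()["up"]),
            "n_down": len(res.direction_sets()["down"]),
        }
        de_union |= set(res.de_genes)
    report["de_contrasts"] = de_summary

    stage_expr = de_mod.stage_mean_expression(cm, lineage="astro")
    profiles = stage_expr.loc[sorted(de_union & set(stage_expr.index))]
    k_temp = min(config.k_temporal, max(2, len(profiles) // 10))
    temporal = de_mod.temporal_clusters(profiles, k=k_temp, seed=config.seed)
    report["temporal_clusters"] = (
        temporal.assignments.value_counts().sort_index().to_dict()
    )

    # --- expression coupling of stage-unique active elements ------------
    coupling = states_mod.expression_coupling(
        unique_sets["astro"], ann, stage_expr, max_tss_dist=config.max_tss_dist
    )
    report["expression_coupling"] = {
        s: {
            "n_genes": len(coupling.gene_sets.get(s, [])),
            "p": coupling.pvalues.get(s),
            "median_own": coupling.medians.get(s, (None, None))[0],
            "median_other": coupling.medians.get(s, (None, None))[1],
        }
        for s in ASTRO_STAGES
    }

    # --- motif enrichment and TF nomination ------------------------------
    thresholds = {
        p.motif_id: calibrate_threshold(p, config.motif_threshold_pvalue)
        for p in ds.pwm_library
    }
    all_called = merge_peaks(list(called.values()), label="called_union")
    called_widths = [iv.length for iv in all_called]
    pool = random_pool(
        config.simulate, all_called, n=3000, seed=config.seed, widths=called_widths
    )
    enr: dict[tuple[str, str], pd.DataFrame] = {}
    for lineage in ("astro", "neuro"):
        for s in (ASTRO_STAGES if lineage == "astro" else NEURO_STAGES):
            targets = unique_sets[lineage][s]
            if len(targets) == 0:
                continue
            bg = gc_matched_background(
                targets,
                pool,
                ds.genome,
                ratio=config.gc_ratio,
                bins=config.gc_bins,
                seed=config.seed,
            )
            enr[(lineage, s)] = motif_enrichment(
                targets,
                bg,
                ds.genome,
                ds.pwm_library,
                thresholds=thresholds,
                fdr_cut=config.motif_fdr_cut,
            )
    venn = {}
    nominations = {}
    for a_stage, n_stage in zip(ASTRO_STAGES, NEURO_STAGES):
        ta = enr.get(("astro", a_stage))
        tn = enr.get(("neuro", n_stage))
        if ta is None or tn is None:
            continue
        part = motif_set_comparison(
            set(ta.index[ta["enriched"]]), set(tn.index[tn["enriched"]])
        )
        venn[f"{a_stage}_vs_{n_stage}"] = {k: sorted(v) for k, v in part.items()}
        nom = nominate_tfs(
            ta, tn, stage_expr, a_stage, ds.motif_to_gene, min_expr=config.min_tf_expr
        )
        nominations[a_stage] = nom.to_dict(orient="records")
    report["motif_venn"] = venn
    report["tf_nominations"] = nominations

    # --- knockdown analyses ----------------------------------------------
    kd_report = {}
    down_sets: dict[str, list[str]] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    for tf, info in truth.tfs.items():
        exp = ds.knockdown(tf)
        stage = info["stage"]
        stage_peaks = unique_sets["astro"][stage]
        motif_hits = scan_regions(
            next(p for p in ds.pwm_library if p.motif_id == info["motif_id"]),
            stage_peaks,
            ds.genome,
            thresholds[info["motif_id"]],
        )
        sites = TargetSiteSet(
            tf=tf,
            stage=stage,
            sites=PeakSet(
                [
                    iv
                    for iv, hit in zip(stage_peaks, motif_hits.to_numpy())
                    if hit
                ],
                label=f"{tf}/targets",
            ),
            motif_id=info["motif_id"],
        )
        effect = kd_chromatin_effect(exp, sites, ds.input_track)
        # linkage needs the chromatin change at every stage peak, motif or not
        effect_all = kd_chromatin_effect(exp, stage_peaks, ds.input_track)
        dereg = kd_deregulated_genes(exp, fdr_cut=config.de_fdr_cut)
        res = dereg.pop("result")
        down_sets[tf] = dereg["down"]
        de_tables[tf] = res.table
        link = link_deregulated_to_sites(
            dereg,
            res.table,
            stage_peaks,
            ann,
            effect_all.delta,
            max_tss_dist=config.max_tss_dist,
        )
        kd_report[tf] = {
            "remodeling_truth": bool(info["remodeling"]),
            "n_target_sites": len(sites.sites),
            "median_delta_log2": float(np.median(effect.delta)),
            "chromatin_p": effect.p,
            "n_down": len(dereg["down"]),
            "n_up": len(dereg["up"]),
            "linkage_p": link.p,
            "linkage_median_delta": {
                c: (float(np.median(v)) if len(v) else None)
                for c, v in link.deltas.items()
            },
        }
    report["knockdowns"] = kd_report

    # --- two-TF co-regulation --------------------------------------------
    detected = [
        set(t.index[(t[["mean_a", "mean_b"]] > 0).any(axis=1)])
        for t in (de_tables["Tfea1"], de_tables["Tfea2"])
    ]
    universe = len(detected[0] & detected[1])
    both_motif_genes = set(truth.tfs["Tfea1"]["target_genes"]) & set(
        truth.tfs["Tfea2"]["target_genes"]
    )
    overlap = coregulation_overlap(
        down_sets["Tfea1"], down_sets["Tfea2"], universe, both_motif_genes
    )
    overlap.pop("overlap_genes")
    overlap.pop("co_bound_genes")
    report["coregulation"] = overlap

    # --- recovery metrics vs truth ----------------------------------------
    recov = {}
    for cls in STAGE_UNIQUE_CLASSES:
        stage = cls.split("_")[0]
        lineage = "astro" if stage in ASTRO_STAGES else "neuro"
        recov[cls] = recovery_metrics(
            unique_sets[lineage][stage], truth.class_peaks(cls)
        )
    # trajectory-label accuracy: primed-then-activated stage vs truth class
    truth_stage = {}
    for eid, r in truth.enhancers.iterrows():
        cls = r["class"]
        truth_stage[eid] = (
            cls.split("_")[0] if cls in ("eA_unique", "lA_unique") else None
        )
    enh_peaks = truth.all_peaks()
    region_for_enh = {}
    for a, b in overlap_pairs(enh_peaks, regions):
        region_for_enh.setdefault(a.name, b.name)
    traj_by_id = {t.region_id: t for t in trajectories}
    n_ok = n_tot = 0
    for eid, expected in truth_stage.items():
        rid = region_for_enh.get(eid)
        got = (
            traj_by_id[rid].astro_activation_stage
            if rid is not None and rid in traj_by_id
            else None
        )
        n_ok += got == expected
        n_tot += 1
    recov["trajectory_label_accuracy"] = n_ok / n_tot

    # clustering ARI vs planted classes on progenitor-primed regions
    enh_class = truth.enhancers["class"].to_dict()
    truth_labels, pred_labels = [], []
    enh_for_region = {}
    for a, b in overlap_pairs(enh_peaks, regions):
        enh_for_region.setdefault(b.name, a.name)
    for rid in primed_idx:
        eid = enh_for_region.get(rid)
        if eid is None:
            continue
        truth_labels.append(enh_class[eid])
        pred_labels.append(int(clustering.assignments.loc[rid]))
    recov["trajectory_ari"] = float(adjusted_rand_score(truth_labels, pred_labels))
    recov["coreg_overlap_truth"] = len(both_motif_genes)
    report["recovery"] = recov
    logger.info("pipeline finished in %.1f s", time.time() - t0)

    if out is not None:
        ds.write_all(out / "data")
        clustering.assignments.to_csv(out / "trajectory_clusters.tsv", sep="\t")
        temporal.assignments.to_csv(out / "temporal_clusters.tsv", sep="\t")
        coords.to_csv(out / "pca_coordinates.tsv", sep="\t")
        for (lineage, s), table in enr.items():
            table.to_csv(out / f"motif_enrichment_{lineage}_{s}.tsv", sep="\t")
        for tf, table in de_tables.items():
            table.to_csv(out / f"kd_de_{tf}.tsv", sep="\t")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
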