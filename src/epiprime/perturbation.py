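"""Knockdown consequence analysis: chromatin effects, deregulated genes, linkage.

A knockdown experiment pairs a control arm and a TF-depleted arm, each with an
H3K27ac track and expression count columns. A "remodeling" TF is one whose
depletion lowers H3K27ac at its motif-bearing target elements; the per-site
change is the difference of log2-over-input enrichments (kd minus control),
tested one-sided with a paired Wilcoxon signed-rank test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation, assign_peaks_to_genes
from .de import CountMatrix, de_test
from .intervals import PeakSet
from .signal import BinnedTrack, log2_enrichment, profile_matrix, quantify

__all__ = [
    "KnockdownExperiment",
    "TargetSiteSet",
    "kd_chromatin_effect",
    "kd_deregulated_genes",
    "link_deregulated_to_sites",
    "coregulation_overlap",
]

logger = logging.getLogger(__name__)


@dataclass
class KnockdownExperiment:
    tf: str
    stage: str
    control_track: BinnedTrack
    kd_track: BinnedTrack
    counts: CountMatrix  # condition column in design: "control" / "kd"

    def __post_init__(self) -> None:
        if self.control_track.bin_size != self.kd_track.bin_size:
            raise ValueError("control and kd tracks must share the bin size")
        conds = set(self.counts.design["condition"])
        if not {"control", "kd"} <= conds:
            raise ValueError("counts design must have control and kd conditions")

    def arm_samples(self, condition: str) -> list[str]:
        d = self.counts.design
        return list(d.index[d["condition"] == condition])


@dataclass
class TargetSiteSet:
    """Stage-unique H3K27ac peaks carrying >= 1 hit of the TF's motif."""

    tf: str
    stage: str
    sites: PeakSet
    motif_id: str = ""


@dataclass
class ChromatinEffect:
    delta: pd.Series  # per-site kd - control log2 enrichment
    p: float  # one-sided paired Wilcoxon (H1: delta < 0)
    test: str
    control_profile: np.ndarray
    kd_profile: np.ndarray
    degenerate: bool = False


def kd_chromatin_effect(
    exp: KnockdownExperiment,
    sites: TargetSiteSet | PeakSet,
    input_track: BinnedTrack,
    pseudocount: float = 1.0,
    profile_window: int = 2000,
    profile_bins: int = 41,
) -> ChromatinEffect:
    """Per-site Delta log2 H3K27ac enrichment (kd - control) with a paired test.

    The one-sided Wilcoxon signed-rank test asks whether knockdown lowered
    acetylation at the sites (H1: Delta < 0). Also returns the mean
    enrichment profiles of both arms for plotting.
    """
    peaks = sites.sites if isinstance(sites, TargetSiteSet) else sites
    keep = [iv for iv in peaks if iv.chrom in exp.control_track.counts]
    if len(keep) < len(peaks):
        logger.warning("dropped %d sites on missing chromosomes", len(peaks) - len(keep))
    peaks = PeakSet(keep, label=peaks.label)
    if len(peaks) < 10:
        raise ValueError("need at least 10 usable sites")

    inp = quantify(input_track, peaks)
    ctrl = log2_enrichment(
        quantify(exp.control_track, peaks),
        inp,
        exp.control_track.library_size,
        input_track.library_size,
        pseudocount,
    )
    kd = log2_enrichment(
        quantify(exp.kd_track, peaks),
        inp,
        exp.kd_track.library_size,
        input_track.library_size,
        pseudocount,
    )
    delta = pd.Series(kd - ctrl, index=peaks.region_ids(), name="delta_log2")

    if np.allclose(delta, 0.0):
        p, degenerate = 1.0, True
    else:
        p = float(stats.wilcoxon(delta, alternative="less").pvalue)
        degenerate = False
    ctrl_prof = profile_matrix(
        exp.control_track, peaks, profile_window, profile_bins, input_track, pseudocount
    )
    kd_prof = profile_matrix(
        exp.kd_track, peaks, profile_window, profile_bins, input_track, pseudocount
    )
    return ChromatinEffect(
        delta=delta,
        p=p,
        test="wilcoxon signed-rank, one-sided (delta < 0)",
        control_profile=ctrl_prof.profile(),
        kd_profile=kd_prof.profile(),
        degenerate=degenerate,
    )


def kd_deregulated_genes(
    exp: KnockdownExperiment, fdr_cut: float = 0.1
) -> dict[str, list[str]]:
    """Up- and down-regulated gene sets of kd vs control at the FDR cutoff."""
    res = de_test(
        exp.counts,
        group_a=exp.arm_samples("control"),
        group_b=exp.arm_samples("kd"),
        fdr_cut=fdr_cut,
    )
    sets = res.direction_sets()
    sets["result"] = res  # full table for downstream classification
    return sets


UNCHANGED_FDR = 0.5
UNCHANGED_LFC = 0.25


@dataclass
class LinkageResult:
    deltas: dict[str, pd.Series]  # direction class -> per-site delta
    p: float | None  # rank-sum p: delta(down) < delta(unchanged)
    skipped: list[str]
    test: str = "mann-whitney, one-sided (down < unchanged)"


def link_deregulated_to_sites(
    gene_sets: dict[str, list[str]],
    de_table: pd.DataFrame,
    stage_peaks: PeakSet,
    ann: GenomeAnnotation,
    delta: pd.Series,
    max_tss_dist: int = 50_000,
    min_class_size: int = 5,
) -> LinkageResult:
    """Partition sites by the regulation direction of their nearest gene.

    Sites are assigned to genes with the standard containment / <50 kb rule;
    classes are down, up and unchanged (fdr >= 0.5 and |log2fc| < 0.25).
    Tests whether down-linked sites lost more acetylation than
    unchanged-linked ones.
    """
    site_gene = assign_peaks_to_genes(stage_peaks, ann, max_tss_dist)
    down, up = set(gene_sets["down"]), set(gene_sets["up"])
    unchanged = set(
        de_table.index[
            (de_table["fdr"] >= UNCHANGED_FDR)
            & (de_table["log2fc"].abs() < UNCHANGED_LFC)
        ]
    )
    classes: dict[str, list[str]] = {"down": [], "up": [], "unchanged": []}
    for rid, gene in site_gene.items():
        if gene is None or rid not in delta.index:
            continue
        if gene in down:
            classes["down"].append(rid)
        elif gene in up:
            classes["up"].append(rid)
        elif gene in unchanged:
            classes["unchanged"].append(rid)
    deltas = {c: delta.loc[rids] for c, rids in classes.items()}
    skipped = [c for c, v in deltas.items() if len(v) < min_class_size]
    if "down" in skipped or "unchanged" in skipped:
        return LinkageResult(deltas=deltas, p=None, skipped=skipped)
    p = float(
        stats.mannwhitneyu(
            deltas["down"], deltas["unchanged"], alternative="less"
        ).pvalue
    )
    return LinkageResult(deltas=deltas, p=p, skipped=skipped)


def coregulation_overlap(
    down_a: set[str] | list[str],
    down_b: set[str] | list[str],
    universe: int,
    genes_with_both_motifs: set[str] | list[str] = (),
) -> dict:
    """Overlap of two TFs' downregulated gene sets with a hypergeometric p.

    ``universe`` is the number of genes detected in both experiments. The
    one-sided p is the probability of an overlap at least this large when the
    two sets are drawn independently from the universe. ``co_bound`` counts
    overlap genes whose regulatory sites carry both TFs' motifs.
    """
    a, b = set(down_a), set(down_b)
    if universe < max(len(a), len(b)):
        raise ValueError("universe smaller than a gene set")
    overlap = a & b
    k = len(overlap)
    p = float(stats.hypergeom.sf(k - 1, universe, len(a), len(b)))
    co_bound = overlap & set(genes_with_both_motifs)
    return {
        "n_down_a": len(a),
        "n_down_b": len(b),
        "universe": universe,
        "overlap": k,
        "overlap_genes": sorted(overlap),
        "p": p,
        "co_bound": len(co_bound),
        "co_bound_genes": sorted(co_bound),
        "test": "hypergeometric, one-sided (overlap >= observed)",
    }
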