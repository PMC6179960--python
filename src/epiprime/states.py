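"""Chromatin-state logic: primed/active calls, trajectories, clustering, coupling.

The state of a regulatory element at one stage follows the two-mark logic:
H3K4me1 without H3K27ac marks a *primed* enhancer, H3K4me1 with H3K27ac an
*active* one; H3K27ac alone is kept as a separate ``acetyl_only`` state so the
2x2 table stays lossless. A region is called *primed-then-activated* at stage
s when it is primed at the stage preceding s and active at s — the signature
of epigenetic priming preceding activation.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .annotation import GenomeAnnotation, assign_nearest_gene
from .intervals import PeakSet

__all__ = [
    "ChromatinState",
    "StateTrajectory",
    "TrajectoryClustering",
    "assign_state",
    "build_trajectories",
    "cluster_trajectories",
    "expression_coupling",
]

ASTRO_STAGES = ("aNPC", "eA", "lA")
NEURO_STAGES = ("nNPC", "eN", "lN")


class ChromatinState(str, Enum):
    NONE = "none"
    PRIMED = "primed"
    ACTIVE = "active"
    ACETYL_ONLY = "acetyl_only"


def assign_state(k4me1_marked: bool, k27ac_marked: bool) -> ChromatinState:
    """Four-way state from the two marks (primed = K4me1 only, active = both)."""
    if k4me1_marked and k27ac_marked:
        return ChromatinState.ACTIVE
    if k4me1_marked:
        return ChromatinState.PRIMED
    if k27ac_marked:
        return ChromatinState.ACETYL_ONLY
    return ChromatinState.NONE


@dataclass
class StateTrajectory:
    """Ordered states for one region across the stages of both lineages."""

    region_id: str
    astro_states: tuple[ChromatinState, ...]
    neuro_states: tuple[ChromatinState, ...]
    astro_activation_stage: str | None = None  # primed-then-activated stage
    neuro_activation_stage: str | None = None


def _activation_stage(
    states: tuple[ChromatinState, ...], stages: tuple[str, ...]
) -> str | None:
    for i in range(1, len(states)):
        if (
            states[i - 1] is ChromatinState.PRIMED
            and states[i] is ChromatinState.ACTIVE
        ):
            return stages[i]
    return None


def build_trajectories(
    k4me1_status: dict[str, pd.DataFrame],
    k27ac_status: dict[str, pd.DataFrame],
    regions: PeakSet,
    stage_order: dict[str, tuple[str, ...]] | None = None,
) -> list[StateTrajectory]:
    """One StateTrajectory per region from per-lineage marked-status tables.

    ``k4me1_status`` / ``k27ac_status`` map lineage ("astro", "neuro") to a
    boolean regions x stages DataFrame. All tables must share the region index.
    """
    stage_order = stage_order or {"astro": ASTRO_STAGES, "neuro": NEURO_STAGES}
    rids = regions.region_ids()
    for lineage in ("astro", "neuro"):
        for tbl in (k4me1_status[lineage], k27ac_status[lineage]):
            if list(tbl.index) != rids:
                raise ValueError(f"{lineage}: status index does not match regions")

    out = []
    for rid in rids:
        per_lineage = {}
        for lineage in ("astro", "neuro"):
            stages = stage_order[lineage]
            k4 = k4me1_status[lineage].loc[rid, list(stages)]
            k27 = k27ac_status[lineage].loc[rid, list(stages)]
            per_lineage[lineage] = tuple(
                assign_state(bool(a), bool(b)) for a, b in zip(k4, k27)
            )
        out.append(
            StateTrajectory(
                region_id=rid,
                astro_states=per_lineage["astro"],
                neuro_states=per_lineage["neuro"],
                astro_activation_stage=_activation_stage(
                    per_lineage["astro"], stage_order["astro"]
                ),
                neuro_activation_stage=_activation_stage(
                    per_lineage["neuro"], stage_order["neuro"]
                ),
            )
        )
    return out


@dataclass
class TrajectoryClustering:
    k: int
    assignments: pd.Series  # region id -> cluster label (0..k-1)
    centroids: np.ndarray  # k x n_features (z-scored space)
    inertia: float
    seed: int


def cluster_trajectories(
    sig: pd.DataFrame,
    k: int = 7,
    seed: int = 0,
    n_restarts: int = 25,
    zscore_rows: bool = True,
) -> TrajectoryClustering:
    """k-means over per-region enrichment patterns (rows z-scored).

    ``sig`` is a regions x (stage, mark, lineage) enrichment table, typically
    restricted to the regions primed (or already active) at the progenitor
    stage. Rows with zero variance cannot be z-scored and are rejected.
    Deterministic given ``seed``; ``n_restarts`` random initialisations keep
    the best within-cluster sum of squares.
    """
    X = sig.to_numpy(dtype=float)
    if zscore_rows:
        sd = X.std(axis=1)
        if (sd == 0).any():
            raise ValueError("rows with zero variance cannot be z-scored")
        X = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    n_distinct = np.unique(X, axis=0).shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct rows")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return TrajectoryClustering(
        k=k,
        assignments=pd.Series(labels, index=sig.index, name="cluster"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
    )


@dataclass
class CouplingResult:
    gene_sets: dict[str, list[str]]  # stage -> non-overlapping assigned genes
    medians: dict[str, tuple[float, float]]  # stage -> (own, other) median expr
    pvalues: dict[str, float]  # stage -> one-sided rank-sum p (own > other)
    skipped: list[str]


def expression_coupling(
    unique_active: dict[str, PeakSet],
    ann: GenomeAnnotation,
    expr: pd.DataFrame,
    max_tss_dist: int = 50_000,
) -> CouplingResult:
    """Couple stage-unique active elements to stage-restricted expression.

    Each stage's unique active peaks are assigned to genes by the
    containment / <50 kb nearest-TSS rule; genes claimed by more than one
    stage are discarded (non-overlapping Venn logic). For each stage, each
    gene is reduced to a stage-preference score — its own-stage expression
    minus the mean of its other-stage expression, so the gene's baseline
    cancels — and a one-sided Mann-Whitney rank-sum test compares the scores
    of the stage's gene set against all remaining genes. Scores are
    independent across genes, so the rank-sum null is exact: with random
    gene-region links the p-values are uniform. ``expr`` is a gene x stage
    table of log2-normalised expression.
    """
    assigned: dict[str, set[str]] = {}
    for stage, peaks in unique_active.items():
        genes = {
            g
            for iv in peaks
            if (g := assign_nearest_gene(iv, ann, max_tss_dist)) is not None
        }
        assigned[stage] = genes & set(expr.index)

    claimed: dict[str, int] = {}
    for genes in assigned.values():
        for g in genes:
            claimed[g] = claimed.get(g, 0) + 1
    gene_sets = {
        stage: sorted(g for g in genes if claimed[g] == 1)
        for stage, genes in assigned.items()
    }

    expr_mat = expr.to_numpy(dtype=float)
    col = {s: i for i, s in enumerate(expr.columns)}
    pos = {g: i for i, g in enumerate(expr.index)}

    medians, pvalues, skipped = {}, {}, []
    stages = list(unique_active)
    for stage in stages:
        genes = gene_sets[stage]
        if not genes:
            skipped.append(stage)
            continue
        gene_idx = np.array([pos[g] for g in genes])
        other_cols = [col[s] for s in expr.columns if s != stage]
        own = expr_mat[gene_idx, col[stage]]
        other = expr_mat[np.ix_(gene_idx, other_cols)].ravel()
        medians[stage] = (float(np.median(own)), float(np.median(other)))
        # per-gene stage preference: own-stage minus mean other-stage signal
        scores = expr_mat[:, col[stage]] - expr_mat[:, other_cols].mean(axis=1)
        in_set = np.zeros(len(expr), dtype=bool)
        in_set[gene_idx] = True
        if np.ptp(scores) == 0:
            pvalues[stage] = 1.0
            continue
        stat = stats.mannwhitneyu(
            scores[in_set], scores[~in_set], alternative="greater"
        )
        pvalues[stage] = float(stat.pvalue)
    return CouplingResult(
        gene_sets=gene_sets, medians=medians, pvalues=pvalues, skipped=skipped
    )
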