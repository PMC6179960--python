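"""Knockdown chromatin effects, deregulated genes, linkage, co-regulation."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiprime.de import CountMatrix
from epiprime.intervals import GenomicInterval, PeakSet
from epiprime.perturbation import (
    KnockdownExperiment,
    TargetSiteSet,
    coregulation_overlap,
    kd_chromatin_effect,
    kd_deregulated_genes,
    link_deregulated_to_sites,
)
from epiprime.signal import BinnedTrack


def make_tracks(rng, n_bins=2000, lam=30.0, sites=None, fold=8.0, kd_retain=None):
    """Control/kd/input tracks with enriched 3-bin sites; kd optionally scaled."""
    sites = sites or []
    mult_c = np.ones(n_bins)
    mult_k = np.ones(n_bins)
    for b in sites:
        mult_c[b : b + 3] = fold
        mult_k[b : b + 3] = fold * (kd_retain if kd_retain is not None else 1.0)
    ctrl = BinnedTrack("ctrl", 200, {"chr1": rng.poisson(lam * mult_c).astype(float)})
    kd = BinnedTrack("kd", 200, {"chr1": rng.poisson(lam * mult_k).astype(float)})
    inp = BinnedTrack("input", 200, {"chr1": rng.poisson(lam, n_bins).astype(float)})
    return ctrl, kd, inp


def make_counts(rng, mu_ctrl, mu_kd, n_rep=3, alpha=0.1):
    genes = [f"g{i}" for i in range(len(mu_ctrl))]
    cols, design = {}, {}
    for cond, mu in (("control", mu_ctrl), ("kd", mu_kd)):
        for r in range(n_rep):
            lam = rng.gamma(1 / alpha, np.asarray(mu) * alpha)
            cols[f"{cond}{r}"] = rng.poisson(lam)
            design[f"{cond}{r}"] = {
                "stage": "eA",
                "lineage": "astro",
                "replicate": r,
                "condition": cond,
            }
    return CountMatrix(
        counts=pd.DataFrame(cols, index=genes),
        design=pd.DataFrame.from_dict(design, orient="index"),
    )


def make_exp(rng, ctrl, kd, mu_ctrl=None, mu_kd=None):
    mu_ctrl = mu_ctrl if mu_ctrl is not None else np.full(50, 200.0)
    mu_kd = mu_kd if mu_kd is not None else mu_ctrl
    return KnockdownExperiment(
        tf="tfX",
        stage="eA",
        control_track=ctrl,
        kd_track=kd,
        counts=make_counts(rng, mu_ctrl, mu_kd),
    )


def site_peaks(site_bins):
    return PeakSet(
        [
            GenomicInterval("chr1", 200 * b, 200 * (b + 3), name=f"site{i}")
            for i, b in enumerate(site_bins)
        ]
    )


class TestKdChromatinEffect:
    def test_remodeling_tf_halving_detected(self, rng):
        # sparse sites so the library-size shift from lost signal stays small
        bins = list(range(100, 6000, 300))  # 20 sites
        ctrl, kd, inp = make_tracks(rng, n_bins=6000, sites=bins, kd_retain=0.5)
        exp = make_exp(rng, ctrl, kd)
        sites = TargetSiteSet(tf="tfX", stage="eA", sites=site_peaks(bins))
        eff = kd_chromatin_effect(exp, sites, inp)
        assert eff.p < 1e-4
        assert np.median(eff.delta) == pytest.approx(-1.0, abs=0.15)
        # profile pair: kd mean profile sits below control at the center
        c = len(eff.control_profile) // 2
        assert eff.kd_profile[c] < eff.control_profile[c]

    def test_non_remodeling_tf_is_null(self, rng):
        bins = list(range(100, 2000, 60))
        ctrl, kd, inp = make_tracks(rng, sites=bins, kd_retain=None)
        exp = make_exp(rng, ctrl, kd)
        sites = TargetSiteSet(tf="tfX", stage="eA", sites=site_peaks(bins))
        eff = kd_chromatin_effect(exp, sites, inp)
        assert eff.p > 0.05
        assert abs(np.median(eff.delta)) < 0.15

    def test_identical_tracks_degenerate(self, rng):
        bins = list(range(100, 2000, 60))
        ctrl, _, inp = make_tracks(rng, sites=bins)
        exp = make_exp(rng, ctrl, ctrl)
        sites = TargetSiteSet(tf="tfX", stage="eA", sites=site_peaks(bins))
        eff = kd_chromatin_effect(exp, sites, inp)
        assert eff.degenerate and eff.p == 1.0
        assert np.allclose(eff.delta, 0.0)

    def test_too_few_sites_rejected(self, rng):
        ctrl, kd, inp = make_tracks(rng, sites=[100])
        exp = make_exp(rng, ctrl, kd)
        sites = TargetSiteSet(tf="tfX", stage="eA", sites=site_peaks([100]))
        with pytest.raises(ValueError):
            kd_chromatin_effect(exp, sites, inp)


class TestKdDeregulatedGenes:
    def test_planted_threefold_recovered(self, rng):
        mu = np.exp(rng.normal(np.log(300), 0.5, 1000))
        mu_kd = mu.copy()
        mu_kd[:100] /= 3.0
        ctrl, kd, inp = make_tracks(rng)
        exp = make_exp(rng, ctrl, kd, mu, mu_kd)
        sets = kd_deregulated_genes(exp)
        down = set(sets["down"])
        assert len(down & {f"g{i}" for i in range(100)}) >= 90

    def test_identical_arms_empty(self, rng):
        mu = np.full(200, 150.0)
        ctrl, kd, inp = make_tracks(rng)
        counts = make_counts(rng, mu, mu, n_rep=3, alpha=0.01)
        base = counts.counts[["control0", "control1", "control2"]]
        dup = base.copy()
        dup.columns = ["kd0", "kd1", "kd2"]
        cm = CountMatrix(
            counts=pd.concat([base, dup], axis=1), design=counts.design
        )
        exp = KnockdownExperiment("tfX", "eA", ctrl, kd, cm)
        sets = kd_deregulated_genes(exp)
        assert sets["down"] == [] and sets["up"] == []

    def test_halved_gene_never_in_up(self, rng):
        mu = np.full(300, 400.0)
        mu_kd = mu.copy()
        mu_kd[:50] /= 2.0
        ctrl, kd, inp = make_tracks(rng)
        exp = make_exp(rng, ctrl, kd, mu, mu_kd)
        sets = kd_deregulated_genes(exp)
        assert not set(sets["up"]) & {f"g{i}" for i in range(50)}


class TestLinkage:
    def _setup(self, rng):
        from epiprime.annotation import GeneModel, GenomeAnnotation

        genes, peaks, deltas = [], [], {}
        gene_sets = {"down": [], "up": []}
        de_rows = {}
        for i in range(60):
            start = 50_000 * i + 1000
            gid = f"g{i:03d}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom="chr1",
                    strand="+",
                    span=GenomicInterval("chr1", start, start + 2000),
                    exons=(GenomicInterval("chr1", start, start + 2000),),
                )
            )
            rid = f"site{i}"
            peaks.append(
                GenomicInterval("chr1", start + 5000, start + 5600, name=rid)
            )
            if i < 20:
                gene_sets["down"].append(gid)
                deltas[rid] = -1.2 + rng.normal(0, 0.1)
                de_rows[gid] = {"log2fc": -1.3, "fdr": 1e-6}
            elif i < 35:
                gene_sets["up"].append(gid)
                deltas[rid] = rng.normal(0, 0.1)
                de_rows[gid] = {"log2fc": 1.0, "fdr": 1e-4}
            else:
                deltas[rid] = rng.normal(0, 0.1)
                de_rows[gid] = {"log2fc": 0.01, "fdr": 0.9}
        ann = GenomeAnnotation(genes)
        de_table = pd.DataFrame.from_dict(de_rows, orient="index")
        return gene_sets, de_table, PeakSet(peaks), ann, pd.Series(deltas)

    def test_down_linked_sites_lose_acetylation(self, rng):
        gene_sets, de_table, peaks, ann, delta = self._setup(rng)
        res = link_deregulated_to_sites(gene_sets, de_table, peaks, ann, delta)
        assert res.p is not None and res.p < 1e-4
        assert np.median(res.deltas["down"]) < -0.5
        assert abs(np.median(res.deltas["up"])) < 0.2

    def test_shuffled_links_null(self, rng):
        gene_sets, de_table, peaks, ann, delta = self._setup(rng)
        # break the gene-site coupling: permute the delta values across sites
        shuffled = pd.Series(
            rng.permutation(delta.to_numpy()), index=delta.index
        )
        res = link_deregulated_to_sites(gene_sets, de_table, peaks, ann, shuffled)
        # no systematic difference remains between the classes
        d = np.median(res.deltas["down"]) - np.median(res.deltas["unchanged"])
        assert abs(d) < 0.8

    def test_small_class_skipped(self, rng):
        gene_sets, de_table, peaks, ann, delta = self._setup(rng)
        gene_sets["down"] = gene_sets["down"][:2]
        res = link_deregulated_to_sites(gene_sets, de_table, peaks, ann, delta)
        assert res.p is None and "down" in res.skipped


class TestCoregulationOverlap:
    def test_identical_sets_minimal_p(self):
        genes = [f"g{i}" for i in range(50)]
        res = coregulation_overlap(genes, genes, universe=1000)
        assert res["overlap"] == 50
        want = math.comb(50, 50) * math.comb(950, 0) / math.comb(1000, 50)
        assert res["p"] == pytest.approx(want, rel=1e-9)

    def test_matches_direct_tail_summation(self):
        a = {f"g{i}" for i in range(50)}
        b = {f"g{i}" for i in range(30, 90)}  # overlap 20, |b| = 60
        res = coregulation_overlap(a, b, universe=1000)
        total = 0.0
        for x in range(20, 51):
            total += (
                math.comb(50, x)
                * math.comb(950, 60 - x)
                / math.comb(1000, 60)
            )
        assert res["p"] == pytest.approx(total, rel=1e-9)

    def test_cobound_counts_intersection(self):
        res = coregulation_overlap(
            ["a", "b", "c"], ["b", "c", "d"], universe=100, genes_with_both_motifs=["c"]
        )
        assert res["overlap"] == 2 and res["co_bound"] == 1

    def test_null_p_uniform(self, rng):
        pvals = []
        universe = [f"g{i}" for i in range(1000)]
        for _ in range(200):
            a = set(rng.choice(universe, 50, replace=False))
            b = set(rng.choice(universe, 60, replace=False))
            pvals.append(coregulation_overlap(a, b, 1000)["p"])
        # discrete p-values are conservative; check stochastic dominance of
        # uniform rather than exact uniformity
        assert stats.kstest(pvals, "uniform", alternative="greater").pvalue > 0.01
        assert np.mean(pvals) > 0.35

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError):
            coregulation_overlap(["a", "b"], ["c"], universe=1)
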