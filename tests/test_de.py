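"""Size factors, NB Wald test calibration/power, temporal clustering, PCA."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from epiprime.de import (
    CountMatrix,
    de_test,
    pca_samples,
    size_factors,
    temporal_clusters,
)


def make_cm(counts, condition=None):
    counts = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(counts.shape[0])],
        columns=[f"s{j}" for j in range(counts.shape[1])],
    )
    design = pd.DataFrame(
        {
            "stage": "x",
            "lineage": "astro",
            "replicate": range(counts.shape[1]),
            "condition": condition or "c",
        },
        index=counts.columns,
    )
    return CountMatrix(counts=counts, design=design)


def nb_counts(rng, mu, alpha, n_samples):
    lam = rng.gamma(1.0 / alpha, np.asarray(mu)[:, None] * alpha, size=(len(mu), n_samples))
    return rng.poisson(lam)


class TestSizeFactors:
    def test_doubled_sample(self):
        base = np.array([[10, 20], [30, 60], [5, 10]])
        f = size_factors(make_cm(base))
        assert f["s1"] / f["s0"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_single_sample_is_unity(self):
        f = size_factors(make_cm(np.array([[5], [7]])))
        assert f.iloc[0] == 1.0

    def test_matches_formula_reapplied(self, rng):
        X = nb_counts(rng, np.exp(rng.normal(4, 1, 300)), 0.1, 5)
        f = size_factors(make_cm(X))
        pos = (X > 0).all(axis=1)
        logg = np.log(X[pos])
        ref = np.exp(np.median(logg - logg.mean(axis=1, keepdims=True), axis=0))
        ref = ref / np.exp(np.mean(np.log(ref)))
        assert np.allclose(f.to_numpy(), ref)

    def test_invariant_to_gene_and_sample_order(self, rng):
        X = nb_counts(rng, np.exp(rng.normal(4, 1, 200)), 0.1, 4)
        cm = make_cm(X)
        f = size_factors(cm)
        perm_genes = cm.counts.sample(frac=1, random_state=0)
        f2 = size_factors(CountMatrix(perm_genes, cm.design))
        assert np.allclose(f.to_numpy(), f2.to_numpy())
        cols = list(cm.counts.columns[::-1])
        f3 = size_factors(CountMatrix(cm.counts[cols], cm.design.loc[cols]))
        assert np.allclose(f3[f.index].to_numpy(), f.to_numpy())

    def test_agrees_with_deseq2_reference(self, rng):
        """Independent oracle: pydeseq2's median-of-ratios size factors."""
        pydeseq2 = pytest.importorskip("pydeseq2.dds")
        import warnings

        X = nb_counts(rng, np.exp(rng.normal(4, 1, 400)), 0.1, 6)
        cm = make_cm(X)
        meta = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3}, index=cm.counts.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = pydeseq2.DeseqDataSet(
                counts=cm.counts.T, metadata=meta, design="~condition", quiet=True
            )
            dds.fit_size_factors()
        ours = size_factors(cm).to_numpy()
        theirs = np.asarray(dds.obs["size_factors"])
        # both conventions normalise to geometric mean 1
        theirs = theirs / np.exp(np.mean(np.log(theirs)))
        assert np.allclose(ours, theirs, rtol=1e-6)


class TestDETest:
    def test_identical_groups_give_no_calls(self, rng):
        X = nb_counts(rng, np.exp(rng.normal(4, 1, 100)), 0.1, 3)
        X = np.hstack([X, X])  # group B duplicates group A exactly
        cm = make_cm(X)
        res = de_test(cm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.allclose(res.table["log2fc"], 0.0)
        assert not res.table["de"].any()

    def test_all_zero_gene_gets_p_one(self, rng):
        X = nb_counts(rng, np.full(20, 100.0), 0.1, 6)
        X[0] = 0
        res = de_test(make_cm(X), ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res.table.loc["g0", "p"] == 1.0
        assert res.table.loc["g0", "log2fc"] == 0.0

    def test_group_swap_symmetry(self, rng):
        X = nb_counts(rng, np.exp(rng.normal(4, 1, 150)), 0.1, 6)
        cm = make_cm(X)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        fwd = de_test(cm, a, b).table
        rev = de_test(cm, b, a).table
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_null_type_i_error_calibrated(self):
        """Seeded null: fraction of p<0.05 within [0.03, 0.07]."""
        rng = np.random.default_rng(42)
        mu = np.exp(rng.normal(np.log(300), 0.8, 2000))
        X = nb_counts(rng, mu, 0.1, 6)
        res = de_test(make_cm(X), ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        frac = float((res.table["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_planted_fourfold_power(self):
        """4-fold change at mu=500, dispersion 0.05, 3 vs 3: >=95% power."""
        rng = np.random.default_rng(43)
        n_genes, n_planted = 2000, 100
        mu = np.exp(rng.normal(np.log(300), 0.8, n_genes))
        mu_a, mu_b = mu.copy(), mu.copy()
        mu_a[:n_planted], mu_b[:n_planted] = 500.0, 125.0
        Xa = nb_counts(rng, mu_a, 0.05, 3)
        Xb = nb_counts(rng, mu_b, 0.05, 3)
        cm = make_cm(np.hstack([Xa, Xb]))
        res = de_test(cm, ["s0", "s1", "s2"], ["s3", "s4", "s5"], fdr_cut=0.1)
        detected = res.table["de"].to_numpy()[:n_planted]
        assert detected.mean() >= 0.95

    def test_bh_matches_step_up_definition(self, rng):
        p = rng.uniform(0, 1, 500)
        ours = multipletests(p, method="fdr_bh")[1]
        # direct implementation of the BH step-up definition
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        want = np.empty(m)
        want[order] = np.minimum(ranked, 1.0)
        res = de_test.__module__  # noqa: F841 - document that de.py uses this routine
        assert np.allclose(ours, want)

    def test_fdr_bounds_p(self, rng):
        X = nb_counts(rng, np.exp(rng.normal(4, 1, 300)), 0.1, 6)
        res = de_test(make_cm(X), ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (res.table["fdr"] >= res.table["p"] - 1e-12).all()

    def test_requires_two_replicates(self, rng):
        X = nb_counts(rng, np.full(10, 50.0), 0.1, 3)
        with pytest.raises(ValueError):
            de_test(make_cm(X), ["s0"], ["s1", "s2"])


class TestTemporalClusters:
    def _profiles(self, rng, n_per=50):
        arch = np.array([[5, 2, 2], [2, 5, 2], [2, 2, 5]], float)
        rows, labels = [], []
        for k in range(3):
            rows.append(arch[k] + rng.normal(0, 0.2, (n_per, 3)))
            labels += [k] * n_per
        df = pd.DataFrame(
            np.vstack(rows),
            index=[f"g{i}" for i in range(3 * n_per)],
            columns=["aNPC", "eA", "lA"],
        )
        return df, np.array(labels)

    def test_recovers_kinetic_archetypes(self, rng):
        df, truth = self._profiles(rng)
        res = temporal_clusters(df, k=3, seed=2)
        assert adjusted_rand_score(truth, res.assignments.to_numpy()) == 1.0

    def test_labels_follow_temporal_order(self, rng):
        df, _ = self._profiles(rng)
        res = temporal_clusters(df, k=3, seed=2)
        peaks = res.centroids.to_numpy().argmax(axis=1)
        assert list(peaks) == sorted(peaks)

    def test_constant_profiles_dropped(self, rng):
        df, _ = self._profiles(rng)
        df.iloc[0] = 7.0
        res = temporal_clusters(df, k=3, seed=2)
        assert df.index[0] in res.dropped
        assert df.index[0] not in res.assignments.index


class TestPCASamples:
    def test_two_groups_separate_on_pc1(self, rng):
        mu = np.exp(rng.normal(4, 1, 300))
        a = nb_counts(rng, mu, 0.05, 3)
        b = nb_counts(rng, mu * rng.uniform(0.2, 5.0, 300), 0.05, 3)
        cm = make_cm(np.hstack([a, b]))
        coords, var = pca_samples(cm)
        assert var[0] > var[1]
        side = np.sign(coords["PC1"].to_numpy())
        assert abs(side[:3].sum()) == 3 and abs(side[3:].sum()) == 3
        assert side[0] != side[3]

    def test_component_variance_matches_eigendecomposition(self, rng):
        from epiprime.de import log_normalized

        X = nb_counts(rng, np.exp(rng.normal(4, 1, 200)), 0.1, 6)
        cm = make_cm(X)
        _, var = pca_samples(cm)
        L = log_normalized(cm).to_numpy().T
        L = L - L.mean(axis=0, keepdims=True)
        # dual eigendecomposition of the gene-centred data
        ev = np.linalg.eigvalsh(L @ L.T / (L.shape[0] - 1))[::-1]
        want = 100.0 * ev[:2] / ev.sum()
        assert np.allclose(var, want, atol=1e-8)

    def test_requires_three_samples(self, rng):
        X = nb_counts(rng, np.full(10, 50.0), 0.1, 2)
        with pytest.raises(ValueError):
            pca_samples(make_cm(X))
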