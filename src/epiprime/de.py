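"""Count normalisation, negative-binomial differential expression, clustering, PCA.

Normalisation uses median-of-ratios size factors. The two-group test is a
negative-binomial Wald test with a common (contrast-wide) dispersion: the
method-of-moments dispersion of each gene's normalised counts, residuals
pooled within groups, is averaged across genes and floored at 0.01. A common
dispersion is essentially noise-free at a few thousand genes, so the Wald
statistic can be referred to the normal distribution while staying calibrated
at the tiny replicate numbers this package targets (a gene-wise plug-in
dispersion with 3 vs 3 samples would be badly anticonservative). P-values are
BH-adjusted and genes are called differentially expressed below an FDR cutoff
(default 0.1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEResult",
    "size_factors",
    "normalized_counts",
    "log_normalized",
    "de_test",
    "temporal_clusters",
    "pca_samples",
    "stage_mean_expression",
]

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 0.01


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus a sample design table.

    ``design`` is indexed by sample id with columns (stage, lineage,
    replicate, condition); it must cover exactly the columns of ``counts``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.is_unique:
            raise ValueError("sample labels must be unique")
        if set(self.counts.columns) != set(self.design.index):
            raise ValueError("design must cover exactly the count columns")
        self.design = self.design.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[samples].copy(), self.design.loc[samples].copy())


def size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over all-positive genes of count_gj / geomean_g(counts).
    Falls back to total-count ratios (with a warning) when no gene is positive
    in every sample.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    X = counts.to_numpy(dtype=float)
    if X.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    pos = (X > 0).all(axis=1)
    if not pos.any():
        logger.warning("no gene positive in all samples; total-count fallback")
        f = X.sum(axis=0)
    else:
        logg = np.log(X[pos])
        geo = logg.mean(axis=1, keepdims=True)
        f = np.exp(np.median(logg - geo, axis=0))
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="size_factor")


def normalized_counts(cm: CountMatrix) -> pd.DataFrame:
    return cm.counts / size_factors(cm)


def log_normalized(cm: CountMatrix) -> pd.DataFrame:
    """log2(count/size_factor + 1): the expression scale used downstream."""
    return np.log2(normalized_counts(cm) + 1.0)


@dataclass
class DEResult:
    table: pd.DataFrame  # gene-indexed: log2fc, p, fdr, mean_a, mean_b, de
    group_a: list[str]
    group_b: list[str]
    fdr_cut: float

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["de"]])

    def direction_sets(self) -> dict[str, list[str]]:
        t = self.table
        return {
            "up": list(t.index[t["de"] & (t["log2fc"] > 0)]),
            "down": list(t.index[t["de"] & (t["log2fc"] < 0)]),
        }


def de_test(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    fdr_cut: float = 0.1,
) -> DEResult:
    """NB Wald test of group B vs group A; log2fc > 0 means higher in B.

    Per gene: normalised group means muA, muB. The dispersion alpha is common
    to the contrast: each gene's method-of-moments estimate
    (s^2 - mu)/mu^2 — residual variance pooled within the two groups — is
    averaged over genes with mean >= 1 and floored at 0.01. Wald statistic
    log2fc / SE with the delta-method SE
    sqrt((1/nA)(1/muA + a) + (1/nB)(1/muB + a)) / ln 2, two-sided normal p,
    BH-FDR across genes. Genes all-zero in both groups get p = 1 and
    log2fc = 0.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    sub = cm.subset_samples(list(group_a) + list(group_b))
    q = normalized_counts(sub)
    qa = q[list(group_a)].to_numpy(dtype=float)
    qb = q[list(group_b)].to_numpy(dtype=float)
    na, nb = qa.shape[1], qb.shape[1]

    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
    resid_ss = ((qa - mu_a[:, None]) ** 2).sum(axis=1) + (
        (qb - mu_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = resid_ss / (na + nb - 2)
    mu0 = (mu_a + mu_b) / 2.0
    ok = mu0 >= 1.0
    if ok.any():
        alpha = float(np.mean((s2[ok] - mu0[ok]) / np.square(mu0[ok])))
    else:
        alpha = DISPERSION_FLOOR
    alpha = max(alpha, DISPERSION_FLOOR)

    pc = 0.5  # stabilises the ratio for zero-count groups
    lfc = np.log2(mu_b + pc) - np.log2(mu_a + pc)
    se = np.sqrt(
        (1.0 / na) * (1.0 / (mu_a + pc) + alpha)
        + (1.0 / nb) * (1.0 / (mu_b + pc) + alpha)
    ) / np.log(2.0)
    wald = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))

    allzero = (mu_a == 0) & (mu_b == 0)
    p[allzero] = 1.0
    lfc[allzero] = 0.0
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "fdr": fdr,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "de": fdr < fdr_cut,
        },
        index=sub.genes,
    )
    return DEResult(table=table, group_a=list(group_a), group_b=list(group_b), fdr_cut=fdr_cut)


@dataclass
class TemporalClusterAssignment:
    assignments: pd.Series  # gene -> cluster id 1..k (temporal order)
    k: int
    centroids: pd.DataFrame  # cluster id x stages (z-scored space)
    dropped: list[str]


def temporal_clusters(
    profiles: pd.DataFrame, k: int = 5, seed: int = 0, n_restarts: int = 25
) -> TemporalClusterAssignment:
    """Cluster gene x stage mean-expression profiles into k kinetic groups.

    Profiles are z-scored per gene (constant profiles are dropped with a
    warning); k-means with ``n_restarts`` initialisations; clusters are
    relabelled 1..k by the stage index at which their centroid peaks, so label
    order follows temporal order.
    """
    from sklearn.cluster import KMeans

    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    dropped = list(profiles.index[~keep])
    if dropped:
        logger.warning("temporal_clusters: dropped %d constant profiles", len(dropped))
    X = X[keep]
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    if k > np.unique(X, axis=0).shape[0]:
        raise ValueError("k exceeds the number of distinct profiles")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    peak_stage = km.cluster_centers_.argmax(axis=1)
    order = np.argsort(peak_stage, kind="stable")
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignments = pd.Series(
        [relabel[l] for l in labels], index=profiles.index[keep], name="cluster"
    )
    centroids = pd.DataFrame(
        km.cluster_centers_[order],
        index=pd.Index(range(1, k + 1), name="cluster"),
        columns=profiles.columns,
    )
    return TemporalClusterAssignment(
        assignments=assignments, k=k, centroids=centroids, dropped=dropped
    )


def pca_samples(cm: CountMatrix, n_components: int = 2):
    """PCA of samples on log2(normalised count + 1), genes centred.

    Returns (coordinates DataFrame samples x PCs, % variance explained).
    The sign of each component is fixed so its largest-magnitude gene loading
    is positive.
    """
    if cm.counts.shape[1] < 3:
        raise ValueError("PCA requires at least 3 samples")
    X = log_normalized(cm).to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(n_components):
        i = np.abs(pca.components_[j]).argmax()
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    coord_df = pd.DataFrame(
        coords,
        index=cm.samples,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    return coord_df, 100.0 * pca.explained_variance_ratio_


def stage_mean_expression(cm: CountMatrix, lineage: str | None = None) -> pd.DataFrame:
    """Gene x stage mean of replicate log2-normalised expression."""
    logx = log_normalized(cm)
    design = cm.design
    if lineage is not None:
        samples = design.index[design["lineage"] == lineage]
        logx = logx[list(samples)]
        design = design.loc[samples]
    stages = list(dict.fromkeys(design["stage"]))
    return pd.DataFrame(
        {s: logx[list(design.index[design["stage"] == s])].mean(axis=1) for s in stages}
    )


def read_counts(counts_path, design_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, design=design)


def write_counts(cm: CountMatrix, counts_path, design_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.design.to_csv(design_path, sep="\t")
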