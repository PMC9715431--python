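"""Inversion genotyping from region-wide PCA structure.

Inside an inversion, samples separate into three clusters along PC1 —
the two arrangement homozygotes at the extremes and heterozygotes in the
middle, the middle cluster showing the highest heterozygosity because the
two arrangements carry diverged haplotypes. Genotypes are therefore called
by 1-D k-means on PC1 with starting centres at the minimum, middle and
maximum scores, and validated by per-cluster heterozygosity and a
Hardy–Weinberg chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import MISSING, GenomicInterval, GenotypeMatrix


@dataclass
class RegionPCA:
    region: GenomicInterval
    pc_scores: np.ndarray  # (n_samples, k)
    loadings: np.ndarray  # (n_snps_used, k) SNP-space axes
    allele_freq: np.ndarray  # training p-hat per used SNP (for projection)
    snp_mask: np.ndarray  # mask into the region matrix of SNPs used
    sample_ids: list[str]
    scaling: str = "patterson"


@dataclass
class InversionCall:
    region: GenomicInterval
    genotype: np.ndarray  # per-sample {0,1,2} or MISSING
    cluster_means: np.ndarray  # PC1 mean per cluster, ascending
    het_by_cluster: np.ndarray  # mean het % per cluster (NaN when empty)
    ambiguous: bool = False  # middle cluster failed the heterozygosity check
    hwe: dict = field(default_factory=dict)  # chi2, df, p (or undefined flag)


def _patterson_scale(
    d: np.ndarray, p: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Centre dosages by 2p and scale by sqrt(p(1-p)); missing (NaN) imputed
    to the SNP mean before scaling. Returns (scaled, p)."""
    if p is None:
        p = np.nanmean(d, axis=0) / 2.0
    mu = 2.0 * p
    idx = np.where(np.isnan(d))
    d = d.copy()
    d[idx] = mu[idx[1]]
    denom = np.sqrt(p * (1.0 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (d - mu) / denom
    x[:, denom == 0] = 0.0
    return x, p


def region_pca(
    gm: GenotypeMatrix, region: GenomicInterval, n_components: int = 10
) -> RegionPCA:
    """PCA of all SNPs in the region with Patterson scaling.

    Uses every polymorphic SNP in the region (no MAF filter or thinning).
    Raises ``ValueError`` when the region has no polymorphic SNP.
    """
    sub = gm.subset_region(region)
    d = sub.dosage_float()
    p = np.nanmean(d, axis=0) / 2.0 if d.size else np.array([])
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError(f"region {region} has <2 polymorphic SNPs")
    x, p_used = _patterson_scale(d[:, poly], p[poly])
    k = min(n_components, min(x.shape) - 1) or 1
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-magnitude score positive per component
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
            loadings[:, j] = -loadings[:, j]
    return RegionPCA(
        region, scores, loadings, p_used, poly, list(gm.sample_ids)
    )


def _kmeans_1d(x: np.ndarray, centers: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Plain Lloyd iterations in 1-D from explicit starting centres.

    Returns (labels, centres); a centre losing all points keeps its position
    (caller detects the empty cluster)."""
    c = centers.astype(float).copy()
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        labels_new = np.argmin(np.abs(x[:, None] - c[None, :]), axis=1)
        for j in range(len(c)):
            if (labels_new == j).any():
                c[j] = x[labels_new == j].mean()
        if (labels_new == labels).all():
            break
        labels = labels_new
    return labels, c


def cluster_genotypes(pca: RegionPCA) -> tuple[np.ndarray, np.ndarray, int]:
    """Cluster PC1 scores into 3 (fallback 2) genotype groups.

    Starting centres are the minimum, middle and maximum PC1 score; if any
    cluster ends empty the clustering degenerates and k=2 (min/max starts)
    is used instead. Returns (labels ordered along PC1 as 0/1/2, centres
    ascending, k). With k=3, label 1 is the putative heterozygote cluster.
    """
    x = pca.pc_scores[:, 0]
    if len(x) < 3:
        raise ValueError("need >= 3 samples to cluster genotypes")
    starts3 = np.array([x.min(), (x.min() + x.max()) / 2.0, x.max()])
    labels, c = _kmeans_1d(x, starts3)
    if len(np.unique(labels)) == 3:
        order = np.argsort(c)
        remap = np.empty(3, dtype=int)
        remap[order] = np.arange(3)
        return remap[labels], c[order], 3
    labels, c = _kmeans_1d(x, np.array([x.min(), x.max()]))
    order = np.argsort(c)
    remap = np.empty(2, dtype=int)
    remap[order] = np.arange(2)
    return remap[labels], c[order], 2


def sample_heterozygosity(
    gm: GenotypeMatrix, region: GenomicInterval | None = None
) -> np.ndarray:
    """Percentage of non-missing sites that are heterozygous, per sample.

    NaN for samples with no non-missing site in the region.
    """
    sub = gm if region is None else gm.subset_region(region)
    het = (sub.dosage == 1).sum(axis=1).astype(float)
    n = (sub.dosage != MISSING).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * het / n
    out[n == 0] = np.nan
    return out


def call_inversion_genotypes(
    gm: GenotypeMatrix, region: GenomicInterval, n_components: int = 10
) -> tuple[InversionCall, RegionPCA]:
    """Full genotype call for one region: PCA, clustering, het validation.

    Cluster labels are oriented so that calls are 0/1/2 along PC1; if the
    middle cluster does not have the maximal mean heterozygosity the call
    set is flagged ``ambiguous`` rather than reassigned.
    """
    pca = region_pca(gm, region, n_components=n_components)
    labels, centers, k = cluster_genotypes(pca)
    het = sample_heterozygosity(gm, region)
    het_by = np.array(
        [het[labels == j].mean() if (labels == j).any() else np.nan for j in range(k)]
    )
    ambiguous = k == 3 and not (np.nanargmax(het_by) == 1)
    genotype = labels.astype(np.int8)
    counts = tuple(int((genotype == g).sum()) for g in range(3))
    call = InversionCall(region, genotype, centers, het_by, ambiguous)
    call.hwe = hwe_test(counts)
    return call, pca


def project_samples(
    pca: RegionPCA,
    new_gm: GenotypeMatrix,
    cluster_means_pc1: np.ndarray,
    ambiguity_margin: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Project new samples on the trained axes and call genotypes.

    New dosages are Patterson-scaled with the *training* allele frequencies
    and projected on the stored loadings. Genotype = nearest cluster mean on
    PC1; the distance must be below ``ambiguity_margin`` x the adjacent
    inter-centre gap, else the call is missing. Samples with no observed
    genotype are missing. Returns (scores (n, k), calls).
    """
    sub = new_gm.subset_region(pca.region)
    d = sub.dosage_float()[:, pca.snp_mask]
    if d.shape[1] == 0:
        raise ValueError("no overlapping SNPs with the trained region PCA")
    all_missing = np.isnan(d).all(axis=1)
    x, _ = _patterson_scale(d, pca.allele_freq)
    scores = x @ pca.loadings
    pc1 = scores[:, 0]
    centers = np.sort(np.asarray(cluster_means_pc1, dtype=float))
    dists = np.abs(pc1[:, None] - centers[None, :])
    nearest = np.argmin(dists, axis=1)
    gaps = np.diff(centers)
    calls = nearest.astype(np.int8)
    for i, j in enumerate(nearest):
        local_gap = min(
            gaps[j - 1] if j > 0 else np.inf, gaps[j] if j < len(gaps) else np.inf
        )
        if dists[i, j] >= ambiguity_margin * local_gap:
            calls[i] = MISSING
    calls[all_missing] = MISSING
    scores[all_missing] = np.nan
    return scores, calls


def diagnostic_snp_genotype(
    inv_allele_counts: np.ndarray,
    total_counts: np.ndarray,
    error: float = 0.01,
) -> int:
    """Maximum-likelihood inversion genotype from diagnostic fixed SNPs.

    Each diagnostic SNP carries one allele fixed in the inverted and the
    other in the standard arrangement. Reads (or observed alleles) at SNP i
    are ``total_counts[i]`` draws of which ``inv_allele_counts[i]`` match the
    inverted arrangement; under genotype g in {0,1,2} the inverted-allele
    probability is g/2 adjusted for error ``error``. Returns the ML genotype
    or :data:`MISSING` when nothing was observed.
    """
    k = np.asarray(inv_allele_counts, dtype=float)
    n = np.asarray(total_counts, dtype=float)
    obs = n > 0
    if not obs.any():
        return MISSING
    k, n = k[obs], n[obs]
    logls = []
    for g in (0, 1, 2):
        p = (g / 2.0) * (1 - 2 * error) + error
        logls.append(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))
    return int(np.argmax(logls))


def hwe_test(genotype_counts: tuple[int, int, int]) -> dict:
    """Pearson chi-square test of Hardy–Weinberg proportions (df=1).

    Expected counts come from the observed allele frequency; no continuity
    correction, matching the asymptotic chi-square convention. Monomorphic
    samples make the test undefined (``{"undefined": True}``).
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n2 + n1) / (2.0 * n)
    if p in (0.0, 1.0):
        return {"undefined": True, "chi2": np.nan, "df": 1, "p": np.nan}
    exp = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return {
        "undefined": False,
        "chi2": chi2,
        "df": 1,
        "p": float(stats.chi2.sf(chi2, 1)),
    }
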