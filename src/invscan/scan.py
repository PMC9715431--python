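"""Local-PCA/MDS genome scan for candidate inversion regions.

The scan slides 100 kb windows along each chromosome, summarises each window
by the top-k eigenpairs of its sample covariance matrix, measures pairwise
dissimilarity between the windows' "PCA maps", embeds the windows with
classical (Torgerson) multidimensional scaling, clusters them with k-means
(k chosen by silhouette), and reports maximal runs of at least ``min_run``
consecutive same-cluster windows whose MDS1 z-score exceeds ``z_thresh``.

A large inversion segregating at intermediate frequency makes the windows it
spans share an unusual sample structure (three clusters along PC1), so they
co-locate in MDS space and form a long outlier run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_core import MISSING, GenomicInterval, GenotypeMatrix, make_windows


@dataclass
class WindowPCA:
    """Rank-k summary of one window's sample covariance.

    Eigenvalues are normalised by the window's total covariance trace so that
    windows with different SNP counts are comparable.
    """

    window: GenomicInterval
    eigenvalues: np.ndarray  # (k,) normalised, descending, >= 0
    eigenvectors: np.ndarray  # (n_samples, k), unit-norm columns
    total_variance: float
    n_snps: int = 0


@dataclass
class MDSResult:
    windows: list[GenomicInterval]
    mds1: np.ndarray
    mds2: np.ndarray
    z1: np.ndarray
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    #: index of each included window in the original tiling; excluded windows
    #: leave gaps here and therefore break outlier runs
    tiling_index: list[int] = field(default_factory=list)


@dataclass
class OutlierRegion:
    region: GenomicInterval
    window_indices: list[int]
    cluster_id: int
    max_run_length: int


def _centered_dosage(gm: GenotypeMatrix, mask: np.ndarray) -> np.ndarray | None:
    """Mean-centred dosages for variants in ``mask``; missing values are
    imputed to the per-SNP mean; monomorphic sites dropped. ``None`` if no
    polymorphic site remains."""
    d = gm.dosage_float()[:, mask]
    if d.size == 0:
        return None
    mu = np.nanmean(d, axis=0)
    keep = ~np.isnan(mu)
    d, mu = d[:, keep], mu[keep]
    idx = np.where(np.isnan(d))
    d[idx] = mu[idx[1]]
    d = d - mu
    poly = d.std(axis=0) > 0
    if not poly.any():
        return None
    return d[:, poly]


def window_pca(
    gm: GenotypeMatrix, window: GenomicInterval, k: int = 2, min_snps: int = 10
) -> WindowPCA | None:
    """Top-k eigenpairs of the window's sample-sample covariance matrix.

    Returns ``None`` (window excluded) when fewer than ``min_snps``
    polymorphic SNPs fall in the window or the covariance is degenerate.
    """
    mask = gm.variant_mask(window)
    d = _centered_dosage(gm, mask)
    if d is None or d.shape[1] < min_snps:
        return None
    cov = d @ d.T / d.shape[1]
    total = float(np.trace(cov))
    if total <= 0:
        return None
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None) / total
    vecs = vecs[:, order]
    # fix eigenvector sign: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return WindowPCA(window, vals, vecs, total, n_snps=d.shape[1])


def pca_map_distance(a: WindowPCA, b: WindowPCA) -> float:
    """Distance between two windows' rank-k PCA maps.

    d^2 = sum_i lam_ai^2 + sum_j lam_bj^2 - 2 sum_ij lam_ai lam_bj (u_ai . u_bj)^2,
    the squared Frobenius distance between the two rank-k covariance
    approximations built from the (trace-normalised) eigenpairs.
    """
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError("windows summarise different sample sets")
    la, lb = a.eigenvalues, b.eigenvalues
    cross = (a.eigenvectors.T @ b.eigenvectors) ** 2
    d2 = float(la @ la + lb @ lb - 2.0 * la @ cross @ lb)
    return float(np.sqrt(max(d2, 0.0)))


def pairwise_distances(pcas: list[WindowPCA]) -> np.ndarray:
    """Symmetric matrix of pca_map_distance over all window pairs (vectorised)."""
    lam = np.stack([p.eigenvalues for p in pcas])  # (w, k)
    U = np.stack([p.eigenvectors for p in pcas])  # (w, n, k)
    sq = np.einsum("wk,wk->w", lam, lam)
    # cross[i,j] = sum_ab lam_ia lam_jb (U_i[:,a].U_j[:,b])^2
    G = np.einsum("ina,jnb->ijab", U, U) ** 2
    cross = np.einsum("ia,ijab,jb->ij", lam, G, lam)
    d2 = sq[:, None] + sq[None, :] - 2.0 * cross
    return np.sqrt(np.clip(d2, 0.0, None))


def classical_mds(D: np.ndarray, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling of a distance matrix.

    B = -1/2 J D^2 J with J the centering matrix; coordinates are the top
    ``dims`` eigenvectors of B scaled by sqrt of their (non-negative)
    eigenvalues. Axis signs fixed by making the largest-magnitude coordinate
    positive. Returns (coords (n, dims), eigenvalues (dims,)).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords, vals


def mds_windows(
    pcas: list[WindowPCA], dims: int = 2, tiling_index: list[int] | None = None
) -> MDSResult:
    """MDS embedding of included windows plus the genome-wide MDS1 z-score."""
    D = pairwise_distances(pcas)
    coords, vals = classical_mds(D, dims=dims)
    mds1, mds2 = coords[:, 0], coords[:, 1] if dims > 1 else np.zeros(len(pcas))
    sd = mds1.std()
    z1 = (mds1 - mds1.mean()) / sd if sd > 0 else np.zeros_like(mds1)
    if tiling_index is None:
        tiling_index = list(range(len(pcas)))
    return MDSResult([p.window for p in pcas], mds1, mds2, z1, vals, tiling_index)


def cluster_windows(
    m: MDSResult,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[np.ndarray, int]:
    """k-means over (MDS1, MDS2); k chosen by maximal mean silhouette.

    Silhouette ties break toward smaller k; a k with more clusters than
    windows is skipped.
    """
    X = np.column_stack([m.mds1, m.mds2])
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in range(k_range[0], k_range[1] + 1):
        if k >= len(X):
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(X, labels, metric="euclidean")
        if sil > best_sil + 1e-12:
            best_k, best_sil, best_labels = k, sil, labels
    if best_labels is None:
        raise ValueError("clustering failed for every k in range")
    return best_labels, best_k


def find_outlier_regions(
    m: MDSResult,
    labels: np.ndarray,
    z_thresh: float = 1.5,
    min_run: int = 10,
    absolute: bool = False,
) -> list[OutlierRegion]:
    """Maximal runs of consecutive qualifying windows.

    A window qualifies when z1 > ``z_thresh`` (|z1| with ``absolute``). Runs
    require adjacent positions in the original tiling, the same chromosome
    and the same cluster label, so excluded windows break runs and runs never
    span chromosomes.
    """
    z = np.abs(m.z1) if absolute else m.z1
    regions: list[OutlierRegion] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_run:
            ws = [m.windows[i] for i in run]
            regions.append(
                OutlierRegion(
                    GenomicInterval(ws[0].chrom, ws[0].start, ws[-1].end),
                    list(run),
                    int(labels[run[0]]),
                    len(run),
                )
            )
        run.clear()

    for i in range(len(m.windows)):
        qualifies = z[i] > z_thresh
        if run:
            same = (
                m.windows[i].chrom == m.windows[run[-1]].chrom
                and labels[i] == labels[run[-1]]
                and m.tiling_index[i] == m.tiling_index[run[-1]] + 1
            )
            if not (qualifies and same):
                flush()
        if qualifies:
            run.append(i)
    flush()
    return regions


def scan_genome(
    gm: GenotypeMatrix,
    chrom_lengths: dict[str, int] | None = None,
    window_size: int = 100_000,
    step: int = 100_000,
    min_snps: int = 10,
    k_range: tuple[int, int] = (2, 10),
    z_thresh: float = 1.5,
    min_run: int = 10,
    seed: int = 0,
) -> tuple[list[OutlierRegion], MDSResult, np.ndarray]:
    """Full scan: windows -> local PCA -> distances -> MDS -> k-means -> runs.

    Returns (regions, mds result over included windows, cluster labels).
    Output is invariant to sample ordering (covariances are).
    """
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(gm.pos[gm.chrom == c].max())
            for c in dict.fromkeys(gm.chrom.astype(str))
        }
    windows = make_windows(chrom_lengths, window_size, step)
    pcas, tiling_index = [], []
    for i, w in enumerate(windows):
        p = window_pca(gm, w, min_snps=min_snps)
        if p is not None:
            pcas.append(p)
            tiling_index.append(i)
    if len(pcas) < k_range[0] + 1:
        raise ValueError("too few analysable windows for the scan")
    m = mds_windows(pcas, tiling_index=tiling_index)
    labels, _ = cluster_windows(m, k_range=k_range, seed=seed)
    regions = find_outlier_regions(m, labels, z_thresh=z_thresh, min_run=min_run)
    return regions, m, labels
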