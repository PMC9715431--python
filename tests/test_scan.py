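"""Local-PCA scan: eigen oracles, distance metric, MDS, clustering, runs."""

import numpy as np
import pytest

from invscan import (
    GenomicInterval,
    MDSResult,
    classical_mds,
    cluster_windows,
    find_outlier_regions,
    mds_windows,
    pairwise_distances,
    pca_map_distance,
    scan_genome,
    window_pca,
)
from invscan.scan import WindowPCA

from conftest import make_gm


def dense_rank_k_cov(p: WindowPCA) -> np.ndarray:
    """Rank-k covariance reconstruction from the normalised eigenpairs."""
    return (p.eigenvectors * p.eigenvalues) @ p.eigenvectors.T


class TestWindowPCA:
    def test_matches_dense_eigendecomposition(self, rng):
        d = rng.integers(0, 3, size=(4, 12)).astype(np.int8)
        gm = make_gm(d)
        p = window_pca(gm, GenomicInterval("chr1", 0, 2000), min_snps=2)
        # oracle: dense covariance of the centred (mean-imputed) dosages
        x = d.astype(float) - d.mean(axis=0)
        x = x[:, x.std(axis=0) > 0]
        cov = x @ x.T / x.shape[1]
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:2]
        expect = vals[order] / np.trace(cov)
        assert np.allclose(p.eigenvalues, expect, atol=1e-10)
        for j in range(2):
            u, v = p.eigenvectors[:, j], vecs[:, order[j]]
            assert min(np.abs(u - v).max(), np.abs(u + v).max()) < 1e-10

    def test_uniform_window_excluded(self):
        gm = make_gm(np.ones((4, 12), dtype=np.int8))
        assert window_pca(gm, GenomicInterval("chr1", 0, 2000), min_snps=2) is None

    def test_deterministic_on_identical_windows(self, rng):
        d = rng.integers(0, 3, size=(5, 10)).astype(np.int8)
        gm = make_gm(np.hstack([d, d]), pos=np.arange(1, 21) * 100)
        a = window_pca(gm, GenomicInterval("chr1", 0, 1000), min_snps=2)
        b = window_pca(gm, GenomicInterval("chr1", 1000, 2000), min_snps=2)
        assert np.allclose(a.eigenvalues, b.eigenvalues)
        assert np.allclose(a.eigenvectors, b.eigenvectors)
        assert pca_map_distance(a, b) == pytest.approx(0.0, abs=1e-12)


def random_window_pca(rng, n=6, k=2):
    lam = np.sort(rng.random(k))[::-1]
    lam = lam / lam.sum()
    q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    w = GenomicInterval("chr1", 0, 100)
    return WindowPCA(w, lam, q[:, :k], 1.0)


class TestPCAMapDistance:
    def test_identity_zero(self, rng):
        # d^2 is exact to machine epsilon; the sqrt brings that to ~1e-8
        a = random_window_pca(rng)
        assert pca_map_distance(a, a) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_rank1_closed_form(self):
        w = GenomicInterval("chr1", 0, 100)
        e = np.eye(4)
        a = WindowPCA(w, np.array([1.0, 0.0]), e[:, :2], 1.0)
        b = WindowPCA(w, np.array([1.0, 0.0]), e[:, 2:4], 1.0)
        assert pca_map_distance(a, b) ** 2 == pytest.approx(2.0)

    def test_matches_dense_frobenius_oracle(self, rng):
        for _ in range(20):
            a, b = random_window_pca(rng), random_window_pca(rng)
            expect = np.linalg.norm(dense_rank_k_cov(a) - dense_rank_k_cov(b))
            assert pca_map_distance(a, b) == pytest.approx(expect, abs=1e-10)

    def test_metric_properties_random(self, rng):
        ps = [random_window_pca(rng) for _ in range(6)]
        D = pairwise_distances(ps)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0, atol=1e-7)
        assert (D >= 0).all()

    def test_mismatched_sample_sets_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_map_distance(random_window_pca(rng, n=5), random_window_pca(rng, n=6))


class TestClassicalMDS:
    def test_two_points_at_distance_four(self):
        D = np.array([[0.0, 4.0], [4.0, 0.0]])
        coords, _ = classical_mds(D, dims=2)
        assert np.allclose(np.abs(coords[:, 0]), 2.0, atol=1e-10)

    def test_planar_configuration_reconstructed(self, rng):
        pts = rng.normal(size=(5, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, _ = classical_mds(D, dims=2)
        D2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(D, D2, atol=1e-8)

    def test_zero_distances_zero_coords(self):
        coords, _ = classical_mds(np.zeros((4, 4)))
        assert np.allclose(coords, 0.0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))


def brute_force_silhouette(X, labels):
    """Textbook silhouette: s(i) = (b - a)/max(a, b), averaged."""
    vals = []
    for i in range(len(X)):
        same = [j for j in range(len(X)) if labels[j] == labels[i] and j != i]
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same]) if same else 0.0
        bs = []
        for c in set(labels) - {labels[i]}:
            other = [j for j in range(len(X)) if labels[j] == c]
            bs.append(np.mean([np.linalg.norm(X[i] - X[j]) for j in other]))
        b = min(bs)
        vals.append(0.0 if not same else (b - a) / max(a, b))
    return float(np.mean(vals))


class TestClusterWindows:
    @staticmethod
    def _mds_of(points):
        pts = np.asarray(points, dtype=float)
        return MDSResult(
            [GenomicInterval("chr1", i * 10, i * 10 + 10) for i in range(len(pts))],
            pts[:, 0],
            pts[:, 1],
            np.zeros(len(pts)),
            tiling_index=list(range(len(pts))),
        )

    def test_two_blobs_chosen_k2(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.05, size=(15, 2)), rng.normal(5, 0.05, size=(15, 2))]
        )
        labels, k = cluster_windows(self._mds_of(pts), seed=0)
        assert k == 2
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[-1]

    def test_silhouette_matches_hand_formula(self):
        from sklearn.metrics import silhouette_score

        X = np.array([[0.0, 0], [0.2, 0], [4.0, 0], [4.1, 0], [8.0, 0]])
        labels = np.array([0, 0, 1, 1, 2])
        assert silhouette_score(X, labels) == pytest.approx(
            brute_force_silhouette(X, labels), abs=1e-12
        )


class TestFindOutlierRegions:
    @staticmethod
    def _mds(z, chrom="chr1"):
        n = len(z)
        return MDSResult(
            [GenomicInterval(chrom, i * 100, (i + 1) * 100) for i in range(n)],
            np.asarray(z, dtype=float),
            np.zeros(n),
            np.asarray(z, dtype=float),
            tiling_index=list(range(n)),
        )

    def test_twelve_window_run_found(self):
        z = [0.0] * 5 + [2.0] * 12 + [0.0] * 5
        regions = find_outlier_regions(self._mds(z), np.zeros(22, dtype=int))
        assert len(regions) == 1
        r = regions[0]
        assert r.max_run_length == 12
        assert (r.region.start, r.region.end) == (500, 1700)

    def test_nine_windows_insufficient(self):
        z = [0.0] * 5 + [2.0] * 9 + [0.0] * 5
        assert find_outlier_regions(self._mds(z), np.zeros(19, dtype=int)) == []

    def test_all_zero_no_regions(self):
        assert find_outlier_regions(self._mds([0.0] * 30), np.zeros(30, dtype=int)) == []

    def test_cluster_change_breaks_run(self):
        z = [2.0] * 20
        labels = np.array([0] * 10 + [1] * 10)
        regions = find_outlier_regions(self._mds(z), labels)
        assert len(regions) == 2
        assert all(r.max_run_length == 10 for r in regions)

    def test_excluded_window_gap_breaks_run(self):
        m = self._mds([2.0] * 20)
        m.tiling_index = list(range(10)) + list(range(11, 21))  # window 10 excluded
        regions = find_outlier_regions(m, np.zeros(20, dtype=int))
        assert [r.max_run_length for r in regions] == [10, 10]


class TestScanEndToEnd:
    def test_sample_order_invariance(self):
        from invscan import InversionSpec, PopulationSpec, simulate_population_vcf

        pop = PopulationSpec(n_samples=20, chrom_length=10_000_000, snp_density=1.0)
        inv = InversionSpec(region=GenomicInterval("chr1", 2_000_000, 4_000_000))
        gm, _ = simulate_population_vcf(pop, inv, seed=5)
        perm = np.random.default_rng(0).permutation(gm.n_samples)
        gm_perm = gm.subset_samples(perm)
        kw = dict(chrom_lengths={"chr1": 10_000_000}, min_run=5, seed=3)
        r1, m1, _ = scan_genome(gm, **kw)
        r2, m2, _ = scan_genome(gm_perm, **kw)
        assert np.allclose(m1.mds1, m2.mds1, atol=1e-6)
        assert [r.region for r in r1] == [r.region for r in r2]
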