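"""Linkage disequilibrium and differentiation statistics.

LD follows the vcftools ``geno-r2`` convention: squared Pearson correlation
of genotype dosages over pairwise-complete samples, after a strict MAF > 5%
filter and 1 kb thinning, averaged over all cross-window SNP pairs for
500 kb window pairs. Differentiation uses the Hudson F_ST estimator with the
ratio-of-sums windowed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import GenomicInterval, GenotypeMatrix, make_windows


@dataclass
class LDResult:
    windows: list[GenomicInterval]
    mean_r2: np.ndarray  # (w, w) symmetric, NaN where undefined
    n_pairs: np.ndarray  # SNP pairs contributing per entry


@dataclass
class FstWindow:
    window: GenomicInterval
    fst: float
    n_snps: int


def maf_filter(gm: GenotypeMatrix, maf: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency strictly above ``maf``."""
    return gm.subset_variants(gm.maf() > maf)


def thin_snps(gm: GenotypeMatrix, bp: int = 1000) -> GenotypeMatrix:
    """At most one SNP per non-overlapping ``bp`` bin; the first is kept."""
    keep = np.zeros(gm.n_variants, dtype=bool)
    last_chrom, last_bin = None, None
    for j in range(gm.n_variants):
        b = (gm.pos[j] - 1) // bp
        if gm.chrom[j] != last_chrom or b != last_bin:
            keep[j] = True
            last_chrom, last_bin = gm.chrom[j], b
    return gm.subset_variants(keep)


def geno_r2(g1: np.ndarray, g2: np.ndarray, min_complete: int = 4) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete samples (NaN = missing); NaN when fewer than
    ``min_complete`` complete pairs remain or either SNP has zero variance.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    if ok.sum() < min_complete:
        return np.nan
    a, b = g1[ok], g2[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return np.nan
    c = np.mean((a - a.mean()) * (b - b.mean()))
    return float(c * c / (va * vb))


def _pairwise_r2(d: np.ndarray, min_complete: int = 4) -> np.ndarray:
    """r^2 matrix over all SNP pairs of a (samples x snps) dosage matrix,
    pairwise-complete. Vectorised when the matrix is complete."""
    n_snps = d.shape[1]
    if not np.isnan(d).any():
        x = d - d.mean(axis=0)
        cov = x.T @ x / d.shape[0]
        v = np.diag(cov)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = cov**2 / np.outer(v, v)
        r2[(v == 0), :] = np.nan
        r2[:, (v == 0)] = np.nan
        if d.shape[0] < min_complete:
            r2[:] = np.nan
        return r2
    r2 = np.full((n_snps, n_snps), np.nan)
    for i in range(n_snps):
        for j in range(i, n_snps):
            r2[i, j] = r2[j, i] = geno_r2(d[:, i], d[:, j], min_complete)
    return r2


def window_pair_mean_r2(
    gm: GenotypeMatrix,
    window_size: int = 500_000,
    chrom_lengths: dict[str, int] | None = None,
    min_complete: int = 4,
) -> LDResult:
    """Mean r^2 over all SNP pairs spanning each pair of 500 kb windows.

    The diagonal uses within-window pairs (each unordered pair once). The
    input is expected to be MAF-filtered and thinned. Entries where a window
    has no SNP, or no pair is defined, are NaN.
    """
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(gm.pos[gm.chrom == c].max())
            for c in dict.fromkeys(gm.chrom.astype(str))
        }
    windows = make_windows(chrom_lengths, window_size, window_size)
    d = gm.dosage_float()
    r2 = _pairwise_r2(d, min_complete)
    member = [np.nonzero(gm.variant_mask(w))[0] for w in windows]
    w = len(windows)
    mean_r2 = np.full((w, w), np.nan)
    n_pairs = np.zeros((w, w), dtype=int)
    for a in range(w):
        ia = member[a]
        for b in range(a, w):
            ib = member[b]
            if len(ia) == 0 or len(ib) == 0:
                continue
            block = r2[np.ix_(ia, ib)]
            if a == b:
                iu = np.triu_indices(len(ia), k=1)
                vals = block[iu]
            else:
                vals = block.ravel()
            vals = vals[~np.isnan(vals)]
            if len(vals):
                mean_r2[a, b] = mean_r2[b, a] = vals.mean()
                n_pairs[a, b] = n_pairs[b, a] = len(vals)
    return LDResult(windows, mean_r2, n_pairs)


def hudson_fst_snp(
    gmA: GenotypeMatrix, gmB: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Hudson numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    with p the alternate-allele frequency and n the number of non-missing
    alleles in each group. SNPs with fewer than 2 alleles in either group
    get NaN components.
    """
    out = []
    for gm in (gmA, gmB):
        d = gm.dosage_float()
        n = 2.0 * (~np.isnan(d)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(d, axis=0) / n
        out.append((p, n))
    (p1, n1), (p2, n2) = out
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n1 < 2) | (n2 < 2)
    num[bad] = np.nan
    den[bad] = np.nan
    return num, den


def hudson_fst_windowed(
    gm: GenotypeMatrix,
    groupA: list[str] | np.ndarray,
    groupB: list[str] | np.ndarray,
    window_size: int = 10_000,
    step: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[FstWindow]:
    """Windowed Hudson F_ST between two sample groups (ratio of sums).

    Window F_ST = sum(num)/sum(den) over the SNPs in the window; negative
    values are reported as computed, windows without usable SNPs get NaN.
    """
    gmA = gm.subset_samples(groupA)
    gmB = gm.subset_samples(groupB)
    if gmA.n_samples < 2 or gmB.n_samples < 2:
        raise ValueError("each group needs >= 2 samples")
    num, den = hudson_fst_snp(gmA, gmB)
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(gm.pos[gm.chrom == c].max())
            for c in dict.fromkeys(gm.chrom.astype(str))
        }
    windows = make_windows(chrom_lengths, window_size, step or window_size)
    out = []
    for w in windows:
        mask = gm.variant_mask(w) & ~np.isnan(num) & ~np.isnan(den)
        s_den = den[mask].sum()
        fst = float(num[mask].sum() / s_den) if mask.any() and s_den > 0 else np.nan
        out.append(FstWindow(w, fst, int(mask.sum())))
    return out


def loess_smooth(x: np.ndarray, y: np.ndarray, frac: float = 0.05) -> np.ndarray:
    """Local-regression smoothing of a windowed track (presentation only)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    ok = ~np.isnan(np.asarray(y, dtype=float))
    sm = lowess(np.asarray(y)[ok], np.asarray(x)[ok], frac=frac, return_sorted=False)
    out = np.full(len(y), np.nan)
    out[ok] = sm
    return out
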