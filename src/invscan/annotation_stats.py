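"""Mutational-load and breakpoint-annotation statistics.

Load is summarised per 500 kb window as the ratio of segregating
nonsynonymous to synonymous SNP counts (pN/pS) and of mean per-site
nucleotide diversity at those sites (piN/piS), computed within a set of
samples homozygous for one arrangement; inversion, standard and genome-wide
window sets are compared with Welch t-tests. Breakpoint statistics cover
distance to the nearest transcription start site, a two-sided binomial test
of gene disruption against genome-wide gene density, and a two-sample
Kolmogorov-Smirnov test of segmental-duplication density in breakpoint
flanks versus random genomic sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_core import (
    GeneModel,
    GenomicInterval,
    GenotypeMatrix,
    interval_union_length,
    make_windows,
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

SYN, NONSYN, NONCODING, EXCLUDED = "syn", "nonsyn", "noncoding", "excluded"


def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


_CODON = _codon_table()


def _cds_layout(gene: GeneModel, ref_seq: dict[str, str]) -> tuple[str, dict[int, int]]:
    """Spliced CDS sequence in translation order and a map from 0-based
    genomic position to index within that sequence."""
    segs = sorted((iv for iv, _ in gene.cds_segments), key=lambda iv: iv.start)
    positions: list[int] = []
    for iv in segs:
        positions.extend(range(iv.start, iv.end))
    seq = "".join(ref_seq[iv.chrom][iv.start : iv.end] for iv in segs)
    if gene.strand == "-":
        positions = positions[::-1]
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq, {p: i for i, p in enumerate(positions)}


def classify_sites_syn_nonsyn(
    gm: GenotypeMatrix, genes: list[GeneModel], ref_seq: dict[str, str]
) -> np.ndarray:
    """Per-variant class in {syn, nonsyn, noncoding, excluded}.

    A CDS SNP is synonymous iff swapping the alternate allele into its codon
    (reference context, strand-aware) preserves the amino acid. Codons
    containing more than one variant site are excluded, as are SNPs whose
    stated reference allele disagrees with the reference sequence.
    """
    classes = np.array([NONCODING] * gm.n_variants, dtype=object)
    # genomic position -> (gene index, cds index); later genes do not
    # overwrite earlier ones (overlapping genes are rare and ambiguous)
    layouts = [_cds_layout(g, ref_seq) for g in genes]
    pos_map: dict[tuple[str, int], tuple[int, int]] = {}
    for gi, g in enumerate(genes):
        chrom = g.span.chrom
        for p, ci in layouts[gi][1].items():
            pos_map.setdefault((chrom, p), (gi, ci))
    codon_hits: dict[tuple[int, int], list[int]] = {}
    for j in range(gm.n_variants):
        key = (str(gm.chrom[j]), int(gm.pos[j]) - 1)
        if key in pos_map:
            gi, ci = pos_map[key]
            codon_hits.setdefault((gi, ci // 3), []).append(j)
    for (gi, codon_idx), variants in codon_hits.items():
        if len(variants) > 1:
            classes[variants] = EXCLUDED
            continue
        j = variants[0]
        gene = genes[gi]
        seq, pmap = layouts[gi]
        ci = pmap[int(gm.pos[j]) - 1]
        codon = seq[codon_idx * 3 : codon_idx * 3 + 3]
        if len(codon) < 3:
            classes[j] = EXCLUDED
            continue
        ref, alt = str(gm.ref[j]), str(gm.alt[j])
        if gene.strand == "-":
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
        offset = ci % 3
        if codon[offset].upper() != ref.upper():
            classes[j] = EXCLUDED
            continue
        mutant = codon[:offset] + alt + codon[offset + 1 :]
        classes[j] = (
            SYN if _CODON[codon.upper()] == _CODON[mutant.upper()] else NONSYN
        )
    return classes


def site_diversity(dosages: np.ndarray) -> float:
    """Unbiased per-site nucleotide diversity 2p(1-p) n/(n-1).

    ``dosages`` are one site's dosage values (NaN = missing); n counts
    non-missing *alleles*. NaN when fewer than 2 alleles are observed.
    Equals the mean pairwise difference over all allele pairs.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    n = 2 * len(d)
    if n < 2:
        return np.nan
    p = d.sum() / n
    return float(2.0 * p * (1.0 - p) * n / (n - 1))


@dataclass
class LoadWindow:
    window: GenomicInterval
    pn: int
    ps: int
    pin: float
    pis: float

    @property
    def pn_ps(self) -> float:
        return self.pn / self.ps if self.ps > 0 else np.nan

    @property
    def pin_pis(self) -> float:
        if np.isnan(self.pis) or self.pis == 0 or np.isnan(self.pin):
            return np.nan
        return self.pin / self.pis


def window_load(
    gm: GenotypeMatrix,
    genes: list[GeneModel],
    ref_seq: dict[str, str],
    window_size: int = 500_000,
    region: GenomicInterval | None = None,
    site_classes: np.ndarray | None = None,
) -> list[LoadWindow]:
    """pN, pS, piN, piS per 500 kb window, restricted to sites segregating
    within the provided sample set.

    ``gm`` should already be subset to one homozygote class. Windows whose
    pS (or piS) is zero yield NaN ratios and are excluded from tests.
    """
    if site_classes is None:
        site_classes = classify_sites_syn_nonsyn(gm, genes, ref_seq)
    p = gm.allele_frequency()
    with np.errstate(invalid="ignore"):
        segregating = (p > 0) & (p < 1)
    d = gm.dosage_float()
    pi = np.array([site_diversity(d[:, j]) for j in range(gm.n_variants)])
    if region is not None:
        lengths = {region.chrom: region.end}
        windows = [
            w
            for w in make_windows(lengths, window_size, window_size)
            if w.overlaps(region)
        ]
        windows = [w.intersect(region) for w in windows]
    else:
        lengths = {
            str(c): int(gm.pos[gm.chrom == c].max())
            for c in dict.fromkeys(gm.chrom.astype(str))
        }
        windows = make_windows(lengths, window_size, window_size)
    out = []
    for w in windows:
        mask = gm.variant_mask(w) & segregating
        syn = mask & (site_classes == SYN)
        nonsyn = mask & (site_classes == NONSYN)
        pin = float(np.nanmean(pi[nonsyn])) if nonsyn.any() else np.nan
        pis = float(np.nanmean(pi[syn])) if syn.any() else np.nan
        out.append(LoadWindow(w, int(nonsyn.sum()), int(syn.sum()), pin, pis))
    return out


def _ratios(windows: list[LoadWindow], which: str) -> np.ndarray:
    vals = np.array([getattr(w, which) for w in windows], dtype=float)
    return vals[~np.isnan(vals)]


def load_tests(
    inv_windows: list[LoadWindow],
    std_windows: list[LoadWindow],
    genome_windows: list[LoadWindow],
) -> dict:
    """Welch t-tests of load ratios between window sets.

    inversion vs standard: two-sided; inversion (and standard) vs
    genome-wide: one-sided for enrichment (greater). Reports t, df, p for
    each comparison and ratio, flagging degenerate comparisons.
    """
    report: dict = {}
    for which in ("pn_ps", "pin_pis"):
        a, b, g = (
            _ratios(inv_windows, which),
            _ratios(std_windows, which),
            _ratios(genome_windows, which),
        )
        entry: dict = {}
        for name, (x, y, alt) in {
            "inv_vs_std": (a, b, "two-sided"),
            "inv_vs_genome": (a, g, "greater"),
            "std_vs_genome": (b, g, "greater"),
        }.items():
            if len(x) < 2 or len(y) < 2 or (x.var() == 0 and y.var() == 0):
                entry[name] = {"flag": "degenerate"}
                continue
            res = stats.ttest_ind(x, y, equal_var=False, alternative=alt)
            entry[name] = {
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
            }
        report[which] = entry
    return report


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Welch t-test (t, df, p); thin scipy wrapper kept for the
    window-set report format."""
    res = stats.ttest_ind(np.asarray(x), np.asarray(y), equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Breakpoint annotation
# ---------------------------------------------------------------------------


def tss_distance(
    breakpoints: list[tuple[str, int]], genes: list[GeneModel]
) -> list[tuple[float, bool]]:
    """Per breakpoint: unsigned bp distance to the nearest TSS and whether
    the breakpoint lies within any gene span (exon, intron or UTR).

    Breakpoint positions are 1-based; distances compare 1-based coordinates.
    """
    if not genes:
        raise ValueError("empty annotation")
    out = []
    for chrom, pos in breakpoints:
        dists = [
            abs(pos - g.tss) for g in genes if g.span.chrom == chrom
        ]
        d = float(min(dists)) if dists else np.nan
        in_gene = any(g.span.contains(chrom, pos - 1) for g in genes)
        out.append((d, in_gene))
    return out


def breakpoint_gene_binomial(k_in_gene: int, n_breakpoints: int, gene_density: float) -> float:
    """Two-sided binomial test p-value by the minimum-likelihood rule.

    P = sum of P(X=j) over all j with P(X=j) <= P(X=k); this is the method
    of R's binom.test.
    """
    if not (0 <= k_in_gene <= n_breakpoints):
        raise ValueError("k must be in [0, n]")
    if not (0 < gene_density < 1):
        raise ValueError("gene density must be in (0, 1)")
    return float(
        stats.binomtest(k_in_gene, n_breakpoints, gene_density, alternative="two-sided").pvalue
    )


def filter_sd_intervals(
    intervals: list[GenomicInterval],
    lengths_bp: np.ndarray,
    identity: np.ndarray,
    repeat_fraction: np.ndarray,
    min_length: int = 1000,
    min_identity: float = 0.70,
    max_repeat_fraction: float = 0.70,
) -> list[GenomicInterval]:
    """Declarative segmental-duplication filter: >=1 kb, >=70% identity and
    <70% of the sequence masked as common repeats."""
    keep = (
        (np.asarray(lengths_bp) >= min_length)
        & (np.asarray(identity) >= min_identity)
        & (np.asarray(repeat_fraction) < max_repeat_fraction)
    )
    return [iv for iv, k in zip(intervals, keep) if k]


def sd_flank_density(
    sites: list[tuple[str, int]],
    sd_intervals: list[GenomicInterval],
    chrom_lengths: dict[str, int],
    flank: int = 500_000,
) -> np.ndarray:
    """Fraction of each site's +-flank covered by SD intervals.

    The flank window is truncated at chromosome edges and the realized
    length is the density denominator.
    """
    out = []
    for chrom, pos in sites:
        lo = max(0, pos - 1 - flank)
        hi = min(chrom_lengths[chrom], pos - 1 + flank)
        win = GenomicInterval(chrom, lo, hi)
        covered = interval_union_length(
            iv.intersect(win) for iv in sd_intervals if iv.overlaps(win)
        )
        out.append(covered / len(win))
    return np.array(out)


def sd_enrichment(
    breakpoint_densities: np.ndarray, genome_densities: np.ndarray
) -> dict:
    """Two-sample KS test of SD density in breakpoint flanks vs random sites.

    Returns D and p; flagged undefined when a sample is empty or all
    densities are zero (no SD intervals supplied).
    """
    a = np.asarray(breakpoint_densities, dtype=float)
    b = np.asarray(genome_densities, dtype=float)
    if len(a) == 0 or len(b) == 0 or (np.all(a == 0) and np.all(b == 0)):
        return {"undefined": True, "D": np.nan, "p": np.nan}
    res = stats.ks_2samp(a, b)
    return {"undefined": False, "D": float(res.statistic), "p": float(res.pvalue)}
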