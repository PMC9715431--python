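"""Synthetic data generators with the statistical structure the pipeline
assumes, so every stage is testable without sequencing data.

The population generator embeds two diverged haplotype classes — an
inverted and a standard arrangement with suppressed recombination between
them — in an otherwise independently segregating background. Divergence is
modelled as per-SNP allele-frequency contrasts between the classes rather
than an explicit coalescent history: this is sufficient to produce the
local-PCA, LD-block, F_ST and heterozygosity signatures the scan and
genotyper rely on. Background LD is zero by construction (independent
SNPs), which makes the inversion's block signal unambiguous in tests.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .adaptation import ClineModel, cline_predict
from .cross_recomb import CrossPanel
from .io_core import MISSING, GenomicInterval, GenotypeMatrix


def _uniform_maf(rng: np.random.Generator, size: int) -> np.ndarray:
    """Default background allele-frequency law: Uniform(0.05, 0.5)."""
    return rng.uniform(0.05, 0.5, size=size)


@dataclass
class InversionSpec:
    """One simulated inversion polymorphism.

    ``divergence`` is the fraction of inversion-region SNPs carrying a
    class-specific allele-frequency contrast; at those SNPs the absolute
    frequency difference between arrangements is ``delta_af``.
    """

    region: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chr1", 20_000_000, 25_000_000)
    )
    inv_freq: float = 0.3
    divergence: float = 0.3
    delta_af: float = 0.9
    #: heterozygosity level of non-divergent inversion sites; None = use the
    #: background allele-frequency law
    within_class_diversity: float | None = None

    def __post_init__(self) -> None:
        for v in (self.inv_freq, self.divergence, self.delta_af):
            if not (0 <= v <= 1):
                raise ValueError("inversion parameters must be in [0, 1]")


@dataclass
class PopulationSpec:
    n_samples: int = 30
    chrom: str = "chr1"
    chrom_length: int = 50_000_000
    snp_density: float = 2.0  # SNPs per kb
    background_maf_law: Callable[[np.random.Generator, int], np.ndarray] = _uniform_maf
    hwe_deviation: float | None = None  # inbreeding coefficient F at the locus
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need >= 2 samples")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")


@dataclass
class PopulationTruth:
    inv_genotype: np.ndarray  # copies of the inverted arrangement per sample
    divergent_pos: np.ndarray  # 1-based positions of class-divergent SNPs
    region: GenomicInterval


def _unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos: np.ndarray = np.array([], dtype=np.int64)
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=2 * (n - len(pos)))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_population_vcf(
    pop: PopulationSpec, inv: InversionSpec, seed: int
) -> tuple[GenotypeMatrix, PopulationTruth]:
    """Diploid genotype matrix with one embedded inversion polymorphism.

    Outside the inversion every haplotype draws alleles independently per
    SNP from the background law. Inside, each haplotype belongs to the
    inverted class with probability ``inv_freq`` (genotype classes follow
    HWE unless ``hwe_deviation`` sets an inbreeding-style perturbation) and
    divergent SNPs carry class-specific frequencies differing by
    ``delta_af``. The truth table records each sample's inversion genotype.
    """
    if not (
        inv.region.chrom == pop.chrom
        and 0 <= inv.region.start
        and inv.region.end <= pop.chrom_length
    ):
        raise ValueError("inversion region outside the simulated chromosome")
    rng = np.random.default_rng(seed)
    n_snps = int(round(pop.snp_density * pop.chrom_length / 1000))
    pos = _unique_positions(rng, n_snps, pop.chrom_length)
    n, n_hap = pop.n_samples, 2 * pop.n_samples

    # haplotype class per sample pair
    q = inv.inv_freq
    if pop.hwe_deviation is None:
        hap_class = rng.random(n_hap) < q
    else:
        f = pop.hwe_deviation
        probs = np.array(
            [
                (1 - q) ** 2 + f * q * (1 - q),
                2 * q * (1 - q) * (1 - f),
                q**2 + f * q * (1 - q),
            ]
        )
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        geno = rng.choice(3, size=n, p=probs)
        hap_class = np.zeros(n_hap, dtype=bool)
        hap_class[0::2] = geno >= 1
        hap_class[1::2] = geno == 2
    p_bg = pop.background_maf_law(rng, n_snps)
    # random allele orientation so dosage means carry no systematic signal
    flip = rng.random(n_snps) < 0.5
    p_bg = np.where(flip, 1 - p_bg, p_bg)
    hap = (rng.random((n_hap, n_snps)) < p_bg).astype(np.int8)

    in_region = (pos - 1 >= inv.region.start) & (pos - 1 < inv.region.end)
    region_idx = np.nonzero(in_region)[0]
    n_div = int(round(inv.divergence * len(region_idx)))
    div_idx = np.sort(rng.choice(region_idx, size=n_div, replace=False))
    if inv.within_class_diversity is not None:
        # set non-divergent region sites to a frequency giving the requested
        # expected heterozygosity 2p(1-p) = target
        target = inv.within_class_diversity
        p_wc = 0.5 * (1 - np.sqrt(max(0.0, 1 - 2 * target)))
        other = np.setdiff1d(region_idx, div_idx)
        hap[:, other] = (rng.random((n_hap, len(other))) < p_wc).astype(np.int8)
    if n_div:
        base = rng.uniform(0, 1 - inv.delta_af, size=n_div)
        hi_is_inv = rng.random(n_div) < 0.5
        p_inv = np.where(hi_is_inv, base + inv.delta_af, base)
        p_std = np.where(hi_is_inv, base, base + inv.delta_af)
        draws = rng.random((n_hap, n_div))
        hap[:, div_idx] = np.where(
            hap_class[:, None], draws < p_inv[None, :], draws < p_std[None, :]
        ).astype(np.int8)

    dosage = (hap[0::2] + hap[1::2]).astype(np.int8)
    if pop.missing_rate > 0:
        miss = rng.random(dosage.shape) < pop.missing_rate
        dosage[miss] = MISSING
    gm = GenotypeMatrix(
        [f"s{i:03d}" for i in range(n)],
        np.array([pop.chrom] * n_snps, dtype=object),
        pos,
        np.array(["A"] * n_snps, dtype=object),
        np.array(["G"] * n_snps, dtype=object),
        dosage,
    )
    truth = PopulationTruth(
        (hap_class[0::2].astype(int) + hap_class[1::2].astype(int)),
        pos[div_idx],
        inv.region,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# F2 intercross
# ---------------------------------------------------------------------------


@dataclass
class CrossSpec:
    n_f2: int = 300
    chrom: str = "chr1"
    chrom_length: int = 100_000_000
    marker_spacing: int = 100_000
    background_rate: float = 0.8  # cM/Mb
    #: (region, F1-parents-heterozygous) pairs; heterozygous parents place
    #: zero crossovers inside the region
    inversion_regions: list[tuple[GenomicInterval, bool]] = field(default_factory=list)
    genotyping_error: float = 0.0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not (0 <= self.genotyping_error < 0.5):
            raise ValueError("genotyping_error must be in [0, 0.5)")


@dataclass
class CrossTruth:
    crossover_positions: list[np.ndarray]  # per F2, both gametes pooled, bp


def simulate_f2_cross(cross: CrossSpec, seed: int) -> tuple[CrossPanel, CrossTruth]:
    """F2 intercross ancestry panel with Poisson crossovers.

    Each F2 receives two gametes; per gamete the crossover count over L Mb
    is Poisson(background_rate x L / 100) with uniform positions (no
    interference). Gametes from inversion-heterozygous F1 parents place no
    crossovers inside those regions. Ancestry states at the markers are
    reported with independent ``genotyping_error`` flips to a random other
    state.
    """
    rng = np.random.default_rng(seed)
    L = cross.chrom_length
    mean_x = cross.background_rate * (L / 1e6) / 100.0
    markers = np.arange(cross.marker_spacing, L + 1, cross.marker_spacing, dtype=np.int64)
    ancestry = np.zeros((cross.n_f2, len(markers)), dtype=np.int8)
    truth: list[np.ndarray] = []
    suppressed = [iv for iv, het in cross.inversion_regions if het]
    for i in range(cross.n_f2):
        xo_all = []
        geno = np.zeros(len(markers), dtype=np.int8)
        for _gamete in range(2):
            k = rng.poisson(mean_x)
            xo = np.sort(rng.uniform(0, L, size=k))
            for iv in suppressed:
                xo = xo[(xo < iv.start) | (xo >= iv.end)]
            start = rng.integers(0, 2)
            # allele at marker m = start XOR (#crossovers before m) % 2
            counts = np.searchsorted(xo, markers - 1)
            geno += ((start + counts) % 2).astype(np.int8)
            xo_all.append(xo)
        obs = geno.copy()
        if cross.genotyping_error > 0:
            flip = rng.random(len(markers)) < cross.genotyping_error
            for j in np.nonzero(flip)[0]:
                obs[j] = rng.choice([s for s in (0, 1, 2) if s != obs[j]])
        ancestry[i] = obs
        truth.append(np.concatenate(xo_all))
    f1_het = {
        iv: np.full(cross.n_f2, het) for iv, het in cross.inversion_regions
    }
    panel = CrossPanel(cross.chrom, markers, ancestry, f1_het)
    return panel, CrossTruth(truth)


# ---------------------------------------------------------------------------
# Transect, coding regions, phenotypes
# ---------------------------------------------------------------------------


@dataclass
class TransectSpec:
    site_positions: np.ndarray  # km along the gradient, strictly increasing
    n_per_site: np.ndarray | int
    true_cline: ClineModel

    def __post_init__(self) -> None:
        x = np.asarray(self.site_positions, dtype=float)
        if not (np.diff(x) > 0).all():
            raise ValueError("site positions must be strictly increasing")
        n = np.broadcast_to(np.asarray(self.n_per_site), x.shape)
        if (n < 1).any():
            raise ValueError("n_per_site must be >= 1")


def simulate_transect_counts(t: TransectSpec, seed: int) -> pd.DataFrame:
    """Binomial allele counts along a transect under the true cline."""
    rng = np.random.default_rng(seed)
    x = np.asarray(t.site_positions, dtype=float)
    n_dip = np.broadcast_to(np.asarray(t.n_per_site), x.shape)
    n_alleles = 2 * n_dip
    p = np.clip(cline_predict(t.true_cline, x), 0.0, 1.0)
    alt = rng.binomial(n_alleles, p)
    return pd.DataFrame(
        {"site": np.arange(len(x)), "x_km": x, "n_alleles": n_alleles, "alt_count": alt}
    )


_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _sense_codons() -> list[str]:
    from Bio.Data.CodonTable import standard_dna_table

    return sorted(standard_dna_table.forward_table)


def simulate_coding_region(
    n_genes: int = 20,
    codons_per_gene: int = 100,
    syn_rate: float = 0.02,
    nonsyn_rate_by_class: dict[str, float] | float = 0.02,
    n_samples_per_class: int = 20,
    gene_spacing: int = 50_000,
    chrom: str = "chr1",
    seed: int = 0,
):
    """Genes with random sense codons plus planted syn/nonsyn variants.

    Rates are per-codon probabilities of carrying a variant of that kind; at
    most one variant is planted per codon. Synonymous variants segregate in
    all samples; nonsynonymous variants segregate only within their sample
    class ("A"/"B", emulating arrangement-homozygote groups), at
    class-specific rates so that load contrasts can be created or withheld.

    Returns (genes, genotype matrix, ref_seq dict, truth table) where the
    truth table lists every variant's 1-based position, site class and the
    sample class it segregates in.
    """
    from .io_core import GeneModel

    if isinstance(nonsyn_rate_by_class, (int, float)):
        nonsyn_rate_by_class = {"A": float(nonsyn_rate_by_class), "B": float(nonsyn_rate_by_class)}
    rng = np.random.default_rng(seed)
    codons = _sense_codons()
    chrom_len = n_genes * gene_spacing + gene_spacing
    seq = np.frombuffer((b"A" * chrom_len), dtype="S1").copy()

    genes: list[GeneModel] = []
    gene_codons: list[str] = []  # translation-order codon string per gene
    for gi in range(n_genes):
        cds0 = gi * gene_spacing + 1000
        n_bp = 3 * codons_per_gene
        strand = "+" if gi % 2 == 0 else "-"
        codon_str = "".join(rng.choice(codons, size=codons_per_gene))
        genomic = codon_str if strand == "+" else codon_str.translate(_COMPLEMENT)[::-1]
        seq[cds0 : cds0 + n_bp] = np.frombuffer(genomic.encode(), dtype="S1")
        iv = GenomicInterval(chrom, cds0, cds0 + n_bp)
        genes.append(
            GeneModel(
                gene_id=f"gene{gi:03d}",
                strand=strand,
                tss=cds0 + 1 if strand == "+" else cds0 + n_bp,
                span=iv,
                cds_segments=[(iv, 0)],
                exons=[iv],
            )
        )
        gene_codons.append(codon_str)

    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"

    def variant_options(codon: str, want_syn: bool) -> list[tuple[int, str]]:
        aa = table[codon]
        opts = []
        for off in range(3):
            for b in _BASES:
                if b == codon[off]:
                    continue
                mut = codon[:off] + b + codon[off + 1 :]
                if (table[mut] == aa) == want_syn:
                    opts.append((off, b))
        return opts

    records = []  # (pos1, ref, alt, site_class, sample_class)
    used: set[tuple[int, int]] = set()
    draws = [("syn", "all", syn_rate)] + [
        ("nonsyn", cls, rate) for cls, rate in sorted(nonsyn_rate_by_class.items())
    ]
    for site_class, sample_class, rate in draws:
        for gi in range(n_genes):
            hit = np.nonzero(rng.random(codons_per_gene) < rate)[0]
            for ci in hit:
                if (gi, ci) in used:
                    continue
                codon = gene_codons[gi][ci * 3 : ci * 3 + 3]
                opts = variant_options(codon, site_class == "syn")
                if not opts:
                    continue
                used.add((gi, ci))
                off, alt = opts[rng.integers(len(opts))]
                g = genes[gi]
                if g.strand == "+":
                    pos0 = g.span.start + ci * 3 + off
                    ref_g, alt_g = codon[off], alt
                else:
                    pos0 = g.span.end - 1 - (ci * 3 + off)
                    ref_g = codon[off].translate(_COMPLEMENT)
                    alt_g = alt.translate(_COMPLEMENT)
                records.append((pos0 + 1, ref_g, alt_g, site_class, sample_class))

    records.sort()
    n_a, n_b = n_samples_per_class, n_samples_per_class
    sample_ids = [f"A{i:02d}" for i in range(n_a)] + [f"B{i:02d}" for i in range(n_b)]
    is_a = np.array([True] * n_a + [False] * n_b)
    dosage = np.zeros((n_a + n_b, len(records)), dtype=np.int8)
    for j, (_, _, _, _, sample_class) in enumerate(records):
        freq = rng.uniform(0.1, 0.9)
        if sample_class == "all":
            carriers = np.ones(n_a + n_b, dtype=bool)
        else:
            carriers = is_a if sample_class == "A" else ~is_a
        dosage[carriers, j] = rng.binomial(2, freq, size=carriers.sum())
    gm = GenotypeMatrix(
        sample_ids,
        np.array([chrom] * len(records), dtype=object),
        np.array([r[0] for r in records], dtype=np.int64),
        np.array([r[1] for r in records], dtype=object),
        np.array([r[2] for r in records], dtype=object),
        dosage,
    )
    truth = pd.DataFrame(
        records, columns=["pos", "ref", "alt", "site_class", "sample_class"]
    )
    ref_seq = {chrom: seq.tobytes().decode()}
    return genes, gm, ref_seq, truth


def simulate_phenotypes(
    genotypes: np.ndarray,
    additive_effect: float,
    covariate_effect: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    body_length_mean: float = 92.0,
    body_length_sd: float = 4.0,
) -> pd.DataFrame:
    """Trait = a x genotype + b x body length + Gaussian noise.

    Body length is an independent Gaussian covariate (mm, deer-mouse scale).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    g = np.asarray(genotypes, dtype=float)
    body = rng.normal(body_length_mean, body_length_sd, size=len(g))
    trait = (
        additive_effect * g
        + covariate_effect * body
        + rng.normal(0.0, noise_sd, size=len(g))
    )
    return pd.DataFrame(
        {
            "sample": [f"s{i:03d}" for i in range(len(g))],
            "genotype": g,
            "body_length": body,
            "trait": trait,
        }
    )
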