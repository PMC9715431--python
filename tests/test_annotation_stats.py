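"""Syn/nonsyn classification, diversity, load windows, breakpoint tests."""

import numpy as np
import pytest
from scipy import stats

from invscan import (
    GeneModel,
    GenomicInterval,
    breakpoint_gene_binomial,
    classify_sites_syn_nonsyn,
    filter_sd_intervals,
    load_tests,
    sd_enrichment,
    sd_flank_density,
    simulate_coding_region,
    site_diversity,
    tss_distance,
    window_load,
)
from invscan.annotation_stats import EXCLUDED, NONSYN, SYN, welch_t

from conftest import make_gm


def gene_plus(seq_cds: str, start0: int = 10, chrom: str = "chr1") -> tuple[GeneModel, dict]:
    iv = GenomicInterval(chrom, start0, start0 + len(seq_cds))
    ref = {chrom: "A" * start0 + seq_cds + "A" * 50}
    g = GeneModel("g", "+", start0 + 1, iv, cds_segments=[(iv, 0)], exons=[iv])
    return g, ref


class TestClassifySites:
    def test_third_position_degeneracy_synonymous(self):
        g, ref = gene_plus("GGA")  # Gly
        gm = make_gm(np.array([[0], [1]], dtype=np.int8), pos=[13])
        gm.ref[0], gm.alt[0] = "A", "C"  # GGA -> GGC, still Gly
        assert classify_sites_syn_nonsyn(gm, [g], ref)[0] == SYN

    def test_first_position_nonsynonymous(self):
        g, ref = gene_plus("GGA")
        gm = make_gm(np.array([[0], [1]], dtype=np.int8), pos=[11])
        gm.ref[0], gm.alt[0] = "G", "A"  # GGA -> AGA, Gly -> Arg
        assert classify_sites_syn_nonsyn(gm, [g], ref)[0] == NONSYN

    def test_multi_variant_codon_excluded(self):
        g, ref = gene_plus("GGAGGA")
        gm = make_gm(np.array([[0, 0], [1, 1]], dtype=np.int8), pos=[11, 12])
        gm.ref[:] = ["G", "G"]
        gm.alt[:] = ["A", "A"]
        assert list(classify_sites_syn_nonsyn(gm, [g], ref)) == [EXCLUDED, EXCLUDED]

    def test_brute_force_translation_oracle(self, rng):
        """Random codon/variant configurations vs direct Bio.Seq translation."""
        from Bio.Seq import Seq
        from Bio.Data.CodonTable import standard_dna_table

        sense = sorted(standard_dna_table.forward_table)
        n_codons = 200
        codon_str = "".join(rng.choice(sense, size=n_codons))
        g, ref = gene_plus(codon_str)
        # one variant per randomly chosen codon
        chosen = rng.choice(n_codons, size=120, replace=False)
        pos, refs, alts, expect = [], [], [], []
        for ci in sorted(chosen):
            off = rng.integers(3)
            base = codon_str[ci * 3 + off]
            alt = rng.choice([b for b in "ACGT" if b != base])
            codon = codon_str[ci * 3 : ci * 3 + 3]
            mutant = codon[:off] + alt + codon[off + 1 :]
            aa_ref = str(Seq(codon).translate())
            aa_alt = str(Seq(mutant).translate())
            pos.append(10 + ci * 3 + off + 1)
            refs.append(base)
            alts.append(str(alt))
            expect.append(SYN if aa_ref == aa_alt else NONSYN)
        gm = make_gm(
            np.vstack([np.zeros(len(pos)), np.ones(len(pos))]).astype(np.int8), pos=pos
        )
        gm.ref[:] = refs
        gm.alt[:] = alts
        assert list(classify_sites_syn_nonsyn(gm, [g], ref)) == expect

    def test_minus_strand_consistency(self):
        genes, gm, ref, truth = simulate_coding_region(
            n_genes=6, codons_per_gene=120, syn_rate=0.05,
            nonsyn_rate_by_class=0.05, seed=15,
        )
        minus_ids = {g.gene_id for g in genes if g.strand == "-"}
        assert minus_ids  # generator alternates strands
        classes = classify_sites_syn_nonsyn(gm, genes, ref)
        expect = truth.set_index("pos").site_class
        assert list(classes) == [expect[int(p)] for p in gm.pos]


class TestSiteDiversity:
    def test_fixed_site_zero(self):
        assert site_diversity(np.array([2.0, 2, 2])) == 0.0

    def test_formula_by_hand(self):
        # p = 0.5, n = 4 alleles -> 2 * 0.25 * 4/3
        assert site_diversity(np.array([0.0, 2.0])) == pytest.approx(2 / 3)

    def test_equals_pairwise_difference_enumeration(self, rng):
        d = rng.integers(0, 3, size=12).astype(float)
        alleles = np.concatenate([[1] * int(x) + [0] * (2 - int(x)) for x in d])
        n = len(alleles)
        diffs = [
            alleles[i] != alleles[j] for i in range(n) for j in range(i + 1, n)
        ]
        assert site_diversity(d) == pytest.approx(np.mean(diffs))

    def test_single_allele_missing(self):
        assert np.isnan(site_diversity(np.array([np.nan, np.nan])))


class TestWindowLoad:
    def test_zero_nonsyn_gives_zero_ratio(self):
        genes, gm, ref, _ = simulate_coding_region(
            n_genes=10, codons_per_gene=100, syn_rate=0.08,
            nonsyn_rate_by_class=0.0, seed=6,
        )
        wins = window_load(gm, genes, ref)
        with_snps = [w for w in wins if w.ps > 0]
        assert with_snps and all(w.pn_ps == 0.0 for w in with_snps)

    def test_segregating_within_set_rule(self):
        genes, gm, ref, truth = simulate_coding_region(
            n_genes=10, codons_per_gene=100, syn_rate=0.0,
            nonsyn_rate_by_class={"A": 0.1, "B": 0.0}, seed=8,
        )
        b_only = gm.subset_samples([s for s in gm.sample_ids if s.startswith("B")])
        wins = window_load(b_only, genes, ref)
        assert all(w.pn == 0 for w in wins)  # A-class variants don't segregate in B

    def test_ratio_tracks_rate_ratio(self):
        genes, gm, ref, truth = simulate_coding_region(
            n_genes=40, codons_per_gene=200, syn_rate=0.05,
            nonsyn_rate_by_class=0.05, seed=10,
        )
        wins = window_load(gm, genes, ref)
        pn = sum(w.pn for w in wins)
        ps = sum(w.ps for w in wins)
        # nonsyn variants are planted per class (two classes at 0.05 each)
        # against one shared syn draw at 0.05 -> expected count ratio 2
        assert pn / ps == pytest.approx(2.0, rel=0.2)


class TestLoadTests:
    def _wins(self, ratios):
        return [
            type("W", (), {"pn_ps": r, "pin_pis": r})() for r in ratios
        ]

    def test_identical_groups_p_near_one(self):
        a = self._wins([0.5, 0.6, 0.4, 0.5])
        rep = load_tests(a, a, a)
        assert rep["pn_ps"]["inv_vs_std"]["p"] == pytest.approx(1.0)

    def test_welch_matches_hand_formula(self):
        x = np.array([0.3, 0.5, 0.4])
        y = np.array([0.6, 0.8, 0.7])
        t, df, p = welch_t(x, y)
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 2)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand))

    def test_null_calibration(self, rng):
        # equal generating rates: two-sided rejection ~ alpha
        rejections = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(0.5, 0.1, size=8)
            y = rng.normal(0.5, 0.1, size=8)
            _, _, p = welch_t(x, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestTSSDistance:
    @pytest.fixture
    def genes(self):
        out = []
        for gid, start, end, strand in [("a", 100, 200, "+"), ("b", 500, 700, "-")]:
            iv = GenomicInterval("chr1", start, end)
            tss = start + 1 if strand == "+" else end
            out.append(GeneModel(gid, strand, tss, iv, exons=[iv]))
        return out

    def test_breakpoint_at_tss(self, genes):
        d, in_gene = tss_distance([("chr1", 101)], genes)[0]
        assert d == 0 and in_gene

    def test_between_genes_min_distance(self, genes):
        d, in_gene = tss_distance([("chr1", 300)], genes)[0]
        assert d == min(300 - 101, 700 - 300)
        assert not in_gene

    def test_matches_linear_scan(self, genes, rng):
        for pos in rng.integers(1, 1000, size=20):
            d, _ = tss_distance([("chr1", int(pos))], genes)[0]
            assert d == min(abs(int(pos) - 101), abs(int(pos) - 700))

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            tss_distance([("chr1", 10)], [])


def binom_two_sided_enumeration(k, n, p):
    """Minimum-likelihood two-sided binomial p-value by full enumeration."""
    probs = np.array([stats.binom.pmf(j, n, p) for j in range(n + 1)])
    return float(probs[probs <= probs[k] * (1 + 1e-10)].sum())


class TestBreakpointBinomial:
    def test_mode_p_near_one(self):
        p = breakpoint_gene_binomial(8, 20, 0.39)  # k = round(20*0.39)
        assert p > 0.8

    @pytest.mark.parametrize("k,n", [(3, 20), (0, 20), (20, 20), (10, 20)])
    def test_matches_enumeration_oracle(self, k, n):
        assert breakpoint_gene_binomial(k, n, 0.39) == pytest.approx(
            binom_two_sided_enumeration(k, n, 0.39), abs=1e-10
        )

    def test_single_trial_edge(self):
        # k=0, n=1, p=0.39: P(X=0)=0.61, P(X=1)=0.39 <= 0.61 -> total 1.0
        assert breakpoint_gene_binomial(0, 1, 0.39) == pytest.approx(
            binom_two_sided_enumeration(0, 1, 0.39)
        )
        assert breakpoint_gene_binomial(0, 1, 0.39) == pytest.approx(1.0)


class TestSDEnrichment:
    def test_identical_samples(self):
        x = np.array([0.1, 0.2, 0.3])
        res = sd_enrichment(x, x)
        assert res["D"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = sd_enrichment(np.array([0.1, 0.2, 0.3]), np.array([0.4, 0.5, 0.6]))
        assert res["D"] == pytest.approx(1.0)

    def test_matches_ecdf_oracle(self, rng):
        a = rng.random(25)
        b = rng.random(40) ** 2
        grid = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert sd_enrichment(a, b)["D"] == pytest.approx(
            np.max(np.abs(ecdf_a - ecdf_b)), abs=1e-12
        )

    def test_empty_sd_set_undefined(self):
        res = sd_enrichment(np.zeros(5), np.zeros(10))
        assert res["undefined"]

    def test_flank_density_truncated_at_edges(self):
        sds = [GenomicInterval("chr1", 0, 100_000)]
        dens = sd_flank_density(
            [("chr1", 1), ("chr1", 100_001)], sds, {"chr1": 2_000_000}
        )
        # first site: flank truncated to [0, 500k), 100k covered
        assert dens[0] == pytest.approx(100_000 / 500_000)
        # second site: flank [0, 600k) realized, 100k covered
        assert dens[1] == pytest.approx(100_000 / 600_000)

    def test_sd_filter_thresholds(self):
        ivs = [GenomicInterval("c", 0, 2000)] * 4
        kept = filter_sd_intervals(
            ivs,
            lengths_bp=[2000, 500, 2000, 2000],
            identity=[0.9, 0.9, 0.5, 0.9],
            repeat_fraction=[0.1, 0.1, 0.1, 0.9],
        )
        assert len(kept) == 1
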