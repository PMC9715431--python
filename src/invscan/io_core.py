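"""Genomic I/O, interval arithmetic and configuration.

All internal coordinates are 0-based half-open; VCF and GFF3 carry 1-based
coordinates and are converted at the I/O boundary. Genotypes are dosages of
the alternate allele in {0, 1, 2} with ``MISSING`` (-1) as a distinct state
that is never silently imputed at I/O time.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING = -1

logger = logging.getLogger("invscan")


def setup_logging(level: int = logging.INFO) -> None:
    """Structured logging to stderr, idempotent."""
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(h)
    logger.setLevel(level)


#: Pipeline defaults. Window sizes follow the scan/LD/F_ST conventions used
#: throughout: 100 kb scan windows, 500 kb LD windows, 10 kb F_ST windows
#: between inversion haplotype classes and 100 kb between ecotypes.
DEFAULT_CONFIG: dict = {
    "scan": {
        "window_size": 100_000,
        "step": 100_000,
        "min_snps": 10,
        "k_range": [2, 10],
        "z_thresh": 1.5,
        "min_run": 10,
        "z_absolute": False,
        "kmeans_restarts": 10,
    },
    "ld": {"maf": 0.05, "thin_bp": 1000, "window_size": 500_000},
    "fst": {
        "haplotype_window": 10_000,
        "ecotype_window": 100_000,
        "loess_frac": 0.05,
    },
    "genotyping": {"ambiguity_margin": 0.5, "diagnostic_error": 0.01},
    "cross": {"marker_spacing": 100_000},
    "load": {"window_size": 500_000},
    "adaptation": {"scaling": 100.0, "dominance": 0.5, "n_assoc_tests": 13},
}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML/TOML config file over :data:`DEFAULT_CONFIG`."""
    import copy

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    path = Path(path)
    if path.suffix in {".toml", ".tml"}:
        import tomllib

        with open(path, "rb") as fh:
            user = tomllib.load(fh)
    else:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        cfg.setdefault(section, {}).update(values)
    return cfg


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return chrom == self.chrom and self.start <= pos0 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def interval_union_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


def make_windows(
    chrom_lengths: dict[str, int], size: int, step: int | None = None
) -> list[GenomicInterval]:
    """Tile each chromosome with windows of ``size`` bp every ``step`` bp.

    The final partial window is retained. With ``step == size`` the tiling
    covers every bp exactly once. A chromosome shorter than ``size`` yields a
    single window covering it.
    """
    if step is None:
        step = size
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    windows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            windows.append(GenomicInterval(chrom, start, min(start + size, length)))
            if start + size >= length:
                break
            start += step
    return windows


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3+ (0-based half-open), comment and track lines skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x biallelic SNPs, dosage-coded.

    ``dosage[i, j]`` is the alternate-allele count of sample ``i`` at variant
    ``j`` in {0, 1, 2} or :data:`MISSING`. ``pos`` is 1-based and strictly
    increasing within each chromosome.
    """

    sample_ids: list[str]
    chrom: np.ndarray  # (n_variants,) str
    pos: np.ndarray  # (n_variants,) int, 1-based
    ref: np.ndarray  # (n_variants,) str
    alt: np.ndarray  # (n_variants,) str
    dosage: np.ndarray  # (n_samples, n_variants) int8

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError("dosage shape mismatch")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or MISSING")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def variant_mask(self, region: GenomicInterval) -> np.ndarray:
        """Boolean mask of variants inside ``region`` (pos converted 0-based)."""
        return (self.chrom == region.chrom) & (self.pos - 1 >= region.start) & (
            self.pos - 1 < region.end
        )

    def subset_region(self, region: GenomicInterval) -> "GenotypeMatrix":
        return self.subset_variants(self.variant_mask(region))

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sample_ids,
            self.chrom[mask],
            self.pos[mask],
            self.ref[mask],
            self.alt[mask],
            self.dosage[:, mask],
        )

    def subset_samples(self, which: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        """Subset by sample id list or boolean/integer index array."""
        arr = np.asarray(which)
        if arr.dtype.kind in "US" or arr.dtype == object:
            idx = [self.sample_ids.index(str(s)) for s in which]
        elif arr.dtype == bool:
            idx = np.nonzero(arr)[0]
        else:
            idx = arr
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.chrom,
            self.pos,
            self.ref,
            self.alt,
            self.dosage[list(idx), :],
        )

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with missing as NaN."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        return d

    def allele_frequency(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing calls."""
        d = self.dosage_float()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)


class VCFParseError(ValueError):
    pass


def read_vcf(path: str | Path, region: GenomicInterval | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF v4.x file (gzip accepted).

    Multiallelic records and indels are dropped; missing genotypes are kept
    as :data:`MISSING`. ``region`` filters with half-open semantics on the
    internal 0-based coordinates.
    """
    from cyvcf2 import VCF

    path = str(path)
    _validate_vcf_header(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 raises on open
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chrom, pos, ref, alt, cols = [], [], [], [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        if region is not None and not region.contains(v.CHROM, v.POS - 1):
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        cols.append(code[v.gt_types])
    dosage = (
        np.array(cols, dtype=np.int8).T
        if cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples,
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object),
        np.array(alt, dtype=object),
        dosage,
    )


def _validate_vcf_header(path: str) -> None:
    import gzip

    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                return
            raise VCFParseError(f"{path}: line {lineno}: expected VCF header, got {line[:40]!r}")
    raise VCFParseError(f"{path}: no #CHROM header line found")


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype columns.

    ``read_vcf(write_vcf(gm))`` reproduces sample ids, coordinates and
    dosages exactly (an empty matrix yields a valid header-only file).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(gm.chrom.astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_variants):
            gts = "\t".join(_GT[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A protein-coding gene: TSS, CDS with phases, exon/intron/UTR structure."""

    gene_id: str
    strand: str
    tss: int  # 1-based; transcript start respecting strand
    span: GenomicInterval
    cds_segments: list[tuple[GenomicInterval, int]] = field(default_factory=list)
    exons: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)
    utrs: list[GenomicInterval] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv, _ in self.cds_segments)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    One model per gene (first mRNA transcript). Genes whose concatenated CDS
    length is not divisible by 3 are excluded with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        mrnas = list(db.children(g, featuretype="mRNA"))
        tx = mrnas[0] if mrnas else g
        strand = g.strand if g.strand in "+-" else "+"
        tss = tx.start if strand == "+" else tx.end
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end)
            for e in db.children(tx, featuretype="exon", order_by="start")
        ]
        cds = [
            (
                GenomicInterval(c.seqid, c.start - 1, c.end),
                int(c.frame) if c.frame not in (None, ".") else 0,
            )
            for c in db.children(tx, featuretype="CDS", order_by="start")
        ]
        utrs = [
            GenomicInterval(u.seqid, u.start - 1, u.end)
            for t in ("five_prime_UTR", "three_prime_UTR", "UTR")
            for u in db.children(tx, featuretype=t, order_by="start")
        ]
        introns = [
            GenomicInterval(g.seqid, a.end, b.start)
            for a, b in zip(exons, exons[1:])
            if b.start > a.end
        ]
        model = GeneModel(
            gene_id=g.id,
            strand=strand,
            tss=tss,
            span=GenomicInterval(g.seqid, g.start - 1, g.end),
            cds_segments=cds,
            exons=exons,
            introns=introns,
            utrs=utrs,
        )
        if cds and model.cds_length % 3 != 0:
            warnings.warn(
                f"gene {g.id}: CDS length {model.cds_length} not divisible by 3; excluded"
            )
            continue
        genes.append(model)
    return genes


def gene_density(genes: Sequence[GeneModel], genome_length: int) -> float:
    """Fraction of the genome covered by gene spans (exons+introns+UTRs)."""
    return interval_union_length(g.span for g in genes) / genome_length
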