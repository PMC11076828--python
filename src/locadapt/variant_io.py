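"""Variant, annotation and sample-table I/O.

Reads VCF 4.2 genotypes into the pipeline's central genotype matrix, applies
the GATK-style hard filters used for the resequencing panel, and classifies
each SNP into a genomic feature class (exon / UTR / intron / promoter /
intergenic) from a GFF3 gene-model file.

Coordinates: files are 1-based inclusive on disk (VCF, GFF3); every in-memory
interval in this package is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

INFO_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

FEATURE_CLASSES = ("exon", "utr", "intron", "promoter", "intergenic")
#: most-specific-wins precedence used by :func:`classify_site`
FEATURE_PRECEDENCE = ("exon", "utr", "intron", "promoter", "intergenic")
CODING_CLASSES = frozenset({"exon", "intron"})
REGULATORY_CLASSES = frozenset({"promoter", "utr"})

MISSING = -1


@dataclass
class SiteRecord:
    """One biallelic SNP: position, alleles, INFO annotations, per-sample data.

    ``genotypes`` holds one (a1, a2) allele pair per sample with -1 for a
    missing allele; ``depths`` the per-sample read depth (DP).
    """

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    info: dict
    depths: np.ndarray
    genotypes: np.ndarray  # (n_samples, 2) int8

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a biallelic SNP: {self.ref}>{self.alt}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass
class FilterConfig:
    """Hard-filter thresholds.

    Defaults are the panel's published cutoffs: per-individual depth >= 3,
    MAF >= 0.05, QD >= 2.0, FS <= 60.0, MQ >= 40.0, MQRankSum >= -12.5,
    ReadPosRankSum >= -8.0.  Rank-sum annotations are only defined for sites
    with both hom and het calls; an absent annotation never fails a site.
    """

    min_depth: int = 3
    maf_min: float = 0.05
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0

    def __post_init__(self) -> None:
        vals = [self.min_depth, self.maf_min, self.qd_min, self.fs_max,
                self.mq_min, self.mqranksum_min, self.readposranksum_min]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all thresholds must be finite")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")


@dataclass
class SampleRegistry:
    """Ordered samples and their population labels."""

    samples: list[str]
    pop_of: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.pop_of[s], None)
        return list(seen)

    def members(self, pop: str) -> list[int]:
        idx = [i for i, s in enumerate(self.samples) if self.pop_of[s] == pop]
        if not idx:
            raise KeyError(f"unknown or empty population: {pop!r}")
        return idx


@dataclass
class GenotypeMatrix:
    """Diploid genotype codes, samples x sites.

    Codes follow the 0/1/2 dosage convention: 0 = hom-ref, 1 = het,
    2 = hom-alt, -1 = missing.  ``sites`` is a DataFrame with columns
    chrom, pos, ref, alt and optionally feature_class and aa (ancestral
    allele used for polarization).
    """

    codes: np.ndarray  # (n_samples, n_sites) int8
    samples: list[str]
    pop_of: dict[str, str]
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.samples), len(self.sites)):
            raise ValueError("codes shape does not match samples x sites")
        missing_labels = [s for s in self.samples if s not in self.pop_of]
        if missing_labels:
            raise ValueError(f"samples without population label: {missing_labels}")

    @property
    def registry(self) -> SampleRegistry:
        return SampleRegistry(list(self.samples), dict(self.pop_of))

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def pop_indices(self, pop: str) -> np.ndarray:
        return np.asarray(self.registry.members(pop), dtype=int)

    def alt_counts(self, pop: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, non-missing haplotype count)."""
        sub = self.codes if pop is None else self.codes[self.pop_indices(pop)]
        ok = sub >= 0
        j = np.where(ok, sub, 0).sum(axis=0)
        n_h = 2 * ok.sum(axis=0)
        return j.astype(float), n_h.astype(float)

    def derived_counts(self, pop: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (derived allele count, non-missing haplotypes), polarized.

        Requires an ``aa`` column in ``sites`` naming the ancestral allele;
        sites where the ancestral allele is neither ref nor alt get count -1
        (caller should drop them).
        """
        if "aa" not in self.sites.columns:
            raise ValueError("sites table has no 'aa' (ancestral allele) column")
        j, n_h = self.alt_counts(pop)
        aa = self.sites["aa"].to_numpy()
        ref = self.sites["ref"].to_numpy()
        alt = self.sites["alt"].to_numpy()
        der = np.where(aa == ref, j, np.where(aa == alt, n_h - j, -1.0))
        return der, n_h


# ---------------------------------------------------------------------------
# population map / environment tables


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>population`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Read ``sample population MAT MAMT MAP`` (TSV, header row)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"environment table must have columns {sorted(required)}")
    return df.set_index("sample")


# ---------------------------------------------------------------------------
# VCF reading / writing


def read_vcf(path: str | Path, pop_map: str | Path | dict[str, str],
             ) -> tuple[list[SiteRecord], SampleRegistry]:
    """Read biallelic SNPs from a VCF 4.2 file.

    Multi-allelic and non-SNP records are skipped (count logged).  Raises if a
    VCF sample is absent from the population map or the file is unsorted
    within a chromosome.
    """
    from cyvcf2 import VCF

    if not isinstance(pop_map, dict):
        pop_map = read_popmap(pop_map)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_map]
    if absent:
        raise ValueError(f"VCF samples missing from population map: {absent}")
    registry = SampleRegistry(samples, {s: pop_map[s] for s in samples})

    records: list[SiteRecord] = []
    n_skipped = 0
    last: tuple[str, int] | None = None
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        key = (v.CHROM, v.POS)
        if last is not None and last[0] == key[0] and key[1] < last[1]:
            raise ValueError(f"VCF not sorted at {key[0]}:{key[1]}")
        last = key
        info = {}
        for k in INFO_FIELDS:
            val = v.INFO.get(k)
            if val is not None:
                info[k] = float(val)
        gt = np.asarray(v.genotype.array())[:, :2].astype(np.int8)
        try:
            depths = v.format("DP")[:, 0].astype(int)
            depths = np.where(depths < 0, 0, depths)
        except (TypeError, KeyError):
            depths = np.full(len(samples), 10**6, dtype=int)
        records.append(SiteRecord(v.CHROM, v.POS, v.REF, v.ALT[0], info,
                                  depths, gt))
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    return records, registry


def write_vcf(path: str | Path, records: Sequence[SiteRecord],
              registry: SampleRegistry) -> None:
    """Write records as a minimal VCF 4.2 text file (GT:DP per sample)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chrom_max: dict[str, int] = {}
        for r in records:
            chrom_max[r.chrom] = max(chrom_max.get(r.chrom, 0), r.pos)
        for chrom in sorted(chrom_max):
            fh.write(f"##contig=<ID={chrom},length={chrom_max[chrom] + 1}>\n")
        for k in INFO_FIELDS:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(registry.samples) + "\n")
        for r in records:
            info = ";".join(f"{k}={r.info[k]:g}" for k in INFO_FIELDS if k in r.info)
            cells = []
            for (a1, a2), dp in zip(r.genotypes, r.depths):
                gt = "./." if a1 < 0 or a2 < 0 else f"{a1}/{a2}"
                cells.append(f"{gt}:{int(dp)}")
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
                     f"{info or '.'}\tGT:DP\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# hard filtering

_RULES = ("qd", "fs", "mq", "mqranksum", "readposranksum", "all_missing", "maf")


def _site_maf(genotypes: np.ndarray) -> float:
    ok = genotypes >= 0
    n = ok.sum()
    if n == 0:
        return np.nan
    p = genotypes[ok].sum() / n
    return min(p, 1.0 - p)


def hard_filter(records: Iterable[SiteRecord], cfg: FilterConfig | None = None,
                ) -> tuple[list[SiteRecord], dict[str, int]]:
    """Apply depth masking and site-level hard filters.

    Genotypes with depth below ``cfg.min_depth`` are set missing.  A site is
    then removed if any INFO annotation violates its threshold, if every
    genotype is missing, or if the minor allele frequency over non-missing
    genotypes falls below ``cfg.maf_min``.  Removed sites are tallied under
    the first failing rule, in the order QD, FS, MQ, MQRankSum,
    ReadPosRankSum, all-missing, MAF.
    """
    cfg = cfg or FilterConfig()
    counts = {r: 0 for r in _RULES}
    kept: list[SiteRecord] = []
    for rec in records:
        gt = rec.genotypes.copy()
        gt[rec.depths < cfg.min_depth] = MISSING
        info = rec.info
        rule = None
        if info.get("QD", np.inf) < cfg.qd_min:
            rule = "qd"
        elif info.get("FS", -np.inf) > cfg.fs_max:
            rule = "fs"
        elif info.get("MQ", np.inf) < cfg.mq_min:
            rule = "mq"
        elif info.get("MQRankSum", np.inf) < cfg.mqranksum_min:
            rule = "mqranksum"
        elif info.get("ReadPosRankSum", np.inf) < cfg.readposranksum_min:
            rule = "readposranksum"
        elif (gt >= 0).sum() == 0:
            rule = "all_missing"
        else:
            maf = _site_maf(gt)
            if maf < cfg.maf_min:
                rule = "maf"
        if rule is None:
            kept.append(replace(rec, genotypes=gt))
        else:
            counts[rule] += 1
    return kept, counts


# ---------------------------------------------------------------------------
# GFF3 gene models and site classification

PROMOTER_BP = 2000


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # CDS intervals
    utrs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Transcription start, as a 0-based position."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def promoter(self) -> tuple[int, int]:
        """2-kb strand-aware window upstream of the TSS, 0-based half-open."""
        if self.strand == "+":
            return max(0, self.start - PROMOTER_BP), self.start
        return self.end, self.end + PROMOTER_BP


class GeneModels:
    """GFF3 gene models with interval trees for per-site classification."""

    def __init__(self, genes: Sequence[Gene]):
        self.genes = list(genes)
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        for g in self.genes:
            trees = self._trees.setdefault(
                g.chrom, {k: IntervalTree() for k in ("gene", "exon", "utr", "promoter")})
            trees["gene"][g.start:g.end] = g.gene_id
            for s, e in g.exons:
                if e > s:
                    trees["exon"][s:e] = g.gene_id
            for s, e in g.utrs:
                if e > s:
                    trees["utr"][s:e] = g.gene_id
            ps, pe = g.promoter
            if pe > ps:
                trees["promoter"][ps:pe] = g.gene_id
        self._warned: set[str] = set()

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneModels":
        genes: dict[str, Gene] = {}
        mrna_to_gene: dict[str, str] = {}
        deferred: list[tuple[str, str, int, int]] = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    continue
                chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
                start0, end0 = int(start) - 1, int(end)  # to half-open
                adict = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
                if ftype == "gene":
                    gid = adict.get("ID", f"{chrom}:{start}")
                    genes[gid] = Gene(gid, chrom, start0, end0, strand)
                elif ftype == "mRNA":
                    mrna_to_gene[adict.get("ID", "")] = adict.get("Parent", "")
                elif ftype in ("CDS", "exon", "five_prime_UTR", "three_prime_UTR", "UTR"):
                    kind = "exon" if ftype in ("CDS",) else (
                        "utr" if "UTR" in ftype else None)
                    if kind is None:
                        continue  # plain exon lines: CDS+UTR already tile them
                    parent = adict.get("Parent", "")
                    deferred.append((kind, parent, start0, end0))
        for kind, parent, s, e in deferred:
            gid = mrna_to_gene.get(parent, parent)
            if gid in genes:
                (genes[gid].exons if kind == "exon" else genes[gid].utrs).append((s, e))
        return cls(list(genes.values()))

    def classify(self, chrom: str, pos1: int) -> str:
        """Feature class of a 1-based site position.

        Precedence: exon (CDS) > UTR > intron > promoter > intergenic;
        promoters count only outside gene bodies.
        """
        trees = self._trees.get(chrom)
        if trees is None:
            if chrom not in self._warned:
                logger.warning("chromosome %s absent from gene models; "
                               "sites classified intergenic", chrom)
                self._warned.add(chrom)
            return "intergenic"
        p = pos1 - 1
        if trees["exon"][p]:
            return "exon"
        if trees["utr"][p]:
            return "utr"
        if trees["gene"][p]:
            return "intron"
        if trees["promoter"][p]:
            return "promoter"
        return "intergenic"

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Gene ids whose bodies overlap [start, end) by >= 1 bp."""
        trees = self._trees.get(chrom)
        if trees is None or end <= start:
            return []
        return sorted({iv.data for iv in trees["gene"][start:end]})


def classify_site(site: SiteRecord, gene_models: GeneModels) -> str:
    return gene_models.classify(site.chrom, site.pos)


def classify_sites(records: Sequence[SiteRecord], gene_models: GeneModels) -> list[str]:
    return [classify_site(r, gene_models) for r in records]


# ---------------------------------------------------------------------------
# genotype encoding


def encode_genotypes(records: Sequence[SiteRecord], registry: SampleRegistry,
                     feature_classes: Sequence[str] | None = None,
                     outgroup: str | None = None) -> GenotypeMatrix:
    """Encode allele pairs as 0/1/2 dosage codes (-1 missing).

    If ``outgroup`` names a sample, that sample is removed from the matrix and
    its homozygous allele recorded per site in an ``aa`` (ancestral allele)
    column; heterozygous or missing outgroup calls give aa = "N".
    """
    n = len(registry.samples)
    codes = np.empty((n, len(records)), dtype=np.int8)
    aa: list[str] = []
    for jx, rec in enumerate(records):
        g = rec.genotypes
        col = np.where((g[:, 0] < 0) | (g[:, 1] < 0), MISSING, g[:, 0] + g[:, 1])
        codes[:, jx] = col.astype(np.int8)
    sites = pd.DataFrame({
        "chrom": [r.chrom for r in records],
        "pos": [r.pos for r in records],
        "ref": [r.ref for r in records],
        "alt": [r.alt for r in records],
    })
    if feature_classes is not None:
        sites["feature_class"] = list(feature_classes)
    samples = list(registry.samples)
    pop_of = dict(registry.pop_of)
    if outgroup is not None:
        k = samples.index(outgroup)
        for jx, rec in enumerate(records):
            a1, a2 = rec.genotypes[k]
            if a1 < 0 or a1 != a2:
                aa.append("N")
            else:
                aa.append(rec.ref if a1 == 0 else rec.alt)
        codes = np.delete(codes, k, axis=0)
        samples.pop(k)
        pop_of = {s: p for s, p in pop_of.items() if s != outgroup}
        sites["aa"] = aa
    return GenotypeMatrix(codes, samples, pop_of, sites)


def load_genotype_matrix(vcf_path: str | Path, pop_map: str | Path | dict,
                         gff3: str | Path | None = None,
                         cfg: FilterConfig | None = None,
                         outgroup: str | None = None,
                         ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """One-call convenience: read, hard-filter, classify, encode."""
    records, registry = read_vcf(vcf_path, pop_map)
    kept, counts = hard_filter(records, cfg)
    classes = None
    if gff3 is not None:
        classes = classify_sites(kept, GeneModels.from_gff3(gff3))
    gm = encode_genotypes(kept, registry, classes, outgroup=outgroup)
    return gm, counts
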