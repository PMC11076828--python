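"""Truth-annotated synthetic input bundles.

Generates a complete analysis input set — VCF, GFF3 gene models, population
map, environment table, per-gene codon alignments and a truth JSON — with the
demographic, selective-sweep and environmental-association structure the
pipeline is designed to detect: three populations (14, 17, 15 diploids) plus
an outgroup sampled from a divergence-bottleneck-growth-migration history,
localized hard sweeps, temperature-monotone allele-frequency clines, and
coding genes with optionally inflated nonsynonymous divergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .coalescent import (DemographicModel, Divergence, Epoch,
                         PopulationHistory, simulate_branches,
                         simulate_haplotype_block, total_branch_length)
from .demography import figure_model
from .mk_test import GENETIC_CODE
from .variant_io import SampleRegistry, SiteRecord, write_vcf

#: per-location climate normals (MAT degC, MAMT degC, MAP mm)
ENV_DEFAULTS = {
    "F": {"MAT": 19.5, "MAMT": 5.8, "MAP": 1743.3},
    "S": {"MAT": 23.5, "MAMT": 12.4, "MAP": 1889.3},
    "W": {"MAT": 24.9, "MAMT": 15.6, "MAP": 1913.0},
}

POP_SIZES_DEFAULT = {"F": 14, "S": 17, "W": 15}

OUTGROUP_POP = "OUT"
OUTGROUP_DIVERGENCE = 60_000.0  # generations; ecological-speciation scale


@dataclass
class SweepSpec:
    """A localized hard sweep: carrier allele adopted with prob exp(-d/lam)."""

    population: str
    chrom: str
    center: int
    lam: float = 50_000.0  # decay length, bp

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("sweep decay length must be positive")


@dataclass
class GeaSpec:
    """Environment-associated causal SNPs: logistic cline in MAMT."""

    n_causal: int = 0
    beta: float = 0.5  # per degC of mean annual minimum temperature


@dataclass
class CodingSpec:
    n_genes: int = 60
    n_selected: int = 3
    n_codons: int = 300      # matches the 3 x 300-bp CDS exon gene layout
    n_ingroup_haplotypes: int = 20
    poly_rate: float = 0.12   # polymorphic sites per codon site
    div_rate: float = 0.05    # fixed differences per codon site
    dn_inflation: float = 8.0


@dataclass
class SimConfig:
    """Generator settings; the defaults are the scaled-down test scenario.

    The demographic scenario defaults to the fitted composite history
    (divergence ~4,650 generations ago from an ancestor of ~58k, growth in F,
    a bottleneck in S, small constant W, asymmetric migration).  The
    paper-scale preset (177 Mb, ~190k SNPs) is obtained with
    ``SimConfig.paper_scale()`` and is intended for manual runs.
    """

    pop_sizes: dict[str, int] = field(
        default_factory=lambda: dict(POP_SIZES_DEFAULT))
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    snp_per_kb: float = 1.0
    block_length: int = 20_000
    scenario: DemographicModel | None = None
    sweeps: list[SweepSpec] = field(default_factory=list)
    gea: GeaSpec = field(default_factory=GeaSpec)
    coding: CodingSpec = field(default_factory=CodingSpec)
    env: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in ENV_DEFAULTS.items()})
    filter_fail_fraction: float = 0.0
    mean_depth: float = 40.0
    #: the density target describes the analysis-ready (MAF-passing) SNP set;
    #: the raw simulation is inflated by this factor before MAF screening
    oversample_factor: float = 2.0
    emit_maf_min: float = 0.05

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.chrom_length < 1:
            raise ValueError("genome dimensions must be positive")
        for s in self.sweeps:
            if not 0 <= s.center < self.chrom_length:
                raise ValueError(f"sweep center outside chromosome: {s}")

    @classmethod
    def paper_scale(cls, **kw) -> "SimConfig":
        return cls(n_chrom=18, chrom_length=9_833_000, snp_per_kb=1.07, **kw)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


def _with_outgroup(model: DemographicModel) -> DemographicModel:
    """Add an outgroup population diverging deep in the ancestor."""
    pops = list(model.populations) + [
        PopulationHistory(OUTGROUP_POP, [Epoch(0.0, 10_000.0)]),
        PopulationHistory("ROOT", [Epoch(0.0, 57_833.0)]),
    ]
    derived = {d.derived for d in model.divergences}
    roots = [p.name for p in model.populations if p.name not in derived]
    anc = roots[-1] if roots else model.populations[0].name
    divs = list(model.divergences) + [
        Divergence(OUTGROUP_DIVERGENCE, OUTGROUP_POP, "ROOT"),
        Divergence(OUTGROUP_DIVERGENCE, anc, "ROOT"),
    ]
    return DemographicModel(model.name + "+outgroup", pops, divs,
                            dict(model.migration), model.mu, model.gen_time,
                            model.k)


@dataclass
class Haplotypes:
    """Phased 0/1 haplotypes for one genome, grouped by population."""

    chroms: list[str]
    positions: dict[str, np.ndarray]         # 1-based, sorted, per chrom
    alleles: dict[str, np.ndarray]           # (n_hap, n_sites) per chrom
    hap_pops: list[str]                      # population of each haplotype

    def pop_hap_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.hap_pops) == pop)


def simulate_neutral(config: SimConfig, rng: np.random.Generator) -> Haplotypes:
    """Neutral haplotypes under the configured demography.

    Chromosomes are simulated as loosely linked non-recombining blocks of
    ``block_length``; the per-site mutation rate is tuned on the realized
    total branch lengths so the expected SNP count hits the density target.
    """
    scenario = config.scenario or figure_model()
    model = _with_outgroup(scenario)
    sample_sizes = {p: 2 * n for p, n in config.pop_sizes.items()}
    sample_sizes[OUTGROUP_POP] = 2
    hap_pops = [p for p, n in sample_sizes.items() for _ in range(n)]

    n_blocks_per_chrom = max(1, config.chrom_length // config.block_length)
    genomes: list[list] = []
    total_tl = 0.0
    for _ in range(config.n_chrom):
        blocks = []
        for _ in range(n_blocks_per_chrom):
            br = simulate_branches(model, sample_sizes, rng)
            blocks.append(br)
            total_tl += total_branch_length(br)
        genomes.append(blocks)

    target = (config.snp_per_kb / 1000.0 * config.chrom_length
              * config.n_chrom * config.oversample_factor)
    block_len_eff = config.chrom_length / n_blocks_per_chrom
    mu_site = target / (total_tl * block_len_eff) if total_tl > 0 else 0.0

    positions: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    chroms = config.chrom_names()
    for chrom, blocks in zip(chroms, genomes):
        pos_parts, allele_parts = [], []
        for b, br in enumerate(blocks):
            lam = mu_site * block_len_eff * total_branch_length(br)
            n_mut = rng.poisson(lam)
            lo = int(b * block_len_eff)
            hi = int((b + 1) * block_len_eff)
            n_mut = min(n_mut, hi - lo)
            if n_mut == 0:
                continue
            block_alleles = simulate_haplotype_block(model, sample_sizes,
                                                     n_mut, rng, branches=br)
            pos = np.sort(rng.choice(np.arange(lo + 1, hi + 1), size=n_mut,
                                     replace=False))
            pos_parts.append(pos)
            allele_parts.append(block_alleles)
        if pos_parts:
            positions[chrom] = np.concatenate(pos_parts)
            alleles[chrom] = np.concatenate(allele_parts, axis=1)
        else:
            positions[chrom] = np.array([], dtype=int)
            alleles[chrom] = np.zeros((len(hap_pops), 0), dtype=np.int8)
    return Haplotypes(chroms, positions, alleles, hap_pops)


def inject_sweep(hap: Haplotypes, spec: SweepSpec,
                 rng: np.random.Generator) -> int:
    """Overwrite the target population's alleles with a carrier haplotype's.

    Each other haplotype in the population independently adopts the carrier's
    allele at each site with probability exp(-d / lam), d the distance to the
    sweep center — fixation at the center, high-frequency derived alleles
    nearby.  Returns the carrier haplotype index.
    """
    idx = hap.pop_hap_indices(spec.population)
    if idx.size == 0:
        raise ValueError(f"sweep population {spec.population!r} has no haplotypes")
    carrier = int(rng.choice(idx))
    pos = hap.positions[spec.chrom]
    alle = hap.alleles[spec.chrom]
    p_adopt = np.exp(-np.abs(pos - spec.center) / spec.lam)
    for h in idx:
        if h == carrier:
            continue
        adopt = rng.random(pos.size) < p_adopt
        alle[h, adopt] = alle[carrier, adopt]
    return carrier


def _solve_alpha(beta: float, mamt: np.ndarray) -> float:
    from scipy.special import expit

    def mean_freq(alpha: float) -> float:
        return float(np.mean(expit(alpha + beta * mamt)))
    lo, hi = -50 - abs(beta) * 50, 50 + abs(beta) * 50
    return brentq(lambda a: mean_freq(a) - 0.5, lo, hi)


def inject_gea(hap: Haplotypes, config: SimConfig,
               rng: np.random.Generator) -> list[tuple[str, int]]:
    """Rewrite allele frequencies of causal SNPs as a logistic MAMT cline.

    For each causal site the per-population derived-allele frequency is
    logistic(alpha + beta * MAMT) with alpha solved so the across-population
    mean is 0.5; haplotype alleles are redrawn Bernoulli within population.
    Returns (chrom, pos) of the causal sites.
    """
    spec = config.gea
    if spec.n_causal == 0:
        return []
    if spec.beta == 0.0:
        import warnings
        warnings.warn("gea beta = 0 with causal SNPs requested: no signal")
    pops = list(config.pop_sizes)
    mamt = np.array([config.env[p]["MAMT"] for p in pops])
    alpha = _solve_alpha(spec.beta, mamt)
    from scipy.special import expit
    freqs = expit(alpha + spec.beta * mamt)

    sites_per_chrom = {c: hap.positions[c].size for c in hap.chroms}
    total = sum(sites_per_chrom.values())
    if total == 0:
        return []
    picks = rng.choice(total, size=min(spec.n_causal, total), replace=False)
    causal: list[tuple[str, int]] = []
    offset = 0
    for chrom in hap.chroms:
        n = sites_per_chrom[chrom]
        local = np.sort(picks[(picks >= offset) & (picks < offset + n)]) - offset
        alle = hap.alleles[chrom]
        for s in local:
            for p, f in zip(pops, freqs):
                idx = hap.pop_hap_indices(p)
                alle[idx, s] = (rng.random(idx.size) < f).astype(np.int8)
            causal.append((chrom, int(hap.positions[chrom][s])))
        offset += n
    return causal


# ---------------------------------------------------------------------------
# gene models and coding alignments

_CODONS_NO_STOP = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
_BASES = "ACGT"


@dataclass
class SynthGene:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    exons: list[tuple[int, int]]
    utrs: list[tuple[int, int]]


def make_gene_models(config: SimConfig, rng: np.random.Generator,
                     ) -> list[SynthGene]:
    """Place non-overlapping genes with exon/intron/UTR structure.

    Layout per gene (+ strand): 5'UTR 150 bp, three 300-bp CDS exons
    separated by 200-bp introns, 3'UTR 150 bp; genes are separated by
    intergenic gaps of at least 2.5 kb so promoters stay clear of neighbors.
    """
    genes: list[SynthGene] = []
    utr, cds, intron = 150, 300, 200
    body = utr + 3 * cds + 2 * intron + utr
    per_chrom = int(np.ceil(config.coding.n_genes / config.n_chrom))
    gid = 0
    for chrom in config.chrom_names():
        cursor = 2_500
        for _ in range(per_chrom):
            if gid >= config.coding.n_genes:
                break
            gap = int(rng.integers(2_500, 8_000))
            start = cursor + gap
            end = start + body
            if end + 2_500 > config.chrom_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            e1 = (start + utr, start + utr + cds)
            e2 = (e1[1] + intron, e1[1] + intron + cds)
            e3 = (e2[1] + intron, e2[1] + intron + cds)
            utrs = [(start, start + utr), (end - utr, end)]
            gid += 1
            genes.append(SynthGene(f"gene{gid:05d}", chrom, start, end, strand,
                                   [e1, e2, e3], utrs))
        if gid >= config.coding.n_genes:
            break
    if gid < config.coding.n_genes:
        raise ValueError(f"only {gid} of {config.coding.n_genes} genes fit "
                         "in the configured genome")
    return genes


def write_gff3(genes: list[SynthGene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.start + 1, g.end
            fh.write(f"{g.chrom}\tsynth\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            fh.write(f"{g.chrom}\tsynth\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tsynth\tCDS\t{xs + 1}\t{xe}\t.\t"
                         f"{g.strand}\t0\tID={g.gene_id}.cds{i};"
                         f"Parent={g.gene_id}.t1\n")
            kinds = ("five_prime_UTR", "three_prime_UTR")
            if g.strand == "-":
                kinds = kinds[::-1]
            for kind, (us, ue) in zip(kinds, g.utrs):
                fh.write(f"{g.chrom}\tsynth\t{kind}\t{us + 1}\t{ue}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.{kind};"
                         f"Parent={g.gene_id}.t1\n")


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(3))]


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(len(_CODONS_NO_STOP), size=n_codons)
    return "".join(_CODONS_NO_STOP[i] for i in idx)


def _is_nonsyn(seq: str, pos: int, new_base: str) -> bool:
    c0 = pos - pos % 3
    old = seq[c0:c0 + 3]
    new = old[:pos % 3] + new_base + old[pos % 3 + 1:]
    return GENETIC_CODE[old] != GENETIC_CODE[new]


def make_gene_alignments(config: SimConfig, genes: list[SynthGene],
                         rng: np.random.Generator,
                         ) -> tuple[dict[str, list[str]], list[str]]:
    """Per-gene ingroup haplotype CDSs + outgroup CDS under a neutral model.

    Neutral genes receive Poisson polymorphism and divergence at the
    configured per-site rates (syn/nonsyn ratio emerging from the code);
    ``n_selected`` genes additionally receive verified-nonsynonymous fixed
    differences inflating Dn by the configured factor.  Returns
    ({gene_id: [hap CDS..., outgroup CDS]}, selected gene ids) with the
    outgroup sequence last in each list.
    """
    spec = config.coding
    sel_ids = [g.gene_id for g in genes[:spec.n_selected]]
    out: dict[str, list[str]] = {}
    for g in genes:
        length = spec.n_codons * 3
        anc = _random_cds(spec.n_codons, rng)
        n_hap = spec.n_ingroup_haplotypes
        haps = [list(anc) for _ in range(n_hap)]
        # ingroup polymorphism: derived allele carried by i of n haplotypes,
        # i drawn from the neutral 1/i spectrum
        n_poly = rng.poisson(spec.poly_rate * length)
        weights = 1.0 / np.arange(1, n_hap)
        weights /= weights.sum()
        for _ in range(n_poly):
            pos = int(rng.integers(length))
            new = _mutate_base(anc[pos], rng)
            i = int(rng.choice(np.arange(1, n_hap), p=weights))
            carriers = rng.choice(n_hap, size=i, replace=False)
            for h in carriers:
                haps[h][pos] = new
        # divergence on the outgroup branch
        og = list(anc)
        n_div = rng.poisson(spec.div_rate * length)
        for _ in range(n_div):
            pos = int(rng.integers(length))
            og[pos] = _mutate_base(og[pos], rng)
        if g.gene_id in sel_ids:
            # extra verified-nonsynonymous fixed differences, placed one per
            # still-untouched codon so pathway averaging cannot dilute them
            n_extra = rng.poisson((spec.dn_inflation - 1.0)
                                  * spec.div_rate * length * 0.75)
            untouched = [ci for ci in range(spec.n_codons)
                         if og[3 * ci:3 * ci + 3] == list(anc[3 * ci:3 * ci + 3])]
            rng.shuffle(untouched)
            for ci in untouched[:n_extra]:
                for _attempt in range(20):
                    pos = 3 * ci + int(rng.integers(3))
                    new = _mutate_base(og[pos], rng)
                    if _is_nonsyn("".join(og), pos, new):
                        og[pos] = new
                        break
        out[g.gene_id] = ["".join(h) for h in haps] + ["".join(og)]
    return out, sel_ids


# ---------------------------------------------------------------------------
# bundle assembly


_FAIL_CHOICES = (
    ("QD", 1.0), ("FS", 80.0), ("MQ", 20.0),
    ("MQRankSum", -15.0), ("ReadPosRankSum", -10.0),
)


@dataclass
class Bundle:
    config: SimConfig
    records: list[SiteRecord]
    registry: SampleRegistry
    genes: list[SynthGene]
    alignments: dict[str, list[str]]
    truth: dict

    def write(self, outdir, force: bool = False) -> Path:
        outdir = Path(outdir)
        if outdir.exists() and any(outdir.iterdir()) and not force:
            raise FileExistsError(f"{outdir} exists; pass force=True")
        (outdir / "genes").mkdir(parents=True, exist_ok=True)
        write_vcf(outdir / "variants.vcf", self.records, self.registry)
        write_gff3(self.genes, outdir / "genes.gff3")
        with open(outdir / "popmap.tsv", "w") as fh:
            for s in self.registry.samples:
                fh.write(f"{s}\t{self.registry.pop_of[s]}\n")
        with open(outdir / "env.tsv", "w") as fh:
            fh.write("sample\tpopulation\tMAT\tMAMT\tMAP\n")
            for s in self.registry.samples:
                p = self.registry.pop_of[s]
                if p == OUTGROUP_POP:
                    continue
                e = self.config.env[p]
                fh.write(f"{s}\t{p}\t{e['MAT']}\t{e['MAMT']}\t{e['MAP']}\n")
        for gid, seqs in self.alignments.items():
            with open(outdir / "genes" / f"{gid}.fasta", "w") as fh:
                for i, seq in enumerate(seqs[:-1]):
                    fh.write(f">{gid}_hap{i + 1}\n{seq}\n")
                fh.write(f">{gid}_outgroup\n{seqs[-1]}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return outdir


def _sample_names(pop_sizes: dict[str, int]) -> tuple[list[str], dict[str, str]]:
    samples, pop_of = [], {}
    for p, n in pop_sizes.items():
        for i in range(n):
            name = f"{p}{i + 1:02d}"
            samples.append(name)
            pop_of[name] = p
    samples.append("OUT01")
    pop_of["OUT01"] = OUTGROUP_POP
    return samples, pop_of


def generate_bundle(config: SimConfig, seed: int) -> Bundle:
    """Simulate, inject signals, and assemble an in-memory bundle.

    All randomness flows from ``seed``; identical (config, seed) pairs give
    byte-identical bundles on write.
    """
    rng = np.random.default_rng(seed)
    hap = simulate_neutral(config, rng)

    carriers = {}
    for sw in config.sweeps:
        carriers[f"{sw.population}:{sw.chrom}:{sw.center}"] = \
            inject_sweep(hap, sw, rng)
    causal = inject_gea(hap, config, rng)

    genes = make_gene_models(config, rng)
    alignments, selected = make_gene_alignments(config, genes, rng)

    samples, pop_of = _sample_names(config.pop_sizes)
    registry = SampleRegistry(samples, pop_of)
    n_dip = len(samples)

    # the emitted set emulates the analysis-ready SNP panel: screen out
    # sites below the MAF threshold across all samples after injections,
    # then subsample to the exact density target (causal sites protected)
    causal_set = {(c, p) for c, p in causal}
    screened: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_pass_total = 0
    for chrom in hap.chroms:
        pos = hap.positions[chrom]
        alle = hap.alleles[chrom]
        tot = alle.sum(axis=0)
        n_hap = alle.shape[0]
        maf = np.minimum(tot, n_hap - tot) / n_hap
        keep = maf >= config.emit_maf_min
        screened[chrom] = (pos[keep], alle[:, keep])
        n_pass_total += int(keep.sum())
    target = int(round(config.snp_per_kb / 1000.0 * config.chrom_length
                       * config.n_chrom))
    if n_pass_total < target:
        import warnings
        warnings.warn(f"achieved density {n_pass_total} SNPs below target "
                      f"{target}; emitting all passing sites")
    if n_pass_total > target:
        flat = [(chrom, i) for chrom in hap.chroms
                for i in range(screened[chrom][0].size)]
        protected = [k for k, (chrom, i) in enumerate(flat)
                     if (chrom, int(screened[chrom][0][i])) in causal_set]
        others = [k for k in range(len(flat)) if k not in set(protected)]
        n_draw = max(0, target - len(protected))
        chosen = set(protected) | set(
            rng.choice(others, size=min(n_draw, len(others)),
                       replace=False).tolist())
        keep_by_chrom: dict[str, list[int]] = {c: [] for c in hap.chroms}
        for k in sorted(chosen):
            chrom, i = flat[k]
            keep_by_chrom[chrom].append(i)
        for chrom in hap.chroms:
            pos, alle = screened[chrom]
            idx = np.array(keep_by_chrom[chrom], dtype=int)
            screened[chrom] = (pos[idx], alle[:, idx])
    causal = [(c, p) for c, p in causal
              if p in set(screened[c][0].tolist())]

    records: list[SiteRecord] = []
    fail_positions: list[str] = []
    for chrom in hap.chroms:
        pos, alle = screened[chrom]
        for s in range(pos.size):
            col = alle[:, s]
            gt = col.reshape(n_dip, 2)
            fail = rng.random() < config.filter_fail_fraction
            info = {
                "QD": float(np.clip(rng.normal(25.0, 5.0), 2.5, None)),
                "FS": float(np.clip(rng.exponential(5.0), None, 55.0)),
                "MQ": float(np.clip(rng.normal(55.0, 3.0), 41.0, None)),
                "MQRankSum": float(np.clip(rng.normal(0.0, 1.0), -5.0, 5.0)),
                "ReadPosRankSum": float(np.clip(rng.normal(0.0, 1.0), -5.0, 5.0)),
            }
            if fail:
                key, bad = _FAIL_CHOICES[int(rng.integers(len(_FAIL_CHOICES)))]
                info[key] = bad
                fail_positions.append(f"{chrom}:{int(pos[s])}")
            depths = rng.poisson(config.mean_depth, size=n_dip)
            depths = np.maximum(depths, 5)
            # ancestral allele is the REF by construction (derived = 1 = ALT)
            records.append(SiteRecord(chrom, int(pos[s]), "A", "G", info,
                                      depths, gt.astype(np.int8)))

    scenario = config.scenario or figure_model()
    truth = {
        "sweeps": [{"population": s.population, "chrom": s.chrom,
                    "center": s.center, "lam": s.lam,
                    "carrier_hap": carriers[f"{s.population}:{s.chrom}:{s.center}"]}
                   for s in config.sweeps],
        "causal_snps": [f"{c}:{p}" for c, p in causal],
        "selected_genes": sorted(selected),
        "filter_fail_sites": fail_positions,
        "demography": {
            "name": scenario.name,
            "divergences": [asdict(d) for d in scenario.divergences],
            "migration": {f"{s}->{d}": m
                          for (s, d), m in scenario.migration.items()},
        },
        "outgroup_sample": "OUT01",
        "n_snps": len(records),
    }
    return Bundle(config, records, registry, genes, alignments, truth)


def emit_bundle(config: SimConfig, seed: int, outdir,
                force: bool = False) -> Bundle:
    """Generate and write a bundle; returns the in-memory object too."""
    bundle = generate_bundle(config, seed)
    bundle.write(outdir, force=force)
    return bundle
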