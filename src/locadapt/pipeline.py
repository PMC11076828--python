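"""Full-analysis orchestration: filter -> diversity -> scans -> MK -> RDA ->
candidate genes.

The candidate-gene rule mirrors the study design: a gene is a high-confidence
candidate when it overlaps a highly differentiated region (HDR; joint FST /
XP-CLR outlier windows) AND contains at least one environment-associated
(RDA-outlier) SNP within its exons.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, gea_rda, mk_test, selection_scan, variant_io

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    popmap: str
    gff3: str
    env: str | None = None
    alignments_dir: str | None = None
    outdir: str = "locadapt_out"
    pairs: list[tuple[str, str]] = field(default_factory=list)
    window_size: int = 20_000
    window_step: int = 5_000
    bin_size: int = 20_000
    z: float = 1.96
    n_perm: int = 199
    seed: int = 0
    outgroup: str | None = None
    exon_only_candidates: bool = True
    filter_cfg: variant_io.FilterConfig = field(
        default_factory=variant_io.FilterConfig)

    def __post_init__(self) -> None:
        for path in (self.vcf, self.popmap, self.gff3):
            if not Path(path).exists():
                raise FileNotFoundError(path)


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """All intersection-region counts for 2-3 named sets (inclusion-exclusion).

    Keys are '&'-joined sorted name combinations; each count is the number of
    elements in exactly that combination of sets.
    """
    names = sorted(sets)
    if len(names) < 2:
        raise ValueError("venn_counts needs at least 2 sets")
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names
                                         if n not in combo))
            out["&".join(combo)] = len(inside - outside)
    return out


def _hash_params(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and emit per-stage TSV/JSON/BED plus a manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: dict[str, float] = {}

    def tick(name: str) -> None:
        stages[name] = round(time.time() - t0, 2)
        logger.info("stage %s done at %.1fs", name, stages[name])

    # --- filter ---
    gm, removal = variant_io.load_genotype_matrix(
        config.vcf, config.popmap, config.gff3, config.filter_cfg,
        outgroup=config.outgroup)
    with open(out / "filter_report.json", "w") as fh:
        json.dump(removal, fh, indent=1, sort_keys=True)
    gene_models = variant_io.GeneModels.from_gff3(config.gff3)
    pops = [p for p in gm.registry.populations]
    pairs = config.pairs or list(combinations(pops, 2))
    tick("filter")

    # --- diversity ---
    for pop in pops:
        df = diversity.pi_windows(gm, pop, config.bin_size)
        df.to_csv(out / f"pi_{pop}.tsv", sep="\t", index=False)
    for a, b in pairs:
        df = diversity.dxy_windows(gm, a, b, config.bin_size)
        df.to_csv(out / f"dxy_{a}_{b}.tsv", sep="\t", index=False)
    tick("diversity")

    # --- PCA ---
    pca = gea_rda.pca_genotypes(gm.codes)
    pd.DataFrame({
        "sample": gm.samples,
        "population": [gm.pop_of[s] for s in gm.samples],
        "PC1": pca["scores"][:, 0],
        "PC2": pca["scores"][:, 1] if pca["scores"].shape[1] > 1 else np.nan,
    }).to_csv(out / "pca.tsv", sep="\t", index=False)
    tick("pca")

    # --- scans and HDRs ---
    chrom_lengths = selection_scan.infer_chrom_lengths(gm)
    windows = selection_scan.sliding_windows(chrom_lengths, config.window_size,
                                             config.window_step)
    hdrs_by_pair: dict[str, list[selection_scan.HDR]] = {}
    hdr_genes: dict[str, set] = {}
    for a, b in pairs:
        pair = f"{a}-{b}"
        fst = selection_scan.wc_fst_windows(gm, a, b, windows=windows)
        xp = selection_scan.xpclr_windows(gm, a, b, windows=windows)
        scan = fst.rename(columns={"value": "fst"}).copy()
        scan["xpclr"] = xp["value"]
        scan["xpclr_norm"] = xp["xpclr_norm"]
        scan["is_outlier_fst"] = selection_scan.call_outliers(
            scan["fst"], "upper", config.z)
        scan["is_outlier_xpclr"] = selection_scan.call_outliers(
            scan["xpclr_norm"], "upper", config.z)
        scan.to_csv(out / f"scan_{pair}.tsv", sep="\t", index=False)
        hdrs = selection_scan.intersect_hdrs(fst, xp, config.z, pair, gm)
        hdrs_by_pair[pair] = hdrs
        selection_scan.hdrs_to_bed(hdrs, out / f"hdrs_{pair}.bed")
        genes = selection_scan.genes_in_regions(hdrs, gene_models)
        hdr_genes[pair] = set(g for lst in genes for g in lst)
    tick("scan")

    # --- Fay & Wu's H (needs polarization) ---
    h_contrasts = {}
    if "aa" in gm.sites.columns:
        for pop in pops:
            h = selection_scan.fay_wu_h_windows(gm, pop, windows=windows)
            h.to_csv(out / f"faywu_h_{pop}.tsv", sep="\t", index=False)
            pop_hdrs = [h_ for pr, hs in hdrs_by_pair.items() if pop in pr
                        for h_ in hs]
            if pop_hdrs and h["value"].notna().any():
                try:
                    h_contrasts[pop] = selection_scan.hdr_contrast(h, pop_hdrs)
                except ValueError:
                    pass
    tick("fay_wu_h")

    # --- MK test ---
    mk_positive: set = set()
    if config.alignments_dir:
        genes = mk_test.read_gene_alignments(config.alignments_dir)
        table = mk_test.mk_table(genes)
        table.to_csv(out / "mk.tsv", sep="\t", index=False)
        mk_positive = set(mk_test.positive_selection_genes(table))
    tick("mk")

    # --- RDA ---
    rda_outlier_sites: set = set()
    rda_genes: set = set()
    if config.env:
        env = variant_io.read_env_table(config.env)
        keep = [i for i, s in enumerate(gm.samples) if s in env.index]
        codes = gm.codes[keep]
        env = env.loc[[gm.samples[i] for i in keep]]
        env_x = env[[c for c in env.columns if c != "population"]]
        fit = gea_rda.rda_fit(codes, env_x)
        gea_rda.rda_axis_test(codes, env_x, fit, config.n_perm, config.seed)
        outlier_idx = gea_rda.loading_outliers(fit, config.z)
        site_ids = (gm.sites["chrom"].astype(str) + ":"
                    + gm.sites["pos"].astype(str))
        rda_outlier_sites = set(site_ids.iloc[outlier_idx])
        loadings = pd.DataFrame(fit.loadings, columns=[
            f"RDA{i + 1}" for i in range(fit.loadings.shape[1])])
        loadings.insert(0, "site", site_ids)
        loadings["is_outlier"] = np.isin(np.arange(len(site_ids)), outlier_idx)
        loadings.to_csv(out / "rda_loadings.tsv", sep="\t", index=False)
        with open(out / "rda_summary.json", "w") as fh:
            json.dump({"r2": fit.r2, "r2_adj": fit.r2_adj,
                       "eigenvalues": fit.eigenvalues.tolist(),
                       "axis_p": fit.axis_p.tolist(),
                       "env_condition_number": fit.env_condition_number,
                       "n_outlier_snps": len(outlier_idx)}, fh, indent=1)
        # genes with an outlier SNP in their exons (or bodies, if configured)
        feature = gm.sites.get("feature_class")
        for i in outlier_idx:
            chrom = gm.sites["chrom"].iloc[i]
            p0 = int(gm.sites["pos"].iloc[i]) - 1
            if config.exon_only_candidates and feature is not None \
                    and feature.iloc[i] != "exon":
                continue
            rda_genes.update(gene_models.genes_overlapping(chrom, p0, p0 + 1))
    tick("rda")

    # --- candidate genes ---
    all_hdr_genes = set().union(*hdr_genes.values()) if hdr_genes else set()
    candidates = sorted(all_hdr_genes & rda_genes)
    report = {
        "per_pair_hdr_counts": {p: len(h) for p, h in hdrs_by_pair.items()},
        "per_pair_hdr_genes": {p: sorted(g) for p, g in hdr_genes.items()},
        "hdr_gene_venn": venn_counts(hdr_genes) if len(hdr_genes) >= 2 else {},
        "n_rda_outlier_snps": len(rda_outlier_sites),
        "temperature_genes": sorted(rda_genes),
        "candidates": candidates,
        "mk_positive_genes": sorted(mk_positive),
        "candidate_mk_overlap": sorted(set(candidates) & mk_positive),
        "h_contrasts": h_contrasts,
    }
    with open(out / "candidates.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    manifest = {
        "params_hash": _hash_params({
            "pairs": pairs, "size": config.window_size,
            "step": config.window_step, "z": config.z,
            "seed": config.seed, "bin": config.bin_size}),
        "seed": config.seed,
        "n_snps": gm.n_sites,
        "n_samples": gm.n_samples,
        "stage_seconds": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    report["manifest"] = manifest
    return report
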