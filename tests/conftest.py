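"""Shared fixtures: toy genotype matrices and small synthetic bundles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from locadapt.variant_io import GenotypeMatrix


def make_gm(codes: np.ndarray, pops: list[str], chrom: str = "chr1",
            positions: list[int] | None = None,
            aa: list[str] | None = None) -> GenotypeMatrix:
    """Genotype matrix from a codes array and per-sample population labels."""
    codes = np.asarray(codes, dtype=np.int8)
    n_samples, n_sites = codes.shape
    samples = [f"s{i}" for i in range(n_samples)]
    pop_of = dict(zip(samples, pops))
    if positions is None:
        positions = list(range(1, n_sites + 1))
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": positions,
        "ref": ["A"] * n_sites,
        "alt": ["G"] * n_sites,
    })
    if aa is not None:
        sites["aa"] = aa
    return GenotypeMatrix(codes, samples, pop_of, sites)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small written bundle with one sweep, GEA signal and coding genes."""
    from locadapt import synthetic_data as sd

    cfg = sd.SimConfig(
        n_chrom=2, chrom_length=1_000_000,
        sweeps=[sd.SweepSpec("F", "chr1", 500_000, lam=150_000.0)],
        gea=sd.GeaSpec(n_causal=20, beta=0.8),
        coding=sd.CodingSpec(n_genes=20, n_selected=2),
        filter_fail_fraction=0.05,
    )
    outdir = tmp_path_factory.mktemp("bundle")
    bundle = sd.emit_bundle(cfg, seed=11, outdir=outdir, force=True)
    return bundle, outdir


@pytest.fixture(scope="session")
def small_gm(small_bundle):
    """Filtered, classified, outgroup-polarized matrix from the small bundle."""
    from locadapt import variant_io

    _, outdir = small_bundle
    gm, counts = variant_io.load_genotype_matrix(
        outdir / "variants.vcf", outdir / "popmap.tsv", outdir / "genes.gff3",
        outgroup="OUT01")
    return gm, counts
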