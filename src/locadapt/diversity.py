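"""Windowed diversity statistics and site-frequency spectra.

Nucleotide diversity (theta-pi) and absolute divergence (DXY) in
non-overlapping bins, 1D and joint site-frequency spectra with hypergeometric
projection, frequency-class summaries, and a Mann-Whitney U test used for the
between-population contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .variant_io import GenotypeMatrix

WINDOW_COLUMNS = ["chrom", "start", "end", "n_sites", "value"]


@dataclass
class SFS:
    """A (possibly projected) site-frequency spectrum.

    ``entries`` is indexed by derived-allele count per population; fractional
    masses arise from projection and are kept as reals.  ``sample_sizes`` are
    haploid projection sizes, one per population in ``dims``.
    """

    dims: list[str]
    sample_sizes: list[int]
    entries: np.ndarray
    polarized: bool
    n_dropped: int = 0

    def __post_init__(self) -> None:
        expected = tuple(m + 1 for m in self.sample_sizes)
        if self.entries.shape != expected:
            raise ValueError(f"entries shape {self.entries.shape} != {expected}")

    @property
    def total(self) -> float:
        return float(self.entries.sum())

    def marginal(self, pop: str) -> "SFS":
        axis = self.dims.index(pop)
        other = tuple(i for i in range(self.entries.ndim) if i != axis)
        return SFS([pop], [self.sample_sizes[axis]],
                   self.entries.sum(axis=other), self.polarized, self.n_dropped)

    def folded(self) -> "SFS":
        if len(self.dims) != 1:
            raise ValueError("folding implemented for 1D spectra")
        m = self.sample_sizes[0]
        out = np.zeros(m + 1)
        for k in range(m + 1):
            lo = min(k, m - k)
            out[lo] += self.entries[k]
        return SFS(list(self.dims), list(self.sample_sizes), out, polarized=False,
                   n_dropped=self.n_dropped)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# dims=" + ",".join(self.dims)
                     + " projections=" + ",".join(map(str, self.sample_sizes))
                     + f" polarized={int(self.polarized)}\n")
            fh.write(" ".join(f"{v:.10g}" for v in self.entries.ravel()) + "\n")

    @classmethod
    def read(cls, path) -> "SFS":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            vals = np.array(fh.readline().split(), dtype=float)
        meta = dict(kv.split("=", 1) for kv in header)
        dims = meta["dims"].split(",")
        sizes = [int(x) for x in meta["projections"].split(",")]
        entries = vals.reshape(tuple(m + 1 for m in sizes))
        return cls(dims, sizes, entries, bool(int(meta.get("polarized", "1"))))


# ---------------------------------------------------------------------------
# windowed statistics


def _windows_for(chrom_sites: pd.DataFrame, bin_size: int,
                 chrom_length: int | None) -> list[tuple[int, int]]:
    last = int(chrom_sites["pos"].max()) if len(chrom_sites) else 0
    length = chrom_length if chrom_length is not None else last
    out = []
    start = 0
    while start < length:
        out.append((start, min(start + bin_size, length)))
        start += bin_size
    return out


def _windowed(gm: GenotypeMatrix, per_site_vals: np.ndarray, usable: np.ndarray,
              bin_size: int, chrom_lengths: dict[str, int] | None,
              per_snp: bool) -> pd.DataFrame:
    """Aggregate per-site contributions into non-overlapping bins.

    ``per_site_vals`` are summed within a bin; the bin value divides by the
    realized bin span (partial end bins divide by their actual length) unless
    ``per_snp``, which averages over usable variant sites.
    """
    rows = []
    pos0 = gm.sites["pos"].to_numpy() - 1
    for chrom, idx in gm.sites.groupby("chrom", sort=True).groups.items():
        idx = np.asarray(idx)
        clen = chrom_lengths.get(str(chrom)) if chrom_lengths else None
        for start, end in _windows_for(gm.sites.loc[idx], bin_size, clen):
            in_win = idx[(pos0[idx] >= start) & (pos0[idx] < end)]
            use = in_win[usable[in_win]]
            n = len(use)
            total = float(per_site_vals[use].sum())
            if per_snp:
                value = total / n if n else np.nan
            else:
                value = total / (end - start)
            rows.append((chrom, start, end, n, value))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def site_pi(j: np.ndarray, n_h: np.ndarray) -> np.ndarray:
    """Per-site expected heterozygosity 2 j (n-j) / (n (n-1))."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n_h >= 2, 2.0 * j * (n_h - j) / (n_h * (n_h - 1.0)), np.nan)


def pi_windows(gm: GenotypeMatrix, pop: str, bin_size: int = 20_000,
               chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Nucleotide diversity per non-overlapping bin, per-site units.

    Each variant site contributes 2 j (n_h - j) / (n_h (n_h - 1)) with its own
    non-missing haplotype count n_h; the bin sum divides by the bin span.
    """
    j, n_h = gm.alt_counts(pop)
    vals = site_pi(j, n_h)
    usable = n_h >= 2
    vals = np.where(usable, vals, 0.0)
    return _windowed(gm, vals, usable, bin_size, chrom_lengths, per_snp=False)


def dxy_windows(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                bin_size: int = 20_000, mode: str = "per_site",
                chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Absolute divergence DXY per bin.

    Per site d = pA (1 - pB) + pB (1 - pA).  ``per_site`` divides the bin sum
    by the bin span (pixy-style, SNP-only input); ``per_snp`` averages d over
    the variant sites genotyped in both populations.
    """
    if mode not in ("per_site", "per_snp"):
        raise ValueError(f"unknown mode {mode!r}")
    ja, na = gm.alt_counts(pop_a)
    jb, nb = gm.alt_counts(pop_b)
    usable = (na >= 1) & (nb >= 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa, pb = ja / na, jb / nb
    d = np.where(usable, pa * (1 - pb) + pb * (1 - pa), 0.0)
    return _windowed(gm, d, usable, bin_size, chrom_lengths,
                     per_snp=(mode == "per_snp"))


# ---------------------------------------------------------------------------
# site-frequency spectra


def projection_weights(j: int, n_h: int, m: int) -> np.ndarray:
    """Hypergeometric projection of j derived of n_h haplotypes onto m.

    Returns the length-(m+1) vector of contributions to derived-count classes
    0..m; an indicator at j when m == n_h.
    """
    denom = comb(n_h, m)
    w = np.zeros(m + 1)
    for k in range(max(0, m - (n_h - j)), min(j, m) + 1):
        w[k] = comb(j, k) * comb(n_h - j, m - k) / denom
    return w


def _pop_site_counts(gm: GenotypeMatrix, pop: str, polarized: bool,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if polarized:
        j, n_h = gm.derived_counts(pop)
        ok = j >= 0
    else:
        j, n_h = gm.alt_counts(pop)
        ok = np.ones_like(j, dtype=bool)
    return j, n_h, ok


def sfs_1d(gm: GenotypeMatrix, pop: str, polarized: bool = True,
           projection_n: int | None = None) -> SFS:
    """1D SFS by hypergeometric projection to ``projection_n`` haplotypes.

    Sites with fewer non-missing haplotypes than the projection size are
    dropped and counted in ``n_dropped``; unpolarized spectra are folded.
    """
    idx = gm.pop_indices(pop)
    m = projection_n if projection_n is not None else 2 * len(idx)
    j, n_h, ok = _pop_site_counts(gm, pop, polarized)
    entries = np.zeros(m + 1)
    dropped = 0
    for jj, nn, keep in zip(j, n_h, ok):
        if not keep:
            dropped += 1
            continue
        if nn < m:
            dropped += 1
            continue
        entries += projection_weights(int(jj), int(nn), m)
    out = SFS([pop], [m], entries, polarized, dropped)
    return out if polarized else out.folded()


def joint_sfs(gm: GenotypeMatrix, pops: Sequence[str],
              projections: Sequence[int] | None = None) -> SFS:
    """Joint (2D/3D) unfolded SFS, product-of-hypergeometrics projection.

    Monomorphic corner cells (all-ancestral, all-derived) are retained; use
    :func:`mask_corners` to flag them for likelihood work.
    """
    if projections is None:
        projections = [2 * len(gm.pop_indices(p)) for p in pops]
    per_pop = [_pop_site_counts(gm, p, polarized=True) for p in pops]
    shape = tuple(m + 1 for m in projections)
    entries = np.zeros(shape)
    dropped = 0
    n_sites = gm.n_sites
    for s in range(n_sites):
        ws = []
        for (j, n_h, ok), m in zip(per_pop, projections):
            if not ok[s] or n_h[s] < m:
                ws = None
                break
            ws.append(projection_weights(int(j[s]), int(n_h[s]), m))
        if ws is None:
            dropped += 1
            continue
        cell = ws[0]
        for w in ws[1:]:
            cell = np.multiply.outer(cell, w)
        entries += cell
    return SFS(list(pops), list(projections), entries, polarized=True,
               n_dropped=dropped)


def mask_corners(entries: np.ndarray) -> np.ndarray:
    """Boolean mask that is False at the all-zero and all-max corner cells."""
    mask = np.ones_like(entries, dtype=bool)
    mask[(0,) * entries.ndim] = False
    mask[tuple(s - 1 for s in entries.shape)] = False
    return mask


def frequency_classes(sfs: SFS, rare_cutoff: float = 0.05) -> dict[str, float]:
    """Proportions of fixed / rare / intermediate classes of a 1D SFS.

    Proportions are over segregating-or-fixed mass (class 0 excluded): fixed
    is the top class, rare the classes with derived frequency below the
    cutoff (class 0 excluded), intermediate the remainder.
    """
    if len(sfs.dims) != 1:
        raise ValueError("frequency_classes needs a 1D SFS")
    m = sfs.sample_sizes[0]
    e = sfs.entries
    top = m if sfs.polarized else m // 2
    total = e[1:top + 1].sum()
    if total <= 0:
        raise ValueError("empty SFS")
    # in a folded spectrum fixed-derived sites fold into class 0 and cannot
    # be distinguished from monomorphic-ancestral ones
    prop_fixed = e[top] / total if sfs.polarized else 0.0
    rare = sum(e[k] for k in range(1, top + 1) if k / m < rare_cutoff)
    prop_rare = rare / total
    return {"prop_fixed": float(prop_fixed), "prop_rare": float(prop_rare),
            "prop_intermediate": float(1.0 - prop_fixed - prop_rare)}


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 alternative: str = "two-sided") -> dict[str, float]:
    """Mann-Whitney U with tie correction.

    Exact enumeration of the permutation distribution when the pooled sample
    has at most 20 observations (ties included); tie-corrected normal
    approximation with continuity correction otherwise.  ``alternative`` is
    ``two-sided`` or ``less`` (first sample stochastically smaller).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0  # U of sample a

    if np.ptp(pooled) == 0:
        return {"U": float(u1), "p": 1.0}

    if n1 + n2 <= 20:
        stats = []
        for idx in itertools.combinations(range(n1 + n2), n1):
            stats.append(ranks[list(idx)].sum())
        stats = np.asarray(stats) - n1 * (n1 + 1) / 2.0
        if alternative == "less":
            p = np.mean(stats <= u1)
        else:
            mu = n1 * n2 / 2.0
            p = np.mean(np.abs(stats - mu) >= abs(u1 - mu) - 1e-12)
        return {"U": float(u1), "p": float(min(1.0, p))}

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return {"U": float(u1), "p": 1.0}
    sigma = np.sqrt(sigma2)
    if alternative == "less":
        z = (u1 - mu + 0.5) / sigma
        p = norm.cdf(z)
    else:
        z = (abs(u1 - mu) - 0.5) / sigma
        p = 2 * norm.sf(max(z, 0.0))
    return {"U": float(u1), "p": float(min(1.0, p))}
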