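"""Sliding-window selective-sweep scans and highly differentiated regions.

Weir & Cockerham (1984) FST and the cross-population composite likelihood
ratio (XP-CLR; Chen, Patterson & Reich 2010) in sliding windows, z-score
outlier calling, intersection and merging of jointly outlying windows into
highly differentiated regions (HDRs), the unnormalized Fay & Wu's H, and
HDR-versus-genome contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .diversity import mann_whitney
from .variant_io import GeneModels, GenotypeMatrix

SCAN_COLUMNS = ["chrom", "start", "end", "n_snps", "value"]


def sliding_windows(chrom_lengths: dict[str, int], size: int, step: int,
                    ) -> pd.DataFrame:
    """Half-open sliding windows tiling each chromosome (partial ends kept)."""
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + size, length)))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def infer_chrom_lengths(gm: GenotypeMatrix) -> dict[str, int]:
    return {str(c): int(g["pos"].max()) for c, g in gm.sites.groupby("chrom")}


def _window_site_indices(gm: GenotypeMatrix, windows: pd.DataFrame,
                         ) -> list[np.ndarray]:
    pos0 = gm.sites["pos"].to_numpy() - 1
    chroms = gm.sites["chrom"].to_numpy()
    out = []
    for chrom, start, end in windows[["chrom", "start", "end"]].itertuples(index=False):
        mask = (chroms == chrom) & (pos0 >= start) & (pos0 < end)
        out.append(np.flatnonzero(mask))
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham FST


def wc_fst_components(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site W&C (1984) variance components (a, a+b+c) for two populations.

    a is the among-population component; b among-individual-within-population;
    c within-individual (half the heterozygote frequency).  Sites where a
    population has < 2 genotyped diploids, or that are monomorphic overall,
    yield NaN components.
    """
    comps = []
    for pop in (pop_a, pop_b):
        idx = gm.pop_indices(pop)
        if len(idx) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 diploids")
        sub = gm.codes[idx]
        ok = sub >= 0
        n_i = ok.sum(axis=0).astype(float)              # genotyped diploids
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = np.where(ok, sub, 0).sum(axis=0) / (2.0 * n_i)
            h_i = (sub == 1).sum(axis=0) / n_i          # observed het freq
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    tot = a + b + c
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(tot) | (tot == 0)
    a = np.where(bad, np.nan, a)
    tot = np.where(bad, np.nan, tot)
    return a, tot


def wc_fst_windows(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                   size: int = 20_000, step: int = 5_000,
                   chrom_lengths: dict[str, int] | None = None,
                   windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Windowed ratio-of-sums W&C FST: sum(a) / sum(a+b+c) over usable sites."""
    if windows is None:
        windows = sliding_windows(chrom_lengths or infer_chrom_lengths(gm),
                                  size, step)
    a, tot = wc_fst_components(gm, pop_a, pop_b)
    usable = np.isfinite(tot)
    rows = []
    for idx, (chrom, start, end) in zip(
            _window_site_indices(gm, windows),
            windows[["chrom", "start", "end"]].itertuples(index=False)):
        use = idx[usable[idx]]
        if len(use) == 0:
            rows.append((chrom, start, end, 0, np.nan))
        else:
            rows.append((chrom, start, end, len(use),
                         float(a[use].sum() / tot[use].sum())))
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


# ---------------------------------------------------------------------------
# XP-CLR


@dataclass
class XpclrParams:
    """Practical settings of the cross-population composite-likelihood scan.

    ``sel_grid``: selection-strength grid (plus an implicit neutral point);
    ``rrate``: recombination rate per bp (1 cM/Mb default); ``max_snps``:
    per-window cap, downsampled evenly; ``n_quad``: frequency-grid points for
    the numerical integration; ``min_snps``: windows below this are NaN.
    """

    sel_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-5.0, -0.5, 30))
    rrate: float = 1e-8
    max_snps: int = 200
    n_quad: int = 64
    min_snps: int = 2


def drift_variance(p_ref: np.ndarray, p_obj: np.ndarray,
                   trim: float = 0.02) -> float:
    """Genome-wide drift variance omega: mean (p_obj - p_ref)^2 / (p_ref q_ref).

    omega calibrates the NEUTRAL frequency-change density, so the largest
    ``trim`` fraction of per-site terms is excluded before averaging —
    selected regions would otherwise inflate it and mask their own signal.
    """
    ok = (p_ref > 0) & (p_ref < 1)
    if not ok.any():
        raise ValueError("no polymorphic reference sites for drift variance")
    terms = (p_obj[ok] - p_ref[ok]) ** 2 / (p_ref[ok] * (1 - p_ref[ok]))
    if trim > 0 and terms.size > 10:
        cut = np.quantile(terms, 1.0 - trim)
        terms = terms[terms <= cut]
    return float(np.mean(terms))


def _trunc_normal_pdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                      ) -> np.ndarray:
    """Density of N(mu, sigma^2) truncated to [0, 1], zero outside."""
    z = norm.cdf((1.0 - mu) / sigma) - norm.cdf(-mu / sigma)
    pdf = norm.pdf((x - mu) / sigma) / (sigma * z)
    return np.where((x >= 0.0) & (x <= 1.0), pdf, 0.0)


def _binom_pmf(k: np.ndarray, n: np.ndarray, lc: np.ndarray,
               y: np.ndarray) -> np.ndarray:
    """exp(lc + k ln y + (n-k) ln(1-y)) with 0 log 0 = 0 (lc: log C(n, k))."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(y), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log1p(-y), 0.0)
    return np.exp(lc + t1 + t2)


def _site_loglik(k: np.ndarray, n: np.ndarray, p1: np.ndarray, omega: float,
                 c: np.ndarray | None, n_quad: int) -> np.ndarray:
    """Per-site log P(k | n) under the neutral (c None) or sweep model.

    The object-population frequency y follows a truncated normal around the
    reference frequency p1 with variance omega p1 (1 - p1).  Under a sweep
    with escape probability c, y = (1 - c) B + c x with B the indicator that
    the sweeping haplotype carried the allele (probability p1) and x the
    neutral frequency; observed counts are binomial in y, integrated on a
    midpoint grid.
    """
    x = (np.arange(n_quad) + 0.5) / n_quad  # midpoint grid on (0, 1)
    w = 1.0 / n_quad
    mu = p1[:, None]
    kk, nn = k[:, None], n[:, None]
    lc = (gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1))
    sigma = np.sqrt(omega * p1 * (1.0 - p1))[:, None]
    dens = _trunc_normal_pdf(x[None, :], mu, sigma)
    # renormalize on the grid so quadrature error cancels in the CLR
    norm_c = (dens * w).sum(axis=1, keepdims=True)
    dens = np.where(norm_c > 0, dens / np.maximum(norm_c, 1e-300), 0.0)
    if c is None:
        pk = _binom_pmf(kk, nn, lc, x[None, :])
    else:
        # integrate over the pre-sweep frequency x and transform inside the
        # binomial: y = (1 - c) B + c x with B ~ Bernoulli(p1)
        cc = np.clip(c, 0.0, 1.0)[:, None]
        pk = ((1.0 - mu) * _binom_pmf(kk, nn, lc, cc * x[None, :])
              + mu * _binom_pmf(kk, nn, lc, (1.0 - cc) + cc * x[None, :]))
    lik = (pk * dens * w).sum(axis=1)
    return np.log(np.maximum(lik, 1e-300))


def xpclr_windows(gm: GenotypeMatrix, ref_pop: str, obj_pop: str,
                  size: int = 20_000, step: int = 5_000,
                  params: XpclrParams | None = None,
                  chrom_lengths: dict[str, int] | None = None,
                  windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Windowed XP-CLR scan of ``obj_pop`` against ``ref_pop``.

    Returns windows with raw CLR values plus an ``xpclr_norm`` z-score column
    (mean 0, SD 1 over the comparison's finite windows).
    """
    params = params or XpclrParams()
    if windows is None:
        windows = sliding_windows(chrom_lengths or infer_chrom_lengths(gm),
                                  size, step)
    j_r, n_r = gm.alt_counts(ref_pop)
    j_o, n_o = gm.alt_counts(obj_pop)
    ok = (n_r >= 2) & (n_o >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_ref_raw = j_r / n_r
        p_obj_raw = j_o / n_o
    omega = drift_variance(p_ref_raw[ok], p_obj_raw[ok])
    # pseudocount keeps the reference frequency (and drift variance) off 0/1
    p1_all = (j_r + 0.5) / (n_r + 1.0)
    pos0 = gm.sites["pos"].to_numpy() - 1

    rows = []
    for idx, (chrom, start, end) in zip(
            _window_site_indices(gm, windows),
            windows[["chrom", "start", "end"]].itertuples(index=False)):
        use = idx[ok[idx]]
        if len(use) < params.min_snps:
            rows.append((chrom, start, end, len(use), np.nan))
            continue
        if len(use) > params.max_snps:
            sel = np.linspace(0, len(use) - 1, params.max_snps).round().astype(int)
            use = use[np.unique(sel)]
        k = j_o[use]
        n = n_o[use]
        p1 = p1_all[use]
        center = (start + end) / 2.0
        d = np.abs(pos0[use] - center)
        ln_neutral = _site_loglik(k, n, p1, omega, None, params.n_quad).sum()
        best = -np.inf
        for s in params.sel_grid:
            c = 1.0 - np.exp(-params.rrate * d / s)
            ln_s = _site_loglik(k, n, p1, omega, c, params.n_quad).sum()
            best = max(best, ln_s)
        clr = 2.0 * (best - ln_neutral)
        rows.append((chrom, start, end, len(use), float(clr)))
    df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    vals = df["value"].to_numpy()
    finite = np.isfinite(vals)
    if finite.any():
        mu, sd = vals[finite].mean(), vals[finite].std(ddof=0)
        df["xpclr_norm"] = np.where(finite,
                                    (vals - mu) / sd if sd > 0 else 0.0,
                                    np.nan)
    else:
        df["xpclr_norm"] = np.nan
    return df


# ---------------------------------------------------------------------------
# outliers and HDRs


def call_outliers(values: Sequence[float], side: str = "upper",
                  z: float = 1.96) -> np.ndarray:
    """Boolean mask of values at least z SDs from the mean (NaN never flagged).

    Mean and SD are computed over finite values only; a constant vector has
    no outliers.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        return np.zeros(v.shape, dtype=bool)
    mu = v[finite].mean()
    sd = v[finite].std(ddof=0)
    if sd == 0:
        return np.zeros(v.shape, dtype=bool)
    if side == "upper":
        mask = v >= mu + z * sd
    elif side == "two":
        mask = np.abs(v - mu) >= z * sd
    else:
        raise ValueError(f"side must be 'upper' or 'two', got {side!r}")
    return mask & finite


@dataclass
class HDR:
    """A maximal run of windows outlying in both FST and XP-CLR."""

    chrom: str
    start: int
    end: int
    member_windows: list[int]
    pair: str = ""
    snps: list[int] = field(default_factory=list)


def intersect_hdrs(fst_windows: pd.DataFrame, xpclr_windows: pd.DataFrame,
                   z: float = 1.96, pair: str = "",
                   gm: GenotypeMatrix | None = None) -> list[HDR]:
    """Merge windows outlier in BOTH statistics into maximal HDR intervals.

    The two scans must share the window grid.  Overlapping and book-ended
    member windows merge; if a genotype matrix is given, contained SNP column
    indices are attached to each HDR.
    """
    key = ["chrom", "start", "end"]
    if not fst_windows[key].reset_index(drop=True).equals(
            xpclr_windows[key].reset_index(drop=True)):
        raise ValueError("FST and XP-CLR scans are on different window grids")
    fst_out = call_outliers(fst_windows["value"], "upper", z)
    xp_col = "xpclr_norm" if "xpclr_norm" in xpclr_windows else "value"
    xp_out = call_outliers(xpclr_windows[xp_col], "upper", z)
    both = fst_out & xp_out
    hdrs: list[HDR] = []
    cur: HDR | None = None
    for i in np.flatnonzero(both):
        chrom = fst_windows["chrom"].iloc[i]
        start = int(fst_windows["start"].iloc[i])
        end = int(fst_windows["end"].iloc[i])
        if cur is not None and cur.chrom == chrom and start <= cur.end:
            cur.end = max(cur.end, end)
            cur.member_windows.append(int(i))
        else:
            if cur is not None:
                hdrs.append(cur)
            cur = HDR(chrom, start, end, [int(i)], pair)
    if cur is not None:
        hdrs.append(cur)
    if gm is not None:
        pos0 = gm.sites["pos"].to_numpy() - 1
        chroms = gm.sites["chrom"].to_numpy()
        for h in hdrs:
            h.snps = list(np.flatnonzero((chroms == h.chrom) & (pos0 >= h.start)
                                         & (pos0 < h.end)))
    return hdrs


def hdrs_to_bed(hdrs: Sequence[HDR], path) -> None:
    with open(path, "w") as fh:
        for h in hdrs:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.pair}\n")


# ---------------------------------------------------------------------------
# Fay & Wu's H


def fay_wu_h_windows(gm: GenotypeMatrix, pop: str, size: int = 20_000,
                     step: int = 5_000,
                     chrom_lengths: dict[str, int] | None = None,
                     windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H per sliding window.

    Per polarized segregating site with derived count i among n haplotypes,
    theta_pi gains 2 i (n - i) / (n (n - 1)) and theta_H gains
    2 i^2 / (n (n - 1)); n is the site's realized non-missing count.
    Windows without polarized segregating sites are NaN.
    """
    if windows is None:
        windows = sliding_windows(chrom_lengths or infer_chrom_lengths(gm),
                                  size, step)
    i_der, n_h = gm.derived_counts(pop)
    seg = (i_der > 0) & (i_der < n_h) & (n_h >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n_h * (n_h - 1.0)
        pi_c = np.where(seg, 2.0 * i_der * (n_h - i_der) / denom, 0.0)
        th_c = np.where(seg, 2.0 * i_der**2 / denom, 0.0)
    rows = []
    for idx, (chrom, start, end) in zip(
            _window_site_indices(gm, windows),
            windows[["chrom", "start", "end"]].itertuples(index=False)):
        use = idx[seg[idx]]
        if len(use) == 0:
            rows.append((chrom, start, end, 0, np.nan, np.nan, np.nan))
        else:
            tp = float(pi_c[use].sum())
            th = float(th_c[use].sum())
            rows.append((chrom, start, end, len(use), tp, th, tp - th))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                       "theta_pi", "theta_h", "value"])


def hdr_contrast(h_windows: pd.DataFrame, hdrs: Sequence[HDR]) -> dict:
    """One-sided Mann-Whitney test that H is lower inside HDRs than outside."""
    in_mask = np.zeros(len(h_windows), dtype=bool)
    for h in hdrs:
        sel = ((h_windows["chrom"] == h.chrom)
               & (h_windows["start"] < h.end) & (h_windows["end"] > h.start))
        in_mask |= sel.to_numpy()
    vals = h_windows["value"].to_numpy()
    inside = vals[in_mask & np.isfinite(vals)]
    outside = vals[~in_mask & np.isfinite(vals)]
    if inside.size == 0 or outside.size == 0:
        raise ValueError("need finite H values both inside and outside HDRs")
    res = mann_whitney(inside, outside, alternative="less")
    return {"U": res["U"], "p": res["p"],
            "mean_in": float(inside.mean()), "mean_out": float(outside.mean()),
            "sd_in": float(inside.std(ddof=0)),
            "sd_out": float(outside.std(ddof=0)),
            "n_in": int(inside.size), "n_out": int(outside.size)}


def genes_in_regions(regions: Sequence[HDR], gene_models: GeneModels,
                     ) -> list[list[str]]:
    """Gene ids whose bodies overlap each region by >= 1 bp."""
    return [gene_models.genes_overlapping(r.chrom, r.start, r.end)
            for r in regions]
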