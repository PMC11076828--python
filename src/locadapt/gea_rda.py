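"""Genotype-environment association by redundancy analysis (RDA).

Constrained ordination of the 0/1/2 genotype matrix on environmental
predictors, permutation tests for axis significance, SNP-loading outliers,
enrichment and distribution contrasts, and a binomial-scaled genotype PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, ks_2samp

from .mk_test import bh_adjust

logger = logging.getLogger(__name__)


def impute_missing(codes: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace missing codes (-1) by the per-SNP mean of observed codes."""
    g = codes.astype(float)
    missing = g < 0
    n_imputed = int(missing.sum())
    if n_imputed:
        col_mean = np.where(missing, np.nan, g).astype(float)
        means = np.nanmean(col_mean, axis=0)
        means = np.where(np.isfinite(means), means, 0.0)
        g = np.where(missing, means[None, :], g)
    return g, n_imputed


@dataclass
class RDAResult:
    """Constrained-ordination output.

    ``scores``: n_samples x n_axes sample coordinates; ``loadings``:
    n_snps x n_axes SNP scores of the constrained axes; ``eigenvalues``
    non-increasing; ``axis_p`` filled by :func:`rda_axis_test`.
    """

    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    total_variance: float
    r2: float
    r2_adj: float
    rank_env: int
    env_condition_number: float
    n_imputed: int = 0
    axis_p: np.ndarray | None = None
    dropped_env: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def _prepare_env(env: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(env, pd.DataFrame):
        cols = list(env.columns)
        e = env.to_numpy(dtype=float)
    else:
        e = np.asarray(env, dtype=float)
        if e.ndim == 1:
            e = e[:, None]
        cols = [f"env{i}" for i in range(e.shape[1])]
    keep = [i for i in range(e.shape[1]) if np.ptp(e[:, i]) > 0]
    dropped = [cols[i] for i in range(e.shape[1]) if i not in keep]
    if dropped:
        logger.warning("dropping constant environment columns: %s", dropped)
    if not keep:
        raise ValueError("all environment columns are constant")
    return e[:, keep], dropped


def _rda_core(g_centered: np.ndarray, e_centered: np.ndarray,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Least-squares fit of G on E and SVD of the fitted values.

    Returns (sample scores, SNP loadings, eigenvalues, rank of E).  Axis
    eigenvalues are the variances of the fitted values along each axis
    (divisor n - 1, matching the total-variance convention).
    """
    n = g_centered.shape[0]
    beta, _, rank, _ = np.linalg.lstsq(e_centered, g_centered, rcond=None)
    fitted = e_centered @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(rank, n - 1)
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    eig = s**2 / (n - 1)
    keep = eig > max(1e-12, eig[0] * 1e-12) if eig.size else np.array([], bool)
    u, s, vt, eig = u[:, keep], s[keep], vt[keep], eig[keep]
    scores = u * s                      # sample scores (site scores)
    loadings = vt.T                     # SNP scores, unit-norm per axis
    return scores, loadings, eig, rank


def rda_fit(codes: np.ndarray, env: pd.DataFrame | np.ndarray) -> RDAResult:
    """Redundancy analysis of genotype codes on environmental predictors.

    Columns of the genotype matrix are centered; missing codes are imputed
    with the per-SNP mean first.  R^2 is constrained / total variance and
    R^2-adjusted uses the Ezekiel correction with p = rank(E).
    """
    e, dropped = _prepare_env(env)
    n = codes.shape[0]
    if n < 3:
        raise ValueError("RDA needs at least 3 samples")
    if e.shape[0] != n:
        raise ValueError("environment rows must match samples")
    g, n_imputed = impute_missing(codes)
    g = g - g.mean(axis=0)
    e_c = e - e.mean(axis=0)
    sv = np.linalg.svd(e_c, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    scores, loadings, eig, rank = _rda_core(g, e_c)
    total_var = float((g**2).sum() / (n - 1))
    r2 = float(eig.sum() / total_var) if total_var > 0 else 0.0
    p = rank
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    return RDAResult(scores, loadings, eig, total_var, r2, r2_adj, rank, cond,
                     n_imputed, dropped_env=dropped)


def _axis_f(eig: np.ndarray, total_var: float, n: int, rank: int) -> np.ndarray:
    """Marginal pseudo-F per constrained axis.

    F_i = lambda_i / (residual variance / residual df) with the residual
    taken after the full constrained fit.
    """
    resid = max(total_var - eig.sum(), 0.0)
    df_resid = max(n - 1 - rank, 1)
    denom = resid / df_resid
    if denom <= 0:
        return np.full(len(eig), np.inf)
    return eig / denom


def rda_axis_test(codes: np.ndarray, env: pd.DataFrame | np.ndarray,
                  fit: RDAResult, n_perm: int = 999, seed: int = 0) -> np.ndarray:
    """Permutation p per constrained axis (rows of E permuted).

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm) for each axis's
    marginal pseudo-F.  The result is also stored on ``fit.axis_p``.
    """
    if n_perm < 99:
        logger.warning("n_perm = %d is low; p-values are coarse", n_perm)
    e, _ = _prepare_env(env)
    g, _ = impute_missing(codes)
    g = g - g.mean(axis=0)
    n = g.shape[0]
    e_c = e - e.mean(axis=0)
    obs_f = _axis_f(fit.eigenvalues, fit.total_variance, n, fit.rank_env)
    n_axes = len(obs_f)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_axes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, eig_p, rank_p = _rda_core(g, e_c[perm])
        f_p = _axis_f(eig_p, fit.total_variance, n, rank_p)
        for i in range(n_axes):
            fp = f_p[i] if i < len(f_p) else 0.0
            if fp >= obs_f[i]:
                exceed[i] += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    fit.axis_p = p
    return p


def loading_outliers(fit: RDAResult, z: float = 1.96,
                     alpha: float = 0.05,
                     axes: list[int] | None = None) -> np.ndarray:
    """SNP indices whose loading is >= z SD from the mean on a significant axis.

    ``axes`` overrides the default choice of axes with permutation p < alpha
    (all axes if no permutation test was run).  Returns the sorted union over
    the chosen axes.
    """
    if fit.loadings.shape[1] == 0:
        return np.array([], dtype=int)
    if axes is None:
        if fit.axis_p is not None:
            axes = [i for i, p in enumerate(fit.axis_p) if p < alpha]
        else:
            axes = list(range(fit.loadings.shape[1]))
    flagged: set[int] = set()
    for ax in axes:
        v = fit.loadings[:, ax]
        sd = v.std(ddof=0)
        if sd == 0 or len(v) < 2:
            continue
        mask = np.abs(v - v.mean()) >= z * sd
        flagged.update(np.flatnonzero(mask).tolist())
    return np.array(sorted(flagged), dtype=int)


# ---------------------------------------------------------------------------
# contrasts and enrichment


def enrichment_chi2(set_a, set_b, universe, correction: bool = False) -> dict:
    """Pearson chi-squared (1 df) on the 2x2 overlap table of two SNP sets.

    Table margins are membership in a x membership in b over the universe;
    no continuity correction by default.  A zero margin raises.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    n11 = len(a & b)
    n10 = len(a) - n11
    n01 = len(b) - n11
    n00 = len(u) - len(a) - len(b) + n11
    table = np.array([[n11, n10], [n01, n00]])
    if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        raise ValueError("degenerate 2x2 table: a margin is zero")
    chi2_stat, p, _, _ = chi2_contingency(table, correction=correction)
    return {"chi2": float(chi2_stat), "p": float(p), "table": table}


def ks_compare(sample_a, sample_b) -> dict:
    """Two-sample two-sided Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(a, b, alternative="two-sided", method="asymp")
    return {"D": float(res.statistic), "p": float(res.pvalue)}


def pca_genotypes(codes: np.ndarray) -> dict:
    """Genotype PCA with binomial scaling.

    Columns are centered and divided by sqrt(2 p (1 - p)) with p the sample
    allele frequency; zero-variance columns are dropped.  Returns sample
    scores and per-PC variance-explained fractions (summing to 1 over the
    retained PCs).
    """
    if codes.shape[0] < 2 or codes.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 SNPs")
    g, _ = impute_missing(codes)
    p_hat = g.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    keep = (scale > 0) & (g.std(axis=0) > 0)
    x = (g[:, keep] - 2.0 * p_hat[keep]) / scale[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    eig = s**2 / (n - 1)
    nz = eig > eig[0] * 1e-12 if eig.size else np.array([], bool)
    eig, u, s = eig[nz], u[:, nz], s[nz]
    return {"scores": u * s, "eigenvalues": eig,
            "variance_explained": eig / eig.sum()}


def term_enrichment(gene_set, annotation: dict[str, list[str]],
                    universe) -> pd.DataFrame:
    """One-sided Fisher over-representation per term with BH FDR.

    ``annotation`` maps gene -> terms over the universe; terms not annotated
    on any universe gene are skipped silently (there are none by
    construction).  Raises on an empty gene set.
    """
    genes = set(gene_set)
    uni = set(universe)
    if not genes:
        raise ValueError("empty gene set")
    if not genes <= uni:
        raise ValueError("gene set must be a subset of the universe")
    term_genes: dict[str, set] = {}
    for g in uni:
        for t in annotation.get(g, []):
            term_genes.setdefault(t, set()).add(g)
    rows = []
    for term, members in sorted(term_genes.items()):
        k = len(genes & members)
        table = [[k, len(genes) - k],
                 [len(members) - k, len(uni) - len(genes) - len(members) + k]]
        _, p = fisher_exact(table, alternative="greater")
        rows.append((term, k, len(members), p))
    df = pd.DataFrame(rows, columns=["term", "n_in_set", "n_in_universe", "p"])
    df["fdr"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df.sort_values("p", kind="stable").reset_index(drop=True)
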