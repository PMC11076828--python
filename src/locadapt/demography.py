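"""SFS-based demographic inference for the three-population system.

A catalog of 15 demographic scenarios (divergence, bottleneck, expansion,
migration, and a composite), expected joint SFS by structured-coalescent
simulation with branch-length accumulation, multinomial composite likelihood,
ECM-style coordinate fitting with random restarts, AIC / Akaike-weight model
comparison, parametric bootstrap CIs, and unit conversions to years and
migrants-per-generation (Nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Callable, Sequence

import numpy as np

from .coalescent import (DemographicModel, Divergence, Epoch,
                         PopulationHistory, branch_sfs)
from .diversity import SFS, mask_corners

MU_DEFAULT = 7.86e-8          # per site per generation
GEN_TIME_DEFAULT = 20.0       # years

POPS = ("F", "S", "W")        # Fuding, Shenzhen, Wenchang


# ---------------------------------------------------------------------------
# model templates


@dataclass
class ModelTemplate:
    """A parameterized demographic scenario.

    ``bounds`` maps free-parameter names to (low, high); ``scales`` marks each
    parameter ``log`` (sizes, times) or ``linear`` (rates).  ``build`` turns a
    full parameter dict into a concrete :class:`DemographicModel`.
    """

    name: str
    bounds: dict[str, tuple[float, float]]
    scales: dict[str, str]
    build: Callable[[dict[str, float]], DemographicModel]

    @property
    def k(self) -> int:
        return len(self.bounds)

    def midpoint(self) -> dict[str, float]:
        out = {}
        for p, (lo, hi) in self.bounds.items():
            if self.scales[p] == "log":
                out[p] = float(np.sqrt(lo * hi))
            else:
                out[p] = (lo + hi) / 2.0
        return out


_NE_B = (100.0, 200_000.0)
_T_B = (100.0, 50_000.0)
_M_B = (0.0, 5e-3)
_G_B = (-5e-4, 5e-4)

_SIZE_PARAMS = {"N_ANC": _NE_B, "N_F": _NE_B, "N_S": _NE_B, "N_W": _NE_B}


def _backbone(p: dict[str, float], growth: dict[str, float] | None = None,
              bottleneck: tuple[str, float, float, float] | None = None,
              migration: dict[tuple[str, str], float] | None = None,
              name: str = "model") -> DemographicModel:
    """One-step three-way divergence at T_DIV with optional decorations."""
    growth = growth or {}
    pops = []
    for q in POPS:
        epochs = [Epoch(0.0, p[f"N_{q}"], growth.get(q, 0.0))]
        if bottleneck and bottleneck[0] == q:
            _, nb, tb, db = bottleneck
            epochs = [Epoch(0.0, p[f"N_{q}"]),
                      Epoch(tb, nb),
                      Epoch(tb + db, p[f"N_{q}"])]
        pops.append(PopulationHistory(q, epochs))
    pops.append(PopulationHistory("ANC", [Epoch(0.0, p["N_ANC"])]))
    divs = [Divergence(p["T_DIV"], q, "ANC") for q in POPS]
    return DemographicModel(name, pops, divs, dict(migration or {}))


def _two_step(p: dict[str, float], first_pair: tuple[str, str],
              name: str) -> DemographicModel:
    """Two of the populations join at T2 into an internal ancestor, which
    joins the third at T1 > T2."""
    a, b = first_pair
    t2 = p["T2"]
    t1 = t2 + p["DT1"]
    pops = [PopulationHistory(q, [Epoch(0.0, p[f"N_{q}"])]) for q in POPS]
    pops.append(PopulationHistory("AB", [Epoch(0.0, p["N_AB"])]))
    pops.append(PopulationHistory("ANC", [Epoch(0.0, p["N_ANC"])]))
    third = next(q for q in POPS if q not in first_pair)
    divs = [Divergence(t2, a, "AB"), Divergence(t2, b, "AB"),
            Divergence(t1, "AB", "ANC"), Divergence(t1, third, "ANC")]
    return DemographicModel(name, pops, divs)


_PAIRS_ALL = [(s, d) for s in POPS for d in POPS if s != d]


def model_catalog() -> dict[str, ModelTemplate]:
    """The 15-scenario catalog.

    1: one-step three-way divergence; 2-4: two-step divergence orders;
    5-7: one-step + bottleneck-with-recovery in W / S / F; 8-10: one-step +
    exponential size change in W / S / F; 11-13: one-step + asymmetric
    migration within one pair (F-S, F-W, S-W); 14: one-step + full asymmetric
    migration; 15: composite of divergence (1), bottleneck in S (6),
    expansion in F (10) and full migration (14).
    """
    cat: dict[str, ModelTemplate] = {}
    base_bounds = dict(_SIZE_PARAMS, T_DIV=_T_B)
    base_scales = {k: "log" for k in base_bounds}

    cat["model1"] = ModelTemplate(
        "model1", dict(base_bounds), dict(base_scales),
        lambda p: _backbone(p, name="model1"))

    for i, pair in zip((2, 3, 4), (("F", "S"), ("F", "W"), ("S", "W"))):
        b = dict(_SIZE_PARAMS, N_AB=_NE_B, T2=_T_B, DT1=_T_B)
        cat[f"model{i}"] = ModelTemplate(
            f"model{i}", b, {k: "log" for k in b},
            lambda p, pr=pair, nm=f"model{i}": _two_step(p, pr, nm))

    for i, q in zip((5, 6, 7), ("W", "S", "F")):
        b = dict(base_bounds, N_BOT=_NE_B, T_BOT=_T_B, D_BOT=(50.0, 20_000.0))
        cat[f"model{i}"] = ModelTemplate(
            f"model{i}", b, {k: "log" for k in b},
            lambda p, q=q, nm=f"model{i}": _backbone(
                p, bottleneck=(q, p["N_BOT"], p["T_BOT"], p["D_BOT"]), name=nm))

    for i, q in zip((8, 9, 10), ("W", "S", "F")):
        b = dict(base_bounds, G=_G_B)
        s = {k: "log" for k in base_bounds}
        s["G"] = "linear"
        cat[f"model{i}"] = ModelTemplate(
            f"model{i}", b, s,
            lambda p, q=q, nm=f"model{i}": _backbone(p, growth={q: p["G"]}, name=nm))

    mig_pairs = {11: [("F", "S"), ("S", "F")], 12: [("F", "W"), ("W", "F")],
                 13: [("S", "W"), ("W", "S")], 14: _PAIRS_ALL}
    for i, pairs in mig_pairs.items():
        b = dict(base_bounds)
        s = {k: "log" for k in b}
        for src, dst in pairs:
            b[f"M_{src}{dst}"] = _M_B
            s[f"M_{src}{dst}"] = "linear"
        cat[f"model{i}"] = ModelTemplate(
            f"model{i}", b, s,
            lambda p, prs=tuple(pairs), nm=f"model{i}": _backbone(
                p, migration={pr: p[f"M_{pr[0]}{pr[1]}"] for pr in prs}, name=nm))

    b15 = dict(base_bounds, N_BOT=_NE_B, T_BOT=_T_B, D_BOT=(50.0, 20_000.0), G=_G_B)
    s15 = {k: "log" for k in b15}
    s15["G"] = "linear"
    for src, dst in _PAIRS_ALL:
        b15[f"M_{src}{dst}"] = _M_B
        s15[f"M_{src}{dst}"] = "linear"
    cat["model15"] = ModelTemplate(
        "model15", b15, s15,
        lambda p: _backbone(p, growth={"F": p["G"]},
                            bottleneck=("S", p["N_BOT"], p["T_BOT"], p["D_BOT"]),
                            migration={pr: p[f"M_{pr[0]}{pr[1]}"] for pr in _PAIRS_ALL},
                            name="model15"))
    for t in cat.values():
        t.build(t.midpoint()).k = t.k  # smoke-checks every template
    return cat


def figure_model(mu: float = MU_DEFAULT, gen_time: float = GEN_TIME_DEFAULT,
                 ) -> DemographicModel:
    """The fitted composite history used as the generator's default scenario.

    Divergence of F, S, W from an ancestor of Ne 57,833 at 4,654 generations
    (93,080 years at 20 y/gen); exponential growth in F to a present Ne of
    6,142 at 1.05e-4 per generation; a 500-generation bottleneck (Ne/10) in S
    around 2,250 generations ago; constant Ne 778 in W; asymmetric migration
    dominated by F->W and S->W.
    """
    n_s = 17_072.0
    model = DemographicModel(
        "figure", populations=[
            PopulationHistory("F", [Epoch(0.0, 6_142.0, 1.05e-4)]),
            PopulationHistory("S", [Epoch(0.0, n_s), Epoch(2_250.0, n_s / 10.0),
                                    Epoch(2_750.0, n_s)]),
            PopulationHistory("W", [Epoch(0.0, 778.0)]),
            PopulationHistory("ANC", [Epoch(0.0, 57_833.0)]),
        ],
        divergences=[Divergence(4_654.0, q, "ANC") for q in POPS],
        migration={("F", "W"): 6.35e-4, ("S", "W"): 2.62e-4,
                   ("S", "F"): 1.48e-4, ("W", "F"): 6.43e-5},
        mu=mu, gen_time=gen_time, k=15)
    return model


# ---------------------------------------------------------------------------
# expected SFS and composite likelihood


def expected_sfs(model: DemographicModel, sample_sizes: dict[str, int],
                 n_sims: int, seed: int) -> SFS:
    """Expected joint SFS, normalized to probabilities over polymorphic cells.

    Branch lengths (not dropped mutations) are accumulated over ``n_sims``
    single-locus genealogies, so each simulation contributes the full
    conditional expectation of the spectrum given its genealogy.
    """
    rng = np.random.default_rng(seed)
    afs = branch_sfs(model, sample_sizes, n_sims, rng)
    mask = mask_corners(afs)
    total = afs[mask].sum()
    if total <= 0:
        raise ValueError("expected SFS has zero polymorphic mass")
    entries = np.where(mask, afs / total, 0.0)
    return SFS(list(sample_sizes), list(sample_sizes.values()), entries,
               polarized=True)


def composite_loglik(obs: SFS | np.ndarray, expected: SFS | np.ndarray,
                     eps: float = 1e-10) -> float:
    """Multinomial composite log-likelihood sum O_c ln E_c.

    Monomorphic corner cells are excluded; expected cells are floored at
    ``eps`` so empty cells cannot produce -inf.  The multinomial coefficient
    (constant in the parameters) is omitted.
    """
    o = obs.entries if isinstance(obs, SFS) else np.asarray(obs, dtype=float)
    e = expected.entries if isinstance(expected, SFS) else np.asarray(expected,
                                                                      dtype=float)
    if o.shape != e.shape:
        raise ValueError(f"SFS shape mismatch: {o.shape} vs {e.shape}")
    mask = mask_corners(o)
    return float(np.sum(o[mask] * np.log(np.maximum(e[mask], eps))))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ModelFit:
    model: str
    params: dict[str, float]
    lnl: float
    k: int
    aic_override: float | None = None
    delta_aic: float = np.nan
    weight: float = np.nan
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    lnl_trace: list[float] = field(default_factory=list)

    @property
    def aic(self) -> float:
        if self.aic_override is not None:
            return self.aic_override
        return 2.0 * self.k - 2.0 * self.lnl


def _golden_1d(f: Callable[[float], float], lo: float, hi: float,
               scale: str, n_iter: int = 8) -> tuple[float, float]:
    """Golden-section maximization of f on [lo, hi] (log grid for 'log')."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    tx = (lambda x: log(x)) if scale == "log" and lo > 0 else (lambda x: x)
    ix = (lambda y: np.exp(y)) if scale == "log" and lo > 0 else (lambda y: y)
    a, b = tx(lo), tx(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(ix(c)), f(ix(d))
    for _ in range(n_iter):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(ix(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(ix(d))
    x = ix((a + b) / 2.0)
    return x, f(x)


def fit_model(obs_sfs: SFS, template: ModelTemplate,
              bounds: dict[str, tuple[float, float]] | None = None,
              n_sims: int = 2_000, n_starts: int = 10, cycles: int = 20,
              seed: int = 0, fixed: dict[str, float] | None = None,
              line_iters: int = 8) -> ModelFit:
    """Maximize the composite likelihood by cyclic coordinate search.

    Each start draws parameters log-uniformly (or uniformly, for linear-scale
    parameters) within bounds and runs ``cycles`` rounds of golden-section
    line searches, one free parameter at a time.  All likelihood evaluations
    share one simulation seed (common random numbers), so the surface each
    start sees is deterministic and the best run is returned.
    """
    bounds = dict(template.bounds, **(bounds or {}))
    fixed = fixed or {}
    free = [p for p in bounds if p not in fixed]
    sample_sizes = dict(zip(obs_sfs.dims, obs_sfs.sample_sizes))
    master = np.random.default_rng(seed)
    sim_seed = int(master.integers(2**31))

    cache: dict[tuple, float] = {}

    def lnl_at(params: dict[str, float]) -> float:
        key = tuple(round(params[p], 12) for p in sorted(params))
        if key not in cache:
            model = template.build(params)
            try:
                exp_sfs = expected_sfs(model, sample_sizes, n_sims, sim_seed)
                cache[key] = composite_loglik(obs_sfs, exp_sfs)
            except ValueError:
                cache[key] = -np.inf
        return cache[key]

    best: tuple[float, dict[str, float]] | None = None
    trace: list[float] = []
    for _ in range(max(1, n_starts)):
        params = dict(fixed)
        for p in free:
            lo, hi = bounds[p]
            if template.scales[p] == "log" and lo > 0:
                params[p] = float(np.exp(master.uniform(np.log(lo), np.log(hi))))
            else:
                params[p] = float(master.uniform(lo, hi))
        cur = lnl_at(params)
        for _cycle in range(cycles):
            improved = False
            for p in free:
                lo, hi = bounds[p]
                if lo == hi:
                    params[p] = lo
                    continue

                def f1(x: float, p=p) -> float:
                    trial = dict(params)
                    trial[p] = x
                    return lnl_at(trial)

                x, fx = _golden_1d(f1, lo, hi, template.scales[p], line_iters)
                if fx > cur + 1e-9:
                    params[p], cur = x, fx
                    improved = True
            if not improved:
                break
        trace.append(cur)
        if best is None or cur > best[0]:
            best = (cur, dict(params))
    if best is None or not np.isfinite(best[0]):
        raise ValueError("no start produced a finite composite likelihood")
    return ModelFit(template.name, best[1], best[0], template.k,
                    lnl_trace=trace)


def compare_models(fits: Sequence[ModelFit]) -> list[ModelFit]:
    """Rank fits by AIC; attach delta-AIC and Akaike weights (sum to 1)."""
    if not fits:
        raise ValueError("need at least one fit")
    aics = np.array([f.aic for f in fits])
    best = aics.min()
    deltas = aics - best
    w = np.exp(-deltas / 2.0)
    w /= w.sum()
    for f, d, wi in zip(fits, deltas, w):
        f.delta_aic = float(d)
        f.weight = float(wi)
    return sorted(fits, key=lambda f: f.aic)


def parametric_bootstrap(obs_sfs: SFS, template: ModelTemplate,
                         mle_params: dict[str, float], n_boot: int = 100,
                         n_sims: int = 2_000, seed: int = 0,
                         n_starts: int = 2, cycles: int = 5,
                         bounds: dict[str, tuple[float, float]] | None = None,
                         line_iters: int = 8,
                         ) -> tuple[dict[str, tuple[float, float]], int]:
    """Percentile 95% CIs from refits of multinomial resamples of the MLE model.

    Each bootstrap replicate draws the observed number of SNPs from the MLE
    expected SFS and refits; failed refits are excluded and counted.
    Returns (per-parameter (2.5%, 97.5%) CIs, number of failures).
    """
    if n_boot == 0:
        import warnings
        warnings.warn("n_boot = 0: returning empty CIs")
        return {}, 0
    rng = np.random.default_rng(seed)
    sample_sizes = dict(zip(obs_sfs.dims, obs_sfs.sample_sizes))
    model = template.build(mle_params)
    exp_sfs = expected_sfs(model, sample_sizes, n_sims, int(rng.integers(2**31)))
    n_snps = int(round(obs_sfs.total))
    probs = exp_sfs.entries.ravel()
    probs = probs / probs.sum()
    estimates: dict[str, list[float]] = {p: [] for p in mle_params}
    n_failed = 0
    for _ in range(n_boot):
        draw = rng.multinomial(n_snps, probs).reshape(exp_sfs.entries.shape)
        boot_obs = SFS(list(obs_sfs.dims), list(obs_sfs.sample_sizes),
                       draw.astype(float), polarized=True)
        try:
            fit = fit_model(boot_obs, template, bounds=bounds, n_sims=n_sims,
                            n_starts=n_starts, cycles=cycles,
                            seed=int(rng.integers(2**31)), line_iters=line_iters)
        except ValueError:
            n_failed += 1
            continue
        for p, v in fit.params.items():
            if p in estimates:
                estimates[p].append(v)
    cis = {}
    for p, vals in estimates.items():
        if vals:
            cis[p] = (float(np.percentile(vals, 2.5)),
                      float(np.percentile(vals, 97.5)))
    return cis, n_failed


# ---------------------------------------------------------------------------
# unit conversions


def generations_to_years(t_generations: float, gen_time: float) -> float:
    return t_generations * gen_time


def nm_product(ne_source: float, m: float) -> float:
    """Expected migrants per generation: source Ne times forward rate."""
    return ne_source * m


def scale_units(model: DemographicModel, mu: float | None = None,
                gen_time: float | None = None) -> dict:
    """Convert a model's times to years and migration rates to Nm products.

    Nm uses the source population's final-epoch (present-day) Ne.  Raises if
    neither the call nor the model supplies mu / generation time.
    """
    mu = mu if mu is not None else model.mu
    gen_time = gen_time if gen_time is not None else model.gen_time
    if mu is None or gen_time is None:
        raise ValueError("mu and gen_time are required for unit scaling")
    times = {f"T_{d.derived}_{d.ancestral}": generations_to_years(d.time, gen_time)
             for d in model.divergences}
    nm = {}
    for (src, dst), m in model.migration.items():
        ne_src = model.pop(src).epochs[0].size_at(0.0)
        nm[f"Nm_{src}{dst}"] = nm_product(ne_src, m)
    return {"mu": mu, "gen_time": gen_time, "T_years": times, "Nm": nm}
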