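"""Single-locus structured-coalescent engine.

Simulates genealogies backward in time under a multi-population demography
with divergence events, piecewise epochs, exponential size change and
asymmetric migration, and turns them into either branch-length-weighted SFS
expectations (low-variance, for likelihood work) or infinite-sites mutation
data (for the synthetic-data generator).

Conventions
-----------
* Time is measured backward from the present in generations.
* Population sizes are diploid Ne; a pair of lineages in a population of
  size N coalesces at rate 1/(2N).
* Migration rates are declared forward in time as ``m[source -> dest]``, the
  per-generation fraction of the *dest* population replaced by migrants from
  *source*.  Backward in time, a lineage currently in ``dest`` therefore
  jumps to ``source`` at rate ``m[source -> dest]``.
* A population's size going backward within an epoch that started (backward)
  at ``t0`` with size ``N0`` at that time and forward growth rate ``g`` is
  ``N(t) = N0 * exp(-g * (t - t0))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, inf, log
from typing import Sequence

import numpy as np


@dataclass
class Epoch:
    """A backward-time span of a population's size history.

    ``start`` is the backward time the epoch begins, ``size`` the diploid Ne
    at that time, and ``growth`` the forward-time exponential rate (positive
    growth means the population was smaller further in the past).
    """

    start: float
    size: float
    growth: float = 0.0

    def size_at(self, t: float) -> float:
        return self.size * exp(-self.growth * (t - self.start))


@dataclass
class PopulationHistory:
    name: str
    epochs: list[Epoch]  # sorted by start; epochs[0].start == 0 for sampled pops

    def epoch_at(self, t: float) -> Epoch:
        cur = self.epochs[0]
        for e in self.epochs:
            if e.start <= t:
                cur = e
            else:
                break
        return cur


@dataclass
class Divergence:
    """Backward in time at ``time``, lineages of ``derived`` join ``ancestral``."""

    time: float
    derived: str
    ancestral: str


@dataclass
class DemographicModel:
    """A population-epoch / divergence / migration demography.

    ``migration[(src, dst)]`` is the forward-time source-to-dest rate; ``mu``
    the per-site per-generation mutation rate, ``gen_time`` years per
    generation and ``k`` the declared number of free parameters (used by
    AIC-based model comparison).
    """

    name: str
    populations: list[PopulationHistory]
    divergences: list[Divergence] = field(default_factory=list)
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    mu: float = 7.86e-8
    gen_time: float = 20.0
    k: int = 0

    def __post_init__(self) -> None:
        for m in self.migration.values():
            if not 0.0 <= m < 1.0:
                raise ValueError("migration rates must lie in [0, 1)")
        for p in self.populations:
            for e in p.epochs:
                if e.size <= 0:
                    raise ValueError(f"non-positive Ne in {p.name}")
        names = {p.name for p in self.populations}
        for d in self.divergences:
            if d.derived not in names or d.ancestral not in names:
                raise ValueError(f"divergence references unknown population: {d}")
            if d.time <= 0:
                raise ValueError("divergence times must be positive")

    def pop(self, name: str) -> PopulationHistory:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def end_time(self, name: str) -> float:
        """Backward time at which ``name`` merges away (inf for the root)."""
        for d in self.divergences:
            if d.derived == name:
                return d.time
        return inf


def _event_times(model: DemographicModel) -> list[float]:
    ts = {d.time for d in model.divergences}
    for p in model.populations:
        ts.update(e.start for e in p.epochs if e.start > 0)
    return sorted(ts)


def simulate_branches(model: DemographicModel,
                      sample_sizes: dict[str, int],
                      rng: np.random.Generator,
                      ) -> list[tuple[frozenset, float]]:
    """Simulate one genealogy; return (descendant haplotype set, length) per branch.

    ``sample_sizes`` maps population name to the number of sampled haploid
    lineages.  Haplotype indices run 0..n-1 grouped by population in
    ``sample_sizes`` order.  Branches subtending none or all samples are
    dropped (they carry no polymorphism).
    """
    lin_pop: list[str] = []
    lin_desc: list[frozenset] = []
    h = 0
    for p in sample_sizes:
        for _ in range(sample_sizes[p]):
            lin_pop.append(p)
            lin_desc.append(frozenset([h]))
            h += 1
    n_total = h
    acc: dict[frozenset, float] = {}

    boundaries = _event_times(model) + [inf]
    div_at: dict[float, list[Divergence]] = {}
    for d in model.divergences:
        div_at.setdefault(d.time, []).append(d)

    t, b_idx = 0.0, 0
    while len(lin_pop) > 1:
        while b_idx < len(boundaries) - 1 and boundaries[b_idx] <= t:
            b_idx += 1
        seg_end = boundaries[b_idx]

        counts: dict[str, int] = {}
        for p in lin_pop:
            counts[p] = counts.get(p, 0) + 1

        # candidate coalescence per occupied population (time-inhomogeneous:
        # the cumulative hazard under exponential size change is inverted
        # analytically; a draw beyond the segment end is simply discarded)
        best_t, best_kind, best_pop = inf, None, None
        for p, k in counts.items():
            if k < 2:
                continue
            ep = model.pop(p).epoch_at(t)
            pairs = k * (k - 1) / 2.0
            n_t = ep.size_at(t)
            e_draw = rng.exponential()
            if ep.growth == 0.0:
                tau = e_draw * 2.0 * n_t / pairs
            else:
                # N(t+tau) = n_t exp(-g tau) backward, so the hazard is
                # pairs/(2 n_t) e^{g tau}; invert its integral
                arg = 1.0 + e_draw * 2.0 * n_t * ep.growth / pairs
                tau = inf if arg <= 0 else log(arg) / ep.growth
            if t + tau < best_t:
                best_t, best_kind, best_pop = t + tau, "coal", p

        # migration: backward, a lineage in dst jumps to src at m[(src, dst)]
        mig_moves: list[tuple[str, str, float]] = []
        m_tot = 0.0
        for (src, dst), m in model.migration.items():
            if m <= 0 or dst not in counts:
                continue
            if model.end_time(src) <= t or model.end_time(dst) <= t:
                continue
            rate = m * counts[dst]
            mig_moves.append((src, dst, rate))
            m_tot += rate
        if m_tot > 0:
            t_mig = t + rng.exponential() / m_tot
            if t_mig < best_t:
                best_t, best_kind = t_mig, "mig"

        step_end = min(best_t, seg_end)
        dt = step_end - t
        if dt > 0:
            for v in lin_desc:
                acc[v] = acc.get(v, 0.0) + dt
        t = step_end

        if best_t <= seg_end and best_kind is not None:
            if best_kind == "coal":
                idx = [i for i, p in enumerate(lin_pop) if p == best_pop]
                i1, i2 = rng.choice(len(idx), size=2, replace=False)
                a, b = idx[i1], idx[i2]
                merged = lin_desc[a] | lin_desc[b]
                for j in sorted((a, b), reverse=True):
                    lin_pop.pop(j)
                    lin_desc.pop(j)
                lin_pop.append(best_pop)
                lin_desc.append(merged)
            else:
                u = rng.uniform(0.0, m_tot)
                cum = 0.0
                for src, dst, rate in mig_moves:
                    cum += rate
                    if u <= cum:
                        idx = [i for i, p in enumerate(lin_pop) if p == dst]
                        lin_pop[idx[rng.integers(len(idx))]] = src
                        break
        elif seg_end in div_at:
            for d in div_at[seg_end]:
                lin_pop = [d.ancestral if p == d.derived else p for p in lin_pop]
        # plain epoch boundary: rates change, loop redraws

    return [(s, ln) for s, ln in acc.items() if 0 < len(s) < n_total]


def _count_vector(desc: frozenset, offsets: np.ndarray) -> tuple[int, ...]:
    idx = np.fromiter(desc, dtype=int)
    return tuple(int(((idx >= lo) & (idx < hi)).sum())
                 for lo, hi in zip(offsets[:-1], offsets[1:]))


def branch_sfs(model: DemographicModel, sample_sizes: dict[str, int],
               n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """Mean branch-length SFS over ``n_sims`` genealogies.

    Cell ``[i, j, ...]`` holds the mean total branch length subtending i
    derived copies in the first population, j in the second, etc.  Multiplied
    by a per-site mutation rate it gives the expected per-site SFS.
    """
    sizes = list(sample_sizes.values())
    offsets = np.cumsum([0] + sizes)
    afs = np.zeros(tuple(n + 1 for n in sizes))
    for _ in range(n_sims):
        for s, ln in simulate_branches(model, sample_sizes, rng):
            afs[_count_vector(s, offsets)] += ln
    return afs / n_sims


def simulate_haplotype_block(model: DemographicModel,
                             sample_sizes: dict[str, int],
                             n_mutations: int,
                             rng: np.random.Generator,
                             branches: Sequence[tuple[frozenset, float]] | None = None,
                             ) -> np.ndarray:
    """One non-recombining block: (n_haplotypes, n_mutations) 0/1 matrix.

    Haplotype rows are grouped by population in ``sample_sizes`` order; each
    mutation (infinite-sites) is a derived allele carried by the haplotypes
    under the branch it lands on, chosen with probability proportional to
    branch length.
    """
    n_hap = sum(sample_sizes.values())
    if branches is None:
        branches = simulate_branches(model, sample_sizes, rng)
    out = np.zeros((n_hap, n_mutations), dtype=np.int8)
    if not branches or n_mutations == 0:
        return out[:, :0] if n_mutations == 0 else out
    lengths = np.array([ln for _, ln in branches])
    picks = rng.choice(len(branches), size=n_mutations, p=lengths / lengths.sum())
    for col, bi in enumerate(picks):
        out[list(branches[bi][0]), col] = 1
    return out


def total_branch_length(branches: Sequence[tuple[frozenset, float]]) -> float:
    return float(sum(ln for _, ln in branches))
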