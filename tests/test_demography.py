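"""demography: model catalog, expected SFS, composite likelihood, AIC, units."""

import numpy as np
import pytest

from locadapt import demography as dm
from locadapt.coalescent import (DemographicModel, Divergence, Epoch,
                                 PopulationHistory)
from locadapt.demography import (ModelFit, compare_models, composite_loglik,
                                 expected_sfs, fit_model, figure_model,
                                 generations_to_years, model_catalog,
                                 nm_product, parametric_bootstrap, scale_units)
from locadapt.diversity import SFS


def two_pop_split(n_a=2000.0, n_b=500.0, n_anc=1000.0, t=1500.0,
                  m_ab=0.0, m_ba=0.0) -> DemographicModel:
    mig = {}
    if m_ab:
        mig[("A", "B")] = m_ab
    if m_ba:
        mig[("B", "A")] = m_ba
    return DemographicModel(
        "split",
        [PopulationHistory("A", [Epoch(0.0, n_a)]),
         PopulationHistory("B", [Epoch(0.0, n_b)]),
         PopulationHistory("ANC", [Epoch(0.0, n_anc)])],
        [Divergence(t, "A", "ANC"), Divergence(t, "B", "ANC")], mig)


class TestModelCatalog:
    def test_fifteen_models(self):
        cat = model_catalog()
        assert len(cat) == 15
        assert set(cat) == {f"model{i}" for i in range(1, 16)}

    def test_model1_single_shared_divergence_time(self):
        cat = model_catalog()
        m = cat["model1"].build(cat["model1"].midpoint())
        times = {d.time for d in m.divergences}
        assert len(times) == 1 and len(m.divergences) == 3

    def test_composite_has_more_free_parameters(self):
        cat = model_catalog()
        assert cat["model15"].k > cat["model1"].k
        assert cat["model14"].k > cat["model11"].k

    def test_every_template_simulates_at_midpoint(self):
        cat = model_catalog()
        rng = np.random.default_rng(0)
        for tpl in cat.values():
            model = tpl.build(tpl.midpoint())
            sfs = expected_sfs(model, {"F": 4, "S": 4, "W": 4}, 30,
                               seed=int(rng.integers(2**31)))
            assert sfs.total == pytest.approx(1.0, abs=1e-9)

    def test_figure_model_nm_values(self):
        scaled = scale_units(figure_model())
        assert scaled["Nm"]["Nm_FW"] == pytest.approx(3.90, abs=0.005)
        assert scaled["T_years"]["T_F_ANC"] == pytest.approx(93_080)


class TestExpectedSfs:
    def test_constant_population_watterson_shape(self):
        model = DemographicModel(
            "c", [PopulationHistory("A", [Epoch(0.0, 1000.0)])])
        sfs = expected_sfs(model, {"A": 4}, 4000, seed=1)
        e = sfs.entries
        ratios = e[1:4] / e[1]
        se = 3 / np.sqrt(4000)  # generous Monte-Carlo band
        assert ratios[1] == pytest.approx(1 / 2, abs=se)
        assert ratios[2] == pytest.approx(1 / 3, abs=se)

    def test_old_divergence_concentrates_in_corners(self):
        model = two_pop_split(t=200_000.0, n_anc=100.0)
        sfs = expected_sfs(model, {"A": 4, "B": 4}, 500, seed=2)
        corner_mass = sfs.entries[0, 4] + sfs.entries[4, 0]
        assert corner_mass > 0.5

    def test_matches_msprime_branch_sfs_im_model(self):
        msprime = pytest.importorskip("msprime")
        model = two_pop_split(n_a=2000, n_b=800, n_anc=1500, t=2500,
                              m_ab=2e-4, m_ba=1e-4)
        ours = expected_sfs(model, {"A": 4, "B": 4}, 3000, seed=3)

        demog = msprime.Demography()
        demog.add_population(name="A", initial_size=2000)
        demog.add_population(name="B", initial_size=800)
        demog.add_population(name="ANC", initial_size=1500)
        # msprime migration matrix is backward: lineages in A move to B at
        # M[A, B]; our forward m[(src, dst)] moves dst lineages into src
        demog.set_migration_rate(source="B", dest="A", rate=2e-4)
        demog.set_migration_rate(source="A", dest="B", rate=1e-4)
        demog.add_population_split(time=2500, derived=["A", "B"],
                                   ancestral="ANC")
        reps = msprime.sim_ancestry(
            samples={"A": 2, "B": 2}, demography=demog, ploidy=2,
            sequence_length=1, num_replicates=3000, random_seed=7)
        afs = np.zeros((5, 5))
        for ts in reps:
            afs += ts.allele_frequency_spectrum(
                sample_sets=[ts.samples(0), ts.samples(1)], mode="branch",
                polarised=True, span_normalise=False)
        from locadapt.diversity import mask_corners
        mask = mask_corners(afs)
        afs_p = np.where(mask, afs / afs[mask].sum(), 0.0)
        # per-cell agreement within 3 Monte-Carlo SEs (both sides stochastic)
        for idx in zip(*np.nonzero(mask)):
            se = 3 * max(afs_p[idx], ours.entries[idx], 1e-3) / np.sqrt(3000)
            assert abs(afs_p[idx] - ours.entries[idx]) < 3 * se + 0.01

    def test_marginal_consistency(self):
        model = two_pop_split()
        joint = expected_sfs(model, {"A": 4, "B": 4}, 2500, seed=4)
        solo_model = DemographicModel(
            "m", [PopulationHistory("A", [Epoch(0.0, 2000.0)]),
                  PopulationHistory("ANC", [Epoch(0.0, 1000.0)])],
            [Divergence(1500.0, "A", "ANC")])
        solo = expected_sfs(solo_model, {"A": 4}, 2500, seed=5)
        marg = joint.entries.sum(axis=1)[1:4]
        marg = marg / marg.sum()
        ref = solo.entries[1:4] / solo.entries[1:4].sum()
        assert np.allclose(marg, ref, atol=0.05)


class TestCompositeLoglik:
    def test_direct_evaluation(self):
        obs = np.array([0.0, 5.0, 5.0, 0.0])
        exp = np.array([0.0, 0.5, 0.5, 0.0])
        assert composite_loglik(obs, exp) == pytest.approx(10 * np.log(0.5))

    def test_truth_maximizes_against_perturbations(self):
        rng = np.random.default_rng(6)
        exp = np.zeros(12)
        exp[1:-1] = rng.uniform(0.1, 1.0, 10)
        exp[1:-1] /= exp[1:-1].sum()
        obs = exp * 1000
        base = composite_loglik(obs, exp)
        for _ in range(25):
            delta = rng.normal(0, 0.02, 10)
            pert = np.clip(exp[1:-1] + delta, 1e-6, None)
            pert = pert / pert.sum()
            full = np.zeros(12)
            full[1:-1] = pert
            assert composite_loglik(obs, full) <= base + 1e-9

    def test_empty_observed_cell_is_noop(self):
        obs = np.array([0.0, 3.0, 0.0, 0.0])
        exp = np.array([0.0, 0.9, 0.1, 0.0])
        exp2 = np.array([0.0, 0.9, 0.0, 0.0])  # empty expected where obs empty
        assert composite_loglik(obs, exp) == pytest.approx(3 * np.log(0.9))
        assert composite_loglik(obs, exp2) == pytest.approx(3 * np.log(0.9))

    def test_scaling_observed_scales_lnl(self):
        rng = np.random.default_rng(7)
        exp = np.zeros(8)
        exp[1:-1] = rng.dirichlet(np.ones(6))
        obs = np.zeros(8)
        obs[1:-1] = rng.uniform(1, 10, 6)
        assert composite_loglik(obs * 3, exp) == pytest.approx(
            3 * composite_loglik(obs, exp))

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            composite_loglik(np.zeros(4), np.zeros(5))


class TestCompareModels:
    def test_printed_aic_pair_delta(self):
        fits = [ModelFit("model15", {}, np.nan, 0, aic_override=2178865.27),
                ModelFit("model10", {}, np.nan, 0, aic_override=2182730.53)]
        ranked = compare_models(fits)
        assert ranked[0].model == "model15"
        assert ranked[1].delta_aic == pytest.approx(3865.26, abs=1e-9)

    def test_single_model_weight_one(self):
        fits = compare_models([ModelFit("m", {}, -10.0, 2)])
        assert fits[0].weight == 1.0
        assert fits[0].aic == pytest.approx(2 * 2 + 20.0)

    def test_closed_form_weights(self):
        fits = [ModelFit("a", {}, np.nan, 0, aic_override=100.0),
                ModelFit("b", {}, np.nan, 0, aic_override=102.0)]
        ranked = compare_models(fits)
        w0 = 1 / (1 + np.exp(-1))
        assert ranked[0].weight == pytest.approx(w0, abs=1e-9)
        assert ranked[1].weight == pytest.approx(1 - w0, abs=1e-9)
        assert sum(f.weight for f in ranked) == pytest.approx(1.0, abs=1e-12)


def one_param_template():
    """Single population, single free size parameter."""
    return dm.ModelTemplate(
        "one", {"N": (100.0, 50_000.0)}, {"N": "log"},
        lambda p: DemographicModel(
            "one", [PopulationHistory("A", [Epoch(0.0, p["N"])])]))


class TestFitModel:
    def test_collapsed_bounds_return_the_point(self):
        obs = SFS(["A"], [6], np.array([0, 5, 3, 2, 1, 1, 0.0]), True)
        fit = fit_model(obs, one_param_template(),
                        bounds={"N": (1234.0, 1234.0)}, n_sims=50,
                        n_starts=1, cycles=1, seed=0)
        assert fit.params["N"] == 1234.0
        assert np.isfinite(fit.lnl)

    def test_single_population_shape_is_size_free(self):
        # a constant population's normalized SFS is independent of N: fits
        # pinned at very different sizes reach the same composite likelihood
        model = one_param_template().build({"N": 5000.0})
        exp = expected_sfs(model, {"A": 6}, 3000, seed=8)
        obs = SFS(["A"], [6], exp.entries * 10_000, True)
        lo = fit_model(obs, one_param_template(), n_sims=500, n_starts=1,
                       cycles=1, seed=1, bounds={"N": (800.0, 800.0)})
        hi = fit_model(obs, one_param_template(), n_sims=500, n_starts=1,
                       cycles=1, seed=1, bounds={"N": (20_000.0, 20_000.0)})
        assert lo.lnl == pytest.approx(hi.lnl, rel=2e-3)

    def test_divergence_time_recovery_within_ten_percent(self):
        # one free parameter with real shape information: the split time
        def build(p):
            return two_pop_split(t=p["T"])

        tpl = dm.ModelTemplate("t", {"T": (200.0, 20_000.0)}, {"T": "log"},
                               build)
        truth = 1500.0
        exp = expected_sfs(build({"T": truth}), {"A": 6, "B": 6}, 8000, seed=9)
        obs = SFS(["A", "B"], [6, 6], exp.entries * 50_000, True)
        fit = fit_model(obs, tpl, n_sims=2000, n_starts=2, cycles=3, seed=2)
        assert fit.params["T"] == pytest.approx(truth, rel=0.10)

    def test_more_starts_never_worse(self):
        obs = SFS(["A"], [6], np.array([0, 50, 30, 20, 10, 5, 0.0]), True)
        f1 = fit_model(obs, one_param_template(), n_sims=100, n_starts=1,
                       cycles=1, seed=3)
        f3 = fit_model(obs, one_param_template(), n_sims=100, n_starts=3,
                       cycles=1, seed=3)
        assert f3.lnl >= f1.lnl - 1e-9


class TestParametricBootstrap:
    def test_seeded_rerun_is_identical(self):
        tpl = one_param_template()
        obs = SFS(["A"], [6], np.array([0, 50, 30, 20, 10, 5, 0.0]), True)
        kw = dict(n_boot=3, n_sims=80, seed=42, n_starts=1, cycles=1)
        ci1, f1 = parametric_bootstrap(obs, tpl, {"N": 2000.0}, **kw)
        ci2, f2 = parametric_bootstrap(obs, tpl, {"N": 2000.0}, **kw)
        assert ci1 == ci2 and f1 == f2

    def test_zero_boot_warns_and_returns_empty(self):
        tpl = one_param_template()
        obs = SFS(["A"], [6], np.array([0, 5, 3, 2, 1, 1, 0.0]), True)
        with pytest.warns(UserWarning):
            cis, failed = parametric_bootstrap(obs, tpl, {"N": 1000.0},
                                               n_boot=0)
        assert cis == {} and failed == 0


class TestScaleUnits:
    def test_nm_from_printed_rates(self):
        assert nm_product(6_142, 6.35e-4) == pytest.approx(3.90, abs=0.005)

    def test_identity_generation_time(self):
        assert generations_to_years(4654, 1.0) == 4654

    def test_divergence_time_in_years(self):
        assert generations_to_years(4_654, 20.0) == pytest.approx(93_080)

    def test_missing_rates_error(self):
        model = two_pop_split()
        model.mu = None
        model.gen_time = None
        with pytest.raises(ValueError):
            scale_units(model)
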