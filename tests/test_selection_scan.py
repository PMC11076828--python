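"""selection_scan: W&C FST, XP-CLR, outliers, HDR merging, Fay & Wu's H."""

import numpy as np
import pandas as pd
import pytest

from locadapt import selection_scan as ss
from locadapt.coalescent import DemographicModel, Epoch, PopulationHistory
from locadapt.selection_scan import (HDR, XpclrParams, call_outliers,
                                     fay_wu_h_windows, hdr_contrast,
                                     intersect_hdrs, sliding_windows,
                                     wc_fst_windows, xpclr_windows)
from locadapt.variant_io import GeneModels, Gene

from conftest import make_gm


def wc_fst_loop_oracle(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Literal per-site transcription of Weir & Cockerham (1984), looped."""
    num = den = 0.0
    r = 2
    for j in range(codes_a.shape[1]):
        col_a = codes_a[:, j][codes_a[:, j] >= 0]
        col_b = codes_b[:, j][codes_b[:, j] >= 0]
        if len(col_a) < 2 or len(col_b) < 2:
            continue
        stats = []
        for col in (col_a, col_b):
            n_i = len(col)
            p_i = col.sum() / (2 * n_i)
            h_i = (col == 1).sum() / n_i
            stats.append((n_i, p_i, h_i))
        nbar = sum(s[0] for s in stats) / r
        nc = (r * nbar - sum(s[0] ** 2 for s in stats) / (r * nbar)) / (r - 1)
        pbar = sum(s[0] * s[1] for s in stats) / (r * nbar)
        s2 = sum(s[0] * (s[1] - pbar) ** 2 for s in stats) / ((r - 1) * nbar)
        hbar = sum(s[0] * s[2] for s in stats) / (r * nbar)
        if nbar <= 1 or nc <= 0:
            continue
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        if a + b + c != 0 and np.isfinite(a + b + c):
            num += a
            den += a + b + c
    return num / den if den else np.nan


class TestWcFst:
    def test_fixed_difference_is_one(self):
        codes = np.array([[0] * 5, [0] * 5, [2] * 5, [2] * 5])
        gm = make_gm(codes, ["A", "A", "B", "B"])
        df = wc_fst_windows(gm, "A", "B", size=100, step=100,
                            chrom_lengths={"chr1": 100})
        assert df["value"].iloc[0] == pytest.approx(1.0)

    def test_identical_populations_non_positive(self):
        rng = np.random.default_rng(0)
        half = rng.integers(0, 3, size=(4, 20))
        codes = np.vstack([half, half])
        gm = make_gm(codes, ["A"] * 4 + ["B"] * 4)
        df = wc_fst_windows(gm, "A", "B", size=100, step=100,
                            chrom_lengths={"chr1": 100})
        assert df["value"].iloc[0] <= 0.0

    def test_matches_loop_oracle(self):
        # Hardy-Weinberg configurations around freqs 0.2 vs 0.8, plus noise
        rng = np.random.default_rng(1)
        codes_a = rng.choice([0, 1, 2], size=(10, 10), p=[0.64, 0.32, 0.04])
        codes_b = rng.choice([0, 1, 2], size=(10, 10), p=[0.04, 0.32, 0.64])
        gm = make_gm(np.vstack([codes_a, codes_b]),
                     ["A"] * 10 + ["B"] * 10)
        df = wc_fst_windows(gm, "A", "B", size=100, step=100,
                            chrom_lengths={"chr1": 100})
        oracle = wc_fst_loop_oracle(codes_a, codes_b)
        assert df["value"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_missing_data_matches_oracle(self):
        rng = np.random.default_rng(2)
        codes = rng.choice([-1, 0, 1, 2], size=(12, 30), p=[0.1, 0.4, 0.3, 0.2])
        gm = make_gm(codes, ["A"] * 6 + ["B"] * 6)
        df = wc_fst_windows(gm, "A", "B", size=100, step=100,
                            chrom_lengths={"chr1": 100})
        oracle = wc_fst_loop_oracle(codes[:6], codes[6:])
        assert df["value"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_small_population_errors(self):
        gm = make_gm(np.zeros((3, 4)), ["A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            wc_fst_windows(gm, "A", "B", size=10, step=10)


class TestXpclr:
    def test_no_frequency_change_gives_near_zero_clr(self):
        rng = np.random.default_rng(3)
        half = rng.integers(0, 3, size=(8, 40))
        codes = np.vstack([half, half])  # obj == ref at every site
        gm = make_gm(codes, ["A"] * 8 + ["B"] * 8,
                     positions=sorted(rng.choice(range(1, 5000), 40,
                                                 replace=False).tolist()))
        df = xpclr_windows(gm, "A", "B", size=5000, step=5000,
                           chrom_lengths={"chr1": 5000})
        # with omega ~ 0 the sweep model cannot improve on neutral by much
        assert abs(df["value"].iloc[0]) < 0.5

    def test_grid_maximization_matches_fine_brute_force(self):
        rng = np.random.default_rng(4)
        codes_ref = rng.choice([0, 1, 2], size=(8, 3))
        codes_obj = rng.choice([0, 1, 2], size=(8, 3))
        gm = make_gm(np.vstack([codes_ref, codes_obj]),
                     ["R"] * 8 + ["O"] * 8, positions=[100, 1500, 2900])
        params = XpclrParams(n_quad=64)
        df = xpclr_windows(gm, "R", "O", size=3000, step=3000, params=params,
                           chrom_lengths={"chr1": 3000})
        clr = df["value"].iloc[0]

        # brute force: same site likelihood code over a 10x finer grid
        j_r, n_r = gm.alt_counts("R")
        j_o, n_o = gm.alt_counts("O")
        p_ref = j_r / n_r
        p_obj = j_o / n_o
        omega = ss.drift_variance(p_ref, p_obj)
        p1 = (j_r + 0.5) / (n_r + 1.0)
        d = np.abs(np.array([100, 1500, 2900]) - 1 - 1500.0)
        neutral = ss._site_loglik(j_o, n_o, p1, omega, None, 64).sum()
        fine = np.logspace(-5, -0.5, 300)
        best = max(ss._site_loglik(j_o, n_o, p1, omega,
                                   1 - np.exp(-1e-8 * d / s), 64).sum()
                   for s in fine)
        brute = 2 * (best - neutral)
        assert clr == pytest.approx(brute, abs=0.05 * max(1.0, abs(brute)))
        assert clr <= brute + 1e-8  # finer grid can only do better

    def test_norm_column_is_zscore(self):
        rng = np.random.default_rng(5)
        codes = rng.choice([0, 1, 2], size=(16, 300))
        gm = make_gm(codes, ["R"] * 8 + ["O"] * 8,
                     positions=sorted(rng.choice(range(1, 30_000), 300,
                                                 replace=False).tolist()))
        df = xpclr_windows(gm, "R", "O", size=2000, step=1000,
                           chrom_lengths={"chr1": 30_000})
        v = df["xpclr_norm"].dropna()
        assert v.mean() == pytest.approx(0.0, abs=1e-9)
        assert v.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_sparse_window_is_nan(self):
        gm = make_gm(np.array([[0, 1]] * 8), ["R"] * 4 + ["O"] * 4,
                     positions=[10, 5010])
        df = xpclr_windows(gm, "R", "O", size=1000, step=1000,
                           chrom_lengths={"chr1": 6000})
        assert np.isnan(df["value"].iloc[0])  # 1 SNP < min_snps


class TestOutliers:
    def test_single_extreme_value_flagged(self):
        v = np.zeros(1000)
        v[17] = 100.0
        mask = call_outliers(v, "upper", 1.96)
        assert mask.sum() == 1 and mask[17]

    def test_constant_vector_no_outliers(self):
        assert call_outliers(np.ones(50), "upper").sum() == 0

    def test_nan_never_outlier(self):
        v = np.array([0.0, 0.0, 0.0, np.nan, 50.0])
        mask = call_outliers(v, "upper", 1.0)
        assert not mask[3] and mask[4]

    def test_upper_tail_fraction_near_nominal(self):
        rng = np.random.default_rng(6)
        v = rng.standard_normal(100_000)
        frac = call_outliers(v, "upper", 1.96).mean()
        assert 0.022 <= frac <= 0.028

    def test_two_tail_fraction_near_nominal(self):
        rng = np.random.default_rng(7)
        v = rng.standard_normal(100_000)
        frac = call_outliers(v, "two", 1.96).mean()
        assert 0.045 <= frac <= 0.055


def _grid(values_fst, values_xp, size=20, step=10, chrom="chr1"):
    n = len(values_fst)
    rows = [(chrom, i * step, i * step + size) for i in range(n)]
    base = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    fst = base.assign(n_snps=5, value=values_fst)
    xp = base.assign(n_snps=5, value=values_xp, xpclr_norm=values_xp)
    return fst, xp


class TestIntersectHdrs:
    def test_disjoint_outlier_sets_give_no_hdr(self):
        fst = np.zeros(100)
        xp = np.zeros(100)
        fst[10] = 100.0
        xp[50] = 100.0
        f, x = _grid(fst, xp)
        assert intersect_hdrs(f, x, z=1.96) == []

    def test_single_joint_outlier_window(self):
        fst = np.zeros(100)
        xp = np.zeros(100)
        fst[10] = xp[10] = 100.0
        f, x = _grid(fst, xp)
        hdrs = intersect_hdrs(f, x, z=1.96)
        assert len(hdrs) == 1
        assert (hdrs[0].start, hdrs[0].end) == (100, 120)

    def test_three_overlapping_windows_merge(self):
        fst = np.zeros(100)
        xp = np.zeros(100)
        for i in (10, 11, 12):
            fst[i] = xp[i] = 100.0
        f, x = _grid(fst, xp, size=20, step=10)
        hdrs = intersect_hdrs(f, x, z=1.96)
        assert len(hdrs) == 1
        h = hdrs[0]
        assert h.end - h.start == 20 + 2 * 10
        assert h.member_windows == [10, 11, 12]

    def test_book_ended_windows_merge(self):
        fst = np.zeros(100)
        xp = np.zeros(100)
        for i in (10, 12):  # [100,120) and [120,140): share a boundary
            fst[i] = xp[i] = 100.0
        f, x = _grid(fst, xp, size=20, step=10)
        assert len(intersect_hdrs(f, x, z=1.96)) == 1

    def test_mismatched_grids_error(self):
        f, x = _grid(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError, match="different window grids"):
            intersect_hdrs(f, x.iloc[1:].reset_index(drop=True), z=1.96)


class TestFayWuH:
    def test_high_frequency_derived_site(self):
        # n = 4 haplotypes, derived count i = 3
        gm = make_gm([[2], [1]], ["A", "A"], aa=["A"])
        df = fay_wu_h_windows(gm, "A", size=10, step=10,
                              chrom_lengths={"chr1": 10})
        assert df["theta_pi"].iloc[0] == pytest.approx(0.5)
        assert df["theta_h"].iloc[0] == pytest.approx(1.5)
        assert df["value"].iloc[0] == pytest.approx(-1.0)

    def test_singleton_site(self):
        gm = make_gm([[1], [0]], ["A", "A"], aa=["A"])
        df = fay_wu_h_windows(gm, "A", size=10, step=10,
                              chrom_lengths={"chr1": 10})
        assert df["value"].iloc[0] == pytest.approx(1 / 3)

    def test_polarization_flips_with_ancestral_allele(self):
        # same genotypes, ancestral = alt: derived count i = n - j
        gm = make_gm([[1], [0]], ["A", "A"], aa=["G"])
        df = fay_wu_h_windows(gm, "A", size=10, step=10,
                              chrom_lengths={"chr1": 10})
        assert df["value"].iloc[0] == pytest.approx(-1.0)  # i = 3 of 4

    def test_neutral_simulation_mean_near_zero(self):
        from locadapt.coalescent import simulate_haplotype_block

        model = DemographicModel(
            "c", [PopulationHistory("A", [Epoch(0.0, 1000.0)])])
        rng = np.random.default_rng(8)
        h_vals = []
        for _ in range(120):
            haps = simulate_haplotype_block(model, {"A": 10}, 12, rng)
            codes = haps[0::2] + haps[1::2]
            gm = make_gm(codes, ["A"] * 5,
                         positions=list(range(1, 13)), aa=["A"] * 12)
            df = fay_wu_h_windows(gm, "A", size=100, step=100,
                                  chrom_lengths={"chr1": 100})
            h_vals.append(df["value"].iloc[0])
        h_vals = np.array(h_vals)
        se = h_vals.std(ddof=1) / np.sqrt(len(h_vals))
        assert abs(h_vals.mean()) < 3 * se + 1e-12


class TestHdrContrast:
    def test_complete_separation(self):
        rows = [("chr1", i * 10, i * 10 + 10, 1, -3.0 if i < 30 else 0.0)
                for i in range(100)]
        h = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                        "value"])
        hdrs = [HDR("chr1", 0, 300, [0], "A-B")]
        out = hdr_contrast(h, hdrs)
        assert out["p"] < 0.001
        assert out["mean_in"] < out["mean_out"]

    def test_identical_distributions_p_near_half(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=200)
        rows = [("chr1", i * 10, i * 10 + 10, 1, vals[i]) for i in range(200)]
        h = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                        "value"])
        hdrs = [HDR("chr1", 0, 1000, [0], "A-B")]
        out = hdr_contrast(h, hdrs)
        assert 0.05 < out["p"] < 0.95


class TestGenesInRegions:
    def test_hand_enumeration_on_toy_models(self):
        genes = [Gene(f"g{i}", "chr1", s, e, "+")
                 for i, (s, e) in enumerate(
                     [(0, 100), (150, 250), (300, 400), (500, 600),
                      (900, 1000)])]
        gmodels = GeneModels(genes)
        hdrs = [HDR("chr1", 90, 320, [0], "A-B"),   # overlaps g0, g1, g2
                HDR("chr1", 600, 650, [1], "A-B")]  # abuts g3: no overlap
        out = ss.genes_in_regions(hdrs, gmodels)
        assert out[0] == ["g0", "g1", "g2"]
        assert out[1] == []
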