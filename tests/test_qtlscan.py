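"""Scan engine checks: forward-backward probabilities against closed
forms, Haley-Knott LOD against an independent two-fit OLS oracle,
permutation thresholds, Bayes intervals, two-locus models, refinement
and the sex-interaction ANOVA."""

import numpy as np
import pandas as pd
import pytest

from bxlink import qtlscan, simdata
from bxlink.genotypes import HET, HOM, MISSING
from bxlink.simdata import QTLEffect, haldane
from bxlink.tumorstats import mean_center_by_sex
from conftest import toy_genotypes


def ols_lod_oracle(y, X_alt_cols, X_null_cols=None):
    """Independent two-fit OLS LOD: (n/2) log10(RSS0/RSS1)."""
    n = len(y)
    X0 = np.column_stack([np.ones(n)] + (X_null_cols or []))
    X1 = np.column_stack([X0] + X_alt_cols)

    def rss(X):
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ b
        return float(r @ r)

    return (n / 2) * np.log10(rss(X0) / rss(X1))


class TestGenoprob:
    def test_typed_marker_zero_error_probability_is_the_call(self):
        gm = toy_genotypes([[0, 1], [1, 0]], [("m1", 0.0), ("m2", 20.0)])
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        np.testing.assert_allclose(probs.chroms["1"].p_het,
                                   [[0, 1], [1, 0]], atol=1e-12)

    def test_midpoint_between_hom_flanks_closed_form(self):
        gm = toy_genotypes([[0, 0]], [("m1", 0.0), ("m2", 20.0)])
        probs = qtlscan.calc_genoprob(gm, step_cm=10.0, error_rate=0.0)
        r = haldane(10.0)
        expected = r * r / ((1 - r) ** 2 + r * r)
        mid = probs.chroms["1"].p_het[0, 1]
        assert mid == pytest.approx(expected, abs=1e-12)
        assert mid == pytest.approx(0.0098, abs=1e-4)

    def test_brute_force_enumeration_of_hidden_states(self):
        # three positions, observe ends; enumerate 2^3 paths directly
        d12, d23 = 10.0, 10.0
        r1, r2 = haldane(d12), haldane(d23)
        obs = (HOM, HET)   # at positions 0 and 2
        num = den = 0.0
        for s0 in (0, 1):
            for s1 in (0, 1):
                for s2 in (0, 1):
                    p = 0.5
                    p *= (1 - r1) if s0 == s1 else r1
                    p *= (1 - r2) if s1 == s2 else r2
                    if s0 == obs[0] and s2 == obs[1]:
                        den += p
                        if s1 == 1:
                            num += p
        gm = toy_genotypes([[obs[0], obs[1]]], [("m1", 0.0), ("m2", 20.0)])
        probs = qtlscan.calc_genoprob(gm, step_cm=10.0, error_rate=0.0)
        assert probs.chroms["1"].p_het[0, 1] == pytest.approx(num / den,
                                                              abs=1e-12)

    def test_all_missing_gives_prior_half(self):
        gm = toy_genotypes([[MISSING, MISSING]],
                           [("m1", 0.0), ("m2", 20.0)])
        probs = qtlscan.calc_genoprob(gm, step_cm=5.0, error_rate=0.0)
        np.testing.assert_allclose(probs.chroms["1"].p_het[0], 0.5,
                                   atol=1e-12)

    def test_probabilities_are_valid(self, small_cohort):
        gm, _ = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=2.0, error_rate=1e-4)
        for cp in probs.chroms.values():
            assert np.all((cp.p_het >= 0) & (cp.p_het <= 1))

    def test_invalid_error_rate_rejected(self, small_cohort):
        gm, _ = small_cohort
        with pytest.raises(ValueError):
            qtlscan.calc_genoprob(gm, error_rate=0.7)


class TestScanone:
    def test_hand_worked_eight_individual_toy(self):
        gm = toy_genotypes([[0]] * 4 + [[1]] * 4, [("m1", 0.0)])
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        y = np.arange(1.0, 9.0)
        scan = qtlscan.scanone_hk(probs, y)
        # RSS0 = 42, RSS1 = 10 -> LOD = 4 log10(4.2)
        assert scan.df["lod"].iloc[0] == pytest.approx(4 * np.log10(4.2),
                                                       abs=1e-8)

    def test_constant_genotype_gives_zero_lod(self):
        gm = toy_genotypes([[1]] * 8, [("m1", 0.0)])
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        scan = qtlscan.scanone_hk(probs, np.arange(8.0))
        assert scan.df["lod"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_equals_marker_regression_oracle_at_typed_markers(
            self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        scan = qtlscan.scanone_hk(probs, y, chroms=["4", "9"])
        for chrom in ("4", "9"):
            sub = scan.df[scan.df["chrom"] == chrom].reset_index(drop=True)
            mask = (gm.map.df["chrom"] == chrom).to_numpy()
            G = gm.geno[:, mask].astype(float)
            for j in range(G.shape[1]):
                expected = ols_lod_oracle(y, [G[:, j]])
                assert sub["lod"].iloc[j] == pytest.approx(expected,
                                                           abs=1e-8)

    def test_interactive_covariate_matches_full_ols_oracle(
            self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        male = (gm.sex == "M").astype(float)
        scan = qtlscan.scanone_hk(probs, y, intcovar=male, chroms=["4"])
        g = gm.genotype_at("c4m07").astype(float)
        expected = ols_lod_oracle(y, [g, g * male], [male])
        row = scan.df[scan.df["name"] == "c4m07"]
        assert row["lod"].iloc[0] == pytest.approx(expected, abs=1e-8)

    def test_x_chromosome_fits_sex_specific_classes(self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        scan = qtlscan.scanone_hk(probs, y, chroms=["X"])
        male = (gm.sex == "M").astype(float)
        g = gm.genotype_at("cXm05").astype(float)
        expected = ols_lod_oracle(y, [g * (1 - male), g * male], [male])
        row = scan.df[scan.df["name"] == "cXm05"]
        assert row["lod"].iloc[0] == pytest.approx(expected, abs=1e-8)

    def test_adding_true_genotype_to_null_kills_the_peak(self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        g = gm.genotype_at("c4m07").astype(float)
        naive = qtlscan.scanone_hk(probs, y, chroms=["4"])
        adjusted = qtlscan.scanone_hk(probs, y, addcovar=g, chroms=["4"])
        row = adjusted.df[adjusted.df["name"] == "c4m07"]
        assert naive.max_lod() > 3.0
        assert row["lod"].iloc[0] < 0.1

    def test_extended_mode_matches_standard_at_typed_markers(
            self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        std = qtlscan.scanone_hk(probs, y, chroms=["4"])
        ext = qtlscan.scanone_hk(probs, y, chroms=["4"], extended=True)
        np.testing.assert_allclose(std.df["lod"], ext.df["lod"], atol=0.02)

    def test_missing_phenotypes_are_dropped(self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        y2 = y.copy()
        y2[:10] = np.nan
        scan = qtlscan.scanone_hk(probs, y2, chroms=["4"])
        keep = np.isfinite(y2)
        g = gm.genotype_at("c4m07").astype(float)
        expected = ols_lod_oracle(y2[keep], [g[keep]])
        row = scan.df[scan.df["name"] == "c4m07"]
        assert row["lod"].iloc[0] == pytest.approx(expected, abs=1e-8)


class TestThresholds:
    def test_alpha_one_returns_minimum_of_maxima(self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        thr = qtlscan.permutation_thresholds(probs, y, alpha=1.0,
                                             n_perm_auto=25, n_perm_x=25,
                                             seed=4)
        assert thr.auto_threshold == pytest.approx(thr.perm_max_auto.min())
        assert thr.x_threshold == pytest.approx(thr.perm_max_x.min())

    def test_alpha_partition_by_genetic_length(self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        thr = qtlscan.permutation_thresholds(probs, y, alpha=0.05,
                                             n_perm_auto=25, n_perm_x=25,
                                             seed=4)
        L_a = probs.genetic_length(probs.autosomes())
        L_x = probs.genetic_length(["X"])
        L = L_a + L_x
        assert thr.alpha_auto == pytest.approx(1 - 0.95 ** (L_a / L))
        assert thr.alpha_x == pytest.approx(1 - 0.95 ** (L_x / L))
        # parts recombine to the genome-wide alpha
        assert (1 - thr.alpha_auto) * (1 - thr.alpha_x) == pytest.approx(0.95)

    def test_zero_permutations_rejected(self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        with pytest.raises(ValueError):
            qtlscan.permutation_thresholds(probs, np.zeros(gm.n),
                                           n_perm_auto=0)


class TestBayesInterval:
    def _scan(self, lods, positions=None):
        pos = positions if positions is not None else \
            np.arange(len(lods), dtype=float)
        return qtlscan.ScanResult(pd.DataFrame(
            {"chrom": "1", "pos_cm": pos, "pos_mb": 2 * pos, "lod": lods}))

    def test_hand_normalized_five_point_toy(self):
        scan = self._scan([0, 1, 3, 1, 0], np.array([0., 10, 20, 30, 40]))
        l, p, r, *_ = qtlscan.bayes_interval(scan, "1")
        assert (l, p, r) == (10.0, 20.0, 30.0)

    def test_point_mass_collapses_to_peak_span(self):
        lods = np.zeros(100)
        lods[40] = 10.0
        l, p, r, *_ = qtlscan.bayes_interval(self._scan(lods), "1")
        assert p == 40.0
        assert r - l <= 2.0   # at most one grid step each side

    def test_flat_curve_covers_95_percent(self):
        scan = self._scan(np.zeros(100))
        l, p, r, *_ = qtlscan.bayes_interval(scan, "1")
        assert (r - l) / 99.0 >= 0.95

    def test_planted_qtl_recovered_inside_interval(self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=2.0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        scan = qtlscan.scanone_hk(probs, y, chroms=["4"])
        l, p, r, lmb, pmb, rmb = qtlscan.bayes_interval(scan, "4")
        assert l <= 60.0 <= r
        assert lmb <= 120.0 <= rmb

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            qtlscan.bayes_interval(self._scan([1.0, 2.0]), "7")


class TestVarianceExplained:
    def test_zero_lod_zero_r2(self):
        assert qtlscan.variance_explained(0.0, 374) == 0.0

    def test_worked_value(self):
        assert qtlscan.variance_explained(5.05, 374) == pytest.approx(
            1 - 10 ** (-2 * 5.05 / 374), abs=1e-12)
        assert qtlscan.variance_explained(5.05, 374) == pytest.approx(
            0.0603, abs=5e-4)

    @pytest.mark.parametrize("r2", [0.01, 0.055, 0.5, 0.9])
    def test_round_trip_identity(self, r2):
        n = 374
        assert qtlscan.variance_explained(
            qtlscan.lod_from_r2(r2, n), n) == pytest.approx(r2, abs=1e-12)


class TestScantwo:
    def _cohort(self, effects, seed, n=374):
        ss = np.random.SeedSequence(seed)
        rngs = [np.random.default_rng(c) for c in ss.spawn(3)]
        gmap = simdata.simulate_map()
        sex = simdata.simulate_sexes(n, 0.5, rngs[0])
        gm = simdata.simulate_genotypes(gmap, n, sex, rng=rngs[1])
        ph = simdata.simulate_phenotypes(gm, effects, rng=rngs[2])
        return gm, ph, sex

    def test_opposite_sign_pair_found_with_opposite_directions(self):
        effects = [QTLEffect("10", 15.0, "weight", 0.48),
                   QTLEffect("10", 110.0, "weight", -0.48)]
        found = 0
        for seed in range(5):
            gm, ph, sex = self._cohort(effects, 200 + seed)
            y = mean_center_by_sex(ph["weight"].to_numpy(), sex)
            probs = qtlscan.calc_genoprob(gm, step_cm=2.0, error_rate=0.0)
            rep = qtlscan.scantwo_chromosome(probs, y, "10",
                                             threshold_second=1.8)
            if rep.second_qtl and rep.directions[0] * rep.directions[1] == -1:
                found += 1
        assert found >= 4

    def test_independent_phenotype_shows_no_interaction(self):
        gm, ph, sex = self._cohort([], 300)
        y = np.random.default_rng(300).normal(size=gm.n)
        probs = qtlscan.calc_genoprob(gm, step_cm=2.0, error_rate=0.0)
        rep = qtlscan.scantwo_chromosome(probs, y, "10",
                                         threshold_second=2.0,
                                         threshold_interaction=2.0)
        assert not rep.interaction

    def test_too_coarse_grid_rejected(self):
        gm = toy_genotypes([[0, 1]] * 10, [("m1", 0.0), ("m2", 20.0)])
        probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0.0)
        with pytest.raises(ValueError):
            qtlscan.scantwo_chromosome(probs, np.arange(10.0), "1")


class TestRefine:
    def test_single_qtl_refines_to_scanone_argmax(self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=2.0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        scan = qtlscan.scanone_hk(probs, y, chroms=["4"])
        peak = scan.peak("4")
        loci, lod, conv = qtlscan.refine_positions(probs, y, [("4", 30.0)])
        assert conv
        assert loci[0][1] == peak["pos_cm"]
        assert lod == pytest.approx(peak["lod"], abs=1e-9)

    def test_already_optimal_positions_do_not_move(self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=2.0, error_rate=0.0)
        y = mean_center_by_sex(pheno["bmi"].to_numpy(), gm.sex)
        scan = qtlscan.scanone_hk(probs, y, chroms=["4"])
        best = float(scan.peak("4")["pos_cm"])
        loci, lod, conv = qtlscan.refine_positions(probs, y, [("4", best)])
        assert loci == [("4", best)] and conv

    def test_two_qtl_recovered_from_offset_starts(self):
        effects = [QTLEffect("10", 14.0, "weight", 0.55),
                   QTLEffect("10", 110.0, "weight", -0.55)]
        hits = 0
        for seed in range(5):
            ss = np.random.SeedSequence(400 + seed)
            rngs = [np.random.default_rng(c) for c in ss.spawn(3)]
            gmap = simdata.simulate_map()
            sex = simdata.simulate_sexes(374, 0.5, rngs[0])
            gm = simdata.simulate_genotypes(gmap, 374, sex, rng=rngs[1])
            ph = simdata.simulate_phenotypes(gm, effects, rng=rngs[2])
            y = mean_center_by_sex(ph["weight"].to_numpy(), sex)
            probs = qtlscan.calc_genoprob(gm, step_cm=2.0, error_rate=0.0)
            loci, lod, conv = qtlscan.refine_positions(
                probs, y, [("10", 24.0), ("10", 100.0)])
            if abs(loci[0][1] - 14.0) <= 10 and abs(loci[1][1] - 110.0) <= 10:
                hits += 1
        assert hits >= 4

    def test_empty_qtl_list_rejected(self, small_cohort):
        gm, pheno = small_cohort
        probs = qtlscan.calc_genoprob(gm, step_cm=2.0, error_rate=0.0)
        with pytest.raises(ValueError):
            qtlscan.refine_positions(probs, np.zeros(gm.n), [])


class TestSexInteraction:
    def test_male_restricted_effect_detected(self):
        rng = np.random.default_rng(9)
        n = 374
        sex = np.array(["M", "F"] * (n // 2), dtype=object)
        g = rng.integers(0, 2, n)
        y = rng.normal(size=n) + 0.5 * g * (sex == "M")
        p, eff = qtlscan.sex_interaction_test(g, sex, y)
        assert p < 0.05
        assert eff["M"] > 0.2 and abs(eff["F"]) < 0.25

    def test_equal_effects_yield_null_p(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 200
            sex = np.array(["M", "F"] * (n // 2), dtype=object)
            g = rng.integers(0, 2, n)
            y = rng.normal(size=n) + 0.4 * g
            p, _ = qtlscan.sex_interaction_test(g, sex, y)
            ps.append(p)
        # null p approximately uniform: mean near 0.5, spread over (0,1)
        assert 0.3 < np.mean(ps) < 0.7
        assert (np.array(ps) < 0.05).mean() <= 0.15

    def test_empty_cell_rejected(self):
        sex = np.array(["M", "M", "F", "F"], dtype=object)
        g = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError):
            qtlscan.sex_interaction_test(g, sex, np.arange(4.0))
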