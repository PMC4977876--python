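"""Generator checks: map geometry, Mendelian segregation, Haldane
recombination, planted effect sizes, tumor coupling, qPCR structure,
and byte-level determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bxlink import simdata
from bxlink.genotypes import HET, MISSING
from bxlink.simdata import (EQTLEffect, MapSpec, ModuleSpec, QPCRSpec,
                            QTLEffect, SimConfig, TumorModel, haldane,
                            inverse_haldane, simulate_expression,
                            simulate_genotypes, simulate_map,
                            simulate_phenotypes, simulate_qpcr,
                            simulate_tumors, simulate_variants)


class TestMap:
    def test_default_panel_has_276_markers_on_20_chromosomes(self):
        gmap = simulate_map()
        assert len(gmap) == 276
        assert gmap.chroms == [str(i) for i in range(1, 20)] + ["X"]

    def test_arithmetic_grid(self):
        gmap = simulate_map(MapSpec(n_autosomes=1, chrom_lengths=[100.0, 90.0],
                                    marker_spacing=10.0))
        sub = gmap.chrom_slice("1")
        assert list(sub["cm"]) == [10.0 * k for k in range(11)]

    def test_degenerate_short_chromosome_gets_single_marker(self):
        gmap = simulate_map(MapSpec(n_autosomes=1, chrom_lengths=[5.0, 5.0],
                                    marker_spacing=10.0))
        assert list(gmap.chrom_slice("1")["cm"]) == [0.0]

    def test_physical_positions_monotone_with_cm(self):
        gmap = simulate_map()
        for c in gmap.chroms:
            mb = gmap.chrom_slice(c)["mb"].to_numpy()
            assert (np.diff(mb) > 0).all()

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            simulate_map(MapSpec(n_autosomes=1, chrom_lengths=[-1.0, 10.0]))


class TestGenotypes:
    def test_haldane_closed_form(self):
        assert haldane(0.0) == 0.0
        assert haldane(10.0) == pytest.approx((1 - np.exp(-0.2)) / 2)
        assert inverse_haldane(haldane(17.0)) == pytest.approx(17.0)

    def test_het_fraction_within_exact_binomial_bounds(self, default_map):
        n = 400
        rng = np.random.default_rng(3)
        sex = simdata.simulate_sexes(n, 0.5, rng)
        gm = simulate_genotypes(default_map, n, sex, seed=3)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        het = (gm.geno == HET).sum(axis=0)
        # 276 markers at 99% bounds: allow the expected handful outside
        assert ((het < lo) | (het > hi)).mean() < 0.05

    def test_adjacent_recombination_matches_haldane(self):
        gmap = simulate_map(MapSpec(n_autosomes=1, chrom_lengths=[10.0, 10.0],
                                    marker_spacing=10.0))
        n = 5000
        sex = np.array(["F"] * n, dtype=object)
        gm = simulate_genotypes(gmap, n, sex, seed=4)
        g = gm.geno[:, :2]
        rec = (g[:, 0] != g[:, 1]).mean()
        r = haldane(10.0)
        se = np.sqrt(r * (1 - r) / n)
        assert abs(rec - r) < 4 * se
        # map-function round trip
        assert abs(inverse_haldane(rec) - 10.0) < 4 * se * 100

    def test_zero_distance_means_complete_linkage(self):
        gmap = simdata.GeneticMap.__new__(simdata.GeneticMap)
        import pandas as pd
        gmap = simdata.simulate_map(MapSpec(n_autosomes=1,
                                            chrom_lengths=[0.5, 10.0],
                                            marker_spacing=0.25))
        n = 500
        gm = simulate_genotypes(gmap, n, np.array(["F"] * n, dtype=object),
                                seed=5)
        sub = gm.geno[:, :2]  # 0.25 cM apart: r ~ 0.0025
        assert (sub[:, 0] != sub[:, 1]).mean() < 0.02

    def test_unlinked_chromosomes_assort_independently(self):
        gmap = simulate_map(MapSpec(n_autosomes=2,
                                    chrom_lengths=[10.0, 10.0, 10.0],
                                    marker_spacing=10.0))
        n = 5000
        gm = simulate_genotypes(gmap, n, np.array(["F"] * n, dtype=object),
                                seed=6)
        a = gm.geno[:, 0]
        b = gm.geno[:, 2]   # first marker of chromosome 2
        r = (a != b).mean()
        assert abs(r - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_error_rate_corrupts_calls(self, default_map):
        # identical seed: the underlying chains agree, only the error layer
        # (drawn after the chains) differs
        n = 200
        sex = np.array(["F"] * n, dtype=object)
        clean = simulate_genotypes(default_map, n, sex, seed=9)
        noisy = simulate_genotypes(default_map, n, sex, error_rate=0.02,
                                   seed=9)
        flips = (clean.geno != noisy.geno).mean()
        assert 0.01 < flips < 0.03

    def test_empty_map_rejected(self):
        import pandas as pd
        from bxlink.genotypes import GeneticMap
        empty = GeneticMap(pd.DataFrame(columns=["marker", "chrom",
                                                 "cm", "mb"]))
        with pytest.raises(ValueError):
            simulate_genotypes(empty, 5, np.array(["F"] * 5, dtype=object))


class TestPhenotypes:
    def test_null_model_has_no_marker_signal(self, default_map):
        n = 374
        rng = np.random.default_rng(12)
        sex = simdata.simulate_sexes(n, 0.5, rng)
        gm = simulate_genotypes(default_map, n, sex, seed=12)
        ph = simulate_phenotypes(gm, [], seed=12)
        y = ph["bmi"].to_numpy()
        r2 = []
        for j in range(0, 276, 10):
            g = gm.geno[:, j].astype(float)
            r2.append(np.corrcoef(g, y)[0, 1] ** 2)
        assert max(r2) < 0.04

    def test_planted_effect_realizes_nominal_variance(self, default_map):
        # a = 0.4826 phenotype SD -> expected R2 = a^2/4 / (a^2/4 + 1)
        a = 0.4826
        expected = a ** 2 / 4 / (a ** 2 / 4 + 1)
        r2 = []
        for seed in range(8):
            n = 374
            ss = np.random.SeedSequence(seed)
            rngs = [np.random.default_rng(c) for c in ss.spawn(3)]
            sex = simdata.simulate_sexes(n, 0.5, rngs[0])
            gm = simulate_genotypes(default_map, n, sex, rng=rngs[1])
            ph = simulate_phenotypes(gm, [QTLEffect("4", 60.0, "bmi", a)],
                                     rng=rngs[2])
            from bxlink.tumorstats import mean_center_by_sex
            y = mean_center_by_sex(ph["bmi"].to_numpy(), sex)
            g = gm.genotype_at("c4m07").astype(float)
            r2.append(np.corrcoef(g, y)[0, 1] ** 2)
        assert np.mean(r2) == pytest.approx(expected, abs=0.02)

    def test_male_restricted_effect_is_absent_in_females(self, default_map):
        n = 600
        ss = np.random.SeedSequence(13)
        rngs = [np.random.default_rng(c) for c in ss.spawn(3)]
        sex = simdata.simulate_sexes(n, 0.5, rngs[0])
        gm = simulate_genotypes(default_map, n, sex, rng=rngs[1])
        ph = simulate_phenotypes(gm, [QTLEffect("9", 40.0, "bmi", 0.8,
                                                sex="M")], rng=rngs[2])
        g = simdata._genotype_near(gm, "9", 40.0).astype(float)
        y = ph["bmi"].to_numpy()
        m = sex == "M"
        r2_m = np.corrcoef(g[m], y[m])[0, 1] ** 2
        r2_f = np.corrcoef(g[~m], y[~m])[0, 1] ** 2
        assert r2_m > 0.05 and r2_f < 0.02

    def test_bmi_is_weight_over_length_squared(self, small_cohort):
        _, ph = small_cohort
        np.testing.assert_allclose(ph["bmi"],
                                   ph["weight"] / ph["length"] ** 2)

    def test_unknown_marker_chromosome_rejected(self, default_map):
        gm = simulate_genotypes(default_map, 10,
                                np.array(["F"] * 10, dtype=object), seed=1)
        with pytest.raises(KeyError):
            simulate_phenotypes(gm, [QTLEffect("99", 0.0, "bmi", 1.0)])


class TestExpression:
    def test_full_loading_no_noise_gives_perfect_rank_correlation(
            self, default_map):
        gm = simulate_genotypes(default_map, 40,
                                np.array(["F"] * 40, dtype=object), seed=2)
        expr, _ = simulate_expression(
            gm, module_spec=ModuleSpec(size=5, loading=1.0), n_genes=10,
            seed=2)
        sub = expr.iloc[:5].to_numpy()
        rho = np.corrcoef(sub)
        assert np.allclose(rho, 1.0, atol=1e-9)

    def test_zero_loading_module_is_background(self, default_map):
        gm = simulate_genotypes(default_map, 200,
                                np.array(["F"] * 200, dtype=object), seed=3)
        expr, _ = simulate_expression(
            gm, module_spec=ModuleSpec(size=10, loading=0.0), n_genes=50,
            seed=3)
        rho = np.corrcoef(expr.iloc[:10].to_numpy())
        off = rho[np.triu_indices(10, 1)]
        assert np.abs(off).max() < 0.25

    def test_planted_cis_effect_recovers_one_sd_mean_difference(
            self, default_map):
        diffs = []
        for seed in range(20):
            gm = simulate_genotypes(default_map, 374,
                                    np.array(["F"] * 374, dtype=object),
                                    seed=seed)
            expr, info = simulate_expression(
                gm, [EQTLEffect("Drv", "c9m05", 1.0)], module_spec=None,
                n_genes=5, seed=seed)
            g = gm.genotype_at("c9m05")
            x = expr.loc["Drv"].to_numpy()
            diffs.append(x[g == 1].mean() - x[g == 0].mean())
        assert np.mean(diffs) == pytest.approx(1.0, abs=0.05)

    def test_cis_gene_placed_at_marker(self, default_map):
        gm = simulate_genotypes(default_map, 20,
                                np.array(["F"] * 20, dtype=object), seed=4)
        _, info = simulate_expression(gm, [EQTLEffect("Drv", "c9m05", 1.0)],
                                      module_spec=None, n_genes=5, seed=4)
        row = info.set_index("gene").loc["Drv"]
        mrow = gm.map.df.set_index("marker").loc["c9m05"]
        assert row["chrom"] == mrow["chrom"] and row["mb"] == mrow["mb"]

    def test_invalid_loading_rejected(self):
        with pytest.raises(ValueError):
            ModuleSpec(loading=1.5)


class TestTumors:
    def _pheno(self, n, seed):
        ss = np.random.SeedSequence(seed)
        rngs = [np.random.default_rng(c) for c in ss.spawn(3)]
        gmap = simulate_map()
        sex = simdata.simulate_sexes(n, 0.5, rngs[0])
        gm = simulate_genotypes(gmap, n, sex, rng=rngs[1])
        return simulate_phenotypes(gm, [], rng=rngs[2]), sex

    def test_zero_coefficient_gives_null_coupling(self):
        rhos = []
        for seed in range(5):
            ph, sex = self._pheno(374, seed)
            tm = TumorModel(bmi_coef_male=0.0, bmi_coef_female=0.0)
            tum = simulate_tumors(ph, tm, seed=seed)
            rho = stats.spearmanr(ph["bmi"], tum["pap20"]).statistic
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_male_coupling_produces_male_correlation(self):
        ph, sex = self._pheno(374, 21)
        tum = simulate_tumors(ph, TumorModel(), seed=21)
        m = sex == "M"
        rho_m = stats.spearmanr(ph.loc[m, "bmi"], tum.loc[m, "pap20"]).statistic
        rho_f = stats.spearmanr(ph.loc[~m, "bmi"], tum.loc[~m, "pap20"]).statistic
        assert rho_m > 0.2 and abs(rho_f) < 0.2

    def test_counts_are_overdispersed(self):
        ph, _ = self._pheno(400, 22)
        tum = simulate_tumors(ph, TumorModel(bmi_coef_male=0,
                                             bmi_coef_female=0), seed=22)
        c = tum["pap20"].to_numpy(float)
        assert c.var() > 1.5 * c.mean()

    def test_censoring_flag_consistent(self):
        ph, _ = self._pheno(200, 23)
        tum = simulate_tumors(ph, TumorModel(), seed=23)
        ev = tum["carcinoma_event"].to_numpy(bool)
        assert (tum.loc[~ev, "carcinoma_time"] == 450.0).all()
        assert (tum.loc[ev, "carcinoma_time"] <= 450.0).all()

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            TumorModel(dispersion=-1.0)


class TestVariantsQpcrGo:
    def test_zero_variants(self):
        info = pd.DataFrame({"gene": ["g1"], "chrom": ["1"], "mb": [5.0]})
        v = simulate_variants(info, planted=(), background_rate=0.0)
        assert len(v) == 0

    def test_planted_variant_at_gene_position(self):
        info = pd.DataFrame({"gene": ["g1", "g2"], "chrom": ["1", "2"],
                             "mb": [5.0, 9.0]})
        v = simulate_variants(info, [("g1", "nonsynonymous", 3)],
                              background_rate=0.0)
        assert len(v) == 3 and set(v["gene"]) == {"g1"}
        assert (v["mb"] == 5.0).all()

    def test_unknown_consequence_rejected(self):
        info = pd.DataFrame({"gene": ["g1"], "chrom": ["1"], "mb": [5.0]})
        with pytest.raises(ValueError):
            simulate_variants(info, [("g1", "bogus", 1)])

    def test_qpcr_sd_zero_realizes_exact_means(self):
        spec = QPCRSpec(sd=0.0)
        ct = simulate_qpcr(spec, seed=1)
        tgt = ct[ct["gene"] == spec.target_gene]
        for grp, mean in spec.group_target_means.items():
            assert (tgt.loc[tgt["group"] == grp, "ct"] == mean).all()
        ref = ct[ct["gene"] == spec.reference_gene]
        assert (ref["ct"] == spec.reference_mean).all()

    def test_qpcr_needs_two_per_group(self):
        with pytest.raises(ValueError):
            QPCRSpec(n_per_group=1)


class TestDeterminism:
    def test_fixed_seed_bit_identical_cohort(self, tmp_path):
        cfg = SimConfig(n_individuals=40, n_genes=30,
                        module_spec=ModuleSpec(size=5), rng_seed=77)
        a = simdata.simulate_cohort(cfg)
        b = simdata.simulate_cohort(cfg)
        assert np.array_equal(a.genotypes.geno, b.genotypes.geno)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.qpcr, b.qpcr)

    def test_ground_truth_round_trip(self, tmp_path):
        cfg = SimConfig(n_individuals=20, n_genes=10,
                        qtl_effects=[QTLEffect("4", 60.0, "bmi", 0.5)],
                        eqtl_effects=[EQTLEffect("Mod000", "c4m07", 1.0)],
                        module_spec=ModuleSpec(size=3), rng_seed=5)
        c = simdata.simulate_cohort(cfg)
        c.truth.to_json(tmp_path / "truth.json")
        back = simdata.GroundTruth.from_json(tmp_path / "truth.json")
        assert back.qtl == c.truth.qtl
        assert back.module_genes == c.truth.module_genes
        # every planted element references an existing marker/gene
        markers = set(c.genotypes.map.markers)
        genes = set(c.expression.index)
        assert all(e["marker"] in markers for e in back.eqtl)
        assert all(g in genes for g in back.module_genes)
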