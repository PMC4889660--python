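"""Permutation thresholds, effect estimation, R², and QTL calling."""

import numpy as np
import pytest

from sgqtl import (
    SelectionConfig,
    SimConfig,
    SimQTL,
    apply_selective_genotyping,
    call_qtls,
    default_map,
    effect_scan,
    estimate_effects,
    genotype_probabilities,
    required_permutations,
    rsq_from_lod,
    scan_em,
    select_tails,
    simulate_f2_population,
    stratified_permutation_threshold,
)
from sgqtl.inference import permutation_threshold_from_nulls
from sgqtl.scan import scan_em as _scan

from conftest import make_population


class TestRequiredPermutations:
    @pytest.mark.parametrize(
        "alpha,se,expected",
        [(0.05, 0.005, 1900), (0.5, 0.5, 1), (0.05, 0.01, 475)],
    )
    def test_binomial_se_sample_size_rule(self, alpha, se, expected):
        n = required_permutations(alpha, se)
        assert n == expected
        assert np.sqrt(alpha * (1 - alpha) / n) <= se
        if n > 1:
            assert np.sqrt(alpha * (1 - alpha) / (n - 1)) > se


class TestRsqFromLod:
    def test_formula_values(self):
        assert rsq_from_lod(224, 0.0) == 0.0
        assert rsq_from_lod(224, 4.0) == pytest.approx(0.0789, abs=5e-4)
        assert rsq_from_lod(224, 1e6) == pytest.approx(1.0)

    def test_monotone_in_lod_and_n(self):
        lods = np.linspace(0, 10, 30)
        vals = [rsq_from_lod(224, l) for l in lods]
        assert np.all(np.diff(vals) > 0)
        ns = range(50, 500, 50)
        vals_n = [rsq_from_lod(n, 4.0) for n in ns]
        assert np.all(np.diff(vals_n) < 0)


class TestEstimateEffects:
    def _population_with_class_means(self, tiny_map, means):
        # 4 individuals per genotype class at every marker, phenotypes set
        # exactly to the class mean
        geno = np.repeat([[0, 0, 0], [1, 1, 1], [2, 2, 2]], 4, axis=0)
        y = np.repeat(means, 4).astype(float)
        return make_population(tiny_map, geno, y)

    @pytest.mark.parametrize(
        "means,a,d",
        [((400.0, 410.0, 420.0), 10.0, 0.0), ((400.0, 420.0, 420.0), 10.0, 10.0)],
    )
    def test_formula_on_known_class_means(self, tiny_map, means, a, d):
        pop = self._population_with_class_means(tiny_map, means)
        grid = genotype_probabilities(pop, step=10.0, error_rate=0.0)
        a_hat, d_hat, class_means = estimate_effects(pop, grid, "1", 10.0)
        assert a_hat == pytest.approx(a, abs=1e-9)
        assert d_hat == pytest.approx(d, abs=1e-9)
        np.testing.assert_allclose(class_means, means, atol=1e-9)

    def test_empty_class_raises(self, tiny_map):
        geno = np.zeros((12, 3), dtype=int)  # all AA: B class empty
        pop = make_population(tiny_map, geno, 400 + np.arange(12.0))
        grid = genotype_probabilities(pop, step=10.0, error_rate=0.0)
        with pytest.raises(ValueError, match="class weight"):
            estimate_effects(pop, grid, "1", 10.0)

    def test_sg_overestimates_effects_among_significant_calls(self):
        # winner's curse of the SG design: class contrasts among the
        # genotyped extremes inflate |a| on average for QTL that clear the
        # threshold (direction only; magnitude depends on conditions)
        gmap = default_map(3, 60.0, 10.0)
        a_true = 2.6
        sig_effects = []
        for seed in range(30):
            cfg = SimConfig(
                map=gmap, n_progeny=200,
                qtls=[SimQTL("2", 30.0, a_protein=a_true)],
                residual_sd={"protein": 5.0, "oil": 5.0},
                bimorphic_fraction=1.0, missing_rate=0.0, seed=seed,
            )
            pop = simulate_f2_population(cfg)
            low, high = select_tails(pop.trait_values("protein"),
                                     SelectionConfig(seed=seed))
            sg = apply_selective_genotyping(pop, low, high)
            grid = genotype_probabilities(sg, step=10.0)
            res = scan_em(sg, grid, trait="protein")
            for rec in call_qtls(res, 3.0, sg, grid):
                if rec.significant and rec.chromosome == "2":
                    sig_effects.append(abs(rec.a))
        assert len(sig_effects) >= 5
        assert np.mean(sig_effects) > a_true

    def test_additive_effect_recovered_at_scale(self):
        gmap = default_map(2, 60.0, 10.0)
        cfg = SimConfig(
            map=gmap, n_progeny=2000, qtls=[SimQTL("1", 30.0, a_protein=5.0)],
            residual_sd={"protein": 5.0, "oil": 5.0},
            bimorphic_fraction=1.0, missing_rate=0.0, seed=21,
        )
        pop = simulate_f2_population(cfg)
        grid = genotype_probabilities(pop, step=10.0, error_rate=0.0)
        a_hat, d_hat, _ = estimate_effects(pop, grid, "1", 30.0)
        se_a = 5.0 * 0.5 * np.sqrt(2 / 500)  # sd * sqrt(1/nAA + 1/nBB)/2
        assert a_hat == pytest.approx(5.0, abs=3 * se_a)
        assert abs(d_hat) < 3 * 5.0 * np.sqrt(1 / 1000 + 0.25 * 2 / 500)


class TestStratifiedPermutation:
    def test_single_stratum_equals_plain_shuffle(self, clean_population):
        grid = genotype_probabilities(clean_population, step=10.0)
        res = stratified_permutation_threshold(
            clean_population, n_perm=100, seed=7, grid=grid
        )
        # independent re-implementation: unstratified shuffle, same RNG use
        rng = np.random.default_rng(7)
        y = clean_population.trait_values("protein")
        work = clean_population.copy()
        naive = np.empty(100)
        for b in range(100):
            work.phenotypes["protein"] = y[rng.permutation(y.size)]
            naive[b] = _scan(work, grid, trait="protein").genome_max_lod
        np.testing.assert_allclose(np.sort(res.null_max_lods), np.sort(naive),
                                   atol=1e-9)
        assert res.threshold == permutation_threshold_from_nulls(naive, 0.05)

    def test_threshold_is_order_statistic_quantile(self):
        nulls = np.arange(1, 201) / 40.0  # 0.025 .. 5.0
        # rank ceil(0.95 * 201) = 191 -> 191/40
        assert permutation_threshold_from_nulls(nulls, 0.05) == pytest.approx(191 / 40)

    def test_sg_threshold_self_consistent_and_seed_stable(self, qtl_population):
        y = qtl_population.trait_values("protein")
        low, high = select_tails(y, SelectionConfig(seed=1))
        sg = apply_selective_genotyping(qtl_population, low, high)
        grid = genotype_probabilities(sg, step=10.0)
        res = {}
        for seed in (11, 12):
            res[seed] = stratified_permutation_threshold(
                sg, n_perm=200, seed=seed, grid=grid
            )
        for r in res.values():
            frac = np.mean(r.null_max_lods > r.threshold)
            assert abs(frac - 0.05) <= 2 * np.sqrt(0.05 * 0.95 / 200)
            assert r.se_alpha == pytest.approx(np.sqrt(0.05 * 0.95 / 200))
        # Monte-Carlo stability: thresholds agree within bootstrap error
        boot_se = []
        for r in res.values():
            rng = np.random.default_rng(0)
            qs = [
                permutation_threshold_from_nulls(
                    rng.choice(r.null_max_lods, r.n_perm, replace=True), 0.05
                )
                for _ in range(200)
            ]
            boot_se.append(np.std(qs))
        diff = abs(res[11].threshold - res[12].threshold)
        assert diff < 2 * np.hypot(*boot_se) + 1e-9

    def test_degenerate_stratum_rejected(self, clean_population):
        pop = clean_population.copy()
        flags = np.zeros(pop.n_individuals, dtype=bool)
        flags[0] = True  # a single genotyped individual
        pop.phenotypes["genotyped"] = flags
        with pytest.raises(ValueError, match="degenerate"):
            stratified_permutation_threshold(pop, n_perm=100, seed=0, step=10.0)


class TestCallQtls:
    def test_no_significant_records_below_threshold(self, clean_population):
        grid = genotype_probabilities(clean_population, step=10.0)
        res = scan_em(clean_population, grid, trait="protein")
        records = call_qtls(res, 1e9, clean_population, grid, include_all=True)
        assert len(records) == len(clean_population.map.chromosomes)
        assert not any(r.significant for r in records)

    def test_qtl_called_on_true_chromosome_with_effects(self, qtl_population):
        grid = genotype_probabilities(qtl_population, step=10.0)
        res = scan_em(qtl_population, grid, trait="protein")
        records = call_qtls(res, 4.0, qtl_population, grid)
        sig = [r for r in records if r.significant]
        assert {r.chromosome for r in sig} == {"2"}
        top = sig[0]
        assert top.a == pytest.approx(6.0, abs=1.5)
        assert 0 < top.r2 < 1
        assert top.r2 == pytest.approx(rsq_from_lod(res.n_phenotyped, top.lod))

    def test_reporting_floor_suppresses_flat_chromosomes(self, qtl_population):
        grid = genotype_probabilities(qtl_population, step=10.0)
        res = scan_em(qtl_population, grid, trait="protein")
        shown = call_qtls(res, 4.0, qtl_population, grid, reporting_floor=1.0)
        everything = call_qtls(res, 4.0, qtl_population, grid, include_all=True)
        assert len(everything) == len(qtl_population.map.chromosomes)
        assert all(r.lod >= 1.0 for r in shown)


class TestEffectScan:
    def test_null_scan_covered_by_three_se(self, clean_population):
        grid = genotype_probabilities(clean_population, step=10.0)
        prof = effect_scan(clean_population, grid, "1", "protein")
        covered = np.mean(np.abs(prof["a"]) < 3 * prof["se_a"])
        assert covered >= 0.95

    def test_trans_phase_qtl_pair_flips_sign(self):
        gmap = default_map(1, 100.0, 5.0)
        cfg = SimConfig(
            map=gmap, n_progeny=400,
            qtls=[SimQTL("1", 25.0, a_protein=6.0),
                  SimQTL("1", 75.0, a_protein=-6.0)],
            residual_sd={"protein": 4.0, "oil": 4.0},
            bimorphic_fraction=1.0, missing_rate=0.0, seed=31,
        )
        pop = simulate_f2_population(cfg)
        grid = genotype_probabilities(pop, step=5.0)
        prof = effect_scan(pop, grid, "1", "protein")
        a = prof.set_index("position")["a"]
        assert a.loc[25.0] > 0 > a.loc[75.0]
        assert np.any(np.diff(np.sign(a.loc[25.0:75.0])) != 0)
        assert abs(prof.attrs["positive_max_cm"] - 25.0) <= 15.0
        assert abs(prof.attrs["negative_max_cm"] - 75.0) <= 15.0

    def test_constant_phenotype_gives_zero_effects(self, clean_population):
        pop = clean_population.copy()
        pop.phenotypes["protein"] = 430.0
        grid = genotype_probabilities(pop, step=10.0)
        prof = effect_scan(pop, grid, "1", "protein")
        np.testing.assert_allclose(prof["a"], 0.0, atol=1e-9)
        np.testing.assert_allclose(prof["d"], 0.0, atol=1e-9)
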