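"""Harmonization and the MR estimator suite against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from trialmr import (SimCohortConfig, bidirectional, harmonize, ivw, mr_egger,
                     mr_presso, make_two_sample, one_sample_mr, simulate_cohort,
                     wald_ratio, weighted_median, weighted_mode)
from trialmr.mr import _weighted_median_point, _weighted_mode_point, _silverman_bandwidth
from trialmr.simulate import simulate_summary_pairs

from conftest import random_pairs
from _oracles import (weighted_median_oracle, wls_with_intercept,
                      wls_zero_intercept_slope)


def _gwas_frame(ids, ea, oa, eaf, beta, se, p=None, n=1000):
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    from scipy import stats
    if p is None:
        p = 2 * stats.norm.sf(np.abs(beta / se))
    return pd.DataFrame({
        "variant_id": ids, "chrom": "1", "pos": range(1, len(ids) + 1),
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "p": p, "n": n})


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        exp = _gwas_frame(["v1"], ["A"], ["G"], [0.3], [0.2], [0.05])
        out = _gwas_frame(["v1"], ["A"], ["G"], [0.31], [0.1], [0.05])
        pairs = harmonize(exp, out)
        assert pairs["action"].tolist() == ["kept"]
        assert pairs["beta_out"].iloc[0] == 0.1

    def test_swapped_alleles_negate_outcome_beta(self):
        exp = _gwas_frame(["v1"], ["A"], ["G"], [0.3], [0.2], [0.05])
        out = _gwas_frame(["v1"], ["G"], ["A"], [0.7], [0.1], [0.05])
        pairs = harmonize(exp, out)
        assert pairs["action"].tolist() == ["flipped"]
        assert pairs["beta_out"].iloc[0] == -0.1
        assert pairs["eaf_out"].iloc[0] == pytest.approx(0.3)

    def test_strand_complement_resolved(self):
        exp = _gwas_frame(["v1"], ["A"], ["G"], [0.3], [0.2], [0.05])
        out = _gwas_frame(["v1"], ["T"], ["C"], [0.3], [0.1], [0.05])
        pairs = harmonize(exp, out)
        assert pairs["action"].tolist() == ["kept"]
        assert pairs["beta_out"].iloc[0] == 0.1

    def test_ambiguous_palindrome_dropped(self):
        exp = _gwas_frame(["v1"], ["A"], ["T"], [0.50], [0.2], [0.05])
        out = _gwas_frame(["v1"], ["A"], ["T"], [0.50], [0.1], [0.05])
        assert harmonize(exp, out).empty

    def test_informative_palindrome_aligned_by_eaf(self):
        exp = _gwas_frame(["v1"], ["A"], ["T"], [0.10], [0.2], [0.05])
        out = _gwas_frame(["v1"], ["A"], ["T"], [0.88], [0.1], [0.05])
        pairs = harmonize(exp, out)
        assert pairs["beta_out"].iloc[0] == -0.1

    def test_irreconcilable_alleles_dropped(self):
        exp = _gwas_frame(["v1"], ["A"], ["G"], [0.3], [0.2], [0.05])
        out = _gwas_frame(["v1"], ["A"], ["C"], [0.3], [0.1], [0.05])
        assert harmonize(exp, out).empty

    def test_idempotence(self):
        exp = _gwas_frame(["v1", "v2"], ["A", "C"], ["G", "T"], [0.3, 0.2],
                          [0.2, -0.1], [0.05, 0.04])
        out = _gwas_frame(["v1", "v2"], ["G", "C"], ["A", "T"], [0.7, 0.2],
                          [0.1, 0.3], [0.05, 0.04])
        once = harmonize(exp, out)
        realigned = _gwas_frame(once["variant_id"], once["effect_allele"],
                                once["other_allele"], once["eaf_out"],
                                once["beta_out"], once["se_out"])
        twice = harmonize(exp, realigned)
        np.testing.assert_allclose(once["beta_out"], twice["beta_out"], atol=1e-14)
        assert (twice["action"] == "kept").all()


class TestWaldRatio:
    def test_zero_outcome_gives_zero(self):
        assert wald_ratio(0.5, 0.01, 0.0, 0.05).beta == 0.0

    def test_arithmetic(self):
        est = wald_ratio(0.5, 0.01, 0.1, 0.05)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_sign_rule(self, rng):
        for _ in range(20):
            g, G = rng.normal(size=2)
            if g == 0:
                continue
            est = wald_ratio(g, 0.01, G, 0.05)
            assert np.sign(est.beta) == np.sign(g) * np.sign(G)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.05)


class TestIvw:
    def test_single_pair_equals_wald_ratio(self, small_pairs):
        one = small_pairs.iloc[:1]
        est = ivw(one)
        wald = wald_ratio(one["beta_exp"].iloc[0], one["se_exp"].iloc[0],
                          one["beta_out"].iloc[0], one["se_out"].iloc[0])
        assert est.beta == pytest.approx(wald.beta, abs=1e-14)
        assert est.se == pytest.approx(wald.se, abs=1e-14)

    def test_duplicated_pair_halves_variance(self, small_pairs):
        one = small_pairs.iloc[:1]
        two = pd.concat([one, one.assign(variant_id="dup")], ignore_index=True)
        assert ivw(two, model="fixed").beta == pytest.approx(ivw(one).beta, abs=1e-14)
        assert ivw(two, model="fixed").se == pytest.approx(ivw(one).se / np.sqrt(2), abs=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_zero_intercept_wls_oracle(self, seed):
        pairs = random_pairs(seed)
        w = (1.0 / pairs["se_out"] ** 2).tolist()
        slope = wls_zero_intercept_slope(pairs["beta_exp"].tolist(),
                                         pairs["beta_out"].tolist(), w)
        assert ivw(pairs).beta == pytest.approx(slope, abs=1e-10)

    def test_random_effects_never_tighter_than_fixed(self, small_pairs):
        assert ivw(small_pairs, model="random").se >= ivw(small_pairs, model="fixed").se

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ivw(random_pairs(0).iloc[:0])


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_middle_ratio(self):
        theta = np.array([0.1, 0.5, 0.3, 0.9, 0.2])
        w = np.ones(5)
        assert _weighted_median_point(theta, w) == pytest.approx(0.3)

    def test_five_pair_instance_matches_hand_interpolation(self):
        theta = [0.10, 0.20, 0.35, 0.50, 0.80]
        w = [1.0, 3.0, 2.0, 1.5, 0.5]
        assert _weighted_median_point(np.array(theta), np.array(w)) == \
            pytest.approx(weighted_median_oracle(theta, w), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(3, 12))
        theta = rng.normal(0, 1, J)
        w = rng.uniform(0.1, 5, J)
        assert _weighted_median_point(theta, w) == \
            pytest.approx(weighted_median_oracle(list(theta), list(w)), abs=1e-12)

    def test_too_few_pairs_rejected(self, small_pairs):
        with pytest.raises(ValueError):
            weighted_median(small_pairs.iloc[:2])

    def test_deterministic_given_seed(self, small_pairs):
        a = weighted_median(small_pairs, n_boot=50, seed=1)
        b = weighted_median(small_pairs, n_boot=50, seed=1)
        assert a.se == b.se


class TestWeightedMode:
    def test_identical_ratios_returned_exactly(self):
        pairs, _ = simulate_summary_pairs(n_variants=5, theta=0.4, se_out=0.03, seed=1)
        pairs["beta_out"] = 0.4 * pairs["beta_exp"]  # all ratios exactly 0.4
        est = weighted_mode(pairs, n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.4, abs=1e-12)

    def test_plurality_cluster_wins(self):
        theta = np.array([0.2, 0.21, 0.19, 0.2, 0.22, 0.18, 0.2, 1.0, 1.02])
        w = np.ones_like(theta)
        assert _weighted_mode_point(theta, w) == pytest.approx(0.2, abs=0.05)

    def test_density_maximum_matches_grid_oracle(self, rng):
        theta = rng.normal(0.3, 0.2, 9)
        w = rng.uniform(0.5, 2, 9)
        h = _silverman_bandwidth(theta, 1.0)
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 20001)
        dens = [sum(wi * np.exp(-0.5 * ((x - ti) / h) ** 2)
                    for ti, wi in zip(theta, w)) for x in grid]
        oracle = grid[int(np.argmax(dens))]
        assert _weighted_mode_point(theta, w) == pytest.approx(oracle, abs=2 * (grid[1] - grid[0]) + 1e-3)


class TestMrEgger:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_oracle(self, seed):
        pairs = random_pairs(seed)
        est = mr_egger(pairs)
        flip = np.sign(pairs["beta_exp"])
        x = (pairs["beta_exp"] * flip).tolist()
        y = (pairs["beta_out"] * flip).tolist()
        w = (1.0 / pairs["se_out"] ** 2).tolist()
        a, b = wls_with_intercept(x, y, w)
        assert est.beta == pytest.approx(b, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(a, abs=1e-10)

    def test_two_pairs_refused(self, small_pairs):
        with pytest.raises(ValueError):
            mr_egger(small_pairs.iloc[:2])

    def test_intercept_zero_constraint_recovers_ivw(self, small_pairs):
        # the zero-intercept WLS slope both defines IVW and is Egger's limit
        w = (1.0 / small_pairs["se_out"] ** 2).tolist()
        slope = wls_zero_intercept_slope(small_pairs["beta_exp"].tolist(),
                                         small_pairs["beta_out"].tolist(), w)
        assert ivw(small_pairs, model="fixed").beta == pytest.approx(slope, abs=1e-12)


class TestMrPresso:
    def test_corrected_equals_ivw_on_unflagged(self):
        pairs, _ = simulate_summary_pairs(n_variants=12, theta=0.2, seed=3)
        pairs.loc[5, "beta_out"] += 8 * pairs.loc[5, "se_out"]
        res = mr_presso(pairs, n_sim=500, seed=0)
        assert res.outliers  # the 8-SE shift must be flagged
        keep = pairs[~pairs["variant_id"].isin(res.outliers)]
        assert res.corrected.beta == pytest.approx(ivw(keep).beta, abs=1e-14)
        assert res.corrected.se == pytest.approx(ivw(keep).se, abs=1e-14)

    def test_too_few_pairs_rejected(self, small_pairs):
        with pytest.raises(ValueError):
            mr_presso(small_pairs.iloc[:3])

    def test_deterministic_given_seed(self, small_pairs):
        a = mr_presso(small_pairs, n_sim=200, seed=5)
        b = mr_presso(small_pairs, n_sim=200, seed=5)
        assert a.global_p == b.global_p
        assert a.outliers == b.outliers


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, -3.0])
    def test_rescaling_exposure_rescales_estimates(self, c, small_pairs):
        scaled = small_pairs.copy()
        scaled["beta_exp"] = small_pairs["beta_exp"] * c
        scaled["se_exp"] = small_pairs["se_exp"] * abs(c)
        for fn in (lambda p: ivw(p).beta,
                   lambda p: weighted_median(p, n_boot=10, seed=0).beta,
                   lambda p: mr_egger(p).beta,
                   lambda p: weighted_mode(p, n_boot=10, seed=0).beta):
            assert fn(scaled) == pytest.approx(fn(small_pairs) / c, rel=1e-6)


class TestOneSample:
    def test_zero_weights_rejected(self):
        cohort, _ = simulate_cohort(SimCohortConfig(n_individuals=500, n_variants=5, seed=1))
        with pytest.raises(ValueError, match="degenerate"):
            one_sample_mr(cohort.pheno, cohort.genotypes,
                          list(cohort.genotypes.columns[:3]), np.zeros(3))

    def test_missing_instrument_column_rejected(self):
        cohort, _ = simulate_cohort(SimCohortConfig(n_individuals=500, n_variants=5, seed=1))
        with pytest.raises(KeyError):
            one_sample_mr(cohort.pheno, cohort.genotypes, ["nope"], np.ones(1))

    def test_null_ci_covers_one(self):
        covered = 0
        for seed in range(60):
            cfg = SimCohortConfig(n_individuals=2_000, n_variants=8, ld_rho=0.0,
                                  ld_block_size=1, causal_logOR=0.0,
                                  variant_effects=tuple([0.3] * 8), seed=seed)
            cohort, _ = simulate_cohort(cfg)
            est = one_sample_mr(cohort.pheno, cohort.genotypes,
                                list(cohort.genotypes.columns), np.ones(8))
            covered += est.ci_low <= 0 <= est.ci_high
        assert covered >= 0.90 * 60

    def test_protective_effect_detected(self):
        below = 0
        for seed in range(40):
            cfg = SimCohortConfig(n_individuals=15_000, n_variants=10, ld_rho=0.0,
                                  ld_block_size=1, causal_logOR=-0.16, h2=0.25,
                                  variant_effects=tuple([0.3] * 10), seed=100 + seed)
            cohort, _ = simulate_cohort(cfg)
            est = one_sample_mr(cohort.pheno, cohort.genotypes,
                                list(cohort.genotypes.columns), np.ones(10))
            below += est.odds_ratio < 1
        assert below >= 0.95 * 40


class TestBidirectional:
    @staticmethod
    def _study(seed):
        eff = [0.35] * 12 + [0.0] * 12
        cfg = SimCohortConfig(
            n_individuals=20_000, n_variants=24, ld_rho=0.0, ld_block_size=1,
            variant_effects=tuple(eff), h2=0.25, causal_logOR=-0.3,
            baseline_prev=0.15, pleiotropic_indices=tuple(range(12, 24)),
            pleiotropy_effect=0.25, seed=seed)
        return make_two_sample(cfg)

    def test_forward_only_causation_asymmetry(self):
        fwd_hits, rev_nulls, used = 0, 0, 0
        for seed in range(10):
            exp, out, _ = self._study(seed)
            cfg = SimCohortConfig(n_individuals=4_000, n_variants=24, ld_rho=0.0,
                                  ld_block_size=1, seed=999 + seed)
            from trialmr import simulate_genotypes
            ref, _ = simulate_genotypes(cfg)
            panels = bidirectional(exp, out, ref, methods=("ivw",), seed=seed)
            if "forward" not in panels or "reverse" not in panels:
                continue
            used += 1
            f, r = panels["forward"]["ivw"], panels["reverse"]["ivw"]
            fwd_hits += not (f.ci_low <= 0 <= f.ci_high)
            rev_nulls += r.ci_low <= 0 <= r.ci_high
        assert used >= 8
        assert fwd_hits >= 0.8 * used
        assert rev_nulls >= 0.8 * used

    def test_swapping_files_swaps_panels(self):
        exp, out, _ = self._study(42)
        from trialmr import simulate_genotypes
        ref, _ = simulate_genotypes(SimCohortConfig(n_individuals=4_000, n_variants=24,
                                                    ld_rho=0.0, ld_block_size=1, seed=5))
        a = bidirectional(exp, out, ref, methods=("ivw",), seed=0)
        b = bidirectional(out, exp, ref, r2_forward=0.001, r2_reverse=0.01,
                          methods=("ivw",), seed=0)
        assert a["forward"]["ivw"].beta == pytest.approx(b["reverse"]["ivw"].beta, abs=1e-12)
        assert a["reverse"]["ivw"].beta == pytest.approx(b["forward"]["ivw"].beta, abs=1e-12)
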