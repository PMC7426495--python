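"""Cross-validation harness: metrics, scheme behaviour, LOPO, size sweeps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtgp.crossval import (
    CVScheme,
    leave_one_population_out,
    monte_carlo_cv,
    predictive_ability_and_bias,
    training_size_sweep,
)
from mtgp.grm import GRM
from mtgp.simulate import SimConfig, simulate_breeding_values, simulate_genotypes, vanraden_grm

from .conftest import make_blup_data


def _fast_mt(name, secondary="secondary", iterations=15, seed=0):
    return CVScheme(
        name=name, secondary=secondary, n_iterations=iterations, base_seed=seed,
        n_iter_gibbs=1200, burn_in=400,
    )


class TestMetric:
    def test_identity_is_perfect_and_unbiased(self):
        r, b = predictive_ability_and_bias([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r, b) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_halved_gebvs_double_the_slope(self):
        obs = np.array([1.0, 2.0, 3.0, 5.0])
        r, b = predictive_ability_and_bias(0.5 * obs, obs)
        assert r == pytest.approx(1.0)
        assert b == pytest.approx(2.0)

    def test_hand_computed_example(self):
        r, b = predictive_ability_and_bias([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert b == pytest.approx(0.6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            predictive_ability_and_bias([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            predictive_ability_and_bias([1.0, 2.0], [1.0, 2.0])


class TestSchemeValidation:
    def test_mt_scheme_requires_secondary(self):
        with pytest.raises(ValueError, match="secondary"):
            CVScheme(name="MT-CV2")

    def test_unknown_scheme_and_bad_fraction(self):
        with pytest.raises(ValueError):
            CVScheme(name="CV9")
        with pytest.raises(ValueError):
            CVScheme(name="ST-CV1", train_fraction=1.2)

    def test_trait_mismatch_rejected_before_fitting(self):
        Y, K, _ = make_blup_data(30, seed=0)
        with pytest.raises(ValueError, match="not in BLUP table"):
            monte_carlo_cv(Y, K, "missing_trait", CVScheme(name="ST-CV1"))


class TestMonteCarloCV:
    def test_null_heritability_gives_null_ability(self):
        # iterations reuse one phenotype realization, so each noise vector
        # carries a conditional bias of order 1/sqrt(n); average over
        # independent noise draws to test the unconditional null
        rng = np.random.default_rng(1)
        _, K, _ = make_blup_data(120, seed=1)
        rep_means = []
        for rep in range(8):
            blups = pd.DataFrame(
                {"primary": rng.standard_normal(120)}, index=K.sample_ids
            )
            scheme = CVScheme(name="ST-CV1", n_iterations=15, base_seed=2 + rep)
            rep_means.append(monte_carlo_cv(blups, K, "primary", scheme).mean)
        sem = np.std(rep_means, ddof=1) / np.sqrt(len(rep_means))
        assert abs(np.mean(rep_means)) < 2 * sem + 0.02

    def test_same_seed_reproduces_bitwise(self):
        Y, K, _ = make_blup_data(80, seed=2)
        scheme = CVScheme(name="ST-CV1", n_iterations=8, base_seed=3)
        r1 = monte_carlo_cv(Y, K, "primary", scheme)
        r2 = monte_carlo_cv(Y, K, "primary", scheme)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.test_ids == r2.test_ids

    def test_splits_are_shared_across_schemes_for_pairing(self):
        Y, K, _ = make_blup_data(60, seed=3)
        st = monte_carlo_cv(Y, K, "primary", CVScheme(name="ST-CV1", n_iterations=4, base_seed=7))
        mt = monte_carlo_cv(Y, K, "primary", _fast_mt("MT-CV2", iterations=4, seed=7))
        assert st.test_ids == mt.test_ids

    def test_trait_assisted_cv2_beats_single_trait_on_correlated_traits(self):
        Y, K, _ = make_blup_data(150, h2=(0.5, 0.35), rg=0.9, seed=4)
        st = monte_carlo_cv(Y, K, "primary", CVScheme(name="ST-CV1", n_iterations=15, base_seed=11))
        mt = monte_carlo_cv(Y, K, "primary", _fast_mt("MT-CV2", iterations=15, seed=11))
        diff = mt.table["r_p"] - st.table["r_p"]
        t, p = stats.ttest_1samp(diff, 0.0, alternative="greater")
        assert p < 0.01


class TestLeaveOnePopulationOut:
    def _structured_data(self, rg=0.9, fst=0.15, seed=5, n=200):
        cfg = SimConfig(n_families=n, n_snps=1200, n_pops=5, fst=fst,
                        mean_depth=30.0, missing_rate=0.0, seed=seed)
        gm, truth = simulate_genotypes(cfg)
        K = GRM(vanraden_grm(truth.true_genotypes), gm.sample_ids)
        G0 = np.array([[1.0, rg], [rg, 1.0]])
        u = simulate_breeding_values(K.values, G0, seed=seed + 1)
        rng = np.random.default_rng(seed + 2)
        Y = u + rng.standard_normal((n, 2)) * np.sqrt([1.0, 1.857])
        blups = pd.DataFrame(Y, index=gm.sample_ids, columns=["primary", "secondary"])
        pops = pd.Series(truth.pop_labels, index=gm.sample_ids)
        return blups, K, pops

    def test_across_population_ability_lower_than_within(self):
        blups, K, pops = self._structured_data()
        st_scheme = CVScheme(name="ST-CV1", n_iterations=20, base_seed=13)
        within = monte_carlo_cv(blups, K, "primary", st_scheme)
        lopo = leave_one_population_out(blups, K, pops, "primary", st_scheme)
        assert lopo["r_p"].mean() < within.mean

    def test_no_structure_limit_matches_within_population_cv(self):
        blups, K, pops = self._structured_data(fst=0.0, seed=6)
        st_scheme = CVScheme(name="ST-CV1", n_iterations=20, base_seed=14)
        within = monte_carlo_cv(blups, K, "primary", st_scheme)
        lopo = leave_one_population_out(blups, K, pops, "primary", st_scheme)
        spread = np.hypot(within.se, lopo["r_p"].std(ddof=1) / np.sqrt(len(lopo)))
        assert abs(lopo["r_p"].mean() - within.mean) < 2 * spread + 0.05

    def test_trait_assisted_prediction_rescues_across_population_folds(self):
        blups, K, pops = self._structured_data()
        st = leave_one_population_out(
            blups, K, pops, "primary", CVScheme(name="ST-CV1", base_seed=15)
        )
        mt = leave_one_population_out(
            blups, K, pops, "primary", _fast_mt("MT-CV2", seed=15)
        )
        merged = st.merge(mt, on="population", suffixes=("_st", "_mt"))
        assert (merged["r_p_mt"] > merged["r_p_st"]).sum() >= 4

    def test_small_population_skipped(self):
        blups, K, pops = self._structured_data(n=60, seed=7)
        pops.iloc[:2] = "tiny"
        pops.iloc[2:31] = "A"
        pops.iloc[31:] = "B"
        res = leave_one_population_out(
            blups, K, pops, "primary", CVScheme(name="ST-CV1", base_seed=16)
        )
        assert set(res["population"]) == {"A", "B"}


class TestTrainingSizeSweep:
    def test_ability_non_decreasing_in_training_size(self):
        Y, K, _ = make_blup_data(200, h2=(0.5, 0.35), rg=0.5, seed=8)
        scheme = CVScheme(name="ST-CV1", base_seed=17)
        res = training_size_sweep(
            Y, K, "primary", scheme, fractions=[0.1, 0.3, 0.6, 1.0], n_replicates=25
        )
        g = res.groupby("fraction")["r_p"].agg(["mean", "sem"])
        for (f_lo, lo), (f_hi, hi) in zip(g.iterrows(), list(g.iterrows())[1:]):
            assert hi["mean"] >= lo["mean"] - 2 * np.hypot(lo["sem"], hi["sem"])

    def test_full_pool_matches_monte_carlo_cv_at_080(self):
        Y, K, _ = make_blup_data(150, h2=(0.5, 0.35), rg=0.5, seed=9)
        scheme = CVScheme(name="ST-CV1", base_seed=18, n_iterations=30)
        res = training_size_sweep(
            Y, K, "primary", scheme, fractions=[1.0], test_fraction=0.2, n_replicates=30
        )
        cv80 = monte_carlo_cv(
            Y, K, "primary", CVScheme(name="ST-CV1", train_fraction=0.8, n_iterations=30, base_seed=18)
        )
        spread = np.hypot(res["r_p"].std(ddof=1) / np.sqrt(30), cv80.se)
        assert abs(res["r_p"].mean() - cv80.mean) < 2 * spread + 0.02

    def test_highly_correlated_secondary_tolerates_smaller_training_sets(self):
        """The training size at which the CV2 curve first drops clearly
        below its full-size value is smaller when the secondary trait is
        strongly correlated (more of the training set can be sacrificed)."""
        drop_points = {}
        for rg in (0.5, 0.9):
            Y, K, _ = make_blup_data(150, h2=(0.5, 0.35), rg=rg, seed=10)
            sch = _fast_mt("MT-CV2", seed=19)
            res = training_size_sweep(
                Y, K, "primary", sch, fractions=[0.2, 0.4, 0.6, 0.8, 1.0], n_replicates=8
            )
            g = res.groupby("fraction")["r_p"].mean()
            full = g.loc[1.0]
            below = g.index[g < full - 0.02]
            drop_points[rg] = below.max() if len(below) else 0.0
        assert drop_points[0.9] <= drop_points[0.5]

    def test_too_small_sizes_skipped(self):
        Y, K, _ = make_blup_data(60, seed=11)
        scheme = CVScheme(name="ST-CV1", base_seed=20)
        res = training_size_sweep(
            Y, K, "primary", scheme, fractions=[0.05, 1.0], n_replicates=2
        )
        assert set(res["fraction"]) == {1.0}
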