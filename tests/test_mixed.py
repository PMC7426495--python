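"""Stage-1 REML: closed-form oracles, invariances, heritability, correlations."""

import numpy as np
import pandas as pd
import pytest

from mtgp.grm import GRM
from mtgp.mixed import (
    HalfSibTrialModel,
    blup_correlation,
    fit_stage1,
    genomic_heritability,
)
from mtgp.simulate import SimConfig, simulate_study

from .oracles import oneway_anova_reml


def _oneway_table(f=30, r=4, sigma_g=2.0, sigma_e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(f) * sigma_g
    rows = []
    for i in range(f):
        for rep in range(r):
            rows.append((f"F{i + 1:04d}", rep + 1, 10.0 + g[i] + rng.standard_normal() * sigma_e))
    return pd.DataFrame(rows, columns=["family", "replicate", "value"])


class TestRemlOracles:
    def test_balanced_oneway_matches_anova_closed_form(self):
        df = _oneway_table()
        groups = [g["value"].to_numpy() for _, g in df.groupby("family")]
        sg_ref, se_ref = oneway_anova_reml(groups)
        res = HalfSibTrialModel(df).fit()
        assert res.converged
        assert res.params["family"] == pytest.approx(sg_ref, abs=1e-6)
        assert res.params["resid"] == pytest.approx(se_ref, abs=1e-6)

    def test_loglik_matches_dense_v_reml(self):
        """MME-based restricted likelihood equals the textbook dense-V form."""
        df = _oneway_table(f=8, r=3, seed=3)
        model = HalfSibTrialModel(df)
        theta = np.array([1.7, 0.9])
        state = model._solve_mme(theta)
        X, y = model.X, model.y
        Z = model.Z[0].toarray()
        V = theta[0] * Z @ Z.T + theta[1] * np.eye(len(y))
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
        ref = -0.5 * (
            np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + y @ P @ y
        )
        assert state["loglik"] == pytest.approx(ref, abs=1e-9)

    def test_null_family_variance_pins_at_bound_and_shrinks_blups(self):
        # seed chosen so the moment estimator (MSB - MSW)/r is negative,
        # i.e. the unconstrained REML optimum lies outside the space
        for seed in range(20):
            df = _oneway_table(f=40, r=3, sigma_g=0.0, sigma_e=1.0, seed=seed)
            groups = [g["value"].to_numpy() for _, g in df.groupby("family")]
            if oneway_anova_reml(groups)[0] < 0:
                break
        res = HalfSibTrialModel(df).fit()
        vary = df["value"].var()
        assert res.params["family"] <= 1.01e-8 * vary
        assert res.blups.abs().max() < 0.05 * df["value"].std()


class TestInvariances:
    def test_record_order_and_label_invariance(self):
        cfg = SimConfig(n_families=40, n_snps=300, n_measures=2, n_reps=2, seed=6)
        study = simulate_study(cfg)
        d = study.plots[study.plots.trait == "T1"]
        K = GRM(study.kinship_true, study.genotypes.sample_ids)
        res1 = HalfSibTrialModel(d, grm=K).fit()
        shuffled = d.sample(frac=1.0, random_state=1)
        res2 = HalfSibTrialModel(shuffled, grm=K).fit()
        # identical optima up to the REML convergence tolerance
        assert np.allclose(res1.params, res2.params, rtol=1e-3, atol=1e-6)
        relabeled = d.assign(location=d["location"].map({"L1": "siteB", "L2": "siteA"}))
        res3 = HalfSibTrialModel(relabeled, grm=K).fit()
        assert np.allclose(res1.params, res3.params, rtol=1e-3, atol=1e-6)
        pd.testing.assert_series_equal(res1.blups, res3.blups, rtol=1e-2, atol=1e-4)

    def test_identity_grm_equals_unstructured_fit(self):
        df = _oneway_table(f=25, r=3, seed=7)
        fams = sorted(df["family"].unique())
        res_plain = HalfSibTrialModel(df).fit()
        res_ident = HalfSibTrialModel(df, grm=GRM(np.eye(25), fams)).fit()
        assert np.allclose(res_plain.params, res_ident.params, rtol=1e-6)
        pd.testing.assert_series_equal(
            res_plain.blups.sort_index(), res_ident.blups.sort_index(), rtol=1e-6
        )

    def test_blups_sum_to_zero(self):
        df = _oneway_table(f=30, r=3, seed=8)
        res = HalfSibTrialModel(df).fit()
        assert abs(res.blups.mean()) < 1e-6 * res.blups.std()


class TestGenomicHeritability:
    def test_hand_arithmetic_example(self):
        vc = {"family": 4.0, "gs": 2.0, "gm": 1.0, "resid": 6.0}
        assert genomic_heritability(vc, s=2, m=10, b=3) == pytest.approx(4.0 / 5.2)
        assert genomic_heritability(vc, s=2, m=10, b=3) == pytest.approx(0.76923, abs=1e-5)

    def test_noise_free_limit_is_one(self):
        vc = {"family": 3.0, "gs": 0.0, "gm": 0.0, "resid": 0.0}
        assert genomic_heritability(vc, s=2, m=10, b=3) == 1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            genomic_heritability({"family": 0.0, "resid": 0.0}, s=1, m=1, b=1)


class TestTrialRecovery:
    def test_yield_trial_variance_components_recovered(self):
        """Components in the magnitude regime of a multi-harvest yield trial
        (family 10.09, family×location 6.74, family×measure 1.18, h2 0.65)
        are recovered within 15% by the full plot-model REML."""
        target = {"family": 10.09, "gs": 6.74, "gm": 1.18}
        s, m, b = 2, 2, 3
        denom = target["family"] / 0.65
        resid = (denom - target["family"] - target["gs"] / s - target["gm"] / m) * (s * m * b)
        env = {"gs": 6.74, "gm": 1.18, "rep": 1.0, "row": 1.0, "col": 1.0, "resid": resid}
        cfg = SimConfig(
            n_families=463, n_snps=1500, n_traits=1,
            G0_true=np.array([[10.09]]), env_vc={k: np.array([v]) for k, v in env.items()},
            n_locations=s, n_measures=m, n_reps=b, mean_depth=20.0, missing_rate=0.0,
            seed=42,
        )
        study = simulate_study(cfg)
        K = GRM(study.kinship_true, study.genotypes.sample_ids)
        res = HalfSibTrialModel(study.plots, grm=K).fit()
        assert res.converged
        realized = study.plots.attrs["realized_vc"]
        u = study.breeding_values["T1"].to_numpy()
        # under g ~ N(0, K sigma2_g) the realized scale is u' K^{-1} u / n
        realized_g = float(u @ np.linalg.solve(study.kinship_true, u) / len(u))
        # family and family×location estimates are negatively correlated
        # (they trade off within a location); each is loosely bounded while
        # their sum is recovered tightly
        refs = {"family": realized_g, "gs": float(realized["gs"][0]),
                "gm": float(realized["gm"][0])}
        for name, ref in refs.items():
            assert res.params[name] == pytest.approx(ref, rel=0.25, abs=0.3)
        assert res.params["family"] + res.params["gs"] == pytest.approx(
            refs["family"] + refs["gs"], rel=0.10
        )
        assert res.params["resid"] == pytest.approx(float(realized["resid"][0]), rel=0.05)
        assert res.genomic_heritability() == pytest.approx(0.65, abs=0.07)

    def test_stage1_blup_table_and_correlation(self):
        cfg = SimConfig.from_heritability(
            [0.5, 0.4], rg=0.8, n_families=120, n_snps=800,
            n_locations=2, n_measures=1, n_reps=3, seed=13,
        )
        study = simulate_study(cfg)
        K = GRM(study.kinship_true, study.genotypes.sample_ids)
        table, results = fit_stage1(study.plots, grm=K)
        assert set(table.columns) == {"T1", "T2"}
        assert len(table) == 120
        # BLUPs track the true breeding values
        r = np.corrcoef(table["T1"], study.breeding_values["T1"])[0, 1]
        assert r > 0.6
        # with independent plot errors per trait the correlation of
        # independently fitted BLUPs attenuates to rg * sqrt(h2_x * h2_y)
        rg_hat = blup_correlation(table, "T1", "T2")
        assert rg_hat == pytest.approx(0.8 * np.sqrt(0.5 * 0.4), abs=0.15)


class TestBlupCorrelation:
    def test_identity_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        t = pd.DataFrame({"a": x, "b": x, "c": -x})
        assert blup_correlation(t, "a", "b") == pytest.approx(1.0)
        assert blup_correlation(t, "a", "c") == pytest.approx(-1.0)

    def test_pairwise_deletion(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, np.nan], "b": [2.0, 4.0, 6.0, np.nan, 5.0]})
        assert blup_correlation(t, "a", "b") == pytest.approx(1.0)

    def test_errors(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="fewer than 3"):
            blup_correlation(t, "a", "b")
        t2 = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero variance"):
            blup_correlation(t2, "a", "b")


class TestChecks:
    def test_check_families_excluded_from_blups(self):
        df = _oneway_table(f=20, r=3, seed=9)
        chk = df["family"].isin(["F0001", "F0002"])
        df = df.assign(check=chk)
        res = HalfSibTrialModel(df).fit()
        assert "F0001" not in res.blups.index
        assert any(name.startswith("check[") for name in res.fe.index)
        assert len(res.blups) == 18
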