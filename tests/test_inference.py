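import numpy as np
import pandas as pd
import pytest

from remindbias.inference import (HYPOTHESIS_IDS, HYPOTHESES, ModelSpec,
                                  correlation_test,
                                  directional_signs, fit_ols,
                                  headline_outcomes, indirect_effect,
                                  mediate_bootstrap, one_sample_t,
                                  render_report, run_all, run_hypothesis,
                                  zscore_nonbinary)
from remindbias.simulate import simulate_mediation_scores


class TestZScore:
    def test_standardises_nonbinary(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        z = zscore_nonbinary(df)
        assert z.x.mean() == pytest.approx(0.0)
        assert z.x.std(ddof=1) == pytest.approx(1.0)

    def test_binary_untouched(self):
        df = pd.DataFrame({"b": [0, 1, 0, 1], "x": [1.0, 2.0, 3.0, 4.0]})
        z = zscore_nonbinary(df)
        assert list(z.b) == [0, 1, 0, 1]
        assert z.x.std(ddof=1) == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_nonbinary(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))

    def test_non_numeric_passthrough(self):
        df = pd.DataFrame({"g": ["a", "b", "a"], "x": [1.0, 2.0, 3.0]})
        assert list(zscore_nonbinary(df).g) == ["a", "b", "a"]


class TestElementaryTests:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, p = correlation_test(x, -x, "pearson", "less")
        assert r == pytest.approx(-1.0)
        assert p < 1e-6

    def test_spearman_invariant_to_monotone_transform(self):
        x = np.linspace(0.1, 3, 20)
        rho, _ = correlation_test(x, np.exp(x), "spearman", "greater")
        assert rho == pytest.approx(1.0)

    def test_one_sided_p_is_half_two_sided(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r2, p2 = correlation_test(x, y, "pearson", "two_sided")
        alt = "greater" if r2 > 0 else "less"
        _, p1 = correlation_test(x, y, "pearson", alt)
        assert p1 == pytest.approx(p2 / 2)

    def test_correlation_requires_variation(self):
        with pytest.raises(ValueError):
            correlation_test([1, 1, 1], [1, 2, 3])

    def test_t_exact_null_symmetric_sample(self):
        mean, t, p, d = one_sample_t([-2.0, -1.0, 1.0, 2.0], "greater")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_t_effect_direction(self, rng):
        x = 3.0 + 0.01 * rng.normal(size=30)
        mean, t, p, d = one_sample_t(x, "greater")
        assert d > 0 and p < 1e-10
        assert d == pytest.approx(mean / x.std(ddof=1))

    def test_t_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0])


def _covariate_frame(n, rng):
    return pd.DataFrame({
        "age": rng.integers(18, 70, n).astype(float),
        "gender": rng.choice(["male", "female", "other"], n, p=[.6, .37, .03]),
        "education": rng.integers(1, 10, n).astype(float),
    })


class TestFitOLS:
    def test_noiseless_identity(self, rng):
        """An outcome that is exactly 0.5 * z(CIT) is fitted perfectly:
        R-squared is 1 and the raw-scale coefficient is recovered (the
        z-scored outcome carries standardised beta 1, which maps back to
        0.5 through the outcome SD)."""
        n = 200
        df = _covariate_frame(n, rng)
        df["cit"] = rng.normal(size=n)
        df["ad"] = rng.normal(size=n)
        zc = (df.cit - df.cit.mean()) / df.cit.std(ddof=1)
        df["y"] = 0.5 * zc
        res = fit_ols(ModelSpec("y", ["cit", "ad"],
                                covariates=["age", "gender", "education"]), df)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        beta_raw = res.term("cit")["beta"] * df.y.std(ddof=1)
        assert beta_raw == pytest.approx(0.5, abs=1e-10)
        assert res.term("ad")["beta"] == pytest.approx(0.0, abs=1e-10)
        assert res.df_resid == res.n - 7  # const, cit, ad, age, 2 dummies, edu

    def test_standardisation_invariance(self, rng):
        """Fitting z-scored data equals fitting raw data and standardising
        the coefficient afterwards (no-interaction models)."""
        n = 300
        df = _covariate_frame(n, rng)
        df["cit"] = rng.normal(2.0, 3.0, n)
        df["ad"] = rng.normal(-1.0, 0.5, n)
        df["y"] = (1.3 * df.cit - 0.7 * df.ad + 0.05 * df.age
                   + rng.normal(0, 2.0, n))
        spec = ModelSpec("y", ["cit", "ad"],
                         covariates=["age", "gender", "education"])
        res = fit_ols(spec, df)
        import statsmodels.api as sm
        X = pd.DataFrame({
            "cit": df.cit, "ad": df.ad, "age": df.age,
            "gender[female]": (df.gender == "female").astype(float),
            "gender[other]": (df.gender == "other").astype(float),
            "education": df.education,
        })
        raw = sm.OLS(df.y, sm.add_constant(X)).fit()
        manual = raw.params["cit"] * df.cit.std(ddof=1) / df.y.std(ddof=1)
        assert res.term("cit")["beta"] == pytest.approx(manual, abs=1e-8)

    def test_interaction_of_zscored_mains(self, rng):
        n = 400
        df = _covariate_frame(n, rng)
        df["m"] = rng.normal(size=n)
        df["cit"] = rng.normal(size=n)
        df["ad"] = rng.normal(size=n)
        zm = (df.m - df.m.mean()) / df.m.std(ddof=1)
        zc = (df.cit - df.cit.mean()) / df.cit.std(ddof=1)
        df["y"] = 0.3 * zm * zc + rng.normal(0, 0.01, n)
        spec = ModelSpec("y", ["m", "cit", "ad"],
                         interactions=[("m", "cit")],
                         covariates=["age", "gender", "education"])
        res = fit_ols(spec, df)
        beta = res.term("m:cit")["beta"]
        # outcome is z-scored, so the planted coefficient shrinks by sd(y)
        assert beta == pytest.approx(0.3 / df.y.std(ddof=1), rel=0.05)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("y", ["y", "x"]).validate()
        with pytest.raises(ValueError):
            ModelSpec("y", ["a"], interactions=[("a", "b")]).validate()

    def test_rank_deficiency_rejected(self, rng):
        n = 50
        df = _covariate_frame(n, rng)
        df["cit"] = rng.normal(size=n)
        df["ad"] = df.cit  # perfectly collinear
        with pytest.raises(ValueError, match="rank"):
            fit_ols(ModelSpec("age", ["cit", "ad"]), df)


class TestHypothesisBattery:
    def test_id_enumeration(self):
        assert set(HYPOTHESES) == set(HYPOTHESIS_IDS)
        assert HYPOTHESIS_IDS == (
            "H1", "H2", "H3", "H4", "H5a", "H5b", "H5c", "H5d", "H5e",
            "H6a", "H6b", "H6c", "H7a", "H7b", "H7c", "H8a", "H8b", "H8c")

    def test_unknown_id_rejected(self, analysis_table):
        with pytest.raises(KeyError):
            run_hypothesis("H9", analysis_table)

    def test_h1_uses_unconfounded_split_half_biases(self, analysis_table):
        res = run_hypothesis("H1", analysis_table)
        r_uncf = np.corrcoef(analysis_table.bias_meta_uncf,
                             analysis_table.bias_rem_uncf)[0, 1]
        assert res.estimate == pytest.approx(r_uncf)
        assert res.alternative == "less"

    def test_sanity_checks_recover_planted_structure(self, analysis_table):
        """On a default (calibrated) cohort the four replication checks all
        come out as in the original study."""
        h1 = run_hypothesis("H1", analysis_table)
        h2 = run_hypothesis("H2", analysis_table)
        h4 = run_hypothesis("H4", analysis_table)
        assert h1.estimate < 0
        assert h2.estimate > 0  # pro-reminder bias planted
        assert h4.estimate > 0 and h4.p < 0.01  # compensatory use

    def test_regressions_report_focal_term(self, analysis_table):
        r5 = run_hypothesis("H5a", analysis_table)
        r8 = run_hypothesis("H8a", analysis_table)
        assert r5.term == "cit" and r8.term == "ad"
        assert r5.kind == "regression" and r5.se is not None
        r7 = run_hypothesis("H7a", analysis_table)
        assert r7.term == "bias_meta_uncf:cit"


class TestMediation:
    def test_product_of_coefficients(self):
        assert indirect_effect(0.15, -0.19) == pytest.approx(-0.0285, abs=1e-12)

    def test_decomposition_and_point_product(self, analysis_table):
        med = mediate_bootstrap(analysis_table, n_boot=50, seed=4)
        assert med.indirect_point == pytest.approx(med.path_a * med.path_b)
        assert med.total_effect == pytest.approx(
            med.direct_effect + med.indirect_point, abs=1e-8)

    def test_bootstrap_deterministic_under_seed(self, analysis_table):
        a = mediate_bootstrap(analysis_table, n_boot=100, seed=9)
        b = mediate_bootstrap(analysis_table, n_boot=100, seed=9)
        c = mediate_bootstrap(analysis_table, n_boot=100, seed=10)
        assert (a.ci_low, a.ci_high, a.acme_boot_mean) == \
            (b.ci_low, b.ci_high, b.acme_boot_mean)
        assert a.ci_low != c.ci_low

    def test_score_level_generator_plants_known_acme(self):
        """The score-level mediation generator's standardised indirect
        effect equals a*b = -0.03 by construction (checked at n=40000)."""
        tab = simulate_mediation_scores(40_000, np.random.default_rng(3))
        med = mediate_bootstrap(tab, n_boot=2, seed=0)
        assert med.indirect_point == pytest.approx(-0.03, abs=0.004)
        assert med.path_a == pytest.approx(0.15, abs=0.015)

    def test_null_mediator_gives_covering_interval(self):
        tab = simulate_mediation_scores(800, np.random.default_rng(8), b=0.0)
        med = mediate_bootstrap(tab, n_boot=300, seed=8)
        assert med.ci_low <= 0.0 <= med.ci_high

    def test_p_value_methods(self, analysis_table):
        ci = mediate_bootstrap(analysis_table, n_boot=100, seed=1, p_method="ci")
        prop = mediate_bootstrap(analysis_table, n_boot=100, seed=1,
                                 p_method="proportion")
        assert ci.p_boot >= 2.0 / 100  # CI inversion is floored
        assert prop.p_boot <= ci.p_boot

    def test_invalid_nboot(self, analysis_table):
        with pytest.raises(ValueError):
            mediate_bootstrap(analysis_table, n_boot=0)


class TestRunAll:
    def test_bundle_enumeration_and_determinism(self, analysis_table):
        a = run_all(analysis_table, n_boot=60, seed=2, timestamp=False)
        b = run_all(analysis_table, n_boot=60, seed=2, timestamp=False)
        assert set(a.hypotheses) == set(HYPOTHESIS_IDS)
        assert len(a.hypotheses) == 18
        assert a.moderation_ad.term == "bias_meta_uncf:ad"
        assert a.to_dict() == b.to_dict()

    def test_bundle_serialises(self, analysis_table, tmp_path):
        bundle = run_all(analysis_table, n_boot=30, seed=0)
        bundle.to_json(tmp_path / "results.json")
        import json
        payload = json.loads((tmp_path / "results.json").read_text())
        assert set(payload["hypotheses"]) == set(HYPOTHESIS_IDS)
        assert "acme_boot_mean" in payload["mediation_cit"]

    def test_headline_and_sign_helpers(self, analysis_table):
        bundle = run_all(analysis_table, n_boot=60, seed=2, timestamp=False)
        ho = headline_outcomes(bundle)
        assert set(ho) == {"cit_overconfidence", "ad_underconfidence",
                           "cit_reduced_reminder_bias", "partial_mediation",
                           "no_moderation"}
        signs = directional_signs(bundle)
        assert set(signs) == set(h for h in HYPOTHESIS_IDS
                                 if not h.startswith("H7"))

    def test_report_renders_every_hypothesis(self, analysis_table):
        bundle = run_all(analysis_table, n_boot=30, seed=0)
        text = render_report(bundle)
        for h_id in HYPOTHESIS_IDS:
            assert f"## {h_id}:" in text
        assert "Mediation" in text


class TestBuildCohortTable:
    def test_join_keeps_retained_rows_only(self, small_scores, analysis_table):
        assert len(analysis_table) < len(small_scores)
        assert {"cit", "ad", "age", "gender", "education", "icar5",
                "dprime"} <= set(analysis_table.columns)
        assert analysis_table.cit.notna().all()
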