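import numpy as np
import pytest
from pandas.testing import assert_frame_equal

from remindbias.config import SimulationConfig
from remindbias.simulate import (CohortDataset, make_fixture_cohort,
                                 sample_traits, simulate_cohort, simulate_task)


def _cfg(**kw):
    base = dict(n_participants=50, seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    @pytest.mark.parametrize("kw", [
        {"n_participants": 0},
        {"trait_corr": 1.5},
        {"acc_fi_mean": 0.9, "acc_fe_mean": 0.8},
        {"catch_fail_rate": -0.1},
        {"choice_slope_median": 0.0},
        {"planted_exclusion_rates": {"bogus": 0.1}},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw).validate()

    def test_roundtrip_and_hash(self, tmp_path):
        cfg = _cfg(seed=9)
        cfg.to_json(tmp_path / "c.json")
        back = SimulationConfig.from_json(tmp_path / "c.json")
        assert back == cfg
        assert back.config_hash() == cfg.config_hash()


class TestSampleTraits:
    def test_null_effects_give_perfect_calibration(self, rng):
        """With every effect and noise term zeroed, true confidence equals
        100*ACC_FI and the true AIP equals the implied OIP."""
        cfg = _cfg(beta_cit_meta=0, beta_ad_meta=0, beta_cit_rem_direct=0,
                   beta_meta_rem=0, meta_bias_mean=0, rem_bias_mean=0,
                   noise_meta_sd=0, noise_rem_sd=0)
        tr = sample_traits(cfg, rng)
        np.testing.assert_allclose(tr.true_confidence, 100 * tr.true_acc_fi)
        np.testing.assert_allclose(tr.true_aip,
                                   10 * tr.true_acc_fi / tr.true_acc_fe)

    def test_trait_effect_signs_recovered_at_large_n(self):
        cfg = SimulationConfig(n_participants=50_000, seed=5, trait_corr=0.0,
                               beta_cit_meta=2.0, beta_ad_meta=-2.0)
        tr = sample_traits(cfg, np.random.default_rng(5))
        assert np.corrcoef(tr.cit_latent, tr.true_meta_bias)[0, 1] > 0
        assert np.corrcoef(tr.ad_latent, tr.true_meta_bias)[0, 1] < 0

    def test_determinism(self):
        cfg = _cfg()
        a = sample_traits(cfg, np.random.default_rng(cfg.seed))
        b = sample_traits(cfg, np.random.default_rng(cfg.seed))
        assert_frame_equal(a, b)

    def test_invariant_ranges(self, rng):
        tr = sample_traits(_cfg(n_participants=500), rng)
        assert tr.true_acc_fi.between(0, 1).all()
        assert tr.true_acc_fe.between(0, 1).all()
        assert tr.true_confidence.between(0, 100).all()
        assert (tr.true_choice_slope > 0).all()
        assert set(tr.gender) <= {"male", "female", "other"}
        assert tr.education.between(1, 9).all()
        assert tr.icar5_true.between(0, 5).all()


class TestSimulateTask:
    def test_trial_structure(self, small_cohort):
        t = small_cohort.trials
        per = t.groupby("participant_id")
        assert (per.size() == 16).all()
        cond = t.groupby(["participant_id", "assigned_condition"]).size().unstack()
        assert (cond["FI"] == 4).all() and (cond["FE"] == 4).all() \
            and (cond["CO"] == 8).all()
        # every value 2-9 appears exactly twice per participant
        vals = t.groupby(["participant_id", "offered_value"]).size().unstack()
        assert (vals == 2).all().all()
        # forced conditions override the decision; CO executes it
        fi = t[t.assigned_condition == "FI"]
        fe = t[t.assigned_condition == "FE"]
        co = t[t.assigned_condition == "CO"]
        assert not fi.executed_with_reminder.any()
        assert fe.executed_with_reminder.all()
        assert (co.executed_with_reminder == (co.decision == "reminder")).all()
        # special circles only on forced trials
        assert (fi.n_special == 6).all() and (fe.n_special == 6).all()
        assert (co.n_special == 0).all() and (co.n_special_correct == 0).all()
        assert (t.n_special_correct <= t.n_special).all()

    def test_forced_values_counterbalanced_by_parity(self, small_cohort):
        t = small_cohort.trials.merge(
            small_cohort.traits[["participant_id", "parity"]], on="participant_id")
        fi = t[t.assigned_condition == "FI"]
        odd, even = {3, 5, 7, 9}, {2, 4, 6, 8}
        got0 = set(fi[fi.parity == 0].offered_value)
        got1 = set(fi[fi.parity == 1].offered_value)
        assert got0 == odd and got1 == even

    def test_step_function_choice_limit(self, weights):
        """A near-zero choice slope makes the decision a step at the AIP."""
        cfg = _cfg(n_participants=2, choice_slope_median=1e-9,
                   choice_slope_sd=0.0, noise_rem_sd=0.0, rem_bias_mean=0.0,
                   beta_meta_rem=0.0, beta_cit_rem_direct=0.0)
        rng = np.random.default_rng(0)
        tr = sample_traits(cfg, rng)
        tr["true_aip"] = 5.5
        trials = simulate_task(tr, rng)
        assert (trials.decision == np.where(trials.offered_value >= 6,
                                            "reminder", "internal")).all()

    def test_perfect_external_accuracy(self, rng):
        tr = sample_traits(
            _cfg(acc_fe_mean=1.0, acc_fe_sd=0.0,
                 planted_exclusion_rates={}), rng)
        trials = simulate_task(tr, rng)
        fe = trials[trials.assigned_condition == "FE"]
        assert (fe.n_special_correct == 6).all()

    def test_decision_override_rate_near_quarter(self, small_cohort):
        """Pseudorandom condition assignment overrides ~25% of decisions
        (half of the 8 forced trials, at ~50% reminder preference)."""
        t = small_cohort.trials
        mismatch = ((t.decision == "reminder") != t.executed_with_reminder).mean()
        assert 0.20 <= mismatch <= 0.30


class TestSimulateCohort:
    def test_row_counts(self, small_cohort):
        n = len(small_cohort.participants)
        assert len(small_cohort.trials) == 16 * n
        assert len(small_cohort.items) == 49 * n

    def test_same_seed_identical_files(self, tmp_path):
        cfg = _cfg()
        simulate_cohort(cfg, outdir=tmp_path / "a")
        simulate_cohort(cfg, outdir=tmp_path / "b")
        for name in ("trials.csv", "items.csv", "participants.csv",
                     "traits.csv", "config.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seed_differs(self):
        a = simulate_cohort(_cfg(seed=1))
        b = simulate_cohort(_cfg(seed=2))
        assert not a.trials.equals(b.trials)

    def test_zero_participants_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(_cfg(n_participants=0))

    def test_item_responses_within_likert_ranges(self, small_cohort, weights):
        merged = small_cohort.items.merge(
            weights[["item_id", "likert_min", "likert_max"]], on="item_id")
        assert (merged.response >= merged.likert_min).all()
        assert (merged.response <= merged.likert_max).all()

    def test_catch_rate_matches_config(self):
        cohort = simulate_cohort(
            _cfg(n_participants=4000, catch_fail_rate=0.25, seed=8))
        fail = (cohort.participants.catch_response != "Do not agree at all").mean()
        assert fail == pytest.approx(0.25, abs=0.03)


class TestCalibration:
    """Cohort-level summary statistics under default parameters."""

    def test_accuracy_means_bracket_study_values(self, analysis_table):
        # retained cohort: aided ~96%, unaided ~59% (+/- 5 points)
        assert 100 * analysis_table.acc_fe.mean() == pytest.approx(96.1, abs=5)
        assert 100 * analysis_table.acc_fi_all.mean() == pytest.approx(59.2, abs=5)

    def test_reminder_usage_near_half(self, small_cohort):
        usage = (small_cohort.trials.decision == "reminder").mean()
        assert usage == pytest.approx(0.499, abs=0.05)

    def test_mean_confidence_realistic(self, analysis_table):
        assert analysis_table.confidence.mean() == pytest.approx(55.6, abs=5)


class TestFixtureCohort:
    def test_shape_and_stability(self):
        a = make_fixture_cohort()
        b = make_fixture_cohort()
        assert isinstance(a, CohortDataset)
        assert len(a.participants) == 20
        assert len(a.trials) == 20 * 16
        assert_frame_equal(a.trials, b.trials)
        assert_frame_equal(a.participants, b.participants)
        assert_frame_equal(a.items, b.items)
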