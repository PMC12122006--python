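"""Configuration objects for the cohort simulator and the analysis pipeline.

The simulator emulates an online intention-offloading cohort: each participant
completes 16 trials of a delayed-intention task (4 Forced Internal, 4 Forced
External, 8 Choice-Only), gives a single prospective confidence rating, answers
49 questionnaire items generated from two correlated latent transdiagnostic
traits ('compulsive behaviour and intrusive thought', CIT, and
'anxious-depression', AD), plus demographic and ability covariates.

Default parameter values are calibrated so that a simulated cohort reproduces
the population-level summary statistics of the study the pipeline targets
(forced-external accuracy ~96%, forced-internal accuracy ~59%, mean reminder
usage ~50%, mean confidence ~56%, mean reminder bias ~+0.5 points, mean
metacognitive bias ~-3.6 percentage points, and standardised CIT/AD effects of
roughly +0.15/-0.23 on the metacognitive bias, -0.10 direct CIT effect on the
reminder bias with a -0.19 confidence-mediated path).  See docs/methods.md for
the calibration arithmetic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

#: planted per-criterion violation rates (fractions of the cohort) chosen to
#: mirror the exclusion tallies of a ~670-person online sample: 9 participants
#: with FI > FE accuracy, 22 with FE accuracy < 70%, 3 with FI accuracy < 10%,
#: and 40 with a negative value-choice correlation, out of 669.
DEFAULT_PLANTED_RATES = {
    "fi_gt_fe": 0.0135,
    "low_fe": 0.033,
    "low_fi": 0.0045,
    "neg_corr": 0.06,
}

PLANTED_KINDS = ("fi_gt_fe", "low_fe", "low_fi", "neg_corr")


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic offloading cohort.

    Effects are expressed on natural scales: metacognitive-bias effects in
    percentage points per SD of the latent trait, reminder-bias effects in
    reward points per SD (or per percentage point of metacognitive bias for
    ``beta_meta_rem``).
    """

    n_participants: int = 600
    seed: int = 0
    #: correlation between the latent CIT and AD factors
    trait_corr: float = 0.4
    #: effect of CIT on the true metacognitive bias (pp per SD)
    beta_cit_meta: float = 5.2
    #: effect of AD on the true metacognitive bias (pp per SD)
    beta_ad_meta: float = -7.8
    #: direct effect of CIT on the true reminder bias (points per SD)
    beta_cit_rem_direct: float = -0.31
    #: effect of the true metacognitive bias on the reminder bias (points/pp)
    beta_meta_rem: float = -0.030
    #: population mean of the true metacognitive bias (pp)
    meta_bias_mean: float = -3.1
    #: population mean of the true reminder bias (points)
    rem_bias_mean: float = 0.42
    #: population distribution of unaided (forced internal) accuracy
    acc_fi_mean: float = 0.595
    acc_fi_sd: float = 0.13
    #: population distribution of reminder-aided (forced external) accuracy
    acc_fe_mean: float = 0.96
    acc_fe_sd: float = 0.04
    #: psychometric choice rule: slope is log-normal with this median (points)
    choice_slope_median: float = 2.0
    #: ... and this SD on the log scale
    choice_slope_sd: float = 0.4
    #: residual SD of the true metacognitive bias (pp)
    noise_meta_sd: float = 26.0
    #: residual SD of the true reminder bias (points)
    noise_rem_sd: float = 2.3
    #: SD of the measurement noise on the single confidence rating (pp)
    conf_noise_sd: float = 2.0
    #: questionnaire item loading magnitude (fraction of the Likert half-range)
    item_loading_scale: float = 0.6
    #: questionnaire item residual SD (fraction of the Likert half-range)
    item_noise_sd: float = 0.8
    #: probability of answering the catch item incorrectly
    catch_fail_rate: float = 0.0135
    #: per-criterion planted violation rates (see DEFAULT_PLANTED_RATES)
    planted_exclusion_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_RATES)
    )
    #: if True (default), each participant's true AIP equals their own implied
    #: OIP minus their true reminder bias; if False it varies around the
    #: population-mean OIP instead, decoupling AIP from OIP so that the
    #: compensation hypothesis (H4) has a well-defined null.
    couple_aip: bool = True

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not -1.0 <= self.trait_corr <= 1.0:
            raise ValueError("trait_corr must lie in [-1, 1]")
        for name in ("acc_fi_mean", "acc_fe_mean", "catch_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.acc_fe_mean <= self.acc_fi_mean:
            raise ValueError("acc_fe_mean must exceed acc_fi_mean (reminders help)")
        for name in (
            "acc_fi_sd", "acc_fe_sd", "choice_slope_sd", "noise_meta_sd",
            "noise_rem_sd", "conf_noise_sd", "item_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.choice_slope_median <= 0:
            raise ValueError("choice_slope_median must be positive")
        extra = set(self.planted_exclusion_rates) - set(PLANTED_KINDS)
        if extra:
            raise ValueError(f"unknown planted exclusion kinds: {sorted(extra)}")
        for kind, rate in self.planted_exclusion_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"planted rate {kind} must lie in [0, 1]")
        if sum(self.planted_exclusion_rates.values()) > 1.0:
            raise ValueError("planted exclusion rates must sum to <= 1")

    @classmethod
    def null(cls, n_participants: int = 600, seed: int = 0) -> "SimulationConfig":
        """A null-effect configuration under which every hypothesis test has
        a true null.

        Every structural effect and planted violation is switched off and the
        AIP is decoupled from the OIP (see ``couple_aip``).  Two further
        adjustments keep the *measured* biases mean-zero, not just the latent
        ones: reminders are made perfectly effective (ACC_FE = 1, so the OIP
        is 10 * ACC_FI with no noisy-ratio Jensen bias) with unaided accuracy
        placing the OIP at the centre of the 2-9 value schedule (the
        threshold estimator's small-sample shrinkage toward the design centre
        is then symmetric and cannot masquerade as a reminder bias), and the
        metacognitive noise is reduced so that confidence ratings stay off
        the bounded scale's ends (a ceiling-truncated rating would otherwise
        read as underconfidence).
        """
        return cls(
            n_participants=n_participants,
            seed=seed,
            beta_cit_meta=0.0,
            beta_ad_meta=0.0,
            beta_cit_rem_direct=0.0,
            beta_meta_rem=0.0,
            meta_bias_mean=0.0,
            rem_bias_mean=0.0,
            acc_fi_mean=0.55,
            acc_fe_mean=1.0,
            acc_fe_sd=0.0,
            noise_meta_sd=10.0,
            catch_fail_rate=0.0,
            planted_exclusion_rates={k: 0.0 for k in PLANTED_KINDS},
            couple_aip=False,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        """Stable short hash of the canonical JSON form, logged with results."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
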