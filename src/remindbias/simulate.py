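"""Synthetic cohort generator for the intention-offloading analysis.

The generator produces, per participant: latent transdiagnostic traits (CIT
and AD), true task abilities and biases, 16 task trials with pre-trial
reminder decisions and binomial special-circle outcomes, a single confidence
rating, 49 factor-structured questionnaire items, a catch item, and
demographic/ability covariates.  All randomness flows from one
``numpy.random.Generator``, so a (config, seed) pair maps to byte-identical
output tables.

Structural model (per participant i, latents standard normal):

    meta_i = meta_bias_mean + beta_cit_meta*CIT_i + beta_ad_meta*AD_i + e_meta
    confidence_i = clamp(100 * acc_fi_i + meta_i, 0, 100)
    rem_i  = rem_bias_mean + beta_meta_rem*meta_i + beta_cit_rem_direct*CIT_i + e_rem
    AIP_i  = 10 * acc_fi_i / acc_fe_i - rem_i          (implied OIP minus bias)
    P(choose reminder | value v) = Phi((v - AIP_i) / slope_i)

On Forced Internal / Forced External trials the assigned condition overrides
the decision; Choice-Only trials execute the decision but end early without
special circles, so only forced trials contribute accuracy data (six special
circles each, Binomial outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .config import PLANTED_KINDS, SimulationConfig
from .factors import CATCH_CORRECT_RESPONSE, default_weights

GENDERS = ("male", "female", "other")
#: gender mix of a typical online convenience sample (male-skewed)
GENDER_PROBS = (0.625, 0.3633, 0.0117)

ODD_VALUES = (3, 5, 7, 9)
EVEN_VALUES = (2, 4, 6, 8)
CO_VALUES = tuple(range(2, 10))
CONDITIONS = ("FI", "FE", "CO")

#: a plausible wrong catch answer used for planted catch failures
CATCH_WRONG_RESPONSE = "Agree slightly"

TRIALS_COLUMNS = [
    "participant_id", "trial_index", "offered_value", "decision",
    "assigned_condition", "executed_with_reminder", "n_special",
    "n_special_correct",
]
PARTICIPANTS_COLUMNS = [
    "participant_id", "age", "gender", "education", "icar5", "dprime",
    "confidence", "catch_response",
]
ITEMS_COLUMNS = ["participant_id", "questionnaire", "item_id", "response"]


@dataclass
class CohortDataset:
    """In-memory synthetic cohort: tables plus the generating config."""

    config: SimulationConfig | None
    traits: pd.DataFrame
    trials: pd.DataFrame
    items: pd.DataFrame
    participants: pd.DataFrame

    def write(self, outdir) -> None:
        """Serialise the cohort to RFC-4180 CSV files (plus config.json)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format="%.10g", lineterminator="\n")
        self.trials.to_csv(outdir / "trials.csv", **kw)
        self.items.to_csv(outdir / "items.csv", **kw)
        self.participants.to_csv(outdir / "participants.csv", **kw)
        self.traits.to_csv(outdir / "traits.csv", **kw)
        if self.config is not None:
            self.config.to_json(outdir / "config.json")


def _participant_ids(n: int) -> np.ndarray:
    width = max(3, len(str(n)))
    return np.array([f"P{i + 1:0{width}d}" for i in range(n)])


def sample_traits(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-participant latent traits, abilities and covariates.

    Planted exclusion violations overwrite the relevant abilities (or invert
    the choice rule) for disjoint, randomly selected subsets of participants,
    at the rates in ``config.planted_exclusion_rates``.
    """
    config.validate()
    n = config.n_participants
    rho = config.trait_corr

    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    cit, ad = z[:, 0], z[:, 1]

    acc_fi = np.clip(rng.normal(config.acc_fi_mean, config.acc_fi_sd, n), 0.01, 0.99)
    acc_fe = np.clip(rng.normal(config.acc_fe_mean, config.acc_fe_sd, n), 0.01, 1.0)

    # planted violations: one kind at most per participant (disjoint sets)
    u = rng.random(n)
    planted = np.full(n, "none", dtype=object)
    lo = 0.0
    for kind in PLANTED_KINDS:
        hi = lo + config.planted_exclusion_rates.get(kind, 0.0)
        planted[(u >= lo) & (u < hi)] = kind
        lo = hi
    m = planted == "fi_gt_fe"
    acc_fi[m], acc_fe[m] = 0.95, 0.78
    m = planted == "low_fe"
    acc_fe[m] = rng.uniform(0.40, 0.60, m.sum())
    acc_fi[m] = rng.uniform(0.15, np.maximum(acc_fe[m] - 0.10, 0.16))
    m = planted == "low_fi"
    acc_fi[m] = 0.02
    inverted = planted == "neg_corr"

    meta = (config.meta_bias_mean
            + config.beta_cit_meta * cit
            + config.beta_ad_meta * ad
            + rng.normal(0.0, config.noise_meta_sd, n))
    confidence_true = np.clip(100.0 * acc_fi + meta, 0.0, 100.0)
    rem = (config.rem_bias_mean
           + config.beta_meta_rem * meta
           + config.beta_cit_rem_direct * cit
           + rng.normal(0.0, config.noise_rem_sd, n))
    oip_implied = 10.0 * acc_fi / acc_fe
    if config.couple_aip:
        aip = oip_implied - rem
    else:
        aip = 10.0 * config.acc_fi_mean / config.acc_fe_mean - rem
    slope = np.exp(rng.normal(np.log(config.choice_slope_median),
                              config.choice_slope_sd, n))

    # covariates; ICAR5 and 2-back d' share a general-ability latent
    g = rng.normal(0.0, 1.0, n)
    age = np.clip(np.round(18 + rng.gamma(2.2, 6.8, n)), 18, 76).astype(int)
    gender = rng.choice(GENDERS, size=n, p=GENDER_PROBS)
    education = np.clip(np.round(rng.normal(5.0, 1.6, n)), 1, 9).astype(int)
    icar5 = rng.binomial(5, ndtr(0.2 + 0.6 * g))
    dprime = 2.0 + 0.6 * g + rng.normal(0.0, 0.4, n)
    catch_fail = rng.random(n) < config.catch_fail_rate
    parity = np.arange(n) % 2  # counterbalanced odd/even value assignment

    return pd.DataFrame({
        "participant_id": _participant_ids(n),
        "cit_latent": cit,
        "ad_latent": ad,
        "true_acc_fi": acc_fi,
        "true_acc_fe": acc_fe,
        "true_meta_bias": meta,
        "true_confidence": confidence_true,
        "true_rem_bias": rem,
        "true_aip": aip,
        "true_choice_slope": slope,
        "age": age,
        "gender": gender,
        "education": education,
        "icar5_true": icar5,
        "dprime_true": dprime,
        "parity": parity,
        "inverted_choice": inverted,
        "catch_fail": catch_fail,
        "planted": planted,
    })


def simulate_task(traits: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate the 16 task trials for every participant in ``traits``.

    Value schedule: the 8 forced trials receive one value parity each
    (FI <- {3,5,7,9} and FE <- {2,4,6,8}, or swapped, counterbalanced across
    participants), and the 8 Choice-Only trials receive each value 2-9 once.
    Every value therefore appears exactly twice per participant.  Trial order
    is randomised (intermixed conditions).
    """
    n = len(traits)
    if n == 0:
        raise ValueError("traits table is empty")
    parity = traits["parity"].to_numpy()
    odd = np.array(ODD_VALUES)
    even = np.array(EVEN_VALUES)
    fi_vals = np.where(parity[:, None] == 0, odd[None, :], even[None, :])
    fe_vals = np.where(parity[:, None] == 0, even[None, :], odd[None, :])
    co_vals = np.tile(np.array(CO_VALUES), (n, 1))
    values = np.concatenate([fi_vals, fe_vals, co_vals], axis=1)  # (n, 16)
    cond = np.concatenate([
        np.full((n, 4), "FI"), np.full((n, 4), "FE"), np.full((n, 8), "CO"),
    ], axis=1)

    # intermixed presentation order
    perm = rng.permuted(np.tile(np.arange(16), (n, 1)), axis=1)
    rows = np.arange(n)[:, None]
    values = values[rows, perm]
    cond = cond[rows, perm]

    aip = traits["true_aip"].to_numpy()[:, None]
    slope = traits["true_choice_slope"].to_numpy()[:, None]
    sign = np.where(traits["inverted_choice"].to_numpy()[:, None], -1.0, 1.0)
    p_rem = ndtr(sign * (values - aip) / slope)
    decision = rng.random((n, 16)) < p_rem

    executed = (cond == "FE") | ((cond == "CO") & decision)
    forced = cond != "CO"
    n_special = np.where(forced, 6, 0)
    p_acc = np.where(cond == "FI",
                     traits["true_acc_fi"].to_numpy()[:, None],
                     traits["true_acc_fe"].to_numpy()[:, None])
    n_correct = np.where(forced, rng.binomial(6, p_acc), 0)

    pid = np.repeat(traits["participant_id"].to_numpy(), 16)
    return pd.DataFrame({
        "participant_id": pid,
        "trial_index": np.tile(np.arange(1, 17), n),
        "offered_value": values.ravel().astype(int),
        "decision": np.where(decision.ravel(), "reminder", "internal"),
        "assigned_condition": cond.ravel(),
        "executed_with_reminder": executed.ravel(),
        "n_special": n_special.ravel().astype(int),
        "n_special_correct": n_correct.ravel().astype(int),
    })


def simulate_items(traits: pd.DataFrame, weights: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Generate 49 Likert item responses per participant from the latents.

    Item j with weight w_j loading on factor F has continuous response
    ``mid_j + item_loading_scale * w_j * half_range_j/2 * F`` plus Gaussian
    noise, rounded and clamped to the item's native Likert range.  Scoring the
    output with the same weight table recovers the latent factors up to a
    monotone transform (rank correlation > 0.9 at default noise).
    """
    required = {"questionnaire", "item_id", "factor", "weight",
                "likert_min", "likert_max"}
    missing = required - set(weights.columns)
    if missing:
        raise ValueError(f"weight table is missing columns: {sorted(missing)}")
    n = len(traits)
    cit = traits["cit_latent"].to_numpy()
    ad = traits["ad_latent"].to_numpy()
    # configuration lives on the traits' generating config via closure-free
    # call sites; scale parameters are passed through attrs for reuse
    loading_scale = traits.attrs.get("item_loading_scale", 0.6)
    noise_sd = traits.attrs.get("item_noise_sd", 0.8)

    lmin = weights["likert_min"].to_numpy(dtype=float)
    lmax = weights["likert_max"].to_numpy(dtype=float)
    half = (lmax - lmin) / 2.0
    mid = (lmax + lmin) / 2.0
    w = weights["weight"].to_numpy(dtype=float)
    latent = np.where((weights["factor"] == "CIT").to_numpy()[:, None],
                      cit[None, :], ad[None, :])  # (J, n)
    a = (loading_scale * w * half / 2.0)[:, None]
    e = rng.normal(0.0, 1.0, latent.shape) * (noise_sd * half / 2.0)[:, None]
    resp = np.clip(np.round(mid[:, None] + a * latent + e),
                   lmin[:, None], lmax[:, None]).astype(int)

    J = len(weights)
    return pd.DataFrame({
        "participant_id": np.tile(traits["participant_id"].to_numpy(), J),
        "questionnaire": np.repeat(weights["questionnaire"].to_numpy(), n),
        "item_id": np.repeat(weights["item_id"].to_numpy(), n),
        "response": resp.ravel(),
    }).sort_values(["participant_id", "questionnaire", "item_id"],
                   kind="stable", ignore_index=True)


def simulate_cohort(config: SimulationConfig,
                    weights: pd.DataFrame | None = None,
                    outdir=None) -> CohortDataset:
    """Generate a full cohort (traits + trials + items + covariates).

    Deterministic under ``config.seed``; optionally serialises the tables to
    ``outdir`` as CSV (plus config.json).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if weights is None:
        weights = default_weights()
    traits = sample_traits(config, rng)
    traits.attrs["item_loading_scale"] = config.item_loading_scale
    traits.attrs["item_noise_sd"] = config.item_noise_sd
    trials = simulate_task(traits, rng)
    items = simulate_items(traits, weights, rng)

    conf = np.clip(np.round(traits["true_confidence"].to_numpy()
                            + rng.normal(0.0, config.conf_noise_sd, len(traits))),
                   0, 100).astype(int)
    catch = np.where(traits["catch_fail"].to_numpy(),
                     CATCH_WRONG_RESPONSE, CATCH_CORRECT_RESPONSE)
    participants = pd.DataFrame({
        "participant_id": traits["participant_id"],
        "age": traits["age"],
        "gender": traits["gender"],
        "education": traits["education"],
        "icar5": traits["icar5_true"],
        "dprime": traits["dprime_true"],
        "confidence": conf,
        "catch_response": catch,
    })
    cohort = CohortDataset(config, traits, trials, items, participants)
    if outdir is not None:
        cohort.write(outdir)
    return cohort


def simulate_mediation_scores(n: int, rng: np.random.Generator, *,
                              a: float = 0.15, b: float = -0.20,
                              direct: float = -0.10,
                              trait_corr: float = 0.4) -> pd.DataFrame:
    """Score-level generator with an exactly known standardised mediation.

    Generates a cohort table (CIT, AD, unconfounded biases, covariates) whose
    population-standardised indirect effect of CIT on the reminder bias
    through the metacognitive bias is exactly ``a * b`` (default -0.03): the
    mediator and outcome are built with unit population variance, so the
    structural path coefficients coincide with the standardised ones.  Used
    for mediation recovery and coverage studies where task-level measurement
    noise would blur the ground truth.
    """
    cit = rng.normal(0.0, 1.0, n)
    ad = trait_corr * cit + np.sqrt(1 - trait_corr ** 2) * rng.normal(0.0, 1.0, n)
    med = a * cit + np.sqrt(1.0 - a ** 2) * rng.normal(0.0, 1.0, n)
    resid_var = 1.0 - (direct ** 2 + b ** 2 + 2.0 * direct * b * a)
    if resid_var <= 0:
        raise ValueError("path coefficients imply non-positive residual variance")
    out = direct * cit + b * med + np.sqrt(resid_var) * rng.normal(0.0, 1.0, n)
    return pd.DataFrame({
        "participant_id": _participant_ids(n),
        "cit": cit,
        "ad": ad,
        "bias_meta_uncf": med,
        "bias_rem_uncf": out,
        "age": np.clip(np.round(18 + rng.gamma(2.2, 6.8, n)), 18, 76).astype(int),
        "gender": rng.choice(GENDERS, size=n, p=GENDER_PROBS),
        "education": np.clip(np.round(rng.normal(5.0, 1.6, n)), 1, 9).astype(int),
    })


# ---------------------------------------------------------------------------
# hand-built 20-participant exclusion fixture
# ---------------------------------------------------------------------------

#: fixed intermixed presentation order for fixture trials: condition sequence
#: with FI values (3,5,7,9), FE values (2,4,6,8) and CO values 2..9 in order.
_FIXTURE_LAYOUT = [
    ("CO", 2), ("FI", 3), ("FE", 2), ("CO", 3), ("FI", 5), ("CO", 4),
    ("FE", 4), ("CO", 5), ("FI", 7), ("CO", 6), ("FE", 6), ("CO", 7),
    ("FI", 9), ("CO", 8), ("FE", 8), ("CO", 9),
]

#: (id, FI correct per trial, FE correct per trial, choice rule, confidence,
#:  catch ok).  Rules: ("cutoff", c) = reminder iff value >= c;
#: ("inverted", c) = reminder iff value <= c; ("all_reminder", None).
#: Planted violations:
#:   P01 P02 -> ACC_FI > ACC_FE          P03 P04 -> ACC_FE < 70%
#:   P05     -> ACC_FI < 10%             P06 P07 -> negative value-choice corr
#:   P08     -> catch failure            P09     -> reminder-bias MAD outlier
#:   P10-P20 -> retained (P10 sits just above the 70% FE boundary at 17/24)
_FIXTURE_PARTICIPANTS = [
    ("P01", (6, 6, 6, 6), (5, 5, 5, 5), ("cutoff", 6), 85, True),
    ("P02", (6, 6, 5, 6), (5, 5, 4, 5), ("cutoff", 6), 80, True),
    ("P03", (3, 3, 3, 3), (4, 3, 4, 3), ("cutoff", 6), 50, True),
    ("P04", (2, 3, 2, 3), (4, 4, 3, 3), ("cutoff", 5), 45, True),
    ("P05", (0, 0, 1, 0), (6, 6, 6, 6), ("cutoff", 6), 30, True),
    ("P06", (4, 4, 4, 4), (6, 6, 6, 6), ("inverted", 4), 55, True),
    ("P07", (3, 4, 3, 4), (6, 5, 6, 6), ("inverted", 5), 50, True),
    ("P08", (4, 4, 3, 4), (6, 6, 6, 6), ("cutoff", 6), 55, False),
    ("P09", (4, 4, 4, 3), (6, 6, 5, 6), ("all_reminder", None), 60, True),
    ("P10", (3, 2, 3, 2), (5, 4, 4, 4), ("cutoff", 6), 30, True),
    ("P11", (3, 3, 3, 3), (6, 6, 6, 6), ("cutoff", 5), 41, True),
    ("P12", (4, 3, 4, 3), (6, 6, 5, 6), ("cutoff", 6), 52, True),
    ("P13", (3, 3, 3, 3), (6, 5, 6, 6), ("cutoff", 5), 46, True),
    ("P14", (4, 4, 3, 4), (6, 6, 6, 6), ("cutoff", 6), 60, True),
    ("P15", (4, 3, 3, 3), (6, 6, 6, 6), ("cutoff", 5), 54, True),
    ("P16", (4, 4, 4, 4), (6, 6, 5, 6), ("cutoff", 6), 69, True),
    ("P17", (4, 4, 4, 4), (6, 6, 6, 6), ("cutoff", 6), 71, True),
    ("P18", (4, 3, 4, 3), (6, 6, 6, 6), ("cutoff", 5), 64, True),
    ("P19", (4, 4, 3, 4), (6, 6, 6, 5), ("cutoff", 6), 71, True),
    ("P20", (3, 3, 4, 3), (6, 6, 6, 6), ("cutoff", 5), 66, True),
]

#: the planted exclusion sets, by criterion (ground truth for tests)
FIXTURE_PLANTED = {
    "c1_fi_gt_fe": ["P01", "P02"],
    "c2_fe_lt_70": ["P03", "P04"],
    "c3_fi_lt_10": ["P05"],
    "c4_neg_value_corr": ["P06", "P07"],
    "c5_mad_outlier": ["P09"],
    "c6_catch_fail": ["P08"],
}


def _fixture_decision(rule, value: int) -> bool:
    kind, cut = rule
    if kind == "cutoff":
        return value >= cut
    if kind == "inverted":
        return value <= cut
    if kind == "all_reminder":
        return True
    raise ValueError(f"unknown fixture rule {kind!r}")


def make_fixture_cohort() -> CohortDataset:
    """Seed-free, byte-stable 20-participant cohort with planted violations.

    Exactly 2 participants have ACC_FI > ACC_FE, 2 have ACC_FE < 70%, 1 has
    ACC_FI < 10%, 2 respond with a negative value-choice correlation, 1 fails
    the catch item and 1 (an all-reminder responder, whose value-choice
    correlation is undefined and therefore retained under that criterion) is
    an extreme reminder-bias outlier.  ``FIXTURE_PLANTED`` records the sets.
    """
    trial_rows, part_rows, item_rows = [], [], []
    weights = default_weights()
    for pid, fi, fe, rule, conf, catch_ok in _FIXTURE_PARTICIPANTS:
        fi_iter, fe_iter = iter(fi), iter(fe)
        for idx, (cond, value) in enumerate(_FIXTURE_LAYOUT, start=1):
            dec = _fixture_decision(rule, value)
            correct = next(fi_iter) if cond == "FI" else (
                next(fe_iter) if cond == "FE" else 0)
            trial_rows.append({
                "participant_id": pid,
                "trial_index": idx,
                "offered_value": value,
                "decision": "reminder" if dec else "internal",
                "assigned_condition": cond,
                "executed_with_reminder": cond == "FE" or (cond == "CO" and dec),
                "n_special": 6 if cond != "CO" else 0,
                "n_special_correct": correct,
            })
        part_rows.append({
            "participant_id": pid,
            "age": 30, "gender": "male", "education": 5,
            "icar5": 3, "dprime": 2.0,
            "confidence": conf,
            "catch_response": CATCH_CORRECT_RESPONSE if catch_ok
            else CATCH_WRONG_RESPONSE,
        })
        for _, wrow in weights.iterrows():
            item_rows.append({
                "participant_id": pid,
                "questionnaire": wrow["questionnaire"],
                "item_id": wrow["item_id"],
                "response": int((wrow["likert_min"] + wrow["likert_max"]) // 2),
            })
    trials = pd.DataFrame(trial_rows, columns=TRIALS_COLUMNS)
    participants = pd.DataFrame(part_rows, columns=PARTICIPANTS_COLUMNS)
    items = pd.DataFrame(item_rows, columns=ITEMS_COLUMNS)
    traits = participants[["participant_id"]].copy()
    return CohortDataset(None, traits, trials, items, participants)
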