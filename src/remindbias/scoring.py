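"""Per-participant key measures of the offloading task.

Six quantities summarise each participant: accuracy without reminders
(ACC_FI) and with reminders (ACC_FE), the optimal indifference point
OIP = 10 * ACC_FI / ACC_FE, the actual indifference point AIP (psychometric
threshold over all 16 reminder decisions), the reminder bias
bias_rem = OIP - AIP (positive = more reminders than individually optimal),
and the metacognitive bias bias_meta = confidence - 100 * ACC_FI (negative =
underconfidence).

Because ACC_FI enters both biases, correlating them on full data would be
circular.  The unconfounded variants therefore split the four Forced
Internal trials by ordinal position: the even FI trials (2nd and 4th in
presentation order) feed the OIP used for bias_rem_uncf, the odd FI trials
(1st and 3rd) feed bias_meta_uncf.  ACC_FE always uses all four Forced
External trials.  AIP uses all 16 decisions regardless - the decision
precedes the condition reveal, so every decision is informative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .psychometric import fit_psychometric_cells

FULL_VALUE_GRID = np.arange(2, 10)

SCORES_COLUMNS = [
    "participant_id", "acc_fi_all", "acc_fi_odd", "acc_fi_even", "acc_fe",
    "confidence", "oip_all", "oip_even", "aip", "aip_slope", "aip_degenerate",
    "bias_rem_all", "bias_rem_uncf", "bias_meta_all", "bias_meta_uncf",
    "n_reminder_choices", "n_reminder_choices_co", "value_choice_corr",
]


class UndefinedOIPError(ValueError):
    """Raised when ACC_FE = 0 leaves the OIP undefined (the participant would
    in any case be excluded by the < 70% forced-external accuracy rule)."""


def accuracy(trials: pd.DataFrame, condition: str, subset: str = "all") -> float:
    """Proportion of special circles handled correctly in forced trials.

    ``subset`` selects trials by their ordinal position among that condition's
    trials in presentation order ("odd" = 1st and 3rd, "even" = 2nd and 4th).
    """
    if condition not in ("FI", "FE"):
        raise ValueError("condition must be 'FI' or 'FE'")
    if subset not in ("all", "odd", "even"):
        raise ValueError("subset must be 'all', 'odd' or 'even'")
    sel = (trials[trials["assigned_condition"] == condition]
           .sort_values("trial_index", kind="stable"))
    if subset != "all":
        ordinal = np.arange(1, len(sel) + 1)
        sel = sel[(ordinal % 2 == 1) if subset == "odd" else (ordinal % 2 == 0)]
    if len(sel) == 0:
        raise ValueError(f"no {condition} trials in subset {subset!r}")
    return float(sel["n_special_correct"].sum() / sel["n_special"].sum())


def optimal_indifference_point(acc_fi: float, acc_fe: float) -> float:
    """OIP = 10 * ACC_FI / ACC_FE, the reward value at which an unbiased
    reward-maximiser is indifferent between strategies."""
    if acc_fe <= 0:
        raise UndefinedOIPError("OIP undefined: forced-external accuracy is 0")
    return 10.0 * acc_fi / acc_fe


def reminder_bias(oip: float, aip: float) -> float:
    """bias_rem = OIP - AIP; positive values mean more reminder use than the
    individually optimal strategy."""
    if not (np.isfinite(oip) and np.isfinite(aip)):
        raise ValueError("OIP and AIP must be finite")
    return float(oip - aip)


def metacognitive_bias(confidence: float, acc_fi: float) -> float:
    """bias_meta = confidence - 100 * ACC_FI (percentage points); negative
    values indicate underconfidence."""
    if not 0.0 <= confidence <= 100.0:
        raise ValueError("confidence must lie in [0, 100]")
    return float(confidence - 100.0 * acc_fi)


def value_choice_correlation(offered_values, decisions) -> float:
    """Pearson correlation between offered value and the 0/1 reminder
    decision; NaN (undefined, not an error) when either input is constant."""
    v = np.asarray(offered_values, dtype=float)
    d = np.asarray(decisions, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 decisions")
    if np.std(v) == 0.0 or np.std(d) == 0.0:
        return float("nan")
    return float(np.corrcoef(v, d)[0, 1])


def _decision_cells(trials: pd.DataFrame, values=FULL_VALUE_GRID):
    """Aggregate one participant-set of trials to (k, n) reminder-decision
    counts on a common offered-value grid."""
    pids = trials["participant_id"].to_numpy()
    order = pd.unique(pids)
    pidx = pd.Categorical(pids, categories=order).codes
    vidx = np.searchsorted(values, trials["offered_value"].to_numpy())
    dec = (trials["decision"] == "reminder").to_numpy().astype(float)
    k = np.zeros((len(order), len(values)))
    n = np.zeros_like(k)
    np.add.at(k, (pidx, vidx), dec)
    np.add.at(n, (pidx, vidx), 1.0)
    return order, k, n


def score_participant(trials: pd.DataFrame, confidence: float) -> dict:
    """All key measures for one participant (16 trials, 4 FI + 4 FE).

    Returns a dict with the ``SCORES_COLUMNS`` fields (sans participant_id).
    """
    cond_counts = trials["assigned_condition"].value_counts()
    if cond_counts.get("FI", 0) != 4 or cond_counts.get("FE", 0) != 4:
        raise ValueError("expected exactly 4 FI and 4 FE trials")
    if len(trials) != 16:
        raise ValueError("expected exactly 16 trials")

    acc_fi_all = accuracy(trials, "FI", "all")
    acc_fi_odd = accuracy(trials, "FI", "odd")
    acc_fi_even = accuracy(trials, "FI", "even")
    acc_fe = accuracy(trials, "FE", "all")

    oip_all = optimal_indifference_point(acc_fi_all, acc_fe)
    oip_even = optimal_indifference_point(acc_fi_even, acc_fe)

    values = trials["offered_value"].to_numpy()
    decisions = (trials["decision"] == "reminder").to_numpy().astype(int)
    from .psychometric import fit_psychometric
    fit = fit_psychometric(values, decisions)

    return {
        "acc_fi_all": acc_fi_all,
        "acc_fi_odd": acc_fi_odd,
        "acc_fi_even": acc_fi_even,
        "acc_fe": acc_fe,
        "confidence": float(confidence),
        "oip_all": oip_all,
        "oip_even": oip_even,
        "aip": fit.threshold,
        "aip_slope": fit.slope,
        "aip_degenerate": fit.degenerate,
        "bias_rem_all": reminder_bias(oip_all, fit.threshold),
        "bias_rem_uncf": reminder_bias(oip_even, fit.threshold),
        "bias_meta_all": metacognitive_bias(confidence, acc_fi_all),
        "bias_meta_uncf": metacognitive_bias(confidence, acc_fi_odd),
        "n_reminder_choices": int(decisions.sum()),
        "n_reminder_choices_co": int(
            decisions[(trials["assigned_condition"] == "CO").to_numpy()].sum()),
        "value_choice_corr": value_choice_correlation(values, decisions),
    }


def score_cohort(trials: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Vectorised scoring of a whole cohort.

    Participants whose OIP is undefined (ACC_FE = 0) receive NaN indifference
    points and biases instead of raising; they are flagged for the downstream
    forced-external accuracy exclusion.
    """
    need = {"participant_id", "trial_index", "offered_value", "decision",
            "assigned_condition", "n_special", "n_special_correct"}
    missing = need - set(trials.columns)
    if missing:
        raise ValueError(f"trials table is missing columns: {sorted(missing)}")
    if "confidence" not in participants.columns:
        raise ValueError("participants table is missing column: confidence")

    t = trials.sort_values(["participant_id", "trial_index"], kind="stable")
    conf = participants.set_index("participant_id")["confidence"]

    # within-condition ordinal positions (presentation order)
    t = t.assign(_ord=t.groupby(["participant_id", "assigned_condition"],
                                sort=False).cumcount() + 1)

    def _acc(cond, parity=None):
        sel = t[t["assigned_condition"] == cond]
        if parity == "odd":
            sel = sel[sel["_ord"] % 2 == 1]
        elif parity == "even":
            sel = sel[sel["_ord"] % 2 == 0]
        g = sel.groupby("participant_id", sort=True)
        return g["n_special_correct"].sum() / g["n_special"].sum()

    acc_fi_all = _acc("FI")
    acc_fi_odd = _acc("FI", "odd")
    acc_fi_even = _acc("FI", "even")
    acc_fe = _acc("FE")

    pid_order, k, n = _decision_cells(t)
    fits = fit_psychometric_cells(k, n, FULL_VALUE_GRID)
    fits.index = pid_order
    fits = fits.sort_index()

    idx = acc_fi_all.index
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = acc_fe.reindex(idx).to_numpy(dtype=float)
        oip_all = np.where(fe > 0, 10.0 * acc_fi_all.to_numpy() / fe, np.nan)
        oip_even = np.where(fe > 0, 10.0 * acc_fi_even.reindex(idx).to_numpy() / fe,
                            np.nan)

    dec = t.assign(_rem=(t["decision"] == "reminder").astype(int),
                   _v=t["offered_value"].astype(float))
    dec["_v2"] = dec["_v"] ** 2
    dec["_vd"] = dec["_v"] * dec["_rem"]
    g = dec.groupby("participant_id", sort=True)
    n_rem = g["_rem"].sum().reindex(idx)
    n_rem_co = (dec[dec["assigned_condition"] == "CO"]
                .groupby("participant_id", sort=True)["_rem"].sum()
                .reindex(idx).fillna(0))
    # Pearson value-choice correlation from per-participant moments
    agg = g.agg(n=("_rem", "size"), sv=("_v", "sum"), sv2=("_v2", "sum"),
                sd_=("_rem", "sum"), svd=("_vd", "sum")).reindex(idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = agg["n"].to_numpy(dtype=float)
        cov = agg["svd"] / m - (agg["sv"] / m) * (agg["sd_"] / m)
        var_v = agg["sv2"] / m - (agg["sv"] / m) ** 2
        pd_ = agg["sd_"] / m
        var_d = pd_ * (1.0 - pd_)
        vcc = pd.Series(np.where((var_v > 0) & (var_d > 0),
                                 cov / np.sqrt(var_v * var_d), np.nan),
                        index=agg.index)

    aip = fits["threshold"].reindex(idx).to_numpy()
    confidence = conf.reindex(idx).to_numpy(dtype=float)
    scores = pd.DataFrame({
        "participant_id": idx,
        "acc_fi_all": acc_fi_all.to_numpy(),
        "acc_fi_odd": acc_fi_odd.reindex(idx).to_numpy(),
        "acc_fi_even": acc_fi_even.reindex(idx).to_numpy(),
        "acc_fe": fe,
        "confidence": confidence,
        "oip_all": oip_all,
        "oip_even": oip_even,
        "aip": aip,
        "aip_slope": fits["slope"].reindex(idx).to_numpy(),
        "aip_degenerate": fits["degenerate"].reindex(idx).to_numpy(),
        "bias_rem_all": oip_all - aip,
        "bias_rem_uncf": oip_even - aip,
        "bias_meta_all": confidence - 100.0 * acc_fi_all.to_numpy(),
        "bias_meta_uncf": confidence - 100.0 * acc_fi_odd.reindex(idx).to_numpy(),
        "n_reminder_choices": n_rem.to_numpy(dtype=int),
        "n_reminder_choices_co": n_rem_co.to_numpy(dtype=int),
        "value_choice_corr": vcc.to_numpy(dtype=float),
    }).reset_index(drop=True)
    return scores[SCORES_COLUMNS]
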