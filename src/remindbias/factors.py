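"""Transdiagnostic factor scoring and ancillary covariate scoring.

Two non-overlapping transdiagnostic factors are scored from 49 questionnaire
items drawn from six clinical questionnaires: 'compulsive behaviour and
intrusive thought' (CIT, 25 items) and 'anxious-depression' (AD, 24 items).
A factor score is simply the weighted sum of the item responses,

    score_F = sum_j w_j * response_j   over the items j assigned to factor F,

with the weights supplied as a table (the published weights are an external
input; see ``default_weights`` for the synthetic stand-in shipped here).
Reverse-keyed items are handled by negative weights - there is no separate
reverse-scoring pass.

Also provided: signal-detection d' for the 2-back working-memory covariate
(log-linear corrected) and ICAR5 cognitive-ability scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

#: the attention-check item embedded in the BIS-11 block; it carries no
#: factor weight and is not one of the 49 scored items
CATCH_ITEM_ID = "BIS11_catch"
CATCH_CORRECT_RESPONSE = "Do not agree at all"

WEIGHTS_COLUMNS = ["questionnaire", "item_id", "factor", "weight",
                   "likert_min", "likert_max"]

#: expected number of weighted items per questionnaire.  The BIS-11 block is
#: presented with 12 items, but one of them is the unweighted catch item, so
#: 11 BIS items carry weights and the table has exactly 49 rows.
QUESTIONNAIRE_COUNTS = {
    "AES": 4, "SDS": 8, "EAT-26": 4, "BIS-11": 11, "OCIR": 11, "STAI": 11,
}
FACTOR_COUNTS = {"AD": 24, "CIT": 25}

#: native Likert response ranges of each questionnaire
LIKERT_RANGES = {
    "AES": (1, 4), "SDS": (1, 4), "EAT-26": (1, 6),
    "BIS-11": (1, 4), "OCIR": (0, 4), "STAI": (1, 4),
}


def default_weights() -> pd.DataFrame:
    """Synthetic default weight table (the published weights are config input).

    Unit-magnitude weights, with one reverse-keyed (negative) item per factor,
    and a synthetic item-to-factor assignment chosen only to satisfy the
    24 AD / 25 CIT split: AD = 11 STAI + 8 SDS + 4 AES + 1 BIS-11 item;
    CIT = 11 OCIR + 10 BIS-11 + 4 EAT-26 items.  Tests and simulator defaults
    use this table; analyses of real data should supply the published weights
    via ``read_weights``.
    """
    rows = []

    def add(questionnaire, count, factor, start=1):
        lmin, lmax = LIKERT_RANGES[questionnaire]
        for i in range(start, start + count):
            rows.append((questionnaire, f"{questionnaire}_{i:02d}", factor,
                         1.0, lmin, lmax))

    add("STAI", 11, "AD")
    add("SDS", 8, "AD")
    add("AES", 4, "AD")
    add("BIS-11", 1, "AD")            # BIS-11_01
    add("BIS-11", 10, "CIT", start=2)  # BIS-11_02 .. BIS-11_11
    add("OCIR", 11, "CIT")
    add("EAT-26", 4, "CIT")
    df = pd.DataFrame(rows, columns=WEIGHTS_COLUMNS)
    # one reverse-keyed item per factor (e.g. a calmness-worded STAI item)
    df.loc[df["item_id"] == "STAI_01", "weight"] = -1.0
    df.loc[df["item_id"] == "OCIR_01", "weight"] = -1.0
    return df


def read_weights(path) -> pd.DataFrame:
    """Read a weight table from JSON ``{"items": [{...}, ...]}``."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    df = pd.DataFrame(payload["items"])
    missing = set(WEIGHTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weight table is missing columns: {sorted(missing)}")
    return df[WEIGHTS_COLUMNS]


def write_weights(weights: pd.DataFrame, path) -> None:
    payload = {"items": weights[WEIGHTS_COLUMNS].to_dict(orient="records")}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


@dataclass
class WeightsValidation:
    """Report of weight-table invariant checks; empty violations = pass."""

    violations: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


def validate_weights(weights: pd.DataFrame) -> WeightsValidation:
    """Check the structural invariants of a factor weight table.

    Report-based: every violated invariant is described, nothing raises.
    """
    report = WeightsValidation()
    missing = set(WEIGHTS_COLUMNS) - set(weights.columns)
    if missing:
        report.violations.append(f"missing-columns: {sorted(missing)}")
        return report
    if len(weights) != 49:
        report.violations.append(f"row-count: expected 49 rows, got {len(weights)}")
    dup = weights.duplicated(subset=["questionnaire", "item_id"])
    if dup.any():
        pairs = weights.loc[dup, ["questionnaire", "item_id"]].values.tolist()
        report.violations.append(f"uniqueness: duplicated (questionnaire, item) {pairs}")
    bad_factor = set(weights["factor"]) - set(FACTOR_COUNTS)
    if bad_factor:
        report.violations.append(f"factor-labels: unknown factors {sorted(bad_factor)}")
    else:
        fc = weights["factor"].value_counts().to_dict()
        for factor, expect in FACTOR_COUNTS.items():
            if fc.get(factor, 0) != expect:
                report.violations.append(
                    f"factor-count: {factor} has {fc.get(factor, 0)} items, expected {expect}")
        per_item = weights.groupby(["questionnaire", "item_id"])["factor"].nunique()
        if (per_item > 1).any():
            report.violations.append("overlap: an item maps to both factors")
    qc = weights["questionnaire"].value_counts().to_dict()
    for q, expect in QUESTIONNAIRE_COUNTS.items():
        if qc.get(q, 0) != expect:
            report.violations.append(
                f"questionnaire-count: {q} has {qc.get(q, 0)} items, expected {expect}")
    unknown_q = set(weights["questionnaire"]) - set(QUESTIONNAIRE_COUNTS)
    if unknown_q:
        report.violations.append(f"questionnaire-labels: unknown {sorted(unknown_q)}")
    if (weights["likert_min"] >= weights["likert_max"]).any():
        report.violations.append("likert-range: likert_min must be < likert_max")
    if not np.isfinite(weights["weight"].to_numpy(dtype=float)).all():
        report.violations.append("weight-values: non-finite weight")
    return report


def score_factors(items: pd.DataFrame, weights: pd.DataFrame,
                  require_valid: bool = True) -> pd.DataFrame:
    """Score CIT and AD for every participant in a long item-response table.

    Participants missing any of the 49 items are flagged (``complete=False``)
    and receive NaN scores rather than a partial sum.

    Parameters
    ----------
    items : DataFrame with columns participant_id, questionnaire, item_id,
        response (long format, one row per participant x item).
    weights : validated FactorWeights table.
    require_valid : raise if the weight table fails validation.
    """
    if require_valid:
        report = validate_weights(weights)
        if not report.passed:
            raise ValueError("invalid weight table: " + "; ".join(report.violations))
    need = {"participant_id", "item_id", "response"}
    missing = need - set(items.columns)
    if missing:
        raise ValueError(f"item table is missing columns: {sorted(missing)}")

    merged = items.merge(weights[["item_id", "factor", "weight",
                                  "likert_min", "likert_max"]],
                         on="item_id", how="inner")
    out_of_range = ((merged["response"] < merged["likert_min"])
                    | (merged["response"] > merged["likert_max"]))
    if out_of_range.any():
        bad = merged.loc[out_of_range, ["participant_id", "item_id"]].iloc[0]
        raise ValueError(
            f"response outside Likert range (first: participant "
            f"{bad['participant_id']}, item {bad['item_id']})")

    merged["contrib"] = merged["weight"] * merged["response"]
    g = merged.groupby("participant_id", sort=True)
    n_items = g.size()
    scores = (merged.pivot_table(index="participant_id", columns="factor",
                                 values="contrib", aggfunc="sum")
              .reindex(columns=["CIT", "AD"]))
    complete = n_items == len(weights)
    result = pd.DataFrame({
        "participant_id": scores.index,
        "cit": scores["CIT"].to_numpy(dtype=float),
        "ad": scores["AD"].to_numpy(dtype=float),
        "complete": complete.reindex(scores.index).to_numpy(),
    }).reset_index(drop=True)
    result.loc[~result["complete"], ["cit", "ad"]] = np.nan
    # participants present in the cohort but absent from the item table are
    # the caller's responsibility (they simply have no row here)
    return result


def score_dprime(n_hits: int, n_misses: int, n_false_alarms: int,
                 n_correct_rejections: int, correction: str = "loglinear") -> float:
    """Signal-detection sensitivity d' = z(hit rate) - z(false-alarm rate).

    The log-linear correction (add 0.5 to every cell before computing rates)
    keeps d' finite for perfect hit or zero false-alarm runs, the standard
    remedy on ~100-trial 2-back blocks.  ``correction="none"`` uses raw rates
    and may return +/-inf.
    """
    for v in (n_hits, n_misses, n_false_alarms, n_correct_rejections):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if n_hits + n_misses == 0:
        raise ValueError("no target trials (hits + misses = 0)")
    if n_false_alarms + n_correct_rejections == 0:
        raise ValueError("no non-target trials (false alarms + correct rejections = 0)")
    if correction == "loglinear":
        hr = (n_hits + 0.5) / (n_hits + n_misses + 1.0)
        far = (n_false_alarms + 0.5) / (n_false_alarms + n_correct_rejections + 1.0)
    elif correction == "none":
        hr = n_hits / (n_hits + n_misses)
        far = n_false_alarms / (n_false_alarms + n_correct_rejections)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(norm.ppf(hr) - norm.ppf(far))


def score_icar(responses, key) -> int:
    """Score the 5-item ICAR cognitive-ability screener: count of key matches."""
    responses = list(responses)
    key = list(key)
    if len(responses) != 5 or len(key) != 5:
        raise ValueError("ICAR5 needs exactly 5 responses and 5 key entries")
    return int(sum(r == k for r, k in zip(responses, key)))
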