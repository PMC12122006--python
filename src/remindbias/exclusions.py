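"""Preregistered participant exclusions.

Six criteria, applied to full-data scores:

1. higher forced-internal than forced-external accuracy (ACC_FI > ACC_FE);
2. forced-external accuracy below 70% (strictly less);
3. forced-internal accuracy below 10% (strictly less);
4. negative value-choice correlation (reminder coded 1) - evidence the
   incentive structure was misunderstood; an undefined correlation (constant
   responder) is NOT excluded here, only flagged;
5. reminder bias or metacognitive bias more than three median absolute
   deviations from the cohort median;
6. wrong answer to the catch item.

Criteria 1-4 and 6 are row-local and commute.  Criterion 5 depends on its
evaluation pool: by default the median and MAD are computed over participants
surviving the other five criteria, so gross violators cannot corrupt the
median (configurable to the full cohort).  The MAD uses the 1.4826
normal-consistency constant by default (the convention of R's ``mad()``,
under which the 3-MAD fence sits at ~3 SD and flags essentially nobody in a
roughly Gaussian cohort); the unscaled literal reading - a fence at ~2 SD
that flags ~4-5% of a Gaussian cohort - is available as a switch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .factors import CATCH_CORRECT_RESPONSE

CRITERIA = ("c1_fi_gt_fe", "c2_fe_lt_70", "c3_fi_lt_10",
            "c4_neg_value_corr", "c5_mad_outlier", "c6_catch_fail")


@dataclass
class ExclusionReport:
    """Per-criterion excluded-participant lists plus the retained set.

    A participant may appear under several criteria; ``total_excluded`` is
    the size of the union.
    """

    c1_fi_gt_fe: list = field(default_factory=list)
    c2_fe_lt_70: list = field(default_factory=list)
    c3_fi_lt_10: list = field(default_factory=list)
    c4_neg_value_corr: list = field(default_factory=list)
    c5_mad_outlier: list = field(default_factory=list)
    c6_catch_fail: list = field(default_factory=list)
    undefined_value_corr: list = field(default_factory=list)
    total_excluded: int = 0
    n_input: int = 0
    retained_ids: list = field(default_factory=list)
    mad_scale: str = "normal"
    mad_pool: str = "post"

    @property
    def excluded_ids(self) -> list:
        ids = set()
        for c in CRITERIA:
            ids.update(getattr(self, c))
        return sorted(ids)

    def per_criterion_counts(self) -> dict:
        return {c: len(getattr(self, c)) for c in CRITERIA}

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["per_criterion_counts"] = self.per_criterion_counts()
        payload["schema_version"] = 1
        Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                              encoding="utf-8")


def _mad(x: np.ndarray, scale: str) -> float:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if scale == "normal":
        mad *= 1.4826
    elif scale != "raw":
        raise ValueError(f"unknown mad scale {scale!r}")
    return float(mad)


def apply_exclusions(scores: pd.DataFrame, catch_responses,
                     mad_scale: str = "normal",
                     mad_pool: str = "post") -> tuple[ExclusionReport, pd.DataFrame]:
    """Apply the six preregistered criteria to a scored cohort.

    Parameters
    ----------
    scores : output of ``score_cohort`` (full-data variants are used: the MAD
        rule is evaluated on ``bias_rem_all`` and ``bias_meta_all``).
    catch_responses : mapping / Series from participant_id to the catch-item
        response string, or a DataFrame with ``participant_id`` and
        ``catch_response`` columns.
    mad_scale : "raw" (3 x median absolute deviation, the literal rule) or
        "normal" (with the 1.4826 consistency constant).
    mad_pool : "post" (median/MAD over survivors of the other criteria) or
        "all" (over the full cohort).

    Returns the report and the retained subset of ``scores``.
    """
    need = {"participant_id", "acc_fi_all", "acc_fe", "value_choice_corr",
            "bias_rem_all", "bias_meta_all"}
    missing = need - set(scores.columns)
    if missing:
        raise ValueError(f"scores table is missing columns: {sorted(missing)}")
    if mad_pool not in ("post", "all"):
        raise ValueError(f"unknown mad pool {mad_pool!r}")

    if isinstance(catch_responses, pd.DataFrame):
        catch = catch_responses.set_index("participant_id")["catch_response"]
    else:
        catch = pd.Series(catch_responses)
    catch = catch.reindex(scores["participant_id"])

    pid = scores["participant_id"].to_numpy()
    acc_fi = scores["acc_fi_all"].to_numpy(dtype=float)
    acc_fe = scores["acc_fe"].to_numpy(dtype=float)
    vcc = scores["value_choice_corr"].to_numpy(dtype=float)

    c1 = acc_fi > acc_fe
    c2 = acc_fe < 0.70
    c3 = acc_fi < 0.10
    c4 = vcc < 0  # NaN compares False: undefined correlations are retained
    c6 = (catch != CATCH_CORRECT_RESPONSE).to_numpy()

    pool = ~(c1 | c2 | c3 | c4 | c6) if mad_pool == "post" \
        else np.ones(len(scores), dtype=bool)
    c5 = np.zeros(len(scores), dtype=bool)
    for col in ("bias_rem_all", "bias_meta_all"):
        x = scores[col].to_numpy(dtype=float)
        px = x[pool & np.isfinite(x)]
        if len(px) == 0:
            continue
        med = float(np.median(px))
        mad = _mad(px, mad_scale)
        c5 |= pool & np.isfinite(x) & (np.abs(x - med) > 3.0 * mad)

    excluded = c1 | c2 | c3 | c4 | c5 | c6
    report = ExclusionReport(
        c1_fi_gt_fe=sorted(pid[c1]),
        c2_fe_lt_70=sorted(pid[c2]),
        c3_fi_lt_10=sorted(pid[c3]),
        c4_neg_value_corr=sorted(pid[c4]),
        c5_mad_outlier=sorted(pid[c5]),
        c6_catch_fail=sorted(pid[c6]),
        undefined_value_corr=sorted(pid[np.isnan(vcc)]),
        total_excluded=int(excluded.sum()),
        n_input=len(scores),
        retained_ids=sorted(pid[~excluded]),
        mad_scale=mad_scale,
        mad_pool=mad_pool,
    )
    return report, scores[~excluded].reset_index(drop=True)
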