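"""Preregistered hypothesis battery and bootstrap mediation.

The battery comprises 18 preregistered tests: four sanity checks (H1-H4:
confidence-offloading link, pro-reminder bias, underconfidence, compensatory
reminder use) and the key individual-differences models (H5a-e, H6a-c,
H7a-c, H8a-c), all ordinary-least-squares regressions of the form

    bias ~ CIT + AD + age + gender + education (+ d' | ICAR5)

with every non-binary variable z-transformed before fitting, gender entered
as a 3-level categorical (male reference) and, for H7, a metacognitive-bias x
CIT interaction (moderation).  H1-H4 are one-sided as preregistered; all
other tests are two-sided.  H1 and H7 use the unconfounded (split-half) bias
variants to avoid the shared-ACC_FI circularity; every other hypothesis uses
the full-data variants.

The mediation analysis (CIT -> metacognitive bias -> reminder bias) uses a
from-scratch nonparametric percentile bootstrap: participants are resampled
with replacement, the mediator and outcome models are refitted on each
resample, and the indirect effect a*b is summarised by its 2.5th/97.5th
percentiles.  Within the mediation the gender covariate is coded numerically
(male 0, female 1, other 2), mirroring the constraint of the original
analysis software; elsewhere gender stays categorical.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

GENDER_CODES = {"male": 0, "female": 1, "other": 2}
DEMOGRAPHICS = ("age", "gender", "education")

HYPOTHESIS_IDS = (
    "H1", "H2", "H3", "H4",
    "H5a", "H5b", "H5c", "H5d", "H5e",
    "H6a", "H6b", "H6c",
    "H7a", "H7b", "H7c",
    "H8a", "H8b", "H8c",
)


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def zscore_nonbinary(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Standardise all non-binary numeric columns to mean 0, sample SD 1.

    Columns with exactly two distinct values are left untouched (dummy
    codes); constant non-binary columns raise.  Non-numeric columns pass
    through unchanged.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        finite = x[np.isfinite(x)]
        n_distinct = len(np.unique(finite))
        if n_distinct == 2:
            continue
        if n_distinct < 2:
            raise ValueError(f"column {col!r} is constant; cannot z-transform")
        sd = finite.std(ddof=1)
        out[col] = (x - finite.mean()) / sd
    return out


def correlation_test(x, y, method: str = "pearson",
                     alternative: str = "two_sided") -> tuple[float, float]:
    """Correlation coefficient and p-value under the stated alternative."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    if method == "pearson":
        res = stats.pearsonr(x, y, alternative=alt)
    elif method == "spearman":
        res = stats.spearmanr(x, y, alternative=alt)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def one_sample_t(x, alternative: str = "two_sided", popmean: float = 0.0):
    """One-sample t-test; returns (mean, t, p, cohens_d) with d = mean/sd."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    res = stats.ttest_1samp(x, popmean, alternative=alt)
    return (float(x.mean()), float(res.statistic), float(res.pvalue),
            float((x.mean() - popmean) / sd))


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative OLS model: outcome, predictors, optional interactions and
    covariates, the z-transform rule, and the gender coding."""

    outcome: str
    predictors: list
    interactions: list = field(default_factory=list)
    covariates: list = field(default_factory=list)
    z_transform: str = "all non-binary variables"
    gender_coding: str = "categorical"

    def validate(self) -> None:
        if self.outcome in self.predictors:
            raise ValueError("outcome cannot also be a predictor")
        mains = set(self.predictors) | set(self.covariates)
        for a, b in self.interactions:
            if a not in mains or b not in mains:
                raise ValueError(
                    f"interaction ({a}, {b}) members must appear as main effects")


@dataclass
class RegressionResult:
    """Standardised OLS fit: per-term (beta, se, t, p) plus fit statistics."""

    terms: dict
    n: int
    r_squared: float
    df_resid: int

    def term(self, name: str) -> dict:
        return self.terms[name]


def _design(table: pd.DataFrame, spec: ModelSpec):
    """Build (y, X) from a cohort table per the spec, z-transforming first."""
    cols = [spec.outcome] + list(spec.predictors) + list(spec.covariates)
    seen, ordered = set(), []
    for c in cols:
        if c not in seen:
            seen.add(c)
            ordered.append(c)
    data = table[ordered].dropna().copy()
    if len(data) == 0:
        raise ValueError("no complete cases")

    if "gender" in ordered:
        if spec.gender_coding == "continuous":
            data["gender"] = data["gender"].map(GENDER_CODES).astype(float)
        elif spec.gender_coding != "categorical":
            raise ValueError(f"unknown gender coding {spec.gender_coding!r}")

    numeric = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    data = zscore_nonbinary(data, numeric)

    X = pd.DataFrame(index=data.index)
    for c in spec.predictors + spec.covariates:
        if c == "gender" and spec.gender_coding == "categorical":
            for level in ("female", "other"):
                dummy = (data["gender"] == level).astype(float)
                if dummy.sum() > 0:  # drop empty levels (small samples)
                    X[f"gender[{level}]"] = dummy
        else:
            X[c] = data[c]
    for a, b in spec.interactions:
        X[f"{a}:{b}"] = X[a] * X[b]
    X = sm.add_constant(X, prepend=True)
    y = data[spec.outcome]
    if len(y) <= X.shape[1]:
        raise ValueError("more model terms than observations")
    return y, X


def fit_ols(spec: ModelSpec, table: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares with conventional standard errors on z-scored
    data (standardised coefficients)."""
    spec.validate()
    y, X = _design(table, spec)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y.to_numpy(), X).fit()
    terms = {
        name: {
            "beta": float(fit.params[name]),
            "se": float(fit.bse[name]),
            "t": float(fit.tvalues[name]),
            "p": float(fit.pvalues[name]),
        }
        for name in X.columns
    }
    return RegressionResult(terms=terms, n=int(fit.nobs),
                            r_squared=float(fit.rsquared),
                            df_resid=int(fit.df_resid))


# ---------------------------------------------------------------------------
# hypothesis battery
# ---------------------------------------------------------------------------

@dataclass
class HypothesisResult:
    """One preregistered test: the focal estimate and its p-value."""

    h_id: str
    kind: str            # "correlation", "t_test" or "regression"
    estimate: float      # r / mean / standardised beta of the focal term
    stat: float          # t statistic (or r for correlations)
    p: float
    n: int
    alternative: str
    term: str | None = None
    se: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _ols_hypothesis(outcome, focus, extra_covs=()):
    return {
        "kind": "regression",
        "spec": ModelSpec(outcome=outcome, predictors=["cit", "ad"],
                          covariates=list(DEMOGRAPHICS) + list(extra_covs)),
        "focus": focus,
    }


def _moderation_hypothesis(moderator, extra_covs=()):
    return {
        "kind": "moderation",
        "spec": ModelSpec(outcome="bias_rem_uncf",
                          predictors=["bias_meta_uncf", "cit", "ad"],
                          interactions=[("bias_meta_uncf", moderator)],
                          covariates=list(DEMOGRAPHICS) + list(extra_covs)),
        "focus": f"bias_meta_uncf:{moderator}",
    }


HYPOTHESES = {
    # sanity checks (one-sided, as preregistered)
    "H1": {"kind": "correlation", "x": "bias_meta_uncf", "y": "bias_rem_uncf",
           "method": "pearson", "alternative": "less"},
    "H2": {"kind": "t_test", "x": "bias_rem_all", "alternative": "greater"},
    "H3": {"kind": "t_test", "x": "bias_meta_all", "alternative": "less"},
    "H4": {"kind": "correlation", "x": "oip_all", "y": "aip",
           "method": "spearman", "alternative": "greater"},
    # CIT and offloading
    "H5a": _ols_hypothesis("bias_rem_all", "cit"),
    "H5b": _ols_hypothesis("n_reminder_choices", "cit"),
    "H5c": _ols_hypothesis("aip", "cit"),
    "H5d": _ols_hypothesis("bias_rem_all", "cit", ["dprime"]),
    "H5e": _ols_hypothesis("bias_rem_all", "cit", ["icar5"]),
    # CIT and confidence
    "H6a": _ols_hypothesis("bias_meta_all", "cit"),
    "H6b": _ols_hypothesis("confidence", "cit"),
    "H6c": _ols_hypothesis("bias_meta_all", "cit", ["icar5"]),
    # moderation of the confidence-offloading link by CIT
    "H7a": _moderation_hypothesis("cit"),
    "H7b": _moderation_hypothesis("cit", ["dprime"]),
    "H7c": _moderation_hypothesis("cit", ["icar5"]),
    # AD and confidence (same models as H6, focal term AD)
    "H8a": _ols_hypothesis("bias_meta_all", "ad"),
    "H8b": _ols_hypothesis("confidence", "ad"),
    "H8c": _ols_hypothesis("bias_meta_all", "ad", ["icar5"]),
}


def run_hypothesis(h_id: str, table: pd.DataFrame) -> HypothesisResult:
    """Run one preregistered test on a scored, filtered cohort table."""
    if h_id not in HYPOTHESES:
        raise KeyError(f"unknown hypothesis id {h_id!r}")
    h = HYPOTHESES[h_id]
    if h["kind"] == "correlation":
        sub = table[[h["x"], h["y"]]].dropna()
        r, p = correlation_test(sub[h["x"]], sub[h["y"]], h["method"],
                                h["alternative"])
        return HypothesisResult(h_id=h_id, kind="correlation", estimate=r,
                                stat=r, p=p, n=len(sub),
                                alternative=h["alternative"],
                                extra={"method": h["method"]})
    if h["kind"] == "t_test":
        x = table[h["x"]].dropna().to_numpy()
        mean, t, p, d = one_sample_t(x, h["alternative"])
        return HypothesisResult(h_id=h_id, kind="t_test", estimate=mean,
                                stat=t, p=p, n=len(x),
                                alternative=h["alternative"],
                                extra={"cohens_d": d})
    # regression / moderation (two-sided)
    res = fit_ols(h["spec"], table)
    focal = res.term(h["focus"])
    return HypothesisResult(h_id=h_id, kind="regression",
                            estimate=focal["beta"], stat=focal["t"],
                            p=focal["p"], n=res.n, alternative="two_sided",
                            term=h["focus"], se=focal["se"],
                            extra={"r_squared": res.r_squared,
                                   "terms": res.terms})


# ---------------------------------------------------------------------------
# bootstrap mediation
# ---------------------------------------------------------------------------

def indirect_effect(path_a: float, path_b: float) -> float:
    """Product-of-coefficients indirect effect a * b."""
    return float(path_a) * float(path_b)


@dataclass
class MediationResult:
    """Mediation decomposition with percentile-bootstrap uncertainty."""

    path_a: float           # treat -> mediator
    path_b: float           # mediator -> outcome, controlling treat
    total_effect: float
    direct_effect: float
    indirect_point: float   # a * b from the full-sample fits
    acme_boot_mean: float
    ci_low: float
    ci_high: float
    p_boot: float
    n_boot: int
    seed: int
    n: int
    n_redraws: int = 0

    @property
    def ci_excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def _ols_coef(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    return beta, rank


def mediate_bootstrap(table: pd.DataFrame, treat: str = "cit",
                      mediator: str = "bias_meta_uncf",
                      outcome: str = "bias_rem_uncf",
                      covariates=("ad", "age", "gender", "education"),
                      n_boot: int = 1000, seed: int = 0,
                      p_method: str = "ci") -> MediationResult:
    """Nonparametric percentile-bootstrap mediation (ACME).

    Fits the mediator model (mediator ~ treat + covariates) and the outcome
    model (outcome ~ treat + mediator + covariates) on each resample of
    participants; the indirect effect per resample is a*b.  All non-binary
    variables (including numerically coded gender) are z-transformed once on
    the full sample before resampling.  Rank-deficient resamples are redrawn
    and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cols = [outcome, mediator, treat] + list(covariates)
    data = table[cols].dropna().copy()
    if "gender" in data.columns:
        data["gender"] = data["gender"].map(GENDER_CODES).astype(float)
    data = zscore_nonbinary(data)
    n = len(data)
    if n < len(cols) + 2:
        raise ValueError("too few complete cases for mediation")

    T = data[treat].to_numpy()
    M = data[mediator].to_numpy()
    Y = data[outcome].to_numpy()
    C = data[list(covariates)].to_numpy()
    ones = np.ones((n, 1))
    X_med = np.column_stack([ones, T, C])       # a = coef 1
    X_out = np.column_stack([ones, T, M, C])    # direct = coef 1, b = coef 2

    beta_m, rank_m = _ols_coef(X_med, M)
    beta_y, rank_y = _ols_coef(X_out, Y)
    beta_t, _ = _ols_coef(X_med, Y)
    if rank_m < X_med.shape[1] or rank_y < X_out.shape[1]:
        raise ValueError("rank-deficient full-sample design")
    path_a = float(beta_m[1])
    direct = float(beta_y[1])
    path_b = float(beta_y[2])
    total = float(beta_t[1])
    point = indirect_effect(path_a, path_b)
    # linear-model decomposition must hold exactly: total = direct + a*b
    if not np.isclose(total, direct + point, atol=1e-8):
        raise RuntimeError("mediation decomposition failed numerically")

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n_redraws = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, n)
        bm, rm = _ols_coef(X_med[idx], M[idx])
        by, ry = _ols_coef(X_out[idx], Y[idx])
        if rm < X_med.shape[1] or ry < X_out.shape[1]:
            n_redraws += 1
            if n_redraws > 10 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        boots[i] = bm[1] * by[2]
        i += 1

    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    frac_le = float(np.mean(boots <= 0.0))
    frac_ge = float(np.mean(boots >= 0.0))
    p = 2.0 * min(frac_le, frac_ge)
    if p_method == "ci":
        # CI inversion cannot resolve below the bootstrap granularity
        p = max(p, 2.0 / n_boot)
    elif p_method != "proportion":
        raise ValueError(f"unknown p_method {p_method!r}")
    return MediationResult(
        path_a=path_a, path_b=path_b, total_effect=total,
        direct_effect=direct, indirect_point=point,
        acme_boot_mean=float(boots.mean()),
        ci_low=float(ci_low), ci_high=float(ci_high),
        p_boot=float(min(p, 1.0)), n_boot=n_boot, seed=seed, n=n,
        n_redraws=n_redraws,
    )


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

@dataclass
class ResultsBundle:
    """Every preregistered test plus the mediation/moderation follow-ups."""

    hypotheses: dict            # h_id -> HypothesisResult
    mediation_cit: MediationResult
    moderation_ad: HypothesisResult
    seed: int
    n: int
    config_hash: str | None = None
    timestamp: str | None = None
    schema_version: int = 1

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "n": self.n,
            "config_hash": self.config_hash,
            "timestamp": self.timestamp,
            "hypotheses": {k: asdict(v) for k, v in self.hypotheses.items()},
            "mediation_cit": asdict(self.mediation_cit),
            "moderation_ad": asdict(self.moderation_ad),
            "notes": ("no multiple-testing correction applied, matching the "
                      "preregistered per-hypothesis analyses"),
        }
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")


def build_cohort_table(scores: pd.DataFrame, factor_scores: pd.DataFrame,
                       participants: pd.DataFrame) -> pd.DataFrame:
    """Join scores, factor scores and covariates into one analysis table."""
    covs = participants[["participant_id", "age", "gender", "education",
                         "icar5", "dprime"]]
    table = (scores.merge(factor_scores[["participant_id", "cit", "ad"]],
                          on="participant_id", how="left")
             .merge(covs, on="participant_id", how="left"))
    return table


def run_all(table: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
            config_hash: str | None = None,
            timestamp: bool = True) -> ResultsBundle:
    """Run the full preregistered battery in order, plus the CIT mediation
    and the AD moderation analogue.  Deterministic for a fixed seed."""
    hypotheses = {h_id: run_hypothesis(h_id, table) for h_id in HYPOTHESIS_IDS}
    mediation = mediate_bootstrap(table, n_boot=n_boot, seed=seed)
    ad_spec = _moderation_hypothesis("ad")
    ad_fit = fit_ols(ad_spec["spec"], table)
    focal = ad_fit.term(ad_spec["focus"])
    moderation_ad = HypothesisResult(
        h_id="moderation_ad", kind="regression", estimate=focal["beta"],
        stat=focal["t"], p=focal["p"], n=ad_fit.n, alternative="two_sided",
        term=ad_spec["focus"], se=focal["se"],
        extra={"r_squared": ad_fit.r_squared})
    ts = (datetime.datetime.now(datetime.timezone.utc).isoformat()
          if timestamp else None)
    n = int(min(h.n for h in hypotheses.values()))
    return ResultsBundle(hypotheses=hypotheses, mediation_cit=mediation,
                         moderation_ad=moderation_ad, seed=seed, n=n,
                         config_hash=config_hash, timestamp=ts)


def headline_outcomes(bundle: ResultsBundle) -> dict:
    """Qualitative pattern of the study's headline findings.

    Returns booleans for: CIT predicting overconfidence (positive,
    significant), AD predicting underconfidence (negative, significant),
    CIT predicting reduced reminder bias (negative, significant), a
    significant negative indirect (mediated) effect with a negative direct
    path (partial mediation), and the absence of a CIT moderation effect.
    """
    h = bundle.hypotheses
    med = bundle.mediation_cit
    return {
        "cit_overconfidence": h["H6a"].estimate > 0 and h["H6a"].significant,
        "ad_underconfidence": h["H8a"].estimate < 0 and h["H8a"].significant,
        "cit_reduced_reminder_bias": h["H5a"].estimate < 0 and h["H5a"].significant,
        "partial_mediation": (med.indirect_point < 0 and med.ci_excludes_zero
                              and med.direct_effect < 0),
        "no_moderation": not h["H7a"].significant,
    }


def directional_signs(bundle: ResultsBundle) -> dict:
    """Sign of every directional estimate in the battery (the moderation
    tests H7a-c have no expected direction and are omitted)."""
    return {h_id: float(np.sign(res.estimate))
            for h_id, res in bundle.hypotheses.items()
            if not h_id.startswith("H7")}


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

_H_TITLES = {
    "H1": "Reminder bias and metacognitive bias are negatively correlated",
    "H2": "Participants use reminders excessively (reminder bias > 0)",
    "H3": "Participants are underconfident (metacognitive bias < 0)",
    "H4": "OIP and AIP are positively correlated (compensatory reminder use)",
    "H5a": "CIT predicts the reminder bias",
    "H5b": "CIT predicts the number of reminders chosen",
    "H5c": "CIT predicts the AIP",
    "H5d": "CIT predicts the reminder bias (working-memory covariate)",
    "H5e": "CIT predicts the reminder bias (cognitive-ability covariate)",
    "H6a": "CIT predicts the metacognitive bias",
    "H6b": "CIT predicts raw confidence",
    "H6c": "CIT predicts the metacognitive bias (cognitive-ability covariate)",
    "H7a": "CIT moderates the confidence-offloading link",
    "H7b": "CIT moderation (working-memory covariate)",
    "H7c": "CIT moderation (cognitive-ability covariate)",
    "H8a": "AD predicts the metacognitive bias",
    "H8b": "AD predicts raw confidence",
    "H8c": "AD predicts the metacognitive bias (cognitive-ability covariate)",
}


def render_report(bundle: ResultsBundle) -> str:
    """Human-readable markdown report, one section per hypothesis."""
    lines = ["# Preregistered analysis report", ""]
    lines.append(f"n = {bundle.n} retained participants; seed = {bundle.seed}; "
                 f"config hash = {bundle.config_hash}")
    lines.append("")
    for h_id in HYPOTHESIS_IDS:
        r = bundle.hypotheses[h_id]
        lines.append(f"## {h_id}: {_H_TITLES[h_id]}")
        if r.kind == "correlation":
            method = r.extra.get("method", "pearson")
            stat = "r" if method == "pearson" else "rho"
            lines.append(f"{stat} = {r.estimate:.3f}, p = {r.p:.4g} "
                         f"({r.alternative}, n = {r.n})")
        elif r.kind == "t_test":
            lines.append(f"m = {r.estimate:.3f}, t({r.n - 1}) = {r.stat:.2f}, "
                         f"p = {r.p:.4g}, d = {r.extra['cohens_d']:.2f} "
                         f"({r.alternative})")
        else:
            lines.append(f"beta = {r.estimate:.3f}, SE = {r.se:.3f}, "
                         f"t = {r.stat:.2f}, p = {r.p:.4g} "
                         f"(term {r.term}, n = {r.n})")
        lines.append("")
    med = bundle.mediation_cit
    lines.append("## Mediation: CIT -> metacognitive bias -> reminder bias")
    lines.append(
        f"a = {med.path_a:.3f}, b = {med.path_b:.3f}, "
        f"indirect (a*b) = {med.indirect_point:.4f}; bootstrap ACME = "
        f"{med.acme_boot_mean:.4f}, 95% CI [{med.ci_low:.4f}, {med.ci_high:.4f}], "
        f"p = {med.p_boot:.4g} ({med.n_boot} resamples); "
        f"direct = {med.direct_effect:.3f}, total = {med.total_effect:.3f}")
    lines.append("")
    m = bundle.moderation_ad
    lines.append("## AD moderation of the confidence-offloading link")
    lines.append(f"beta = {m.estimate:.3f}, SE = {m.se:.3f}, t = {m.stat:.2f}, "
                 f"p = {m.p:.4g} (term {m.term}, n = {m.n})")
    lines.append("")
    lines.append("_No multiple-testing correction applied (preregistered "
                 "per-hypothesis analyses)._")
    return "\n".join(lines) + "\n"
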