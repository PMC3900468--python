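"""Validation statistics for a point-based risk index on a survival cohort.

This module reproduces the standard external-validation pipeline for a
dementia risk score: complete-case filtering, discrimination (the
c-statistic, i.e. the probability that a random incident case scores above a
random non-case, with DeLong confidence intervals, overall / by sex / by
outcome / on a reduced common-variable index), within-study score quartiles,
crude incidence per 1000 person-years by quartile, Cox proportional-hazards
quartile hazard ratios with a linear-trend test, and a young-old vs old-old
per-quartile case-rate comparison.

The c-statistic is computed on incident-case binary status (not a
time-dependent concordance); Cox models use the Breslow tie approximation by
default (Efron available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .scorecards import ScoreCard, build_scorecard, score_cohort

OUTCOME_COLUMN = {"ad": "event_ad", "any_dementia": "event_dementia"}

#: Wald coefficients beyond this magnitude are treated as a monotone
#: partial likelihood (no finite maximiser); the CI is flagged unbounded.
_MONOTONE_COEF = 15.0


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Discrimination


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    outcome: str = "ad"
    subgroup: str = "overall"

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "outcome": self.outcome, "subgroup": self.subgroup,
        }


def _check_two_class(labels: np.ndarray) -> tuple[int, int]:
    n_cases = int(labels.sum())
    n_controls = int(len(labels) - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise EvaluationError("c-statistic requires both cases and non-cases")
    return n_cases, n_controls


def c_statistic(scores, labels) -> float:
    """Mann-Whitney concordance: P(case score > control score) + 1/2 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels must have equal length")
    n1, n0 = _check_two_class(labels)
    ranks = stats.rankdata(scores)  # midranks handle ties
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong variance of the AUC from placement values (structural
    components), midrank form."""
    m, n = len(cases), len(controls)
    all_scores = np.concatenate([cases, controls])
    tx = stats.rankdata(all_scores)
    tz_cases = stats.rankdata(cases)
    tz_controls = stats.rankdata(controls)
    v10 = (tx[:m] - tz_cases) / n              # placements of cases among controls
    v01 = 1.0 - (tx[m:] - tz_controls) / m     # placements of controls among cases
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_confidence_interval(scores, labels, level: float = 0.95,
                            outcome: str = "ad", subgroup: str = "overall",
                            method: str = "delong", n_boot: int = 2000,
                            seed: int = 0) -> AUCResult:
    """c-statistic with a confidence interval (DeLong by default, optional
    percentile bootstrap for cross-checking), truncated to [0, 1].

    Degenerate-variance inputs (e.g. perfect separation) return a zero-width
    interval at the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1, n0 = _check_two_class(labels)
    if n1 < 2 or n0 < 2:
        raise EvaluationError("confidence interval needs >=2 cases and >=2 controls")
    auc = c_statistic(scores, labels)
    if method == "delong":
        var = _delong_variance(scores[labels == 1], scores[labels == 0])
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(max(var, 0.0))
        lo, hi = auc - half, auc + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx1 = np.flatnonzero(labels == 1)
        idx0 = np.flatnonzero(labels == 0)
        reps = np.empty(n_boot)
        for b in range(n_boot):  # stratified resampling keeps both classes
            take = np.concatenate([rng.choice(idx1, n1), rng.choice(idx0, n0)])
            reps[b] = c_statistic(scores[take], labels[take])
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    else:
        raise EvaluationError(f"unknown CI method {method!r}")
    return AUCResult(auc, float(max(0.0, min(lo, auc))), float(min(1.0, max(hi, auc))),
                     n1, n0, outcome, subgroup)


# ---------------------------------------------------------------------------
# Quartiles and incidence


def assign_quartiles(scores) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Within-sample quartile labels (1-4) and the three cut points.

    Cut points are the 25th/50th/75th percentiles (linear interpolation);
    intervals are (-inf, q25], (q25, q50], (q50, q75], (q75, inf) — a score
    tied with a boundary falls in the lower quartile, matching the
    half-open printed quartile ranges of the index's validation tables.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise EvaluationError("cannot assign quartiles to an empty score vector")
    q25, q50, q75 = np.quantile(scores, [0.25, 0.5, 0.75])
    if q25 == q75:
        warnings.warn("degenerate score distribution: quartile boundaries coincide",
                      stacklevel=2)
    labels = 1 + (scores > q25).astype(int) + (scores > q50).astype(int) \
        + (scores > q75).astype(int)
    return labels, (float(q25), float(q50), float(q75))


def incidence_rates(followup_years, events, quartile_labels) -> dict[int, dict]:
    """Crude incidence per 1000 person-years within each quartile."""
    fu = np.asarray(followup_years, dtype=float)
    ev = np.asarray(events, dtype=int)
    ql = np.asarray(quartile_labels, dtype=int)
    out: dict[int, dict] = {}
    for q in sorted(np.unique(ql)):
        sel = ql == q
        py = float(fu[sel].sum())
        n_events = int(ev[sel].sum())
        if py <= 0:
            raise EvaluationError(f"quartile {q}: zero person-years")
        out[q] = {
            "n": int(sel.sum()),
            "events": n_events,
            "person_years": py,
            "incidence_per_1000py": 1000.0 * n_events / py,
            "zero_events": n_events == 0,  # rate 0 with effectively unbounded CI
        }
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class QuartileAnalysis:
    boundaries: tuple[float, float, float]
    quartiles: dict[int, dict]       # n, median_score, score_range, events,
                                     # person_years, incidence, HR + CI
    trend_p: float
    outcome: str = "ad"
    reference_quartile: int = 1
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "boundaries": list(self.boundaries),
            "quartiles": {str(k): v for k, v in self.quartiles.items()},
            "trend_p": self.trend_p,
            "outcome": self.outcome,
            "reference_quartile": self.reference_quartile,
            "flags": list(self.flags),
        }


def _cox_fit(time: np.ndarray, status: np.ndarray, exog: np.ndarray,
             ties: str = "breslow"):
    model = PHReg(time, exog, status=status, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def fit_score_coefficient(df: pd.DataFrame, scores, outcome: str = "ad",
                          ties: str = "breslow") -> dict:
    """Cox fit with the risk score as a single continuous covariate; used
    for per-point log-hazard recovery checks."""
    col = OUTCOME_COLUMN[outcome]
    exog = np.asarray(scores, dtype=float).reshape(-1, 1)
    res = _cox_fit(df["followup_years"].to_numpy(float),
                   df[col].to_numpy(int), exog, ties)
    coef = float(res.params[0])
    se = float(np.sqrt(res.cov_params()[0, 0]))
    return {"coef": coef, "se": se,
            "ci_low": coef - 1.959963984540054 * se,
            "ci_high": coef + 1.959963984540054 * se}


def cox_quartile_hr(df: pd.DataFrame, scores, outcome: str = "ad",
                    ties: str = "breslow") -> QuartileAnalysis:
    """Quartile dose-response analysis.

    Fits a Cox model with indicator covariates for quartiles 2-4 (quartile 1
    is the reference) and reports hazard ratios with Wald 95% CIs, per-
    quartile crude incidence, and a linear-trend p-value from a second model
    with the quartile entered as an ordinal 1-4 covariate (Wald test).
    """
    col = OUTCOME_COLUMN[outcome]
    scores = np.asarray(scores, dtype=float)
    labels, boundaries = assign_quartiles(scores)
    time = df["followup_years"].to_numpy(float)
    status = df[col].to_numpy(int)
    rates = incidence_rates(time, status, labels)
    if rates.get(1, {}).get("events", 0) == 0:
        raise EvaluationError("no events in the reference quartile")
    flags: list[str] = []
    quartiles: dict[int, dict] = {}
    for q in (1, 2, 3, 4):
        sel = labels == q
        entry = dict(rates.get(q, {"n": 0, "events": 0, "person_years": 0.0,
                                   "incidence_per_1000py": float("nan"),
                                   "zero_events": True}))
        if sel.any():
            entry["median_score"] = float(np.median(scores[sel]))
            entry["score_range"] = (float(scores[sel].min()), float(scores[sel].max()))
        else:
            entry["median_score"] = float("nan")
            entry["score_range"] = (float("nan"), float("nan"))
        quartiles[q] = entry
    quartiles[1].update(hazard_ratio=1.0, hr_ci_low=1.0, hr_ci_high=1.0)

    present = sorted(set(labels) - {1})
    if not present:
        # no contrast between quartiles
        for q in (2, 3, 4):
            quartiles[q].update(hazard_ratio=1.0, hr_ci_low=float("nan"),
                                hr_ci_high=float("nan"))
        flags.append("degenerate_quartiles")
        return QuartileAnalysis(boundaries, quartiles, 1.0, outcome, 1, flags)
    exog = np.column_stack([(labels == q).astype(float) for q in present])

    try:
        res = _cox_fit(time, status, exog, ties)
    except Exception as exc:  # noqa: BLE001 - surfaced, not swallowed
        raise EvaluationError(f"Cox quartile model failed to converge: {exc}") from exc
    cov = res.cov_params()
    z = 1.959963984540054
    for j, q in enumerate(present):
        coef = float(res.params[j])
        se = float(np.sqrt(cov[j, j]))
        if not np.isfinite(coef) or abs(coef) > _MONOTONE_COEF:
            flags.append(f"monotone_likelihood_q{q}")
            quartiles[q].update(hazard_ratio=float(np.exp(np.sign(coef) * np.inf)),
                                hr_ci_low=0.0, hr_ci_high=float("inf"))
            continue
        quartiles[q].update(
            hazard_ratio=float(np.exp(coef)),
            hr_ci_low=float(np.exp(coef - z * se)),
            hr_ci_high=float(np.exp(coef + z * se)),
        )

    trend_res = _cox_fit(time, status, labels.astype(float).reshape(-1, 1), ties)
    t_coef = float(trend_res.params[0])
    t_se = float(np.sqrt(trend_res.cov_params()[0, 0]))
    if t_se == 0 or not np.isfinite(t_se):
        trend_p = 1.0
    else:
        trend_p = float(2.0 * stats.norm.sf(abs(t_coef / t_se)))
    return QuartileAnalysis(boundaries, quartiles, trend_p, outcome, 1, flags)


# ---------------------------------------------------------------------------
# Filtering and full index evaluation


def filter_analysis_set(df: pd.DataFrame, card: ScoreCard,
                        missing_policy: str = "strict") -> tuple[pd.DataFrame, dict]:
    """Complete-case analysis set: drop prevalent (baseline) dementia,
    missing outcome, and — under the strict policy — any record missing a
    card factor.  Returns the filtered frame and a per-reason exclusion log.
    """
    if df.empty:
        raise EvaluationError("empty cohort")
    log = {"input_n": int(len(df))}
    keep = pd.Series(True, index=df.index)
    baseline = df.get("baseline_dementia", pd.Series(0, index=df.index)).fillna(0).astype(int) == 1
    log["baseline_dementia"] = int(baseline.sum())
    keep &= ~baseline
    missing_outcome = pd.Series(False, index=df.index)
    for col in ("event_dementia", "event_ad", "followup_years"):
        if col in df.columns:
            missing_outcome |= df[col].isna()
        else:
            raise EvaluationError(f"cohort lacks outcome column {col!r}")
    log["missing_outcome"] = int((missing_outcome & keep).sum())
    keep &= ~missing_outcome
    if missing_policy == "strict":
        incomplete = pd.Series(False, index=df.index)
        for fname in card.value_factor_names():
            if fname in df.columns:
                incomplete |= df[fname].isna()
            else:
                incomplete |= True
        log["incomplete_factors"] = int((incomplete & keep).sum())
        keep &= ~incomplete
    else:
        log["incomplete_factors"] = 0
    out = df.loc[keep]
    log["analyzed_n"] = int(len(out))
    if out.empty:
        raise EvaluationError("no participants remain after exclusions")
    return out, log


def evaluate_index(df: pd.DataFrame, card: ScoreCard,
                   outcomes: tuple[str, ...] = ("ad", "any_dementia"),
                   subgroups: tuple[str, ...] = ("overall", "male", "female"),
                   common_card: ScoreCard | None = None,
                   missing_policy: str = "strict") -> dict:
    """Discrimination report: one AUC (DeLong CI) per outcome x subgroup,
    plus a common-variable rerun on the same analysis set (no re-filtering)
    and the full-minus-common AUC difference."""
    analysis, log = filter_analysis_set(df, card, missing_policy)
    scores = score_cohort(analysis, card, missing_policy)
    common_card = common_card or build_scorecard("anu_adri_common")
    common_scores = score_cohort(analysis, common_card, missing_policy)
    report: dict = {"exclusions": log, "outcomes": {}}
    for outcome in outcomes:
        col = OUTCOME_COLUMN[outcome]
        labels = analysis[col].astype(int).to_numpy()
        block: dict = {}
        for subgroup in subgroups:
            mask = np.ones(len(analysis), dtype=bool) if subgroup == "overall" \
                else (analysis["sex"] == subgroup).to_numpy()
            block[subgroup] = auc_confidence_interval(
                scores.to_numpy()[mask], labels[mask],
                outcome=outcome, subgroup=subgroup).to_dict()
        common = auc_confidence_interval(common_scores.to_numpy(), labels,
                                         outcome=outcome,
                                         subgroup="common_variables")
        block["common_variables"] = common.to_dict()
        block["common_minus_full_auc"] = common.auc - block["overall"]["auc"]
        report["outcomes"][outcome] = block
    return report


# ---------------------------------------------------------------------------
# Age-split quartile comparison


@dataclass
class AgeSplitComparison:
    split_age: int
    quartiles: dict[int, dict]

    def to_dict(self) -> dict:
        return {"split_age": self.split_age,
                "quartiles": {str(k): v for k, v in self.quartiles.items()}}


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise EvaluationError("expected a 2x2 table")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise EvaluationError("chi-square undefined: empty margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def age_split_comparison(df: pd.DataFrame, scores, split_age: int = 70,
                         outcome: str = "any_dementia") -> AgeSplitComparison:
    """Per-quartile comparison of case percentages between young-old
    (< split_age) and old-old (>= split_age) participants.

    Quartiles are computed on the full sample; within each quartile a 2x2
    age-group x case Pearson chi-square (no continuity correction) is
    reported.  Quartiles where one age group is absent (or a margin is
    empty) get a null chi-square entry rather than an error.
    """
    col = OUTCOME_COLUMN[outcome]
    scores = np.asarray(scores, dtype=float)
    labels, _ = assign_quartiles(scores)
    young = (df["age"].to_numpy(float) < split_age)
    old = ~young
    if not young.any() or not old.any():
        raise EvaluationError("both age groups must be non-empty")
    cases = df[col].to_numpy(int)
    out: dict[int, dict] = {}
    for q in (1, 2, 3, 4):
        sel = labels == q
        ny, cy = int((sel & young).sum()), int(cases[sel & young].sum())
        no, co = int((sel & old).sum()), int(cases[sel & old].sum())
        entry = {
            "n_young": ny, "cases_young": cy,
            "pct_young": 100.0 * cy / ny if ny else float("nan"),
            "n_old": no, "cases_old": co,
            "pct_old": 100.0 * co / no if no else float("nan"),
        }
        table = np.array([[cy, ny - cy], [co, no - co]], dtype=float)
        try:
            chi2, p = chi_square_2x2(table)
            entry["chi_square"], entry["p_value"] = chi2, p
        except EvaluationError:
            entry["chi_square"], entry["p_value"] = None, None
        out[q] = entry
    return AgeSplitComparison(split_age, out)
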