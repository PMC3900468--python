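"""Synthetic validation cohorts with a proportional-hazards dementia process.

The three cohorts the index was validated on (a US memory-and-aging panel, a
Swedish old-old population study, and a US cardiovascular-health cohort) are
not publicly deposited, so this module generates stand-in cohorts that
reproduce the published marginal category frequencies of each cohort, the
cohort-specific factor availability, and mean follow-up lengths, with a
configurable dose-response between the risk score and time to dementia.

The outcome model is the simplest proportional-hazards construction: an
exponential event time with rate ``baseline_hazard * exp(beta_per_point *
(score - mean score))`` (a Weibull shape parameter is exposed for
extension), independent exponential censoring, and incident dementia
classified as Alzheimer's disease with probability ``ad_fraction``
(AD accounts for roughly three quarters of dementia).  Factors are sampled
independently (only marginals are published); this is a deliberate,
documented simplification.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scorecards import SEXES, ScoreCard, build_scorecard, score_cohort

OUTCOME_COLUMNS = ("followup_years", "event_dementia", "event_ad", "baseline_dementia")


def _norm(counts: dict[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


# Published per-cohort category counts (normalised to probabilities below).
# The sex marginal uses the printed percentage directly; age-band
# distributions are conditional on sex.
_MAP = {
    "male_fraction": 0.248,
    "age_by_sex": {
        "male": {"<65": 6, "65-69": 12, "70-74": 39, "75-79": 69,
                 "80-84": 104, "85-89": 53, ">=90": 17},
        "female": {"<65": 40, "65-69": 73, "70-74": 98, "75-79": 199,
                   "80-84": 247, "85-89": 149, ">=90": 57},
    },
    "factors": {
        "education": {"<8": 42, "8-11": 60, ">11": 1061},
        "diabetes": {"no": 1016, "yes": 147},
        "tbi": {"no": 1098, "yes": 65},
        "cognitive_activity": {"low": 408, "moderate": 600, "high": 155},
        "social_network": {"high": 97, "medium_high": 328, "medium_low": 422, "low": 125},
        "smoking": {"never": 685, "former": 432, "current": 44},
        "alcohol": {"abstainer": 193, "light_moderate": 887, "heavy": 80},
        "physical_activity": {"low": 465, "medium": 495, "high": 203},
    },
    "min_age": 54,
    "censor_time_mean": 3.5,
    "complete_fraction": 903 / 1164,
}

_KP = {
    "male_fraction": 0.25,
    "age_by_sex": {
        "male": {"70-74": 6, "75-79": 141, "80-84": 106, "85-89": 50, ">=90": 22},
        "female": {"70-74": 15, "75-79": 376, "80-84": 306, "85-89": 194, ">=90": 85},
    },
    "factors": {
        "education": {"<8": 654, "8-11": 253, ">11": 389},
        "diabetes": {"no": 1187, "yes": 114},
        "tbi": {"no": 877, "yes": 86},
        "social_network": {"high": 13, "medium_high": 226, "medium_low": 880, "low": 84},
        "smoking": {"never": 867, "current": 104},
        "alcohol": {"abstainer": 391, "light_moderate": 577},
    },
    "min_age": 74,
    "censor_time_mean": 6.0,
    "complete_fraction": 905 / 1301,
}

_CVHS = {
    "male_fraction": 0.409,
    "age_by_sex": {
        "male": {"<65": 30, "65-69": 356, "70-74": 607, "75-79": 263,
                 "80-84": 86, "85-89": 24, ">=90": 3},
        "female": {"<65": 62, "65-69": 626, "70-74": 787, "75-79": 355,
                   "80-84": 123, "85-89": 18, ">=90": 1},
    },
    "factors": {
        "education": {"<8": 367, "8-11": 439, ">11": 2537},
        "diabetes": {"no": 2805, "yes": 537},
        "depressive_symptoms": {"no": 2811, "yes": 180},
        "smoking": {"never": 1558, "former": 1426, "current": 364},
        "alcohol": {"abstainer": 1585, "light_moderate": 1634, "heavy": 129},
        "physical_activity": {"low": 993, "medium": 1677, "high": 671},
        "fish_intake": {"0-0.25": 388, "0.26-2": 1168, "2.1-4": 1263, ">=4.1": 119},
    },
    "min_age": 62,
    "censor_time_mean": 6.0,
    "complete_fraction": 2496 / 3375,
}

COHORT_PRESETS = {"map_like": _MAP, "kp_like": _KP, "cvhs_like": _CVHS}
_PRESET_VARIANT = {"map_like": "anu_adri_map", "kp_like": "anu_adri_kp",
                   "cvhs_like": "anu_adri_cvhs"}

# Marginals for the comparator-index factors (blood pressure, cholesterol,
# BMI class, binary activity); these are not published for the validation
# cohorts and are synthetic, plausible-prevalence placeholders.
CAIDE_FACTOR_PROBS = {
    "caide_education": {">=10": 0.80, "7-9": 0.12, "<7": 0.08},
    "systolic_bp": {"normal": 0.55, "high": 0.45},
    "bmi": {"normal": 0.80, "obese": 0.20},
    "cholesterol": {"normal": 0.70, "high": 0.30},
    "caide_physical_activity": {"active": 0.60, "inactive": 0.40},
}

#: Inclusive integer age support per band; the open-ended >=90 band is
#: bounded at 99 so a uniform draw is well defined.
AGE_BANDS = {"<65": (None, 64), "65-69": (65, 69), "70-74": (70, 74),
             "75-79": (75, 79), "80-84": (80, 84), "85-89": (85, 89),
             ">=90": (90, 99)}


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Full description of one synthetic cohort draw.

    ``beta_per_point`` is the log-hazard increment per risk-score point (0
    switches the dose-response off); ``baseline_hazard`` is the yearly
    dementia hazard of an average-scoring participant; ``censor_time_mean``
    is the mean of the exponential censoring time in years;
    ``missingness`` is the probability that a participant has one factor
    value blanked (defaults per cohort reproduce the published
    complete-case fractions when enabled).
    """

    n: int = 1000
    scorecard_variant: str = "anu_adri_cvhs"
    male_fraction: float = 0.409
    age_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    category_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    min_age: int = 62
    beta_per_point: float = 0.05
    baseline_hazard: float = 0.02
    weibull_shape: float = 1.0
    ad_fraction: float = 0.75
    censor_time_mean: float = 6.0
    missingness: float = 0.0
    include_caide_factors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SyntheticConfigError("n must be >= 1")
        if self.baseline_hazard <= 0:
            raise SyntheticConfigError("baseline_hazard must be > 0")
        if not (0.0 <= self.ad_fraction <= 1.0):
            raise SyntheticConfigError("ad_fraction must lie in [0, 1]")
        if not (0.0 <= self.missingness <= 1.0):
            raise SyntheticConfigError("missingness must lie in [0, 1]")
        for name, probs in list(self.category_probs.items()) + [
            (f"age[{s}]", p) for s, p in self.age_probs.items()
        ]:
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise SyntheticConfigError(
                    f"probabilities for {name} sum to {total}, expected 1"
                )

    @classmethod
    def for_cohort(cls, name: str, n: int, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Preset configuration emulating one of the three validation cohorts."""
        if name not in COHORT_PRESETS:
            raise SyntheticConfigError(
                f"unknown cohort {name!r}; choose from {sorted(COHORT_PRESETS)}"
            )
        p = COHORT_PRESETS[name]
        kwargs: dict = dict(
            n=n,
            seed=seed,
            scorecard_variant=_PRESET_VARIANT[name],
            male_fraction=p["male_fraction"],
            age_probs={s: _norm(c) for s, c in p["age_by_sex"].items()},
            category_probs={f: _norm(c) for f, c in p["factors"].items()},
            min_age=p["min_age"],
            censor_time_mean=p["censor_time_mean"],
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float], n: int) -> np.ndarray:
    labels = list(probs)
    return rng.choice(labels, size=n, p=np.asarray([probs[l] for l in labels]))


def sample_factors(config: SyntheticConfig,
                   rng: np.random.Generator | None = None,
                   card: ScoreCard | None = None) -> pd.DataFrame:
    """Draw baseline records (outcome fields unset).

    Sex is drawn first, the age band conditional on sex, then a uniform
    integer age within the band (the cohort's minimum age bounds the lowest
    band).  All other factors are drawn independently from their category
    distributions.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    card = card or build_scorecard(config.scorecard_variant)
    n = config.n
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    age = np.empty(n, dtype=int)
    for s in SEXES:
        idx = np.flatnonzero(sex == s)
        if idx.size == 0:
            continue
        probs = config.age_probs.get(s)
        if not probs:
            raise SyntheticConfigError(f"no age distribution for sex {s!r}")
        bands = _draw_categorical(rng, probs, idx.size)
        for band in probs:
            lo, hi = AGE_BANDS[band]
            # the cohort's minimum entry age truncates the lowest band(s)
            lo = config.min_age if lo is None else max(lo, config.min_age)
            sel = idx[bands == band]
            age[sel] = rng.integers(lo, hi + 1, size=sel.size)
    data: dict[str, np.ndarray] = {
        "id": np.array([f"P{i:06d}" for i in range(n)]),
        "sex": sex,
        "age": age,
    }
    value_factors = set(card.value_factor_names())
    for fname, probs in config.category_probs.items():
        if fname not in value_factors:
            raise SyntheticConfigError(
                f"category_probs includes {fname!r}, not a value factor of "
                f"scorecard {card.name!r}"
            )
        labels = set(probs)
        known = set(card[fname].labels())
        if not labels <= known:
            raise SyntheticConfigError(
                f"probability vector for {fname!r} has labels {sorted(labels - known)} "
                "unknown to the scorecard"
            )
        data[fname] = _draw_categorical(rng, probs, n)
    missing_cols = value_factors - set(config.category_probs)
    if missing_cols:
        raise SyntheticConfigError(
            f"no category probabilities for scorecard factors {sorted(missing_cols)}"
        )
    if config.include_caide_factors:
        for fname, probs in CAIDE_FACTOR_PROBS.items():
            data[fname] = _draw_categorical(rng, probs, n)
    return pd.DataFrame(data)


def simulate_outcome(participants: pd.DataFrame, config: SyntheticConfig,
                     rng: np.random.Generator | None = None,
                     scores: pd.Series | None = None) -> pd.DataFrame:
    """Attach proportional-hazards outcomes to baseline records.

    The dementia time is Weibull (exponential at the default shape 1) with
    rate ``baseline_hazard * exp(beta_per_point * (score - mean score))``;
    centring keeps the baseline hazard interpretable as that of an
    average-scoring participant.  Censoring is exponential with mean
    ``censor_time_mean``; an incident dementia is AD with probability
    ``ad_fraction``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if scores is None:
        card = build_scorecard(config.scorecard_variant)
        scores = score_cohort(participants, card, missing_policy="strict")
    s = scores.to_numpy(dtype=float)
    rate = config.baseline_hazard * np.exp(config.beta_per_point * (s - s.mean()))
    u = rng.random(len(s))
    t_event = (-np.log(u) / rate) ** (1.0 / config.weibull_shape)
    if config.censor_time_mean <= 0:
        t_censor = np.zeros(len(s))
    else:
        t_censor = rng.exponential(config.censor_time_mean, size=len(s))
    event = t_event <= t_censor
    is_ad = event & (rng.random(len(s)) < config.ad_fraction)
    out = participants.copy()
    out["followup_years"] = np.minimum(t_event, t_censor)
    out["event_dementia"] = event.astype(int)
    out["event_ad"] = is_ad.astype(int)
    out["baseline_dementia"] = 0
    out.attrs["true_scores"] = dict(zip(out["id"], scores.astype(int)))
    return out


def _inject_missingness(df: pd.DataFrame, config: SyntheticConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Blank one uniformly chosen factor value for a ``missingness`` share
    of participants, so the complete-case fraction is 1 - missingness in
    expectation."""
    if config.missingness <= 0:
        return df
    factor_cols = [c for c in config.category_probs if c in df.columns]
    if not factor_cols:
        return df
    df = df.copy()
    hit = rng.random(len(df)) < config.missingness
    which = rng.integers(0, len(factor_cols), size=len(df))
    for j, col in enumerate(factor_cols):
        df.loc[hit & (which == j), col] = np.nan
    return df


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Full draw: factors -> true scores -> outcomes -> optional missingness.

    Outcomes are simulated from the complete (pre-missingness) records, so
    injected missingness is non-informative.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    card = build_scorecard(config.scorecard_variant)
    base = sample_factors(config, rng, card)
    scores = score_cohort(base, card, missing_policy="strict")
    cohort = simulate_outcome(base, config, rng, scores)
    return _inject_missingness(cohort, config, rng)


def make_fixture(name: str, n: int, seed: int, path: str | Path,
                 missingness: float | None = None, **overrides) -> Path:
    """Write a cohort CSV (plus an adjacent ``<stem>.meta.json`` recording
    the seed and configuration) emulating one of the validation cohorts.

    Unavailable factors are omitted as columns, matching each cohort's
    published factor availability.  Idempotent for a fixed seed.
    """
    if missingness is not None:
        overrides["missingness"] = missingness
    config = SyntheticConfig.for_cohort(name, n=n, seed=seed, **overrides)
    cohort = generate_cohort(config)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, float_format="%.6f")
    meta = {"cohort": name, "seed": seed, "config": config.to_dict()}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return path
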