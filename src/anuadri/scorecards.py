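"""Point-based risk index scorecards and individual scoring.

The ANU-ADRI is an additive self-report index of Alzheimer's disease risk:
each risk or protective factor is a small categorical variable whose levels
carry integer points (negative for protective levels, e.g. high cognitive
activity or light-to-moderate alcohol use), and an individual's score is the
plain sum of the selected category points.  Age points are stratified by sex.
The CAIDE midlife risk score is carried as a comparator index in the same
representation.

The published point table ships as JSON under ``anuadri/data``; cohort
variants of the index (validation cohorts measured only 8-10 of the 15
factors) are factor subsets of the full table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

MISSING = None  # sentinel for an unobserved factor value

SEXES = ("male", "female")

#: Factor subsets for each supported scorecard variant.  Cohort variants
#: mirror which factors each validation cohort actually measured; the
#: "common" variant is the intersection available in all three cohorts
#: (age/sex, education, diabetes, smoking, alcohol).
VARIANT_FACTORS: dict[str, tuple[str, ...]] = {
    "anu_adri_full": (
        "age", "education", "diabetes", "tbi", "depressive_symptoms",
        "cognitive_activity", "social_network", "smoking", "alcohol",
        "physical_activity", "fish_intake",
    ),
    "anu_adri_map": (
        "age", "education", "diabetes", "tbi", "cognitive_activity",
        "social_network", "smoking", "alcohol", "physical_activity",
    ),
    "anu_adri_kp": (
        "age", "education", "diabetes", "tbi", "social_network",
        "smoking", "alcohol",
    ),
    "anu_adri_cvhs": (
        "age", "education", "diabetes", "depressive_symptoms", "smoking",
        "alcohol", "physical_activity", "fish_intake",
    ),
    "anu_adri_common": ("age", "education", "diabetes", "smoking", "alcohol"),
    "caide": (
        "caide_age", "sex", "caide_education", "systolic_bp", "bmi",
        "cholesterol", "caide_physical_activity",
    ),
    "caide_no_bmi": (
        "caide_age", "sex", "caide_education", "systolic_bp",
        "cholesterol", "caide_physical_activity",
    ),
    "caide_no_bmi_no_chol": (
        "caide_age", "sex", "caide_education", "systolic_bp",
        "caide_physical_activity",
    ),
}

#: The KP cohort asked only about current vs never smoking.
_KP_SMOKING_LABELS = ("never", "current")


class ScorecardError(ValueError):
    """Invalid scorecard construction or scoring request."""


@dataclass(frozen=True)
class FactorCategory:
    """One level of a categorical risk factor and its integer points.

    ``age_min``/``age_max`` (inclusive integer years) are set only for
    categories of age-derived factors.
    """

    label: str
    points: int
    age_min: int | None = None
    age_max: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.points, int) or isinstance(self.points, bool):
            raise ScorecardError(f"points must be an integer, got {self.points!r}")


@dataclass
class RiskFactor:
    """A categorical risk/protective factor.

    Exactly one of ``categories`` (unstratified) or ``by_sex`` (a per-sex
    category list; used only for the sex-stratified age factor) is set.
    ``derived_from`` marks factors whose category is resolved from the
    participant record itself ("age" or "sex") rather than from a factor
    column.
    """

    name: str
    categories: list[FactorCategory] | None = None
    by_sex: dict[str, list[FactorCategory]] | None = None
    derived_from: str | None = None

    def __post_init__(self) -> None:
        if (self.categories is None) == (self.by_sex is None):
            raise ScorecardError(
                f"factor {self.name!r}: exactly one of categories/by_sex required"
            )
        for cats in self._strata().values():
            if len(cats) < 2:
                raise ScorecardError(f"factor {self.name!r}: need >=2 categories")
            labels = [c.label for c in cats]
            if len(set(labels)) != len(labels):
                raise ScorecardError(f"factor {self.name!r}: duplicate labels")

    def _strata(self) -> dict[str | None, list[FactorCategory]]:
        if self.by_sex is not None:
            return dict(self.by_sex)
        return {None: list(self.categories or [])}

    @property
    def stratified_by_sex(self) -> bool:
        return self.by_sex is not None

    @property
    def protective(self) -> bool:
        return any(c.points < 0 for cats in self._strata().values() for c in cats)

    def all_categories(self) -> list[FactorCategory]:
        return [c for cats in self._strata().values() for c in cats]

    def labels(self, sex: str | None = None) -> list[str]:
        if self.stratified_by_sex:
            if sex is None:  # union over strata, order preserved
                seen: dict[str, None] = {}
                for cats in self._strata().values():
                    for c in cats:
                        seen.setdefault(c.label, None)
                return list(seen)
            return [c.label for c in (self.by_sex or {})[sex]]
        return [c.label for c in (self.categories or [])]

    def points_for(self, label: str, sex: str | None = None) -> int:
        cats = (self.by_sex or {})[sex] if self.stratified_by_sex else self.categories
        for c in cats or []:
            if c.label == label:
                return c.points
        raise ScorecardError(f"factor {self.name!r}: unknown category {label!r}")

    def category_for_age(self, age_years: float, sex: str | None = None) -> FactorCategory:
        """Resolve an age-derived factor's category; fractional ages floor."""
        if self.derived_from != "age":
            raise ScorecardError(f"factor {self.name!r} is not age-derived")
        age = math.floor(age_years)
        cats = (self.by_sex or {})[sex] if self.stratified_by_sex else self.categories
        for c in cats or []:
            if (c.age_min is None or age >= c.age_min) and (
                c.age_max is None or age <= c.age_max
            ):
                return c
        raise ScorecardError(f"factor {self.name!r}: no age band for age {age}")

    def min_points(self) -> int:
        return min(c.points for c in self.all_categories())

    def max_points(self) -> int:
        return max(c.points for c in self.all_categories())


@dataclass
class ScoreCard:
    """An ordered collection of risk factors forming an additive index."""

    name: str
    factors: list[RiskFactor]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ScorecardError(f"scorecard {self.name!r}: duplicate factor names")

    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def __getitem__(self, name: str) -> RiskFactor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def value_factor_names(self) -> list[str]:
        """Factors whose category comes from a data column (not age/sex)."""
        return [f.name for f in self.factors if f.derived_from is None]

    # --- JSON serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(_card_to_dict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScoreCard":
        return _card_from_dict(json.loads(text))


@dataclass
class Participant:
    """One baseline record of a dementia-free cohort member."""

    id: str
    sex: str
    age_years: float
    factor_values: dict[str, str | None] = field(default_factory=dict)
    followup_years: float = 0.0
    event_dementia: int = 0
    event_ad: int = 0
    baseline_dementia: int = 0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ScorecardError(f"sex must be male/female, got {self.sex!r}")
        if self.age_years < 0:
            raise ScorecardError("age_years must be >= 0")
        if self.followup_years < 0:
            raise ScorecardError("followup_years must be >= 0")
        if self.event_ad and not self.event_dementia:
            raise ScorecardError("event_ad=1 requires event_dementia=1 (AD is a dementia subtype)")


@dataclass(frozen=True)
class ScoreResult:
    participant_id: str
    score: int
    n_factors_used: int
    missing_factors: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Building scorecards


def _category_from_dict(d: Mapping) -> FactorCategory:
    return FactorCategory(
        label=d["label"],
        points=int(d["points"]),
        age_min=d.get("age_min"),
        age_max=d.get("age_max"),
    )


def _card_from_dict(doc: Mapping) -> ScoreCard:
    factors = []
    for fd in doc["factors"]:
        cats = fd["categories"]
        if isinstance(cats, dict):
            by_sex = {s: [_category_from_dict(c) for c in cl] for s, cl in cats.items()}
            factors.append(RiskFactor(fd["name"], by_sex=by_sex,
                                      derived_from=fd.get("derived_from")))
        else:
            factors.append(RiskFactor(fd["name"],
                                      categories=[_category_from_dict(c) for c in cats],
                                      derived_from=fd.get("derived_from")))
    return ScoreCard(doc["name"], factors, dict(doc.get("metadata", {})))


def _card_to_dict(card: ScoreCard) -> dict:
    def cat(c: FactorCategory) -> dict:
        d = {"label": c.label, "points": c.points}
        if c.age_min is not None:
            d["age_min"] = c.age_min
        if c.age_max is not None:
            d["age_max"] = c.age_max
        return d

    factors = []
    for f in card.factors:
        fd: dict = {"name": f.name, "stratified_by_sex": f.stratified_by_sex}
        if f.derived_from:
            fd["derived_from"] = f.derived_from
        if f.by_sex is not None:
            fd["categories"] = {s: [cat(c) for c in cl] for s, cl in f.by_sex.items()}
        else:
            fd["categories"] = [cat(c) for c in f.categories or []]
        factors.append(fd)
    return {"name": card.name, "metadata": card.metadata, "factors": factors}


def _load_bundled(name: str) -> ScoreCard:
    text = resources.files("anuadri.data").joinpath(f"{name}.json").read_text()
    return _card_from_dict(json.loads(text))


def _subset_categories(factor: RiskFactor, keep: Iterable[str]) -> RiskFactor:
    keep = set(keep)
    return RiskFactor(
        factor.name,
        categories=[c for c in (factor.categories or []) if c.label in keep],
        derived_from=factor.derived_from,
    )


def build_scorecard(variant: str, overrides: Mapping[str, Mapping[str, int]] | None = None) -> ScoreCard:
    """Build a named scorecard variant from the bundled point tables.

    Parameters
    ----------
    variant
        One of ``anu_adri_full``, the cohort subsets ``anu_adri_map`` /
        ``anu_adri_kp`` / ``anu_adri_cvhs``, the cross-cohort
        ``anu_adri_common``, or ``caide`` / ``caide_no_bmi`` /
        ``caide_no_bmi_no_chol``.
    overrides
        Optional ``{factor_name: {category_label: points}}`` replacing
        individual point values (e.g. assigning points to heavy alcohol use,
        which the published table leaves unscored).
    """
    if variant not in VARIANT_FACTORS:
        raise ScorecardError(
            f"unknown scorecard variant {variant!r}; choose from {sorted(VARIANT_FACTORS)}"
        )
    base = _load_bundled("caide" if variant.startswith("caide") else "anu_adri")
    wanted = VARIANT_FACTORS[variant]
    factors = [base[name] for name in wanted]
    if variant == "anu_adri_kp":
        factors = [
            _subset_categories(f, _KP_SMOKING_LABELS) if f.name == "smoking" else f
            for f in factors
        ]
    card = ScoreCard(variant, factors, dict(base.metadata))
    if overrides:
        card = apply_overrides(card, overrides)
    return card


def apply_overrides(card: ScoreCard, overrides: Mapping[str, Mapping[str, int]]) -> ScoreCard:
    """Return a copy of ``card`` with selected category points replaced."""
    factor_map = {f.name: f for f in card.factors}
    for fname in overrides:
        if fname not in factor_map:
            raise ScorecardError(f"override references unknown factor {fname!r}")
    new_factors = []
    for f in card.factors:
        ov = overrides.get(f.name)
        if not ov:
            new_factors.append(f)
            continue
        known = {c.label for c in f.all_categories()}
        for label in ov:
            if label not in known:
                raise ScorecardError(
                    f"override references unknown category {label!r} of factor {f.name!r}"
                )

        def patch(cats: list[FactorCategory]) -> list[FactorCategory]:
            return [
                FactorCategory(c.label, int(ov.get(c.label, c.points)), c.age_min, c.age_max)
                for c in cats
            ]

        if f.by_sex is not None:
            nf = RiskFactor(f.name, by_sex={s: patch(cl) for s, cl in f.by_sex.items()},
                            derived_from=f.derived_from)
        else:
            nf = RiskFactor(f.name, categories=patch(f.categories or []),
                            derived_from=f.derived_from)
        new_factors.append(nf)
    return ScoreCard(card.name, new_factors, dict(card.metadata))


# ---------------------------------------------------------------------------
# Scoring


def _factor_points(p: Participant, factor: RiskFactor) -> int | None:
    """Points contributed by one factor, or None if the value is missing."""
    if factor.derived_from == "age":
        sex = p.sex if factor.stratified_by_sex else None
        return factor.category_for_age(p.age_years, sex).points
    if factor.derived_from == "sex":
        return factor.points_for(p.sex)
    value = p.factor_values.get(factor.name, MISSING)
    if value is MISSING or (isinstance(value, float) and math.isnan(value)):
        return None
    return factor.points_for(value)


def score_participant(p: Participant, card: ScoreCard,
                      missing_policy: str = "strict") -> ScoreResult:
    """Score one participant: the sum of selected category points.

    Under ``strict`` (the default, matching a complete-case analysis) any
    missing factor raises; under ``skip`` missing factors contribute 0 and
    are reported in ``missing_factors``.
    """
    if missing_policy not in ("strict", "skip"):
        raise ScorecardError(f"unknown missing_policy {missing_policy!r}")
    if p.baseline_dementia:
        raise ScorecardError(
            f"participant {p.id}: prevalent dementia at baseline is excluded from scoring"
        )
    total = 0
    used = 0
    missing: list[str] = []
    for factor in card.factors:
        pts = _factor_points(p, factor)
        if pts is None:
            if missing_policy == "strict":
                raise ScorecardError(
                    f"participant {p.id}: missing value for factor {factor.name!r} "
                    "under strict policy"
                )
            missing.append(factor.name)
        else:
            total += pts
            used += 1
    return ScoreResult(p.id, total, used, tuple(missing))


def score_cohort(df: pd.DataFrame, card: ScoreCard,
                 missing_policy: str = "strict") -> pd.Series:
    """Vectorised scoring of a cohort table.

    ``df`` follows the participant data dictionary: ``sex`` and ``age``
    columns plus one column per (non-derived) card factor holding category
    labels, NaN/empty meaning missing.  Returns an integer Series of scores
    aligned to ``df.index`` (float with NaN never occurs: strict raises,
    skip treats missing as 0).
    """
    if missing_policy not in ("strict", "skip"):
        raise ScorecardError(f"unknown missing_policy {missing_policy!r}")
    total = pd.Series(0, index=df.index, dtype="int64")
    for factor in card.factors:
        if factor.derived_from == "age":
            ages = df["age"].astype(float)
            if factor.stratified_by_sex:
                pts = pd.Series(0, index=df.index, dtype="int64")
                for sex in SEXES:
                    mask = df["sex"] == sex
                    if mask.any():
                        pts.loc[mask] = _age_points(ages[mask], factor, sex)
            else:
                pts = _age_points(ages, factor, None)
        elif factor.derived_from == "sex":
            table = {lab: factor.points_for(lab) for lab in factor.labels()}
            pts = df["sex"].map(table)
        else:
            if factor.name not in df.columns:
                if missing_policy == "skip":
                    continue
                raise ScorecardError(f"cohort table lacks factor column {factor.name!r}")
            col = df[factor.name]
            table = {lab: factor.points_for(lab) for lab in factor.labels()}
            pts = col.map(table)
            unknown = col.notna() & pts.isna()
            if unknown.any():
                bad = sorted(col[unknown].unique())
                raise ScorecardError(
                    f"unknown categories {bad!r} for factor {factor.name!r}"
                )
            if pts.isna().any():
                if missing_policy == "strict":
                    raise ScorecardError(
                        f"missing values for factor {factor.name!r} under strict policy"
                    )
                pts = pts.fillna(0)
        total = total + pts.astype("int64")
    return total


def _age_points(ages: pd.Series, factor: RiskFactor, sex: str | None) -> pd.Series:
    cats = (factor.by_sex or {})[sex] if factor.stratified_by_sex else factor.categories
    floored = ages.apply(math.floor)
    out = pd.Series(pd.NA, index=ages.index, dtype="object")
    for c in cats or []:
        lo = -1 if c.age_min is None else c.age_min
        hi = 10**9 if c.age_max is None else c.age_max
        out[(floored >= lo) & (floored <= hi)] = c.points
    if out.isna().any():
        raise ScorecardError(f"ages outside the bands of factor {factor.name!r}")
    return out.astype("int64")


# ---------------------------------------------------------------------------
# Ranges and weight derivation


def theoretical_range(card: ScoreCard) -> tuple[int, int]:
    """Theoretical (min, max) total score of a scorecard.

    The minimum sums each factor's lowest-point category (for the
    sex-stratified age factor, the minimum over both sexes' bands); the
    maximum is analogous.
    """
    if not card.factors:
        raise ScorecardError("empty scorecard has no score range")
    lo = sum(f.min_points() for f in card.factors)
    hi = sum(f.max_points() for f in card.factors)
    return lo, hi


def derive_points(risk_ratio: float, scale: float) -> int:
    """Convert a pooled risk/odds ratio to integer points.

    Points are the log risk ratio (the beta-weight of the factor) scaled by
    a constant and rounded half away from zero, so protective ratios (<1)
    yield negative points.  The bundled published table, not this function,
    is the source of truth for the ANU-ADRI points.
    """
    if not (risk_ratio > 0):
        raise ScorecardError("risk_ratio must be positive")
    if not (scale > 0):
        raise ScorecardError("scale must be positive")
    x = scale * math.log(risk_ratio)
    return int(math.copysign(math.floor(abs(x) + 0.5), x))
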