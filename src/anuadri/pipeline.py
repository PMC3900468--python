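"""Cohort CSV I/O, run configuration, and the end-to-end analysis pipeline.

A run goes: read (or simulate) a cohort -> complete-case filter -> score ->
quartiles + incidence + Cox hazard ratios -> c-statistics (overall, by sex,
common variables) -> optional age-split comparison -> optional CAIDE
comparator -> a JSON results document (mirroring the structure of the
index's published validation tables) plus a Markdown report and a manifest,
all under one run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluation as ev
from .scorecards import ScoreCard, ScorecardError, build_scorecard, score_cohort
from .synthetic import SyntheticConfig, generate_cohort

log = logging.getLogger("anuadri")

MANDATORY_COLUMNS = ("id", "sex", "age", "followup_years",
                     "event_ad", "event_dementia", "baseline_dementia")
_NUMERIC_COLUMNS = ("age", "followup_years", "event_ad", "event_dementia",
                    "baseline_dementia")


class PipelineError(RuntimeError):
    """A hard, stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (file paths resolved at run time)."""

    input_csv: str | None = None
    synthetic: dict | None = None          # SyntheticConfig kwargs, or
    synthetic_cohort: str | None = None    # a cohort preset name
    n: int = 2000
    # None = infer from the synthetic cohort preset, else the full index
    scorecard_variant: str | None = None
    outcomes: tuple[str, ...] = ("ad", "any_dementia")
    subgroups: tuple[str, ...] = ("overall", "male", "female")
    missing_policy: str = "strict"
    ties: str = "breslow"
    ci_method: str = "delong"
    age_split: int | None = 70
    include_caide: bool = False
    output_dir: str = "anuadri_run"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys {sorted(unknown)}")
        for key in ("outcomes", "subgroups"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# CSV reading and validation


def read_cohort_csv(path: str | Path, card: ScoreCard) -> tuple[pd.DataFrame, dict]:
    """Parse a participant CSV against a scorecard's data dictionary.

    Structural problems (missing mandatory columns, unparseable numerics)
    are hard errors; per-row data problems (unknown category labels,
    negative follow-up, an AD event without a dementia event) are collected
    into the returned validation report.  Factor columns absent from the
    card are ignored; card factors absent from the CSV are reported (they
    make strict scoring impossible but are not structural failures).
    """
    path = Path(path)
    if not path.exists():
        raise PipelineError("read", f"input file {path} does not exist")
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=True)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PipelineError("read", f"missing mandatory columns {missing_cols}")
    for col in _NUMERIC_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise PipelineError("read", f"column {col!r} is not numeric: {exc}") from exc
    report: dict = {"n_rows": int(len(df)), "issues": []}

    def flag(mask: pd.Series, kind: str, detail: str = "") -> None:
        for rid in df.loc[mask, "id"].tolist():
            report["issues"].append({"id": rid, "kind": kind, "detail": detail})

    flag((df["event_ad"].fillna(0) > df["event_dementia"].fillna(0)),
         "ad_without_dementia", "event_ad=1 but event_dementia=0")
    flag(df["followup_years"] < 0, "negative_followup")
    flag(~df["sex"].isin(("male", "female")), "unknown_sex")
    for factor in card.factors:
        if factor.derived_from is not None:
            continue
        if factor.name not in df.columns:
            report["issues"].append(
                {"id": None, "kind": "missing_factor_column", "detail": factor.name})
            continue
        known = set(factor.labels())
        col = df[factor.name]
        bad = col.notna() & ~col.isin(known)
        flag(bad, "unknown_category", factor.name)
    report["n_issues"] = len(report["issues"])
    return df, report


# ---------------------------------------------------------------------------
# Pipeline


def _score_summary(scores: pd.Series) -> dict:
    qlabels, boundaries = ev.assign_quartiles(scores)
    quartiles = {}
    for q in (1, 2, 3, 4):
        sel = qlabels == q
        vals = scores.to_numpy()[sel]
        quartiles[str(q)] = {
            "n": int(sel.sum()),
            "median": float(pd.Series(vals).median()) if sel.any() else math.nan,
            "range": [float(vals.min()), float(vals.max())] if sel.any() else [math.nan] * 2,
        }
    return {"mean": float(scores.mean()), "sd": float(scores.std(ddof=1)),
            "boundaries": list(boundaries), "quartiles": quartiles}


def _caide_block(analysis: pd.DataFrame, config: RunConfig) -> dict:
    """CAIDE comparator: AUCs for the full comparator card and the variants
    excluding BMI, and BMI + cholesterol (the older validation cohorts make
    midlife adiposity/cholesterol weights inapplicable)."""
    block: dict = {}
    for variant in ("caide", "caide_no_bmi", "caide_no_bmi_no_chol"):
        card = build_scorecard(variant)
        needed = [f for f in card.value_factor_names() if f not in analysis.columns]
        if needed:
            raise PipelineError(
                "caide", f"cohort lacks columns {needed} required by {variant}")
        scores = score_cohort(analysis, card, config.missing_policy)
        entry: dict = {}
        for outcome in config.outcomes:
            col = ev.OUTCOME_COLUMN[outcome]
            entry[outcome] = ev.auc_confidence_interval(
                scores.to_numpy(), analysis[col].astype(int).to_numpy(),
                outcome=outcome, subgroup=variant,
                method=config.ci_method, seed=config.seed).to_dict()
        block[variant] = entry
    return block


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the full validation pipeline and (optionally) write the run
    directory: results.json, report.md, manifest.json, run.log."""
    outdir = Path(config.output_dir)
    handler = None
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(handler)
    try:
        return _run(config, outdir, write)
    finally:
        if handler is not None:
            log.removeHandler(handler)
            handler.close()


def _resolve_variant(config: RunConfig) -> str:
    if config.scorecard_variant:
        return config.scorecard_variant
    if config.synthetic_cohort:
        from .synthetic import _PRESET_VARIANT

        return _PRESET_VARIANT[config.synthetic_cohort]
    return "anu_adri_full"


def _run(config: RunConfig, outdir: Path, write: bool) -> dict:
    variant = _resolve_variant(config)
    try:
        card = build_scorecard(variant)
    except ScorecardError as exc:
        raise PipelineError("scorecard", str(exc)) from exc

    # --- input stage
    if config.input_csv:
        cohort, validation = read_cohort_csv(config.input_csv, card)
        source = {"kind": "csv", "path": str(config.input_csv)}
    else:
        kwargs = dict(config.synthetic or {})
        kwargs.setdefault("n", config.n)
        kwargs.setdefault("seed", config.seed)
        kwargs.setdefault("include_caide_factors", config.include_caide)
        if config.synthetic_cohort:
            syn = SyntheticConfig.for_cohort(config.synthetic_cohort, **kwargs)
        else:
            kwargs.setdefault("scorecard_variant", variant)
            syn = SyntheticConfig(**kwargs)
        cohort = generate_cohort(syn)
        validation = {"n_rows": int(len(cohort)), "issues": [], "n_issues": 0}
        source = {"kind": "synthetic", "config": syn.to_dict()}
    log.info("input: %d participants", len(cohort))

    # --- filter stage
    try:
        analysis, exclusions = ev.filter_analysis_set(cohort, card, config.missing_policy)
    except ev.EvaluationError as exc:
        raise PipelineError("filter", str(exc)) from exc
    log.info("filter: %d in, %d analyzed (excluded: baseline=%d outcome=%d incomplete=%d)",
             exclusions["input_n"], exclusions["analyzed_n"],
             exclusions["baseline_dementia"], exclusions["missing_outcome"],
             exclusions["incomplete_factors"])

    # --- score stage
    try:
        scores = score_cohort(analysis, card, config.missing_policy)
    except ScorecardError as exc:
        raise PipelineError("score", str(exc)) from exc
    log.info("score: mean %.2f sd %.2f", scores.mean(), scores.std(ddof=1))

    results: dict = {
        "scorecard_variant": variant,
        "seed": config.seed,
        "source": source,
        "validation": validation,
        "exclusions": exclusions,
        "score_summary": _score_summary(scores),
    }

    # --- quartiles + incidence + Cox (per outcome)
    results["quartile_analysis"] = {}
    for outcome in config.outcomes:
        try:
            qa = ev.cox_quartile_hr(analysis, scores, outcome=outcome, ties=config.ties)
        except ev.EvaluationError as exc:
            raise PipelineError("cox", f"outcome {outcome}: {exc}") from exc
        results["quartile_analysis"][outcome] = qa.to_dict()
        log.info("cox[%s]: trend p = %.3g", outcome, qa.trend_p)

    # --- discrimination
    try:
        auc_report = ev.evaluate_index(cohort, card, config.outcomes,
                                       config.subgroups,
                                       missing_policy=config.missing_policy)
    except ev.EvaluationError as exc:
        raise PipelineError("auc", str(exc)) from exc
    results["auc"] = auc_report["outcomes"]
    for outcome, block in results["auc"].items():
        log.info("auc[%s]: overall %.3f", outcome, block["overall"]["auc"])

    # --- age split
    if config.age_split is not None:
        try:
            results["age_split"] = ev.age_split_comparison(
                analysis, scores, split_age=config.age_split).to_dict()
        except ev.EvaluationError as exc:
            log.warning("age split skipped: %s", exc)
            results["age_split"] = {"skipped": str(exc)}

    # --- CAIDE comparator
    if config.include_caide:
        results["caide"] = _caide_block(analysis, config)

    if write:
        (outdir / "results.json").write_text(json.dumps(results, indent=2) + "\n")
        (outdir / "report.md").write_text(render_report(results))
        manifest = {"config": config.to_dict(), "seed": config.seed,
                    "outputs": ["results.json", "report.md", "run.log"]}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        log.info("wrote %s", outdir)
    return results


# ---------------------------------------------------------------------------
# Report rendering


def _fmt_auc(d: dict) -> str:
    return f"{d['auc']:.3f} ({d['ci_low']:.3f}-{d['ci_high']:.3f})"


def render_report(results: dict) -> str:
    """Human-readable Markdown mirror of the results document."""
    lines = [
        f"# Risk index validation report ({results['scorecard_variant']})",
        "",
        f"Seed: {results['seed']}  |  analyzed n = {results['exclusions']['analyzed_n']} "
        f"of {results['exclusions']['input_n']}",
        "",
        "## Score distribution",
        "",
        f"Mean (SD): {results['score_summary']['mean']:.2f} "
        f"({results['score_summary']['sd']:.2f})",
        "",
        "| Quartile | n | Median | Range |",
        "|---|---|---|---|",
    ]
    for q, d in results["score_summary"]["quartiles"].items():
        lines.append(f"| Q{q} | {d['n']} | {d['median']:.1f} | "
                     f"{d['range'][0]:.1f} to {d['range'][1]:.1f} |")
    lines += ["", "## Discrimination (c-statistics)", ""]
    for outcome, block in results["auc"].items():
        lines.append(f"### Outcome: {outcome}")
        lines.append("")
        for sub in ("overall", "male", "female", "common_variables"):
            if sub in block:
                lines.append(f"- {sub}: {_fmt_auc(block[sub])}")
        lines.append("")
    lines += ["## Quartile dose-response", ""]
    for outcome, qa in results["quartile_analysis"].items():
        lines += [f"### Outcome: {outcome}", "",
                  "| Quartile | n | Events | Incidence /1000 PY | HR (95% CI) |",
                  "|---|---|---|---|---|"]
        for q in ("1", "2", "3", "4"):
            d = qa["quartiles"][q]
            hr = ("reference" if q == "1" else
                  f"{d['hazard_ratio']:.2f} ({d['hr_ci_low']:.2f}-{d['hr_ci_high']:.2f})")
            lines.append(f"| Q{q} | {d['n']} | {d['events']} | "
                         f"{d['incidence_per_1000py']:.2f} | {hr} |")
        lines += ["", f"P for linear trend: {qa['trend_p']:.2g}", ""]
    if "age_split" in results and "quartiles" in results.get("age_split", {}):
        a = results["age_split"]
        lines += [f"## Dementia cases by quartile, age < vs >= {a['split_age']}", "",
                  "| Quartile | n young | cases (%) | n old | cases (%) | chi2, p |",
                  "|---|---|---|---|---|---|"]
        for q in ("1", "2", "3", "4"):
            d = a["quartiles"][q]
            chi = ("-" if d["chi_square"] is None else
                   f"{d['chi_square']:.2f}, p={d['p_value']:.3g}")
            lines.append(
                f"| Q{q} | {d['n_young']} | {d['cases_young']} ({d['pct_young']:.0f}%) "
                f"| {d['n_old']} | {d['cases_old']} ({d['pct_old']:.0f}%) | {chi} |")
        lines.append("")
    if "caide" in results:
        lines += ["## CAIDE comparator (c-statistics)", ""]
        for variant, entry in results["caide"].items():
            for outcome, d in entry.items():
                lines.append(f"- {variant} / {outcome}: {_fmt_auc(d)}")
        lines.append("")
    return "\n".join(lines) + "\n"
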