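"""End-to-end orchestration: simulate -> pair -> standardize -> label -> evaluate.

The report mirrors a clinical predictor study: a cohort/audiometric summary,
univariate + stepwise multivariate logistic tables for three analyses
(pre-resection indicators vs preoperative HP; post-resection indicators vs
postoperative HP; intraoperative differences vs postoperative HP among
preop-HP patients), ROC summaries with Youden cutoffs, and paired AUC
comparisons between raw and standardized indicators.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .config import PipelineConfig, SimulationConfig, StandardizationConfig
from .features import INDICATORS
from .hearing import outcome_table
from .simulate import simulate_cohort
from .standardize import index_patient
from .stats import (LogisticResult, compare_aucs, group_comparisons,
                    multivariate_stepwise, roc_analysis, univariate_logistic)

log = logging.getLogger("baepstd")

_IND_DISPLAY = {
    "la_i": "La-I", "la_ii": "La-II", "la_iii": "La-III", "la_iv": "La-IV",
    "la_v": "La-V", "la_i_iii": "La-I-III", "la_iii_v": "La-III-V",
    "la_i_v": "La-I-V", "am_i": "Am-I", "am_v": "Am-V",
}


def display_name(column: str) -> str:
    """Human-readable indicator name for a wide-table column."""
    for prefix, fmt in (("raw_pre_", "{}"), ("raw_post_", "{}"),
                        ("sti_pre_", "STI_AS-{}"), ("sti_post_", "STI_AS-{}"),
                        ("d_", "D-{}"), ("std_", "STD_AS-{}")):
        if column.startswith(prefix):
            return fmt.format(_IND_DISPLAY[column[len(prefix):]])
    return column


@dataclass
class AnalysisReport:
    cohort_summary: dict
    hearing_outcomes: dict
    group_comparisons: pd.DataFrame
    blocks: dict                      # analysis name -> tables
    pairing_yield: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return _jsonify({
            "schema_version": 1,
            "cohort_summary": self.cohort_summary,
            "hearing_outcomes": self.hearing_outcomes,
            "group_comparisons": self.group_comparisons.to_dict("records"),
            "blocks": {
                name: {k: (v.to_dict("records") if isinstance(v, pd.DataFrame) else v)
                       for k, v in tables.items()}
                for name, tables in self.blocks.items()},
            "pairing_yield": self.pairing_yield.to_dict("records"),
            "provenance": self.provenance,
        })


def _jsonify(x):
    if isinstance(x, dict):
        return {str(k): _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if not np.isfinite(v) else v
    if isinstance(x, np.integer):
        return int(x)
    if isinstance(x, np.bool_):
        return bool(x)
    return x


# ---------------------------------------------------------------------------
# evaluation battery on a wide per-patient index table


def _analysis_block(wide: pd.DataFrame, predictors: list, outcome: str,
                    alpha: float, direction: str,
                    roc_vars: list, auc_pairs: list) -> dict:
    """One table-set: univariate scan, stepwise multivariate, ROC, AUC tests."""
    y = wide[outcome].astype(float)
    uni_rows, candidates = [], []
    for col in predictors:
        if col not in wide.columns or wide[col].notna().sum() < 3:
            continue
        res = univariate_logistic(wide[col], y, variable=col)
        row = res.as_dict()
        row["variable"] = display_name(col)
        uni_rows.append(row)
        if res.p_value <= alpha and res.status == "ok":
            candidates.append(col)
    uni = pd.DataFrame(uni_rows)

    multi_rows = []
    if candidates:
        for res in multivariate_stepwise(wide[candidates], y,
                                         direction=direction, alpha=alpha):
            row = res.as_dict()
            row["variable"] = display_name(row["variable"])
            multi_rows.append(row)
    multi = pd.DataFrame(multi_rows,
                         columns=[*LogisticResult.__dataclass_fields__])

    roc_rows = []
    for col in roc_vars:
        if col in wide.columns and wide[col].notna().sum() >= 3:
            r = roc_analysis(wide[col], y, variable=col)
            row = r.as_dict()
            row["variable"] = display_name(col)
            roc_rows.append(row)
    roc = pd.DataFrame(roc_rows)

    cmp_rows = []
    for a, b in auc_pairs:
        if a in wide.columns and b in wide.columns:
            mask = wide[a].notna() & wide[b].notna() & y.notna()
            if mask.sum() >= 3 and y[mask].nunique() == 2:
                p = compare_aucs(wide.loc[mask, a], wide.loc[mask, b], y[mask])
                cmp_rows.append({"a": display_name(a), "b": display_name(b),
                                 "p_value": p})
    comparisons = pd.DataFrame(cmp_rows)

    return {"univariate": uni, "multivariate": multi, "roc": roc,
            "auc_comparisons": comparisons,
            "n_outcome_pos": int(y.sum()), "n": int(y.notna().sum())}


def evaluate_indices(wide: pd.DataFrame, alpha: float = 0.05,
                     direction: str = "backward") -> dict:
    """Run the three predictor analyses on a wide per-patient index table."""
    blocks = {}
    pre_raw = [f"raw_pre_{i}" for i in INDICATORS]
    pre_sti = [f"sti_pre_{i}" for i in INDICATORS]
    blocks["pre_resection"] = _analysis_block(
        wide, pre_raw + pre_sti, "hp_pre", alpha, direction,
        roc_vars=["raw_pre_la_v", "raw_pre_am_v", "sti_pre_la_v", "sti_pre_am_v"],
        auc_pairs=[("sti_pre_am_v", "raw_pre_am_v"),
                   ("sti_pre_am_v", "raw_pre_la_v"),
                   ("sti_pre_la_v", "raw_pre_la_v")])

    post_raw = [f"raw_post_{i}" for i in INDICATORS]
    post_sti = [f"sti_post_{i}" for i in INDICATORS]
    blocks["post_resection"] = _analysis_block(
        wide, post_raw + post_sti, "hp_post", alpha, direction,
        roc_vars=["raw_post_la_v", "raw_post_am_v", "sti_post_la_v",
                  "sti_post_am_v"],
        auc_pairs=[("sti_post_am_v", "raw_post_am_v"),
                   ("sti_post_am_v", "raw_post_la_v"),
                   ("sti_post_la_v", "raw_post_la_v")])

    sub = wide[wide["hp_pre"].astype(bool)]
    diff_vars = [f"d_{i}" for i in INDICATORS] + [f"std_{i}" for i in INDICATORS]
    if len(sub) >= 3 and sub["hp_post"].astype(float).nunique() == 2:
        blocks["intraoperative_difference"] = _analysis_block(
            sub, diff_vars, "hp_post", alpha, direction,
            roc_vars=["d_am_v", "std_am_v", "d_la_v", "std_la_v"],
            auc_pairs=[("std_am_v", "d_am_v")])
    return blocks


def cohort_indices(sim_config: SimulationConfig,
                   std_config: StandardizationConfig | None = None) -> pd.DataFrame:
    """Simulate a cohort and return its wide per-patient index table.

    One row per patient: raw and STI indicator values per phase, D/STD
    differences, and the HP labels derived from the simulated audiometry.
    """
    cohort = simulate_cohort(sim_config)
    hearing = bio.hp_labels(bio.hearing_wide(bio.cohort_hearing_frame(cohort)))
    std = std_config or StandardizationConfig()
    per_patient = [index_patient(p.id, p.feature_stream_affected,
                                 p.feature_stream_healthy, std)
                   for p in cohort]
    return bio.indices_wide(bio.indices_frame(per_patient, labels=hearing))


# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> AnalysisReport:
    """Execute every stage on a synthetic cohort and assemble the report.

    Deterministic given ``config.simulation.seed``.  When ``outdir`` is given
    (or taken from the config) every stage artifact is persisted there.
    """
    config.validate()
    outdir = Path(outdir) if outdir is not None else Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("simulating cohort: n=%d seed=%d",
             config.simulation.n_patients, config.simulation.seed)
    cohort = simulate_cohort(config.simulation)
    bio.write_cohort(cohort, outdir, config=config.simulation)

    hearing = bio.hp_labels(bio.hearing_wide(bio.cohort_hearing_frame(cohort)))

    per_patient, yields = [], []
    for p in cohort:
        pi = index_patient(p.id, p.feature_stream_affected,
                           p.feature_stream_healthy, config.standardization)
        per_patient.append(pi)
        n_epochs = len(p.feature_stream_affected)
        n_pairs = sum(pi.n_pairs.values())
        yields.append({"patient_id": p.id, "affected_epochs": n_epochs,
                       "pairs": n_pairs,
                       "pre_pairs": pi.n_pairs["pre_resection"],
                       "post_pairs": pi.n_pairs["post_resection"]})
        log.debug("patient %s: %d/%d epochs paired", p.id, n_pairs, n_epochs)
    pairing_yield = pd.DataFrame(yields)
    log.info("pairing yield: %.1f%% of affected epochs paired",
             100.0 * pairing_yield["pairs"].sum()
             / max(1, pairing_yield["affected_epochs"].sum()))

    indices = bio.indices_frame(per_patient, labels=hearing)
    bio.write_indices(indices, outdir / "indices.csv")
    wide = bio.indices_wide(indices)

    pre_hp = hearing["hp_pre"].astype(bool)
    outcomes = outcome_table(
        [_aud(r, "pre") for _, r in hearing.iterrows()],
        [_aud(r, "post") for _, r in hearing[pre_hp].iterrows()])

    summary = {
        "n_patients": len(cohort),
        "age_mean": float(np.mean([p.age for p in cohort])),
        "tumor_diameter_mean": float(np.mean([p.tumor_diameter for p in cohort])),
        "female_pct": 100.0 * np.mean([p.sex == "F" for p in cohort]),
        "left_side_pct": 100.0 * np.mean([p.affected_side == "left" for p in cohort]),
        "koos_counts": dict(pd.Series([p.koos_grade for p in cohort])
                            .value_counts().sort_index()),
    }

    groups = group_comparisons(hearing)
    blocks = evaluate_indices(wide, alpha=config.stats.alpha,
                              direction=config.stats.stepwise_direction)

    # hash the scientific configuration only: output location and verbosity
    # do not affect results
    cfg_dict = config.as_dict()
    cfg_dict.pop("output_dir", None)
    cfg_dict.pop("verbosity", None)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    report = AnalysisReport(
        cohort_summary=summary,
        hearing_outcomes=outcomes,
        group_comparisons=groups,
        blocks=blocks,
        pairing_yield=pairing_yield,
        provenance={
            "seed": config.simulation.seed,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "generated_utc": datetime.now(timezone.utc).isoformat(),
        },
    )
    write_report(report, outdir)
    return report


def _aud(row, stage):
    from .hearing import Audiometry
    return Audiometry(pta=row[f"pta_{stage}"], wrs=row[f"wrs_{stage}"], stage=stage)


def _md_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, r in df.iterrows():
        lines.append("| " + " | ".join(fmt(r[c]) for c in cols) + " |")
    return "\n".join(lines)


def write_report(report: AnalysisReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report.as_dict(), indent=2, default=str) + "\n")
    for name, tables in report.blocks.items():
        for kind in ("univariate", "multivariate", "roc", "auc_comparisons"):
            df = tables[kind]
            if isinstance(df, pd.DataFrame) and not df.empty:
                df.to_csv(outdir / f"{name}_{kind}.csv", index=False)
    (outdir / "report.md").write_text(render_markdown(report))


def render_markdown(report: AnalysisReport) -> str:
    lines = ["# Standardized-BAEP analysis report", ""]
    s = report.cohort_summary
    lines += [f"Cohort: {s['n_patients']} patients; "
              f"mean age {s['age_mean']:.1f} y; "
              f"mean tumor diameter {s['tumor_diameter_mean']:.1f} mm.", ""]
    ho = report.hearing_outcomes
    lines += ["## Hearing outcomes", "",
              f"Preoperative HP: {ho['pre']['hp_count']}/{ho['n_patients']} "
              f"({ho['pre']['hp_rate_pct']}%)."]
    if "post" in ho:
        lines += [f"Postoperative HP: {ho['post']['hp_count']}/"
                  f"{ho['post']['denominator']} of preop-HP patients "
                  f"({ho['post']['hp_rate_pct']}%; "
                  f"{ho['post']['hp_rate_pct_of_cohort']}% of the cohort)."]
    lines.append("")
    for name, tables in report.blocks.items():
        lines += [f"## {name.replace('_', ' ').title()} "
                  f"(n={tables['n']}, HP={tables['n_outcome_pos']})", ""]
        for kind, title in (("univariate", "Univariate logistic regression"),
                            ("multivariate", "Stepwise multivariate model"),
                            ("roc", "ROC analysis"),
                            ("auc_comparisons", "Paired AUC comparisons")):
            df = tables[kind]
            if isinstance(df, pd.DataFrame) and not df.empty:
                lines += [f"### {title}", "", _md_table(df), ""]
    return "\n".join(lines) + "\n"
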