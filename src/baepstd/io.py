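"""Columnar text dialects used between pipeline stages.

Three CSV schemas, each carrying a versioned ``# schema=...`` header comment:

* ``features.csv`` — one row per averaged epoch and ear:
  patient_id, side, timestamp_s, phase, la_i..la_v, la_i_iii, la_iii_v,
  la_i_v, am_i, am_v (latencies ms, amplitudes uV, empty = wave absent).
* ``hearing.csv`` — one row per patient, ear and stage:
  patient_id, ear, stage, pta_db, wrs_pct.
* ``indices.csv`` — one row per patient, phase and indicator:
  patient_id, phase, indicator, raw_affected, raw_healthy, sti, d, std,
  hp_pre, hp_post (d/std reported on post_resection rows).

A JSON manifest records the generating configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import INDICATORS, WaveFeatures
from .hearing import classify_aao_hns

SCHEMA_FEATURES = "baepstd.features.v1"
SCHEMA_HEARING = "baepstd.hearing.v1"
SCHEMA_INDICES = "baepstd.indices.v1"

FEATURE_COLUMNS = ["patient_id", "side", "timestamp_s", "phase", *INDICATORS]
HEARING_COLUMNS = ["patient_id", "ear", "stage", "pta_db", "wrs_pct"]
INDEX_COLUMNS = ["patient_id", "phase", "indicator", "raw_affected",
                 "raw_healthy", "sti", "d", "std", "hp_pre", "hp_post"]


def _write_csv(df: pd.DataFrame, path, schema: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema={schema}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path, expected_schema: str | None = None) -> pd.DataFrame:
    # round_trip parsing keeps stage outputs bit-reproducible from text
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# cohort


def cohort_features_frame(cohort) -> pd.DataFrame:
    rows = []
    for p in cohort:
        for stream in (p.feature_stream_affected, p.feature_stream_healthy):
            for f in stream:
                d = f.as_dict()
                rows.append({"patient_id": p.id, "side": d.pop("side"),
                             "timestamp_s": d.pop("timestamp"),
                             "phase": d.pop("phase"), **d})
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def cohort_hearing_frame(cohort) -> pd.DataFrame:
    rows = []
    for p in cohort:
        for ear, pre, post in (("affected", p.audiometry_pre, p.audiometry_post),
                               ("healthy", p.healthy_audiometry_pre,
                                p.healthy_audiometry_post)):
            rows.append({"patient_id": p.id, "ear": ear, "stage": "pre",
                         "pta_db": pre.pta, "wrs_pct": pre.wrs})
            rows.append({"patient_id": p.id, "ear": ear, "stage": "post",
                         "pta_db": post.pta, "wrs_pct": post.wrs})
    return pd.DataFrame(rows, columns=HEARING_COLUMNS)


def write_cohort(cohort, outdir, config=None, seed=None) -> dict:
    """Write features.csv, hearing.csv and manifest.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"features": outdir / "features.csv",
             "hearing": outdir / "hearing.csv",
             "manifest": outdir / "manifest.json"}
    _write_csv(cohort_features_frame(cohort), paths["features"], SCHEMA_FEATURES)
    _write_csv(cohort_hearing_frame(cohort), paths["hearing"], SCHEMA_HEARING)
    manifest = {"schema_version": 1,
                "n_patients": len(cohort),
                "seed": seed if seed is not None else getattr(config, "seed", None),
                "config": asdict(config) if config is not None else None}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return paths


def read_features(path) -> pd.DataFrame:
    df = _read_csv(path, SCHEMA_FEATURES)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"features file missing columns: {sorted(missing)}")
    return df


def features_to_streams(df: pd.DataFrame) -> dict:
    """Group a features table into per-patient (affected, healthy) streams."""
    out = {}
    for pid, g in df.groupby("patient_id", sort=True):
        streams = {"affected": [], "healthy": []}
        for _, row in g.sort_values("timestamp_s").iterrows():
            vals = {ind: (None if pd.isna(row[ind]) else float(row[ind]))
                    for ind in INDICATORS}
            streams[row["side"]].append(WaveFeatures(
                side=row["side"], timestamp=float(row["timestamp_s"]),
                phase=row["phase"], **vals))
        out[pid] = (streams["affected"], streams["healthy"])
    return out


def read_hearing(path) -> pd.DataFrame:
    df = _read_csv(path, SCHEMA_HEARING)
    missing = set(HEARING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hearing file missing columns: {sorted(missing)}")
    return df


def hearing_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot hearing.csv to one row per patient with pre/post, both ears."""
    rows = {}
    for _, r in df.iterrows():
        d = rows.setdefault(r["patient_id"], {"patient_id": r["patient_id"]})
        prefix = "" if r["ear"] == "affected" else "healthy_"
        d[f"{prefix}pta_{r['stage']}"] = r["pta_db"]
        d[f"{prefix}wrs_{r['stage']}"] = r["wrs_pct"]
    wide = pd.DataFrame(sorted(rows.values(), key=lambda d: d["patient_id"]))
    return wide


def hp_labels(wide: pd.DataFrame) -> pd.DataFrame:
    """Attach AAO-HNS classes and HP booleans to a wide hearing table."""
    from .hearing import Audiometry
    out = wide.copy()
    for stage in ("pre", "post"):
        classes, hp = [], []
        for _, r in wide.iterrows():
            cls = classify_aao_hns(Audiometry(pta=r[f"pta_{stage}"],
                                              wrs=r[f"wrs_{stage}"], stage=stage))
            classes.append(cls.aao_class)
            hp.append(cls.hp)
        out[f"aao_{stage}"] = classes
        out[f"hp_{stage}"] = hp
    return out


# ---------------------------------------------------------------------------
# indices


def indices_frame(patient_indices: list, labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format index table from per-patient standardization results."""
    lab = {}
    if labels is not None:
        lab = {r["patient_id"]: (bool(r["hp_pre"]), bool(r["hp_post"]))
               for _, r in labels.iterrows()}
    rows = []
    for pi in patient_indices:
        hp_pre, hp_post = lab.get(pi.patient_id, (np.nan, np.nan))
        for phase, summary, sti in (("pre_resection", pi.pre, pi.sti_pre),
                                    ("post_resection", pi.post, pi.sti_post)):
            if summary is None:
                continue
            for ind in INDICATORS:
                d = std = None
                if phase == "post_resection" and pi.diff is not None:
                    d, std = pi.diff.d.get(ind), pi.diff.std.get(ind)
                rows.append({
                    "patient_id": pi.patient_id, "phase": phase, "indicator": ind,
                    "raw_affected": summary.affected.get(ind),
                    "raw_healthy": summary.healthy.get(ind),
                    "sti": sti.get(ind) if sti else None,
                    "d": d, "std": std,
                    "hp_pre": hp_pre, "hp_post": hp_post,
                })
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


def write_indices(df: pd.DataFrame, path) -> None:
    _write_csv(df, path, SCHEMA_INDICES)


def read_indices(path) -> pd.DataFrame:
    df = _read_csv(path, SCHEMA_INDICES)
    missing = set(INDEX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"indices file missing columns: {sorted(missing)}")
    return df


def indices_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot indices.csv to one analysis row per patient.

    Columns: raw_pre_<ind>, sti_pre_<ind>, raw_post_<ind>, sti_post_<ind>,
    d_<ind>, std_<ind>, hp_pre, hp_post.
    """
    rows = {}
    for _, r in df.iterrows():
        d = rows.setdefault(r["patient_id"], {"patient_id": r["patient_id"],
                                              "hp_pre": r["hp_pre"],
                                              "hp_post": r["hp_post"]})
        tag = "pre" if r["phase"] == "pre_resection" else "post"
        ind = r["indicator"]
        d[f"raw_{tag}_{ind}"] = r["raw_affected"]
        d[f"sti_{tag}_{ind}"] = r["sti"]
        if tag == "post":
            d[f"d_{ind}"] = r["d"]
            d[f"std_{ind}"] = r["std"]
    return pd.DataFrame(sorted(rows.values(), key=lambda d: d["patient_id"]))
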