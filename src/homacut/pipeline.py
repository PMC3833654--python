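"""End-to-end analysis pipeline and cohort CSV I/O.

``run_pipeline`` wires the stages together — generate or load a cohort,
compute HOMA-IR, derive component thresholds and classify metabolic
syndrome, build the weight-status reference, select the normal-metabolic
reference population, tabulate reference HOMA-IR 95th percentiles,
derive ROC-optimal cut-offs in three pubertal strata (total, Tanner I,
Tanner >= II), fit quintile odds-ratio models, and compute
insulin-resistance prevalence tables — and writes a report directory:
human-readable TSV tables plus a machine-readable JSON manifest carrying
every threshold, count and seed used. Output is deterministic given the
seed: same config twice yields byte-identical manifests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, classification, cutoffs, metrics, synthetic
from .errors import InputError

__all__ = ["RunConfig", "run_pipeline", "read_cohort_csv", "write_cohort_csv"]

log = logging.getLogger("homacut")

_SEX_DIALECTS = {
    "M": "M", "F": "F", "m": "M", "f": "F",
    "1": "M", "2": "F", "male": "M", "female": "F",
    "MALE": "M", "FEMALE": "F", "Male": "M", "Female": "F",
}


def read_cohort_csv(path) -> synthetic.Cohort:
    """Read a cohort CSV with the documented schema.

    Sex may be encoded as M/F, male/female or 1/2; it is normalised to
    M/F. Missing or extra columns and non-numeric cells are errors that
    name the offending column / row.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    missing = [c for c in metrics.COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"cohort CSV {path} missing columns: {missing}")
    extra = [c for c in df.columns if c not in metrics.COHORT_COLUMNS]
    if extra:
        raise InputError(f"cohort CSV {path} has unknown columns: {extra}")

    sex = []
    for i, raw in enumerate(df["sex"]):
        key = str(raw).strip()
        if key not in _SEX_DIALECTS:
            raise InputError(f"row {i + 2}: unrecognised sex code {raw!r}")
        sex.append(_SEX_DIALECTS[key])
    df["sex"] = sex

    numeric = [c for c in metrics.COHORT_COLUMNS if c not in ("id", "sex")]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise InputError(f"row {row}: non-numeric value in column {col!r}")
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0]) + 2
            raise InputError(f"row {row}: missing value in column {col!r}")
        df[col] = converted
    df["tanner"] = df["tanner"].astype(int)
    return synthetic.Cohort(data=df[metrics.COHORT_COLUMNS], provenance=str(path))


def write_cohort_csv(cohort: synthetic.Cohort | pd.DataFrame, path) -> None:
    """Write a cohort to CSV with full float precision (round-trip safe)."""
    df = cohort.data if isinstance(cohort, synthetic.Cohort) else cohort
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run.

    Exactly one of ``cohort_csv`` (ingest) or ``generator`` (simulate)
    must be set. ``cutoff_methods`` chooses which cut-off families are
    reported; ``age_band_width`` / ``n_height_bands`` parameterise the
    component-threshold strata.
    """

    cohort_csv: str | Path | None = None
    generator: synthetic.GeneratorConfig | None = None
    seed: int = 0
    out_dir: str | Path | None = None
    age_band_width: float = 1.0
    n_height_bands: int = 3
    cutoff_methods: tuple = ("youden", "distance", "p95")
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.cohort_csv is None) == (self.generator is None):
            raise InputError("exactly one of cohort_csv or generator must be set")
        for m in self.cutoff_methods:
            if m not in ("youden", "distance", "p95"):
                raise InputError(f"unknown cutoff method {m!r}")


#: ROC strata mirroring the three pubertal panels: total, prepubertal, pubertal.
ROC_STRATA = {
    "total": lambda d: pd.Series(True, index=d.index),
    "tanner_I": lambda d: d["tanner"] == 1,
    "tanner_ge_II": lambda d: d["tanner"] >= 2,
}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; return the report bundle as a dict.

    The bundle carries the cohort summary by component count, the
    quintile odds-ratio tables, the reference p95 table, the ROC cut-off
    results per pubertal stratum, the prevalence tables, and a manifest
    of every threshold and seed used. When ``config.out_dir`` is set the
    tables are also written as TSV and the manifest as JSON.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)

    # --- stage: input -----------------------------------------------------
    if config.generator is not None:
        gen = config.generator
        if gen.seed != config.seed:
            gen = synthetic.GeneratorConfig(**{**gen.__dict__, "seed": config.seed})
        cohort = synthetic.generate_cohort(gen)
    else:
        cohort = read_cohort_csv(config.cohort_csv)
    df = cohort.data.copy()
    df["homa_ir"] = metrics.compute_homa_ir(df["insulin"], df["glucose"])
    log.info("cohort loaded: n=%d", len(df))

    # --- stage: weight status (growth reference from the cohort itself) ---
    growth_ref = metrics.GrowthReference.from_samples(df["bmi"], df["age"], df["sex"])
    weight = metrics.classify_weight_status_frame(df, growth_ref)

    # --- stage: MS classification -----------------------------------------
    thresholds = classification.derive_component_thresholds(
        df,
        age_group_width=config.age_band_width,
        n_height_bands=config.n_height_bands,
    )
    profiles = classification.classify_components(df, thresholds)
    n_ms = int(profiles["ms"].sum())
    log.info("MS classification: %d/%d subjects (%.1f%%)", n_ms, len(df), 100 * n_ms / len(df))

    # --- stage: reference population & p95 table ---------------------------
    reference = classification.select_reference_population(df, profiles, weight)
    log.info("reference population: n=%d", len(reference))
    ref_table = cutoffs.derive_reference_p95_table(reference)

    # --- stage: ROC cut-offs per pubertal stratum ---------------------------
    p95_by_stratum = {
        "total": float(ref_table.loc["total", "p95"]),
        "tanner_I": float(ref_table.loc["tanner_I", "p95"]),
        "tanner_ge_II": float(ref_table.loc["tanner_ge_II", "p95"]),
    }
    roc_results = {}
    for name, pred in ROC_STRATA.items():
        mask = pred(df).to_numpy(dtype=bool)
        scores = df.loc[mask, "homa_ir"].to_numpy()
        labels = profiles.loc[mask, "ms"].to_numpy()
        roc = cutoffs.build_roc(scores, labels)
        entry = {"n": int(mask.sum()), "n_ms": int(labels.sum()), "auc": roc.auc}
        if "youden" in config.cutoff_methods:
            entry["youden"] = cutoffs.optimal_cutoff(roc, "youden").__dict__
        if "distance" in config.cutoff_methods:
            entry["distance"] = cutoffs.optimal_cutoff(roc, "distance").__dict__
        if "p95" in config.cutoff_methods:
            cut = p95_by_stratum[name]
            sens, spec = cutoffs.operating_characteristics(roc, cut)
            entry["p95"] = cutoffs.CutoffResult(
                cutoff=cut,
                sensitivity=sens,
                specificity=spec,
                youden=cutoffs.youden_index(sens, spec),
                distance_sq=cutoffs.distance_to_corner_sq(sens, spec),
                method="percentile",
            ).__dict__
        roc_results[name] = entry

    # --- stage: quintile odds ratios ----------------------------------------
    quint = association.assign_quintiles(df["homa_ir"])
    covars = pd.DataFrame(
        {
            "age": df["age"].to_numpy(),
            "sex": (df["sex"] == "M").astype(float).to_numpy(),
            "tanner": df["tanner"].to_numpy(dtype=float),
        }
    )
    or_tables = {}
    for outcome in ["ms", "central_obesity", "low_hdl", "high_tg", "ifg", "high_bp"]:
        or_tables[outcome] = association.fit_logistic_or(
            profiles[outcome].to_numpy(dtype=float), quint.quintile, covars
        )

    # --- stage: prevalence of insulin resistance -----------------------------
    ir_cutoffs = {}
    if "youden" in config.cutoff_methods or "distance" in config.cutoff_methods:
        key = "youden" if "youden" in config.cutoff_methods else "distance"
        ir_cutoffs[f"roc_{roc_results['total'][key]['cutoff']:.2f}"] = roc_results[
            "total"
        ][key]["cutoff"]
    if "p95" in config.cutoff_methods:
        ir_cutoffs[f"p95_{p95_by_stratum['total']:.2f}"] = p95_by_stratum["total"]
    prevalence = association.prevalence_of_ir(df, profiles, weight, ir_cutoffs)

    # --- stage: summary table ------------------------------------------------
    summary = synthetic.summarize_by_component_count(df, profiles)

    manifest = {
        "seed": config.seed,
        "n_subjects": len(df),
        "n_ms": n_ms,
        "ms_prevalence_pct": 100.0 * n_ms / len(df),
        "n_reference": len(reference),
        "component_thresholds": {
            "fixed": {
                "tg_cut": {"value": thresholds.tg_cut, "provenance": "fixed"},
                "hdl_cut": {"value": thresholds.hdl_cut, "provenance": "fixed"},
                "glucose_cut": {"value": thresholds.glucose_cut, "provenance": "fixed"},
            },
            "derived": json.loads(thresholds.to_json()),
            "provenance_derived": "cohort-derived percentiles",
        },
        "quintile_bounds": quint.bounds.tolist(),
        "reference_p95_table": ref_table.reset_index().to_dict(orient="records"),
        "roc": roc_results,
        "ir_cutoffs": ir_cutoffs,
        "quintile_or": {
            k: v.reset_index(names="quintile").to_dict(orient="records")
            for k, v in or_tables.items()
        },
        "prevalence_pct": prevalence.prevalence.reset_index(names="group").to_dict(
            orient="records"
        ),
        "prevalence_group_n": prevalence.group_n.to_dict(),
        "weight_status_chi2": prevalence.weight_status_chi2.reset_index(
            names="cutoff"
        ).to_dict(orient="records"),
        "summary_by_component_count": summary.to_dict(orient="records"),
    }
    manifest = _jsonable(manifest)

    bundle = {
        "cohort": df,
        "profiles": profiles,
        "weight": weight,
        "thresholds": thresholds,
        "reference": reference,
        "reference_p95_table": ref_table,
        "roc": roc_results,
        "quintile": quint,
        "quintile_or": or_tables,
        "prevalence": prevalence,
        "summary": summary,
        "manifest": manifest,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(df[metrics.COHORT_COLUMNS], out / "cohort.csv")
        profiles.to_csv(out / "profiles.csv", index=False)
        summary.to_csv(out / "summary_by_component_count.tsv", sep="\t", index=False)
        pd.concat(or_tables, names=["outcome"]).to_csv(
            out / "quintile_odds_ratios.tsv", sep="\t"
        )
        ref_table.to_csv(out / "reference_p95.tsv", sep="\t")
        prevalence.prevalence.to_csv(out / "ir_prevalence.tsv", sep="\t")
        (out / "roc_cutoffs.json").write_text(
            json.dumps(_jsonable(roc_results), indent=2, sort_keys=True)
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.info("report written to %s", out)

    return bundle
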