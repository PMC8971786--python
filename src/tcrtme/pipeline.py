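"""End-to-end orchestration: simulate -> repertoire metrics -> densities ->
comparisons -> survival, with reproducible configuration and a run manifest.

Every figure-like output of the analysis is a tidy CSV table (with a JSON
column-schema sidecar): per-sample repertoire summaries, long-format density
records, a comparison table (contrast, n, statistic, p, p_adjusted,
direction), an ROC row for response prediction, and univariate/multivariate
survival fits. A ``manifest.json`` records the config hash, seed, stage
sample sizes, applied filters and output checksums; re-running with the same
config and seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import InsufficientDataError, UndefinedStatisticError
from .io import sha256_of, write_table
from .repertoire import summarize
from .stats import bh_adjust, cox_stage, group_test, km_logrank, paired_test, roc_auc, spearman
from .synthetic import CohortConfig, SimulatedCohort, generate_cohort
from .density import density_table

__all__ = ["load_config", "run_pipeline", "repertoire_stage", "density_stage",
           "compare_stage", "survival_stage"]

logger = logging.getLogger(__name__)

REPERTOIRE_METRICS = ("total_tcr", "unique_tcr", "clonal_proportion", "d50", "h_norm")


def load_config(source: str | Path | dict) -> dict:
    """Load a run configuration from YAML (or pass a dict through)."""
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------
def repertoire_stage(
    repertoires: dict[tuple[str, str], pd.DataFrame]
) -> pd.DataFrame:
    """Per-sample repertoire summary table (one row per patient x timepoint)."""
    rows = []
    for (pid, tp), rep in sorted(repertoires.items()):
        s = summarize(rep)
        row = {
            "patient_id": pid,
            "timepoint": tp,
            "total_tcr": s.total_tcr,
            "unique_tcr": s.unique_tcr,
            "clonal_proportion": s.clonal_proportion,
            "d50": s.d50,
            "h_norm": s.h_norm,
        }
        for label, frac in s.abundance_groups.items():
            row[f"abund_{label}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)


def density_stage(
    cells: dict[tuple[str, str], pd.DataFrame], phenotypes: list[str]
) -> pd.DataFrame:
    """Long-format mIF density table over all samples and compartments."""
    parts = [
        density_table(tbl, phenotypes, sample_id=pid, timepoint=tp)
        for (pid, tp), tbl in sorted(cells.items())
    ]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


def _paired_vectors(df: pd.DataFrame, value: str, key: str = "patient_id"):
    wide = df.pivot_table(index=key, columns="timepoint", values=value, aggfunc="first")
    wide = wide.dropna()
    return wide["pre"].to_numpy(), wide["post"].to_numpy()


def compare_stage(
    summary: pd.DataFrame, density: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pre/post and responder contrasts with group-wise BH adjustment.

    Biomarker families for the FDR adjustment are: one family per mIF marker
    (its compartment-specific paired and responder contrasts together), one
    family for the TCR repertoire metrics, and one for TMB.
    """
    results = []  # (biomarker, ComparisonResult)

    for metric in REPERTOIRE_METRICS:
        if metric not in summary.columns:
            continue
        pre, post = _paired_vectors(summary, metric)
        try:
            results.append(("TCR", paired_test(pre, post, f"pre-vs-post {metric}")))
        except InsufficientDataError:
            logger.info("skipping %s: too few pairs", metric)

    pre_tmb, post_tmb = _paired_vectors(clinical, "tmb")
    try:
        results.append(("TMB", paired_test(pre_tmb, post_tmb, "pre-vs-post TMB")))
    except InsufficientDataError:
        logger.info("skipping TMB: too few pairs")

    responders = clinical.drop_duplicates("patient_id").set_index("patient_id")["responder"]
    if len(density):
        for (marker, compartment), sub in density.groupby(["marker", "compartment"]):
            pre, post = _paired_vectors(sub, "density", key="sample_id")
            label = f"pre-vs-post {marker} {compartment}"
            try:
                results.append((marker, paired_test(pre, post, label)))
            except InsufficientDataError:
                logger.info("skipping %s: too few pairs", label)
            for tp, tp_sub in sub.groupby("timepoint"):
                merged = tp_sub.merge(
                    responders.rename("responder"),
                    left_on="sample_id", right_index=True, how="inner",
                )
                a = merged.loc[merged["responder"], "density"]
                b = merged.loc[~merged["responder"], "density"]
                label = f"responder-vs-non {marker} {compartment} {tp}"
                try:
                    results.append((marker, group_test(a, b, label)))
                except InsufficientDataError:
                    logger.info("skipping %s: group too small", label)

    table = pd.DataFrame(
        {
            "biomarker": [b for b, _ in results],
            "contrast": [r.contrast for _, r in results],
            "n": [r.n for _, r in results],
            "statistic": [r.statistic for _, r in results],
            "p_value": [r.p_value for _, r in results],
            "direction": [r.direction for _, r in results],
        }
    )
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p_value"], table["biomarker"])

    # response prediction: pre-treatment stromal FOXP3 density ROC
    roc_rows = []
    if len(density):
        pre_stroma = density[
            (density["timepoint"] == "pre")
            & (density["compartment"] == "stroma")
            & (density["marker"].str.startswith("FOXP3"))
        ]
        merged = pre_stroma.merge(
            responders.rename("responder"), left_on="sample_id", right_index=True
        )
        if len(merged):
            try:
                auc, lo, hi = roc_auc(
                    merged["density"].to_numpy(),
                    merged["responder"].to_numpy(),
                    seed=0,
                )
                roc_rows.append(
                    {
                        "predictor": "pre-NAC stromal FOXP3 density",
                        "n": len(merged),
                        "auc": auc,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
            except UndefinedStatisticError:
                logger.info("ROC skipped: single response class")

    # neoantigen vs TMB correlation rides along as a correlation row
    post_rows = clinical[clinical["timepoint"] == "post"]
    try:
        rho, p = spearman(post_rows["tmb"], post_rows["neoantigen"])
        corr = pd.DataFrame(
            {
                "biomarker": ["TMB"],
                "contrast": ["spearman TMB-vs-neoantigen post"],
                "n": [len(post_rows)],
                "statistic": [rho],
                "p_value": [p],
                "direction": [int(np.sign(rho))],
                "p_adjusted": [p],
            }
        )
        table = pd.concat([table, corr], ignore_index=True)
    except (InsufficientDataError, UndefinedStatisticError):
        pass

    return table, pd.DataFrame(roc_rows)


def survival_stage(clinical: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survival associations on the per-patient table.

    Univariable Cox screening (post-treatment CD8 density, TMB, regimen,
    response) followed by the backward-eliminated multivariable stage, plus a
    Kaplan-Meier/log-rank comparison of CD8-high vs CD8-low (median split).
    """
    patients = clinical[clinical["timepoint"] == "post"].copy()
    patients["xelox"] = (patients["regimen"] == "XELOX").astype(float)
    patients["responder_num"] = patients["responder"].astype(float)
    candidates = ["cd8_density", "tmb", "xelox", "responder_num"]
    usable = [c for c in candidates if patients[c].nunique() > 1]
    frame = patients[["os_months", "os_event", *usable]].astype(float)
    fits = cox_stage(frame, "os_months", "os_event", usable)
    cox_table = pd.DataFrame(
        {
            "variable": [f.variable for f in fits],
            "stage": [f.stage for f in fits],
            "hazard_ratio": [f.hazard_ratio for f in fits],
            "ci_low": [f.ci_low for f in fits],
            "ci_high": [f.ci_high for f in fits],
            "p_value": [f.p_value for f in fits],
            "n": [f.n for f in fits],
            "events": [f.events for f in fits],
            "converged": [f.converged for f in fits],
        }
    )

    median_cd8 = patients["cd8_density"].median()
    group = np.where(patients["cd8_density"] > median_cd8, "CD8-high", "CD8-low")
    km_rows = []
    if len(set(group)) == 2:
        chi2, p, medians = km_logrank(patients["os_months"], patients["os_event"], group)
        for g, med in medians.items():
            km_rows.append(
                {"group": g, "median_survival": med, "chi_square": chi2, "p_value": p}
            )
    return cox_table, pd.DataFrame(km_rows)


# --------------------------------------------------------------------------
# the run
# --------------------------------------------------------------------------
def run_pipeline(
    config: str | Path | dict,
    output_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Execute all stages on a simulated cohort and write result tables.

    ``config`` is a YAML path or dict with keys ``cohort`` (CohortConfig
    fields), ``seed``, ``output_dir``, optional ``phenotypes`` (marker
    combinations for the density stage) and ``write_repertoires``. Flag-style
    arguments override config values. Returns the run manifest (also written
    to ``manifest.json``).
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if output_dir is not None:
        cfg["output_dir"] = str(output_dir)
    if "output_dir" not in cfg:
        raise ValueError("config must provide output_dir (or pass output_dir=)")
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    cohort_kwargs = dict(cfg.get("cohort", {}))
    if "seed" in cfg:
        cohort_kwargs["seed"] = int(cfg["seed"])
    if "effect_sizes" in cohort_kwargs:
        cohort_kwargs["effect_sizes"] = {
            k: tuple(v) for k, v in cohort_kwargs["effect_sizes"].items()
        }
    cohort_config = CohortConfig(**cohort_kwargs)

    logger.info("stage simulate: n_patients=%d seed=%d",
                cohort_config.n_patients, cohort_config.seed)
    cohort: SimulatedCohort = generate_cohort(cohort_config)

    outputs: dict[str, Path] = {}
    outputs["clinical"] = write_table(cohort.clinical, outdir / "clinical.csv")

    if cfg.get("write_repertoires", False):
        from .io import write_airr

        repdir = outdir / "repertoires"
        repdir.mkdir(exist_ok=True)
        for (pid, tp), rep in sorted(cohort.repertoires.items()):
            write_airr(rep, repdir / f"{pid}_{tp}.airr.tsv")

    logger.info("stage repertoire: %d samples", len(cohort.repertoires))
    summary = repertoire_stage(cohort.repertoires)
    outputs["repertoire_summary"] = write_table(summary, outdir / "repertoire_summary.csv")

    phenotypes = list(cfg.get("phenotypes", [f"{m}+" for m in cohort_config.effect_sizes]))
    logger.info("stage density: %d samples, %d phenotypes", len(cohort.cells), len(phenotypes))
    density = density_stage(cohort.cells, phenotypes)
    outputs["density"] = write_table(density, outdir / "density.csv")

    logger.info("stage compare")
    comparisons, roc = compare_stage(summary, density, cohort.clinical)
    outputs["comparisons"] = write_table(comparisons, outdir / "comparisons.csv")
    outputs["roc"] = write_table(roc, outdir / "roc.csv")

    logger.info("stage survive")
    cox_table, km_table = survival_stage(cohort.clinical)
    outputs["survival"] = write_table(cox_table, outdir / "survival.csv")
    outputs["km"] = write_table(km_table, outdir / "km.csv")

    manifest = {
        "config_hash": _config_hash(
            {k: v for k, v in cfg.items() if k != "output_dir"}
        ),
        "seed": cohort_config.seed,
        "package_version": __version__,
        "cohort": dataclasses.asdict(cohort_config),
        "n": {
            "patients": cohort_config.n_patients,
            "repertoire_samples": len(cohort.repertoires),
            "density_records": int(len(density)),
            "comparisons": int(len(comparisons)),
        },
        "outputs": {name: {"path": str(p), "sha256": sha256_of(p)}
                    for name, p in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str) + "\n")
    return manifest
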