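"""End-to-end workflow: simulate, analyze, report.

``run_analyze`` walks a directory of paired en-face images plus a covariate
CSV, applies the quality gate, and measures each eye's obstructive and
contralateral quadrants; ``run_report`` turns the per-eye table into the
three cohort reports (group summary, regression, duration sub-analysis)
plus a JSON run summary.  All outputs embed the resolved configuration and
are byte-deterministic for identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import EmptyMaskError, InputError
from .images import EnFaceImage, Quadrant
from .io import (
    read_enface,
    read_faz_mask,
    write_enface,
    write_faz_mask,
    write_table,
)
from .reflectivity import corrected_reflectivity, quality_gate
from .stats import (
    duration_subanalysis,
    group_comparison,
    paired_quadrant_test,
    regression_suite,
)
from .synthetic import SyntheticConfig, config_to_dict, generate_cohort
from .vascular import vessel_metrics

logger = logging.getLogger(__name__)

#: covariates screened in the regression stage when present in the table
REGRESSION_PREDICTORS = [
    "sex_female",
    "age",
    "laterality_os",
    "hypertension",
    "diabetes",
    "iop_mmhg",
    "refractive_error_se",
    "bcva_logmar",
    "threshold",
    "injections_per_year",
    "duration_months",
    "sfct_um",
    "cmt_um",
    "vessel_density_pct",
    "faz_area_mm2",
    "faz_perimeter_mm",
    "faz_circularity",
]


@dataclass
class RunConfig:
    """Resolved options of one pipeline run; defaults are the operative
    conventions documented in each module."""

    input_dir: str | Path | None = None
    output_dir: str | Path | None = None
    threshold_scope: str = "quadrant"  # "quadrant" | "image"
    sd_convention: str = "sample"  # "sample" | "population"
    min_particle_px: int = 3
    connectivity: int = 8
    min_quality: float = 65.0
    contralateral_rule: str = "diagonal"  # "diagonal" | "metadata"
    overall_scope: str = "image"
    equal_var_ttest: bool = True
    multivariate_entry_p: float = 0.2
    duration_split_months: float = 36.0
    seed: int = 0

    @property
    def sd_ddof(self) -> int:
        return 1 if self.sd_convention == "sample" else 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("input_dir", "output_dir"):
            if d[k] is not None:
                d[k] = str(d[k])
        d["package_version"] = __version__
        return d


# ---------------------------------------------------------------------------
# simulate


def simulate_to_dir(config: SyntheticConfig, outdir: str | Path) -> pd.DataFrame:
    """Write a synthetic cohort to disk in the pipeline's input layout.

    Produces ``<eye_id>_struct.tif`` / ``<eye_id>_octa.tif`` /
    ``<eye_id>_faz.png`` per eye, ``covariates.csv``, a ``truth.json``
    (planted effects; for validation only) and a config echo.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eyes, table = generate_cohort(config)
    truth = {}
    for eye in eyes:
        write_enface(eye.structural, outdir / f"{eye.eye_id}_struct.tif")
        write_enface(eye.octa, outdir / f"{eye.eye_id}_octa.tif")
        write_faz_mask(eye.faz, outdir / f"{eye.eye_id}_faz.png")
        truth[eye.eye_id] = {
            "delta": eye.truth["delta"],
            "obstructive_quadrant": (
                eye.truth["obstructive_quadrant"].value
                if eye.truth["obstructive_quadrant"] is not None
                else None
            ),
        }
    write_table(table, outdir / "covariates.csv", provenance=config_to_dict(config))
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(config_to_dict(config), fh, indent=1, sort_keys=True)
    return table


# ---------------------------------------------------------------------------
# analyze


def _find_image(indir: Path, eye_id: str, kind: str) -> Path | None:
    for ext in (".tif", ".tiff", ".png"):
        p = indir / f"{eye_id}_{kind}{ext}"
        if p.exists():
            return p
    return None


def analyze_eye(
    structural: EnFaceImage,
    octa: EnFaceImage,
    quadrant: Quadrant,
    config: RunConfig,
) -> dict[str, dict]:
    """Measure the analysis quadrant and its contralateral counterpart."""
    out = {}
    for role, q in (
        ("obstructive", quadrant),
        ("contralateral", quadrant.opposite),
    ):
        res = corrected_reflectivity(
            structural,
            octa,
            q,
            min_particle_px=config.min_particle_px,
            connectivity=config.connectivity,
            sd_ddof=config.sd_ddof,
            threshold_scope=config.threshold_scope,
            overall_scope=config.overall_scope,
        )
        out[role] = {
            "quadrant": q.value,
            "threshold": res.threshold,
            "hss_area_px": res.hss_area_px,
            "particle_count": res.particle_count,
            "mean_on_hss": res.mean_on_hss,
            "overall_mean": res.overall_mean,
            "corrected_reflectivity": res.corrected,
        }
    return out


def run_analyze(
    config: RunConfig, covariates: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Analyze every eye in ``config.input_dir``.

    Returns a tidy results table (one row per eye and measured quadrant
    role) and the exclusion log (one entry per skipped eye with reason).
    Rows are ordered by eye_id for determinism.
    """
    indir = Path(config.input_dir)
    if covariates is None:
        cov_path = indir / "covariates.csv"
        if not cov_path.exists():
            raise InputError(f"covariate table not found: {cov_path}")
        covariates = pd.read_csv(cov_path, comment="#")
    if "eye_id" not in covariates.columns:
        raise InputError("covariate table must have an 'eye_id' column")

    rows: list[dict] = []
    exclusions: list[dict] = []
    for rec in covariates.sort_values("eye_id").to_dict("records"):
        eye_id = str(rec["eye_id"])
        struct_path = _find_image(indir, eye_id, "struct")
        octa_path = _find_image(indir, eye_id, "octa")
        if struct_path is None or octa_path is None:
            exclusions.append({"eye_id": eye_id, "reason": "missing image pair"})
            logger.warning("analyze: %s skipped (missing image pair)", eye_id)
            continue
        quality = float(rec["quality"]) if "quality" in rec else None
        structural = read_enface(struct_path, quality=quality)
        octa = read_enface(octa_path, quality=quality)
        if not quality_gate(structural, config.min_quality):
            exclusions.append(
                {
                    "eye_id": eye_id,
                    "reason": f"image quality {quality:.1f} below "
                    f"{config.min_quality:.0f}",
                }
            )
            continue
        try:
            if config.contralateral_rule == "metadata" and "contralateral" in rec:
                quadrant = Quadrant(rec["quadrant"])
                contral = Quadrant(rec["contralateral"])
                roles = {"obstructive": quadrant, "contralateral": contral}
                measured = {
                    role: analyze_eye(structural, octa, q, config)["obstructive"]
                    for role, q in roles.items()
                }
            else:
                quadrant = Quadrant(rec["quadrant"])
                measured = analyze_eye(structural, octa, quadrant, config)
        except EmptyMaskError:
            exclusions.append({"eye_id": eye_id, "reason": "no HSS area"})
            logger.warning("analyze: %s skipped (no HSS area)", eye_id)
            continue

        vm = None
        faz_path = _find_image(indir, eye_id, "faz")
        if faz_path is not None:
            vm = vessel_metrics(octa, read_faz_mask(faz_path))
        for role in ("obstructive", "contralateral"):
            row = {"eye_id": eye_id, "role": role, **measured[role]}
            if "group" in rec:
                row["group"] = rec["group"]
            if vm is not None:
                row.update(
                    vessel_density_pct=vm.vessel_density_pct,
                    faz_area_mm2=vm.faz_area_mm2,
                    faz_perimeter_mm=vm.faz_perimeter_mm,
                    faz_circularity=vm.faz_circularity,
                )
            rows.append(row)
    if not rows:
        raise InputError("empty cohort: no eye passed input checks")
    results = pd.DataFrame(rows)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(results, outdir / "results.csv", provenance=config.to_dict())
        with open(outdir / "exclusions.json", "w") as fh:
            json.dump(exclusions, fh, indent=1)
    return results, exclusions


def eye_table(results: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy results to one row per eye, joined with covariates.

    The obstructive-role metrics keep their names; the contralateral
    corrected reflectivity lands in ``contralateral_reflectivity``.  Binary
    covariates are recoded to 0/1 indicator columns for the regression
    stage.
    """
    obs = results[results["role"] == "obstructive"].set_index("eye_id")
    contra = results[results["role"] == "contralateral"].set_index("eye_id")
    table = obs.drop(columns=["role"]).copy()
    table["contralateral_reflectivity"] = contra["corrected_reflectivity"]
    merged = covariates.merge(
        table.reset_index(), on="eye_id", how="inner", suffixes=("", "_measured")
    )
    missing = set(covariates["eye_id"]) - set(merged["eye_id"])
    for eye_id in sorted(missing):
        logger.info("eye_table: %s has covariates but no results (join miss)", eye_id)
    if "sex" in merged.columns:
        merged["sex_female"] = (merged["sex"] == "F").astype(int)
    if "laterality" in merged.columns:
        merged["laterality_os"] = (merged["laterality"] == "OS").astype(int)
    return merged


# ---------------------------------------------------------------------------
# report


def run_report(
    results: pd.DataFrame,
    covariates: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Produce the three cohort reports and the JSON summary.

    Returns ``{"table1": DataFrame, "table2": DataFrame, "table3":
    DataFrame | None, "summary": dict}``: group summaries (mean +/- SD and
    omnibus P per metric), the univariate/multivariate regression table on
    disease eyes, and the duration sub-analysis.  Writes them under
    ``config.output_dir`` when set.
    """
    table = eye_table(results, covariates)
    if "group" not in table.columns:
        raise InputError("covariate table must carry a 'group' column")
    groups = sorted(table["group"].unique())

    # --- table 1: per-metric group summary
    skip = {"eye_id", "quality"}
    metrics = [
        c
        for c in table.columns
        if c not in skip and pd.api.types.is_numeric_dtype(table[c])
    ]
    t1_rows = []
    comparisons: dict[str, object] = {}
    for metric in metrics:
        row: dict = {"metric": metric}
        usable = [
            g
            for g in groups
            if table.loc[table["group"] == g, metric].dropna().size >= 2
        ]
        for g in groups:
            vals = table.loc[table["group"] == g, metric].dropna()
            row[f"{g}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{g}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{g}_n"] = int(len(vals))
        if len(usable) >= 2:
            gc = group_comparison(
                table[table["group"].isin(usable)],
                metric,
                equal_var=config.equal_var_ttest,
            )
            row["anova_p"] = gc.anova_p
            comparisons[metric] = gc
        else:
            row["anova_p"] = np.nan
        t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows)

    # --- table 2: regression on disease eyes
    disease = table[table["group"] != "control"]
    predictors = [p for p in REGRESSION_PREDICTORS if p in disease.columns]
    table2 = None
    suite = None
    if len(groups) < 2:
        logger.warning("report: single-group input, group comparison skipped")
    if len(disease) >= 5 and predictors:
        suite = regression_suite(
            disease,
            outcome="corrected_reflectivity",
            predictors=[
                p
                for p in predictors
                if disease[p].dropna().nunique() > 1
            ],
            entry_p=config.multivariate_entry_p,
        )
        multi = {r.predictor: r for r in suite.multivariate}
        table2 = pd.DataFrame(
            [
                {
                    "predictor": r.predictor,
                    "univariate_beta": r.standardized_beta,
                    "univariate_p": r.p_value,
                    "multivariate_beta": (
                        multi[r.predictor].standardized_beta
                        if r.predictor in multi
                        else np.nan
                    ),
                    "multivariate_p": (
                        multi[r.predictor].p_value if r.predictor in multi else np.nan
                    ),
                }
                for r in suite.univariate
            ]
        )

    # --- table 3: duration sub-analysis on disease eyes
    table3 = None
    sub = None
    if {"duration_months", "injections_per_year"} <= set(disease.columns):
        usable = disease.dropna(subset=["duration_months", "injections_per_year"])
        early = usable["duration_months"] < config.duration_split_months
        if len(usable) and early.any() and (~early).any():
            sub = duration_subanalysis(
                usable,
                split_months=config.duration_split_months,
                equal_var=config.equal_var_ttest,
            )
            table3 = pd.DataFrame(
                [
                    {
                        "stratum": "early",
                        "n": sub.n_early,
                        "reflectivity_vs_other_p": sub.reflectivity_p,
                        "injections_vs_other_p": sub.injections_p,
                        "regression_beta": sub.early.standardized_beta,
                        "regression_r2": sub.early.r_squared,
                        "regression_p": sub.early.p_value,
                    },
                    {
                        "stratum": "late",
                        "n": sub.n_late,
                        "reflectivity_vs_other_p": sub.reflectivity_p,
                        "injections_vs_other_p": sub.injections_p,
                        "regression_beta": sub.late.standardized_beta,
                        "regression_r2": sub.late.r_squared,
                        "regression_p": sub.late.p_value,
                    },
                ]
            )
        else:
            logger.warning("report: duration sub-analysis skipped (empty stratum)")

    # --- summary
    summary: dict = {"config": config.to_dict(), "n_eyes": int(len(table))}
    if "corrected_reflectivity" in comparisons:
        gc = comparisons["corrected_reflectivity"]
        summary["reflectivity_anova"] = {
            "F": gc.anova_f,
            "p": gc.anova_p,
            "group_means": gc.group_means,
            "pairwise": [
                {
                    "groups": [pc.group_a, pc.group_b],
                    "t": pc.t_statistic,
                    "p_raw": pc.p_raw,
                    "p_bonferroni": pc.p_bonferroni,
                }
                for pc in gc.pairwise
            ],
        }
    paired = table.dropna(subset=["contralateral_reflectivity"])
    paired = paired[paired["group"] != "control"]
    if len(paired) >= 2:
        t, p = paired_quadrant_test(
            paired["corrected_reflectivity"].to_numpy(),
            paired["contralateral_reflectivity"].to_numpy(),
        )
        summary["paired_quadrant_test"] = {
            "t": t,
            "p": p,
            "mean_difference": float(
                (
                    paired["corrected_reflectivity"]
                    - paired["contralateral_reflectivity"]
                ).mean()
            ),
            "n": int(len(paired)),
        }

    out = {"table1": table1, "table2": table2, "table3": table3, "summary": summary}
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        prov = config.to_dict()
        write_table(table1, outdir / "table1_group_summary.csv", provenance=prov)
        if table2 is not None:
            write_table(table2, outdir / "table2_regression.csv", provenance=prov)
        if table3 is not None:
            write_table(table3, outdir / "table3_duration.csv", provenance=prov)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    return out
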