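"""End-to-end pipeline: simulate -> quantify -> asymmetry -> analyze.

Each stage reads and writes plain files under the run's output directory,
and a JSON manifest records every tunable, the seed, per-stage row counts
and every excluded image with its reason, so a run is auditable and
repeatable: identical config + seed gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as oio
from .asym import AI_COLUMNS, pair_asymmetry_profile
from .errors import OctaAsymError, ValidationError
from .metrics import (
    DEFAULT_REFERENCE_AL_MM,
    quality_check,
    quantify_angiogram,
)
from .stats import (
    ALPHA,
    DEFAULT_ADJUSTMENT,
    categorical_association,
    compare_groups,
    correlate,
    fit_adjusted_regression,
)
from .synth import CohortSpec, default_cohort_spec, generate_cohort

log = logging.getLogger("octa_asym")

STAGES = ("simulate", "quantify", "asymmetry", "analyze")


@dataclass
class RunConfig:
    """Configuration of a pipeline run; every tunable is logged."""

    out_dir: str = "octa_run"
    stages: Sequence[str] = STAGES
    seed: int = 0
    image_dir: Optional[str] = None     # input for quantify (default: out/images)
    cohort_csv: Optional[str] = None    # input for analyze (default: out/cohort.csv)
    render_images: bool = True
    binarize_method: str = "otsu"
    binarize_threshold: Optional[float] = None
    closing_radius_px: int = 2
    reference_al_mm: float = DEFAULT_REFERENCE_AL_MM
    min_signal_strength: int = 8
    alpha: float = ALPHA
    cohort_spec: Optional[CohortSpec] = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValidationError("no stages selected")


def _config_echo(config: RunConfig) -> dict:
    d = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if f.name == "cohort_spec":
            v = "default" if v is None else "custom"
        elif f.name == "stages":
            v = list(v)
        d[f.name] = v
    return d


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages in order and write a manifest.

    Returns the output directory. Any stage error propagates with the
    stage name prefixed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import octa_asym

    manifest: dict = {
        "config": _config_echo(config),
        "version": octa_asym.__version__,
        "seed": config.seed,
        "stages": {},
        "exclusions": [],
    }
    try:
        for stage in STAGES:
            if stage in config.stages:
                runner = globals()[f"_stage_{stage}"]
                manifest["stages"][stage] = runner(config, out, manifest)
    except OctaAsymError as exc:
        raise type(exc)(f"[stage failed] {exc}") from exc
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
    return out


def _stage_simulate(config: RunConfig, out: Path, manifest: dict) -> dict:
    spec = config.cohort_spec or default_cohort_spec(seed=config.seed)
    if config.cohort_spec is not None and spec.seed != config.seed:
        spec = dataclasses.replace(spec, seed=config.seed)
    result = generate_cohort(spec, render_images=config.render_images)
    if config.render_images:
        table, images = result
        img_dir = out / "images"
        n_img = 0
        for _, row in table.iterrows():
            od_img, os_img, _truth = images[row["patient_id"]]
            for img, ss in ((od_img, row["ss_od"]), (os_img, row["ss_os"])):
                img.signal_strength = int(ss)
                img.axial_length_mm = float(row["axial_length_mm"])
                oio.save_angiogram(img, img_dir, row["patient_id"])
                n_img += 1
    else:
        table, n_img = result, 0
    oio.write_cohort_csv(table, out / "cohort.csv")
    counts = table["group"].value_counts()
    info = {
        "patients": int(len(table)),
        "images": n_img,
        "group_counts": {g: int(counts.get(g, 0)) for g in
                         [gr.name for gr in spec.groups]},
    }
    log.info("simulate: %s", info)
    return info


def _stage_quantify(config: RunConfig, out: Path, manifest: dict) -> dict:
    img_dir = Path(config.image_dir or out / "images")
    if not img_dir.is_dir():
        raise ValidationError(f"image directory not found: {img_dir}")
    rows: List[dict] = []
    tifs = sorted(img_dir.glob("*.tif")) + sorted(img_dir.glob("*.png"))
    tifs = [p for p in tifs if "truth" not in p.stem]
    if not tifs:
        raise ValidationError(f"no angiogram images under {img_dir}")
    for path in tifs:
        image = oio.load_angiogram(path)
        ok, reason = quality_check(image, min_ss=config.min_signal_strength)
        if not ok:
            manifest["exclusions"].append({"image": path.name,
                                           "reason": reason})
            continue
        m = quantify_angiogram(
            image,
            binarize_method=config.binarize_method,
            threshold=config.binarize_threshold,
            closing_radius_px=config.closing_radius_px,
        )
        pid, lat = path.stem.rsplit("_", 1)
        rows.append({
            "patient_id": pid,
            "laterality": lat,
            "perfusion_density": m.perfusion_density,
            "vessel_density": m.vessel_density,
            "faz_area": m.faz_area,
            "faz_perimeter": m.faz_perimeter,
            "faz_circularity": m.faz_circularity,
            "layer_tag": m.layer_tag or "",
            "corrected": int(m.corrected),
        })
    table = pd.DataFrame(rows)
    oio.write_metrics_csv(table, out / "metrics.csv")
    info = {"images_quantified": len(rows),
            "images_excluded": len(manifest["exclusions"])}
    log.info("quantify: %s", info)
    return info


def _stage_asymmetry(config: RunConfig, out: Path, manifest: dict) -> dict:
    metrics_path = out / "metrics.csv"
    if not metrics_path.exists():
        raise ValidationError(f"metrics table not found: {metrics_path}")
    long = pd.read_csv(metrics_path, dtype={"patient_id": str})
    wide_rows = []
    for pid, grp in long.groupby("patient_id"):
        eyes = {str(r["laterality"]): r for _, r in grp.iterrows()}
        if "OD" not in eyes or "OS" not in eyes:
            manifest["exclusions"].append(
                {"patient": pid, "reason": "missing fellow eye"}
            )
            continue
        row = {"patient_id": pid}
        for stem, col in (("spd", "perfusion_density"),
                          ("svd", "vessel_density"),
                          ("faza", "faz_area"),
                          ("fazp", "faz_perimeter"),
                          ("fazc", "faz_circularity")):
            row[f"{stem}_od"] = eyes["OD"][col]
            row[f"{stem}_os"] = eyes["OS"][col]
        wide_rows.append(row)
    wide = pd.DataFrame(wide_rows)
    profiles = []
    for pair in oio.metrics_table_to_pairs(wide):
        profiles.append(pair_asymmetry_profile(pair).as_dict())
    ai = pd.DataFrame(profiles)
    for col in AI_COLUMNS:
        if col not in ai.columns:
            ai[col] = np.nan
    oio.write_ai_csv(ai, out / "ai.csv")
    info = {"pairs": len(ai)}
    log.info("asymmetry: %s", info)
    return info


def _merge_cohort_ai(cohort: pd.DataFrame, out: Path) -> pd.DataFrame:
    ai_path = out / "ai.csv"
    if ai_path.exists():
        ai = oio.read_ai_csv(ai_path)
        merged = cohort.drop(
            columns=[c for c in AI_COLUMNS if c in cohort.columns]
        ).merge(ai, on="patient_id", how="inner")
        if len(merged):
            return merged
    if all(c in cohort.columns for c in AI_COLUMNS):
        return cohort
    raise ValidationError("no AI columns available for analysis")


def _stage_analyze(config: RunConfig, out: Path, manifest: dict) -> dict:
    cohort_path = Path(config.cohort_csv or out / "cohort.csv")
    if not cohort_path.exists():
        raise ValidationError(f"cohort table not found: {cohort_path}")
    cohort = oio.read_cohort_csv(cohort_path)
    table = _merge_cohort_ai(cohort, out)
    report = analyze_cohort(table, alpha=config.alpha, seed=config.seed)
    report["table1"].to_csv(out / "table1.csv", index=False)
    report["table2"].to_csv(out / "table2.csv", index=False)
    report["correlations"].to_csv(out / "correlations.csv", index=False)
    report["regressions"].to_csv(out / "regressions.csv", index=False)
    (out / "analysis_log.txt").write_text("\n".join(report["log"]) + "\n")
    info = {"patients_analyzed": int(len(table)),
            "outcomes": len(AI_COLUMNS)}
    log.info("analyze: %s", info)
    return info


def analyze_cohort(
    table: pd.DataFrame, alpha: float = ALPHA, seed: int = 0
) -> Dict[str, object]:
    """Cohort statistics: demographics tests, per-outcome group
    comparisons, HbA1c/age correlations and adjusted regressions.

    Returns a dict of DataFrames (``table1``, ``table2``,
    ``correlations``, ``regressions``) plus a ``log`` list recording every
    test-path decision.
    """
    groups_present = [g for g in table["group"].unique()]
    lines: List[str] = []

    # Table 1: demographics by group
    t1_rows = []
    for var in ("age", "hba1c", "axial_length_mm", "cmt_um"):
        if var not in table.columns:
            continue
        row: dict = {"variable": var}
        for g in groups_present:
            v = table.loc[table["group"] == g, var].dropna()
            row[f"{g} mean"] = v.mean() if len(v) else np.nan
            row[f"{g} sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
        try:
            cmp_ = compare_groups(table, var, alpha=alpha)
            row["p"] = cmp_.omnibus_p
            lines.append(f"table1 {var}: {cmp_.method} "
                         f"(normality p={cmp_.normality_p:.3g}, "
                         f"homogeneity p={cmp_.homogeneity_p:.3g})")
        except OctaAsymError as exc:
            row["p"] = np.nan
            lines.append(f"table1 {var}: skipped ({exc})")
        t1_rows.append(row)
    for var in ("sex", "race", "htn", "hld", "obesity", "insulin", "smoking"):
        if var not in table.columns:
            continue
        try:
            assoc = categorical_association(table, var, seed=seed)
            t1_rows.append({"variable": var, "p": assoc.p})
            lines.append(f"table1 {var}: {assoc.method} "
                         f"(min expected={assoc.min_expected:.2f})")
        except OctaAsymError as exc:
            lines.append(f"table1 {var}: skipped ({exc})")

    # Table 2: AI group means +/- SD and group comparisons
    t2_rows = []
    for col in AI_COLUMNS:
        if col not in table.columns or table[col].dropna().empty:
            continue
        row = {"outcome": col}
        for g in groups_present:
            v = table.loc[table["group"] == g, col].dropna()
            row[f"{g} mean"] = v.mean() if len(v) else np.nan
            row[f"{g} sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
        try:
            cmp_ = compare_groups(table, col, alpha=alpha)
            row["method"] = cmp_.method
            row["omnibus_p"] = cmp_.omnibus_p
            for (g1, g2), res in cmp_.pairwise.items():
                row[f"p {g1} vs {g2}"] = res["p_adj"]
            lines.append(f"table2 {col}: {cmp_.method} "
                         f"(normality p={cmp_.normality_p:.3g}, "
                         f"homogeneity p={cmp_.homogeneity_p:.3g})")
        except OctaAsymError as exc:
            lines.append(f"table2 {col}: skipped ({exc})")
        t2_rows.append(row)

    # correlations: age and HbA1c against every AI
    corr_rows = []
    for x in ("age", "hba1c", "axial_length_mm", "cmt_um"):
        if x not in table.columns:
            continue
        for col in AI_COLUMNS:
            if col not in table.columns:
                continue
            try:
                c = correlate(table, x, col)
                corr_rows.append({"x": x, "y": col, "r": c.r, "p": c.p,
                                  "n": c.n})
            except OctaAsymError as exc:
                lines.append(f"correlation {x}~{col}: skipped ({exc})")

    # adjusted regressions: HbA1c exposure on each AI
    reg_rows = []
    if "hba1c" in table.columns:
        for col in AI_COLUMNS:
            if col not in table.columns:
                continue
            try:
                r = fit_adjusted_regression(
                    table, col, "hba1c",
                    adjustment=[a for a in DEFAULT_ADJUSTMENT
                                if a in table.columns],
                )
                lo, hi = r.exposure_ci
                reg_rows.append({
                    "outcome": col, "exposure": "hba1c",
                    "beta": r.exposure_beta, "ci_low": lo, "ci_high": hi,
                    "p": r.exposure_p, "n": r.n,
                })
            except OctaAsymError as exc:
                lines.append(f"regression hba1c->{col}: skipped ({exc})")

    return {
        "table1": pd.DataFrame(t1_rows),
        "table2": pd.DataFrame(t2_rows),
        "correlations": pd.DataFrame(corr_rows),
        "regressions": pd.DataFrame(reg_rows),
        "log": lines,
    }
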