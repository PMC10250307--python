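"""Readers and writers for cohort tables, metrics tables and angiograms.

All tables are plain CSV with a documented, fixed header. Missing values
are written as empty fields; ``N/A`` and ``NA`` are accepted on read.
Angiograms travel as 8-bit grayscale TIFF with a JSON metadata sidecar;
ground truth as a PNG mask plus JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .asym import AI_COLUMNS, EyePairMetrics
from .errors import SchemaError
from .metrics import EnFaceAngiogram, VascularMetrics
from .synth import GROUPS, AngiogramTruth

#: required columns of a cohort CSV (extra columns are preserved)
COHORT_REQUIRED = (
    "patient_id", "group", "age", "sex", "race", "hba1c", "htn", "hld",
    "obesity", "insulin", "smoking", "axial_length_mm", "cmt_um",
    "ss_od", "ss_os",
)

#: per-eye metric stems of a metrics CSV
METRIC_STEMS = ("spd", "svd", "dpd", "dvd", "faza", "fazp", "fazc")

_NA_VALUES = ["", "N/A", "NA", "NaN", "nan"]

_SEX_LEVELS = {"F", "M"}


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table; missing values become empty fields."""
    missing = [c for c in COHORT_REQUIRED if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing required columns: {missing}")
    table.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` for a missing required column, an
    unrecognized sex code or an unrecognized group label — unexpected
    codings fail loudly rather than being coerced.
    """
    table = pd.read_csv(
        path, na_values=_NA_VALUES, keep_default_na=False,
        dtype={"patient_id": str},
    )
    missing = [c for c in COHORT_REQUIRED if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing required columns: {missing}")
    bad_sex = set(table["sex"].dropna().astype(str)) - _SEX_LEVELS
    if bad_sex:
        raise SchemaError(
            f"unrecognized sex codes {sorted(bad_sex)}; expected F/M"
        )
    bad_group = set(table["group"].dropna().astype(str)) - set(GROUPS)
    if bad_group:
        raise SchemaError(f"unrecognized group labels {sorted(bad_group)}")
    return table


def write_metrics_csv(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False, na_rep="")


def read_metrics_csv(
    path, column_map: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """Read a per-patient, per-eye metrics table (supplementary-style).

    Expected columns: ``patient_id`` plus ``<stem>_od`` / ``<stem>_os`` for
    each metric stem in :data:`METRIC_STEMS` (absent stems allowed; their
    AIs will be missing). ``column_map`` renames non-conforming headers
    onto this schema before validation.
    """
    table = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False,
                        dtype={"patient_id": str})
    if column_map:
        table = table.rename(columns=column_map)
    if "patient_id" not in table.columns:
        raise SchemaError("metrics CSV missing required column: patient_id")
    present = [
        s for s in METRIC_STEMS
        if f"{s}_od" in table.columns and f"{s}_os" in table.columns
    ]
    if not present:
        raise SchemaError(
            "metrics CSV contains no <metric>_od/<metric>_os column pairs"
        )
    return table


def metrics_table_to_pairs(table: pd.DataFrame) -> List[EyePairMetrics]:
    """Convert a wide metrics table into superficial-layer eye pairs.

    Only the superficial stems (spd/svd/faz*) map onto
    :class:`VascularMetrics` objects; deep-layer stems are carried through
    the table-level AI computation instead.
    """
    pairs = []
    for _, row in table.iterrows():
        def mk(eye: str) -> VascularMetrics:
            return VascularMetrics(
                perfusion_density=float(row.get(f"spd_{eye}", np.nan)),
                vessel_density=float(row.get(f"svd_{eye}", np.nan)),
                faz_area=float(row.get(f"faza_{eye}", np.nan)),
                faz_perimeter=float(row.get(f"fazp_{eye}", np.nan)),
                faz_circularity=float(row.get(f"fazc_{eye}", np.nan)),
                layer_tag="SRL",
            )
        pairs.append(EyePairMetrics(str(row["patient_id"]), mk("od"), mk("os")))
    return pairs


def write_ai_csv(profiles: pd.DataFrame, path) -> None:
    cols = ["patient_id", *AI_COLUMNS]
    missing = [c for c in cols if c not in profiles.columns]
    if missing:
        raise SchemaError(f"AI table missing columns: {missing}")
    profiles[cols].to_csv(path, index=False, na_rep="")


def read_ai_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False,
                        dtype={"patient_id": str})
    missing = [c for c in ("patient_id", *AI_COLUMNS) if c not in table.columns]
    if missing:
        raise SchemaError(f"AI CSV missing columns: {missing}")
    return table


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

def save_angiogram(
    image: EnFaceAngiogram,
    directory,
    patient_id: str,
    truth: Optional[AngiogramTruth] = None,
) -> Path:
    """Write ``<patient_id>_<laterality>.tif`` plus JSON sidecar (and, when
    ground truth is given, a PNG mask and truth sidecar)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{patient_id}_{image.laterality}"
    tif_path = directory / f"{stem}.tif"
    tifffile.imwrite(tif_path, np.asarray(image.pixels, dtype=np.uint8))
    meta = {
        "patient_id": patient_id,
        "laterality": image.laterality,
        "field_mm": image.field_mm,
        "signal_strength": image.signal_strength,
        "axial_length_mm": image.axial_length_mm,
        "layer_tag": image.layer_tag,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        Image.fromarray(
            (truth.vessel_mask.astype(np.uint8)) * 255
        ).save(directory / f"{stem}_truth_mask.png")
        truth_meta = {
            "faz_area_mm2": truth.faz_area_mm2,
            "n_segments": truth.n_segments,
            "n_dropped": truth.n_dropped,
            "faz_contour_mm": truth.faz_contour_mm.tolist(),
        }
        (directory / f"{stem}_truth.json").write_text(
            json.dumps(truth_meta)
        )
    return tif_path


def load_angiogram(tif_path) -> EnFaceAngiogram:
    """Load a TIFF/PNG angiogram with its JSON sidecar."""
    tif_path = Path(tif_path)
    if tif_path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(tif_path)
    else:
        pixels = np.asarray(Image.open(tif_path).convert("L"))
    meta_path = tif_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return EnFaceAngiogram(
        pixels=pixels,
        field_mm=float(meta.get("field_mm", 3.0)),
        laterality=meta.get("laterality", "OD"),
        signal_strength=meta.get("signal_strength"),
        axial_length_mm=meta.get("axial_length_mm"),
        layer_tag=meta.get("layer_tag"),
    )
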