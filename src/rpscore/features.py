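"""Blood-feature dictionary, derived indicators, labels and feature sets.

The cohort table is a flat :class:`pandas.DataFrame` with one row per
patient.  Columns fall into four blocks:

* clinical features (``distance_anal_verge`` [cm], ``cea`` [ng/mL],
  ``tumor_grade`` [ordinal 1-3], ``age`` [years], ``sex`` [0=female,
  1=male], ``clinical_T`` [1-4], ``clinical_N`` [0-2]);
* the pre-treatment blood panel, prefixed ``pre_``: a 17-feature complete
  blood count with differential plus a 12-feature chemistry panel;
* the early-treatment blood panel, prefixed ``early_``: the same 17 CBC
  features drawn 1-2 weeks after the start of chemoradiotherapy (no
  chemistry is re-measured at that visit, so there is no early albumin);
* outcomes: AJCC tumor regression grade ``trg`` in {0,1,2,3} and
  pathologic stages ``ypT`` (0-4) and ``ypN`` (0-2).

Cell counts are stored in cells/uL (= /mm^3); platelets in 10^3/uL;
albumin in g/dL; distance from the anal verge in cm.  The authoritative
column dictionary (units included) is shipped as ``schema.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    MissingDataError,
    UndefinedIndicatorError,
    UnsupportedIndicatorError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Feature dictionary
# ---------------------------------------------------------------------------

#: 17 complete-blood-count-with-differential features (both epochs).
CBC_FEATURES: tuple[str, ...] = (
    "RBC", "HB", "Hct", "MCV", "MCH", "MCHC", "RDW",
    "PLT", "PCT", "MPV", "PDW",
    "WBC", "neutrophil", "lymphocyte", "monocyte", "eosinophil", "basophil",
)

#: 12 blood-chemistry features (pre-treatment only).
CHEMISTRY_FEATURES: tuple[str, ...] = (
    "calcium", "phosphorus", "glucose", "uric_acid", "cholesterol",
    "total_protein", "albumin", "total_bilirubin", "AST", "ALT",
    "ALP", "creatinine",
)

#: Tumor-related clinical trio used by the smallest feature set.
TUMOR_CLINICAL_FEATURES: tuple[str, ...] = ("distance_anal_verge", "cea", "tumor_grade")

#: Full clinical block.  Membership beyond the tumor trio is a package
#: assumption (demographics plus clinical stage); see the methods note.
CLINICAL_FEATURES: tuple[str, ...] = TUMOR_CLINICAL_FEATURES + (
    "age", "sex", "clinical_T", "clinical_N",
)

#: Clinical features tested with a chi-squared rather than rank test and
#: encoded as integer codes in feature matrices.
CATEGORICAL_FEATURES: frozenset[str] = frozenset(
    {"tumor_grade", "sex", "clinical_T", "clinical_N"}
)

OUTCOME_COLUMNS: tuple[str, ...] = ("trg", "ypT", "ypN")

PRE_COLUMNS: tuple[str, ...] = tuple(f"pre_{f}" for f in CBC_FEATURES + CHEMISTRY_FEATURES)
EARLY_COLUMNS: tuple[str, ...] = tuple(f"early_{f}" for f in CBC_FEATURES)

#: Stable column order of a cohort CSV.
COHORT_COLUMNS: tuple[str, ...] = (
    ("id",) + CLINICAL_FEATURES + PRE_COLUMNS + EARLY_COLUMNS + OUTCOME_COLUMNS
)

FEATURE_SET_NAMES: tuple[str, ...] = (
    "tumor_clinical", "clinical", "clinical_pre", "clinical_early", "clinical_pre_early",
)


def feature_set_columns(set_name: str) -> list[str]:
    """Ordered column list for one of the five model feature sets.

    The derived inflammatory/nutritional indicators are deliberately not
    part of any model feature set; they serve as competing baseline
    predictors only.
    """
    if set_name == "tumor_clinical":
        return list(TUMOR_CLINICAL_FEATURES)
    if set_name == "clinical":
        return list(CLINICAL_FEATURES)
    if set_name == "clinical_pre":
        return list(CLINICAL_FEATURES) + list(PRE_COLUMNS)
    if set_name == "clinical_early":
        return list(CLINICAL_FEATURES) + list(EARLY_COLUMNS)
    if set_name == "clinical_pre_early":
        return list(CLINICAL_FEATURES) + list(PRE_COLUMNS) + list(EARLY_COLUMNS)
    raise ValidationError(
        f"unknown feature set {set_name!r}; expected one of {FEATURE_SET_NAMES}"
    )


def load_schema() -> list[dict]:
    """Load the shipped column dictionary (name, unit, kind, epoch)."""
    text = resources.files("rpscore").joinpath("schema.yaml").read_text()
    return yaml.safe_load(text)["columns"]


# ---------------------------------------------------------------------------
# Patient record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """One patient's clinical features, blood panels and outcomes.

    ``pre_panel`` maps plain feature names (``"PLT"``, ``"albumin"``, ...)
    to pre-treatment values and additionally carries ``"CEA"`` (the serum
    tumor marker is drawn with the pre-treatment panel).  ``early_panel``
    holds the 17 CBC features only — chemistry is not re-measured at the
    early-treatment visit.
    """

    id: str
    clinical: dict
    pre_panel: dict
    early_panel: dict
    outcomes: dict

    def __post_init__(self) -> None:
        bad = set(self.early_panel) - set(CBC_FEATURES)
        if bad:
            raise ValidationError(
                f"early panel may only contain CBC features; got {sorted(bad)}"
            )


def record_from_row(row: Mapping) -> PatientRecord:
    """Build a :class:`PatientRecord` from one cohort-table row."""
    pre = {f: row.get(f"pre_{f}") for f in CBC_FEATURES + CHEMISTRY_FEATURES}
    pre["CEA"] = row.get("cea")
    return PatientRecord(
        id=str(row.get("id", "")),
        clinical={f: row.get(f) for f in CLINICAL_FEATURES},
        pre_panel=pre,
        early_panel={f: row.get(f"early_{f}") for f in CBC_FEATURES},
        outcomes={k: row.get(k) for k in OUTCOME_COLUMNS},
    )


# ---------------------------------------------------------------------------
# Derived indicators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndicatorSet:
    """Systemic inflammatory/nutritional indicators for one epoch.

    ``pni`` is ``None`` for the early epoch: the prognostic nutritional
    index needs serum albumin, which is only measured pre-treatment.
    """

    nlr: float
    plr: float
    lmr: float
    pni: float | None
    epoch: str


def prognostic_nutritional_index(albumin_g_dl: float, lymphocyte_per_ul: float) -> float:
    """PNI = 10 x serum albumin (g/dL) + 0.005 x lymphocyte count (/mm^3)."""
    if albumin_g_dl < 0 or lymphocyte_per_ul < 0:
        raise ValidationError("albumin and lymphocyte count must be non-negative")
    return 10.0 * float(albumin_g_dl) + 0.005 * float(lymphocyte_per_ul)


def compute_indicators(
    panel: Mapping[str, float], epoch: str, albumin: float | None = None
) -> IndicatorSet:
    """Compute NLR, PLR, LMR (and PNI when pre-treatment) from a CBC panel.

    Parameters
    ----------
    panel
        Mapping with ``neutrophil``, ``lymphocyte``, ``monocyte`` in
        cells/uL and ``PLT`` in 10^3/uL.
    epoch
        ``"pre"`` or ``"early"``.
    albumin
        Serum albumin in g/dL; only meaningful (and only accepted) for the
        pre-treatment epoch.

    Notes
    -----
    PLR is the platelet-to-lymphocyte ratio with both counts per uL, so
    the stored platelet value (10^3/uL) is converted before dividing.
    """
    if epoch not in ("pre", "early"):
        raise ValidationError(f"epoch must be 'pre' or 'early', got {epoch!r}")
    if epoch == "early" and albumin is not None:
        raise UnsupportedIndicatorError(
            "PNI is undefined for the early epoch: no early-treatment albumin"
        )
    try:
        neut = float(panel["neutrophil"])
        lymph = float(panel["lymphocyte"])
        mono = float(panel["monocyte"])
        plt = float(panel["PLT"])
    except (KeyError, TypeError) as exc:
        raise MissingDataError(f"indicator input missing from panel: {exc}") from exc
    if lymph <= 0:
        raise UndefinedIndicatorError("lymphocyte count must be > 0 for NLR/PLR/LMR")
    if mono <= 0:
        raise UndefinedIndicatorError("monocyte count must be > 0 for LMR")
    pni = None
    if epoch == "pre" and albumin is not None:
        pni = prognostic_nutritional_index(albumin, lymph)
    return IndicatorSet(
        nlr=neut / lymph,
        plr=plt * 1000.0 / lymph,
        lmr=lymph / mono,
        pni=pni,
        epoch=epoch,
    )


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def derive_label(trg) -> int:
    """Binary response label: 1 = poor responder (TRG 2-3), 0 = good (TRG 0-1).

    The positive class is the poor responder, so every predictor score is
    oriented as "higher = less likely to respond".
    """
    if trg not in (0, 1, 2, 3):
        raise ValidationError(f"TRG must be in {{0,1,2,3}}, got {trg!r}")
    return int(trg >= 2)


def labels_from_frame(df: pd.DataFrame) -> np.ndarray:
    """Vector of poor-responder labels for a cohort table."""
    trg = df["trg"].to_numpy()
    if not np.isin(trg, [0, 1, 2, 3]).all():
        raise ValidationError("cohort contains TRG values outside {0,1,2,3}")
    return (trg >= 2).astype(int)


def derive_downstaging(record) -> dict[str, bool]:
    """Downstaging outcomes for one patient.

    overall = ypT0-2N0 (M0 by study population); t_down / n_down compare
    pathologic with clinical stage.
    """
    if isinstance(record, PatientRecord):
        ct, cn = record.clinical.get("clinical_T"), record.clinical.get("clinical_N")
        ypt, ypn = record.outcomes.get("ypT"), record.outcomes.get("ypN")
    else:
        ct, cn = record.get("clinical_T"), record.get("clinical_N")
        ypt, ypn = record.get("ypT"), record.get("ypN")
    for name, val in (("clinical_T", ct), ("clinical_N", cn), ("ypT", ypt), ("ypN", ypn)):
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise ValidationError(f"stage {name} is missing; downstaging undefined")
    return {
        "overall": bool(ypt <= 2 and ypn == 0),
        "t_down": bool(ypt < ct),
        "n_down": bool(ypn < cn),
    }


def downstaging_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized downstaging table (overall, t_down, n_down) for a cohort."""
    for col in ("clinical_T", "clinical_N", "ypT", "ypN"):
        if col not in df or df[col].isna().any():
            raise ValidationError(f"stage column {col!r} missing or incomplete")
    return pd.DataFrame(
        {
            "overall": (df["ypT"] <= 2) & (df["ypN"] == 0),
            "t_down": df["ypT"] < df["clinical_T"],
            "n_down": df["ypN"] < df["clinical_N"],
        },
        index=df.index,
    )


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------

def assemble_features(data, set_name: str) -> pd.DataFrame:
    """Feature matrix for one named feature set, in stable column order.

    Accepts a cohort table or a single row (Series / mapping).  Categorical
    features are already integer-coded in the cohort table, so assembly is
    a column projection; values pass through unchanged (missing stays NaN,
    handled downstream by training-set median imputation).
    """
    cols = feature_set_columns(set_name)
    if isinstance(data, pd.DataFrame):
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValidationError(f"cohort table lacks feature columns {missing}")
        return data[cols].astype(float)
    if isinstance(data, PatientRecord):
        data = _record_to_row(data)
    row = {c: data[c] for c in cols}
    return pd.DataFrame([row], columns=cols).astype(float)


def _record_to_row(record: PatientRecord) -> dict:
    row = {"id": record.id, **record.clinical, **record.outcomes}
    for f, v in record.pre_panel.items():
        if f != "CEA":
            row[f"pre_{f}"] = v
    for f, v in record.early_panel.items():
        row[f"early_{f}"] = v
    return row
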