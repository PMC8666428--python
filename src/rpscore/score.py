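"""Response Prediction Score: importance averaging, derivation, evaluation.

The score-derivation procedure:

1.  Fit the chosen linear family on N repeated representative splits
    (``benchmark.run_benchmark``) and average the per-repeat coefficients
    feature-wise — unselected features contribute 0 — giving the
    generalized importance beta_k of every feature.
2.  Rank features by the magnitude of the *standardized-scale* mean
    coefficient (unit-free, so counts and centimetres are comparable);
    the reported score weights stay on the raw scale so the score is a
    plain weighted sum of laboratory values.
3.  Choose the score size K_o: for K = 1..K_max build the candidate score
    from the top-K features and test it against the responder label with
    a two-sided Mann-Whitney U; K_o is the argmin-P (smallest K on ties).
4.  Audit sign consistency: the fraction of repeats in which each
    feature's coefficient agrees in sign with its mean.

The published five-term score (early-treatment monocyte, distance from
the anal verge, early-treatment platelet/neutrophil/eosinophil) ships as
the constant :data:`PUBLISHED_RPS`; higher scores mean a lower chance of
responding to chemoradiotherapy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .benchmark import BenchConfig, ModelRunResult, run_benchmark
from .exceptions import (
    MissingDataError,
    UnsupportedModelError,
    ValidationError,
)
from .features import (
    assemble_features,
    downstaging_frame,
    labels_from_frame,
)
from .metrics import auroc, mann_whitney_u
from .splitting import SplitConfig

__all__ = [
    "ScoreDefinition", "PUBLISHED_RPS", "ImportanceTable",
    "generalized_importance", "select_score_size", "evaluate_score",
    "score_frame", "sign_consistency_audit", "compare_predictors",
    "stratify_quartiles", "derive_score", "StratificationReport",
]


# ---------------------------------------------------------------------------
# Score definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreDefinition:
    """An ordered list of (feature, raw-scale weight) terms; no intercept."""

    terms: tuple[tuple[str, float], ...]
    provenance: str = "derived"
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [f for f, _ in self.terms]
        if len(set(names)) != len(names):
            raise ValidationError("score features must be unique")
        if any(w == 0 for _, w in self.terms):
            raise ValidationError("score weights must be non-zero")

    @property
    def k_o(self) -> int:
        return len(self.terms)

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.terms]

    def to_json(self) -> str:
        return json.dumps(
            {
                "provenance": self.provenance,
                "terms": [{"feature": f, "weight": w, "unit": self.units.get(f, "")}
                          for f, w in self.terms],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreDefinition":
        obj = json.loads(text)
        return cls(
            terms=tuple((t["feature"], float(t["weight"])) for t in obj["terms"]),
            provenance=obj.get("provenance", "derived"),
            units={t["feature"]: t.get("unit", "") for t in obj["terms"]},
        )


#: The published five-term Response Prediction Score.  Units: cell counts
#: per uL, platelets in 10^3/uL, distance in cm.
PUBLISHED_RPS = ScoreDefinition(
    terms=(
        ("early_monocyte", 0.000559),
        ("distance_anal_verge", 0.026172),
        ("early_PLT", 0.001021),
        ("early_neutrophil", 0.000049),
        ("early_eosinophil", -0.000433),
    ),
    provenance="published",
    units={
        "early_monocyte": "cells/uL",
        "distance_anal_verge": "cm",
        "early_PLT": "10^3/uL",
        "early_neutrophil": "cells/uL",
        "early_eosinophil": "cells/uL",
    },
)


def evaluate_score(defn: ScoreDefinition, record: Mapping[str, float]) -> float:
    """Weighted sum of the score's features for one patient; no intercept."""
    total = 0.0
    for feature, weight in defn.terms:
        try:
            value = record[feature]
        except (KeyError, IndexError) as exc:
            raise MissingDataError(f"record lacks score feature {feature!r}") from exc
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise MissingDataError(f"score feature {feature!r} is missing")
        total += weight * float(value)
    return total


def score_frame(defn: ScoreDefinition, df: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`evaluate_score` over a cohort table (NaN where
    any input is missing)."""
    missing = [f for f in defn.features if f not in df.columns]
    if missing:
        raise MissingDataError(f"table lacks score features {missing}")
    out = pd.Series(0.0, index=df.index)
    for feature, weight in defn.terms:
        out = out + weight * df[feature].astype(float)
    return out


# ---------------------------------------------------------------------------
# Generalized importance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceTable:
    """Per-feature across-repeat coefficient summary.

    ``table`` columns: feature, beta_raw (mean raw-scale coefficient, 0
    imputed for unselected repeats), beta_std (same on the standardized
    scale — the ranking key), sd_raw, selection_count, sign_consistency
    (fraction of selecting repeats whose sign matches sign(beta_std);
    NaN when never selected).  Rows are ranked by \\|beta_std\\|
    descending, ties alphabetically.
    """

    table: pd.DataFrame
    n_repeats: int
    model_kind: str
    feature_set: str

    @property
    def ranked_features(self) -> list[str]:
        return self.table["feature"].tolist()


def generalized_importance(
    results: Sequence[ModelRunResult],
    model_kind: str | None = None,
    feature_set: str | None = None,
) -> ImportanceTable:
    """Average per-repeat linear coefficients into generalized importance.

    All results must come from one linear (coefficient-producing) model
    family on one feature set; pass ``model_kind``/``feature_set`` to
    filter a mixed result list.
    """
    subset = [
        r for r in results
        if (model_kind is None or r.model_kind == model_kind)
        and (feature_set is None or r.feature_set == feature_set)
    ]
    if len(subset) < 2:
        raise ValidationError("need at least 2 repeats to average importance")
    kinds = {r.model_kind for r in subset}
    sets_ = {r.feature_set for r in subset}
    if len(kinds) > 1 or len(sets_) > 1:
        raise ValidationError(
            f"results mix model kinds {kinds} / feature sets {sets_}; filter first"
        )
    if any(r.coefficients_raw is None for r in subset):
        raise UnsupportedModelError(
            f"importance is defined only for linear models, not {kinds.pop()!r}"
        )
    n = len(subset)
    features = list(subset[0].coefficients_raw.keys())
    raw = np.array([[r.coefficients_raw[f] for f in features] for r in subset])
    std = np.array([[r.coefficients_std[f] for f in features] for r in subset])
    sel = np.array([[f in r.selected_features for f in features] for r in subset])

    beta_raw = raw.mean(axis=0)
    beta_std = std.mean(axis=0)
    sel_count = sel.sum(axis=0)
    sign_ok = np.full(len(features), np.nan)
    for j in range(len(features)):
        chosen = sel[:, j]
        if chosen.any():
            # reference sign pinned to +1 when the mean is exactly zero
            ref = np.sign(beta_std[j]) or 1.0
            sign_ok[j] = float((np.sign(std[chosen, j]) == ref).mean())
    table = pd.DataFrame(
        {
            "feature": features,
            "beta_raw": beta_raw,
            "beta_std": beta_std,
            "sd_raw": raw.std(axis=0, ddof=1),
            "selection_count": sel_count,
            "selection_fraction": sel_count / n,
            "sign_consistency": sign_ok,
        }
    )
    table = table.sort_values(
        by=["beta_std", "feature"],
        key=lambda s: -s.abs() if s.name == "beta_std" else s,
    ).reset_index(drop=True)
    return ImportanceTable(
        table=table, n_repeats=n,
        model_kind=subset[0].model_kind, feature_set=subset[0].feature_set,
    )


def select_score_size(
    importance: ImportanceTable,
    feature_frame: pd.DataFrame,
    labels: np.ndarray,
    k_max: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Pick the score size K_o by the significance curve.

    For each K the candidate score is the raw-weight sum of the top-K
    features (ranked by \\|beta_std\\|), evaluated on all patients (missing
    inputs filled with the cohort median); P_K is the two-sided
    Mann-Whitney P between responder groups.  Returns (K_o, curve) with
    K_o = argmin P_K, ties to the smallest K.  Degenerate (all-equal)
    scores get P = 1.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes")
    k_max = min(k_max, len(importance.table))
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    filled = feature_frame.fillna(feature_frame.median(numeric_only=True))
    rows = []
    for k in range(1, k_max + 1):
        top = importance.table.iloc[:k]
        score = np.zeros(len(filled))
        for _, t in top.iterrows():
            score = score + t["beta_raw"] * filled[t["feature"]].to_numpy(dtype=float)
        a, b = score[y == 1], score[y == 0]
        if np.allclose(score, score[0]):
            p = 1.0
        else:
            _, p = mann_whitney_u(a, b)
        rows.append({"K": k, "p_value": p})
    curve = pd.DataFrame(rows)
    k_o = int(curve.loc[curve["p_value"].idxmin(), "K"])  # idxmin = first min
    return k_o, curve


def sign_consistency_audit(
    results: Sequence[ModelRunResult], features: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-feature sign-consistency table across repeats.

    For each feature: the number of repeats in which it was selected and
    the fraction of those whose coefficient sign matches the sign of its
    mean coefficient (NaN when never selected).
    """
    if not results:
        raise ValidationError("results must be non-empty")
    imp = generalized_importance(results)
    table = imp.table
    if features is not None:
        unknown = set(features) - set(table["feature"])
        if unknown:
            raise ValidationError(f"unknown features {sorted(unknown)}")
        table = table[table["feature"].isin(features)]
        table = table.set_index("feature").loc[list(features)].reset_index()
    return table[["feature", "selection_count", "sign_consistency"]].copy()


def derive_score(
    cohort: pd.DataFrame,
    n_repeats: int = 100,
    master_seed: int = 0,
    model_kind: str = "ridge",
    feature_set: str = "clinical_early",
    k_max: int = 10,
    selection_p: float = 0.1,
    split: SplitConfig | None = None,
) -> tuple[ScoreDefinition, ImportanceTable, pd.DataFrame, list[ModelRunResult]]:
    """End-to-end score derivation on one cohort.

    Runs the repeated benchmark for a single (model, feature set) cell,
    averages coefficients, picks K_o from the significance curve and
    returns (definition, importance, P-value curve, per-repeat results).
    """
    config = BenchConfig(
        n_repeats=n_repeats, model_kinds=(model_kind,), feature_sets=(feature_set,),
        selection_p=selection_p, master_seed=master_seed,
        split=split or SplitConfig(),
    )
    _, results = run_benchmark(cohort, config)
    importance = generalized_importance(results, model_kind, feature_set)
    frame = assemble_features(cohort, feature_set)
    k_o, curve = select_score_size(
        importance, frame, labels_from_frame(cohort), k_max=k_max
    )
    top = importance.table.iloc[:k_o]
    terms = tuple(
        (str(t["feature"]), float(t["beta_raw"]))
        for _, t in top.iterrows() if t["beta_raw"] != 0.0
    )
    defn = ScoreDefinition(terms=terms, provenance="derived")
    return defn, importance, curve, results


# ---------------------------------------------------------------------------
# Predictor comparison and stratification
# ---------------------------------------------------------------------------

def _indicator_columns(df: pd.DataFrame) -> dict[str, pd.Series]:
    """Inflammatory/nutritional indicator series for a cohort table.

    PLR converts platelets (10^3/uL) to /uL before dividing; PNI exists
    only pre-treatment (no early albumin).  Division by a non-positive
    denominator yields NaN for that patient and the record is excluded
    from the indicator's ROC.
    """
    out: dict[str, pd.Series] = {}
    for epoch in ("pre", "early"):
        neut = df[f"{epoch}_neutrophil"]
        lymph = df[f"{epoch}_lymphocyte"].where(df[f"{epoch}_lymphocyte"] > 0)
        mono = df[f"{epoch}_monocyte"].where(df[f"{epoch}_monocyte"] > 0)
        plt = df[f"{epoch}_PLT"]
        out[f"{epoch}_NLR"] = neut / lymph
        out[f"{epoch}_PLR"] = plt * 1000.0 / lymph
        out[f"{epoch}_LMR"] = lymph / mono
    out["pre_PNI"] = 10.0 * df["pre_albumin"] + 0.005 * df["pre_lymphocyte"]
    return out


def compare_predictors(
    cohort: pd.DataFrame, score_defn: ScoreDefinition = PUBLISHED_RPS
) -> pd.DataFrame:
    """AUROC of every candidate predictor against the poor-responder label.

    Candidates: each single blood feature (both panels), the four
    pre-treatment and three early-treatment indicators, and the score.
    Predictors whose AUROC falls below 0.5 are re-reported as their
    negation with a ``-`` name prefix (a low value of, e.g., the
    lymphocyte-to-monocyte ratio predicts poor response).  Rows are
    sorted by AUROC descending.
    """
    y = labels_from_frame(cohort)
    predictors: dict[str, pd.Series] = {}
    from .features import EARLY_COLUMNS, PRE_COLUMNS  # local to avoid cycle noise

    for col in list(PRE_COLUMNS) + list(EARLY_COLUMNS):
        predictors[col] = cohort[col]
    predictors.update(_indicator_columns(cohort))
    predictors["RPS" if score_defn.provenance == "published" else "score"] = (
        score_frame(score_defn, cohort)
    )
    rows = []
    for name, series in predictors.items():
        v = series.to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 2 or len(np.unique(y[ok])) < 2:
            continue
        a = auroc(v[ok], y[ok])
        if a < 0.5:
            name, a = f"-{name}", 1.0 - a
        rows.append({"predictor": name, "auroc": a, "n_used": int(ok.sum())})
    return (
        pd.DataFrame(rows)
        .sort_values("auroc", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class StratificationReport:
    """Quartile-group outcome tables for a score.

    thresholds: (Q1, median, Q3) of the scores (linear-interpolation
    quantiles).  Groups: (-inf,Q1], (Q1,median], (median,Q3], (Q3,inf).
    ``trg_table``: group x TRG counts; ``rates``: per-group good-response
    and downstaging rates.
    """

    thresholds: tuple[float, float, float]
    group_sizes: np.ndarray
    trg_table: pd.DataFrame
    rates: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.rates.copy()
        out.insert(1, "n", self.group_sizes)
        return out


def stratify_quartiles(scores, outcomes: pd.DataFrame) -> StratificationReport:
    """Group patients by score quartiles and tabulate response outcomes.

    ``outcomes`` must carry trg, clinical_T/N, ypT/ypN.  Emits an
    empty-group warning (rather than failing) when heavy score ties leave
    a quartile group unpopulated.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 8:
        raise ValidationError("need at least 8 scores for quartile groups")
    if s.size != len(outcomes):
        raise ValidationError("scores and outcomes must align")
    q1, med, q3 = (float(np.quantile(s, q)) for q in (0.25, 0.5, 0.75))
    group = np.digitize(s, [q1, med, q3], right=True)  # 0..3
    sizes = np.array([(group == g).sum() for g in range(4)])
    if (sizes == 0).any():
        warnings.warn("tied scores left a quartile group empty", stacklevel=2)
    trg = outcomes["trg"].to_numpy()
    trg_table = pd.DataFrame(
        {f"TRG{t}": [((group == g) & (trg == t)).sum() for g in range(4)]
         for t in range(4)},
        index=[f"Q{g + 1}" for g in range(4)],
    )
    down = downstaging_frame(outcomes)
    good = (trg <= 1).astype(float)
    rows = []
    for g in range(4):
        mask = group == g
        denom = max(int(mask.sum()), 1)
        rows.append(
            {
                "group": f"Q{g + 1}",
                "good_response_rate": good[mask].mean() if mask.any() else np.nan,
                "overall_downstaging_rate": down.loc[mask, "overall"].mean()
                if mask.any() else np.nan,
                "t_downstaging_rate": down.loc[mask, "t_down"].mean()
                if mask.any() else np.nan,
                "n_downstaging_rate": down.loc[mask, "n_down"].mean()
                if mask.any() else np.nan,
                "_n": denom,
            }
        )
    rates = pd.DataFrame(rows).drop(columns="_n")
    return StratificationReport(
        thresholds=(q1, med, q3), group_sizes=sizes,
        trg_table=trg_table, rates=rates,
    )
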