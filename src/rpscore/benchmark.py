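"""Repeated model benchmark: split -> select -> fit -> evaluate, N times.

Each repeat draws a fresh MLM split (70/15/15 with 10% mutation by
default), runs univariate feature selection on the training rows only
(Mann-Whitney U for continuous features, Pearson chi-squared for
categorical ones, P < 0.1 retained), standardizes with training-set
center/scale, grid-searches each model family's hyperparameters on
tuning-set AUROC, and records AUROC/AUPRC on all three folds.  Feature
selection is skipped for the two small clinical-only feature sets and for
the lasso (its penalty selects) and neural-network (it extracts rather
than selects) families.

For linear families the standardized-scale coefficients are
back-transformed to raw units (beta_raw = beta_std / scale) and stored per
repeat; features that did not survive selection get coefficient 0 so that
across-repeat averages encode both magnitude and selection frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import Lasso, LogisticRegression, Ridge
from sklearn.neural_network import MLPClassifier

from .exceptions import ConfigurationError, FittingError, ValidationError
from .features import (
    CATEGORICAL_FEATURES,
    FEATURE_SET_NAMES,
    assemble_features,
    labels_from_frame,
)
from .metrics import auprc, auroc, chi_squared, mann_whitney_u, youden_cutpoint
from .splitting import SplitConfig, mlm_split, standardize

logger = logging.getLogger(__name__)

MODEL_KINDS: tuple[str, ...] = ("logistic", "ridge", "lasso", "gboost", "rforest", "nn2")
LINEAR_KINDS: frozenset[str] = frozenset({"logistic", "ridge", "lasso"})

#: Families that skip the univariate selection step.
NO_SELECTION_KINDS: frozenset[str] = frozenset({"lasso", "nn2"})
#: Feature sets small enough that selection is not applied.
NO_SELECTION_SETS: frozenset[str] = frozenset({"tumor_clinical", "clinical"})

# Grids run simple -> complex so that tuning-AUROC ties resolve to the
# less complex configuration (for penalized linear models, the stronger
# penalty).
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "logistic": [{}],
    "ridge": [{"alpha": a} for a in np.logspace(3, -3, 7)],
    "lasso": [{"alpha": a} for a in np.logspace(3, -3, 7)],
    "gboost": [
        {"n_estimators": ne, "max_depth": md, "learning_rate": lr}
        for ne in (50, 200) for md in (2, 3) for lr in (0.05, 0.1)
    ],
    "rforest": [
        {"n_estimators": ne, "max_depth": md}
        for ne in (200, 500) for md in (3, None)
    ],
    "nn2": [{"hidden_layer_sizes": (h,)} for h in (8, 16, 32)],
}


@dataclass(frozen=True)
class BenchConfig:
    """Benchmark settings (desk default: 100 repeats, linear models only)."""

    n_repeats: int = 100
    model_kinds: tuple[str, ...] = ("logistic", "ridge")
    feature_sets: tuple[str, ...] = FEATURE_SET_NAMES
    selection_p: float = 0.1
    master_seed: int = 0
    grids: dict[str, list[dict]] = field(default_factory=lambda: {})
    split: SplitConfig = field(default_factory=SplitConfig)
    #: Permutation-null mode: each repeat shuffles the label vector with
    #: its own seed before selection/fitting, making repeats independent
    #: draws from the "labels independent of features" null.  Used for
    #: calibration diagnostics.
    permute_labels: bool = False

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ConfigurationError(f"n_repeats must be >= 2, got {self.n_repeats}")
        if not 0.0 < self.selection_p < 1.0:
            raise ConfigurationError(
                f"selection_p must be in (0,1), got {self.selection_p}"
            )
        bad = set(self.model_kinds) - set(MODEL_KINDS)
        if bad:
            raise ConfigurationError(f"unknown model kinds {sorted(bad)}")
        bad = set(self.feature_sets) - set(FEATURE_SET_NAMES)
        if bad:
            raise ConfigurationError(f"unknown feature sets {sorted(bad)}")

    def grid_for(self, kind: str) -> list[dict]:
        return self.grids.get(kind, DEFAULT_GRIDS[kind])


@dataclass
class ModelRunResult:
    """One repeat's fitted-model summary for one (model, feature set) cell."""

    repeat_id: int
    model_kind: str
    feature_set: str
    selected_features: list[str]
    coefficients_raw: dict[str, float] | None
    coefficients_std: dict[str, float] | None
    hyperparams: dict
    metrics: dict[str, dict[str, float]]  # fold -> {"auroc":..,"auprc":..}
    cutpoint: tuple[float, float, float]  # threshold, sensitivity, specificity


def select_features(
    x_train: pd.DataFrame,
    y_train: np.ndarray,
    threshold: float = 0.1,
    categorical: frozenset[str] = CATEGORICAL_FEATURES,
) -> list[str]:
    """Univariate selection on training rows only; original order kept.

    Continuous features: two-sided Mann-Whitney U between label groups.
    Categorical features: Pearson chi-squared on the label x category
    contingency table (categories absent from the training rows are
    dropped; degenerate tables score P = 1).  Features with P < threshold
    survive.  May return an empty list; the caller decides the fallback.
    """
    y = np.asarray(y_train).astype(int)
    per_class = min((y == 0).sum(), (y == 1).sum())
    if per_class < 10:
        warnings.warn(
            f"fewer than 10 training rows in a class ({per_class}); "
            "selection P-values are unstable", stacklevel=2)
    kept: list[str] = []
    for col in x_train.columns:
        v = x_train[col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < 2 or len(np.unique(v[ok])) < 2:
            continue
        vv, yy = v[ok], y[ok]
        if col in categorical:
            cats = np.unique(vv)
            table = np.array(
                [[(vv[yy == g] == c).sum() for c in cats] for g in (0, 1)]
            )
            table = table[:, table.sum(axis=0) > 0]
            if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
                continue
            _, p = chi_squared(table)
        else:
            a, b = vv[yy == 0], vv[yy == 1]
            if a.size == 0 or b.size == 0:
                continue
            _, p = mann_whitney_u(a, b)
        if p < threshold:
            kept.append(col)
    return kept


class FittedModel:
    """A fitted predictor plus its preprocessing state.

    ``predict`` maps a raw-scale feature frame to a continuous
    poor-responder risk score.  For linear families the raw-scale and
    standardized-scale coefficients are exposed.
    """

    def __init__(self, kind, estimator, features, standardization, hyperparams):
        self.kind = kind
        self.estimator = estimator
        self.features = list(features)
        self.standardization = standardization
        self.hyperparams = dict(hyperparams)

    def _prepare(self, x: pd.DataFrame) -> np.ndarray:
        z = self.standardization.transform(x[self.features].to_numpy(dtype=float))
        return np.nan_to_num(z, nan=0.0)  # imputed at the training mean

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        z = self._prepare(x)
        if self.kind in ("ridge", "lasso"):
            return self.estimator.predict(z)
        return self.estimator.predict_proba(z)[:, 1]

    @property
    def coefficients_std(self) -> dict[str, float] | None:
        if self.kind not in LINEAR_KINDS:
            return None
        coef = np.ravel(self.estimator.coef_)
        return dict(zip(self.features, coef.astype(float)))

    @property
    def coefficients_raw(self) -> dict[str, float] | None:
        std = self.coefficients_std
        if std is None:
            return None
        return {
            f: c / s
            for (f, c), s in zip(std.items(), self.standardization.scale)
        }


def _make_estimator(kind: str, params: dict, seed: int):
    if kind == "logistic":
        # C=inf => unpenalized maximum-likelihood fit
        return LogisticRegression(C=np.inf, max_iter=2000, **params)
    if kind == "ridge":
        return Ridge(**params)
    if kind == "lasso":
        return Lasso(max_iter=5000, **params)
    if kind == "gboost":
        return GradientBoostingClassifier(random_state=seed, **params)
    if kind == "rforest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if kind == "nn2":
        return MLPClassifier(
            activation="logistic", early_stopping=True, max_iter=400,
            random_state=seed, **params)
    raise ConfigurationError(f"unknown model kind {kind!r}")


def fit_model(
    kind: str,
    x_train: pd.DataFrame,
    y_train: np.ndarray,
    x_tune: pd.DataFrame,
    y_tune: np.ndarray,
    grid: Sequence[dict] | None = None,
    seed: int = 0,
) -> FittedModel:
    """Grid-search one model family; selection criterion = tuning AUROC.

    Features are standardized with training-set center/scale (missing
    values imputed at the training mean after centering).  The grid is
    scanned in its given simple-to-complex order and ties keep the earlier
    (simpler) configuration.
    """
    y_train = np.asarray(y_train).astype(int)
    y_tune = np.asarray(y_tune).astype(int)
    if len(np.unique(y_train)) < 2:
        raise FittingError("training labels contain a single class")
    grid = list(grid) if grid is not None else DEFAULT_GRIDS[kind]
    features = list(x_train.columns)
    xt = x_train.to_numpy(dtype=float)
    # train-mean imputation before computing the standardization
    _, st = standardize(xt)
    best: FittedModel | None = None
    best_score = -np.inf
    for params in grid:
        est = _make_estimator(kind, params, seed)
        model = FittedModel(kind, est, features, st, params)
        zt = model._prepare(x_train)
        if kind in ("ridge", "lasso"):
            est.fit(zt, y_train.astype(float))
        else:
            est.fit(zt, y_train)
        try:
            score = auroc(model.predict(x_tune), y_tune)
        except Exception:  # degenerate tuning labels/scores
            score = 0.5
        if score > best_score:
            best, best_score = model, score
    assert best is not None
    return best


def run_benchmark(
    cohort: pd.DataFrame, config: BenchConfig | None = None
) -> tuple[pd.DataFrame, list[ModelRunResult]]:
    """Run the full repeated benchmark on a cohort table.

    Returns the aggregate table (mean and sd of AUROC/AUPRC per
    (model_kind, feature_set, fold) over repeats) and the per-repeat
    results.  Fully deterministic for a fixed ``config.master_seed``.
    Failed repeat-cells are logged and excluded; more than 10% failures
    aborts.
    """
    config = config or BenchConfig()
    labels = labels_from_frame(cohort)
    if len(np.unique(labels)) < 2:
        raise ValidationError("cohort must contain both responder classes")
    split_matrix = assemble_features(cohort, "clinical_pre_early").to_numpy()

    children = np.random.SeedSequence(config.master_seed).spawn(config.n_repeats)
    results: list[ModelRunResult] = []
    n_failed = 0
    n_cells = 0
    feature_frames = {fs: assemble_features(cohort, fs) for fs in config.feature_sets}
    for r, child in enumerate(children):
        ints = child.generate_state(3)
        rep_labels = labels
        if config.permute_labels:
            rep_labels = np.random.default_rng(int(ints[2])).permutation(labels)
        split_cfg = SplitConfig(
            fractions=config.split.fractions,
            mutation_rate=config.split.mutation_rate,
            seed=int(ints[0] % (2**31)),
            ks_init=config.split.ks_init,
            holdout_method=config.split.holdout_method,
        )
        assignment = mlm_split(split_matrix, split_cfg)
        fit_seed = int(ints[1] % (2**31))
        for fs in config.feature_sets:
            x = feature_frames[fs]
            for kind in config.model_kinds:
                n_cells += 1
                try:
                    results.append(
                        _run_cell(r, kind, fs, x, rep_labels, assignment, config, fit_seed)
                    )
                except Exception as exc:
                    n_failed += 1
                    logger.warning(
                        "repeat %d cell (%s, %s) failed: %s", r, kind, fs, exc
                    )
    if n_cells and n_failed > 0.1 * n_cells:
        raise FittingError(
            f"{n_failed}/{n_cells} benchmark cells failed; aborting"
        )
    return aggregate_results(results), results


def _run_cell(r, kind, fs, x, labels, assignment, config, fit_seed) -> ModelRunResult:
    tr, tu, va = assignment.train_idx, assignment.tune_idx, assignment.valid_idx
    x_tr = x.iloc[tr]
    y_tr, y_tu, y_va = labels[tr], labels[tu], labels[va]
    if kind in NO_SELECTION_KINDS or fs in NO_SELECTION_SETS:
        selected = list(x.columns)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected = select_features(x_tr, y_tr, config.selection_p)
        if not selected:  # fall back to the full set rather than fail
            logger.info("repeat %d (%s,%s): empty selection, using all features",
                        r, kind, fs)
            selected = list(x.columns)
    model = fit_model(
        kind, x_tr[selected], y_tr, x.iloc[tu][selected], y_tu,
        grid=config.grid_for(kind), seed=fit_seed,
    )
    metrics = {}
    for fold, idx, y in (("train", tr, y_tr), ("tune", tu, y_tu), ("valid", va, y_va)):
        s = model.predict(x.iloc[idx][selected])
        metrics[fold] = {"auroc": auroc(s, y), "auprc": auprc(s, y)}
    cut = youden_cutpoint(model.predict(x.iloc[va][selected]), y_va)

    coef_raw = coef_std = None
    if kind in LINEAR_KINDS:
        raw, std = model.coefficients_raw, model.coefficients_std
        coef_raw = {f: raw.get(f, 0.0) for f in x.columns}
        coef_std = {f: std.get(f, 0.0) for f in x.columns}
    return ModelRunResult(
        repeat_id=r, model_kind=kind, feature_set=fs,
        selected_features=selected, coefficients_raw=coef_raw,
        coefficients_std=coef_std, hyperparams=model.hyperparams,
        metrics=metrics, cutpoint=cut,
    )


def aggregate_results(results: list[ModelRunResult]) -> pd.DataFrame:
    """Mean and sd of AUROC/AUPRC per (model_kind, feature_set, fold)."""
    rows = []
    for res in results:
        for fold, m in res.metrics.items():
            rows.append(
                {"model_kind": res.model_kind, "feature_set": res.feature_set,
                 "fold": fold, **m}
            )
    if not rows:
        return pd.DataFrame(
            columns=["model_kind", "feature_set", "fold",
                     "auroc_mean", "auroc_sd", "auprc_mean", "auprc_sd", "n_repeats"]
        )
    df = pd.DataFrame(rows)
    agg = df.groupby(["model_kind", "feature_set", "fold"], sort=True).agg(
        auroc_mean=("auroc", "mean"), auroc_sd=("auroc", "std"),
        auprc_mean=("auprc", "mean"), auprc_sd=("auprc", "std"),
        n_repeats=("auroc", "size"),
    )
    return agg.reset_index()
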