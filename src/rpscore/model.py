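"""Model/Results facade over the score-derivation workflow.

:class:`ResponseScoreModel` bundles one cohort table with the derivation
settings (model family, feature set, number of repeats, split
configuration); ``fit()`` runs the repeated benchmark, coefficient
averaging and score-size selection and returns a
:class:`ResponseScoreResults` carrying the importance table (with
across-repeat dispersions and sign-consistency diagnostics), the derived
score definition, the significance curve and fold-wise performance, plus
``summary()``, prediction, comparison, stratification and plotting
helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .benchmark import LINEAR_KINDS, aggregate_results
from .cohort import read_cohort
from .exceptions import ValidationError
from .features import assemble_features, labels_from_frame
from .score import (
    ScoreDefinition,
    compare_predictors,
    derive_score,
    score_frame,
    stratify_quartiles,
)
from .splitting import SplitConfig

__all__ = ["ResponseScoreModel", "ResponseScoreResults"]


class ResponseScoreModel:
    """Specification of a score derivation on one cohort.

    Parameters
    ----------
    data
        Cohort table (see :mod:`rpscore.features` for the column layout).
    model_kind
        Linear family whose coefficients define the score (default
        ``"ridge"``).
    feature_set
        One of the five named feature sets (default ``"clinical_early"``).
    n_repeats
        Number of repeated splits averaged into the importance.
    k_max
        Largest score size considered by the significance curve.
    seed
        Master seed for the whole derivation.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        model_kind: str = "ridge",
        feature_set: str = "clinical_early",
        n_repeats: int = 100,
        k_max: int = 10,
        selection_p: float = 0.1,
        split: SplitConfig | None = None,
        seed: int = 0,
    ) -> None:
        if model_kind not in LINEAR_KINDS:
            raise ValidationError(
                f"score derivation needs a linear family, got {model_kind!r}"
            )
        assemble_features(data, feature_set)  # validates columns early
        labels_from_frame(data)
        self.data = data
        self.model_kind = model_kind
        self.feature_set = feature_set
        self.n_repeats = n_repeats
        self.k_max = k_max
        self.selection_p = selection_p
        self.split = split or SplitConfig()
        self.seed = seed

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ResponseScoreModel":
        """Build the model from a cohort CSV."""
        return cls(read_cohort(path), **kwargs)

    def fit(self) -> "ResponseScoreResults":
        """Run the derivation and return its results."""
        defn, importance, curve, results = derive_score(
            self.data,
            n_repeats=self.n_repeats,
            master_seed=self.seed,
            model_kind=self.model_kind,
            feature_set=self.feature_set,
            k_max=self.k_max,
            selection_p=self.selection_p,
            split=self.split,
        )
        return ResponseScoreResults(self, defn, importance, curve, results)


class ResponseScoreResults:
    """Fitted score derivation: estimates, diagnostics and reporting."""

    def __init__(self, model, score, importance, pvalue_curve, run_results):
        self.model = model
        self.score: ScoreDefinition = score
        self.importance = importance
        self.pvalue_curve = pvalue_curve
        self.run_results = run_results
        self.benchmark = aggregate_results(run_results)

    # -- estimates ------------------------------------------------------

    @property
    def k_o(self) -> int:
        return self.score.k_o

    @property
    def min_p(self) -> float:
        return float(self.pvalue_curve["p_value"].min())

    def predict(self, data: pd.DataFrame | None = None) -> pd.Series:
        """Score every patient of ``data`` (default: the training cohort)."""
        df = self.model.data if data is None else data
        return score_frame(self.score, df)

    def stratify(self, data: pd.DataFrame | None = None):
        """Quartile stratification of outcomes by the derived score."""
        df = self.model.data if data is None else data
        return stratify_quartiles(self.predict(df), df)

    def compare(self, data: pd.DataFrame | None = None) -> pd.DataFrame:
        """AUROC comparison of the score against single features and
        inflammatory/nutritional indicators."""
        df = self.model.data if data is None else data
        return compare_predictors(df, self.score)

    # -- reporting ------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        """Plain-text summary of the derivation."""
        m = self.model
        v = self.benchmark.query("fold == 'valid'").iloc[0]
        lines = [
            "Response score derivation",
            "=" * 60,
            f"model family:    {m.model_kind}    feature set: {m.feature_set}",
            f"repeats:         {len({r.repeat_id for r in self.run_results})}"
            f"    cohort n: {len(m.data)}    seed: {m.seed}",
            f"validation AUROC {v['auroc_mean']:.4f} +/- {v['auroc_sd']:.4f}"
            f"    AUPRC {v['auprc_mean']:.4f} +/- {v['auprc_sd']:.4f}",
            f"score size K_o:  {self.k_o}    min Mann-Whitney P: {self.min_p:.3e}",
            "",
            f"top {top} features by |standardized mean coefficient|:",
            f"{'feature':<24}{'beta_raw':>12}{'beta_std':>10}"
            f"{'sel%':>7}{'sign%':>7}",
            "-" * 60,
        ]
        for _, t in self.importance.table.head(top).iterrows():
            sign = t["sign_consistency"]
            lines.append(
                f"{t['feature']:<24}{t['beta_raw']:>12.6f}{t['beta_std']:>10.4f}"
                f"{100 * t['selection_fraction']:>6.0f}%"
                f"{('   n/a' if np.isnan(sign) else f'{100 * sign:>6.0f}%')}"
            )
        lines += ["", "derived score (raw-scale weights):"]
        for f, w in self.score.terms:
            lines.append(f"  {w:+.6f} x {f}")
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------

    def plot_pvalue_curve(self, ax=None):
        """Significance curve P_K vs score size K (log-scaled P)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.pvalue_curve["K"], self.pvalue_curve["p_value"], "o-")
        ax.axvline(self.k_o, color="grey", ls="--", lw=1)
        ax.set_yscale("log")
        ax.set_xlabel("number of score features K")
        ax.set_ylabel("Mann-Whitney P (score vs label)")
        return ax

    def plot_sign_consistency(self, top: int = 10, ax=None):
        """Bar chart of per-feature coefficient sign consistency."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.importance.table.head(top)
        ax.barh(t["feature"][::-1], t["sign_consistency"][::-1])
        ax.set_xlim(0, 1)
        ax.set_xlabel("fraction of repeats with consistent coefficient sign")
        return ax
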