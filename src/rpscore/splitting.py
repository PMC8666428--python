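"""Representative data splitting: Kennard-Stone and its mutated variant.

Random train/test splits on small clinical cohorts can leave the training
set unrepresentative of the full feature space.  The Kennard-Stone (KS)
algorithm instead selects training samples greedily so each new pick is as
far as possible (max-min Euclidean distance on standardized features) from
everything already selected, covering the sample space uniformly.  The
Morais-Lima-Martin (MLM) variant restores some randomness by mutating the
KS result: a fixed fraction of KS-chosen training samples is swapped 1-for-1
with randomly chosen held-out samples.

This module produces three-way training/tuning/validation partitions
(default 70/15/15 with a 10% mutation rate).  The 30% held-out remainder is
itself divided by a second KS pass so that both held-out sets are
representative; a purely random division is available via
``SplitConfig.holdout_method``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import ConfigurationError, ValidationError

__all__ = ["SplitConfig", "SplitAssignment", "Standardization", "standardize",
           "kennard_stone", "mlm_split"]


@dataclass(frozen=True)
class SplitConfig:
    """Parameters of the MLM three-way split.

    fractions: (train, tune, valid), positive, summing to 1.
    mutation_rate: fraction of KS-chosen training rows swapped with
        held-out rows; in [0, 0.5).
    seed: seeds the mutation draw (and the random holdout division when
        selected).
    ks_init: ``"farthest_pair"`` (classic KS: start from the two mutually
        farthest samples) or ``"max_mean"`` (start from the single sample
        with the largest mean distance to all others).
    holdout_method: ``"ks"`` or ``"random"`` division of the non-training
        pool into tuning and validation.
    """

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    mutation_rate: float = 0.10
    seed: int = 0
    ks_init: str = "farthest_pair"
    holdout_method: str = "ks"

    def __post_init__(self) -> None:
        f = self.fractions
        if len(f) != 3 or any(x <= 0 for x in f):
            raise ConfigurationError(f"fractions must be three positive numbers, got {f}")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ConfigurationError(f"fractions must sum to 1 within 1e-9, got {sum(f)}")
        if not 0.0 <= self.mutation_rate < 0.5:
            raise ConfigurationError(
                f"mutation_rate must be in [0, 0.5), got {self.mutation_rate}"
            )
        if self.ks_init not in ("farthest_pair", "max_mean"):
            raise ConfigurationError(f"unknown ks_init {self.ks_init!r}")
        if self.holdout_method not in ("ks", "random"):
            raise ConfigurationError(f"unknown holdout_method {self.holdout_method!r}")


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint, exhaustive train/tune/valid row-index partition."""

    train_idx: np.ndarray
    tune_idx: np.ndarray
    valid_idx: np.ndarray
    n_swapped: int = 0

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in
                 (self.train_idx, self.tune_idx, self.valid_idx)]
        allidx = np.concatenate(parts)
        n = allidx.size
        if len(np.unique(allidx)) != n or set(allidx.tolist()) != set(range(n)):
            raise ValidationError("split must partition 0..n-1 exactly once")

    @property
    def n(self) -> int:
        return self.train_idx.size + self.tune_idx.size + self.valid_idx.size

    def fold_of(self) -> np.ndarray:
        """Per-row fold name array ('train'/'tune'/'valid')."""
        out = np.empty(self.n, dtype=object)
        out[self.train_idx] = "train"
        out[self.tune_idx] = "tune"
        out[self.valid_idx] = "valid"
        return out


@dataclass(frozen=True)
class Standardization:
    """Per-column center/scale; population (ddof=0) convention.

    Zero-variance columns keep scale 1 and are flagged in
    ``zero_variance``.
    """

    center: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def transform(self, matrix) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.center) / self.scale

    def inverse(self, matrix) -> np.ndarray:
        return np.asarray(matrix, dtype=float) * self.scale + self.center


def standardize(matrix) -> tuple[np.ndarray, Standardization]:
    """Center and scale columns to mean 0 / sd 1 (population sd).

    Returns the transformed matrix and the fitted transform.  Columns with
    zero variance are centered but left unscaled (scale 1) and flagged.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("matrix must be 2-D with at least 2 rows")
    if np.isnan(x).all(axis=0).any():
        raise ValidationError("matrix has an all-missing column")
    center = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)  # ddof=0
    zero = sd == 0
    scale = np.where(zero, 1.0, sd)
    st = Standardization(center=center, scale=scale, zero_variance=zero)
    return st.transform(x), st


def kennard_stone(matrix, n_select: int, init: str = "farthest_pair") -> list[int]:
    """Greedy max-min representative selection.

    Starting from the two mutually farthest rows (classic KS; or from the
    row of maximal mean distance with ``init="max_mean"``), repeatedly adds
    the row whose minimum Euclidean distance to the already-selected rows
    is largest.  Deterministic: ties break toward the lowest row index.
    Returns indices in selection order.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if not 1 <= n_select <= n:
        raise ValidationError(f"n_select must be in [1, {n}], got {n_select}")
    dist = squareform(pdist(x))
    if init == "farthest_pair":
        # argmax scans row-major, so the first hit is the lexicographically
        # smallest (i, j) pair among ties
        i, j = np.unravel_index(np.argmax(dist), dist.shape)
        i, j = int(min(i, j)), int(max(i, j))
        selected = [i] if n_select == 1 else [i, j]
    elif init == "max_mean":
        selected = [int(np.argmax(dist.mean(axis=0)))]
    else:
        raise ValidationError(f"unknown init {init!r}")
    min_dist = dist[:, selected].min(axis=1)
    while len(selected) < n_select:
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))  # first max = lowest index on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[:, nxt])
    return selected


def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Rounded (train, tune, valid) sizes; valid takes the remainder."""
    n_train = int(np.rint(fractions[0] * n))
    n_tune = int(np.rint(fractions[1] * n))
    n_valid = n - n_train - n_tune
    if min(n_train, n_tune, n_valid) < 1:
        raise ValidationError(
            f"fractions {fractions} infeasible for n={n}: a fold would be empty"
        )
    return n_train, n_tune, n_valid


def mlm_split(matrix, config: SplitConfig | None = None) -> SplitAssignment:
    """MLM three-way split: KS training selection, mutation, KS holdout pass.

    1. Standardize the matrix and KS-select ``round(train_fraction * n)``
       training rows.
    2. Mutate: ``m = round(mutation_rate * n_train)`` training rows, chosen
       uniformly at random (seeded), swap membership 1-for-1 with ``m``
       uniformly chosen held-out rows.
    3. Divide the held-out pool into tuning and validation with a second
       KS pass over the pool (tuning = KS-selected rows), or uniformly at
       random with ``holdout_method="random"``.

    Fully reproducible from ``config.seed``.
    """
    config = config or SplitConfig()
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 10:
        raise ValidationError(f"need at least 10 rows to split, got {n}")
    n_train, n_tune, n_valid = split_sizes(n, config.fractions)
    z, _ = standardize(np.where(np.isnan(x), np.nanmean(x, axis=0), x))

    train = np.array(kennard_stone(z, n_train, init=config.ks_init), dtype=int)
    pool = np.setdiff1d(np.arange(n), train)

    rng = np.random.default_rng(config.seed)
    m = int(np.rint(config.mutation_rate * n_train))
    if m > 0:
        out_rows = rng.choice(train, size=m, replace=False)
        in_rows = rng.choice(pool, size=m, replace=False)
        train = np.sort(np.concatenate([np.setdiff1d(train, out_rows), in_rows]))
        pool = np.setdiff1d(np.arange(n), train)
    else:
        train = np.sort(train)

    if config.holdout_method == "ks":
        tune_local = kennard_stone(z[pool], n_tune, init=config.ks_init)
        tune = np.sort(pool[np.asarray(tune_local, dtype=int)])
    else:
        tune = np.sort(rng.choice(pool, size=n_tune, replace=False))
    valid = np.setdiff1d(pool, tune)
    return SplitAssignment(train_idx=train, tune_idx=tune, valid_idx=valid, n_swapped=m)
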