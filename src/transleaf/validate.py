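"""Error metrics and cross-validation schemes.

Four error metrics are computed on the kilogram scale from observed
(``a``) / predicted (``p``) pairs:

* MPE  = mean((p - a) / a) * 100        (signed; positive = overestimation)
* MAE  = mean(|p - a|)                  (kg)
* MAPE = mean(|p - a| / a) * 100
* MAAPE = mean(arctan(|p - a| / a))     (radians by default)

The printed MAAPE formula carries a "x100" factor, but all published
MAAPE values (0.38-0.52) are consistent with the plain mean arctangent
in radians; radians is therefore the default, with ``times_100=True``
available.

Three cross-validation schemes share one contract: every record is held
out exactly once, held-out predictions are Baskerville-corrected with
the *training-fold* residual variance, and pooled metrics are computed
over the union of held-out pairs (tree-weighted), alongside per-fold /
per-species / per-group metric sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from .data_io import TreeRecord
from .design import JoinedItem, ModelSpec, build_design, _as_pairs
from .fit import fit_ols
from .predict import predict_leaf_mass

__all__ = [
    "MetricError",
    "CVError",
    "CrownClassCoverageError",
    "PredictionSet",
    "MetricSet",
    "CVResult",
    "compute_metrics",
    "kfold_cv",
    "loso_cv",
    "logo_cv",
    "error_distribution",
    "ErrorDistribution",
]


class MetricError(ValueError):
    pass


class CVError(ValueError):
    pass


class CrownClassCoverageError(CVError):
    """A training fold lacks a crown-class level present in its test fold."""


@dataclass
class PredictionSet:
    """Observed/predicted mass pairs with optional species/unit labels."""

    observed: np.ndarray
    predicted: np.ndarray
    species: np.ndarray | None = None
    labels: np.ndarray | None = None  # fold or group label per pair

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed.shape != self.predicted.shape or self.observed.ndim != 1:
            raise MetricError("observed and predicted must be 1-D arrays of equal length")
        if self.observed.size == 0:
            raise MetricError("empty prediction set")
        if np.any(~np.isfinite(self.observed)) or np.any(self.observed <= 0):
            raise MetricError("observed masses must be finite and > 0")
        if np.any(~np.isfinite(self.predicted)) or np.any(self.predicted <= 0):
            raise MetricError("predicted masses must be finite and > 0")

    @property
    def n(self) -> int:
        return int(self.observed.size)

    def subset(self, mask: np.ndarray) -> "PredictionSet":
        return PredictionSet(
            observed=self.observed[mask],
            predicted=self.predicted[mask],
            species=None if self.species is None else self.species[mask],
            labels=None if self.labels is None else self.labels[mask],
        )


@dataclass(frozen=True)
class MetricSet:
    """The four error metrics plus signed mean error (kg) and n."""

    mpe: float
    mae: float
    mape: float
    maape: float
    n: int
    me: float  # mean (p - a), kg; same overestimation-positive sign as MPE

    def to_dict(self) -> dict:
        return {"mpe": self.mpe, "mae": self.mae, "mape": self.mape,
                "maape": self.maape, "me": self.me, "n": self.n}


def compute_metrics(preds: PredictionSet, maape_times_100: bool = False) -> MetricSet:
    """Compute MPE / MAE / MAPE / MAAPE (and mean error) for a set of pairs."""
    a, p = preds.observed, preds.predicted
    rel = (p - a) / a
    maape = float(np.mean(np.arctan(np.abs(rel))))
    if maape_times_100:
        maape *= 100.0
    return MetricSet(
        mpe=float(np.mean(rel) * 100.0),
        mae=float(np.mean(np.abs(p - a))),
        mape=float(np.mean(np.abs(rel)) * 100.0),
        maape=maape,
        n=preds.n,
        me=float(np.mean(p - a)),
    )


@dataclass
class CVResult:
    """Held-out predictions and metrics for one cross-validation run."""

    scheme: str  # kfold | loso | logo
    per_unit: dict[str, MetricSet]
    pooled: MetricSet
    predictions: PredictionSet
    seed: int | None = None
    group_field: str | None = None

    def to_dict(self, include_pairs: bool = False) -> dict:
        d = {
            "scheme": self.scheme,
            "seed": self.seed,
            "group_field": self.group_field,
            "pooled": self.pooled.to_dict(),
            "per_unit": {k: v.to_dict() for k, v in self.per_unit.items()},
        }
        if include_pairs:
            d["pairs"] = {
                "observed": self.predictions.observed.tolist(),
                "predicted": self.predictions.predicted.tolist(),
                "labels": None if self.predictions.labels is None
                else [str(x) for x in self.predictions.labels],
            }
        return d


def _records(joined: Sequence[JoinedItem]) -> list[TreeRecord]:
    return [t for t, _ in _as_pairs(joined)]


def _check_response(joined: Sequence[JoinedItem]) -> np.ndarray:
    masses = []
    for t in _records(joined):
        if t.leaf_mass is None:
            raise CVError(f"tree {t.tree_id} has no observed leaf mass; cannot cross-validate")
        masses.append(t.leaf_mass)
    return np.array(masses, dtype=float)


def _check_cc_coverage(train, test, unit: str, spec: ModelSpec) -> None:
    if spec.intercept_mode != "crown_class":
        return
    train_levels = {t.cc for t in _records(train)}
    test_levels = {t.cc for t in _records(test)}
    missing = test_levels - train_levels
    if missing:
        raise CrownClassCoverageError(
            f"training set for {unit} lacks crown class(es) "
            f"{sorted(c.value for c in missing)} present in its test set; "
            "stratify folds by crown class or use fewer/larger folds"
        )


def _held_out_eval(train, test, spec: ModelSpec, sigma2_mode: str) -> np.ndarray:
    model = fit_ols(build_design(train, spec), sigma2_mode=sigma2_mode)
    return predict_leaf_mass(model, test, correct=True)


def _assemble(scheme, unit_order, unit_masks, observed, predicted, species,
              labels, seed=None, group_field=None) -> CVResult:
    preds = PredictionSet(observed=observed, predicted=predicted,
                          species=species, labels=labels)
    per_unit = {u: compute_metrics(preds.subset(m)) for u, m in zip(unit_order, unit_masks)}
    return CVResult(scheme=scheme, per_unit=per_unit, pooled=compute_metrics(preds),
                    predictions=preds, seed=seed, group_field=group_field)


def kfold_cv(
    joined: Sequence[JoinedItem],
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    stratify_by_cc: bool = False,
    sigma2_mode: str = "unbiased",
) -> CVResult:
    """Random k-fold cross-validation, bitwise reproducible per seed.

    Records are randomly permuted and cut into k near-equal contiguous
    blocks (optionally dealt per crown class when ``stratify_by_cc``).
    """
    n = len(joined)
    if k < 2:
        raise CVError("k must be >= 2")
    if k > n:
        raise CVError(f"k = {k} exceeds the number of records n = {n}")
    observed_all = _check_response(joined)

    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if stratify_by_cc:
        recs = _records(joined)
        for cc in {t.cc for t in recs}:
            idx = np.array([i for i, t in enumerate(recs) if t.cc == cc])
            idx = rng.permutation(idx)
            for pos, i in enumerate(idx):
                fold_of[i] = pos % k
    else:
        perm = rng.permutation(n)
        for f, block in enumerate(np.array_split(perm, k)):
            fold_of[block] = f

    observed = np.empty(n)
    predicted = np.empty(n)
    species = np.array([t.species for t in _records(joined)], dtype=object)
    labels = np.array([f"fold_{f}" for f in fold_of], dtype=object)
    unit_masks = []
    unit_order = []
    for f in range(k):
        test_mask = fold_of == f
        test = [joined[i] for i in np.flatnonzero(test_mask)]
        train = [joined[i] for i in np.flatnonzero(~test_mask)]
        _check_cc_coverage(train, test, f"fold {f}", spec)
        predicted[test_mask] = _held_out_eval(train, test, spec, sigma2_mode)
        observed[test_mask] = observed_all[test_mask]
        unit_masks.append(test_mask)
        unit_order.append(f"fold_{f}")

    return _assemble("kfold", unit_order, unit_masks, observed, predicted,
                     species, labels, seed=seed)


def logo_cv(
    joined: Sequence[JoinedItem],
    spec: ModelSpec,
    group_field: str = "study_id",
    sigma2_mode: str = "unbiased",
) -> CVResult:
    """Leave-one-group-out CV over an arbitrary record field.

    ``group_field="species"`` reproduces leave-one-species-out exactly.
    Fully deterministic (no randomness).
    """
    recs = _records(joined)
    observed_all = _check_response(joined)
    labels_list = []
    for t in recs:
        v = getattr(t, group_field, None)
        if v is None:
            raise CVError(f"tree {t.tree_id} has no {group_field!r} label")
        labels_list.append(str(v))
    labels = np.array(labels_list, dtype=object)
    groups = sorted(set(labels_list))
    if len(groups) < 2:
        raise CVError(f"need >= 2 distinct {group_field!r} labels, got {len(groups)}")

    n = len(joined)
    observed = np.empty(n)
    predicted = np.empty(n)
    species = np.array([t.species for t in recs], dtype=object)
    unit_masks = []
    for g in groups:
        mask = labels == g
        test = [joined[i] for i in np.flatnonzero(mask)]
        train = [joined[i] for i in np.flatnonzero(~mask)]
        _check_cc_coverage(train, test, f"{group_field} {g!r}", spec)
        predicted[mask] = _held_out_eval(train, test, spec, sigma2_mode)
        observed[mask] = observed_all[mask]
        unit_masks.append(mask)

    scheme = "loso" if group_field == "species" else "logo"
    return _assemble(scheme, groups, unit_masks, observed, predicted,
                     species, labels, group_field=group_field)


def loso_cv(
    joined: Sequence[JoinedItem],
    spec: ModelSpec,
    sigma2_mode: str = "unbiased",
) -> CVResult:
    """Leave-one-species-out CV: refit excluding each species, predict its
    trees from published traits; per-species and pooled metrics."""
    return logo_cv(joined, spec, group_field="species", sigma2_mode=sigma2_mode)


@dataclass(frozen=True)
class ErrorDistribution:
    """Per-tree percentage errors with summary statistics (reported, not
    asserted: right-skew shows as mean > median)."""

    errors_pct: np.ndarray
    median: float
    mean: float
    skewness: float


def error_distribution(preds: PredictionSet) -> ErrorDistribution:
    """Per-tree (p - a)/a * 100 values and their summary."""
    errs = (preds.predicted - preds.observed) / preds.observed * 100.0
    return ErrorDistribution(
        errors_pct=errs,
        median=float(np.median(errs)),
        mean=float(np.mean(errs)),
        skewness=float(scipy.stats.skew(errs)) if errs.size > 2 else math.nan,
    )
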