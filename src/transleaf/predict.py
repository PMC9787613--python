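"""Back-transformed leaf-mass prediction in kilograms.

Predictions are ``exp(linear predictor)`` optionally multiplied by the
Baskerville lognormal bias-correction factor ``exp(sigma2 / 2)``.
Packaged published coefficient sets for the six equations are available
via :func:`published_model`; since the source table prints no residual
variance, each packaged set carries ``sigma2 = (published log-scale
RMSE)**2`` as a documented proxy so corrected prediction works out of
the box.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Protocol, Sequence, Union

import numpy as np

from .design import JoinedItem, ModelSpec, build_design
from .fit import FittedModel

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionError",
    "CoefficientSet",
    "baskerville_cf",
    "predict_leaf_mass",
    "published_model",
    "extrapolation_flags",
    "CALIBRATION_DBH_RANGE",
]

#: DBH range (cm) of the calibration data; outside it predictions are
#: extrapolations and trigger a logged warning, never an error.
CALIBRATION_DBH_RANGE = (3.05, 114.05)


class PredictionError(ValueError):
    pass


class LinearPredictor(Protocol):
    spec: ModelSpec
    coefficients: dict[str, float]
    sigma2: float | None


@dataclass(frozen=True)
class CoefficientSet:
    """An immutable named coefficient vector usable for prediction."""

    spec: ModelSpec
    coefficients: dict[str, float]
    sigma2: float | None = None
    standard_errors: dict[str, float] | None = None
    source: str = "fitted"

    def with_coefficients(self, **updates: float) -> "CoefficientSet":
        coefs = dict(self.coefficients)
        unknown = set(updates) - set(coefs)
        if unknown:
            raise PredictionError(f"unknown coefficient name(s): {sorted(unknown)}")
        coefs.update(updates)
        return CoefficientSet(spec=self.spec, coefficients=coefs, sigma2=self.sigma2,
                              standard_errors=self.standard_errors, source="custom")


@lru_cache(maxsize=1)
def _published_table() -> dict:
    ref = resources.files("transleaf.data") / "published_coefficients.json"
    return json.loads(ref.read_text(encoding="utf-8"))


def published_model(eq_id: str) -> CoefficientSet:
    """The packaged published coefficient set for ``eq1`` .. ``eq6``."""
    table = _published_table()
    if eq_id not in table:
        raise PredictionError(f"unknown published model {eq_id!r} (expected eq1..eq6)")
    entry = table[eq_id]
    spec = ModelSpec.equation(eq_id)
    rmse = float(entry["fit_reference"]["rmse"])
    return CoefficientSet(
        spec=spec,
        coefficients={k: float(v) for k, v in entry["coefficients"].items()},
        standard_errors={k: float(v) for k, v in entry["standard_errors"].items()},
        sigma2=rmse ** 2,
        source=f"table3_{eq_id}",
    )


def published_fit_reference(eq_id: str) -> dict:
    """Published fit statistics (adjusted R2, RMSE, AIC) for an equation."""
    table = _published_table()
    if eq_id not in table:
        raise PredictionError(f"unknown published model {eq_id!r}")
    return dict(table[eq_id]["fit_reference"])


def baskerville_cf(sigma2: float) -> float:
    """Multiplicative lognormal back-transform correction, exp(sigma2/2)."""
    if not math.isfinite(sigma2) or sigma2 < 0:
        raise PredictionError(f"sigma2 must be finite and >= 0, got {sigma2!r}")
    return math.exp(sigma2 / 2.0)


def _model_parts(model: Union[FittedModel, CoefficientSet]):
    if isinstance(model, (FittedModel, CoefficientSet)):
        return model.spec, model.coefficients, model.sigma2
    raise PredictionError(f"cannot predict from {type(model).__name__}")


def predict_leaf_mass(
    model: Union[FittedModel, CoefficientSet],
    joined: Sequence[JoinedItem],
    correct: bool = True,
) -> np.ndarray:
    """Per-tree predicted dry leaf mass (kg), strictly positive.

    ``correct=True`` multiplies by the Baskerville factor computed from
    the model's ``sigma2``.  A crown class absent from the model's
    coefficient set is an error (never an extrapolated average); DBH
    outside the calibration range only logs an extrapolation warning.
    """
    spec, coefs, sigma2 = _model_parts(model)
    design = build_design(joined, spec, require_response=False)

    beta = np.empty(len(design.columns))
    for j, col in enumerate(design.columns):
        if col not in coefs:
            if col.startswith("cc_"):
                raise PredictionError(
                    f"crown class {col[3:]!r} was not seen at fit time; "
                    "no intercept is available for it"
                )
            raise PredictionError(f"model has no coefficient for design column {col!r}")
        beta[j] = coefs[col]

    n_extrap = int(np.sum(extrapolation_flags(joined)))
    if n_extrap:
        logger.warning(
            "%d tree(s) have DBH outside the calibration range %s cm; "
            "predictions are extrapolations", n_extrap, CALIBRATION_DBH_RANGE,
        )

    lp = design.X @ beta
    cf = 1.0
    if correct:
        if sigma2 is None:
            raise PredictionError(
                "corrected back-transformation requires the model to carry sigma2"
            )
        cf = baskerville_cf(sigma2)
    return np.exp(lp) * cf


def extrapolation_flags(joined: Sequence[JoinedItem]) -> np.ndarray:
    """Boolean flag per tree: DBH outside the calibration range."""
    lo, hi = CALIBRATION_DBH_RANGE
    dbhs = np.array(
        [it.dbh if not isinstance(it, tuple) else it[0].dbh for it in joined]
    )
    return (dbhs < lo) | (dbhs > hi)
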