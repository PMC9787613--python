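"""Ordinary least squares on the log scale, fit statistics, backward
stepwise AIC selection and (generalized) variance-inflation screening."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import scipy.linalg

from .design import DesignMatrix, JoinedItem, ModelSpec, build_design

__all__ = [
    "FitError",
    "RankDeficiencyError",
    "FittedModel",
    "fit_ols",
    "model_stats",
    "backward_stepwise",
    "vif",
]


class FitError(ValueError):
    pass


class RankDeficiencyError(FitError):
    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear column(s): {self.columns}")


@dataclass
class FittedModel:
    """OLS fit of ln(leaf mass) with named coefficients.

    ``sigma2`` is the residual variance used by the back-transform
    correction.  By default it is the unbiased mean squared residual
    RSS/(n-k); ``sigma2_mode="ml"`` switches to RSS/n.
    """

    spec: ModelSpec
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    sigma2: float
    n: int
    k: int
    rss: float
    tss: float
    columns: list[str]
    sigma2_mode: str = "unbiased"
    fit_stats: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "spec": {
                "eq_id": self.spec.eq_id,
                "terms": list(self.spec.terms),
                "intercept_mode": self.spec.intercept_mode,
                "mat_offset": self.spec.mat_offset,
            },
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "sigma2": self.sigma2,
            "sigma2_mode": self.sigma2_mode,
            "n": self.n,
            "k": self.k,
            "rss": self.rss,
            "tss": self.tss,
            "columns": self.columns,
            "fit_stats": self.fit_stats,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        spec = ModelSpec(
            eq_id=d["spec"]["eq_id"],
            terms=tuple(d["spec"]["terms"]),
            intercept_mode=d["spec"]["intercept_mode"],
            mat_offset=d["spec"]["mat_offset"],
        )
        return cls(
            spec=spec,
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            standard_errors={k: float(v) for k, v in d["standard_errors"].items()},
            sigma2=float(d["sigma2"]),
            sigma2_mode=d.get("sigma2_mode", "unbiased"),
            n=int(d["n"]),
            k=int(d["k"]),
            rss=float(d["rss"]),
            tss=float(d["tss"]),
            columns=list(d["columns"]),
            fit_stats={k: float(v) for k, v in d.get("fit_stats", {}).items()},
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FittedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _collinear_columns(X: np.ndarray, columns: Sequence[str]) -> list[str]:
    # QR with pivoting: trailing pivots with ~zero R diagonal are redundant.
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [columns[j] for j in sorted(piv[rank:])]


def fit_ols(design: DesignMatrix, sigma2_mode: str = "unbiased") -> FittedModel:
    """Least-squares fit of a built design matrix.

    Coefficient standard errors use the unbiased residual variance
    RSS/(n-k) regardless of ``sigma2_mode``, which only selects the
    residual-variance convention stored as ``sigma2`` for the
    back-transform correction.
    """
    if design.y is None:
        raise FitError("design has no response; build with require_response=True")
    if sigma2_mode not in ("unbiased", "ml"):
        raise FitError("sigma2_mode must be 'unbiased' or 'ml'")
    X, y = design.X, design.y
    n, k = X.shape
    if n <= k:
        raise FitError(f"n = {n} rows <= k = {k} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise RankDeficiencyError(_collinear_columns(X, design.columns))

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    ybar = float(y.mean())
    tss = float(((y - ybar) ** 2).sum())

    s2_unbiased = rss / (n - k)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv), 0.0, None) * s2_unbiased)

    model = FittedModel(
        spec=design.spec,
        coefficients={c: float(b) for c, b in zip(design.columns, beta)},
        standard_errors={c: float(s) for c, s in zip(design.columns, se)},
        sigma2=s2_unbiased if sigma2_mode == "unbiased" else rss / n,
        sigma2_mode=sigma2_mode,
        n=n,
        k=k,
        rss=rss,
        tss=tss,
        columns=list(design.columns),
    )
    model.fit_stats = model_stats(model)
    return model


def model_stats(m: FittedModel) -> dict[str, float]:
    """Fit statistics of a log-scale OLS fit.

    AIC uses the full Gaussian log-likelihood and counts the residual
    variance as a parameter: AIC = -2 lnL + 2 (k + 1).  Published AIC
    values may differ by a data-independent constant (software
    convention); AIC *differences* between specs on the same data are
    convention-free.
    """
    n, k, rss, tss = m.n, m.k, m.rss, m.tss
    if rss <= 0.0:
        loglik = math.inf
        aic = -math.inf
        adj_r2, r2, rmse = 1.0, 1.0, 0.0
    else:
        loglik = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
        aic = -2.0 * loglik + 2.0 * (k + 1)
        r2 = 1.0 - rss / tss if tss > 0 else math.nan
        adj_r2 = 1.0 - (rss / (n - k)) / (tss / (n - 1)) if tss > 0 else math.nan
        rmse = math.sqrt(rss / (n - k))
    return {"adj_r2": adj_r2, "r2": r2, "rmse": rmse, "aic": aic, "log_likelihood": loglik}


def backward_stepwise(
    joined: Sequence[JoinedItem],
    full_spec: ModelSpec,
    sigma2_mode: str = "unbiased",
) -> tuple[ModelSpec, list[tuple[ModelSpec, float]]]:
    """Backward stepwise selection by AIC.

    At each iteration the single term whose removal most decreases AIC is
    dropped; the process stops when no removal decreases AIC.  The
    intercept block is structural and never a removal candidate, and the
    model always keeps at least one term.  Ties are broken toward the
    term listed later in spec order.  The trace records every candidate
    evaluation as ``(spec, aic)``, starting with the full model.
    """
    current = full_spec
    current_fit = fit_ols(build_design(joined, current), sigma2_mode=sigma2_mode)
    current_aic = current_fit.fit_stats["aic"]
    trace: list[tuple[ModelSpec, float]] = [(current, current_aic)]

    while len(current.terms) >= 2:
        best_term: str | None = None
        best_spec: ModelSpec | None = None
        best_aic = math.inf
        for term in current.terms:  # spec order; <= prefers later-listed on ties
            cand = current.drop(term)
            cand_fit = fit_ols(build_design(joined, cand), sigma2_mode=sigma2_mode)
            cand_aic = cand_fit.fit_stats["aic"]
            trace.append((cand, cand_aic))
            if cand_aic <= best_aic:
                best_term, best_spec, best_aic = term, cand, cand_aic
        if best_spec is not None and best_aic < current_aic:
            current, current_aic = best_spec, best_aic
        else:
            break
    return current, trace


def vif(joined: Sequence[JoinedItem], spec: ModelSpec) -> dict[str, float]:
    """Generalized variance inflation factors for a model spec.

    The cell-means intercept block is re-expressed as a global constant
    plus reference-level indicators so that continuous-term VIFs are
    well defined; each continuous term then gets the classic
    1/(1 - R2_aux) value and the crown-class indicator group gets a
    generalized VIF reported on the squared-comparable scale
    (GVIF^(1/df), i.e. the square of GVIF^(1/(2 df))).

    Perfect collinearity is reported as ``inf``, not raised.
    """
    design = build_design(joined, spec, require_response=False)
    n = design.n
    term_idx = [design.columns.index(t) for t in design.term_columns]
    terms = design.X[:, term_idx]

    blocks: list[np.ndarray] = []
    names: list[tuple[str, int, int]] = []  # (name, start, ncols) into W
    start = 0
    if spec.intercept_mode == "crown_class" and len(design.intercept_columns) > 1:
        cc_idx = [design.columns.index(c) for c in design.intercept_columns]
        dummies = design.X[:, cc_idx[1:]]  # first present level is the reference
        blocks.append(dummies)
        names.append(("crown_class", start, dummies.shape[1]))
        start += dummies.shape[1]
    for j, t in enumerate(design.term_columns):
        blocks.append(terms[:, [j]])
        names.append((t, start, 1))
        start += 1

    W = np.column_stack(blocks)
    Wc = W - W.mean(axis=0)
    sd = Wc.std(axis=0)
    if np.any(sd == 0):
        # constant column: undefined correlation -> infinite inflation
        return {name: math.inf for name, _, _ in names}
    R = np.corrcoef(Wc, rowvar=False)
    R = np.atleast_2d(R)
    det_R = float(np.linalg.det(R))

    out: dict[str, float] = {}
    p = W.shape[1]
    for name, s, width in names:
        idx = list(range(s, s + width))
        rest = [j for j in range(p) if j not in idx]
        det_g = float(np.linalg.det(R[np.ix_(idx, idx)])) if width > 1 else 1.0
        det_rest = float(np.linalg.det(R[np.ix_(rest, rest)])) if rest else 1.0
        if det_R <= 0 or not math.isfinite(det_R):
            out[name] = math.inf
            continue
        gvif = det_g * det_rest / det_R
        if width == 1:
            out[name] = gvif
        else:
            out[name] = gvif ** (1.0 / width)  # (GVIF^(1/(2 df)))^2
    return out
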