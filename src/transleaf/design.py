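"""Log-scale response and design-matrix construction for the six equations.

The response is ln(dry leaf mass, kg).  Predictor terms are natural logs
of the raw quantities; mean annual temperature is translated by a
constant offset (default +30 degC) before the log so the argument stays
positive at the coldest calibration sites.

Crown class enters as a *cell-means* intercept block: one indicator
column per crown-class level present in the data, no global constant
(matching the five published intercepts per equation).  The DBH-only
equation (eq3) instead uses a single global intercept.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np

from .data_io import (
    CROWN_CLASS_ORDER,
    CrownClass,
    SpeciesTraits,
    TreeRecord,
    parse_crown_class,
)

__all__ = [
    "DesignError",
    "ModelSpec",
    "DesignMatrix",
    "TERM_ORDER",
    "EQUATION_TERMS",
    "build_design",
    "encode_crown_class",
]


class DesignError(ValueError):
    """Invalid model specification or untransformable data."""


#: Canonical term order (used for deterministic columns and tie-breaking).
TERM_ORDER: tuple[str, ...] = (
    "lnDBH", "lnLL", "lnLCR", "lnSG", "lnSGp", "lnST", "lnMAT30", "lnMAP",
)

#: Term sets of the six published equations.
EQUATION_TERMS: dict[str, tuple[str, ...]] = {
    "eq1": ("lnDBH", "lnLL", "lnLCR", "lnSG", "lnST", "lnMAT30", "lnMAP"),
    "eq2": ("lnDBH", "lnLL", "lnLCR", "lnSGp", "lnST", "lnMAT30", "lnMAP"),
    "eq3": ("lnDBH",),
    "eq4": ("lnDBH", "lnLCR"),
    "eq5": ("lnDBH", "lnLCR", "lnMAT30", "lnMAP"),
    "eq6": ("lnDBH", "lnLL", "lnLCR", "lnST", "lnMAT30", "lnMAP"),
}

DEFAULT_MAT_OFFSET = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Which terms a model uses and how its intercept is parameterized."""

    eq_id: str
    terms: tuple[str, ...]
    intercept_mode: str  # "crown_class" | "single"
    mat_offset: float = DEFAULT_MAT_OFFSET

    def __post_init__(self):
        unknown = [t for t in self.terms if t not in TERM_ORDER]
        if unknown:
            raise DesignError(f"unknown term(s): {unknown}")
        if len(set(self.terms)) != len(self.terms):
            raise DesignError("duplicate terms in spec")
        if "lnSG" in self.terms and "lnSGp" in self.terms:
            raise DesignError("a model may use observed (lnSG) or published (lnSGp) "
                              "specific gravity, never both")
        if self.intercept_mode not in ("crown_class", "single"):
            raise DesignError(f"unknown intercept_mode {self.intercept_mode!r}")
        if not self.terms:
            raise DesignError("spec must have at least one term")

    @classmethod
    def equation(cls, eq_id: str, mat_offset: float = DEFAULT_MAT_OFFSET) -> "ModelSpec":
        """The spec of one of the six published equations (``eq1``..``eq6``)."""
        if eq_id not in EQUATION_TERMS:
            raise DesignError(f"unknown equation id {eq_id!r} (expected eq1..eq6)")
        mode = "single" if eq_id == "eq3" else "crown_class"
        return cls(eq_id=eq_id, terms=EQUATION_TERMS[eq_id],
                   intercept_mode=mode, mat_offset=mat_offset)

    def drop(self, term: str) -> "ModelSpec":
        """A copy with one term removed (used by backward stepwise)."""
        if term not in self.terms:
            raise DesignError(f"term {term!r} not in spec")
        rest = tuple(t for t in self.terms if t != term)
        return replace(self, eq_id="custom", terms=rest)


def encode_crown_class(cc: Union[str, int, CrownClass]) -> np.ndarray:
    """Five-element indicator vector in the fixed level order
    (open_grown, dominant, codominant, intermediate, overtopped)."""
    level = parse_crown_class(cc)
    return np.array([1.0 if level == c else 0.0 for c in CROWN_CLASS_ORDER])


@dataclass
class DesignMatrix:
    """Rows aligned to the input records, intercept block first."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray | None
    spec: ModelSpec
    tree_ids: list[str]
    cc: list[CrownClass]
    intercept_columns: list[str]
    term_columns: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_csv(self, dest: Union[str, Path, TextIO]) -> None:
        """Audit export: response (if any) plus all design columns."""
        close = False
        if isinstance(dest, (str, Path)):
            fh: TextIO = open(dest, "w", encoding="utf-8", newline="")
            close = True
        else:
            fh = dest
        try:
            w = csv.writer(fh)
            header = ["tree_id"] + (["ln_leaf_mass"] if self.y is not None else []) + self.columns
            w.writerow(header)
            for i in range(self.n):
                row = [self.tree_ids[i]]
                if self.y is not None:
                    row.append(repr(float(self.y[i])))
                row.extend(repr(float(v)) for v in self.X[i])
                w.writerow(row)
        finally:
            if close:
                fh.close()


JoinedItem = Union[TreeRecord, tuple[TreeRecord, SpeciesTraits]]


def _as_pairs(joined: Sequence[JoinedItem]) -> list[tuple[TreeRecord, SpeciesTraits | None]]:
    out: list[tuple[TreeRecord, SpeciesTraits | None]] = []
    for item in joined:
        if isinstance(item, TreeRecord):
            out.append((item, None))
        else:
            out.append((item[0], item[1]))
    return out


def build_design(
    joined: Sequence[JoinedItem],
    spec: ModelSpec,
    require_response: bool = True,
) -> DesignMatrix:
    """Build the design matrix and (optionally) the log-mass response.

    Deterministic and row-order preserving.  Raises :class:`DesignError`
    identifying offending rows when a required field is missing or a log
    argument is non-positive.
    """
    pairs = _as_pairs(joined)
    n = len(pairs)
    if n == 0:
        raise DesignError("no records")

    problems: list[str] = []

    def _raw(term: str, tree: TreeRecord, traits: SpeciesTraits | None, i: int) -> float:
        if term == "lnDBH":
            return tree.dbh
        if term == "lnLCR":
            return tree.lcr
        if term == "lnMAP":
            return tree.map_mm
        if term == "lnMAT30":
            v = tree.mat + spec.mat_offset
            if v <= 0:
                problems.append(
                    f"row {i}: mat + offset = {tree.mat} + {spec.mat_offset} <= 0"
                )
                return math.nan
            return v
        if term == "lnSG":
            if tree.sg_obs is None:
                problems.append(f"row {i} (tree {tree.tree_id}): sg_obs required by lnSG but missing")
                return math.nan
            return tree.sg_obs
        if traits is None:
            problems.append(
                f"row {i} (tree {tree.tree_id}): species traits required by {term} "
                "but record is not joined to a trait table"
            )
            return math.nan
        if term == "lnLL":
            return traits.ll
        if term == "lnST":
            return traits.st
        if term == "lnSGp":
            return traits.sg_pub
        raise DesignError(f"unknown term {term!r}")

    term_cols: dict[str, np.ndarray] = {}
    for term in spec.terms:
        vals = np.array([_raw(term, t, tr, i) for i, (t, tr) in enumerate(pairs)])
        with np.errstate(invalid="ignore", divide="ignore"):
            term_cols[term] = np.log(vals)

    y: np.ndarray | None = None
    if require_response:
        missing = [i for i, (t, _) in enumerate(pairs) if t.leaf_mass is None]
        if missing:
            problems.append(
                f"leaf_mass missing in fitting context for row(s) {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        else:
            y = np.log(np.array([t.leaf_mass for t, _ in pairs], dtype=float))

    if problems:
        raise DesignError("; ".join(problems[:20]))

    if spec.intercept_mode == "crown_class":
        levels = [c for c in CROWN_CLASS_ORDER if any(t.cc == c for t, _ in pairs)]
        icols = [f"cc_{c.value}" for c in levels]
        iblock = np.column_stack(
            [[1.0 if t.cc == c else 0.0 for t, _ in pairs] for c in levels]
        )
    else:
        icols = ["intercept"]
        iblock = np.ones((n, 1))

    X = np.column_stack([iblock] + [term_cols[t] for t in spec.terms])
    columns = icols + list(spec.terms)
    if not np.all(np.isfinite(X)):
        bad = sorted(set(np.argwhere(~np.isfinite(X))[:, 0].tolist()))
        raise DesignError(f"non-finite design entries in row(s) {bad[:10]}")
    if y is not None and not np.all(np.isfinite(y)):
        bad = sorted(set(np.argwhere(~np.isfinite(y)).ravel().tolist()))
        raise DesignError(f"non-finite response in row(s) {bad[:10]}")

    return DesignMatrix(
        X=X,
        columns=columns,
        y=y,
        spec=spec,
        tree_ids=[t.tree_id for t, _ in pairs],
        cc=[t.cc for t, _ in pairs],
        intercept_columns=icols,
        term_columns=list(spec.terms),
    )
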