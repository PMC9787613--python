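"""Dominance-analysis decomposition of model-explained variance.

The model R2 (against a constant-only baseline) is split into
nonnegative per-group contributions by averaging sequential R2
increments over orderings of the predictor groups.  Exact averaging
uses the subset identity

    share(g) = sum over S subset of G\\{g} of  w(|S|) * (R2(S + g) - R2(S)),
    w(s) = s! (p - s - 1)! / p!

which equals the mean over all p! orderings of the increment when g
enters.  The crown-class intercept block participates as one group,
entering as its indicator degrees of freedom beyond the global constant.
Shares are normalized to percent of the full model's R2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .design import JoinedItem, ModelSpec, build_design

__all__ = [
    "GroupingError",
    "ImportanceResult",
    "dominance_importance",
    "sequential_r2",
    "DEFAULT_GROUP_NAMES",
]


class GroupingError(ValueError):
    pass


#: Display names of the default one-term groups.
DEFAULT_GROUP_NAMES: dict[str, str] = {
    "lnDBH": "DBH",
    "lnLL": "LL",
    "lnLCR": "LCR",
    "lnSG": "SG",
    "lnSGp": "SGp",
    "lnST": "ST",
    "lnMAT30": "MAT",
    "lnMAP": "MAP",
}


@dataclass(frozen=True)
class ImportanceResult:
    """Per-group share of model-explained variance, in percent."""

    shares: dict[str, float]  # group -> % of model R2 (sums to 100)
    raw_contributions: dict[str, float]  # group -> R2 units
    r2_full: float
    method: str  # exact | sampled
    n_orderings: int
    groups: dict[str, tuple[str, ...]]


class _R2Engine:
    """Centered-response R2 of group subsets, with caching.

    Works on a reference parameterization: global constant + crown-class
    indicator columns beyond the constant + continuous term columns.
    """

    def __init__(self, joined: Sequence[JoinedItem], spec: ModelSpec,
                 groups: Mapping[str, Sequence[str]] | None):
        design = build_design(joined, spec, require_response=True)
        n = design.n
        cols: dict[str, np.ndarray] = {}
        if spec.intercept_mode == "crown_class":
            cc_idx = [design.columns.index(c) for c in design.intercept_columns]
            if len(cc_idx) < 2:
                raise GroupingError(
                    "crown-class group needs >= 2 observed levels to carry "
                    "degrees of freedom beyond the constant"
                )
            cols["CC"] = design.X[:, cc_idx[1:]]
        for t in design.term_columns:
            cols[t] = design.X[:, [design.columns.index(t)]]

        if groups is None:
            self.groups: dict[str, tuple[str, ...]] = {}
            if "CC" in cols:
                self.groups["CC"] = ("CC",)
            for t in design.term_columns:
                self.groups[DEFAULT_GROUP_NAMES[t]] = (t,)
        else:
            self.groups = {g: tuple(ts) for g, ts in groups.items()}
            flat = [t for ts in self.groups.values() for t in ts]
            expected = sorted(cols)
            if sorted(flat) != expected:
                raise GroupingError(
                    f"groups must partition the model's term set {expected}, got {sorted(flat)}"
                )

        self._cols = cols
        self._const = np.ones((n, 1))
        y = design.y
        self._y = y
        self._tss = float(((y - y.mean()) ** 2).sum())
        if self._tss <= 0:
            raise GroupingError("response has zero variance")
        self._cache: dict[frozenset, float] = {}

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    def r2(self, subset: frozenset) -> float:
        if subset in self._cache:
            return self._cache[subset]
        blocks = [self._const]
        for g in self.groups:
            if g in subset:
                for t in self.groups[g]:
                    blocks.append(self._cols[t])
        X = np.column_stack(blocks)
        # lstsq tolerates rank deficiency (minimum-norm solution on the
        # reduced rank), matching the documented submodel behaviour
        beta, _, _, _ = np.linalg.lstsq(X, self._y, rcond=None)
        resid = self._y - X @ beta
        rss = float(resid @ resid)
        val = 1.0 - rss / self._tss
        self._cache[subset] = val
        return val


def sequential_r2(
    joined: Sequence[JoinedItem],
    spec: ModelSpec,
    ordering: Sequence[str],
    groups: Mapping[str, Sequence[str]] | None = None,
) -> list[float]:
    """R2 increments as groups enter in the given order (they telescope
    to the full model's R2)."""
    eng = _R2Engine(joined, spec, groups)
    if sorted(ordering) != sorted(eng.group_names):
        raise GroupingError(
            f"ordering must be a permutation of {sorted(eng.group_names)}"
        )
    increments = []
    entered: frozenset = frozenset()
    for g in ordering:
        nxt = entered | {g}
        increments.append(eng.r2(frozenset(nxt)) - eng.r2(entered))
        entered = frozenset(nxt)
    return increments


def dominance_importance(
    joined: Sequence[JoinedItem],
    spec: ModelSpec,
    groups: Mapping[str, Sequence[str]] | None = None,
    exact_threshold: int = 10,
    n_samples: int = 10000,
    seed: int | None = None,
) -> ImportanceResult:
    """Averaged-over-orderings share of model R2 per predictor group.

    Exact subset-average computation when the number of groups is at most
    ``exact_threshold``; otherwise uniformly sampled orderings (``seed``
    mandatory in that case).
    """
    eng = _R2Engine(joined, spec, groups)
    names = eng.group_names
    p = len(names)
    full = frozenset(names)
    r2_full = eng.r2(full)

    contributions: dict[str, float] = {}
    if p <= exact_threshold:
        method = "exact"
        n_orderings = math.factorial(p)
        fact = [math.factorial(i) for i in range(p + 1)]
        for g in names:
            others = [o for o in names if o != g]
            total = 0.0
            for r in range(p):
                w = fact[r] * fact[p - r - 1] / fact[p]
                for combo in itertools.combinations(others, r):
                    s = frozenset(combo)
                    total += w * (eng.r2(s | {g}) - eng.r2(s))
            contributions[g] = total
    else:
        if seed is None:
            raise GroupingError(
                f"{p} groups exceed exact_threshold={exact_threshold}; "
                "sampled mode requires a seed"
            )
        method = "sampled"
        n_orderings = n_samples
        rng = np.random.default_rng(seed)
        sums = {g: 0.0 for g in names}
        arr = np.array(names, dtype=object)
        for _ in range(n_samples):
            order = rng.permutation(arr)
            entered: frozenset = frozenset()
            for g in order:
                nxt = frozenset(entered | {g})
                sums[str(g)] += eng.r2(nxt) - eng.r2(entered)
                entered = nxt
        contributions = {g: sums[g] / n_samples for g in names}

    total = sum(contributions.values())  # telescopes to r2_full (exact mode)
    if total <= 0:
        raise GroupingError("model explains no variance; shares undefined")
    shares = {g: 100.0 * c / total for g, c in contributions.items()}
    return ImportanceResult(
        shares=shares,
        raw_contributions=contributions,
        r2_full=r2_full,
        method=method,
        n_orderings=n_orderings,
        groups=dict(eng.groups),
    )
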