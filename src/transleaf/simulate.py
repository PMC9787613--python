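"""Synthetic tree-table generator with the statistical structure the
log-linear leaf-mass models assume, plus a parameter-recovery harness.

ln(leaf mass) is generated as the linear predictor of a coefficient set
(default: the packaged published full model with published specific
gravity, ``eq2``) plus Normal(0, sigma) noise; the default sigma of 0.50
matches the published log-scale RMSE of that model.  Covariate
distributions are fixtures calibrated to the published calibration-data
summaries (overall DBH mean 23.01 cm / SD 14.5 cm; LCR on (0.1, 1);
MAT in [-0.4, 20.7] degC; MAP in [275, 3084] mm), optionally resolved
per species from the packaged per-species summary table.

An optional "low-vigor" contamination multiplies true leaf mass of a
random subset by Uniform(0.2, 0.6), reproducing a right-skewed
percentage-error distribution without asserting any particular field
mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import (
    CROWN_CLASS_ORDER,
    SpeciesTraits,
    TraitTable,
    TreeRecord,
    attach_traits,
    packaged_species_stats,
    packaged_traits,
)
from .design import build_design
from .fit import FittedModel
from .predict import CoefficientSet, published_model

__all__ = [
    "SimError",
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "recovery_report",
    "RecoveryReport",
    "RecoveryRow",
]

# Published overall calibration summaries used for global moment matching.
DBH_MEAN_CM = 23.01
DBH_SD_CM = 14.5
LCR_MEAN = 0.52
LCR_SD = 0.18
MAT_RANGE_C = (-0.4, 20.7)
MAP_RANGE_MM = (275.0, 3084.0)


class SimError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic dataset draw."""

    n_trees: int = 3628
    seed: int = 0
    coefficients: CoefficientSet | None = None  # default: published eq2
    sigma: float = 0.50
    trait_table: TraitTable | None = None  # default: packaged 61 species
    #: "uniform" | "observed" (packaged per-species sample sizes) | mapping
    species_weights: str | dict = "uniform"
    dbh_dist: str = "global"  # "global" | "per_species"
    lcr_dist: str = "global"  # "global" | "per_species"
    cc_mechanism: str = "independent"  # "independent" | "linked"
    #: Class probabilities in level order (open_grown .. overtopped).
    cc_probs: tuple[float, ...] = (0.05, 0.20, 0.40, 0.20, 0.15)
    n_sites: int = 25
    mat_range: tuple[float, float] = MAT_RANGE_C
    map_range: tuple[float, float] = MAP_RANGE_MM
    contamination: float = 0.0
    contamination_factor: tuple[float, float] = (0.2, 0.6)

    def __post_init__(self):
        if self.n_trees < 1:
            raise SimError("n_trees must be >= 1")
        if self.sigma < 0:
            raise SimError("sigma must be >= 0")
        if not (0 <= self.contamination < 1):
            raise SimError("contamination must be in [0, 1)")
        if abs(sum(self.cc_probs) - 1.0) > 1e-9 or len(self.cc_probs) != 5:
            raise SimError("cc_probs must be 5 probabilities summing to 1")
        if self.n_sites < 1:
            raise SimError("n_sites must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset (reproducible from config)."""

    coefficients: dict[str, float]
    sigma: float
    eta: np.ndarray  # per-tree noiseless log mass
    contaminated: np.ndarray  # bool flags
    config: SimConfig

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "sigma": self.sigma,
            "eta": self.eta.tolist(),
            "contaminated": self.contaminated.astype(int).tolist(),
            "seed": self.config.seed,
            "n_trees": self.config.n_trees,
        }


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to a target mean and SD."""
    sdlog2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sdlog2 / 2.0, math.sqrt(sdlog2)


def _beta_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Moment-match a Beta on (lo, hi) to a target mean and SD (clamped to
    a valid, non-degenerate shape)."""
    span = hi - lo
    m = min(max((mean - lo) / span, 0.05), 0.95)
    v = min((sd / span) ** 2, 0.9 * m * (1 - m))
    nu = m * (1 - m) / v - 1.0
    return max(m * nu, 0.05), max((1 - m) * nu, 0.05)


def simulate_dataset(cfg: SimConfig) -> tuple[list[TreeRecord], SimTruth]:
    """Draw a synthetic tree table; identical (cfg, seed) => identical output."""
    rng = np.random.default_rng(cfg.seed)
    traits = cfg.trait_table if cfg.trait_table is not None else packaged_traits()
    names = traits.species
    if not names:
        raise SimError("species pool is empty")
    n = cfg.n_trees

    # species mix
    if cfg.species_weights == "uniform":
        w = np.full(len(names), 1.0 / len(names))
    elif cfg.species_weights == "observed":
        stats = packaged_species_stats()
        counts = np.array([stats[s].n_attr if s in stats else 1 for s in names], dtype=float)
        w = counts / counts.sum()
    elif isinstance(cfg.species_weights, dict):
        counts = np.array([float(cfg.species_weights.get(s, 0.0)) for s in names])
        if counts.sum() <= 0:
            raise SimError("species_weights assigns zero total weight")
        w = counts / counts.sum()
    else:
        raise SimError(f"unknown species_weights {cfg.species_weights!r}")
    sp_idx = rng.choice(len(names), size=n, p=w)

    # DBH (lognormal) and LCR (scaled Beta), globally or per species
    stats = packaged_species_stats()
    if cfg.dbh_dist == "per_species":
        meanlog = np.empty(len(names))
        sdlog = np.empty(len(names))
        for j, s in enumerate(names):
            st = stats.get(s)
            mean = st.dbh_mean if st else DBH_MEAN_CM
            sd = st.dbh_sd if (st and st.dbh_sd) else max(0.25 * mean, 1.0)
            meanlog[j], sdlog[j] = _lognormal_params(mean, sd)
        dbh = np.exp(rng.normal(meanlog[sp_idx], sdlog[sp_idx]))
    elif cfg.dbh_dist == "global":
        ml, sl = _lognormal_params(DBH_MEAN_CM, DBH_SD_CM)
        dbh = np.exp(rng.normal(ml, sl, size=n))
    else:
        raise SimError(f"unknown dbh_dist {cfg.dbh_dist!r}")

    lo, hi = 0.1, 1.0
    if cfg.lcr_dist == "per_species":
        a = np.empty(len(names))
        b = np.empty(len(names))
        for j, s in enumerate(names):
            st = stats.get(s)
            mean = st.lcr_mean if st else LCR_MEAN
            sd = st.lcr_sd if (st and st.lcr_sd) else 0.1
            a[j], b[j] = _beta_params(mean, sd, lo, hi)
        lcr = lo + (hi - lo) * rng.beta(a[sp_idx], b[sp_idx])
    elif cfg.lcr_dist == "global":
        a0, b0 = _beta_params(LCR_MEAN, LCR_SD, lo, hi)
        lcr = lo + (hi - lo) * rng.beta(a0, b0, size=n)
    else:
        raise SimError(f"unknown lcr_dist {cfg.lcr_dist!r}")

    # crown class
    if cfg.cc_mechanism == "independent":
        cc_idx = rng.choice(5, size=n, p=cfg.cc_probs)
        cc = [CROWN_CLASS_ORDER[i] for i in cc_idx]
    elif cfg.cc_mechanism == "linked":
        # latent canopy position driven by size and crown length, cut at
        # empirical quantiles so class frequencies match cc_probs
        z_dbh = (np.log(dbh) - np.log(dbh).mean()) / max(np.log(dbh).std(), 1e-12)
        z_lcr = (lcr - lcr.mean()) / max(lcr.std(), 1e-12)
        z = z_dbh + z_lcr + 0.8 * rng.logistic(0.0, 1.0, size=n)
        # ascending latent -> overtopped .. open_grown
        probs_asc = np.array(cfg.cc_probs[::-1])
        cuts = np.quantile(z, np.cumsum(probs_asc)[:-1])
        klass = np.searchsorted(cuts, z, side="right")  # 0..4 ascending
        asc_levels = list(CROWN_CLASS_ORDER[::-1])
        cc = [asc_levels[i] for i in klass]
    else:
        raise SimError(f"unknown cc_mechanism {cfg.cc_mechanism!r}")

    # climate: per-site pairs within the calibration ranges
    site_mat = rng.uniform(cfg.mat_range[0], cfg.mat_range[1], size=cfg.n_sites)
    site_map = rng.uniform(cfg.map_range[0], cfg.map_range[1], size=cfg.n_sites)
    site_idx = rng.integers(0, cfg.n_sites, size=n)

    records = [
        TreeRecord(
            tree_id=f"t{i:06d}",
            species=names[sp_idx[i]],
            dbh=float(dbh[i]),
            lcr=float(lcr[i]),
            cc=cc[i],
            mat=float(site_mat[site_idx[i]]),
            map_mm=float(site_map[site_idx[i]]),
            study_id=f"site{site_idx[i]:03d}",
        )
        for i in range(n)
    ]

    cs = cfg.coefficients if cfg.coefficients is not None else published_model("eq2")
    joined = attach_traits(records, traits)
    if "lnSG" in cs.spec.terms:
        # observed specific gravity: species published value + tree-level spread
        sg = np.array([tr.sg_pub for _, tr in joined]) + rng.normal(0.0, 0.04, size=n)
        sg = np.clip(sg, 0.15, None)
        for r, v in zip(records, sg):
            r.sg_obs = float(v)
    design = build_design(joined, cs.spec, require_response=False)
    beta = np.array([cs.coefficients[c] for c in design.columns])
    eta = design.X @ beta

    eps = rng.normal(0.0, cfg.sigma, size=n)
    mass = np.exp(eta + eps)
    contaminated = rng.random(n) < cfg.contamination
    if contaminated.any():
        factors = rng.uniform(*cfg.contamination_factor, size=n)
        mass = np.where(contaminated, mass * factors, mass)
    for r, m in zip(records, mass):
        r.leaf_mass = float(m)

    truth = SimTruth(
        coefficients={c: float(cs.coefficients[c]) for c in design.columns},
        sigma=cfg.sigma,
        eta=eta,
        contaminated=contaminated,
        config=cfg,
    )
    return records, truth


@dataclass(frozen=True)
class RecoveryRow:
    name: str
    truth: float
    estimate: float
    se: float
    z: float


@dataclass
class RecoveryReport:
    rows: list[RecoveryRow]

    def all_within(self, z_max: float = 3.0) -> bool:
        return all(abs(r.z) <= z_max for r in self.rows)


def recovery_report(truth: SimTruth, fitted: FittedModel) -> RecoveryReport:
    """Per-coefficient (truth, estimate, SE, z); z = (est - truth)/SE.

    Requires the fitted model to estimate exactly the generating
    coefficient set (same spec and crown-class levels).
    """
    if set(fitted.coefficients) != set(truth.coefficients):
        raise SimError(
            "fitted model does not match the generating spec: "
            f"fitted {sorted(fitted.coefficients)} vs truth {sorted(truth.coefficients)}"
        )
    rows = []
    for name in fitted.columns:
        tv = truth.coefficients[name]
        est = fitted.coefficients[name]
        se = fitted.standard_errors[name]
        if se < 1e-10:  # numerically noiseless fit
            z = 0.0 if math.isclose(est, tv, rel_tol=1e-7, abs_tol=1e-7) else math.inf
        else:
            z = (est - tv) / se
        rows.append(RecoveryRow(name=name, truth=tv, estimate=est, se=se, z=z))
    return RecoveryReport(rows=rows)
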