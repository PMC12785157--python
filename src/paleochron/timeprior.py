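"""Fossil-calibration densities and the birth–death node-age prior.

A calibration constrains the age of the most recent common ancestor of two
anchor tips.  The working density is the soft-bounded uniform: constant
height on [t_min, t_max], a power-law lower tail on (0, t_min) carrying
total mass pL, and an exponential upper tail on (t_max, inf) carrying mass
pU, both tails matched for continuity at the bounds.  pL = 1e-300 makes
the minimum effectively hard; pL = 0.1 gives the soft-minimum variant.
Uncalibrated interior node ages follow the birth–death-with-species-
sampling kernel conditional on the root age.

Ages are in Ma throughout this module; the MCMC layer converts to its
internal 100-Ma unit at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import TimeTree

HARD_PL = 1e-300   # lower-tail mass that renders a minimum bound hard
DEFAULT_PU = 0.025

STYLES = ("hard_min_soft_max", "soft_min_soft_max", "max_only", "min_only")


@dataclass
class CalibrationSpec:
    """One node-age constraint (bounds in Ma, MRCA anchor semantics)."""

    name: str
    tip_a: str
    tip_b: str
    t_min: float | None = None
    t_max: float | None = None
    p_lower: float = HARD_PL
    p_upper: float = DEFAULT_PU
    style: str = "hard_min_soft_max"
    rank: str = "Phylum"
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise ValueError(f"unknown calibration style {self.style!r}")
        if self.style == "max_only":
            self.t_min = None
        if self.style == "min_only":
            self.t_max = None
        if self.t_min is not None and self.t_max is not None \
                and not self.t_min < self.t_max:
            raise ValueError(f"{self.name}: t_min must be < t_max")
        if self.t_min is None and self.t_max is None:
            raise ValueError(f"{self.name}: needs at least one bound")
        if not (0.0 <= self.p_lower < 0.5 and 0.0 <= self.p_upper < 0.5):
            raise ValueError("tail probabilities must lie in [0, 0.5)")
        self.flags = frozenset(self.flags)

    def resolve(self, tree: TimeTree) -> int:
        """Node index of the MRCA of the two anchor tips."""
        return tree.mrca(self.tip_a, self.tip_b)

    # -- density -----------------------------------------------------------
    def _pieces(self) -> tuple[float, float, float, float, float]:
        """(t_min, t_max, interior height h, lower power theta, upper rate)."""
        lo = 0.0 if self.t_min is None else float(self.t_min)
        pL = 0.0 if self.t_min is None else float(self.p_lower)
        if self.t_max is None:
            # min_only: no finite interior; exponential body above t_min with
            # mass (1 - pL) and a power lower tail of mass pL.  Height chosen
            # as for a unit-width interior so the tail shapes stay continuous.
            hi = math.inf
        else:
            hi = float(self.t_max)
        pU = 0.0 if self.t_max is None else float(self.p_upper)
        if math.isinf(hi):
            # interpret as exponential with rate such that mean = 2*t_min
            rate = 1.0 / max(lo, 1.0)
            h = (1.0 - pL) * rate
        else:
            h = (1.0 - pL - pU) / (hi - lo)
            rate = h / pU if pU > 0 else math.inf
        theta = h * lo / pL if (lo > 0 and pL > 0) else math.inf
        return lo, hi, h, theta, rate

    def log_density(self, t: float) -> float:
        if t <= 0:
            raise ValueError("age must be positive")
        lo, hi, h, theta, rate = self._pieces()
        if t < lo:
            # power tail: f(t) = (theta * pL / lo) * (t/lo)^(theta-1)
            pL = self.p_lower
            if pL <= 0 or math.isinf(theta):
                return -math.inf
            logf = (math.log(theta) + math.log(pL) - math.log(lo)
                    + (theta - 1.0) * math.log(t / lo))
            return logf if math.isfinite(logf) else -math.inf
        if math.isinf(hi):
            # exponential body above the minimum
            return math.log(h) - (t - lo) * (h / (1.0 - self.p_lower))
        if t <= hi:
            return math.log(h)
        pU = self.p_upper
        if pU <= 0:
            return -math.inf
        return math.log(h) - rate * (t - hi)

    def density(self, t: float) -> float:
        ld = self.log_density(t)
        return math.exp(ld) if ld > -math.inf else 0.0


def calibration_density(t, spec: CalibrationSpec):
    """Density of the calibration at age(s) ``t`` (Ma); vectorised."""
    if np.isscalar(t):
        return spec.density(float(t))
    return np.array([spec.density(float(x)) for x in np.asarray(t).ravel()])


def calibration_log_density(t: float, spec: CalibrationSpec) -> float:
    return spec.log_density(t)


@dataclass
class RootConstraint:
    """Maximum root age (Ma); soft by default, optionally a hard cap."""

    t_max: float
    p_upper: float = DEFAULT_PU
    hard: bool = False

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("root maximum must be positive")

    def as_calibration(self, tree: TimeTree) -> CalibrationSpec:
        tips = tree.tips_below(tree.root)
        return CalibrationSpec(
            "root", tree.taxon_names[tips[0]], tree.taxon_names[tips[-1]],
            t_min=None, t_max=self.t_max,
            p_upper=0.0 if self.hard else self.p_upper, style="max_only",
            rank="Root")


@dataclass
class BirthDeathParams:
    """Birth–death-with-sampling tree-shape parameters.

    Rates are per lineage per 100 Ma; ``rho`` is the sampling fraction.
    """

    lam: float = 1.0
    mu: float = 1.0
    rho: float = 0.0012

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.mu < 0 or not 0 < self.rho <= 1:
            raise ValueError("require lambda > 0, mu >= 0, 0 < rho <= 1")


def _bd_p01(t: np.ndarray, lam: float, mu: float, rho: float):
    """P(0,t) and p1(t) of the birth–death-with-sampling kernel."""
    if abs(lam - mu) < 1e-12:
        P0 = rho / (1.0 + rho * lam * t)
        p1 = rho / (1.0 + rho * lam * t) ** 2
        return P0, p1
    e = np.exp((mu - lam) * t)
    P0 = rho * (lam - mu) / (rho * lam + (lam * (1 - rho) - mu) * e)
    p1 = (1.0 / rho) * P0 ** 2 * e
    return P0, p1


def bd_node_density(t, bd: BirthDeathParams, root_age: float):
    """Density of an interior node age conditional on the root age.

    The birth–death-with-species-sampling kernel g(t) = lam * p1(t) / v(t1)
    with v(t1) = 1 - P(0,t1) * exp((mu-lam) t1) / rho; the lam = mu case is
    handled by its analytic limit.  ``t`` and ``root_age`` share one time
    unit (the caller's); the kernel is scale-consistent as long as rates
    are per that unit.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any((t_arr <= 0) | (t_arr >= root_age)):
        raise ValueError("node age must lie strictly inside (0, root_age)")
    lam, mu, rho = bd.lam, bd.mu, bd.rho
    _, p1 = _bd_p01(t_arr, lam, mu, rho)
    if abs(lam - mu) < 1e-12:
        v1 = rho * lam * root_age / (1.0 + rho * lam * root_age)
    else:
        P0_1, _ = _bd_p01(np.array([root_age]), lam, mu, rho)
        v1 = 1.0 - P0_1[0] * math.exp((mu - lam) * root_age) / rho
    out = lam * p1 / v1
    return float(out[0]) if np.isscalar(t) else out


def bd_node_cdf_grid(bd: BirthDeathParams, root_age: float,
                     n: int = 4097) -> tuple[np.ndarray, np.ndarray]:
    """Grid and CDF of the kernel on (0, root_age) (trapezoid quadrature)."""
    ts = np.linspace(root_age * 1e-9, root_age * (1 - 1e-9), n)
    dens = bd_node_density(ts, bd, root_age)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (dens[1:] + dens[:-1]) * np.diff(ts))])
    cdf /= cdf[-1]
    return ts, cdf


def sample_bd_node_ages(bd: BirthDeathParams, root_age: float, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling of the kernel (interpolated grid quantiles)."""
    ts, cdf = bd_node_cdf_grid(bd, root_age)
    u = rng.random(size)
    return np.interp(u, cdf, ts)


class TimePrior:
    """Joint (unnormalised) log prior over internal-node ages.

    Calibrated nodes contribute their calibration log-density, uncalibrated
    non-root nodes the birth–death kernel conditional on the current root
    age, and the root its own constraint density.  Any violated ordering
    constraint (or a hard root cap) gives -inf.  Because calibrations on
    nested nodes interact through the ordering constraints, the *effective*
    marginal prior at a node generally differs from its user-specified
    density; sample it with a prior-only chain (``usedata = 0``).
    """

    def __init__(self, tree: TimeTree, calibrations: list[CalibrationSpec],
                 bd: BirthDeathParams | None = None,
                 root_constraint: RootConstraint | None = None):
        self.tree = tree
        self.bd = bd or BirthDeathParams()
        self.root_constraint = root_constraint
        self.cal_of: dict[int, CalibrationSpec] = {}
        for spec in calibrations:
            node = spec.resolve(tree)
            if tree.is_tip(node):
                raise ValueError(f"calibration {spec.name} anchors a tip")
            if node in self.cal_of:
                raise ValueError(
                    f"two calibrations resolve to node {node} "
                    f"({self.cal_of[node].name}, {spec.name})")
            self.cal_of[node] = spec
        self.root_cal: CalibrationSpec | None = None
        if tree.root in self.cal_of:
            self.root_cal = self.cal_of.pop(tree.root)
        elif root_constraint is not None:
            self.root_cal = root_constraint.as_calibration(tree)
        self.uncalibrated = [v for v in tree.internal_nodes
                             if v != tree.root and v not in self.cal_of]

    def log_prior(self, internal_ages: np.ndarray) -> float:
        """Log prior of a vector of internal-node ages (Ma), indexed in the
        tree's internal-node order (node n_tips + i -> internal_ages[i])."""
        tree = self.tree
        ages = np.empty(tree.n_nodes)
        ages[: tree.n_tips] = tree.ages[: tree.n_tips]
        ages[tree.n_tips:] = internal_ages

        for v in tree.internal_nodes:
            av = ages[v]
            for c in tree.children[v]:
                if ages[c] >= av:
                    return -math.inf
        root_age = float(ages[tree.root])
        total = 0.0
        if self.root_cal is not None:
            if self.root_constraint is not None and self.root_constraint.hard \
                    and root_age > self.root_constraint.t_max:
                return -math.inf
            total += self.root_cal.log_density(root_age)
        for node, spec in self.cal_of.items():
            total += spec.log_density(float(ages[node]))
        if self.uncalibrated:
            ts = ages[self.uncalibrated]
            dens = bd_node_density(np.clip(ts, root_age * 1e-12,
                                           root_age * (1 - 1e-12)),
                                   self.bd, root_age)
            if np.any(dens <= 0):
                return -math.inf
            total += float(np.sum(np.log(dens)))
        if not math.isfinite(total):
            return -math.inf
        return total


def joint_log_prior(internal_ages: np.ndarray, tree: TimeTree,
                    calibrations: list[CalibrationSpec],
                    bd: BirthDeathParams | None = None,
                    root_constraint: RootConstraint | None = None) -> float:
    """Functional wrapper over :class:`TimePrior`."""
    return TimePrior(tree, calibrations, bd, root_constraint).log_prior(
        np.asarray(internal_ages, dtype=float))


# -- calibration table I/O --------------------------------------------------

_TSV_COLS = ["name", "tip_anchor_1", "tip_anchor_2", "min_Ma", "max_Ma",
             "pL", "pU", "style", "rank", "flags"]


def write_calibration_tsv(specs: list[CalibrationSpec], path) -> None:
    rows = []
    for s in specs:
        rows.append({
            "name": s.name, "tip_anchor_1": s.tip_a, "tip_anchor_2": s.tip_b,
            "min_Ma": "" if s.t_min is None else repr(s.t_min),
            "max_Ma": "" if s.t_max is None else repr(s.t_max),
            "pL": repr(s.p_lower), "pU": repr(s.p_upper),
            "style": s.style, "rank": s.rank,
            "flags": ";".join(sorted(s.flags)),
        })
    pd.DataFrame(rows, columns=_TSV_COLS).to_csv(path, sep="\t", index=False)


def read_calibration_tsv(path) -> list[CalibrationSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    specs = []
    for _, r in df.iterrows():
        specs.append(CalibrationSpec(
            name=r["name"], tip_a=r["tip_anchor_1"], tip_b=r["tip_anchor_2"],
            t_min=float(r["min_Ma"]) if r["min_Ma"] else None,
            t_max=float(r["max_Ma"]) if r["max_Ma"] else None,
            p_lower=float(r["pL"]), p_upper=float(r["pU"]),
            style=r["style"], rank=r["rank"],
            flags=frozenset(f for f in r.get("flags", "").split(";") if f)))
    return specs
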