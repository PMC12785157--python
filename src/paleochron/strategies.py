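"""Calibration strategies, sensitivity gradients and dating diagnostics.

Encodes the seven-strategy calibration experiment: strategies A1-A3 vary
the maximum bound applied to early-embryophyte-type nodes (a conservative
515.5 Ma versus a relaxed 1042 Ma) and the minimum bound of the crown node
(469 Ma hard versus 940.4 Ma soft); strategies B1-B4 vary fossil count
(55 vs 52 after dropping three uncertain algal fossils), data partitioning
(1 vs 3 codon-position partitions) and the sigma^2 rate-heterogeneity
prior (Gamma(1,10) vs Gamma(10,10)).  Also provides the S1-S4 sequential
calibration-removal gradients, the infinite-sites regression, the
prior/posterior overlap coefficient, and a suite runner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gaussian_kde, pearsonr

from .clock import ClockHyperParams, GammaSpec, RGENE_DEFAULT, \
    SIGMA2_DEFAULT, SIGMA2_HIGH_HET
from .mcmc import DatingModel, MCMCTrace, run_chain
from .timeprior import BirthDeathParams, CalibrationSpec, RootConstraint, \
    TimePrior
from .trees import TimeTree

# The two alternative maximum bounds for early-embryophyte-type nodes and
# the two alternative crown-node minimum bounds (Ma).  The conservative
# maximum is quoted both as 515 and 515.5 in different places; 515.5 is
# used, with 515 accepted as an alias.
EARLY_MAX_CONSERVATIVE = 515.5
EARLY_MAX_RELAXED = 1042.0
CROWN_MIN_YOUNG = 469.0
CROWN_MIN_OLD = 940.4
SOFT_MIN_PL = 0.1

RANK_ORDER = ["Genus", "Family", "Order", "Class", "Phylum", "Kingdom",
              "Root"]


@dataclass
class StrategyConfig:
    """One calibration strategy: a fossil subset plus prior settings."""

    name: str
    calibrations: list[CalibrationSpec]
    n_partitions: int = 1
    sigma2_prior: GammaSpec = field(default_factory=lambda: SIGMA2_DEFAULT)
    rgene_prior: GammaSpec = field(default_factory=lambda: RGENE_DEFAULT)
    description: str = ""

    def __post_init__(self) -> None:
        if self.n_partitions not in (1, 3):
            raise ValueError("n_partitions must be 1 or 3")

    @property
    def n_fossils(self) -> int:
        return len(self.calibrations)

    def clock(self) -> ClockHyperParams:
        return ClockHyperParams(rgene=self.rgene_prior,
                                sigma2=self.sigma2_prior)

    def to_yaml(self, path) -> None:
        payload = {
            "name": self.name,
            "calibrations": [c.name for c in self.calibrations],
            "n_partitions": self.n_partitions,
            "rgene_gamma": [self.rgene_prior.a, self.rgene_prior.b],
            "sigma2_gamma": [self.sigma2_prior.a, self.sigma2_prior.b],
            "description": self.description,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path,
                  calibration_table: list[CalibrationSpec]) -> "StrategyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        by_name = {c.name: c for c in calibration_table}
        return cls(
            name=d["name"],
            calibrations=[by_name[n] for n in d["calibrations"]],
            n_partitions=int(d.get("n_partitions", 1)),
            rgene_prior=GammaSpec(*d.get("rgene_gamma", [1.0, 33.3333])),
            sigma2_prior=GammaSpec(*d.get("sigma2_gamma", [1.0, 10.0])),
            description=d.get("description", ""))


def _with_early_max(specs: list[CalibrationSpec],
                    t_max: float) -> list[CalibrationSpec]:
    out = []
    for s in specs:
        if "early_embryophyta" in s.flags:
            out.append(replace(s, t_max=t_max))
        else:
            out.append(s)
    return out


def _with_crown_min(specs: list[CalibrationSpec], t_min: float,
                    soft: bool) -> list[CalibrationSpec]:
    out = []
    for s in specs:
        if "crown_viridiplantae" in s.flags:
            out.append(replace(
                s, t_min=t_min,
                p_lower=SOFT_MIN_PL if soft else s.p_lower,
                style="soft_min_soft_max" if soft else s.style))
        else:
            out.append(s)
    return out


def build_paper_strategies(calibration_table: list[CalibrationSpec]
                           ) -> dict[str, StrategyConfig]:
    """The seven strategies from a flagged calibration table.

    The table must mark the strategy-A subset (``strategy_A`` flag), the
    nodes sharing the early-embryophyte maximum (``early_embryophyta``),
    the crown node whose minimum switches (``crown_viridiplantae``) and the
    uncertain algal fossils (``uncertain_algal``).
    """
    a_set = [s for s in calibration_table if "strategy_A" in s.flags]
    if not a_set:
        raise ValueError("no calibrations flagged strategy_A")
    if not any("early_embryophyta" in s.flags for s in a_set):
        raise ValueError("no early_embryophyta marker in the A subset")
    full = list(calibration_table)
    no_algal = [s for s in full if "uncertain_algal" not in s.flags]

    a1 = _with_crown_min(_with_early_max(a_set, EARLY_MAX_CONSERVATIVE),
                         CROWN_MIN_YOUNG, soft=False)
    a2 = _with_crown_min(_with_early_max(a_set, EARLY_MAX_RELAXED),
                         CROWN_MIN_YOUNG, soft=False)
    a3 = _with_crown_min(_with_early_max(a_set, EARLY_MAX_RELAXED),
                         CROWN_MIN_OLD, soft=True)
    b_base = _with_crown_min(_with_early_max(full, EARLY_MAX_RELAXED),
                             CROWN_MIN_OLD, soft=True)
    b2_cals = _with_crown_min(_with_early_max(no_algal, EARLY_MAX_RELAXED),
                              CROWN_MIN_OLD, soft=True)

    return {
        "A1": StrategyConfig("A1", a1, description=(
            "22 fossils; conservative early-embryophyte max "
            f"({EARLY_MAX_CONSERVATIVE} Ma)")),
        "A2": StrategyConfig("A2", a2, description=(
            f"22 fossils; relaxed early-embryophyte max "
            f"({EARLY_MAX_RELAXED} Ma)")),
        "A3": StrategyConfig("A3", a3, description=(
            f"22 fossils; crown minimum {CROWN_MIN_OLD} Ma, soft")),
        "B1": StrategyConfig("B1", b_base,
                             description="55 fossils"),
        "B2": StrategyConfig("B2", b2_cals,
                             description="52 fossils (algal drops)"),
        "B3": StrategyConfig("B3", b_base, n_partitions=3,
                             description="55 fossils; 3 codon partitions"),
        "B4": StrategyConfig("B4", b_base, sigma2_prior=SIGMA2_HIGH_HET,
                             description="55 fossils; sigma2 ~ Gamma(10,10)"),
    }


def sensitivity_gradients(calibration_table: list[CalibrationSpec]
                          ) -> dict[str, list[CalibrationSpec]]:
    """Nested S1-S4 subsets by sequential rank removal.

    S1 keeps everything; S2 drops calibrations at or below Order rank; S3
    at or below Class; S4 at or below Phylum.  Unknown rank labels raise.
    """
    for s in calibration_table:
        if s.rank not in RANK_ORDER:
            raise ValueError(f"calibration {s.name} has unknown rank "
                             f"{s.rank!r}")

    def keep_above(rank: str) -> list[CalibrationSpec]:
        cut = RANK_ORDER.index(rank)
        return [s for s in calibration_table
                if RANK_ORDER.index(s.rank) > cut]

    return {
        "S1": list(calibration_table),
        "S2": keep_above("Order"),
        "S3": keep_above("Class"),
        "S4": keep_above("Phylum"),
    }


def infinite_sites_regression(summary: pd.DataFrame
                              ) -> tuple[float, float]:
    """Through-origin regression of HPD width on posterior mean age.

    ``summary`` needs columns ``mean``, ``hpd_low``, ``hpd_high`` (one row
    per node).  Returns (slope, R^2) with slope = sum(xy)/sum(x^2) and the
    uncentred R^2 of the through-origin fit.  The slope measures how far
    dating precision is calibration-limited rather than data-limited.
    """
    if len(summary) < 3:
        raise ValueError("need at least three nodes")
    x = summary["mean"].to_numpy(dtype=float)
    y = (summary["hpd_high"] - summary["hpd_low"]).to_numpy(dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        return 0.0, 1.0
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    if syy == 0:
        return slope, 1.0
    resid = y - slope * x
    r2 = 1.0 - float(np.sum(resid ** 2)) / syy
    return slope, r2


def prior_posterior_overlap(samples_a, samples_b,
                            grid_size: int = 512) -> float:
    """Overlap coefficient of two sample sets: integral of min(kde_a, kde_b).

    1 means the posterior learned nothing beyond the (effective) prior at
    this node; values near 0 mean the data moved the node away from its
    prior.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if len(a) < 100 or len(b) < 100:
        raise ValueError("need at least 100 samples per distribution")
    if a.std() == 0 or b.std() == 0:
        # degenerate spike(s): overlap is 1 if they coincide, else 0
        return float(a.std() == b.std() == 0 and a[0] == b[0])
    ka, kb = gaussian_kde(a), gaussian_kde(b)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    fa, fb = ka(grid), kb(grid)
    return float(np.trapezoid(np.minimum(fa, fb), grid))


@dataclass
class StrategyResult:
    """Posterior and effective-prior output of one strategy run."""

    strategy: StrategyConfig
    posterior: MCMCTrace
    effective_prior: MCMCTrace
    summary: pd.DataFrame              # per node: posterior + prior columns
    infinite_sites_slope: float
    infinite_sites_r2: float
    overlap: dict[str, float]          # node label -> prior/posterior overlap


def summarize_with_prior(posterior: MCMCTrace, prior: MCMCTrace,
                         level: float = 0.95) -> pd.DataFrame:
    post = posterior.summary(level)
    pri = prior.summary(level).rename(columns={
        "mean": "prior_mean", "hpd_low": "prior_hpd_low",
        "hpd_high": "prior_hpd_high", "ess": "prior_ess"})
    return post.join(pri)


def run_strategy(strategy: StrategyConfig, tree: TimeTree,
                 likelihoods_by_npart: dict[int, list] | None,
                 bd: BirthDeathParams, root_constraint: RootConstraint,
                 n_iter: int, seed: int, thin: int = 20,
                 overlap_nodes: list[int] | None = None) -> StrategyResult:
    """One posterior + one effective-prior chain under a strategy.

    ``likelihoods_by_npart`` maps a partition count to its surrogate list
    (e.g. {1: [sur], 3: [sur_pos1, sur_pos2, sur_pos3]}); calibrations that
    do not resolve in ``tree`` are dropped (the subtree case).
    """
    usable = []
    tipset = set(tree.taxon_names)
    for c in strategy.calibrations:
        if c.tip_a in tipset and c.tip_b in tipset:
            usable.append(c)
    prior = TimePrior(tree, usable, bd, root_constraint)
    liks = None
    if likelihoods_by_npart is not None:
        if strategy.n_partitions not in likelihoods_by_npart:
            raise KeyError(
                f"no likelihood set for {strategy.n_partitions} partitions")
        liks = likelihoods_by_npart[strategy.n_partitions]
    model = DatingModel(tree, prior, strategy.clock(), liks)
    post = run_chain(model, n_iter, seed=seed, use_data=True, thin=thin)
    pri = run_chain(model, n_iter, seed=seed + 1, use_data=False, thin=thin)
    summary = summarize_with_prior(post, pri)
    slope, r2 = infinite_sites_regression(summary)
    overlaps = {}
    targets = overlap_nodes if overlap_nodes is not None \
        else [prior_node for prior_node in prior.cal_of]
    for node in targets:
        col = node - tree.n_tips
        overlaps[f"node{node}"] = prior_posterior_overlap(
            post.ages[:, col], pri.ages[:, col])
    return StrategyResult(strategy, post, pri, summary, slope, r2, overlaps)


def run_strategy_suite(strategies: dict[str, StrategyConfig],
                       tree: TimeTree,
                       likelihoods_by_npart: dict[int, list] | None,
                       bd: BirthDeathParams,
                       root_constraint: RootConstraint,
                       n_iter: int, seeds: list[int], thin: int = 20
                       ) -> tuple[dict[str, StrategyResult], pd.DataFrame]:
    """Run every strategy (first seed) and build the cross-strategy table.

    Extra seeds run duplicate posterior chains per strategy for the
    convergence gate.  Returns (results, comparison) where comparison has
    one row per (node, strategy) with posterior means, HPDs and the delta
    to the first strategy.
    """
    results: dict[str, StrategyResult] = {}
    for k, (name, strat) in enumerate(strategies.items()):
        results[name] = run_strategy(
            strat, tree, likelihoods_by_npart, bd, root_constraint,
            n_iter, seed=seeds[0] + 977 * k, thin=thin)
    first = next(iter(results))
    rows = []
    for name, res in results.items():
        base = results[first].summary
        for node, r in res.summary.iterrows():
            rows.append({
                "strategy": name, "node": node, "mean": r["mean"],
                "hpd_low": r["hpd_low"], "hpd_high": r["hpd_high"],
                "delta_vs_first": r["mean"] - base.loc[node, "mean"],
            })
    return results, pd.DataFrame(rows)


def compare_sensitivity(summaries: dict[str, pd.DataFrame]
                        ) -> pd.DataFrame:
    """Per-node age agreement of S2..Sk with S1.

    Returns Pearson correlation and mean absolute age difference of each
    gradient's posterior mean node ages against S1's.
    """
    if "S1" not in summaries:
        raise ValueError("need an S1 baseline")
    base = summaries["S1"]["mean"]
    rows = []
    for name, summ in summaries.items():
        if name == "S1":
            continue
        joined = pd.concat([base, summ["mean"]], axis=1, keys=["s1", "s"])
        r = pearsonr(joined["s1"], joined["s"]).statistic
        mad = float(np.abs(joined["s1"] - joined["s"]).mean())
        rows.append({"gradient": name, "pearson_r": float(r),
                     "mean_abs_diff": mad})
    return pd.DataFrame(rows).set_index("gradient")


# -- control files ----------------------------------------------------------

def dump_control(path, *, usedata: int, bd: BirthDeathParams,
                 rgene: GammaSpec, sigma2: GammaSpec,
                 burnin: int, nsample: int, thin: int = 100) -> None:
    """Write a YAML control file mirroring the classic key names."""
    payload = {
        "usedata": usedata,
        "BDparas": [bd.lam, bd.mu, bd.rho],
        "rgene_gamma": [rgene.a, rgene.b],
        "sigma2_gamma": [sigma2.a, sigma2.b],
        "burnin": burnin,
        "nsample": nsample,
        "thin": thin,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_control(path) -> dict:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["BDparas"] = BirthDeathParams(*d["BDparas"])
    d["rgene_gamma"] = GammaSpec(*d["rgene_gamma"])
    d["sigma2_gamma"] = GammaSpec(*d["sigma2_gamma"])
    return d
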