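"""Synthetic trees, rates, alignments and fossil calibrations.

Generates data with the statistical structure the dating analysis assumes:
ultrametric birth–death time trees with (optional) incomplete sampling,
i.i.d. lognormal branch rates, GTR+Gamma sequences with lineage-specific
equilibrium GC targets (switched once on each lineage's stem branch) and
per-codon-position rate multipliers, and fossil-style calibration bounds
placed relative to true node ages — including a deliberately-too-tight
maximum bound for studying prior/posterior interaction.

Time is handled in Ma externally; birth–death rates are per lineage per
100 Ma, matching the dating model's rate scale.  All generators are
deterministic given (seed, config).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .clock import sample_branch_rates
from .likelihood import SubstModel
from .supermatrix import SuperMatrix
from .timeprior import CalibrationSpec, HARD_PL, DEFAULT_PU, BirthDeathParams
from .trees import TimeTree

HUNDRED_MA = 100.0


@dataclass
class SimConfig:
    """Configuration for a full synthetic dating dataset."""

    seed: int = 0
    n_tips: int = 12
    root_age: float = 900.0              # Ma
    bd: BirthDeathParams | None = None   # derived from n_tips/root_age if None
    clock_mean: float = 0.03             # substitutions/site/100 Ma
    sigma2: float = 0.1                  # variance of log branch rates
    n_sites: int = 999
    gamma_shape: float | None = 0.5
    p_invariant: float = 0.0
    composition_map: dict[str, float] | None = None   # lineage -> target GC
    position_multipliers: tuple[float, float, float] = (1.0, 0.8, 1.2)

    def __post_init__(self) -> None:
        m = np.asarray(self.position_multipliers, dtype=float)
        if np.any(m <= 0):
            raise ValueError("position multipliers must be positive")
        self.position_multipliers = tuple(m / m.mean())
        if self.bd is None:
            self.bd = bd_for_target(self.n_tips, self.root_age)


def bd_for_target(n_tips: int, root_age: float, turnover: float = 0.5,
                  rho: float = 1.0) -> BirthDeathParams:
    """Birth–death rates whose expected survivor count at the root age
    matches ``n_tips`` (so exact-count conditioning is feasible): the net
    diversification lam - mu solves 2*exp((lam-mu)*T) = n_tips / rho, with
    mu = turnover * lam.  Rates per 100 Ma."""
    T = root_age / HUNDRED_MA
    net = math.log(max(n_tips / rho, 2.0) / 2.0) / T
    lam = net / (1.0 - turnover) if turnover < 1 else 1.0
    lam = max(lam, 1e-3)
    return BirthDeathParams(lam=lam, mu=turnover * lam, rho=rho)


# -- birth–death trees ------------------------------------------------------

def simulate_bd_forward(bd: BirthDeathParams, duration: float,
                        rng: np.random.Generator, n_start: int = 1) -> int:
    """Unconditioned forward birth–death: surviving-lineage count after
    ``duration`` (same time unit as the rates)."""
    n = n_start
    t = 0.0
    lam, mu = bd.lam, bd.mu
    while n > 0:
        total = n * (lam + mu)
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        if rng.random() < lam / (lam + mu):
            n += 1
        else:
            n -= 1
    return n


def simulate_bd_tree(bd: BirthDeathParams, root_age: float, n_tips: int,
                     seed: int, max_attempts: int = 10_000) -> TimeTree:
    """Ultrametric birth–death tree conditioned on the root age and on
    exactly ``n_tips`` surviving *sampled* tips.

    Forward simulation from the two root lineages with rejection: a draw is
    kept when, after uniform tip subsampling at fraction ``rho``, exactly
    ``n_tips`` tips remain and both root children retain at least one (so
    the root is the MRCA of the sample at exactly ``root_age``).  Rates are
    per 100 Ma; ``root_age`` is in Ma.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed)
    T = root_age / HUNDRED_MA
    lam, mu, rho = bd.lam, bd.mu, bd.rho
    for _ in range(max_attempts):
        nodes: list[dict] = [
            {"age": root_age, "children": [], "side": -1},  # root, id 0
        ]
        active: list[int] = []
        for side in range(2):
            nodes.append({"age": None, "children": [], "side": side,
                          "parent": 0, "start": 0.0})
            nodes[0]["children"].append(len(nodes) - 1)
            active.append(len(nodes) - 1)
        t = 0.0   # elapsed time since the root, in 100-Ma units
        ok = True
        while active:
            k = len(active)
            t += rng.exponential(1.0 / (k * (lam + mu)))
            if t >= T:
                break
            if len(nodes) > 40 * max(n_tips, 8):
                ok = False      # runaway clade; reject early
                break
            i = active[rng.integers(k)]
            if rng.random() < lam / (lam + mu):
                nodes[i]["age"] = root_age - t * HUNDRED_MA
                for _ in range(2):
                    nodes.append({"age": None, "children": [],
                                  "side": nodes[i]["side"], "parent": i})
                    nodes[i]["children"].append(len(nodes) - 1)
                active.remove(i)
                active.extend([len(nodes) - 2, len(nodes) - 1])
            else:
                nodes[i]["age"] = root_age - t * HUNDRED_MA
                nodes[i]["extinct"] = True
                active.remove(i)
        if not ok or not active:
            continue
        for i in active:
            nodes[i]["age"] = 0.0
        survivors = list(active)
        if rho < 1.0:
            sampled = [i for i in survivors if rng.random() < rho]
        else:
            sampled = survivors
        if len(sampled) != n_tips:
            continue
        sides = {nodes[i]["side"] for i in sampled}
        if sides != {0, 1}:
            continue
        return _prune_to_timetree(nodes, sampled)
    raise RuntimeError(
        f"could not condition a birth–death tree on {n_tips} sampled tips "
        f"at root age {root_age} within {max_attempts} attempts")


def _prune_to_timetree(nodes: list[dict], sampled: list[int]) -> TimeTree:
    keep = set(sampled)
    # sampled-descendant counts, tip -> root
    n_samp = [0] * len(nodes)
    for i in sampled:
        j = i
        n_samp[j] += 1
        while "parent" in nodes[j]:
            j = nodes[j]["parent"]
            n_samp[j] += 1

    def reduced_children(i: int) -> list[int]:
        out = []
        for c in nodes[i]["children"]:
            if n_samp[c] == 0:
                continue
            while len([g for g in nodes[c]["children"] if n_samp[g] > 0]) == 1 \
                    and c not in keep:
                c = next(g for g in nodes[c]["children"] if n_samp[g] > 0)
            out.append(c)
        return out

    tip_ids = sorted(sampled, key=lambda i: nodes[i]["age"])
    names = [f"t{k+1}" for k in range(len(tip_ids))]
    tip_index = {nid: k for k, nid in enumerate(tip_ids)}
    parent: list[int] = [-1] * len(tip_ids)
    ages: list[float] = [nodes[i]["age"] for i in tip_ids]

    internal_map: dict[int, int] = {}

    def build(i: int, parent_idx: int) -> None:
        if i in tip_index:
            parent[tip_index[i]] = parent_idx
            return
        idx = len(parent)
        parent.append(parent_idx)
        ages.append(nodes[i]["age"])
        internal_map[i] = idx
        for c in reduced_children(i):
            build(c, idx)

    build(0, -1)
    return TimeTree(names, np.array(parent), np.array(ages))


# -- branch rates -----------------------------------------------------------

def simulate_branch_rates(tree: TimeTree, clock_mean: float, sigma2: float,
                          seed: int) -> np.ndarray:
    """Per-node branch rates (slot for the branch above each non-root node;
    the root slot holds clock_mean and is unused).  Rates are i.i.d.
    lognormal with E[rate] = clock_mean, Var[log rate] = sigma2."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = np.random.default_rng(seed)
    rates = sample_branch_rates(tree.n_nodes, clock_mean, sigma2, rng)
    rates[tree.root] = clock_mean
    return rates


# -- sequence evolution ------------------------------------------------------

def _freqs_for_gc(gc: float) -> np.ndarray:
    if not 0 < gc < 1:
        raise ValueError("GC target must be in (0, 1)")
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def _gtr_generator(exch: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    s = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for x, (i, j) in zip(exch, pairs):
        s[i, j] = s[j, i] = x
    Q = s * freqs[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(freqs, np.diag(Q))
    if scale <= 0:
        raise ValueError("invalid rate matrix")
    return Q / scale


def _node_freqs(tree: TimeTree, base: np.ndarray,
                lineage_of: dict[str, str] | None,
                composition_map: dict[str, float] | None) -> np.ndarray:
    """Per-node equilibrium frequencies: the lineage's target from its stem
    node downward, the base frequencies elsewhere."""
    F = np.tile(base, (tree.n_nodes, 1))
    if not composition_map:
        return F
    if not lineage_of:
        raise ValueError("composition_map given but no lineage assignment")
    for lineage, gc in composition_map.items():
        tips = [tree.tip_index(t) for t, ln in lineage_of.items()
                if ln == lineage]
        if not tips:
            continue
        if len(tips) == 1:
            stem = tips[0]
        else:
            names = [tree.taxon_names[i] for i in tips]
            stem = tree.mrca(names[0], names[1])
            for nm in names[2:]:
                stem = tree.mrca(tree.taxon_names[tree.tips_below(stem)[0]], nm)
        target = _freqs_for_gc(gc)
        stack = [stem]
        while stack:
            v = stack.pop()
            F[v] = target
            stack.extend(tree.children[v])
    return F


def simulate_alignment(tree: TimeTree, rates: np.ndarray, model: SubstModel,
                       n_sites: int, seed: int,
                       lineage_of: dict[str, str] | None = None,
                       composition_map: dict[str, float] | None = None,
                       position_multipliers=(1.0, 1.0, 1.0),
                       gene_lengths: list[int] | None = None) -> SuperMatrix:
    """Evolve sequences root-to-tips under GTR+Gamma.

    ``rates`` are per-node branch rates (substitutions/site/100 Ma); branch
    lengths in substitutions are rate * age-difference/100.  When
    ``composition_map`` is given, exchangeabilities are held fixed and the
    equilibrium frequencies switch to each lineage's GC target on that
    lineage's stem branch (non-stationary composition).  Codon-position
    rate multipliers are normalised to mean 1.  Returns a SuperMatrix whose
    taxa are the tree's tips.
    """
    rng = np.random.default_rng(seed)
    n_sites = 3 * max(1, round(n_sites / 3))
    mult = np.asarray(position_multipliers, dtype=float)
    mult = mult / mult.mean()
    cat_rates, cat_w = model.category_rates()
    ncat = len(cat_rates)
    if model.p_invariant > 0:
        # invariant sites get rate 0 with probability p_invariant
        cat_rates = np.concatenate([[0.0], cat_rates])
        cat_w = np.concatenate([[model.p_invariant],
                                (1 - model.p_invariant) * cat_w])
        ncat += 1
    site_cat = rng.choice(ncat, size=n_sites, p=cat_w)
    site_pos = np.arange(n_sites) % 3
    site_rate = cat_rates[site_cat] * mult[site_pos]

    F = _node_freqs(tree, model.freqs, lineage_of, composition_map)
    seqs = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    root = tree.root
    seqs[root] = rng.choice(4, size=n_sites, p=F[root])

    order = [v for v in reversed(tree.postorder()) if v != root]
    groups = {}
    for key in sorted(set(zip(site_cat, site_pos))):
        groups[key] = np.flatnonzero((site_cat == key[0]) & (site_pos == key[1]))
    for v in order:
        p = tree.parent[v]
        dt = (tree.ages[p] - tree.ages[v]) / HUNDRED_MA
        Q = _gtr_generator(model.exch, F[v])
        rp = np.sqrt(F[v])
        B = 0.5 * ((Q * rp[:, None]) / rp[None, :]
                   + ((Q * rp[:, None]) / rp[None, :]).T)
        w, E = np.linalg.eigh(B)
        U = E / rp[:, None]
        Vinv = E.T * rp[None, :]
        blen = rates[v] * dt
        child = seqs[v]
        parent_states = seqs[p]
        for (ci, _pi), idx in groups.items():
            t_eff = blen * site_rate[idx[0]]
            if t_eff == 0:
                child[idx] = parent_states[idx]
                continue
            P = np.clip((U * np.exp(w * t_eff)[None, :]) @ Vinv, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            u = rng.random(len(idx))
            child[idx] = (u[:, None] > cum[parent_states[idx]]).sum(axis=1)
    alpha = np.array(list("ACGT"))
    tip_seqs = alpha[seqs[: tree.n_tips]]
    if gene_lengths is None:
        gene_lengths = [n_sites]
    if sum(gene_lengths) != n_sites:
        raise ValueError("gene lengths must sum to n_sites")
    boundaries = []
    off = 0
    for gi, gl in enumerate(gene_lengths):
        boundaries.append((f"gene{gi+1}", off, off + gl))
        off += gl
    return SuperMatrix(list(tree.taxon_names), tip_seqs, boundaries,
                       dict(lineage_of or {}))


# -- calibrations -----------------------------------------------------------

def make_calibrations(true_tree: TimeTree, node_selectors,
                      min_frac: float = 0.8, max_factor: float = 1.5,
                      pL: float = HARD_PL, pU: float = DEFAULT_PU,
                      mode: str = "bracket",
                      ranks: list[str] | None = None) -> list[CalibrationSpec]:
    """Calibration specs anchored on true nodes of a simulated tree.

    ``node_selectors`` is a list of internal node indices or (tipA, tipB)
    name pairs.  Bounds are min_frac*true_age and max_factor*true_age; with
    ``mode="tight_max"`` the maximum (max_factor < 1 allowed) deliberately
    falls below the true age, reproducing an over-constrained calibration.
    ``ranks`` optionally labels each spec for sensitivity filtering.
    """
    if mode not in ("bracket", "tight_max"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "bracket" and not (0 < min_frac <= 1 <= max_factor):
        raise ValueError("bracket mode needs 0 < min_frac <= 1 <= max_factor")
    specs = []
    for k, sel in enumerate(node_selectors):
        if isinstance(sel, (tuple, list)):
            node = true_tree.mrca(sel[0], sel[1])
        else:
            node = int(sel)
        if true_tree.is_tip(node):
            raise ValueError(f"selector {sel!r} resolves to a tip")
        tips = true_tree.tips_below(node)
        # pick one tip from each child clade so the MRCA resolves back
        c0, c1 = true_tree.children[node][0], true_tree.children[node][-1]
        a = true_tree.taxon_names[true_tree.tips_below(c0)[0]]
        b = true_tree.taxon_names[true_tree.tips_below(c1)[0]]
        age = float(true_tree.ages[node])
        t_min = min_frac * age
        t_max = max_factor * age
        if t_min >= t_max:
            raise ValueError(f"degenerate bounds for node {node}")
        style = "hard_min_soft_max" if pL <= HARD_PL else "soft_min_soft_max"
        specs.append(CalibrationSpec(
            name=f"cal{k+1}_node{node}", tip_a=a, tip_b=b,
            t_min=t_min, t_max=t_max, p_lower=pL, p_upper=pU, style=style,
            rank=(ranks[k] if ranks else "Phylum"),
            flags=frozenset(["tight_max"] if mode == "tight_max" else [])))
    return specs


def save_truth_json(path, tree: TimeTree, rates: np.ndarray,
                    config: SimConfig | None = None) -> None:
    """Sidecar recording the true simulation parameters."""
    payload = {
        "newick": tree.to_newick(),
        "internal_ages_Ma": tree.ages[tree.n_tips:].tolist(),
        "branch_rates": np.asarray(rates).tolist(),
    }
    if config is not None:
        payload["config"] = {
            "seed": config.seed, "n_tips": config.n_tips,
            "root_age": config.root_age, "clock_mean": config.clock_mean,
            "sigma2": config.sigma2, "n_sites": config.n_sites,
            "bd": {"lam": config.bd.lam, "mu": config.bd.mu,
                   "rho": config.bd.rho},
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def simulate_study(config: SimConfig, model: SubstModel | None = None,
                   lineage_of: dict[str, str] | None = None):
    """Tree + rates + alignment under one configuration.

    Returns ``(tree, rates, matrix)``; sub-seeds are derived from
    ``config.seed`` so the three stages are independently reproducible.
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    tree = simulate_bd_tree(config.bd, config.root_age, config.n_tips,
                            seeds[0])
    rates = simulate_branch_rates(tree, config.clock_mean, config.sigma2,
                                  seeds[1])
    if model is None:
        model = SubstModel(gamma_shape=config.gamma_shape,
                           p_invariant=config.p_invariant)
    matrix = simulate_alignment(
        tree, rates, model, config.n_sites, seeds[2],
        lineage_of=lineage_of, composition_map=config.composition_map,
        position_multipliers=config.position_multipliers)
    return tree, rates, matrix


# -- a structured calibration table mirroring a 55-fossil design -------------

def reference_calibration_table() -> list[CalibrationSpec]:
    """A synthetic 55-row calibration table with the marker structure the
    strategy builder expects: 22 phylum-level specs flagged ``strategy_A``
    (several of them ``early_embryophyta``, one ``crown_viridiplantae``),
    33 lower-rank additions, and three flagged ``uncertain_algal``.

    Anchor tips are placeholders (``xN``/``yN``): the table exercises
    strategy construction and sensitivity filtering without a tree.
    """
    specs: list[CalibrationSpec] = []

    def add(name, rank, t_min, t_max, flags=()):
        specs.append(CalibrationSpec(
            name=name, tip_a=f"x{len(specs)}", tip_b=f"y{len(specs)}",
            t_min=t_min, t_max=t_max, rank=rank, flags=frozenset(flags)))

    add("crown_Viridiplantae", "Kingdom", 469.0, 3500.0,
        ("strategy_A", "crown_viridiplantae"))
    add("crown_Embryophyta", "Kingdom", 470.0, 515.0,
        ("strategy_A", "early_embryophyta"))
    for i in range(4):
        add(f"early_embryophyte_{i+1}", "Phylum", 430.0 - 5 * i, 515.0,
            ("strategy_A", "early_embryophyta"))
    for i in range(16):
        add(f"phylum_fossil_{i+1}", "Phylum", 350.0 - 10 * i, 900.0 - 10 * i,
            ("strategy_A",))
    assert len(specs) == 22
    add("Pterospermella", "Class", 1200.0, 1900.0, ("uncertain_algal",))
    add("Palaeastrum", "Class", 750.0, 1500.0, ("uncertain_algal",))
    add("Trochiliscus", "Class", 405.0, 1000.0, ("uncertain_algal",))
    for i in range(7):
        add(f"class_fossil_{i+1}", "Class", 300.0 - 5 * i, 600.0)
    for i in range(11):
        add(f"order_fossil_{i+1}", "Order", 200.0 - 5 * i, 450.0)
    for i in range(8):
        add(f"family_fossil_{i+1}", "Family", 100.0 - 5 * i, 300.0)
    for i in range(4):
        add(f"genus_fossil_{i+1}", "Genus", 50.0 - 5 * i, 150.0)
    assert len(specs) == 55
    return specs
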