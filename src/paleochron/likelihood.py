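"""GTR+Gamma(+I) phylogenetic likelihood and its quadratic surrogate.

Exact likelihood on a fixed rooted topology by Felsenstein pruning, with
site-pattern compression and discrete-gamma rate mixing; branch-length
maximum-likelihood estimation; and the second-order Taylor surrogate
(log-likelihood, gradient g and Hessian H at the branch-length MLE) used
for approximate-likelihood divergence-time estimation.

Under a reversible model the likelihood depends on the unrooted tree only,
so only the *sum* of the two root-child branch lengths is identifiable.
All branch-length vectors here therefore live in "unrooted parameter"
space: one parameter per non-root node, except that the root's second
child shares (and is pooled into) the first child's parameter.  The
mapping from a rooted time tree is provided by :class:`BranchMap`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees import TimeTree

STATES = "ACGT"
# IUPAC nucleotide codes -> state-presence vectors for tip partials
AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT", ".": "ACGT",
}
_TIPVEC = {
    ch: np.array([1.0 if s in chars else 0.0 for s in STATES])
    for ch, chars in AMBIG.items()
}


def discrete_gamma_rates(shape: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of equal-probability discrete-gamma categories (mean 1).

    Category means computed analytically from the incomplete gamma
    function (the quantile/mean method): with X ~ Gamma(shape, scale=1/shape),
    the mean of X restricted to quantile bin i, times n_categories.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    cuts = gamma_dist.ppf(np.arange(1, k) / k, shape, scale=1.0 / shape)
    cuts = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X; X in (a,b)] = I(shape+1, b*shape) - I(shape+1, a*shape) for mean-1 gamma
    upper = gammainc(shape + 1, cuts[1:] * shape)
    upper[-1] = 1.0
    lower = gammainc(shape + 1, cuts[:-1] * shape)
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass
class SubstModel:
    """A scaled reversible nucleotide model (GTR+Gamma+I).

    ``exch`` are the six exchangeabilities in order AC, AG, AT, CG, CT, GT;
    ``freqs`` the equilibrium base frequencies (A, C, G, T).  The generator
    is scaled to mean rate 1 at stationarity, so branch lengths are in
    expected substitutions per site.
    """

    exch: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    gamma_shape: float | None = None
    n_categories: int = 4
    p_invariant: float = 0.0

    def __post_init__(self) -> None:
        self.exch = np.asarray(self.exch, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.exch <= 0):
            raise ValueError("exchange rates must be positive")
        if abs(self.freqs.sum() - 1.0) > 1e-8 or np.any(self.freqs <= 0):
            raise ValueError("frequencies must be positive and sum to 1")
        if not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("p_invariant must be in [0, 1)")

    @classmethod
    def jc(cls, **kw) -> "SubstModel":
        return cls(np.ones(6), np.full(4, 0.25), **kw)

    def rate_matrix(self) -> np.ndarray:
        """The scaled GTR generator Q (rows sum to 0, mean rate 1)."""
        s = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for x, (i, j) in zip(self.exch, pairs):
            s[i, j] = s[j, i] = x
        Q = s * self.freqs[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(self.freqs, np.diag(Q))
        return Q / scale

    def eigensystem(self):
        """Symmetric eigendecomposition of Q: returns (eigvals, U, Vinv)
        with Q = U diag(w) Vinv."""
        Q = self.rate_matrix()
        rp = np.sqrt(self.freqs)
        B = (Q * rp[:, None]) / rp[None, :]
        B = 0.5 * (B + B.T)
        w, E = np.linalg.eigh(B)
        U = E / rp[:, None]
        Vinv = E.T * rp[None, :]
        return w, U, Vinv

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the discrete mixture, excluding the invariant
        class; variable-class rates are scaled by 1/(1-p_inv) so the overall
        mean rate stays 1."""
        if self.gamma_shape is None:
            rates = np.array([1.0])
            weights = np.array([1.0])
        else:
            rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)
            weights = np.full(self.n_categories, 1.0 / self.n_categories)
        if self.p_invariant > 0:
            rates = rates / (1.0 - self.p_invariant)
        return rates, weights


def transition_matrix(model: SubstModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the scaled generator; rows sum to 1."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    w, U, Vinv = model.eigensystem()
    P = (U * np.exp(w * t)[None, :]) @ Vinv
    return np.clip(P, 0.0, None)


class BranchMap:
    """Mapping between a rooted tree's branches and unrooted parameters.

    ``param_of[node]`` gives the parameter index for the branch above each
    non-root node; the root's second child maps to the same parameter as
    the first child (their lengths are pooled).
    """

    def __init__(self, tree: TimeTree):
        self.tree = tree
        self.param_of = np.full(tree.n_nodes, -1, dtype=int)
        root_children = tree.children[tree.root]
        merged = root_children[1] if len(root_children) == 2 else None
        k = 0
        for v in range(tree.n_nodes):
            if v == tree.root or v == merged:
                continue
            self.param_of[v] = k
            k += 1
        if merged is not None:
            self.param_of[merged] = self.param_of[root_children[0]]
        self.merged_child = merged
        self.primary_child = root_children[0] if merged is not None else None
        self.n_params = k

    def from_rooted(self, rooted_blens: np.ndarray) -> np.ndarray:
        """Pool the two root-child branch lengths into one parameter."""
        b = np.zeros(self.n_params)
        for v in range(self.tree.n_nodes):
            p = self.param_of[v]
            if p >= 0:
                b[p] += rooted_blens[v]
        return b

    def to_node_lengths(self, params: np.ndarray) -> np.ndarray:
        """Expand parameters to per-node branch lengths; the pooled basal
        parameter is assigned wholly to the primary root child (likelihood
        is invariant to the split under a reversible model)."""
        b = np.zeros(self.tree.n_nodes)
        for v in range(self.tree.n_nodes):
            p = self.param_of[v]
            if p >= 0:
                b[v] = params[p]
        if self.merged_child is not None:
            b[self.merged_child] = 0.0
        return b


class PruningLikelihood:
    """Felsenstein-pruning likelihood evaluator on a fixed topology.

    Compresses alignment columns into unique site patterns once; evaluates
    total and per-site log-likelihoods for arbitrary branch lengths.
    """

    def __init__(self, tree: TimeTree, taxa: list[str], sequences,
                 model: SubstModel):
        self.tree = tree
        self.model = model
        seq_of = {t: np.asarray(list(s), dtype="<U1") if isinstance(s, str)
                  else np.asarray(s, dtype="<U1")
                  for t, s in zip(taxa, sequences)}
        missing = [t for t in tree.taxon_names if t not in seq_of]
        if missing:
            raise KeyError(f"taxa in tree missing from alignment: {missing}")
        chars = np.vstack([seq_of[t] for t in tree.taxon_names])
        self.n_sites = chars.shape[1]
        patterns, self.pattern_index, counts = np.unique(
            chars, axis=1, return_inverse=True, return_counts=True)
        self.weights = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        # tip partials: (n_tips, n_patterns, 4)
        self.tip_partials = np.empty((tree.n_tips, self.n_patterns, 4))
        for i in range(tree.n_tips):
            for j in range(self.n_patterns):
                ch = patterns[i, j]
                self.tip_partials[i, j] = _TIPVEC.get(ch, _TIPVEC["N"])
        self.postorder = [v for v in tree.postorder()]
        self.w, self.U, self.Vinv = model.eigensystem()
        self.rates, self.rate_weights = model.category_rates()

    def _transition_tensor(self, blens: np.ndarray) -> np.ndarray:
        """(n_nodes, n_cat, 4, 4) transition matrices for branch above each
        node (identity at root slot)."""
        t = blens[:, None] * self.rates[None, :]          # (nodes, cat)
        exps = np.exp(self.w[None, None, :] * t[:, :, None])
        P = np.einsum("ik,nck,kj->ncij", self.U, exps, self.Vinv)
        return np.clip(P, 0.0, None)

    def site_logliks(self, node_blens: np.ndarray) -> np.ndarray:
        """Per-site log-likelihoods (in original site order)."""
        tree, model = self.tree, self.model
        ncat = len(self.rates)
        P = self._transition_tensor(node_blens)
        partials: dict[int, np.ndarray] = {}
        scale_log = np.zeros(self.n_patterns)
        for v in self.postorder:
            if tree.is_tip(v):
                partials[v] = np.broadcast_to(
                    self.tip_partials[v][:, None, :],
                    (self.n_patterns, ncat, 4)).copy()
                continue
            acc = np.ones((self.n_patterns, ncat, 4))
            for c in tree.children[v]:
                down = np.einsum("cij,pcj->pci", P[c], partials[c])
                acc *= down
                del partials[c]
            m = acc.max(axis=(1, 2))
            m = np.where(m > 0, m, 1.0)
            acc /= m[:, None, None]
            scale_log += np.log(m)
            partials[v] = acc
        root = partials[tree.root]
        per_cat = np.einsum("j,pcj->pc", model.freqs, root)
        lik = per_cat @ self.rate_weights
        p_inv = model.p_invariant
        if p_inv > 0:
            # invariant-class site likelihood: zero-length tree
            inv = np.einsum("j,pj->p", model.freqs,
                            np.prod(self.tip_partials, axis=0))
            pat_lik = (1 - p_inv) * lik * np.exp(scale_log) + p_inv * inv
            pat_ll = np.log(pat_lik)
        else:
            pat_ll = np.log(lik) + scale_log
        return pat_ll[self.pattern_index]

    def loglik(self, node_blens: np.ndarray) -> float:
        return float(np.sum(self.site_logliks(node_blens)))


def pruning_loglik(tree: TimeTree, taxa, sequences, model: SubstModel,
                   node_blens: np.ndarray | None = None
                   ) -> tuple[float, np.ndarray]:
    """Total and per-site log-likelihood of an alignment on a tree.

    If ``node_blens`` is None, branch lengths are the tree's age
    differences (useful when the tree already carries substitution-scaled
    lengths via its ages).
    """
    ev = PruningLikelihood(tree, list(taxa), sequences, model)
    if node_blens is None:
        node_blens = tree.branch_lengths()
    site = ev.site_logliks(np.asarray(node_blens, dtype=float))
    return float(site.sum()), site


@dataclass
class LikelihoodSurrogate:
    """Second-order Taylor expansion of the log-likelihood around the MLE.

    ``b_hat``, ``gradient`` and ``hessian`` are in unrooted-parameter space
    (see module docstring); ``loglik`` is the exact value at ``b_hat``.
    """

    b_hat: np.ndarray
    gradient: np.ndarray
    hessian: np.ndarray
    loglik: float

    def __call__(self, b: np.ndarray) -> float:
        return approx_loglik(self, b)

    def to_json(self, path) -> None:
        payload = {
            "b_hat": self.b_hat.tolist(),
            "gradient": self.gradient.tolist(),
            "hessian": self.hessian.tolist(),
            "loglik": self.loglik,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LikelihoodSurrogate":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["b_hat"]), np.array(d["gradient"]),
                   np.array(d["hessian"]), float(d["loglik"]))


def approx_loglik(surrogate: LikelihoodSurrogate, b: np.ndarray) -> float:
    """logL(b_hat) + g.(b-b_hat) + (1/2)(b-b_hat)' H (b-b_hat)."""
    b = np.asarray(b, dtype=float)
    if b.shape != surrogate.b_hat.shape:
        raise ValueError("branch-length vector has wrong dimension")
    d = b - surrogate.b_hat
    return float(surrogate.loglik + surrogate.gradient @ d
                 + 0.5 * d @ surrogate.hessian @ d)


def mle_branch_lengths(tree: TimeTree, taxa, sequences, model: SubstModel,
                       b0: np.ndarray | None = None,
                       gtol: float = 1e-6,
                       max_iter: int = 500) -> LikelihoodSurrogate:
    """Maximise the likelihood over branch lengths; return the surrogate.

    L-BFGS-B on the unrooted branch parameters with a small positive lower
    bound; gradient and Hessian by central finite differences, Hessian
    symmetrised.  Non-convergence raises.
    """
    ev = PruningLikelihood(tree, list(taxa), sequences, model)
    bmap = BranchMap(tree)
    n = bmap.n_params

    def negll(params: np.ndarray) -> float:
        return -ev.loglik(bmap.to_node_lengths(params))

    if b0 is None:
        b0 = np.full(n, 0.1)
    b0 = np.asarray(b0, dtype=float)
    res = minimize(negll, b0, method="L-BFGS-B",
                   bounds=[(1e-8, 50.0)] * n,
                   options={"maxiter": max_iter, "ftol": 1e-12,
                            "gtol": gtol})
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RuntimeError(f"branch-length optimisation failed: {res.message}")
    b_hat = res.x
    g = _fd_gradient(lambda b: -negll(b), b_hat)
    H = _fd_hessian(lambda b: -negll(b), b_hat)
    return LikelihoodSurrogate(b_hat, g, H, -float(res.fun))


def _fd_gradient(f, x: np.ndarray) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        h = 1e-5 * max(abs(x[i]), 0.01)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 1e-9)
        g[i] = (f(xp) - f(xm)) / (xp[i] - xm[i])
    return g


def _fd_hessian(f, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian, symmetrised; step 1e-4*max(x_i, 0.01)."""
    n = len(x)
    h = np.array([1e-4 * max(abs(xi), 0.01) for xi in x])
    H = np.zeros((n, n))
    f0 = f(x)
    fp = np.zeros(n)
    fm = np.zeros(n)
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] = max(xm[i] - h[i], 1e-9)
        fp[i], fm[i] = f(xp), f(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / (h[i] ** 2)
    for i in range(n):
        for j in range(i + 1, n):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xmm = x.copy()
            xmm[i] = max(xmm[i] - h[i], 1e-9)
            xmm[j] = max(xmm[j] - h[j], 1e-9)
            H[i, j] = H[j, i] = (
                f(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + f(xmm)
            ) / (2 * h[i] * h[j])
    return 0.5 * (H + H.T)
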