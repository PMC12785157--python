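import math

import numpy as np
import pytest

from paleochron.likelihood import (
    BranchMap, PruningLikelihood, SubstModel, approx_loglik,
    discrete_gamma_rates, mle_branch_lengths, pruning_loglik,
    transition_matrix, LikelihoodSurrogate)
from paleochron.trees import TimeTree

STATE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def brute_force_loglik(tree, seqs_by_taxon, model, node_blens):
    """Exhaustive sum over all internal-state assignments and categories."""
    rates, weights = model.category_rates()
    internals = [v for v in tree.postorder() if not tree.is_tip(v)]
    n_sites = len(next(iter(seqs_by_taxon.values())))
    Ps = {}
    for ci, r in enumerate(rates):
        for v in range(tree.n_nodes):
            if v != tree.root:
                Ps[(ci, v)] = transition_matrix(model, node_blens[v] * r)
    total = 0.0
    for site in range(n_sites):
        tip_state = {i: STATE_INDEX[seqs_by_taxon[tree.taxon_names[i]][site]]
                     for i in range(tree.n_tips)}
        lik = 0.0
        for ci, w in enumerate(weights):
            for assign in np.ndindex(*([4] * len(internals))):
                states = dict(tip_state)
                for v, s in zip(internals, assign):
                    states[v] = s
                p = model.freqs[states[tree.root]]
                for v in range(tree.n_nodes):
                    if v != tree.root:
                        p *= Ps[(ci, v)][states[tree.parent[v]], states[v]]
                lik += w * p
        if model.p_invariant > 0:
            vals = list(tip_state.values())
            inv = model.freqs[vals[0]] if len(set(vals)) == 1 else 0.0
            lik = (1 - model.p_invariant) * lik + model.p_invariant * inv
        total += math.log(lik)
    return total


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        m = SubstModel(np.array([1, 2, 3, 4, 5, 6.0]),
                       np.array([0.1, 0.2, 0.3, 0.4]))
        assert np.allclose(transition_matrix(m, 0.0), np.eye(4))

    @pytest.mark.parametrize("t", [0.01, 0.3, 2.0, 11.0])
    def test_rows_sum_to_one(self, t):
        m = SubstModel(np.array([1, 2, 3, 4, 5, 6.0]),
                       np.array([0.1, 0.2, 0.3, 0.4]))
        assert np.allclose(transition_matrix(m, t).sum(axis=1), 1.0,
                           atol=1e-12)

    def test_long_branch_reaches_equilibrium(self):
        freqs = np.array([0.12, 0.28, 0.33, 0.27])
        m = SubstModel(np.array([1, 2, 3, 4, 5, 6.0]), freqs)
        P = transition_matrix(m, 50.0)
        assert np.allclose(P, np.tile(freqs, (4, 1)), atol=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(SubstModel.jc(), -0.1)

    def test_mean_rate_is_one(self):
        m = SubstModel(np.array([1, 2, 3, 4, 5, 6.0]),
                       np.array([0.1, 0.2, 0.3, 0.4]))
        Q = m.rate_matrix()
        assert -np.dot(m.freqs, np.diag(Q)) == pytest.approx(1.0)


class TestDiscreteGamma:
    @pytest.mark.parametrize("shape", [0.2, 0.5, 1.0, 5.0])
    def test_category_means_average_to_one(self, shape):
        r = discrete_gamma_rates(shape, 4)
        assert r.mean() == pytest.approx(1.0)
        assert np.all(np.diff(r) > 0)

    def test_large_shape_approaches_equal_rates(self):
        r = discrete_gamma_rates(200.0, 4)
        assert np.all(np.abs(r - 1) < 0.1)


class TestPruning:
    @pytest.mark.parametrize("model", [
        SubstModel.jc(),
        SubstModel(np.array([1, 2, 3, 4, 5, 6.0]),
                   np.array([0.1, 0.2, 0.3, 0.4])),
        SubstModel(np.array([1, 2, 3, 4, 5, 6.0]),
                   np.array([0.1, 0.2, 0.3, 0.4]), gamma_shape=0.5),
        SubstModel.jc(gamma_shape=0.8, p_invariant=0.2),
    ], ids=["jc", "gtr", "gtr_gamma", "jc_gamma_inv"])
    def test_matches_exhaustive_enumeration(self, quartet_tree, model, rng):
        n_sites = 20
        seqs = {t: "".join(rng.choice(list("ACGT"), n_sites))
                for t in quartet_tree.taxon_names}
        blens = np.array([0.1, 0.2, 0.15, 0.3, 0.25, 0.12, 0.0])
        total, site = pruning_loglik(quartet_tree, list(seqs),
                                     list(seqs.values()), model,
                                     node_blens=blens)
        oracle = brute_force_loglik(quartet_tree, seqs, model, blens)
        assert total == pytest.approx(oracle, abs=1e-9)
        assert site.sum() == pytest.approx(total, abs=1e-8)

    def test_single_taxon_base_case(self):
        tree = TimeTree(["a"], np.array([-1]), np.array([0.0]))
        model = SubstModel(np.array([1, 2, 3, 4, 5, 6.0]),
                           np.array([0.1, 0.2, 0.3, 0.4]))
        total, _ = pruning_loglik(tree, ["a"], ["ACGT"], model,
                                  node_blens=np.zeros(1))
        assert total == pytest.approx(float(np.sum(np.log(model.freqs))))

    def test_rerooting_leaves_loglik_unchanged(self, rng):
        # same unrooted tree, root placed on different edges of the central
        # branch (pulley principle for reversible models)
        model = SubstModel(np.array([1, 2, 3, 4, 5, 6.0]),
                           np.array([0.1, 0.2, 0.3, 0.4]), gamma_shape=0.7)
        seqs = {t: "".join(rng.choice(list("ACGT"), 50))
                for t in "abcd"}
        t1 = TimeTree.from_newick(
            "((a:0.10,b:0.20):0.05,(c:0.15,d:0.30):0.07);")
        # same unrooted tree, the whole central branch on the (c,d) side
        t2 = TimeTree.from_newick(
            "((a:0.10,b:0.20):0.12,(c:0.15,d:0.30):0.0);")
        ll1, _ = pruning_loglik(t1, list(seqs), list(seqs.values()), model)
        ll2, _ = pruning_loglik(t2, list(seqs), list(seqs.values()), model,
                                node_blens=t2.branch_lengths())
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_taxon_reordering_invariance(self, quartet_tree, rng):
        model = SubstModel.jc(gamma_shape=0.5)
        seqs = {t: "".join(rng.choice(list("ACGT"), 40))
                for t in quartet_tree.taxon_names}
        order1 = list(seqs)
        order2 = order1[::-1]
        ll1, _ = pruning_loglik(quartet_tree, order1,
                                [seqs[t] for t in order1], model)
        ll2, _ = pruning_loglik(quartet_tree, order2,
                                [seqs[t] for t in order2], model)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_missing_taxon_rejected(self, quartet_tree):
        with pytest.raises(KeyError):
            pruning_loglik(quartet_tree, ["a", "b", "c"],
                           ["AC", "AC", "AC"], SubstModel.jc())


class TestBranchMLE:
    def test_identical_sequences_boundary_mle(self):
        tree = TimeTree.from_newick("(a:0.1,b:0.1);")
        sur = mle_branch_lengths(tree, ["a", "b"], ["ACGTACGT" * 10] * 2,
                                 SubstModel.jc())
        assert sur.b_hat.sum() == pytest.approx(0.0, abs=1e-6)

    def test_jc_closed_form_distance(self):
        # 100 sites, 10 differences: b = -(3/4) ln(1 - 4*0.1/3)
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        tree = TimeTree.from_newick("(a:0.05,b:0.05);")
        sur = mle_branch_lengths(tree, ["a", "b"], [a, b], SubstModel.jc())
        expected = -0.75 * math.log(1 - 4 * 0.1 / 3)
        assert sur.b_hat.sum() == pytest.approx(expected, abs=1e-4)

    def test_interior_optimum_conditions(self, quartet_tree, rng):
        from paleochron.synthetic import simulate_alignment
        model = SubstModel.jc()
        rates = np.full(quartet_tree.n_nodes, 0.05)
        m = simulate_alignment(quartet_tree, rates, model, 500, seed=9)
        seqs = ["".join(r) for r in m.sequences]
        sur = mle_branch_lengths(quartet_tree, m.taxa, seqs, model)
        assert np.abs(sur.gradient).max() < 1e-3
        evals = np.linalg.eigvalsh(sur.hessian)
        assert np.all(evals <= 1e-6)

    def test_surrogate_quadratic_is_exact_for_quadratics(self):
        H = -np.array([[2.0, 0.3], [0.3, 1.0]])
        g = np.array([0.1, -0.2])
        sur = LikelihoodSurrogate(np.array([1.0, 2.0]), g, H, -5.0)
        b = np.array([1.3, 1.7])
        d = b - sur.b_hat
        assert approx_loglik(sur, b) == pytest.approx(
            -5.0 + g @ d + 0.5 * d @ H @ d)

    def test_dimension_mismatch_rejected(self):
        sur = LikelihoodSurrogate(np.zeros(3), np.zeros(3), np.eye(3), 0.0)
        with pytest.raises(ValueError):
            approx_loglik(sur, np.zeros(2))

    def test_surrogate_tracks_exact_likelihood_near_mle(self):
        from paleochron.synthetic import SimConfig, simulate_study
        cfg = SimConfig(seed=21, n_tips=6, root_age=600.0, sigma2=0.0,
                        n_sites=600, gamma_shape=None)
        tree, rates, matrix = simulate_study(cfg)
        model = SubstModel(gamma_shape=None)
        seqs = ["".join(r) for r in matrix.sequences]
        sur = mle_branch_lengths(tree, matrix.taxa, seqs, model)
        ev = PruningLikelihood(tree, matrix.taxa, seqs, model)
        bmap = BranchMap(tree)
        rng = np.random.default_rng(4)
        exacts, approxs = [], []
        for _ in range(20):
            b = sur.b_hat * (1 + 0.2 * (rng.random(len(sur.b_hat)) - 0.5))
            exacts.append(ev.loglik(bmap.to_node_lengths(b)))
            approxs.append(approx_loglik(sur, b))
        exacts, approxs = np.array(exacts), np.array(approxs)
        err = np.abs(exacts - approxs)
        # second-order surrogate: within ±10% of the MLE the error stays
        # far below 1% of the log-likelihood scale (and small absolutely)
        assert err.max() < 0.01 * abs(sur.loglik)
        assert err.max() < 0.06

    def test_surrogate_json_round_trip(self, tmp_path):
        sur = LikelihoodSurrogate(np.array([0.1, 0.2]), np.zeros(2),
                                  -np.eye(2), -12.5)
        p = tmp_path / "sur.json"
        sur.to_json(p)
        back = LikelihoodSurrogate.from_json(p)
        assert np.allclose(back.b_hat, sur.b_hat)
        assert back.loglik == sur.loglik
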