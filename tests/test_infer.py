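"""Log-densities against independent oracles; MH kernels against closed forms."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from phyloval import infer, simulate
from phyloval.infer import (
    ModelSpec,
    NarrowExchangeKernel,
    NodeSlideKernel,
    RandomWalkKernel,
    RootScaleKernel,
    ScaleKernel,
    TreeScaleKernel,
    UpDownKernel,
    burnin_thin,
    coalescent_log_density,
    ess,
    lognormal_log_density,
    mh_run,
    phylo_bm_log_density,
    thin_indices,
    yule_log_density,
)
from phyloval.simulate import BMParams, CoalescentParams, LogNormalParams
from phyloval.treekit import parse_newick, rf_distance, root_height

LN = LogNormalParams(-3.25, 0.2)


# ----------------------------------------------------------------------
# densities
# ----------------------------------------------------------------------

class TestLogNormalDensity:
    def test_normalization_by_quadrature(self):
        val, err = integrate.quad(lambda x: math.exp(lognormal_log_density(x, LN)), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_scipy(self):
        for x in (0.01, 0.05, 0.2):
            assert lognormal_log_density(x, LN) == pytest.approx(
                stats.lognorm.logpdf(x, s=LN.s, scale=math.exp(LN.m)), abs=1e-12
            )

    def test_mode_by_derivative_sign_change(self):
        mode = math.exp(LN.m - LN.s**2)
        eps = 1e-6
        up = lognormal_log_density(mode * (1 + eps), LN)
        dn = lognormal_log_density(mode * (1 - eps), LN)
        at = lognormal_log_density(mode, LN)
        assert at > up and at > dn

    def test_plugin_value_at_log_mean(self):
        x = math.exp(LN.m)
        expected = -math.log(x * LN.s * math.sqrt(2 * math.pi))
        assert lognormal_log_density(x, LN) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_support(self):
        assert lognormal_log_density(0.0, LN) == -math.inf
        assert lognormal_log_density(-1.0, LN) == -math.inf


class TestYuleDensity:
    def test_single_lineage_no_event_probability(self):
        t = parse_newick("(A:3.0);")
        assert yule_log_density(t, 0.7) == pytest.approx(-0.7 * 3.0)

    def test_two_tip_closed_form(self):
        # split at time t before present, origin tau: log b - b(tau - t) - 2bt
        tau, tsplit, b = 5.0, 2.0, 0.4
        t = parse_newick(f"(A:{tsplit},B:{tsplit}):{tau - tsplit};")
        expected = math.log(b) - b * (tau - tsplit) - 2 * b * tsplit
        assert yule_log_density(t, b) == pytest.approx(expected)

    def test_origin_below_root_raises(self):
        t = parse_newick("(A:2.0,B:2.0);")
        with pytest.raises(Exception):
            yule_log_density(t, 1.0, origin_age=1.0)

    def test_importance_sampling_identity(self, rng):
        # E_{b1}[ f(tree; b2)/f(tree; b1) ] = 1 over the shared tree space
        b1, b2, tau = 0.6, 0.75, 2.0
        ratios = []
        for _ in range(4000):
            t = simulate.simulate_yule_origin(b1, tau, rng)
            ratios.append(math.exp(yule_log_density(t, b2) - yule_log_density(t, b1)))
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / math.sqrt(ratios.size)
        assert ratios.mean() == pytest.approx(1.0, abs=4 * se)


class TestCoalescentDensity:
    def test_two_tip_exponential(self):
        t = parse_newick("(A:1.3,B:1.3);")
        ne = 2.0
        assert coalescent_log_density(t, ne) == pytest.approx(
            math.log(1 / ne) - 1.3 / ne
        )

    def test_label_permutation_invariance(self, rng):
        t = simulate.simulate_coalescent(CoalescentParams(6), rng)
        d1 = coalescent_log_density(t, 1.0)
        perm = {f"t{i+1}": f"t{(i+3) % 6 + 1}" for i in range(6)}
        for tip in t.tips():
            tip.label = perm[tip.label]
        assert coalescent_log_density(t, 1.0) == pytest.approx(d1)

    def test_four_tip_hand_enumeration(self):
        # ages: 0 -> a1 (k=4), a1 -> a2 (k=3), a2 -> a3 (k=2)
        a1, a2, a3, ne = 0.3, 0.8, 2.0, 1.5
        nwk = (
            f"((A:{a1},B:{a1}):{a3 - a1},(C:{a2},D:{a2}):{a3 - a2}):0.0;"
        )
        t = parse_newick(nwk)
        expected = (
            -3 * math.log(ne)
            - (4 * 3 / (2 * ne)) * a1
            - (3 * 2 / (2 * ne)) * (a2 - a1)
            - (2 * 1 / (2 * ne)) * (a3 - a2)
        )
        assert coalescent_log_density(t, ne) == pytest.approx(expected)


def _bm_covariance(tree, r):
    """Dense shared-path covariance oracle, built from pairwise MRCA depths."""
    tips = tree.tips()
    heights = tree.heights()
    h = root_height(tree)

    def mrca_age(a, b):
        anc_a = set()
        node = a
        while node is not None:
            anc_a.add(id(node))
            node = node.parent
        node = b
        while id(node) not in anc_a:
            node = node.parent
        return heights[node]

    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = h - (mrca_age(tips[i], tips[j]) if i != j else 0.0)
    return tips, r * C


class TestPhyloBMDensity:
    def test_two_tip_independence(self):
        tree = parse_newick("(A:1.5,B:1.5);")
        y = {"A": 0.3, "B": -1.1}
        p = BMParams(0.7, 0.1)
        expected = sum(
            stats.norm.logpdf(y[k], loc=0.1, scale=math.sqrt(0.7 * 1.5)) for k in y
        )
        assert phylo_bm_log_density(y, tree, p) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_pruning_matches_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate.simulate_coalescent(CoalescentParams(5), rng)
        r, y0 = 0.8, 0.5
        traits = simulate.simulate_phylo_bm(tree, BMParams(r, y0), rng)
        tips, C = _bm_covariance(tree, r)
        y = np.array([traits[t.label] for t in tips])
        oracle = stats.multivariate_normal.logpdf(y, mean=np.full(len(y), y0), cov=C)
        assert phylo_bm_log_density(traits, tree, BMParams(r, y0)) == pytest.approx(
            oracle, abs=1e-8
        )

    def test_scaling_identity(self, rng):
        # log f(y; r) = log f(y/sqrt(c); r/c) - (s/2) log c
        tree = simulate.simulate_coalescent(CoalescentParams(6), rng)
        traits = simulate.simulate_phylo_bm(tree, BMParams(1.0, 0.0), rng)
        c = 2.7
        scaled = {k: v / math.sqrt(c) for k, v in traits.items()}
        lhs = phylo_bm_log_density(traits, tree, BMParams(1.0, 0.0))
        rhs = (
            phylo_bm_log_density(scaled, tree, BMParams(1.0 / c, 0.0))
            - (len(traits) / 2) * math.log(c)
        )
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_zero_length_cherry_is_singular(self):
        tree = parse_newick("((A:0.0,B:0.0):1.0,C:1.0);")
        with pytest.raises(ValueError, match="singular"):
            phylo_bm_log_density({"A": 0, "B": 0, "C": 1}, tree, BMParams(1.0))


# ----------------------------------------------------------------------
# proposal kernels
# ----------------------------------------------------------------------

class TestScaleKernel:
    def test_unit_tuning_is_identity(self, rng):
        k = ScaleKernel("x", tuning=1.0)
        scalars, tree, lhr = k.propose({"x": 2.0}, None, rng)
        assert scalars["x"] == 2.0 and lhr == 0.0

    def test_hastings_ratio_identity_on_grid(self):
        # q(x|x') = q(x'|x) * exp(log HR) for the log-uniform multiplier
        a, x = 0.5, 1.7
        c = 1.0 / (2 * abs(math.log(a)))  # density of log u

        def q(src, dst):
            u = dst / src
            if not (a <= u <= 1 / a):
                return 0.0
            return c / dst  # p(log u) / |d(dst)/d(log u)|

        for u in (0.55, 0.8, 1.0, 1.3, 1.9):
            xp = x * u
            assert q(xp, x) == pytest.approx(q(x, xp) * math.exp(math.log(u)), rel=1e-12)

    def test_mh_with_scale_kernel_recovers_lognormal_target(self):
        rng = np.random.default_rng(5)
        model = ModelSpec(scalar_priors={"x": lambda v: lognormal_log_density(v, LN)})
        trace = mh_run(
            model, {"x": math.exp(LN.m)}, None, [(1.0, ScaleKernel("x", 0.75))],
            40_000, 20, rng,
        )
        draws = burnin_thin(trace.table["x"].to_numpy(), 0.1, 300)
        ks = stats.kstest(np.log(draws), "norm", args=(LN.m, LN.s))
        assert ks.pvalue > 0.01


class TestTreeKernels:
    def _prior_chain(self, s, kernels, chain, rng, ne=1.0):
        model = ModelSpec(
            scalar_priors={},
            tree_prior=lambda t, sc: coalescent_log_density(t, ne),
        )
        init = simulate.simulate_coalescent(CoalescentParams(s, ne), rng)
        return mh_run(model, {}, init, kernels, chain, 10, rng)

    def test_node_slide_falls_back_to_root_scale_on_two_tips(self, rng):
        tree = parse_newick("(A:1.0,B:1.0);")
        _, new_tree, lhr = NodeSlideKernel().propose({}, tree, rng)
        assert root_height(new_tree) != pytest.approx(1.0)  # root moved
        assert lhr != 0.0 or root_height(new_tree) != 1.0

    def test_moves_preserve_validity(self, rng):
        tree = simulate.simulate_coalescent(CoalescentParams(10), rng)
        kernels = [NodeSlideKernel(), RootScaleKernel(), TreeScaleKernel(),
                   NarrowExchangeKernel()]
        for i in range(2000):
            k = kernels[i % len(kernels)]
            prop = k.propose({}, tree, rng)
            if prop is None:
                continue
            _, tree, _ = prop
            if i % 100 == 0:
                tree.validate()
        tree.validate()

    def test_prior_sampling_recovers_coalescent_root_height(self):
        # "sampling from the prior": kernels must leave the prior invariant
        rng = np.random.default_rng(17)
        kernels = [(3.0, NodeSlideKernel()), (1.0, RootScaleKernel(0.75)),
                   (2.0, NarrowExchangeKernel()), (1.0, TreeScaleKernel(0.9))]
        means = []
        for seed in range(6):
            trace = self._prior_chain(5, kernels, 12_000, np.random.default_rng(seed))
            means.append(burnin_thin(trace.table.root_height.to_numpy(), 0.2, 300).mean())
        # E[root height] = 2 Ne (1 - 1/s) = 1.6
        assert np.mean(means) == pytest.approx(1.6, abs=0.12)

    def test_narrow_exchange_reaches_all_three_topologies_uniformly(self):
        rng = np.random.default_rng(23)
        kernels = [(2.0, NodeSlideKernel()), (1.0, RootScaleKernel(0.75)),
                   (2.0, NarrowExchangeKernel())]
        trace = self._prior_chain(3, kernels, 30_000, rng)
        refs = [parse_newick(n) for n in
                ["((t1:1,t2:1):1,t3:2);", "((t1:1,t3:1):1,t2:2);", "((t2:1,t3:1):1,t1:2);"]]
        counts = np.zeros(3, dtype=int)
        trees = [parse_newick(nk) for nk in trace.trees[500:]]
        for t in trees:
            for j, ref in enumerate(refs):
                if rf_distance(t, ref) == 0:
                    counts[j] += 1
                    break
        assert counts.sum() == len(trees)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_five_tip_rf_distribution_matches_direct_simulation(self):
        # MCMC prior samples vs direct simulator, via RF distance to a fixed tree
        rng = np.random.default_rng(31)
        ref = simulate.simulate_coalescent(CoalescentParams(5), rng)
        kernels = [(3.0, NodeSlideKernel()), (1.0, RootScaleKernel(0.75)),
                   (2.0, NarrowExchangeKernel()), (1.0, TreeScaleKernel(0.9))]
        trace = self._prior_chain(5, kernels, 40_000, rng)
        mcmc_rf = np.array([
            rf_distance(parse_newick(nk), ref) for nk in trace.trees[400::4]
        ])
        direct_rf = np.array([
            rf_distance(simulate.simulate_coalescent(CoalescentParams(5), rng), ref)
            for _ in range(4000)
        ])
        cats = [0, 2, 4, 6]
        obs = np.array([(mcmc_rf == c).sum() for c in cats])
        expected_p = np.array([(direct_rf == c).sum() for c in cats]) / direct_rf.size
        # guard against zero expected categories
        keep = expected_p > 0
        chi = stats.chisquare(obs[keep], expected_p[keep] / expected_p[keep].sum() * obs[keep].sum())
        assert chi.pvalue > 0.01

    def test_updown_preserves_prior(self):
        # joint (scalar, heights) move must leave a joint prior invariant:
        # x ~ LogNormal, tree ~ coalescent, independent
        rng = np.random.default_rng(41)
        model = ModelSpec(
            scalar_priors={"x": lambda v: lognormal_log_density(v, LN)},
            tree_prior=lambda t, sc: coalescent_log_density(t, 1.0),
        )
        init = simulate.simulate_coalescent(CoalescentParams(5), rng)
        kernels = [(2.0, ScaleKernel("x", 0.75)), (2.0, NodeSlideKernel()),
                   (1.0, RootScaleKernel(0.75)), (2.0, UpDownKernel("x", 0.8))]
        trace = mh_run(model, {"x": 0.04}, init, kernels, 40_000, 20, rng)
        draws = burnin_thin(trace.table, 0.1, 400)
        ks = stats.kstest(np.log(draws["x"]), "norm", args=(LN.m, LN.s))
        assert ks.pvalue > 0.01
        se = draws.root_height.std(ddof=1) / math.sqrt(ess(trace.table.root_height[180:]))
        assert draws.root_height.mean() == pytest.approx(1.6, abs=4 * se)


# ----------------------------------------------------------------------
# the MH engine
# ----------------------------------------------------------------------

class TestMhRun:
    def test_conjugate_normal_posterior(self):
        # prior N(0,1), one obs y ~ N(theta,1): posterior N(y/2, 1/2)
        y = 1.4

        def prior(t):
            return stats.norm.logpdf(t, 0, 1)

        model = ModelSpec(
            scalar_priors={"theta": prior},
            data_log_density=lambda sc, tr: stats.norm.logpdf(y, sc["theta"], 1.0),
        )
        means, variances, ess_total = [], [], 0.0
        for seed in range(4):
            trace = mh_run(model, {"theta": 0.0}, None,
                           [(1.0, RandomWalkKernel("theta", 1.0))], 20_000, 10,
                           np.random.default_rng(seed))
            post = trace.table["theta"][200:]
            means.append(post.mean())
            variances.append(post.var(ddof=1))
            ess_total += ess(post)
        se = math.sqrt(0.5 / ess_total)
        assert np.mean(means) == pytest.approx(y / 2, abs=3 * se)
        assert np.mean(variances) == pytest.approx(0.5, rel=0.1)

    def test_prior_only_run_recovers_lognormal(self):
        rng = np.random.default_rng(8)
        model = ModelSpec(scalar_priors={"lam": lambda v: lognormal_log_density(v, LN)})
        trace = mh_run(model, {"lam": 0.05}, None, [(1.0, ScaleKernel("lam", 0.75))],
                       40_000, 20, rng)
        draws = burnin_thin(trace.table["lam"].to_numpy(), 0.1, 300)
        assert stats.kstest(np.log(draws), "norm", args=(LN.m, LN.s)).pvalue > 0.01

    def test_zero_weight_topology_moves_freeze_topology(self, rng):
        init = simulate.simulate_coalescent(CoalescentParams(6), rng)
        model = ModelSpec(scalar_priors={},
                          tree_prior=lambda t, sc: coalescent_log_density(t, 1.0))
        trace = mh_run(model, {}, init,
                       [(1.0, NodeSlideKernel()), (1.0, RootScaleKernel())],
                       2000, 20, rng)
        for nk in trace.trees:
            assert rf_distance(parse_newick(nk), init) == 0

    def test_infinite_initial_density_refused(self, rng):
        model = ModelSpec(scalar_priors={"x": lambda v: -math.inf})
        with pytest.raises(ValueError, match="initial"):
            mh_run(model, {"x": 1.0}, None, [(1.0, ScaleKernel("x"))], 100, 10, rng)

    def test_trace_shape_and_iteration_indices(self, rng):
        model = ModelSpec(scalar_priors={"x": lambda v: lognormal_log_density(v, LN)})
        trace = mh_run(model, {"x": 0.04}, None, [(1.0, ScaleKernel("x"))], 1000, 100, rng)
        assert len(trace.table) == 1000 // 100 + 1
        assert list(trace.table.Sample) == sorted(trace.table.Sample)

    def test_acceptance_bookkeeping(self, rng):
        model = ModelSpec(scalar_priors={"x": lambda v: lognormal_log_density(v, LN)})
        trace = mh_run(model, {"x": 0.04}, None, [(1.0, ScaleKernel("x"))], 500, 50, rng)
        acc, prop = trace.acceptance["scale[x]"]
        assert prop == 500 and 0 < acc <= prop


# ----------------------------------------------------------------------
# ESS and thinning
# ----------------------------------------------------------------------

class TestEss:
    def test_iid_normal_ess_near_n(self):
        ok = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            e = ess(g.normal(size=10_000))
            ok += 0.8 <= e / 10_000 <= 1.2
        assert ok >= 95

    def test_ar1_ess_matches_theory(self):
        # AR(1) with rho: ESS/N -> (1 - rho) / (1 + rho) = 1/3 at rho = 0.5
        g = np.random.default_rng(2)
        n, rho = 200_000, 0.5
        eps = g.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        assert ess(x) == pytest.approx(n / 3, rel=0.2)

    def test_constant_chain_raises(self):
        with pytest.raises(ValueError):
            ess(np.ones(100))

    def test_too_short_chain_raises(self):
        with pytest.raises(ValueError):
            ess(np.arange(5))


class TestBurninThin:
    def test_fig_caption_numbers(self):
        idx = thin_indices(10_000, 0.10, 200)
        assert len(idx) == 200
        assert idx[0] == 1000 and idx[-1] == 9999  # rows 1001..10000, 1-based
        assert len(np.unique(idx)) == 200

    def test_identity_when_L_equals_available(self):
        idx = thin_indices(100, 0.0, 100)
        assert np.array_equal(idx, np.arange(100))

    def test_single_sample_is_last_row(self):
        assert thin_indices(50, 0.1, 1).tolist() == [49]

    def test_oversized_L_raises_with_guidance(self):
        with pytest.raises(ValueError, match="ESS"):
            thin_indices(100, 0.5, 60)

    def test_tracelog_thinning_keeps_rows_and_trees_aligned(self, rng):
        model = ModelSpec(
            scalar_priors={},
            tree_prior=lambda t, sc: coalescent_log_density(t, 1.0),
        )
        init = simulate.simulate_coalescent(CoalescentParams(4), rng)
        trace = mh_run(model, {}, init, [(1.0, NodeSlideKernel())], 500, 10, rng)
        th = burnin_thin(trace, 0.1, 20)
        assert len(th.table) == 20 and len(th.trees) == 20
        assert th.table.root_height.iloc[-1] == pytest.approx(
            root_height(parse_newick(th.trees[-1]))
        )


class TestTraceIO:
    def test_roundtrip(self, tmp_path, rng):
        model = ModelSpec(
            scalar_priors={},
            tree_prior=lambda t, sc: coalescent_log_density(t, 1.0),
        )
        init = simulate.simulate_coalescent(CoalescentParams(4), rng)
        trace = mh_run(model, {}, init, [(1.0, NodeSlideKernel())], 200, 10, rng)
        infer.write_trace(trace, tmp_path / "t.log", tmp_path / "t.trees")
        back = infer.read_trace(tmp_path / "t.log", tmp_path / "t.trees")
        assert len(back.table) == len(trace.table)
        assert back.trees == trace.trees
        assert back.table.posterior.iloc[3] == pytest.approx(trace.table.posterior.iloc[3])
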