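"""Penalized-likelihood dating engine: objective, optimizer, CV, bootstrap."""

import numpy as np
import pytest
from scipy.optimize import minimize

import plchron as pc
from plchron import pl_dating as pld
from plchron.branch_lengths import SubstitutionModel
from plchron.phylo_core import CalibrationSet


# ---------------------------------------------------------------------------
# Independent oracle: the objective coded directly from the formula,
# for the fixed 3-taxon shape ((A,B),C) with root age T and internal age a.
# ---------------------------------------------------------------------------

def oracle_objective_3taxon(x, a, T, rates, lam):
    """x = counts for edges (A, B, internal, C); rates likewise."""
    rA, rB, rI, rC = rates
    ts = np.array([a, a, T - a, T])
    ll = 0.0
    for xe, r, t in zip(x, rates, ts):
        rt = r * t
        ll += (xe * np.log(rt) if xe > 0 else 0.0) - rt
    phi = (rI - rA) ** 2 + (rI - rB) ** 2  # parent-edge differences
    phi += (rI - rC) ** 2 / 2.0            # sample variance at the root
    return ll - lam * phi


def three_taxon_problem(bA=0.02, bB=0.03, bI=0.04, bC=0.10, T=100.0,
                        L=1000.0):
    tree = pc.read_tree(f"((A:{bA},B:{bB}):{bI},C:{bC});")
    cals = CalibrationSet().add({"A", "B", "C"}, T, T)
    x = np.array([bA, bB, bI, bC]) * L
    return tree, cals, x, T, L


class TestObjective:
    def test_matches_independent_formula(self):
        tree, cals, x, T, L = three_taxon_problem()
        prob = pld._PLProblem(tree, cals, L)
        # postorder: A, B, AB, C, root — map explicit ages/rates
        a = 40.0
        rates_by_node = np.zeros(prob.n)
        by_label = {}
        for i, nd in enumerate(prob.nodes):
            key = frozenset(
                lf.taxon.label for lf in nd.leaf_iter()
            )
            by_label[key] = i
        ages = np.zeros(prob.n)
        ages[by_label[frozenset("ABC")]] = T
        ages[by_label[frozenset("AB")]] = a
        r = {"A": 0.3, "B": 0.5, "AB": 0.7, "C": 0.4}
        rates_by_node[by_label[frozenset("A")]] = r["A"]
        rates_by_node[by_label[frozenset("B")]] = r["B"]
        rates_by_node[by_label[frozenset("AB")]] = r["AB"]
        rates_by_node[by_label[frozenset("C")]] = r["C"]
        for lam in (0.0, 1.0, 100.0):
            got = pc.pl_objective(tree, ages, rates_by_node, lam, L)
            # oracle edge order: A, B, internal, C
            want = oracle_objective_3taxon(
                x, a, T, [r["A"], r["B"], r["AB"], r["C"]], lam
            )
            assert got == pytest.approx(want, rel=1e-12)

    def test_single_edge_stationarity_value(self):
        # at the ML point r*t = x the Poisson term is x ln x - x
        tree = pc.read_tree("(A:0.05,B:0.0);")
        L = 1000.0
        x = 0.05 * L
        prob = pld._PLProblem(tree, None, L, require_bounded_root=False)
        ages = np.zeros(prob.n)
        ages[prob.root] = 10.0
        rates = np.zeros(prob.n)
        for i in prob.edges:
            rates[i] = x / 10.0 if prob.x[i] > 0 else 1e-9
        got = pc.pl_objective(tree, ages, rates, 0.0, L)
        # the zero-count edge contributes -r*t ~ -1e-8
        assert got == pytest.approx(x * np.log(x) - x, rel=1e-6)

    def test_penalty_null_when_rates_equal(self):
        tree, cals, x, T, L = three_taxon_problem()
        prob = pld._PLProblem(tree, cals, L)
        ages = np.zeros(prob.n)
        ages[prob.root] = T
        internal = [i for i in prob.internals if i != prob.root][0]
        ages[internal] = 30.0
        rates = np.zeros(prob.n)
        rates[prob.edges] = 0.42
        vals = {lam: pc.pl_objective(tree, ages, rates, lam, L)
                for lam in (0.0, 1.0, 1e6)}
        assert vals[0.0] == pytest.approx(vals[1e6], rel=1e-14)

    def test_negative_duration_rejected(self):
        tree, cals, x, T, L = three_taxon_problem()
        prob = pld._PLProblem(tree, cals, L)
        ages = np.zeros(prob.n)
        ages[prob.root] = 10.0
        internal = [i for i in prob.internals if i != prob.root][0]
        ages[internal] = 50.0  # older than the root
        rates = np.zeros(prob.n)
        rates[prob.edges] = 1.0
        with pytest.raises(pld.PLError):
            pc.pl_objective(tree, ages, rates, 1.0, L)

    @pytest.mark.parametrize("lam", [0.0, 10.0, 1e5])
    def test_analytic_gradient_matches_numeric(self, lam):
        rng = np.random.default_rng(0)
        chron = pc.simulate_chronogram(n_taxa=6, root_age=100, seed=1)
        rated = pc.apply_rates(
            chron, pc.RateScenario(base_rate=2e-3, sigma=0.3), seed=1
        )
        phy = pc.to_phylogram(rated, 5000, "poisson", seed=1)
        cals = CalibrationSet().add(
            [lf.taxon.label for lf in phy.leaf_node_iter()], 90, 110
        )
        prob = pld._PLProblem(phy, cals, 5000)
        x0 = prob.initial_params()
        x0[: prob.n_internal] = np.clip(
            x0[: prob.n_internal] + rng.uniform(-0.2, 0.2, prob.n_internal),
            0.05, 0.95,
        )
        x0[prob.n_internal:] += rng.normal(0, 0.3, prob.n_edges)
        _, g = prob.neg_objective_and_grad(x0, lam)
        num = np.zeros_like(g)
        for i in range(len(x0)):
            e = np.zeros_like(x0)
            e[i] = 1e-7
            num[i] = (
                prob.neg_objective_and_grad(x0 + e, lam)[0]
                - prob.neg_objective_and_grad(x0 - e, lam)[0]
            ) / 2e-7
        assert np.allclose(g, num, rtol=1e-4, atol=1e-6)


class TestFitPL:
    def test_clock_limit_lambda_invariant(self):
        # strictly clock-like data with a fixed root age: ages are the
        # path-proportional truth, identical across lambda
        chron = pc.template_chronogram(50.0)
        rated = pc.apply_rates(chron, pc.RateScenario(base_rate=1e-3))
        phy = pc.to_phylogram(rated, 55_000, "expectation")
        cals = CalibrationSet().add(
            [lf.taxon.label for lf in phy.leaf_node_iter()], 475, 475
        )
        for lam in (0.01, 1.0, 1e6):
            fit = pc.fit_pl(phy, cals, lam, 55_000, restarts=2, seed=0,
                            ftol=1e-15, maxiter=100_000)
            assert fit.node_age(pc.INGROUP_TAXA) == pytest.approx(
                50.0, rel=1e-4
            )
            assert fit.node_age(
                set(pc.INGROUP_TAXA) | set(pc.SISTER_TAXA)
            ) == pytest.approx(400.0, rel=1e-4)

    @pytest.mark.parametrize("lam", [0.1, 10.0, 1000.0])
    def test_matches_brute_force_grid_oracle(self, lam):
        tree, cals, x, T, L = three_taxon_problem()
        fit = pc.fit_pl(tree, cals, lam, L, restarts=4, seed=2,
                        ftol=1e-15, maxiter=50000)

        def neg_given_age(a):
            def f(logr):
                return -oracle_objective_3taxon(
                    x, a, T, np.exp(logr), lam
                )
            best = None
            for start in ([0, 0, 0, 0], np.log([0.2, 0.3, 0.4, 1.0])):
                res = minimize(f, np.asarray(start, float),
                               method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12,
                                        "maxiter": 20000})
                if best is None or res.fun < best:
                    best = res.fun
            return best

        grid = np.linspace(0.5, T - 0.5, 120)
        coarse = np.array([neg_given_age(a) for a in grid])
        a_best = grid[int(np.argmin(coarse))]
        fine = np.linspace(max(a_best - 2, 0.01), min(a_best + 2, T), 60)
        vals = np.array([neg_given_age(a) for a in fine])
        oracle_best = -vals.min()
        assert fit.objective == pytest.approx(oracle_best, rel=1e-3)

    def test_calibration_bounds_respected(self):
        b = pc.paper_scenario("nuclear-like", L=10_000)
        phy = pc.to_phylogram(
            pc.apply_rates(b.chronogram, b.scenario, seed=4),
            b.L, "poisson", seed=4,
        )
        fit = pc.fit_pl(phy, b.calibrations, 10.0, b.L, restarts=2, seed=0)
        iso = fit.node_age(set(pc.INGROUP_TAXA) | set(pc.SISTER_TAXA))
        root = fit.chronogram.seed_node.age
        assert 358.0 - 1e-6 <= iso <= 485.0 + 1e-6
        assert 421.0 - 1e-6 <= root <= 485.0 + 1e-6
        pc.phylo_core.check_chronogram(fit.chronogram)

    def test_infeasible_calibrations_rejected(self):
        tree, _, _, _, L = three_taxon_problem()
        cals = CalibrationSet().add({"A", "B"}, 50, 60).add(
            {"A", "B", "C"}, 10, 20
        )
        with pytest.raises(pld.PLError, match="infeasible|minimum"):
            pc.fit_pl(tree, cals, 1.0, L)

    def test_unbounded_root_rejected(self):
        tree, _, _, _, L = three_taxon_problem()
        cals = CalibrationSet().add({"A", "B", "C"}, 10, None)
        with pytest.raises(pld.PLError, match="unbounded"):
            pc.fit_pl(tree, cals, 1.0, L)

    def test_scaling_invariance(self):
        # b -> c*b with L -> L/c leaves x and hence the fit unchanged
        b = pc.paper_scenario("nuclear-like", L=20_000)
        phy = pc.to_phylogram(
            pc.apply_rates(b.chronogram, b.scenario, seed=6),
            b.L, "poisson", seed=6,
        )
        c = 7.0
        scaled = phy.clone(depth=1)
        for nd in scaled.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = nd.edge.length * c
        f1 = pc.fit_pl(phy, b.calibrations, 100.0, b.L, restarts=1, seed=0,
                       ftol=1e-15, maxiter=100_000)
        f2 = pc.fit_pl(scaled, b.calibrations, 100.0, b.L / c,
                       restarts=1, seed=0, ftol=1e-15, maxiter=100_000)
        assert np.allclose(f1.ages, f2.ages, rtol=1e-4, atol=1e-3)
        assert f1.objective == pytest.approx(f2.objective, rel=1e-9)

    def test_rate_variance_non_increasing_in_lambda(self):
        b = pc.paper_scenario("chloroplast-like", L=20_000)
        phy = pc.to_phylogram(
            pc.apply_rates(b.chronogram, b.scenario, seed=8),
            20_000, "poisson", seed=8,
        )
        prob = pld._PLProblem(phy, b.calibrations, 20_000)
        # continuation from the clock end downward: at weak smoothing the
        # surface is ridge-like and fresh starts can otherwise stall in
        # local basins that spuriously break monotonicity
        variances, warm = [], None
        for lam in pld.default_lambda_grid()[::-1]:
            fit = pc.fit_pl(phy, b.calibrations, lam, 20_000, restarts=2,
                            seed=0, warm_start=warm, _problem=prob)
            warm = np.concatenate([
                prob.p_from_ages(fit.ages),
                np.log(np.maximum(fit.rates[prob.edges], 1e-300)),
            ])
            variances.append(np.var(fit.rates[prob.edges]))
        variances = variances[::-1]  # ascending lambda order
        diffs = np.diff(variances)
        assert np.all(diffs <= 1e-6 * (1 + np.abs(variances[:-1])))


class TestGradientCheck:
    def test_clock_data_passes(self):
        chron = pc.simulate_chronogram(n_taxa=6, root_age=100, seed=9)
        rated = pc.apply_rates(chron, pc.RateScenario(base_rate=2e-3))
        phy = pc.to_phylogram(rated, 10_000, "expectation")
        cals = CalibrationSet().add(
            [lf.taxon.label for lf in phy.leaf_node_iter()], 100, 100
        )
        for lam in (0.1, 1e4):
            fit = pc.fit_pl(phy, cals, lam, 10_000, restarts=3, seed=0)
            assert pc.gradient_check(fit)

    def test_flat_ridge_fails(self):
        # lambda = 0 with a free internal node: any internal age fits the
        # data equally well once rates compensate -> no single optimum
        tree, cals, _, _, L = three_taxon_problem()
        fit = pc.fit_pl(tree, cals, 0.0, L, restarts=6, seed=3)
        assert not pc.gradient_check(fit)

    def test_stable_across_seeds(self):
        chron = pc.simulate_chronogram(n_taxa=5, root_age=80, seed=12)
        rated = pc.apply_rates(chron, pc.RateScenario(base_rate=2e-3))
        phy = pc.to_phylogram(rated, 8_000, "poisson", seed=12)
        cals = CalibrationSet().add(
            [lf.taxon.label for lf in phy.leaf_node_iter()], 80, 80
        )
        outcomes = {
            pc.gradient_check(
                pc.fit_pl(phy, cals, 100.0, 8_000, restarts=3, seed=s)
            )
            for s in range(4)
        }
        assert len(outcomes) == 1


class TestCrossValidate:
    def test_too_few_tips_rejected(self):
        tree, cals, _, _, L = three_taxon_problem()
        with pytest.raises(pld.PLError, match="4 terminal"):
            pc.cross_validate(tree, cals, L)

    def test_clock_data_flat_curve(self):
        chron = pc.simulate_chronogram(n_taxa=6, root_age=100, seed=20)
        rated = pc.apply_rates(chron, pc.RateScenario(base_rate=2e-3))
        phy = pc.to_phylogram(rated, 20_000, "expectation")
        cals = CalibrationSet().add(
            [lf.taxon.label for lf in phy.leaf_node_iter()], 100, 100
        )
        lams = np.array([1.0, 100.0, 1e4])
        cv = pc.cross_validate(phy, cals, 20_000, lambdas=lams, seed=0)
        spread = cv.scores.max() - cv.scores.min()
        assert spread <= 1e-3 * (1 + cv.scores.min())

    def test_heterogeneity_direction(self):
        # erratic chloroplast-like variation tolerates more smoothing than
        # the near-clock nuclear-like regime
        opts = {}
        for name in ("chloroplast-like", "nuclear-like"):
            b = pc.paper_scenario(name, L=30_000)
            phy = pc.to_phylogram(
                pc.apply_rates(b.chronogram, b.scenario, seed=1),
                b.L, "poisson", seed=1,
            )
            opts[name] = pc.cross_validate(
                phy, b.calibrations, b.L, seed=1
            ).optimum
        assert opts["chloroplast-like"] > opts["nuclear-like"]


class TestSmoothingSweep:
    def test_clock_constant_age(self):
        chron = pc.simulate_chronogram(n_taxa=6, root_age=100, seed=30)
        rated = pc.apply_rates(chron, pc.RateScenario(base_rate=2e-3))
        phy = pc.to_phylogram(rated, 20_000, "expectation")
        tips = [lf.taxon.label for lf in phy.leaf_node_iter()]
        cals = CalibrationSet().add(tips, 100, 100)
        target = tips[:3]
        node = pc.mrca(phy, target)
        clade = [lf.taxon.label for lf in node.leaf_iter()]
        sweep = pc.smoothing_sweep(
            phy, cals, 20_000, clade,
            lambdas=np.array([0.1, 10.0, 1e4]), seed=0,
        )
        assert sweep["age"].max() - sweep["age"].min() < 1e-3 * 100


class TestBootstrap:
    def _clock_setup(self, L, seed=40):
        chron = pc.simulate_chronogram(n_taxa=6, root_age=100, seed=seed)
        rated = pc.apply_rates(chron, pc.RateScenario(base_rate=2e-3))
        phy = pc.to_phylogram(rated, L, "expectation")
        aln = pc.simulate_alignment(phy, SubstitutionModel.jc(), L, seed=seed)
        tips = [lf.taxon.label for lf in phy.leaf_node_iter()]
        cals = CalibrationSet().add(tips, 100, 100)
        node = pc.mrca(chron, tips[:2])
        clade = [lf.taxon.label for lf in node.leaf_iter()]
        truth = node.age
        return phy, aln, cals, clade, truth

    def test_interval_narrow_at_large_L(self):
        phy, aln, cals, clade, truth = self._clock_setup(L=20_000)
        bd = pc.bootstrap_dates(
            aln, phy, cals, clade, lam=100.0, n=8, seed=0,
            model=SubstitutionModel.jc(), optimize_model=False,
        )
        width = bd.interval[1] - bd.interval[0]
        assert width < 0.15 * truth
        assert bd.n_failed == 0

    def test_deterministic_given_seed(self):
        phy, aln, cals, clade, _ = self._clock_setup(L=3_000)
        kw = dict(lam=100.0, n=4, seed=7, model=SubstitutionModel.jc(),
                  optimize_model=False)
        b1 = pc.bootstrap_dates(aln, phy, cals, clade, **kw)
        b2 = pc.bootstrap_dates(aln, phy, cals, clade, **kw)
        assert np.array_equal(b1.ages, b2.ages)
        assert b1.interval == b2.interval
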