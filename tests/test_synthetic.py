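"""Chronogram, rate-scenario, phylogram and alignment simulation."""

import numpy as np
import pytest

import plchron as pc
from plchron.branch_lengths import SubstitutionModel
from plchron.diagnostics import lognormal_qq
from plchron.phylo_core import check_chronogram, clade_leaves, mrca
from plchron.synthetic_data import (
    RateScenario,
    apply_rates,
    paper_scenario,
    simulate_alignment,
    simulate_chronogram,
    template_chronogram,
    to_phylogram,
)


class TestChronogramSimulation:
    def test_minimal_structure(self):
        t = simulate_chronogram(n_taxa=3, root_age=100, seed=0)
        assert len(list(t.leaf_node_iter())) == 3
        assert t.seed_node.age == pytest.approx(100.0)
        check_chronogram(t)

    def test_template_crown_configurable(self):
        for crown in (20.0, 50.0, 120.0):
            t = simulate_chronogram(model="template", crown_age=crown)
            assert mrca(t, pc.INGROUP_TAXA).age == pytest.approx(crown)
            # the rest of the tree is untouched
            assert mrca(
                t, set(pc.INGROUP_TAXA) | set(pc.SISTER_TAXA)
            ).age == pytest.approx(400.0)
            check_chronogram(t)

    def test_template_shape(self, template):
        assert len(list(template.leaf_node_iter())) == 32
        assert template.seed_node.age == pytest.approx(475.0)
        crown = mrca(template, pc.INGROUP_TAXA)
        assert len(clade_leaves(crown)) == 6
        stem = crown.parent_node.age - crown.age
        assert stem == pytest.approx(350.0)

    def test_yule_lineage_growth(self):
        # pure birth at rate b for time tau: E[N] = e^(b*tau)
        b, tau, reps = 1.0, 1.5, 400
        counts = [
            len(list(simulate_chronogram(
                max_time=tau, birth_rate=b, death_rate=0.0, seed=s
            ).leaf_node_iter()))
            for s in range(reps)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(reps)
        assert abs(mean - np.exp(b * tau)) < 3 * se + 0.05

    def test_reproducible_per_seed(self):
        t1 = simulate_chronogram(n_taxa=8, root_age=50, seed=42)
        t2 = simulate_chronogram(n_taxa=8, root_age=50, seed=42)
        assert pc.write_tree(t1) == pc.write_tree(t2)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_chronogram(n_taxa=2, root_age=10)
        with pytest.raises(ValueError):
            simulate_chronogram(n_taxa=5, root_age=-1)
        with pytest.raises(ValueError):
            simulate_chronogram(model="star", n_taxa=5)


class TestApplyRates:
    def test_deterministic_no_dispersion(self, template):
        rated = apply_rates(template, RateScenario(base_rate=1e-3), seed=0)
        rates = [nd.rate for nd in rated.preorder_node_iter()
                 if nd.parent_node]
        assert np.allclose(rates, 1e-3)

    def test_clade_multiplier_ratio(self, template):
        sc = RateScenario(
            base_rate=1e-3,
            clade_multipliers={frozenset(pc.SISTER_TAXA): 4.5},
        )
        rated = apply_rates(template, sc, seed=0)
        node = mrca(rated, pc.SISTER_TAXA)
        inside = [nd.rate for nd in node.preorder_iter() if nd is not node]
        outside = [
            nd.rate for nd in rated.preorder_node_iter()
            if nd.parent_node is not None and nd.rate != inside[0]
        ]
        assert np.mean(inside) / np.mean(outside) == pytest.approx(4.5)
        # stem edge itself not touched by a clade multiplier
        assert node.rate == pytest.approx(1e-3)

    def test_stem_multiplier_targets_single_edge(self, template):
        sc = RateScenario(
            base_rate=1e-3,
            stem_multipliers={frozenset(pc.INGROUP_TAXA): 0.25},
        )
        rated = apply_rates(template, sc, seed=0)
        node = mrca(rated, pc.INGROUP_TAXA)
        assert node.rate == pytest.approx(0.25e-3)
        others = [nd.rate for nd in rated.preorder_node_iter()
                  if nd.parent_node is not None and nd is not node]
        assert np.allclose(others, 1e-3)

    def test_lognormal_dispersion_qq(self, template):
        draws = []
        sc = RateScenario(base_rate=1e-3, sigma=0.3)
        for seed in range(200):
            rated = apply_rates(template, sc, seed=seed)
            draws.extend(
                nd.rate for nd in rated.preorder_node_iter()
                if nd.parent_node
            )
        report = lognormal_qq(np.array(draws))
        assert report.r_squared > 0.99

    def test_contradictory_clade_definitions_rejected(self, template):
        # two different taxon sets resolving to the same clade with
        # different factors are ambiguous
        sc = RateScenario(
            base_rate=1e-3,
            clade_multipliers={
                frozenset(pc.INGROUP_TAXA): 2.0,
                frozenset(("I_lacustris", "I_echinospora")): 3.0,
            },
        )
        # these resolve to different nodes: allowed (nested)
        apply_rates(template, sc, seed=0)
        sc2 = RateScenario(
            base_rate=1e-3,
            clade_multipliers={
                frozenset(pc.INGROUP_TAXA): 2.0,
                frozenset((("I_coromandelina", "I_histrix"))): 3.0,
            },
        )
        with pytest.raises(ValueError, match="contradictory"):
            apply_rates(template, sc2, seed=0)

    def test_nested_multipliers_multiply(self, template):
        sc = RateScenario(
            base_rate=1e-3,
            clade_multipliers={
                frozenset(pc.INGROUP_TAXA): 2.0,
                frozenset(("I_lacustris", "I_echinospora")): 3.0,
            },
        )
        rated = apply_rates(template, sc, seed=0)
        leaf = next(nd for nd in rated.leaf_node_iter()
                    if nd.taxon.label == "I_lacustris")
        assert leaf.rate == pytest.approx(6e-3)

    def test_bit_reproducible(self, template):
        sc = RateScenario(base_rate=1e-3, sigma=0.4)
        r1 = apply_rates(template, sc, seed=9)
        r2 = apply_rates(template, sc, seed=9)
        v1 = [nd.rate for nd in r1.preorder_node_iter() if nd.parent_node]
        v2 = [nd.rate for nd in r2.preorder_node_iter() if nd.parent_node]
        assert v1 == v2


class TestToPhylogram:
    def test_expectation_exact(self, template):
        rated = apply_rates(template, RateScenario(base_rate=1e-3), seed=0)
        phy = to_phylogram(rated, 1000, "expectation")
        stem = mrca(phy, pc.INGROUP_TAXA)
        assert stem.edge.length == pytest.approx(350 * 1e-3)

    def test_poisson_moments(self):
        r, t, L, reps = 1e-3, 100.0, 2000, 3000
        tree = pc.read_tree("(A:1,B:1);")
        for nd in tree.preorder_node_iter():
            nd.age = t if nd.parent_node is None else 0.0
            if nd.parent_node is not None:
                nd.rate = r
        draws = np.array([
            next(
                nd.edge.length
                for nd in to_phylogram(tree, L, "poisson", seed=s)
                .leaf_node_iter()
            )
            for s in range(reps)
        ])
        expect = r * t
        se_mean = np.sqrt(expect / L / reps)
        assert abs(draws.mean() - expect) < 3 * se_mean
        assert draws.var() == pytest.approx(expect / L, rel=0.15)

    def test_large_L_converges_to_expectation(self, template):
        rated = apply_rates(template, RateScenario(base_rate=1e-3), seed=0)
        exp = to_phylogram(rated, 1, "expectation")
        poi = to_phylogram(rated, 10_000_000, "poisson", seed=1)
        e = np.array([nd.edge.length for nd in exp.preorder_node_iter()
                      if nd.parent_node])
        p = np.array([nd.edge.length for nd in poi.preorder_node_iter()
                      if nd.parent_node])
        assert np.allclose(p, e, rtol=0.02, atol=1e-4)


class TestSimulateAlignment:
    def test_zero_length_star_identical(self):
        tree = pc.read_tree("(A:0,B:0,C:0);")
        aln = simulate_alignment(tree, SubstitutionModel.jc(), 50, seed=0)
        assert (aln.data == aln.data[0]).all()

    def test_jc_mismatch_closed_form(self):
        t, L = 0.3, 40_000
        tree = pc.read_tree(f"(A:{t / 2},B:{t / 2});")
        aln = simulate_alignment(tree, SubstitutionModel.jc(), L, seed=1)
        mismatch = (aln.data[0] != aln.data[1]).mean()
        expect = 0.75 * (1 - np.exp(-4 * t / 3))
        se = np.sqrt(expect * (1 - expect) / L)
        assert abs(mismatch - expect) < 3 * se

    def test_stationary_base_composition(self, gtr_model):
        tree = pc.read_tree("(A:0.02,B:0.02);")
        L = 50_000
        aln = simulate_alignment(tree, gtr_model, L, seed=2)
        freqs = np.array([
            (aln.data == b).mean() for b in (b"A", b"C", b"G", b"T")
        ])
        for got, want in zip(freqs, gtr_model.frequencies):
            se = np.sqrt(want * (1 - want) / (2 * L))
            assert abs(got - want) < 4 * se

    def test_reproducible(self, template):
        rated = apply_rates(template, RateScenario(base_rate=1e-3), seed=0)
        phy = to_phylogram(rated, 500, "expectation")
        a1 = simulate_alignment(phy, SubstitutionModel.jc(), 500, seed=3)
        a2 = simulate_alignment(phy, SubstitutionModel.jc(), 500, seed=3)
        assert (a1.data == a2.data).all()


class TestPaperScenarios:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            paper_scenario("mitochondrial-like")

    def test_calibration_feasibility(self):
        for name in ("chloroplast-like", "nuclear-like"):
            b = paper_scenario(name)
            iso = mrca(
                b.chronogram, set(pc.INGROUP_TAXA) | set(pc.SISTER_TAXA)
            )
            root = b.chronogram.seed_node
            cals = sorted(
                b.calibrations, key=lambda c: len(c.taxa)
            )
            assert cals[0].min_age <= iso.age <= cals[0].max_age
            assert cals[1].min_age <= root.age <= cals[1].max_age

    def test_default_lengths(self):
        assert paper_scenario("chloroplast-like").L == 55_000
        assert paper_scenario("nuclear-like").L == 694_000
        assert paper_scenario("nuclear-like", L=50_000).L == 50_000

    def test_stochastic_path_ratio_centred_on_target(self):
        # with dispersion the per-seed ratio is noisy but centred
        b = paper_scenario("chloroplast-like")
        ratios = []
        for seed in range(25):
            phy = to_phylogram(
                apply_rates(b.chronogram, b.scenario, seed=seed),
                b.L, "expectation",
            )
            ratios.append(
                pc.clade_path_ratio(phy, pc.SISTER_TAXA, pc.INGROUP_TAXA)
            )
        assert np.median(ratios) == pytest.approx(4.5, rel=0.35)
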