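"""Region assignment, continuity flows, volume metrics, pendelluft decomposition."""

import numpy as np
import pytest

import cardioflow as cf
from cardioflow.airflow import (
    aggregate_flow_decomposition,
    assign_regions_to_terminals,
    compute_terminal_flows,
    compute_volume_metrics,
    decompose_bifurcation_flow,
    propagate_flows,
)


class TestAssignment:
    def test_single_terminal_gets_everything(self):
        seg = cf.AirwaySegment(0, None, [], [0, 0, 0], [0, 0, 5.0], 0.5, 0)
        tree = cf.AirwayTree({0: seg})
        centers = np.random.default_rng(0).uniform(-5, 5, (20, 3))
        assert np.all(assign_regions_to_terminals(centers, tree) == 0)

    def test_tie_breaks_to_lower_airway_id(self, single_bifurcation_tree):
        # equidistant from both terminal end-points (2,0,8) and (-2,0,8)
        centers = np.array([[0.0, 0.0, 8.0]])
        assert assign_regions_to_terminals(centers, single_bifurcation_tree)[0] == 1

    def test_matches_brute_force_nearest_endpoint(self, small_tree):
        rng = np.random.default_rng(1)
        centers = rng.uniform(-8, 8, (100, 3))
        got = assign_regions_to_terminals(centers, small_tree)
        term = small_tree.terminal_ids
        ends = np.array([small_tree[i].distal_point for i in term])
        for c, g in zip(centers, got):
            d = np.linalg.norm(ends - c, axis=1)
            assert g == term[int(np.argmin(d))]

    def test_empty_regions_rejected(self, small_tree):
        with pytest.raises(ValueError):
            assign_regions_to_terminals(np.zeros((0, 3)), small_tree)


class TestTerminalFlows:
    def test_constant_volumes_give_zero_flow(self):
        t = np.linspace(0, 400, 19, endpoint=False)
        v = np.ones((3, 19)) * 5.0
        fs = compute_terminal_flows(v, t, np.array([7, 7, 7]), period_ms=400.0)
        assert np.allclose(fs.flows[7], 0.0)

    def test_sinusoidal_volume_gives_cosine_flow(self):
        # V = V0 + A sin(wt) -> Q = A w cos(wt).  Second-order central
        # differences at n samples/cycle carry a relative error of
        # (2*pi/n)^2 / 6, i.e. ~1.8% at 19 phases; assert that bound.
        t = np.linspace(0, 400, 19, endpoint=False)
        w = 2 * np.pi / 400.0
        a = 10.0
        v = (100.0 + a * np.sin(w * t))[None, :]
        fs = compute_terminal_flows(v, t, np.array([0]), period_ms=400.0)
        expect = a * w * np.cos(w * t)
        bound = (2 * np.pi / 19) ** 2 / 6
        assert np.max(np.abs(fs.flows[0] - expect)) < 1.05 * bound * a * w
        # and convergence: 100 phases/cycle is well under 0.1%
        t2 = np.linspace(0, 400, 100, endpoint=False)
        v2 = (100.0 + a * np.sin(w * t2))[None, :]
        fs2 = compute_terminal_flows(v2, t2, np.array([0]), period_ms=400.0)
        assert np.max(np.abs(fs2.flows[0] - a * w * np.cos(w * t2))) < 1e-3 * a * w

    def test_two_regions_sum_linearly(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 400, 19, endpoint=False)
        v = rng.uniform(1, 2, (2, 19))
        both = compute_terminal_flows(v, t, np.array([0, 0]), period_ms=400.0)
        one = compute_terminal_flows(v[:1], t, np.array([0]), period_ms=400.0)
        two = compute_terminal_flows(v[1:], t, np.array([0]), period_ms=400.0)
        assert np.allclose(both.flows[0], one.flows[0] + two.flows[0])

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError):
            compute_terminal_flows(np.ones((1, 1)), np.array([0.0]), np.array([0]))


class TestPropagation:
    def test_single_bifurcation_sum(self, single_bifurcation_tree):
        t = np.array([0.0, 1.0])
        term = cf.FlowSeries(
            times=t, flows={1: np.array([1.0, 1.0]), 2: np.array([2.0, 2.0])}
        )
        fs = propagate_flows(single_bifurcation_tree, term)
        assert np.allclose(fs.flows[0], 3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_subtree_sum_oracle_random_trees(self, seed):
        tree = cf.generate_airway_tree(n_generations=6, seed=seed)  # 32 terminals
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 400, 10)
        # integer-valued flows keep floating-point sums exact regardless of
        # summation order, so "exact" equality with the oracle is well defined
        term = cf.FlowSeries(
            times=t,
            flows={
                i: rng.integers(-100, 100, 10).astype(float)
                for i in tree.terminal_ids
            },
        )
        fs = propagate_flows(tree, term)

        def descendants(aid):
            seg = tree[aid]
            if not seg.child_ids:
                return [aid]
            return sum((descendants(c) for c in seg.child_ids), [])

        for aid in tree.segments:
            expect = sum(term.flows[d] for d in descendants(aid))
            assert np.array_equal(fs.flows[aid], expect)

    def test_negating_terminals_negates_everything(self, small_tree):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 400, 5)
        flows = {i: rng.standard_normal(5) for i in small_tree.terminal_ids}
        fs_pos = propagate_flows(small_tree, cf.FlowSeries(times=t, flows=flows))
        fs_neg = propagate_flows(
            small_tree, cf.FlowSeries(times=t, flows={i: -q for i, q in flows.items()})
        )
        for aid in small_tree.segments:
            assert np.allclose(fs_neg.flows[aid], -fs_pos.flows[aid])

    def test_missing_terminal_trace_rejected(self, single_bifurcation_tree):
        term = cf.FlowSeries(times=np.array([0.0]), flows={1: np.array([1.0])})
        with pytest.raises(ValueError, match="2"):
            propagate_flows(single_bifurcation_tree, term)


class TestVolumeMetrics:
    def test_constant_volumes_zero_tidal(self):
        t = np.linspace(0, 400, 19)
        m = compute_volume_metrics(np.ones((4, 19)), t, 150.0)
        assert m.tidal_volume_ml == 0.0

    def test_sinusoidal_tidal_closed_form(self):
        t = np.linspace(0, 2 * np.pi, 400)
        v = (1000.0 + 100.0 * np.sin(t))[None, :]  # mm^3
        m = compute_volume_metrics(v, t, 150.0)
        assert abs(m.tidal_volume_ml - 0.2) < 1e-3

    def test_minute_volume_is_product(self):
        t = np.linspace(0, 2 * np.pi, 400)
        v = (1000.0 + 100.0 * np.sin(t))[None, :]
        m = compute_volume_metrics(v, t, 150.0)
        assert abs(m.minute_volume_ml - 30.0) < 0.2

    def test_displacement_path_length(self):
        t = np.array([0.0, 1.0, 2.0])
        v = np.ones((1, 3))
        pos = np.array([[[0, 0, 0], [3, 4, 0], [3, 4, 12]]], dtype=float)
        m = compute_volume_metrics(v, t, 150.0, region_displacements=pos)
        assert np.allclose(m.displacement_um, 5 + 12)


class TestDecomposition:
    @pytest.mark.parametrize(
        "qa,qb,qc,tot,bulk,pend",
        [
            (1.0, 0.5, 0.5, 2.0, 2.0, 0.0),      # pure bulk
            (0.0, 1.0, -1.0, 2.0, 0.0, 2.0),     # pure pendelluft
            (1.0, 2.0, -1.0, 4.0, 2.0, 2.0),     # mixed
        ],
    )
    def test_flow_regimes(self, qa, qb, qc, tot, bulk, pend):
        q_tot, q_bulk, q_pend = decompose_bifurcation_flow(qa, qb, qc)
        assert (q_tot, q_bulk, q_pend) == (tot, bulk, pend)

    def test_identity_and_nonnegativity_random(self):
        rng = np.random.default_rng(4)
        qb = rng.standard_normal(1000)
        qc = rng.standard_normal(1000)
        q_tot, q_bulk, q_pend = decompose_bifurcation_flow(qb + qc, qb, qc)
        assert np.array_equal(q_tot, q_bulk + q_pend)
        assert np.all(q_pend >= 0) and np.all(q_bulk >= 0)
        assert np.all(q_pend <= q_tot + 1e-15)

    def test_continuity_violation_raises_with_label(self):
        with pytest.raises(ValueError, match="bif7"):
            decompose_bifurcation_flow(1.0, 2.0, 2.0, label="bif7")


class TestAggregation:
    def _series(self, tree, terminal_flows, period=400.0, n=40):
        t = np.linspace(0, period, n, endpoint=False)
        flows = {i: f(t) for i, f in terminal_flows.items()}
        return propagate_flows(
            tree, cf.FlowSeries(times=t, flows=flows, period_ms=period)
        )

    def test_synchronous_expansion_has_zero_pendelluft(self, small_tree):
        rng = np.random.default_rng(5)
        amps = {i: rng.uniform(0.5, 2) for i in small_tree.terminal_ids}
        fs = self._series(
            small_tree,
            {i: (lambda t, a=a: a * np.sin(2 * np.pi * t / 400)) for i, a in amps.items()},
        )
        dec = aggregate_flow_decomposition(fs, small_tree)
        assert dec.q_pend < 1e-12 * dec.q_tot
        assert dec.pendelluft_fraction < 1e-12

    def test_antiphase_terminals_have_zero_bulk(self, single_bifurcation_tree):
        fs = self._series(
            single_bifurcation_tree,
            {
                1: lambda t: np.sin(2 * np.pi * t / 400),
                2: lambda t: -np.sin(2 * np.pi * t / 400),
            },
        )
        dec = aggregate_flow_decomposition(fs, single_bifurcation_tree)
        assert dec.q_bulk < 1e-14
        assert abs(dec.pendelluft_fraction - 1.0) < 1e-12

    def test_time_reversal_leaves_components_unchanged(self, small_tree):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 400, 40, endpoint=False)
        flows = {i: rng.standard_normal(40) for i in small_tree.terminal_ids}
        fwd = propagate_flows(
            small_tree, cf.FlowSeries(times=t, flows=flows, period_ms=400.0)
        )
        rev_flows = {i: -q for i, q in flows.items()}
        rev = propagate_flows(
            small_tree, cf.FlowSeries(times=t, flows=rev_flows, period_ms=400.0)
        )
        d1 = aggregate_flow_decomposition(fwd, small_tree)
        d2 = aggregate_flow_decomposition(rev, small_tree)
        assert np.isclose(d1.q_tot, d2.q_tot)
        assert np.isclose(d1.q_bulk, d2.q_bulk)
        assert np.isclose(d1.q_pend, d2.q_pend)

    def test_root_flow_closes_with_lung_volume_derivative(self, small_tree):
        """Continuity closure: tracheal flow equals d/dt of total lung volume."""
        f = cf.generate_expansion_field(small_tree, seed=7)
        from cardioflow.mixing import flows_from_field

        fs = flows_from_field(f, small_tree)
        dv = f.dvdt(fs.times).sum(axis=0)
        rms = np.sqrt(np.mean((fs.flows[0] - dv) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(dv**2))

    def test_per_generation_breakdown_sums_to_totals(self, small_tree):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 400, 20, endpoint=False)
        flows = {i: rng.standard_normal(20) for i in small_tree.terminal_ids}
        fs = propagate_flows(
            small_tree, cf.FlowSeries(times=t, flows=flows, period_ms=400.0)
        )
        dec = aggregate_flow_decomposition(fs, small_tree)
        assert np.isclose(dec.per_generation.q_pend.sum(), dec.q_pend)
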