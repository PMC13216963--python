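"""Ladder least squares against closed-form and brute-force oracles, plus
anchoring, exclusion and parameter-recovery behavior."""

import numpy as np
import pytest
from scipy.optimize import minimize

from acidscale import (
    AnchorSet,
    LadderMeasurement,
    LadderScale,
    anchor_offset,
    consistency_s,
    exclude_inconsistent,
    fit_ladder,
    scale_report,
)
from acidscale.synthetic import SyntheticScaleSpec, gen_ladder


class TestFitLadder:
    def test_consistent_chain_exact(self, pin_a):
        ms = [LadderMeasurement("a", "b", 1.0), LadderMeasurement("b", "c", 1.0)]
        fit = fit_ladder(ms, pin_a)
        assert fit.values == pytest.approx({"a": 0.0, "b": 1.0, "c": 2.0})
        assert fit.ss == pytest.approx(0.0, abs=1e-20)

    def test_triangle_closed_form(self, triangle_measurements, pin_a):
        fit = fit_ladder(triangle_measurements, pin_a)
        assert fit.values["b"] == pytest.approx(1.0333, abs=1e-4)
        assert fit.values["c"] == pytest.approx(2.0667, abs=1e-4)
        assert fit.s == pytest.approx(0.0577, abs=1e-4)
        assert (fit.n_m, fit.n_c) == (3, 2)

    def test_normal_equations_satisfied(self, triangle_measurements, pin_a):
        """Gradient of SS w.r.t. each free value vanishes at the solution."""
        fit = fit_ladder(triangle_measurements, pin_a)
        for node in ("b", "c"):
            grad = 0.0
            for m in triangle_measurements:
                r = m.delta - (fit.values[m.node_b] - fit.values[m.node_a])
                grad += -2 * r * ((m.node_b == node) - (m.node_a == node))
            assert grad == pytest.approx(0.0, abs=1e-9)

    def test_translation_invariance(self, triangle_measurements):
        lo = fit_ladder(triangle_measurements, AnchorSet("fixed_single", {"a": 0.0}))
        hi = fit_ladder(triangle_measurements, AnchorSet("fixed_single", {"a": 5.0}))
        for n in lo.values:
            assert hi.values[n] == pytest.approx(lo.values[n] + 5.0)
        assert hi.s == pytest.approx(lo.s)
        np.testing.assert_allclose(
            hi.residuals["residual"], lo.residuals["residual"], atol=1e-12
        )

    def test_relabeling_invariance(self, triangle_measurements, pin_a):
        ren = {"a": "x", "b": "y", "c": "z"}
        renamed = [
            LadderMeasurement(ren[m.node_a], ren[m.node_b], m.delta)
            for m in triangle_measurements
        ]
        fit1 = fit_ladder(triangle_measurements, pin_a)
        fit2 = fit_ladder(renamed, AnchorSet("fixed_single", {"x": 0.0}))
        for old, new in ren.items():
            assert fit2.values[new] == pytest.approx(fit1.values[old])
        assert fit2.s == pytest.approx(fit1.s)

    def test_disconnected_graph_reported(self, pin_a):
        ms = [LadderMeasurement("a", "b", 1.0), LadderMeasurement("c", "d", 1.0)]
        with pytest.raises(ValueError, match="disconnected"):
            fit_ladder(ms, pin_a)

    def test_matches_brute_force_on_random_small_graphs(self, rng):
        """Oracle: direct numerical minimization of SS over the free values,
        for every random connected graph with at most 5 nodes."""
        for trial in range(12):
            n = int(rng.integers(3, 6))
            truth, ms, _ = gen_ladder(
                SyntheticScaleSpec(
                    n_nodes=n, n_edges=n + 2, noise_sd=0.3, seed=int(rng.integers(2**31))
                )
            )
            nodes = sorted(truth)
            anchors = AnchorSet("fixed_single", {nodes[0]: 0.0})
            fit = fit_ladder(ms, anchors)

            free = nodes[1:]

            def ss(x):
                vals = {nodes[0]: 0.0, **dict(zip(free, x))}
                return sum(
                    (m.delta - (vals[m.node_b] - vals[m.node_a])) ** 2 for m in ms
                )

            res = minimize(ss, np.zeros(len(free)), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
            oracle = dict(zip(free, res.x))
            for node in free:
                assert fit.values[node] == pytest.approx(oracle[node], abs=1e-6)

    def test_sklearn_param_interface(self):
        est = LadderScale(exclusion_threshold=0.75)
        assert est.get_params()["exclusion_threshold"] == 0.75
        est.set_params(precision=2)
        assert est.precision == 2


class TestConsistency:
    def test_from_triangle(self):
        assert consistency_s(0.003333, 3, 2) == pytest.approx(0.0577, abs=1e-4)

    def test_zero_residuals(self):
        assert consistency_s(0.0, 5, 3) == 0.0

    def test_exhausted_dof_undefined(self):
        assert consistency_s(0.0, 3, 3) is None

    def test_nc_counts_anchors_switch(self, triangle_measurements, pin_a):
        default = fit_ladder(triangle_measurements, pin_a)
        alt = fit_ladder(triangle_measurements, pin_a, nc_counts_anchors=True)
        assert default.n_c == 2
        assert alt.n_c == 3
        assert alt.s is None  # n_m = n_c exhausts the degrees of freedom


class TestAnchoring:
    def test_offset_is_mean_of_differences(self):
        rel = {"a": 0.0, "b": 1.0, "c": 2.0}
        calc = {"a": 10.1, "b": 11.0, "c": 12.2}
        assert anchor_offset(rel, calc) == pytest.approx(10.1)

    def test_single_anchor(self):
        assert anchor_offset({"a": 0.0}, {"a": 40.8}) == pytest.approx(40.8)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="no anchor"):
            anchor_offset({"a": 0.0}, {"z": 40.8})

    def test_offset_recovery_under_noise(self, rng):
        """Nine noisy computational anchors recover the planted offset to
        within three standard errors."""
        truth, ms, _ = gen_ladder(
            SyntheticScaleSpec(n_nodes=12, n_edges=24, noise_sd=0.0, seed=7)
        )
        anchor_nodes = sorted(truth)[:9]
        sigma = 1.5
        calc = {n: truth[n] + 40.8 + rng.normal(0, sigma) for n in anchor_nodes}
        fit = fit_ladder(ms, AnchorSet("offset_multi", calc))
        # the gauge-fixed relative values reproduce truth up to a shift, so
        # the fitted scale equals truth + offset with offset near 40.8
        recovered = np.mean([fit.values[n] - truth[n] for n in truth])
        assert recovered == pytest.approx(40.8, abs=3 * sigma / np.sqrt(9))


class TestExclusion:
    def test_single_outlier_excluded(self, pin_a):
        ms = [
            LadderMeasurement("a", "b", 1.0),
            LadderMeasurement("b", "c", 1.0),
            LadderMeasurement("a", "c", 2.0),
            LadderMeasurement("a", "c", 3.5),  # inconsistent by 1.5
        ]
        fit = exclude_inconsistent(ms, pin_a, threshold=0.75)
        assert fit.excluded_edges == [("a", "c")]
        assert fit.ss == pytest.approx(0.0, abs=1e-18)
        # excluded edges stay in the report, flagged
        flagged = fit.residuals[fit.residuals["excluded"]]
        assert len(flagged) == 1

    def test_no_outliers_noop(self, triangle_measurements, pin_a):
        fit = exclude_inconsistent(triangle_measurements, pin_a, threshold=0.75)
        plain = fit_ladder(triangle_measurements, pin_a)
        assert fit.excluded_edges == []
        assert fit.values == pytest.approx(plain.values)

    def test_planted_outliers_found(self):
        """On a well-connected 20-node graph the three planted +-1.0
        outliers, and only those, are excluded.  Leverage shrinks an
        outlier's residual by roughly the per-edge hat value, so the graph
        must be dense enough for the error to surface above the cutoff."""
        spec = SyntheticScaleSpec(
            n_nodes=20, n_edges=100, noise_sd=0.05, outlier_count=3,
            outlier_magnitude=1.0, seed=0,
        )
        truth, ms, outlier_idx = gen_ladder(spec)
        first = sorted(truth)[0]
        fit = exclude_inconsistent(
            ms, AnchorSet("fixed_single", {first: truth[first]}), threshold=0.75
        )
        planted = {(ms[i].node_a, ms[i].node_b) for i in outlier_idx}
        assert set(fit.excluded_edges) == planted

    def test_no_clean_edge_excluded_across_seeds(self):
        """Whatever subset of planted outliers surfaces above the cutoff,
        clean measurements are never excluded at this noise level."""
        for seed in range(8):
            spec = SyntheticScaleSpec(
                n_nodes=20, n_edges=100, noise_sd=0.05, outlier_count=3,
                outlier_magnitude=1.0, seed=seed,
            )
            truth, ms, outlier_idx = gen_ladder(spec)
            first = sorted(truth)[0]
            fit = exclude_inconsistent(
                ms, AnchorSet("fixed_single", {first: truth[first]}), threshold=0.75
            )
            planted = {(ms[i].node_a, ms[i].node_b) for i in outlier_idx}
            assert set(fit.excluded_edges) <= planted

    def test_parallel_contradictory_edges(self, pin_a):
        """Of two contradictory duplicate measurements exactly one is
        removed; the fit then reproduces the survivor exactly and the graph
        stays whole."""
        ms = [
            LadderMeasurement("a", "b", 0.0, source="first"),
            LadderMeasurement("a", "b", 2.0, source="second"),
        ]
        fit = exclude_inconsistent(ms, pin_a, threshold=0.75)
        assert fit.excluded_edges == [("a", "b")]
        assert fit.values["b"] in (pytest.approx(0.0), pytest.approx(2.0))
        assert fit.ss == pytest.approx(0.0, abs=1e-20)
        assert set(fit.values) == {"a", "b"}


class TestRecovery:
    def test_rmse_decreases_with_edge_count(self):
        rmses = []
        for n_edges in (35, 120):
            errs = []
            for seed in range(8):
                spec = SyntheticScaleSpec(
                    n_nodes=20, n_edges=n_edges, noise_sd=0.2, seed=seed
                )
                truth, ms, _ = gen_ladder(spec)
                first = sorted(truth)[0]
                fit = fit_ladder(ms, AnchorSet("fixed_single", {first: truth[first]}))
                errs.extend(fit.values[n] - truth[n] for n in truth)
            rmses.append(np.sqrt(np.mean(np.square(errs))))
        assert rmses[1] < rmses[0]

    def test_s_estimates_noise_level(self):
        """At the measured ladder's dimensions the consistency parameter
        estimates the generating noise within +-50%."""
        sigma = 0.07
        ss = []
        for seed in range(60):
            spec = SyntheticScaleSpec(n_nodes=33, n_edges=64, noise_sd=sigma, seed=seed)
            truth, ms, _ = gen_ladder(spec)
            first = sorted(truth)[0]
            fit = fit_ladder(ms, AnchorSet("fixed_single", {first: truth[first]}))
            ss.append(fit.s)
        assert all(0.5 * sigma <= s <= 1.5 * sigma for s in ss)


class TestReport:
    def test_sorted_and_span(self, triangle_measurements, pin_a):
        fit = fit_ladder(triangle_measurements, pin_a)
        rep = scale_report(fit)
        assert list(rep["node"]) == ["a", "b", "c"]
        assert rep.attrs["span"] == pytest.approx(2.0667, abs=1e-4)

    def test_single_node_span_zero(self):
        ms = [LadderMeasurement("a", "b", 0.0)]
        fit = fit_ladder(ms, AnchorSet("fixed_single", {"a": 0.0}))
        assert fit.values["b"] == pytest.approx(0.0)
        rep = scale_report(fit)
        assert rep.attrs["span"] == pytest.approx(0.0)
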