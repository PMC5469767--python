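"""Breakpoint regression, PDUI statistics, and classification."""

import math

import numpy as np
import pytest

from apascope import apa_core
from apascope.apa_core import (
    adjust_bh,
    classify_apa,
    compare_groups,
    correct_bias,
    detect_distal_end,
    fit_breakpoint,
)
from apascope.errors import CoverageError
from apascope.synthetic_data import simulate_coverage

from conftest import (
    brute_force_breakpoint,
    brute_force_distal_end,
    fisher_two_sided_enumeration,
    make_track,
)


class TestDetectDistalEnd:
    def test_sharp_cliff(self):
        v = np.concatenate([np.full(400, 10.0), np.zeros(300)])
        assert detect_distal_end(make_track(v)) == 400

    def test_gap_within_tolerance_is_bridged(self):
        v = np.concatenate([np.full(400, 10.0), np.zeros(30), np.full(170, 10.0)])
        assert detect_distal_end(make_track(v)) == 600

    def test_gap_beyond_tolerance_terminates(self):
        v = np.concatenate([np.full(400, 10.0), np.zeros(60), np.full(140, 10.0)])
        assert detect_distal_end(make_track(v), gap_tol=50) == 400

    def test_zero_anchor_is_untestable(self):
        v = np.concatenate([np.zeros(100), np.full(100, 5.0)])
        assert detect_distal_end(make_track(v)) is None

    def test_matches_literal_scan_on_random_piecewise_tracks(self, rng):
        for _ in range(50):
            pieces = [
                np.full(rng.integers(10, 120), rng.choice([0.0, 0.5, 2.0, 10.0, 40.0]))
                for _ in range(rng.integers(3, 10))
            ]
            v = np.concatenate(pieces)
            expected = brute_force_distal_end(v)
            got = detect_distal_end(make_track(v))
            assert got == expected


class TestFitBreakpoint:
    def test_exact_step_function(self):
        v = np.concatenate([np.full(50, 10.0), np.full(50, 4.0)])
        fit = fit_breakpoint([make_track(v)], min_flank=10)
        assert fit.breakpoint == 49
        assert fit.w_long["s1"] == pytest.approx(4.0)
        assert fit.w_short["s1"] == pytest.approx(6.0)
        assert fit.pdui["s1"] == pytest.approx(0.4)
        assert fit.rss == pytest.approx(0.0, abs=1e-9)

    def test_uniform_track_is_degenerate_with_pdui_one(self):
        fit = fit_breakpoint([make_track(np.full(200, 7.0))], min_flank=20)
        assert fit.degenerate
        assert fit.breakpoint == 20  # smallest admissible P by tie-break
        assert fit.pdui["s1"] == pytest.approx(1.0)

    def test_too_short_region_is_untestable(self):
        fit = fit_breakpoint([make_track(np.full(40, 5.0))], min_flank=50)
        assert not fit.testable and fit.breakpoint is None

    def test_all_zero_track_has_undefined_pdui(self):
        v = np.concatenate([np.full(100, 8.0), np.full(100, 2.0)])
        fit = fit_breakpoint([make_track(v, "a"), make_track(np.zeros(200), "b")], min_flank=20)
        assert fit.pdui["a"] is not None
        assert fit.pdui["b"] is None

    @pytest.mark.parametrize("n_samples", [1, 2, 4])
    def test_matches_exhaustive_enumeration(self, rng, n_samples):
        """Joint fit equals brute-force enumeration over every candidate P."""
        for _ in range(10):
            D = int(rng.integers(120, 400))
            p_true = int(rng.integers(40, D - 40))
            tracks = [
                make_track(
                    simulate_coverage(D, p_true, float(rng.uniform(0.1, 0.9)), 30.0, 0.0, rng),
                    sample_id=f"s{k}",
                )
                for k in range(n_samples)
            ]
            fit = fit_breakpoint(tracks, min_flank=30)
            P, rss, weights = brute_force_breakpoint([t.values for t in tracks], min_flank=30)
            assert fit.breakpoint == P
            assert fit.rss == pytest.approx(rss, rel=1e-9)
            for (wl, ws), sid in zip(weights, [t.sample_id for t in tracks]):
                assert fit.w_long[sid] == pytest.approx(wl, rel=1e-9)
                assert fit.w_short[sid] == pytest.approx(ws, rel=1e-9, abs=1e-12)

    def test_scale_invariance(self, rng):
        """Multiplying all tracks by a constant leaves P* and PDUIs unchanged."""
        D, p_true = 300, 120
        tracks = [
            make_track(simulate_coverage(D, p_true, 0.4, 40.0, 0.0, rng), sample_id=f"s{k}")
            for k in range(3)
        ]
        scaled = [make_track(t.values * 37.5, sample_id=t.sample_id) for t in tracks]
        f1, f2 = fit_breakpoint(tracks), fit_breakpoint(scaled)
        assert f1.breakpoint == f2.breakpoint
        for s in f1.pdui:
            assert f1.pdui[s] == pytest.approx(f2.pdui[s], rel=1e-9)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(CoverageError):
            fit_breakpoint([make_track(np.zeros(100)), make_track(np.zeros(101))])


class TestCorrectBias:
    def test_mode_none_is_identity(self, rng):
        t = make_track(rng.poisson(20, 300).astype(float))
        out = correct_bias(t, "none")
        np.testing.assert_array_equal(out.values, t.values)

    def test_detrend_reduces_cv_on_linear_ramp(self):
        v = np.linspace(40.0, 10.0, 400)
        out = correct_bias(make_track(v), "linear_detrend")
        cv = lambda x: x.std() / x.mean()
        assert cv(out.values) < cv(v)
        assert out.values.mean() == pytest.approx(v.mean(), rel=1e-6)

    def test_short_track_falls_back_to_identity(self):
        t = make_track(np.full(50, 5.0))
        out = correct_bias(t, "linear_detrend")
        np.testing.assert_array_equal(out.values, t.values)

    def test_detrend_shrinks_pdui_bias_under_simulated_decay(self, rng):
        """Paired simulation: 5'->3' decay biases PDUI down; detrending
        moves the mean estimate back toward the true mixing fraction."""
        pi, D, p_true = 0.5, 500, 200
        err_raw, err_corr = [], []
        for _ in range(40):
            v = simulate_coverage(D, p_true, pi, 60.0, 0.5, rng)
            raw = fit_breakpoint([make_track(v)], min_flank=50)
            corr = fit_breakpoint([correct_bias(make_track(v), "linear_detrend")], min_flank=50)
            err_raw.append(raw.pdui["s1"] - pi)
            err_corr.append(corr.pdui["s1"] - pi)
        assert abs(np.mean(err_corr)) < abs(np.mean(err_raw))


class TestCompareGroups:
    @staticmethod
    def _fit_with_pduis(pdui_a, pdui_b, wl=4.0, ws=6.0):
        fit = apa_core.APAFit(gene_id="g", distal_end=400, breakpoint=150)
        for i, p in enumerate(pdui_a):
            sid = f"a{i}"
            fit.pdui[sid] = p
            fit.w_long[sid] = wl * p / max(pdui_a[0], 1e-9)
            fit.w_short[sid] = ws
        for i, p in enumerate(pdui_b):
            sid = f"b{i}"
            fit.pdui[sid] = p
            fit.w_long[sid] = wl * p / max(pdui_a[0], 1e-9)
            fit.w_short[sid] = ws
        return fit

    def test_dpdui_arithmetic(self):
        fit = self._fit_with_pduis([0.9, 0.9, 0.9], [0.3, 0.3, 0.3])
        comp = compare_groups(fit, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert comp.dpdui == pytest.approx(0.6)

    def test_identical_groups_are_null(self):
        fit = self._fit_with_pduis([0.5, 0.5], [0.5, 0.5])
        comp = compare_groups(fit, ["a0", "a1"], ["b0", "b1"])
        assert comp.dpdui == pytest.approx(0.0)
        assert comp.p_value == pytest.approx(1.0)

    def test_antisymmetry_under_group_swap(self, rng):
        D, p_true = 400, 160
        tracks = [
            make_track(simulate_coverage(D, p_true, pi, 50.0, 0.0, rng), sample_id=s)
            for s, pi in [("a0", 0.8), ("a1", 0.8), ("b0", 0.3), ("b1", 0.3)]
        ]
        fit = fit_breakpoint(tracks)
        ab = compare_groups(fit, ["a0", "a1"], ["b0", "b1"])
        ba = compare_groups(fit, ["b0", "b1"], ["a0", "a1"])
        assert ab.dpdui == pytest.approx(-ba.dpdui)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        from scipy import stats

        table = [[90, 10], [30, 70]]
        _, p_scipy = stats.fisher_exact(table)
        assert p_scipy == pytest.approx(fisher_two_sided_enumeration(table), abs=1e-12)

    def test_missing_group_pdui_raises(self):
        fit = apa_core.APAFit(gene_id="g", distal_end=400, breakpoint=150)
        fit.pdui = {"a0": 0.5, "b0": None}
        fit.w_long, fit.w_short = {"a0": 2.0, "b0": 0.0}, {"a0": 2.0, "b0": 0.0}
        with pytest.raises(CoverageError):
            compare_groups(fit, ["a0"], ["b0"])


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_identity(self):
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_empty(self):
        assert adjust_bh([]).size == 0

    def test_order_preserving_and_monotone_in_rank(self, rng):
        p = rng.uniform(size=30)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestClassifyAPA:
    @pytest.mark.parametrize(
        "dpdui,q,expected",
        [
            (0.6, 0.001, "lengthened"),
            (-0.25, 0.04, "shortened"),
            (0.5, 0.2, "unchanged"),
            (0.1, 0.001, "unchanged"),  # below the effect floor
        ],
    )
    def test_rules(self, dpdui, q, expected):
        comp = apa_core.APAComparison(
            gene_id="g", pdui_mean_a=0.5 + dpdui / 2, pdui_mean_b=0.5 - dpdui / 2,
            dpdui=dpdui, p_value=q / 2, counts_2x2=((1, 1), (1, 1)), q_value=q,
        )
        assert classify_apa(comp) == expected

    def test_unset_q_raises(self):
        comp = apa_core.APAComparison(
            gene_id="g", pdui_mean_a=0.9, pdui_mean_b=0.3, dpdui=0.6,
            p_value=0.01, counts_2x2=((1, 1), (1, 1)),
        )
        assert math.isnan(comp.q_value)
        with pytest.raises(ValueError):
            classify_apa(comp)
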