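"""Bifurcation scans, switch-point detection, hysteresis and sensitivities."""

import numpy as np
import pytest

from glyswitch.bifurcation import (bistability_region, hysteresis_paths,
                                   scan, switch_points)
from glyswitch.errors import ConfigurationError
from glyswitch.reduction import node_switch_points

COARSE = np.concatenate([np.arange(0.5, 6.0, 0.5), np.arange(6.0, 26.0, 2.0)])


class TestScan:
    def test_empty_grid_gives_empty_diagram(self, cfg_both):
        diagram = scan(cfg_both, "glucose", [], detect_switches=False)
        assert diagram.points == [] and diagram.max_coexisting() == 0

    def test_saturating_single_branch_without_loops(self, cfg_no_loops):
        """Neither loop active: one branch, monotone nondecreasing flux."""
        diagram = scan(cfg_no_loops, "glucose", COARSE, detect_switches=False)
        assert diagram.max_coexisting() == 1
        flux = [p[0].flux for p in diagram.points]
        assert np.all(np.diff(flux) >= -1e-9)
        assert diagram.switch_up is None and diagram.switch_down is None

    def test_both_loops_multistable_window(self, cfg_both):
        """PFKL + PKM2 at K/P = 10: a glucose window with coexisting stable
        low/high states separated by an unstable state."""
        diagram = scan(cfg_both, "glucose", COARSE)
        assert diagram.max_coexisting() == 3
        assert int(diagram.n_stable().max()) == 2
        assert int(diagram.n_unstable().max()) == 1
        assert diagram.switch_down < 1.0
        assert 8.5 < diagram.switch_up < 10.0

    def test_unknown_parameter_rejected(self, cfg_both):
        with pytest.raises(ConfigurationError):
            scan(cfg_both, "temperature", [1, 2])

    def test_diagram_serializes_to_csv(self, cfg_loop1):
        diagram = scan(cfg_loop1, "glucose", [2.0, 5.0], detect_switches=False)
        text = diagram.to_csv()
        assert "flux" in text and "stability" in text


class TestSwitchPoints:
    def test_monostable_diagram_has_no_switches(self, cfg_no_loops):
        up, down = switch_points(cfg_no_loops, "glucose", COARSE)
        assert up is None and down is None

    def test_fold_pairing_count_parity(self, cfg_both):
        """Crossing a detected switch point changes the number of coexisting
        states by exactly 2 (a stable/unstable pair is created or lost)."""
        grid = np.concatenate([[0.05, 0.15, 0.25, 0.35, 0.45], COARSE])
        up, down = switch_points(cfg_both, "glucose", grid)
        from glyswitch.steady_state import find_steady_states
        for edge in (up, down):
            lo = len(find_steady_states(edge - 0.05, cfg_both,
                                        method="reduction"))
            hi = len(find_steady_states(edge + 0.05, cfg_both,
                                        method="reduction"))
            assert abs(hi - lo) == 2

    def test_loop2_window_sits_higher_than_loop1(self, cfg_loop1, cfg_loop2):
        up1, down1 = switch_points(cfg_loop1, "glucose", COARSE)
        up2, down2 = switch_points(cfg_loop2, "glucose", COARSE)
        assert down2 > down1
        assert 0.5 * (up2 + down2) > 0.5 * (up1 + down1)

    def test_switch_up_nonincreasing_in_kp(self, cfg_both):
        """Raising the kinase/phosphatase ratio moves switch-up to lower
        glucose (stronger F26BP activation of PFK)."""
        ups = []
        for kp in (3.0, 5.0, 10.0):
            up, _ = switch_points(cfg_both.with_kp_ratio(kp), "glucose",
                                  COARSE)
            ups.append(up)
        assert ups[0] > ups[1] > ups[2]


class TestNodeBistability:
    def test_node_kp_window_disappears_at_high_kp(self, cfg_loop1):
        """Three-enzyme F6P node: bistable over a wide K/P range but lost
        above roughly 10."""
        assert node_switch_points(cfg_loop1.with_kp_ratio(50.0))[0] is None
        assert node_switch_points(cfg_loop1.with_kp_ratio(20.0))[0] is None
        for kp in (0.5, 1.0, 5.0, 10.0):
            up, down = node_switch_points(cfg_loop1.with_kp_ratio(kp))
            assert up is not None and down is not None

    def test_node_window_shifts_to_higher_f6p_at_lower_kp(self, cfg_loop1):
        up1, _ = node_switch_points(cfg_loop1.with_kp_ratio(1.0))
        up5, _ = node_switch_points(cfg_loop1.with_kp_ratio(5.0))
        assert up1 > up5

    def test_bistability_region_interval_or_absent(self, cfg_both):
        region = bistability_region(cfg_both, "glucose", (0.5, 25.0),
                                    n_coarse=26)
        assert region is not None
        down, up = region
        assert down < up


class TestHysteresis:
    def test_paths_differ_inside_window_and_agree_outside(self, cfg_both):
        grid = np.concatenate([np.arange(0.25, 9.0, 0.5), [12.0, 16.0, 20.0]])
        table = hysteresis_paths(cfg_both, grid)
        up, down = switch_points(cfg_both, "glucose", COARSE)
        inside = (table.glucose > down + 0.3) & (table.glucose < up - 0.3)
        outside = (table.glucose < down - 0.3) | (table.glucose > up + 0.3)
        gap = (table.flux_down_scan - table.flux_up_scan).abs()
        rel = gap / table[["flux_up_scan", "flux_down_scan"]].max(axis=1)
        assert (rel[inside] > 0.5).all()       # distinct branches
        assert (rel[outside] < 1e-6).all()     # identical outside


class TestSensitivities:
    def test_pfkfb_level_leaves_diagram_unchanged(self, cfg_both):
        """Steady-state diagrams at 100/50/20/10% PFKFB superimpose."""
        from glyswitch.steady_state import find_steady_states
        baseline = None
        for level in (1.0, 0.5, 0.2, 0.1):
            sols = find_steady_states(5.0, cfg_both.with_levels(PFKFB=level),
                                      method="reduction")
            arr = np.array([s.state.as_array() for s in sols])
            if baseline is None:
                baseline = arr
            else:
                np.testing.assert_allclose(arr, baseline, rtol=1e-6)

    def test_degenerate_fold_range_single_evaluation(self, cfg_both):
        from glyswitch.bifurcation import enzyme_sensitivity
        table = enzyme_sensitivity(cfg_both, "PK", fold_range=1.0,
                                   glucose_grid=COARSE)
        assert len(table) == 1 and bool(table.bistable.iloc[0])

    def test_hk_window_narrower_than_pk(self, cfg_both):
        """Bistability survives a wide range of PK levels but only a narrow
        range of HK levels (supply-side fragility)."""
        from glyswitch.bifurcation import enzyme_sensitivity
        def decades(enzyme):
            table = enzyme_sensitivity(cfg_both, enzyme, fold_range=100.0,
                                       n_levels=7, glucose_grid=COARSE)
            ok = table[table.bistable]
            if len(ok) < 2:
                return 0.0
            return float(np.log10(ok.level.max() / ok.level.min()))
        assert decades("PK") > decades("HK")

    def test_lactate_variation_leaves_diagram_unchanged(self, cfg_both):
        from glyswitch.bifurcation import environment_sensitivity
        table = environment_sensitivity(cfg_both, "LAC", (0.5, 5.0, 20.0),
                                        glucose_grid=COARSE)
        assert table.max_coexisting.nunique() == 1
        assert float(table.switch_up.max() - table.switch_up.min()) < 0.15

    def test_unknown_environment_axis_rejected(self, cfg_both):
        from glyswitch.bifurcation import environment_sensitivity
        with pytest.raises(ConfigurationError):
            environment_sensitivity(cfg_both, "PH", (7.0,))
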