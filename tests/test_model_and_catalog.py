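"""Stoichiometry of the ODE right-hand side, flux-balance invariants, and
the isozyme catalog / configuration layer."""

import numpy as np
import pytest

from glyswitch.catalog import (ModelConfig, build_config, loop_status,
                               table1_catalog)
from glyswitch.errors import ConfigurationError
from glyswitch.model import flux_balance_residuals, fluxes, rate_chain, rhs
from glyswitch.state import SPECIES, Environment, MetaboliteState


def _random_state(seed=3):
    rng = np.random.default_rng(seed)
    return MetaboliteState.from_array(10.0 ** rng.uniform(-3, 0.5, 12))


class TestRhs:
    def test_rhs_is_stoichiometric_sum_of_fluxes(self, cfg_both):
        state = _random_state()
        v = fluxes(state, cfg_both.env, cfg_both)
        d = rhs(state, cfg_both.env, cfg_both)
        expect = {
            "GLC": v["GLUT"] - v["HK"],
            "G6P": v["HK"] - v["PGI"],
            "F6P": v["PGI"] - v["PFK"] - v["PFKFB"],
            "F16BP": v["PFK"] - v["ALDO"],
            "F26BP": v["PFKFB"],
            "DHAP": v["ALDO"] - v["TPI"],
            "GAP": v["ALDO"] + v["TPI"] - v["GAPDH"],
            "BPG13": v["GAPDH"] - v["PGK"],
            "PG3": v["PGK"] - v["PGAM"],
            "PG2": v["PGAM"] - v["ENO"],
            "PEP": v["ENO"] - v["PK"],
            "PYR": v["PK"] - v["LDH"] - v["MCT_MITO"] - v["ALA_SINK"],
        }
        for i, name in enumerate(SPECIES):
            assert d[i] == pytest.approx(expect[name], rel=1e-12), name

    def test_empty_cell_with_empty_reservoirs_is_at_rest(self, cfg_both):
        """All-zero intermediates with no glucose and drained external pools
        give identically zero derivatives."""
        env = Environment(GLC_EXT=0.0, LAC=0.0, ALA=0.0, PYR_M=0.0)
        zero = MetaboliteState.from_array(np.zeros(12))
        assert np.all(rhs(zero, env, cfg_both.replace(env=env)) == 0.0)

    def test_flux_balance_at_solver_roots(self, cfg_both, both_states_5mm):
        """Every accepted root satisfies the chain flux equalities to 1e-6
        relative, and max |rhs| < 1e-8 mM/h."""
        assert len(both_states_5mm) >= 2
        for sol in both_states_5mm:
            assert sol.residual_norm < 1e-8
            res = flux_balance_residuals(sol.state, cfg_both.env, cfg_both)
            for key, value in res.items():
                assert abs(value) < 1e-6, (key, value)

    def test_f16bp_decoupled_when_both_activations_absent(self, cfg_no_loops):
        """With PFKP and PKM1 the F16BP concentration feeds back on nothing
        but the aldolase mass balance: finite-difference sensitivity of every
        other balance to F16BP is zero."""
        state = _random_state(7)
        h = 1e-6 * state.F16BP
        up = rhs(state.replace(F16BP=state.F16BP + h), cfg_no_loops.env,
                 cfg_no_loops)
        dn = rhs(state.replace(F16BP=state.F16BP - h), cfg_no_loops.env,
                 cfg_no_loops)
        sens = (up - dn) / (2 * h)
        coupled = {"F16BP", "DHAP", "GAP"}   # aldolase terms only
        for i, name in enumerate(SPECIES):
            if name not in coupled:
                assert abs(sens[i]) < 1e-6, name

    def test_rate_chain_dispatch_and_unknown_enzyme(self, cfg_both):
        state = _random_state()
        v = rate_chain("GAPDH", state, cfg_both.env, cfg_both)
        assert v == fluxes(state, cfg_both.env, cfg_both)["GAPDH"]
        with pytest.raises(ConfigurationError):
            rate_chain("NOT_AN_ENZYME", state, cfg_both.env, cfg_both)


class TestCatalog:
    def test_reported_isozyme_constants(self, catalog):
        assert catalog["PFKM"].ka_f16bp == 0.35
        assert catalog["PFKL"].ka_f16bp == 0.65
        assert catalog["PFKP"].ka_f16bp is None
        assert catalog["PKL"].ki_atp == 0.05
        assert catalog["PKL"].ka_f16bp == 0.01
        assert catalog["PKL"].km_pep == 0.6
        assert catalog["PKR"].ki_atp == 0.12
        assert catalog["PKM1"].ki_atp == 2.5
        assert catalog["PKM1"].km_pep == 0.08
        assert catalog["PKM1"].ka_f16bp is None
        assert catalog["PKM2"].ki_atp == 3.5
        assert catalog["PKM2"].ka_f16bp == 0.04
        assert catalog["PKM2"].km_pep == 0.4

    def test_pfkfb_tissue_presets(self, catalog):
        assert catalog["PFKFB1_liver"].kp_ratio == 2.0
        assert catalog["PFKFB1_liver"].kp_range == (1.5, 2.5)
        assert catalog["PFKFB1_muscle"].kp_ratio == 0.4
        assert catalog["PFKFB2_heart"].kp_ratio == 1.8
        assert catalog["PFKFB3_brain"].kp_ratio == 3.1
        assert catalog["PFKFB3_inducible"].kp_ratio == 710.0
        assert catalog["PFKFB4_testis"].kp_ratio == 4.1

    @pytest.mark.parametrize("pfk,pk,loop1,loop2", [
        ("PFKP", "PKM1", False, False),
        ("PFKL", "PKM1", True, False),
        ("PFKP", "PKM2", False, True),
        ("PFKL", "PKM2", True, True),
        ("PFKM", "PKM1", True, False),
    ])
    def test_loop_status_pure_isoforms(self, pfk, pk, loop1, loop2):
        status = loop_status(build_config(pfk, pk, 10.0))
        assert status.loop1_active is loop1
        assert status.loop2_active is loop2

    def test_loop_status_mixture_positive_weight_rule(self):
        status = loop_status(build_config({"PFKP": 0.9, "PFKL": 0.1},
                                          "PKM1", 10.0))
        assert status.loop1_active and not status.loop2_active

    def test_build_config_rejects_unknown_isoform(self):
        with pytest.raises(ConfigurationError, match="PFKL"):
            build_config("PFKX", "PKM1", 10.0)
        with pytest.raises(ConfigurationError):
            build_config("PFKL", "PKM9", 10.0)
        with pytest.raises(ConfigurationError):
            build_config("PFKL", "PKM1", -1.0)

    def test_yaml_round_trip_preserves_rate_evaluations(self, cfg_both,
                                                        tmp_path):
        path = tmp_path / "cfg.yaml"
        cfg_both.to_yaml(path)
        loaded = ModelConfig.from_yaml(path)
        assert loaded.digest() == cfg_both.digest()
        state = _random_state(11)
        v0 = fluxes(state, cfg_both.env, cfg_both)
        v1 = fluxes(state, loaded.env, loaded)
        for key in v0:
            assert v1[key] == pytest.approx(v0[key], rel=1e-15)

    def test_catalog_csv_contains_reported_values(self):
        from glyswitch.catalog import catalog_to_csv
        text = catalog_to_csv()
        assert "PKM2" in text and "3.5" in text and "710" in text
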