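"""Unit tests for the enzyme rate laws and their allosteric structure."""

import numpy as np
import pytest
from scipy.optimize import brentq

from glyswitch import ratelaws as rl
from glyswitch.errors import ConfigurationError, DomainError
from glyswitch.ratelaws import ChainParams

ATP, ADP, AMP = 3.0, 0.5, 0.1
V_PFK = 1968.88


class TestPFK:
    def test_no_substrate_no_flux(self, catalog):
        assert rl.rate_pfk(0.0, ATP, 1.0, 0.05, AMP, catalog["PFKL"],
                           v_max=V_PFK) == 0.0

    def test_stronger_activation_for_muscle_isoform(self, catalog):
        """PFKM's lower F16BP activation constant gives it a higher rate than
        PFKL at identical state."""
        args = (0.15, ATP, 0.5, 0.0, AMP)
        assert (rl.rate_pfk(*args, catalog["PFKM"], v_max=V_PFK)
                >= rl.rate_pfk(*args, catalog["PFKL"], v_max=V_PFK))

    def test_activation_ratio_regression_pin(self, catalog):
        """Rate at F16BP = 10*Ka over rate at F16BP = 0, PFKL (frozen)."""
        hi = rl.rate_pfk(0.15, ATP, 6.5, 0.0, AMP, catalog["PFKL"], v_max=V_PFK)
        lo = rl.rate_pfk(0.15, ATP, 0.0, 0.0, AMP, catalog["PFKL"], v_max=V_PFK)
        assert hi / lo == pytest.approx(1951.150967971109, rel=1e-12)

    @pytest.mark.parametrize("effector", ["F16BP", "F26BP"])
    def test_rate_strictly_increasing_in_activators(self, catalog, effector):
        grid = np.linspace(0.0, 2.0, 30)
        rates = []
        for x in grid:
            f16, f26 = (x, 0.01) if effector == "F16BP" else (0.5, x)
            rates.append(rl.rate_pfk(0.2, ATP, f16, f26, AMP, catalog["PFKL"],
                                     v_max=V_PFK))
        assert np.all(np.diff(rates) > 0)

    def test_pfkp_is_structurally_insensitive_to_f16bp(self, catalog):
        r0 = rl.rate_pfk(0.2, ATP, 0.0, 0.01, AMP, catalog["PFKP"], v_max=V_PFK)
        r1 = rl.rate_pfk(0.2, ATP, 5.0, 0.01, AMP, catalog["PFKP"], v_max=V_PFK)
        assert r0 == r1

    def test_negative_concentration_rejected(self, catalog):
        with pytest.raises(DomainError):
            rl.rate_pfk(-0.1, ATP, 0.0, 0.0, AMP, catalog["PFKL"])


class TestPFKMixture:
    def _pfk_cat(self, catalog):
        return {k: v for k, v in catalog.items()
                if k.startswith("PFK") and not k.startswith("PFKFB")}

    def test_degenerate_mixture_equals_pure(self, catalog):
        cat = self._pfk_cat(catalog)
        args = (0.15, ATP, 1.0, 0.005, AMP)
        assert (rl.mixture_rate_pfk({"PFKL": 1.0}, *args, cat, v_max=V_PFK)
                == rl.rate_pfk(*args, catalog["PFKL"], v_max=V_PFK))

    def test_5050_between_pure_rates(self, catalog):
        cat = self._pfk_cat(catalog)
        args = (0.15, ATP, 1.0, 0.005, AMP)
        pure_l = rl.rate_pfk(*args, catalog["PFKL"], v_max=V_PFK)
        pure_p = rl.rate_pfk(*args, catalog["PFKP"], v_max=V_PFK)
        mix = rl.mixture_rate_pfk({"PFKL": 0.5, "PFKP": 0.5}, *args, cat,
                                  v_max=V_PFK)
        assert min(pure_l, pure_p) <= mix <= max(pure_l, pure_p)

    def test_8020_regression_pin(self, catalog):
        mix = rl.mixture_rate_pfk({"PFKL": 0.8, "PFKP": 0.2},
                                  0.15, ATP, 1.0, 0.005, AMP,
                                  self._pfk_cat(catalog), v_max=V_PFK)
        assert mix == pytest.approx(25.833190077450233, rel=1e-12)

    def test_bad_weights_rejected(self, catalog):
        cat = self._pfk_cat(catalog)
        with pytest.raises(ConfigurationError):
            rl.mixture_rate_pfk({"PFKL": 0.8}, 0.1, ATP, 0, 0, AMP, cat)
        with pytest.raises(ConfigurationError):
            rl.mixture_rate_pfk({"NOPE": 1.0}, 0.1, ATP, 0, 0, AMP, cat)


class TestPK:
    def test_no_pep_no_flux(self, catalog):
        assert rl.rate_pk(0.0, ADP, 1.0, ATP, 0.1, catalog["PKM2"]) == 0.0

    def test_atp_inhibits(self, catalog):
        rates = [rl.rate_pk(0.3, ADP, 0.5, atp, 0.1, catalog["PKM2"])
                 for atp in (1.0, 3.0, 6.0)]
        assert rates[0] > rates[1] > rates[2]

    def test_f16bp_activates_non_m1_isoforms(self, catalog):
        for name in ("PKM2", "PKL", "PKR"):
            lo = rl.rate_pk(0.3, ADP, 0.0, ATP, 0.1, catalog[name])
            hi = rl.rate_pk(0.3, ADP, 1.0, ATP, 0.1, catalog[name])
            assert hi > lo, name
        # PKM1 carries no activation term at all
        assert (rl.rate_pk(0.3, ADP, 0.0, ATP, 0.1, catalog["PKM1"])
                == rl.rate_pk(0.3, ADP, 1.0, ATP, 0.1, catalog["PKM1"]))

    def test_pkm1_reaches_half_max_at_lower_pep_than_pkm2(self, catalog):
        """With F16BP = 0 the muscle isoform's PEP half-saturation (0.08 mM)
        sits far below PKM2's (0.4 mM)."""
        def half_pep(iso):
            cap = rl.rate_pk(1e6, ADP, 0.0, ATP, 0.1, iso)
            return brentq(lambda p: rl.rate_pk(p, ADP, 0.0, ATP, 0.1, iso)
                          - 0.5 * cap, 1e-6, 100.0)
        assert half_pep(catalog["PKM1"]) < half_pep(catalog["PKM2"])

    def test_pkm2_regression_pin(self, catalog):
        rate = rl.rate_pk(0.2, ADP, 0.04, ATP, 0.1, catalog["PKM2"],
                          v_max=1000.0)
        assert rate == pytest.approx(47.672133265420015, rel=1e-12)


class TestPFKFB:
    def test_internal_zero_independent_of_level(self, catalog):
        """The F26BP at which kinase and phosphatase balance does not depend
        on the expression level (both domains scale equally)."""
        iso = catalog["PFKFB3_brain"]
        zeros = []
        for level in (1.0, 0.5, 0.2, 0.1):
            z = brentq(lambda x: rl.rate_pfkfb_net(0.2, ATP, x, 0.05, iso,
                                                   level), 0.0, 10.0)
            zeros.append(z)
        assert np.ptp(zeros) < 1e-12
        assert zeros[0] == pytest.approx(
            rl.pfkfb_f26bp_star(0.2, ATP, 0.05, iso), rel=1e-9)

    def test_pure_phosphatase_limit(self, catalog):
        iso = catalog["PFKFB1_muscle"].replace(kp_ratio=1e-9)
        assert rl.rate_pfkfb_net(0.2, ATP, 0.05, 0.05, iso) < 0

    def test_f26bp_zero_increases_with_kp(self, catalog):
        """Bisection on the net rate confirms a higher K/P raises the F26BP
        set point (independent scalar-solver oracle)."""
        iso1 = catalog["PFKFB3_brain"].replace(kp_ratio=1.0)
        iso10 = catalog["PFKFB3_brain"].replace(kp_ratio=10.0)
        z1 = brentq(lambda x: rl.rate_pfkfb_net(0.2, ATP, x, 0.05, iso1),
                    0.0, 10.0)
        z10 = brentq(lambda x: rl.rate_pfkfb_net(0.2, ATP, x, 0.05, iso10),
                     0.0, 10.0)
        assert z10 > z1


class TestChainEnzymes:
    def test_hk_no_glucose_no_flux(self):
        assert rl.rate_hk(0.0, ATP, 0.1, ChainParams()) == 0.0

    def test_hk_monotone_in_g6p(self):
        p = ChainParams()
        rates = [rl.rate_hk(5.0, ATP, g, p) for g in np.linspace(0, 5, 40)]
        assert np.all(np.diff(rates) < 0)

    def test_hk_half_inhibition_at_ki(self):
        """The G6P giving half the uninhibited rate equals the inhibition
        constant (Hill form crosses 1 exactly at Ki)."""
        p = ChainParams()
        full = rl.rate_hk(5.0, ATP, 0.0, p)
        assert rl.rate_hk(5.0, ATP, p.ki_hk_g6p, p) == pytest.approx(
            0.5 * full, rel=1e-12)

    def test_gapdh_forward_requires_nad(self):
        assert rl.rate_gapdh(0.1, 0.0, 0.0, 0.06, ChainParams()) == 0.0

    def test_ldh_sign_flips_at_equilibrium(self):
        p = ChainParams()
        pyr_eq = 1.8 * 0.6 / (0.06 * p.keq_ldh)
        assert rl.rate_ldh(pyr_eq * 0.5, 0.6, 0.06, 1.8, p) < 0
        assert rl.rate_ldh(pyr_eq * 2.0, 0.6, 0.06, 1.8, p) > 0
        assert rl.rate_ldh(pyr_eq, 0.6, 0.06, 1.8, p) == pytest.approx(0.0,
                                                                       abs=1e-9)

    def test_aldo_regression_pin(self):
        rate = rl.rate_aldo(0.5, 0.04, 0.02, ChainParams())
        assert rate == pytest.approx(5.404433792690234, rel=1e-12)

    def test_reversible_laws_vanish_at_equilibrium(self):
        p = ChainParams()
        assert rl.rate_pgi(1.0, p.q_pgi * 1.0, p) == pytest.approx(0, abs=1e-12)
        assert rl.rate_tpi(1.0, p.q_tpi * 1.0, p) == pytest.approx(0, abs=1e-12)
        assert rl.rate_eno(0.1, p.q_eno * 0.1, p) == pytest.approx(0, abs=1e-12)

    def test_rates_continuous_on_positive_orthant(self, catalog):
        """No division-by-zero poles over a broad concentration grid."""
        p = ChainParams()
        for x in np.geomspace(1e-9, 50.0, 25):
            for fn in (lambda: rl.rate_hk(x, ATP, x, p),
                       lambda: rl.rate_aldo(x, x, x, p),
                       lambda: rl.rate_gapdh(x, x, 0.6, 0.06, p),
                       lambda: rl.rate_ldh(x, 0.6, 0.06, x, p),
                       lambda: rl.rate_pfk(x, ATP, x, x, AMP,
                                           catalog["PFKL"], v_max=V_PFK),
                       lambda: rl.rate_pk(x, ADP, x, ATP, x, catalog["PKM2"])):
                assert np.isfinite(fn())
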