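"""Per-component membrane current tests: reversal zeros, gate closure,
modulation factors, pump/exchanger behaviour and the summed breakdown."""

import numpy as np
import pytest

from usmcsim import _kernels as K
from usmcsim._layout import COMPONENTS, NCOMP, NSTATES, STATE_INDEX
from usmcsim.biophys import IonicMilieu, PhysicalContext, nernst_potential
from usmcsim.currents import (cdi_factor, component_mask, default_components,
                              eval_ical, eval_icat, eval_iclca, eval_ih,
                              eval_ik1, eval_ik2, eval_ika, eval_ikb,
                              eval_ikca, eval_ina, eval_inak, eval_incx,
                              eval_inscc, mg_inhibition, ncx_allosteric,
                              ncx_reversal, total_current)
from usmcsim.parameters import Params
from usmcsim.model import CellState


@pytest.fixture(scope="module")
def derived(params):
    return K.derived_from_params(params.vector)


def ek(derived):
    return float(derived[K.D_E_K])


class TestReversalZeros:
    """Every ohmic component is exactly zero at its reversal potential."""

    def test_ical(self, params):
        assert eval_ical(params["e_cal"], 0.5, 0.5, 0.5, 1e-4) == 0.0

    def test_icat(self, params):
        assert eval_icat(params["e_cat"], 0.5, 0.5) == 0.0

    def test_ina(self, derived):
        assert eval_ina(float(derived[K.D_E_NA]), 0.5, 0.5) == \
            pytest.approx(0.0, abs=1e-12)

    def test_ih(self, derived):
        assert eval_ih(float(derived[K.D_E_H]), 0.5) == \
            pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("fn,gates", [
        (eval_ik1, (0.5, 0.5, 0.5)),
        (eval_ik2, (0.5, 0.5, 0.5)),
        (eval_ika, (0.5, 0.5)),
        (eval_ikb, ()),
    ])
    def test_potassium_components(self, derived, fn, gates):
        assert fn(ek(derived), *gates) == pytest.approx(0.0, abs=1e-12)

    def test_ikca(self, derived):
        assert eval_ikca(ek(derived), 0.5, 0.5, 1e-3) == \
            pytest.approx(0.0, abs=1e-12)

    def test_iclca(self, derived):
        assert eval_iclca(float(derived[K.D_E_CL]), 0.5, 1e-3) == \
            pytest.approx(0.0, abs=1e-9)

    def test_inscc(self, derived):
        assert eval_inscc(float(derived[K.D_E_NS])) == \
            pytest.approx(0.0, abs=1e-9)

    def test_incx_zero_at_exchanger_reversal(self, params):
        ca = 1.16e-4
        e_rev = ncx_reversal(params, ca_i=ca)
        i, flux = eval_incx(e_rev, ca, params)
        assert i == pytest.approx(0.0, abs=1e-10)
        assert flux == pytest.approx(0.0, abs=1e-14)


class TestGateClosure:
    """Any multiplicative gate at zero silences the component."""

    def test_closed_gates(self):
        v = -20.0
        assert eval_ical(v, 0.0, 0.7, 0.7, 1e-4) == 0.0
        assert eval_ical(v, 0.7, 0.0, 0.0, 1e-4) == 0.0
        assert eval_icat(v, 0.0, 0.8) == 0.0
        assert eval_ina(v, 0.5, 0.0) == 0.0
        assert eval_ih(v, 0.0) == 0.0
        assert eval_ik1(v, 0.0, 0.5, 0.5) == 0.0
        assert eval_ik2(v, 0.0, 0.5, 0.5) == 0.0
        assert eval_ika(v, 0.0, 0.5) == 0.0
        assert eval_ikca(v, 0.0, 0.0, 1e-3) == 0.0
        assert eval_iclca(v, 0.0, 1e-3) == 0.0

    def test_gate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            eval_ical(-20.0, 1.5, 0.5, 0.5, 1e-4)
        with pytest.raises(ValueError):
            eval_ina(-20.0, -0.1, 0.5)


@pytest.fixture(scope="module")
def tables(params):
    vgrid = np.arange(-120.0, 60.1, 1.0)
    out = {}
    yinf = np.empty(K.NGATES)
    tau = np.empty(K.NGATES)
    rows = []
    for v in vgrid:
        K.gate_tables(v, 1.16e-4, params.vector, yinf, tau)
        rows.append(yinf.copy())
        assert np.all(tau > 0.0)
    arr = np.asarray(rows)
    for name, idx in STATE_INDEX.items():
        if idx >= 2:
            out[name] = arr[:, idx - 2]
    return out


class TestSteadyStateOrientation:
    """Activation curves nondecreasing in V; inactivation nonincreasing."""

    ACTIVATION = ["d", "m", "b", "q", "p", "s", "xa", "xab", "c"]
    INACTIVATION = ["f1", "f2", "h", "g", "r1", "r2", "k1", "k2", "x", "y"]

    @pytest.mark.parametrize("gate", ACTIVATION)
    def test_activation_nondecreasing(self, tables, gate):
        assert np.all(np.diff(tables[gate]) >= -1e-12)

    @pytest.mark.parametrize("gate", INACTIVATION)
    def test_inactivation_nonincreasing(self, tables, gate):
        assert np.all(np.diff(tables[gate]) <= 1e-12)

    def test_gates_bounded(self, tables):
        for name, y in tables.items():
            if name == "w":
                continue
            assert np.all((y >= 0.0) & (y <= 1.0)), name


class TestModulationFactors:
    def test_cdi_halves_current_at_half_saturation(self, params):
        km = params["km_cdi"]
        full = eval_ical(-10.0, 0.5, 0.5, 0.5, 1e-9, params)
        at_km = eval_ical(-10.0, 0.5, 0.5, 0.5, km, params)
        assert at_km == pytest.approx(full / 2.0, rel=1e-6)

    def test_cdi_hill_coefficient_is_four(self, params):
        from test_biophys import logit_slope
        km = params["km_cdi"]
        s = logit_slope(lambda ca: cdi_factor(ca, params), km)
        assert s == pytest.approx(4.0, rel=1e-6)

    def test_mg_inhibition_midpoint_and_slope(self, params):
        from test_biophys import logit_slope
        km = params["ns_km_mg"]
        assert mg_inhibition(km, params) == pytest.approx(0.5)
        s = logit_slope(lambda mg: mg_inhibition(mg, params), km)
        assert s == pytest.approx(params["ns_n_mg"], rel=1e-6)

    def test_nscc_zero_cation_leaves_leak_only(self, params):
        # suppressing the permeant-cation saturation leaves the leak term
        p = params.copy()
        v = -50.0
        full = eval_inscc(v, p)
        p2 = p.update({"g_ns": 0.0})
        leak_only = eval_inscc(v, p2)
        assert abs(leak_only) < abs(full)
        d = K.derived_from_params(p2.vector)
        expected = p2["g_ns_leak"] * (v - float(d[K.D_E_NS]))
        assert leak_only == pytest.approx(expected, rel=1e-12)


class TestPumpExchanger:
    def test_inak_vanishes_without_external_potassium(self, params):
        m = IonicMilieu(k_o=1e-9)
        assert eval_inak(-50.0, params, m) == pytest.approx(0.0, abs=1e-10)

    def test_inak_nonnegative_on_grid(self, params):
        for v in np.arange(-120, 61, 10.0):
            for nai in (2.0, 6.0, 12.0):
                m = IonicMilieu(na_i=nai)
                assert eval_inak(float(v), params, m) >= 0.0

    def test_inak_q10_ratio(self, params):
        cold = params.update({"temperature": 298.15,
                              "nak_tref": 298.15})
        warm = params.update({"temperature": 308.15,
                              "nak_tref": 298.15})
        r = eval_inak(-50.0, warm) / eval_inak(-50.0, cold)
        # reversals shift slightly with T; the pump factor dominates
        assert r == pytest.approx(1.87, rel=0.02)

    def test_ncx_reversal_positive_and_extrusion_at_rest(self, params,
                                                         equilibrium):
        e_rev = ncx_reversal(params, ca_i=equilibrium["ca_i"])
        assert e_rev > 0.0
        i, flux = eval_incx(equilibrium["v"], equilibrium["ca_i"], params)
        assert i < 0.0          # forward mode: net inward current
        assert flux < 0.0       # ... extruding Ca

    def test_ncx_allosteric_monotone(self, params):
        grid = np.logspace(-5, -2.5, 40)
        vals = [ncx_allosteric(ca, params) for ca in grid]
        assert np.all(np.diff(vals) > 0)

    def test_ncx_flux_sign_linked_to_current(self, params):
        for v in (-80.0, -20.0, 40.0):
            i, flux = eval_incx(v, 1.16e-4, params)
            assert np.sign(i) == np.sign(flux)


class TestBK:
    def test_beta_proportion_zero_reduces_to_alpha_only(self, params):
        p = params.update({"bk_ab_frac": 0.0})
        v, ca = -20.0, 1e-3
        total = eval_ikca(v, 0.4, 0.9, ca, p)
        d = K.derived_from_params(p.vector)
        alpha_only = p["g_bk"] * 0.4 * (v - float(d[K.D_E_K]))
        assert total == pytest.approx(alpha_only, rel=1e-12)

    def test_half_activation_shifts_left_with_calcium(self, params):
        yinf = np.empty(K.NGATES)
        tau = np.empty(K.NGATES)
        vgrid = np.arange(-100.0, 200.0, 0.5)

        def vhalf(ca):
            acts = []
            for v in vgrid:
                K.gate_tables(v, ca, params.vector, yinf, tau)
                acts.append(yinf[16])
            return np.interp(0.5, acts, vgrid)

        cas = np.logspace(-4.2, -2.6, 6)
        vh = [vhalf(ca) for ca in cas]
        assert np.all(np.diff(vh) < 0)


class TestTotalCurrent:
    def test_breakdown_has_exactly_fourteen_components(self, equilibrium):
        itot, br = total_current(equilibrium.vector)
        assert len(br) == 14
        assert set(br) == set(COMPONENTS)

    def test_breakdown_sums_to_total(self, equilibrium):
        itot, br = total_current(equilibrium.vector)
        assert sum(br.values()) == pytest.approx(itot, rel=1e-12, abs=1e-15)

    def test_all_conductances_zero_gives_zero(self, params):
        zeroed = {g: 0.0 for g in
                  ("g_cal", "g_cat", "g_na", "g_h", "g_k1", "g_k2", "g_ka",
                   "g_bk", "g_kb", "g_cl", "g_ns", "g_ns_leak", "inak_max",
                   "ncx_vmax")}
        p = params.update(zeroed)
        itot, br = total_current(CellState.default().vector, p)
        assert itot == 0.0
        assert all(v == 0.0 for v in br.values())

    def test_component_mask(self):
        m = component_mask(disabled=("inscc",))
        assert m.sum() == 13
        m = component_mask(enabled=("ical", "ik1"))
        assert m.sum() == 2
        with pytest.raises(KeyError):
            component_mask(disabled=("bogus",))

    def test_registry_lists_all_components(self, params):
        specs = default_components(params)
        assert set(specs) == set(COMPONENTS)
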