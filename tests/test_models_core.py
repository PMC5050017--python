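"""Unit and property tests for the reduced decay models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pumpdecay import (
    CaModulationParams,
    CouplingSimParams,
    DepletionParams,
    Epoch,
    InactivationParams,
    Protocol,
    PumpParams,
    coupled_pump_exchanger,
    depletion_steady_state,
    depletion_transient,
    extract_features,
    fractional_decay,
    inactivation_steady_state,
    inactivation_transient,
    make_protocol,
    peak_current,
)
from pumpdecay.errors import DomainError, ValidationError

from conftest import bisect_depletion_root


class TestPeakCurrent:
    @pytest.mark.parametrize(
        "na, expected",
        [
            (0.0, 0.0),
            (4.0, 0.395062),  # (4/4.5)^2 * (4/8)
            (40.0, 0.886783),
        ],
    )
    def test_three_site_binding_values(self, na, expected):
        assert peak_current(na, PumpParams(Imax=1.0)) == pytest.approx(expected, abs=1e-6)

    def test_saturates_to_imax(self):
        p = PumpParams(Imax=3.7)
        assert peak_current(1e9, p) == pytest.approx(3.7, rel=1e-6)

    def test_rejects_negative_na(self):
        with pytest.raises(DomainError):
            peak_current(-1.0, PumpParams())

    @given(na=st.floats(0.01, 500), na2=st.floats(0.01, 500))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing(self, na, na2):
        p = PumpParams(Imax=1.0)
        lo, hi = sorted((na, na2))
        if hi - lo > 1e-9:
            assert peak_current(hi, p) > peak_current(lo, p)


class TestDepletionSteadyState:
    def test_no_pumping_no_depletion(self):
        nass, iss = depletion_steady_state(DepletionParams(pump=PumpParams(Imax=0.0), NaB=25))
        assert nass == 25.0 and iss == 0.0

    def test_unrestricted_diffusion_limit(self):
        p = DepletionParams(pump=PumpParams(Imax=4.0), NaB=25.0, Kdiff=1e6)
        nass, iss = depletion_steady_state(p)
        assert nass == pytest.approx(25.0, rel=1e-6)
        assert iss == pytest.approx(peak_current(25.0, p.pump), rel=1e-6)

    def test_reference_root(self):
        p = DepletionParams(pump=PumpParams(Imax=4.0), NaB=10.0, Kdiff=0.06)
        nass, iss = depletion_steady_state(p)
        assert nass == pytest.approx(1.32, abs=0.01)
        assert iss == pytest.approx(0.52, abs=0.01)

    def test_residual_below_tolerance(self):
        p = DepletionParams(pump=PumpParams(Imax=4.0), NaB=10.0)
        nass, iss = depletion_steady_state(p)
        resid = peak_current(nass, p.pump) - (p.NaB - nass) * p.Kdiff
        assert abs(resid) < 1e-10 * max(1.0, p.pump.Imax)

    def test_newton_matches_bisection_oracle_over_grid(self):
        """Safeguarded Newton agrees with interval bisection to 1e-9
        relative across 3 decades of Imax, NaB and Kdiff (27 points)."""
        for imax in (0.16, 1.6, 16.0):
            for nab in (2.5, 25.0, 250.0):
                for kdiff in (0.006, 0.06, 0.6):
                    p = DepletionParams(pump=PumpParams(Imax=imax), NaB=nab, Kdiff=kdiff)
                    nass, _ = depletion_steady_state(p)
                    oracle = bisect_depletion_root(p)
                    assert abs(nass - oracle) < 1e-9 * max(oracle, 1e-12)


class TestDepletionTransient:
    def test_no_pumping_flat(self, standard_protocol):
        p = DepletionParams(pump=PumpParams(Imax=0.0), NaB=10.0)
        tr = depletion_transient(standard_protocol, p)
        assert np.all(tr.i_pApF == 0.0)
        assert np.allclose(tr.extras["na_ss_mM"], 10.0)

    def test_requires_k_epoch(self, depl_params):
        proto = Protocol((Epoch("na", 0, 10, Na_mM=7),))
        with pytest.raises(ValidationError):
            depletion_transient(proto, depl_params)

    @pytest.mark.parametrize("imax,nab,kdiff", [(1.6, 25.0, 0.06), (4.0, 10.0, 0.06), (0.5, 40.0, 0.1)])
    def test_long_time_limit_is_steady_state(self, imax, nab, kdiff):
        p = DepletionParams(pump=PumpParams(Imax=imax), NaB=nab, Kdiff=kdiff)
        proto = Protocol((Epoch("na", 0, 2, Na_mM=nab), Epoch("k", 2, 150, K_mM=7)))
        tr = depletion_transient(proto, p, dt=0.05)
        _, iss = depletion_steady_state(p)
        assert tr.i_pApF[-1] == pytest.approx(iss, rel=1e-6)

    def test_monotone_decay_toward_steady_state(self, standard_protocol):
        p = DepletionParams(pump=PumpParams(Imax=4.0), NaB=10.0)
        tr = depletion_transient(standard_protocol, p)
        k = standard_protocol.k_epochs()[0]
        mask = tr.window(k.start_s, k.end_s)
        cur = tr.i_pApF[mask]
        assert cur[0] == pytest.approx(peak_current(10.0, p.pump), rel=1e-6)
        assert np.all(np.diff(cur) <= 1e-12)

    def test_fixed_point_consistency_random_parameter_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = DepletionParams(
                pump=PumpParams(Imax=float(rng.uniform(0.2, 8.0))),
                NaB=float(rng.uniform(3.0, 60.0)),
                Kdiff=float(rng.uniform(0.02, 0.3)),
            )
            proto = Protocol((Epoch("na", 0, 1, Na_mM=p.NaB), Epoch("k", 1, 200, K_mM=7)))
            tr = depletion_transient(proto, p, dt=0.1)
            _, iss = depletion_steady_state(p)
            assert tr.i_pApF[-1] == pytest.approx(iss, rel=1e-6)


class TestInactivationSteadyState:
    def test_half_occupancy_at_kd(self, inact_params):
        fo, _, _ = inactivation_steady_state(4.0, inact_params)
        assert fo == 0.5

    def test_saturating_na_removes_inactivation(self, inact_params):
        fo, a_ss, ratio = inactivation_steady_state(1e9, inact_params)
        assert fo == pytest.approx(0.0, abs=1e-8)
        assert ratio == pytest.approx(1.0, abs=1e-7)

    def test_reference_value_at_12mM(self, inact_params):
        fo, a_ss, ratio = inactivation_steady_state(12.0, inact_params)
        assert fo == pytest.approx(0.25)
        assert ratio == pytest.approx(0.545455, abs=1e-6)
        assert 1 - ratio == pytest.approx(0.454545, abs=1e-6)

    @pytest.mark.parametrize("na, fdec", [(2.5, 0.672), (40.0, 0.233)])
    def test_fractional_decay_defaults(self, na, fdec, inact_params):
        assert fractional_decay(na, inact_params) == pytest.approx(fdec, abs=5e-4)

    def test_fractional_decay_strictly_decreasing_in_na(self, inact_params):
        na = np.linspace(0.5, 100, 300)
        f = np.array([fractional_decay(x, inact_params) for x in na])
        assert np.all(np.diff(f) < 0)
        assert np.all((f >= 0) & (f <= 1))


class TestInactivationTransient:
    def test_matches_closed_form_within_epochs(self, standard_protocol, inact_params):
        na = 25.0
        tr = inactivation_transient(standard_protocol, inact_params, na_i_mM=na)
        fo = 4.0 / 29.0
        lam = inact_params.kr_cycling + inact_params.ki * fo
        a_inf = inact_params.kr_cycling / lam
        k = standard_protocol.k_epochs()[0]
        mask = tr.window(k.start_s, k.end_s)
        tt = tr.time_s[mask] - k.start_s
        closed = a_inf + (1.0 - a_inf) * np.exp(-lam * tt)
        assert np.max(np.abs(tr.extras["availability"][mask] - closed)) < 1e-6
        assert a_inf == pytest.approx(0.68504, abs=1e-5)
        assert 1.0 / lam == pytest.approx(2.2835, abs=1e-4)

    def test_no_inactivation_when_ki_zero(self, pump, standard_protocol):
        params = InactivationParams(pump=pump, ki=0.0)
        tr = inactivation_transient(standard_protocol, params)
        assert np.allclose(tr.extras["availability"], 1.0)

    def test_rest_recovery_between_pulses(self, inact_params):
        proto = make_protocol("deoxyglucose_rundown", n_pulses=2, rest_s=30.0)
        tr = inactivation_transient(proto, inact_params, na_i_mM=25.0)
        a = tr.extras["availability"]
        t = tr.time_s
        # availability rises during the rest epoch after the first K pulse
        rest = proto.epochs[2]
        mask = tr.window(rest.start_s, rest.end_s)
        assert np.all(np.diff(a[mask]) > 0)
        # recovery rate is kr_rest, not kr_cycling
        a0 = a[mask][0]
        expected = 1.0 - (1.0 - a0) * np.exp(-inact_params.kr_rest * (t[mask] - t[mask][0]))
        assert np.max(np.abs(a[mask] - expected)) < 1e-6

    def test_availability_always_in_unit_interval(self, inact_params):
        proto = make_protocol("ca_elevation")
        ca = CaModulationParams(m_min=0.0, a_reset=1.0)
        tr = inactivation_transient(proto, inact_params, ca_mod=ca, na_i_mM=5.0, a0=0.3)
        a = tr.extras["availability"]
        assert np.all((a >= 0.0) & (a <= 1.0 + 1e-12))

    def test_full_ca_block_removes_decay(self, inact_params):
        """With the modifier floored at zero immediately after the Ca
        episode, the post-Ca K epoch decays only through recovery kinetics:
        availability cannot fall below its a_reset starting point."""
        proto = make_protocol("ca_elevation", gap_s=2.0, recovery_s=2.0)
        ca = CaModulationParams(m_min=0.0, tau_ca_s=1e7, a_reset=1.0)
        tr = inactivation_transient(proto, inact_params, ca_mod=ca, na_i_mM=25.0)
        post = proto.k_epochs()[1]
        feats = extract_features(tr, proto, t_plateau=10.0).epochs[1]
        assert feats.F_decay == pytest.approx(0.0, abs=1e-6)


class TestCoupledPumpExchanger:
    def test_exchanger_loading_rate(self):
        """90 pA of 3:1 exchanger current into 3 pL loads Na at 0.93 mM/s."""
        params = CouplingSimParams(Imax_pA=300.0, V_cyto_pL=3.0, Na0=10.0, k_pip=0.0)
        i_pump_at_na0 = 300.0 * 10.0 / 15.0
        assert params.ncx_fraction * i_pump_at_na0 == pytest.approx(60.0)
        # use an ncx_fraction that yields exactly 90 pA for the rate check
        params = CouplingSimParams(Imax_pA=300.0, V_cyto_pL=3.0, Na0=10.0,
                                   ncx_fraction=90.0 / i_pump_at_na0)
        sched = Protocol((Epoch("load", 0, 5, Ca_mM=5.0),))
        tr = coupled_pump_exchanger(params, sched, dt=0.001)
        dna_dt = (tr.extras["na_mM"][10] - tr.extras["na_mM"][0]) / (10 * 0.001)
        assert dna_dt == pytest.approx(0.93, abs=0.01)

    def test_closed_pool_decays_toward_zero(self):
        params = CouplingSimParams(k_pip=0.0)
        sched = Protocol((Epoch("k", 0, 300, K_mM=7.0),))
        tr = coupled_pump_exchanger(params, sched, dt=0.05)
        na = tr.extras["na_mM"]
        assert np.all(np.diff(na) < 1e-12)
        assert na[-1] < 0.05 * params.Na0
        assert tr.i_pApF[-1] < 0.05 * tr.i_pApF[0]

    def test_preloading_raises_subsequent_peak(self):
        params = CouplingSimParams()

        def peak(preload: bool) -> float:
            epochs = (
                Epoch("pre", 0, 30, Ca_mM=5.0, Ni=not preload),
                Epoch("k", 30, 20, K_mM=7.0),
            )
            tr = coupled_pump_exchanger(params, Protocol(epochs))
            return float(tr.i_pApF.max())

        assert peak(True) > peak(False)

    def test_invalid_volume_rejected(self):
        with pytest.raises(ValidationError):
            CouplingSimParams(V_cyto_pL=-1.0)
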