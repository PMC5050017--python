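"""Synthetic experiment generator: determinism, noise statistics, presets
and full pipeline closure."""

import numpy as np
import pytest
from scipy import stats

from pumpdecay import (
    CaModulationParams,
    InactivationParams,
    SynthConfig,
    extract_features,
    fit_hill,
    inactivation_steady_state,
    make_protocol,
    read_trace,
    synth_ca_experiment,
    synth_na_titration,
    synth_trace,
    write_trace,
)
from pumpdecay.errors import ValidationError
from pumpdecay.synthetic_data import table1_control_params


class TestSynthTrace:
    def test_seed_determinism(self):
        a = synth_trace(SynthConfig(seed=5, noise_sd=0.05))
        b = synth_trace(SynthConfig(seed=5, noise_sd=0.05))
        assert np.array_equal(a.i_pApF, b.i_pApF)
        assert np.array_equal(a.cm_pF, b.cm_pF)

    def test_different_seeds_differ(self):
        a = synth_trace(SynthConfig(seed=5, noise_sd=0.05))
        b = synth_trace(SynthConfig(seed=6, noise_sd=0.05))
        assert not np.array_equal(a.i_pApF, b.i_pApF)

    def test_seed_required(self):
        with pytest.raises(ValidationError):
            SynthConfig(seed=None)

    def test_noise_sd_within_chi2_interval(self):
        """Residual SD of an sd=0.05 trace lies in the 99% chi-square
        interval around 0.05."""
        cfg = SynthConfig(seed=17, noise_sd=0.05)
        noiseless = synth_trace(SynthConfig(seed=17, noise_sd=0.0))
        noisy = synth_trace(cfg)
        resid = noisy.i_pApF - noiseless.i_pApF
        n = resid.size
        s2 = float(np.sum(resid**2)) / 0.05**2
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n)
        assert lo < s2 < hi

    def test_extracted_decay_matches_closed_form(self):
        """At 25 mM Na with default rates the extracted fractional decay
        approaches the closed-form 0.315 (plateau at 10 s is slightly shy
        of the asymptote)."""
        tr = synth_trace(SynthConfig(seed=1, na_i_mM=25.0))
        proto = make_protocol("standard_k_pulse")
        feats = extract_features(tr, proto, t_plateau=10.0).epochs[0]
        assert feats.F_decay == pytest.approx(0.31496, abs=0.01)

    def test_capacitance_step_on_k_application(self):
        cfg = SynthConfig(seed=2, cm_avail_coupling=0.0)
        tr = synth_trace(cfg)
        proto = cfg.protocol
        k = proto.k_epochs()[0]
        pre = tr.cm_pF[tr.window(k.start_s - 1.0, k.start_s)].mean()
        during = tr.cm_pF[tr.window(k.start_s, k.start_s + 1.0)].mean()
        assert during / pre == pytest.approx(1.0 + cfg.dCm_K_frac, rel=1e-6)

    def test_capacitance_tracks_availability_affinely(self):
        """With the Ca term disabled, capacitance is an affine image of the
        availability time course."""
        cfg = SynthConfig(seed=3, dCm_K_frac=0.0, dCm_Ca_frac=0.0,
                          cm_avail_coupling=0.01)
        tr = synth_trace(cfg)
        a = tr.extras["availability"]
        pred = cfg.Cm0_pF * (1.0 + cfg.cm_avail_coupling * (a - 1.0))
        assert np.max(np.abs(tr.cm_pF - pred)) < 1e-9

    def test_metadata_records_generator_truth(self):
        cfg = SynthConfig(seed=9, na_i_mM=12.0, noise_sd=0.02)
        tr = synth_trace(cfg)
        assert tr.metadata["seed"] == 9
        assert tr.metadata["Na_i_mM"] == 12.0
        assert tr.metadata["noise_sd"] == 0.02
        assert tr.metadata["model"] == "inactivation"


class TestNaTitration:
    def test_empty_reps_empty_table(self):
        df = synth_na_titration("inactivation", [5.0, 10.0], reps=0, seed=1)
        assert df.empty

    def test_noiseless_plateau_peak_ratio_matches_closed_form(self):
        na_grid = [5.0, 10.0, 25.0, 40.0]
        df = synth_na_titration("inactivation", na_grid, reps=1, seed=1)
        params = InactivationParams()
        for _, row in df.iterrows():
            _, a_ss, _ = inactivation_steady_state(row.Na_mM, params)
            # plateau at 10 s sits within 2% of the steady availability
            assert row.I_plateau / row.I_peak == pytest.approx(a_ss, rel=0.02)

    def test_hill_truth_recovery_with_noise(self):
        """Median fitted K50 over noisy replicates lands within 10% of the
        generating K50 (the concentration-response recovery contract)."""
        truth = {"K50": 19.0, "h": 2.4, "ymax": 1.0}
        df = synth_na_titration(
            "hill", [2.5, 5, 10, 15, 20, 25, 30, 40], reps=25,
            noise_frac=0.05, seed=11, hill_truth=truth,
        )
        k50s = [
            fit_hill(sub["Na_mM"], sub["I_peak"]).K50
            for _, sub in df.groupby("rep")
        ]
        assert 17.1 <= float(np.median(k50s)) <= 20.9

    def test_unknown_model_rejected(self):
        with pytest.raises(ValidationError):
            synth_na_titration("voltage", [5.0], seed=1)


@pytest.fixture(scope="module")
def preset():
    cfg = table1_control_params()
    trace = synth_ca_experiment("table1_control", seed=0)
    feats = extract_features(trace, cfg["protocol"],
                             t_plateau=cfg["t_plateau_s"]).epochs
    return cfg, feats


class TestTable1ControlPreset:
    def test_pre_ca_fractional_decay(self, preset):
        _, feats = preset
        assert feats[0].F_decay == pytest.approx(0.65, abs=0.01)

    def test_post_ca_fractional_decay(self, preset):
        _, feats = preset
        assert feats[1].F_decay == pytest.approx(0.28, abs=0.01)

    def test_peak_enhancement_ratio(self, preset):
        _, feats = preset
        assert feats[1].I_peak / feats[0].I_peak == pytest.approx(1.54, abs=0.01)

    def test_neutral_modifier_reproduces_unmodulated_trace(self):
        """m_min=1 with no availability reset means the Ca episode has no
        after-effect at all."""
        neutral = CaModulationParams(m_min=1.0, a_reset=None)
        a = synth_ca_experiment("custom", seed=4, ca_mod=neutral)
        b = synth_ca_experiment("custom", seed=4, ca_mod=None)
        assert np.array_equal(a.i_pApF, b.i_pApF)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValidationError):
            synth_ca_experiment("table1_blebbistatin", seed=0)


class TestPipelineClosure:
    @pytest.mark.parametrize("model", ["inactivation", "depletion", "cycle"])
    def test_synth_write_read_extract_recovers_truth(self, model, tmp_path):
        """Full loop: generate -> CSV -> parse -> features; the extracted
        peak matches the generator truth embedded in the metadata."""
        proto = make_protocol("standard_k_pulse")
        cfg = SynthConfig(model=model, protocol=proto, seed=21, na_i_mM=25.0,
                          dt_s=0.02)
        tr = synth_trace(cfg)
        path = tmp_path / "trace.csv"
        write_trace(tr, path)
        back = read_trace(path)
        assert back.metadata["seed"] == 21
        feats = extract_features(back, proto, t_plateau=10.0).epochs[0]
        assert feats.defined
        # extracted peak is baseline-subtracted (the cycle model carries a
        # tiny contaminating-K standing current outside the K epoch)
        truth_peak = float(np.max(tr.i_pApF)) - feats.baseline_pApF
        assert feats.I_peak == pytest.approx(truth_peak, rel=1e-6)
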