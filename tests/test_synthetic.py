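import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

import circuitclock as cc
from circuitclock.data_io import PharmEpoch, StimulusEvent
from circuitclock.synthetic import (
    AcuteProtocol,
    LongtermProtocol,
    PopulationConfig,
    ResponseComponent,
    electrical_components,
    waveform,
)


class TestWaveformExponent:
    def test_cosine_half_width(self):
        assert cc.solve_waveform_exponent(12.0, 24.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [2.0, 4.0, 7.0, 12.0, 18.0, 20.0])
    def test_matches_bisection_oracle_and_measured_width(self, width):
        period = 24.0
        k = cc.solve_waveform_exponent(width, period)

        def measured_width(kk):
            # w decreases from 1 at the peak to -1 half a cycle out; the
            # zero crossing at t* gives a half-max width of 2 t*
            t_star = brentq(
                lambda t: waveform(t, 0.0, period, kk), 1e-9, period / 2 - 1e-9
            )
            return 2.0 * t_star

        k_oracle = brentq(
            lambda kk: measured_width(kk) - width, 0.05, 200.0, xtol=1e-12
        )
        assert k == pytest.approx(k_oracle, rel=1e-6)
        assert abs(measured_width(k) - width) < 1.0 / 60.0  # within one minute

    def test_width_beyond_unimodal_limit_errors(self):
        with pytest.raises(ValueError, match="unimodal"):
            cc.solve_waveform_exponent(23.9, 24.0)

    def test_width_bounds_errors(self):
        with pytest.raises(ValueError):
            cc.solve_waveform_exponent(24.0, 24.0)
        with pytest.raises(ValueError):
            cc.solve_waveform_exponent(0.0, 24.0)


class TestRateFunction:
    def test_flat_cell_identity(self):
        spec = cc.CellSpec("u", baseline_rate=5.0)
        assert cc.rate_function(spec, 100.0, duration=1000.0) == 5.0

    def test_envelope_closed_form_peak_and_trough(self):
        spec = cc.CellSpec(
            "u", rhythmic=True, baseline_rate=10.0, peak_trough_amplitude=10.0,
            peak_time=0.0, peak_ref="rec", peak_width=12.0,
        )
        assert cc.circadian_envelope(spec, 0.0) == pytest.approx(15.0)
        assert cc.circadian_envelope(spec, 12 * 3600.0) == pytest.approx(5.0)

    def test_pharmacological_gating_of_inhibition(self):
        comp = ResponseComponent("GABA", "inhibition", 0.005, 0.150, 0.1)
        spec = cc.CellSpec("u", baseline_rate=5.0, components=(comp,))
        stim = [StimulusEvent(10.0, "electrical"), StimulusEvent(500.0, "electrical")]
        epochs = [PharmEpoch("baseline", 0.0, 100.0), PharmEpoch("BIC", 100.0, 1000.0)]
        t_resp = 10.0 + 0.050
        assert cc.rate_function(spec, t_resp, stim, epochs, 1000.0) == pytest.approx(0.5)
        assert cc.rate_function(spec, 500.05, stim, epochs, 1000.0) == pytest.approx(5.0)

    def test_mixed_cell_net_inhibited_then_excited(self):
        spec = cc.CellSpec(
            "u", baseline_rate=5.0, components=electrical_components("Mixed")
        )
        stim = [StimulusEvent(10.0, "electrical"), StimulusEvent(500.0, "electrical")]
        epochs = [PharmEpoch("baseline", 0.0, 100.0), PharmEpoch("BIC", 100.0, 1000.0)]
        # both components overlap at +20 ms: shunted drive at baseline,
        # unmasked glutamatergic excitation under BIC
        assert cc.rate_function(spec, 10.020, stim, epochs, 1000.0) == pytest.approx(2.5)
        assert cc.rate_function(spec, 500.020, stim, epochs, 1000.0) == pytest.approx(25.0)

    def test_ttx_silences_even_chr2(self):
        comp = ResponseComponent("ChR2", "excitation", 0.002, 0.015, 40.0, "opto_wide")
        spec = cc.CellSpec("u", baseline_rate=5.0, components=(comp,))
        stim = [StimulusEvent(10.0, "opto_wide")]
        epochs = [PharmEpoch("TTX", 0.0, 100.0)]
        assert cc.rate_function(spec, 10.005, stim, epochs, 100.0) == 0.0

    def test_time_outside_session_errors(self):
        spec = cc.CellSpec("u")
        with pytest.raises(ValueError):
            cc.rate_function(spec, 2000.0, duration=1000.0)


class TestSimulateSession:
    def test_zero_rate_cell_is_silent(self):
        specs = [cc.CellSpec("u", baseline_rate=0.0)]
        session, _ = cc.simulate_session(
            specs, AcuteProtocol(baseline_min=5, bic_min=0, bic_iglux_min=0), seed=0
        )
        assert session.trains[0].n_spikes() == 0

    def test_homogeneous_count_within_poisson_bounds(self):
        proto = AcuteProtocol(baseline_min=25, bic_min=0, bic_iglux_min=0, opto=False)
        for seed in range(5):
            specs = [cc.CellSpec("u", baseline_rate=10.0, components=())]
            session, _ = cc.simulate_session(specs, proto, seed=seed)
            n = session.trains[0].n_spikes()
            expected = 10.0 * proto.duration
            assert abs(n - expected) < 4 * np.sqrt(expected)

    def test_same_seed_bit_identical(self, tmp_path):
        cfg = PopulationConfig(n_cells=5)
        for d in ("a", "b"):
            specs = cc.sample_population(cfg, seed=3)
            session, _ = cc.simulate_session(
                specs, AcuteProtocol(baseline_min=5, bic_min=5, bic_iglux_min=5),
                seed=3,
            )
            cc.write_session(session, tmp_path / d)
        assert (tmp_path / "a" / "spikes.tsv").read_bytes() == (
            tmp_path / "b" / "spikes.tsv"
        ).read_bytes()

    def test_thinning_piecewise_rate_chi2(self):
        """Counts per epoch of a pharmacologically gated cell are Poisson."""
        comp = ResponseComponent("GABA", "inhibition", 0.0, 1.0, 0.5)
        # inhibition covers [stim, stim+1) of every 2-s cycle at baseline only
        proto = AcuteProtocol(
            baseline_min=10, bic_min=10, bic_iglux_min=0, opto=False
        )
        counts, expected = [], []
        for seed in range(30):
            spec = cc.CellSpec("u", baseline_rate=8.0, components=(comp,),
                               latency_jitter_sd=0.0)
            session, _ = cc.simulate_session([spec], proto, seed=100 + seed)
            t = session.trains[0].spike_times
            counts.append(
                [np.sum(t < 600.0), np.sum(t >= 600.0)]
            )
            # baseline epoch: half of each cycle at 8 Hz, half at 4 Hz
            expected.append([600.0 * (0.5 * 8 + 0.5 * 4), 600.0 * 8])
        counts = np.array(counts, dtype=float)
        expected = np.array(expected, dtype=float)
        z = (counts - expected) / np.sqrt(expected)
        # 60 standardised Poisson counts: mean ~0, variance ~1
        assert abs(z.mean()) < 0.5
        assert 0.5 < z.var() < 2.0

    def test_truth_table_bijective_with_trains(self):
        specs = cc.sample_population(PopulationConfig(n_cells=12), seed=1)
        session, truth = cc.simulate_session(
            specs, AcuteProtocol(baseline_min=2, bic_min=0, bic_iglux_min=0), seed=1
        )
        assert sorted(truth["unit_id"]) == sorted(t.unit_id for t in session.trains)


class TestGatingProperty:
    def test_synaptic_cells_flat_under_full_blockade(self):
        """Post-stimulus rate under BIC+iGlu-X matches baseline for synaptic cells."""
        proto = AcuteProtocol(baseline_min=0.1, bic_min=0.1, bic_iglux_min=25,
                              opto=False)
        for cls in ("GABA_inhibited", "Mixed", "Glu_activated"):
            spec = cc.CellSpec(
                "u", true_class=cls, baseline_rate=5.0,
                components=electrical_components(cls),
            )
            session, _ = cc.simulate_session([spec], proto, seed=17)
            t = session.trains[0].spike_times
            ep = session.epoch("BIC_iGluX")
            stims = session.stimulus_times("electrical")
            stims = stims[(stims >= ep.start) & (stims < ep.end - 0.3)]
            post = sum(
                np.sum((t >= s) & (t < s + 0.3)) for s in stims
            ) / (0.3 * stims.size)
            assert abs(post - 5.0) < 4 * np.sqrt(5.0 / (0.3 * stims.size))


class TestSamplePopulation:
    def test_reproducible_under_seed(self):
        a = cc.sample_population(PopulationConfig(n_cells=40), seed=5)
        b = cc.sample_population(PopulationConfig(n_cells=40), seed=5)
        assert [s.unit_id for s in a] == [s.unit_id for s in b]
        assert [s.true_class for s in a] == [s.true_class for s in b]
        assert [s.peak_time for s in a] == [s.peak_time for s in b]

    def test_all_nonresponsive_config(self):
        cfg = PopulationConfig(
            n_cells=20,
            class_probs={"non_responsive": 1.0},
            rhythmic_fractions={"non_responsive": 0.0},
        )
        specs = cc.sample_population(cfg, seed=0)
        assert all(s.true_class == "non_responsive" for s in specs)
        assert all(not s.rhythmic and not s.components for s in specs)

    def test_rhythmic_fraction_binomial(self):
        cfg = PopulationConfig(
            n_cells=100,
            class_probs={"non_responsive": 1.0},
            rhythmic_fractions={"non_responsive": 0.8},
        )
        n_rhythmic = sum(s.rhythmic for s in cc.sample_population(cfg, seed=2))
        assert stats.binom.ppf(0.001, 100, 0.8) <= n_rhythmic <= stats.binom.ppf(0.999, 100, 0.8)

    def test_scn_removed_mode(self):
        cfg = PopulationConfig(n_cells=50, scn_intact=False)
        specs = cc.sample_population(cfg, seed=4)
        assert all(not s.components for s in specs)
        assert all(s.peak_ref == "rec" for s in specs)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(class_probs={"non_responsive": 0.9, "Mixed": 0.4})
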