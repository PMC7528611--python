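import numpy as np
import pytest
from scipy import stats

import circuitclock as cc
from circuitclock.data_io import PharmEpoch, SpikeTrain
from circuitclock.stim_response import (
    PSTH,
    analysis_epochs,
    build_psth,
    detect_response,
    null_call_rate_expectation,
    response_amplitude,
    response_latency,
)
from circuitclock.synthetic import AcuteProtocol, ResponseComponent


def _train(times):
    return SpikeTrain("u", "sl", np.asarray(times, dtype=float), 0.0, 0.0)


EPOCH = PharmEpoch("baseline", 0.0, 100.0)


class TestBuildPsth:
    def test_direct_counting(self):
        train = _train([9.95, 10.01])
        psth = build_psth(train, np.array([10.0]), EPOCH, pre=0.1, post=0.1,
                          bin_width=0.01)
        assert psth.n_trials == 1
        counts = dict(zip(np.round(psth.bin_starts, 3), psth.counts))
        assert counts[-0.05] == 1 and counts[0.01] == 1
        assert psth.counts.sum() == 2

    def test_truncated_trial_dropped(self):
        train = _train([50.0])
        events = np.array([10.0, 99.95])  # second event's post window leaves epoch
        psth = build_psth(train, events, EPOCH, pre=0.5, post=0.1)
        assert psth.n_trials == 1

    def test_baseline_rate_estimate(self, rng):
        # 5 Hz homogeneous spikes, 750 trials of 0.5 s pre-window
        duration = 2000.0
        train = _train(np.sort(rng.uniform(0, duration, int(5 * duration))))
        events = np.arange(1.0, 1501.0, 2.0)
        psth = build_psth(train, events, PharmEpoch("baseline", 0.0, duration))
        assert psth.n_trials == 750
        assert psth.baseline_rate == pytest.approx(5.0, abs=0.35)

    def test_no_usable_trials_errors(self):
        with pytest.raises(ValueError, match="no usable stimulus"):
            build_psth(_train([1.0]), np.array([200.0]), EPOCH)


class TestDetectResponse:
    def _psth(self, counts, baseline_rate=5.0, n_trials=750):
        counts = np.asarray(counts)
        return PSTH(
            bin_starts=np.arange(counts.size) * 0.025,
            bin_width=0.025,
            counts=counts,
            n_trials=n_trials,
            pre_window=0.5,
            baseline_rate=baseline_rate,
        )

    def test_all_bins_at_expectation_is_none(self):
        assert detect_response(self._psth([94, 94, 94, 94])) == "none"

    def test_poisson_quantile_oracle_per_bin(self):
        # mu = 5 * 0.025 * 750 = 93.75; scipy puts the 99% limits at (70, 120)
        mu = 93.75
        lo, up = stats.poisson.ppf([0.005, 0.995], mu)
        assert (lo, up) == (70.0, 120.0)
        assert detect_response(self._psth([94, 150, 94, 94]), correction=None) == "excited"
        assert detect_response(self._psth([94, 40, 94, 94]), correction=None) == "inhibited"

    def test_first_crossing_wins(self):
        psth = self._psth([40, 150, 94, 94])
        assert detect_response(psth, correction=None) == "inhibited"
        psth = self._psth([150, 40, 94, 94])
        assert detect_response(psth, correction=None) == "excited"

    def test_zero_baseline_cannot_be_inhibited(self):
        assert detect_response(self._psth([0, 0, 0, 0], baseline_rate=0.0)) == "none"
        assert detect_response(self._psth([9, 0, 0, 0], baseline_rate=0.0)) == "excited"

    def test_sidak_correction_widens_bounds(self):
        # a count just outside the per-bin limits is inside the corrected ones
        psth = self._psth([121, 94, 94, 94])
        assert detect_response(psth, correction=None) == "excited"
        assert detect_response(psth, correction="sidak") == "none"

    def test_null_audit_matches_nominal_levels(self):
        per_bin = null_call_rate_expectation(correction=None, n_sims=40_000)
        corrected = null_call_rate_expectation(correction="sidak", n_sims=40_000)
        assert 0.02 < per_bin < 0.06  # ~4x the per-bin alpha, as expected
        assert corrected < 0.02


class TestAmplitude:
    def _session(self, cls, seed=0):
        spec = cc.CellSpec(
            "u", baseline_rate=5.0,
            components=cc.synthetic.electrical_components(cls),
        )
        proto = AcuteProtocol(baseline_min=25, bic_min=0, bic_iglux_min=0, opto=False)
        session, _ = cc.simulate_session([spec], proto, seed=seed)
        return session

    def test_no_modulation_amplitude_near_zero(self):
        session = self._session("non_responsive")
        amp = response_amplitude(
            session.trains[0], session.stimulus_times("electrical"),
            session.epochs[0],
        )
        assert abs(amp) < 1.5

    def test_excitation_amplitude_recovered(self):
        session = self._session("Glu_activated")
        amp = response_amplitude(
            session.trains[0], session.stimulus_times("electrical"),
            session.epochs[0],
        )
        assert amp == pytest.approx(20.0, abs=3.0)

    def test_inhibition_amplitude_recovered(self):
        session = self._session("GABA_inhibited")
        amp = response_amplitude(
            session.trains[0], session.stimulus_times("electrical"),
            session.epochs[0],
        )
        assert amp == pytest.approx(-4.5, abs=1.5)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        spikes = np.sort(rng.uniform(0, 500, 2000))
        events = np.arange(10.0, 490.0, 2.0)
        base = response_amplitude(_train(spikes), events,
                                  PharmEpoch("baseline", 0.0, 500.0))
        shift = 1000.0
        shifted = response_amplitude(
            _train(spikes + shift), events + shift,
            PharmEpoch("baseline", shift, shift + 500.0),
        )
        assert base == pytest.approx(shifted)


class TestLatency:
    def _session(self, latency_s, seed=0, magnitude=20.0):
        comp = ResponseComponent("glutamate", "excitation", latency_s, 0.050,
                                 magnitude)
        spec = cc.CellSpec("u", baseline_rate=5.0, components=(comp,))
        proto = AcuteProtocol(baseline_min=25, bic_min=0, bic_iglux_min=0, opto=False)
        session, _ = cc.simulate_session([spec], proto, seed=seed)
        return session

    def test_onset_at_zero_estimates_near_zero(self):
        session = self._session(0.0)
        lat = response_latency(
            session.trains[0], session.stimulus_times("electrical"),
            session.epochs[0],
        )
        assert lat is not None and lat <= 0.001

    def test_no_response_leaves_latency_undefined(self):
        spec = cc.CellSpec("u", baseline_rate=5.0)
        proto = AcuteProtocol(baseline_min=25, bic_min=0, bic_iglux_min=0, opto=False)
        session, _ = cc.simulate_session([spec], proto, seed=12)
        call = cc.call_response(
            session.trains[0], session.stimulus_times("electrical"),
            session.epochs[0], "electrical",
        )
        assert call.direction == "none"
        assert call.latency is None

    def test_population_median_monotone_in_truth(self):
        """Medians across cells rise with true latency on a coarse grid."""
        medians = []
        for latency_ms in (2, 20, 40):
            ests = []
            for seed in range(7):
                session = self._session(latency_ms / 1000.0, seed=40 + seed)
                lat = response_latency(
                    session.trains[0], session.stimulus_times("electrical"),
                    session.epochs[0],
                )
                if lat is not None:
                    ests.append(lat)
            medians.append(np.median(ests) * 1000)
        assert medians[0] <= medians[1] <= medians[2]
        assert medians[2] > medians[0]

    def test_inhibited_cells_faster_than_polysynaptic_activations(self):
        """Monosynaptic inhibition onset precedes the disinhibitory activation."""
        proto = AcuteProtocol(baseline_min=25, bic_min=0, bic_iglux_min=0, opto=False)
        fx = cc.EffectSizes()
        lat_inh, lat_act = [], []
        for seed in range(6):
            specs = [
                cc.CellSpec("inh", baseline_rate=5.0,
                            components=cc.synthetic.electrical_components("GABA_inhibited", fx)),
                cc.CellSpec("act", baseline_rate=5.0,
                            components=cc.synthetic.electrical_components("GABA_activated", fx)),
            ]
            session, _ = cc.simulate_session(specs, proto, seed=60 + seed)
            ev = session.stimulus_times("electrical")
            ep = session.epochs[0]
            a = response_latency(session.train("inh"), ev, ep)
            b = response_latency(session.train("act"), ev, ep)
            if a is not None:
                lat_inh.append(a)
            if b is not None:
                lat_act.append(b)
        assert np.mean(lat_inh) < np.mean(lat_act)


def test_analysis_epochs_trailing_25_minutes(acute_session_sixpack):
    session, _ = acute_session_sixpack
    eps = analysis_epochs(session)
    by_label = {e.label: e for e in eps}
    assert by_label["baseline"].duration == pytest.approx(25 * 60.0)
    assert by_label["baseline"].end == session.epoch("baseline").end
    assert by_label["BIC"].duration == pytest.approx(25 * 60.0)
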