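"""Simulate an acute stimulation session with known ground truth.

Builds a small population spanning the evoked-response classes, runs the
standard acute protocol (1 h baseline → 30 min BIC → 30 min BIC+iGlu-X,
electrical pulses every 2 s) and prints what was generated.
"""

from circuitclock import AcuteProtocol, PopulationConfig, sample_population, simulate_session

config = PopulationConfig(n_cells=10)
specs = sample_population(config, seed=42)
session, truth = simulate_session(specs, AcuteProtocol(), seed=42)

print(f"session {session.session_id}: {session.duration/3600:.1f} h, "
      f"{len(session.trains)} units, {len(session.stimuli)} stimuli, "
      f"epochs {[e.label for e in session.epochs]}")
print(truth[["unit_id", "true_class", "opto_identity", "region"]].to_string(index=False))
total = sum(t.n_spikes() for t in session.trains)
print(f"total spikes: {total}  (mean rate "
      f"{total/len(session.trains)/session.duration:.2f} Hz/unit)")
print("Each row is one simulated unit; true_class is the ground-truth synaptic "
      "input pattern the analysis pipeline should recover.")
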