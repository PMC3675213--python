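"""Replay a session through the per-trial online adaptation protocol.

Run 1 is calibration only. From run 2 on, each trial is classified by a
CSP+LDA model retrained on all trials of the previous run plus the
already-revealed trials of the current run, so trial k of a run trains
on 40 + (k-1) trials and never sees the future.
"""

from sensebci import EffectSpec, ParadigmSpec, generate_session, simulate_online

session = generate_session(ParadigmSpec(), EffectSpec(), seed=1)
trace = simulate_online(session, band="broad", window=(4.0, 7.0))

print(f"predictions: {trace.n_predictions} (runs 2-4; run 1 calibrates)")
first = trace.records.iloc[0]
print(f"first prediction: run {first.run_index}, trial {first.k_in_run}, "
      f"training set size {first.training_set_size}")
last = trace.records.iloc[-1]
print(f"last prediction: run {last.run_index}, trial {last.k_in_run}, "
      f"training set size {last.training_set_size}")
for run, acc in trace.run_accuracy.items():
    print(f"run {run} online accuracy: {acc:.3f}")
print(f"overall: {trace.overall_accuracy:.3f} -- with stationary synthetic "
      "data this matches offline CV at comparable training size")
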