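"""Back-fit a recording and extract the classical microstate statistics.

Labels every sample of a synthetic subject with its best-correlated planted
template, then prints mean duration (ms), occurrence rate (/s), coverage,
and the segment-mode transition matrix next to the planted jump matrix.
"""
import numpy as np

import msdyn as m

cfg = m.SimulationConfig(duration=480.0, snr=8.0, seed=7)
rec, truth = m.simulate_subject(cfg)
filtered = m.bandpass(m.average_reference(rec))
seq = m.backfit(filtered, truth.templates)

props = m.microstate_properties(seq)
print("state  duration_ms  occurrence_/s  coverage")
for name in "ABCD":
    print(f"  {name}    {props['mean_duration_ms'][name]:9.1f}"
          f"  {props['occurrence_per_s'][name]:10.2f}"
          f"  {props['coverage'][name]:8.3f}")

tm = m.transition_matrix(seq, mode="segment")
err = np.max(np.abs(tm.probs - truth.jump_matrix.probs))
print("\nsegment transition matrix (rows sum to 1, zero diagonal):")
print(np.round(tm.probs, 3))
print(f"max |error| vs planted jump matrix: {err:.3f}")
# Per-sample fitting fragments dwells at the carrier's amplitude troughs, so
# raw durations read low; the jump structure (which state follows which) is
# recovered almost exactly.
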