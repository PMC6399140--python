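"""Simulate one resting-state subject and derive its microstate templates.

Generates 2 minutes of 31-channel EEG with four planted topographies riding
a 10 Hz carrier, then runs the segmentation stack: average reference,
2-20 Hz zero-phase band-pass, GFP, peak picking, and AAHC clustering at k=4.
Prints the explained variance and how well each recovered template matches
its planted map (1.0 = perfect, polarity-free).
"""
import numpy as np

import msdyn as m
from msdyn.gfp import peak_maps

cfg = m.SimulationConfig(duration=120.0, snr=4.0, seed=42)
rec, truth = m.simulate_subject(cfg)

filtered = m.bandpass(m.average_reference(rec))          # 2-20 Hz, zero phase
gfp = m.smooth_gfp(m.compute_gfp(filtered))              # 5-tap Gaussian
peaks = m.subsample_peaks(m.find_gfp_peaks(gfp), 10_000, seed=0)
maps, gfp_at_peaks = peak_maps(filtered, peaks)
solution = m.aahc(maps, gfp_at_peaks, k=4)

print(f"{peaks.n_selected} GFP peaks clustered, GEV = {solution.gev:.3f}")
aligned, _ = m.align_templates(solution.templates, truth.templates)
for i, name in enumerate("ABCD"):
    corr = m.spatial_correlation(aligned.maps[i], truth.templates.maps[i])
    print(f"template {name}: |spatial corr| to planted map = {corr:.3f}")
# GEV is the GFP-weighted variance the 4 templates explain at the peaks;
# correlations near 1 mean the planted topographies were recovered.
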