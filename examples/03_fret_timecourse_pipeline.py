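"""Quantify per-cell FRET ratio timecourses from a synthetic stack.

Simulates 12 cells with a 10% ratio step at frame 10 under 2% multiplicative
noise plus one over-bright cell, then runs the full pipeline: background
subtraction, per-cell R_t = FRET/donor, brightness QC, R/R0 normalisation
and signal-to-noise ratios.
"""

import numpy as np

from lockrkit.fret_quant import (
    background_subtract,
    normalize,
    qc_exclude,
    ratio_trace,
    snr,
)
from lockrkit.synthetic import MicroscopySimConfig, simulate_microscopy

cfg = MicroscopySimConfig(
    seed=20,
    image_shape=(320, 320),
    n_cells=12,
    noise_cv=0.02,
    step_amplitude=0.10,
    stimulus_frame=10,
    bright_outlier_cell=7,
)
sim = simulate_microscopy(cfg)

stack = background_subtract(sim.stack, sim.background_roi)
qc = qc_exclude(list(sim.true_acceptor.index), sim.true_acceptor.to_numpy())
print("QC excluded (acceptor > mean + 3 s.d.):", qc.excluded)

traces = [
    ratio_trace(stack, roi) for roi in sim.cell_rois if roi.label in qc.kept
]
traces = normalize(traces, "r0")

amps = [t.R[cfg.stimulus_frame :].mean() - t.R0 for t in traces]
print(f"mean recovered step amplitude: {np.mean(amps):.4f} (planted 0.10)")
print(f"mean R/R0 plateau: {np.mean([t.normalized[-1] for t in traces]):.4f} "
      "(expected ~1.10: a 10% ratio rise over basal)")

snrs = [snr(t, (0, cfg.stimulus_frame)) for t in traces]
print(f"median single-cell SNR (max rise / baseline s.d.): {np.median(snrs):.1f}")
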