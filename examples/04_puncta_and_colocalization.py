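"""Detect ratio-bright puncta and compare puncta vs diffuse Ras activity.

Simulates cells containing 1-um condensate-like puncta whose FRET ratio is
twice the cell body's, detects them with the circularity (>0.5) and area
(>1 um^2) particle filters, and contrasts mean ratios inside and outside
the puncta, plus channel co-localization statistics.
"""

import numpy as np

from lockrkit.fret_quant import ratio_image
from lockrkit.imaging_stats import (
    detect_puncta,
    manders_coloc,
    pearson_coloc,
    region_ratio_stats,
)
from lockrkit.synthetic import MicroscopySimConfig, simulate_microscopy

cfg = MicroscopySimConfig(
    seed=30,
    n_cells=4,
    n_puncta_per_cell=5,
    puncta_radius_um=1.0,
    puncta_ratio_multiplier=2.0,
    pixel_size_um=0.2,
    image_shape=(340, 340),
    cell_axes_um=(12.0, 10.0),
    step_amplitude=0.0,  # static cells: ratio stays at baseline
    noise_cv=0.02,
)
sim = simulate_microscopy(cfg)
frame_fret = sim.stack.channels["fret"][-1]
frame_donor = sim.stack.channels["donor"][-1]

for roi in sim.cell_rois:
    ps = detect_puncta(frame_fret, cfg.pixel_size_um, "otsu", mask=roi.mask)
    areas = [round(p.area_um2, 2) for p in ps.components]
    print(f"{roi.label}: {len(ps)} puncta (planted 5), areas um^2 = {areas}")

roi = sim.cell_rois[0]
field, _, _ = ratio_image(frame_fret - 100.0, frame_donor - 100.0)  # bg level 100
stats = region_ratio_stats(field, sim.puncta_masks[roi.label], roi.mask)
print(f"\nmean ratio in puncta:  {stats.mean_ratio_puncta:.3f} (planted 2.0)")
print(f"mean ratio in diffuse: {stats.mean_ratio_diffuse:.3f} (planted 1.0)")

# co-localization of the ratio-bright puncta with an independent marker
# channel imaging the same structures (idealised marker + 2% noise)
rng = np.random.default_rng(31)
marker = 100.0 * sim.puncta_masks[roi.label].astype(float)
marker *= 1.0 + 0.02 * rng.standard_normal(marker.shape)
r = pearson_coloc(frame_fret, marker, roi.mask)
m1, m2 = manders_coloc(frame_fret, marker, roi.mask)
print(f"\nFRET vs puncta marker within the cell: Pearson r = {r:.3f}, "
      f"Manders M1 = {m1:.3f}, M2 = {m2:.3f}")
# M1 < 1: only part of the FRET-channel intensity sits inside the marker's
# supra-threshold puncta; M2 ~ 1: essentially all marker intensity lies
# where the FRET channel is above threshold.
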