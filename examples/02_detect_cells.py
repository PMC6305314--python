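"""PCA/ICA cell detection with rule-based refinement.

Builds a movie with 5 known somata, converts to dF/F, unmixes it with
spatio-temporal ICA, binarizes the component filters into candidate
ROIs, and refines them (size/roundness window, >30% overlap merging,
low-fluorescence exclusion).  Prints each surviving ROI and its overlap
with the best-matching ground-truth cell.
"""

import numpy as np

from calimba import cells, synthetic
from calimba.activity import delta_f_over_f

movie, truth = synthetic.make_movie(
    synthetic.MovieParams(
        n_frames=300, height=96, width=96, n_cells=5, snr=10,
        motion_amplitude_px=0, n_corrupted=0, n_dust=0,
        spike_rate_per_frame=0.05, vessels=False,
    ),
    seed=11,
)
dff = delta_f_over_f(movie)
ica = cells.pca_ica(dff, n_pcs=15, n_ics=15, mu=0.5, seed=0)
candidates = cells.filters_to_rois(ica)
rois = cells.refine(candidates, movie)

print(f"{len(candidates)} candidate ROIs -> {len(rois)} after refinement "
      f"(truth: {truth.cell_masks.shape[0]} cells)")
print("label  area_px  roundness  best-IoU")
for roi in rois:
    best = max(
        (truth.cell_masks[k] & roi.mask).sum() / (truth.cell_masks[k] | roi.mask).sum()
        for k in range(truth.cell_masks.shape[0])
    )
    print(f"{roi.label:5d}  {roi.area_px:7d}  {roi.roundness:9.2f}  {best:8.2f}")
print("IoU >= 0.5 means the ROI covers the same pixels as a planted cell")
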