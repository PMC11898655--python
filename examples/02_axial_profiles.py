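"""Extract length-normalized axial HADA profiles and average them.

Cells are skeletonized, the medial axis is smoothed and extended to the
mask boundary, and intensity is averaged across a 10-px transverse band
(about 1.06 um) at each axial station, then resampled to 101 normalized
positions.
"""

import numpy as np

from poleprof import profiles, synthgen, workflow

scenes, gt = synthgen.generate_population("control", n=30, seed=11)
pop = workflow.extract_population_profiles(scenes, "hada", ground_truth=gt)
print(f"profiled {len(pop.profiles)} cells, excluded {len(pop.excluded)}")

septate = [p for cid, p in pop.profiles.items() if gt[cid].septate]
mean = profiles.average_profiles(septate)
interior = mean.mean[30:71]
print(f"septate-cell mean profile: n={mean.n_cells}, "
      f"max {mean.mean.max():.1f} counts at the poles")
print(f"pole values {mean.mean[0]:.1f} / {mean.mean[100]:.1f}; "
      f"septal region (30-70% of length) peaks at {interior.max():.1f} "
      f"at position {0.30 + 0.01 * int(np.argmax(interior)):.2f}")
print("A three-peak shape (pole / septum / pole) with polar maxima is the")
print("control-strain signature of polar cell-wall synthesis.")
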