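"""Generate a small synthetic DCE-MRI lesion cohort and inspect its geometry.

Builds 5 lesions per outcome class with the calibrated presets (class 0 =
no re-excision: smooth margins; class 1 = re-excision: lobulated margins,
right-skewed enhancement histogram) and prints per-class shape statistics.
Lower solidity/extent in class 1 is the geometric signature the classifier
later exploits.
"""

import numpy as np

from bcsradiomics.morphology import shape_features
from bcsradiomics.phantom import default_cohort_spec, generate_cohort

lesions = generate_cohort(default_cohort_spec(seed=42, n_per_class=5))
print(f"generated {len(lesions)} lesions on a "
      f"{lesions[0].mask.shape} grid, spacing {lesions[0].spacing} mm\n")

for label in (0, 1):
    group = [l for l in lesions if l.label == label]
    sol = [shape_features(l.mask, l.spacing).solidity for l in group]
    ext = [shape_features(l.mask, l.spacing).extent for l in group]
    vox = [int(l.mask.sum()) for l in group]
    name = "no re-excision" if label == 0 else "re-excision   "
    print(f"class {label} ({name}): solidity {np.mean(sol):.3f} +/- {np.std(sol):.3f}, "
          f"extent {np.mean(ext):.3f} +/- {np.std(ext):.3f}, "
          f"volume {np.mean(vox):.0f} voxels")

print("\nSolidity near 1 means the lesion fills its convex hull (well-"
      "circumscribed); the re-excision class sits visibly lower on both "
      "shape descriptors.")
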