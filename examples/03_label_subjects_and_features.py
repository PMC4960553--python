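"""Create MR-based clustered images (MRcIs) and in-ROI class-ratio features.

Applying a trained model to a subject assigns every in-mask voxel the class
of its nearest protocluster, producing an integer label volume (the MRcI).
Within the tumor ROI, the fraction of each class yields K log10 class-ratio
features per subject — the input to grading. The per-class mean
protocluster profile (radar-chart data) shows each class's MR signature.
"""

import numpy as np

from mrci import (
    PhantomSpec,
    generate_cohort,
    cohort_feature_matrix,
    train_two_level,
    label_subject,
    class_ratios,
    radar_chart_data,
)
from mrci.io_preprocess import CHANNEL_ORDER

subjects, _ = generate_cohort(PhantomSpec(), n_lgg=3, n_hgg=4, seed=7)
features = cohort_feature_matrix([vs for vs, _ in subjects])
codebook, labeling = train_two_level(features, K=6, kmeans_seed=0)

print("per-class mean protocluster profile (z-scored):")
print("class " + " ".join(f"{c:>7}" for c in CHANNEL_ORDER))
for k, profile in radar_chart_data(codebook, labeling).items():
    print(f"  {k}   " + " ".join(f"{v:7.2f}" for v in profile))

print("\nlog10 class ratios inside the tumor ROI:")
header = "  ".join(f"r{k}" for k in range(1, 7))
print(f"subject  grade  {header}")
for vs, truth in subjects:
    mrci_img = label_subject(vs, codebook, labeling)
    feats = class_ratios(mrci_img, vs.roi_mask, grade=truth.grade)
    row = "  ".join(f"{v:5.2f}" for v in feats.log_ratios)
    print(f"{vs.subject_id:>7}  {truth.grade:>4}  {row}")

# The MRcI itself is an integer volume: 0 outside the brain, 1..K inside.
vs, truth = subjects[0]
img = label_subject(vs, codebook, labeling)
counts = np.bincount(img.labels[vs.brain_mask], minlength=7)[1:]
print(f"\n{vs.subject_id} whole-brain class counts: {counts.tolist()}")
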