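"""Train the two-level clustering model: batch SOM, then K-means++.

Level 1: a 20x20 batch-learning self-organizing map quantizes the pooled,
z-normalized 4-channel intensities (sampled on a 5x5x5 voxel lattice) into
400 protoclusters. Level 2: K-means++ groups the 400 protocluster weight
vectors into K classes, relabeled so class 1 has the highest mean weight.
The trained model is saved as a versioned JSON bundle whose bytes are
identical across reruns with the same seed.
"""

from pathlib import Path

from mrci import (
    PhantomSpec,
    generate_cohort,
    cohort_feature_matrix,
    train_two_level,
    save_model,
    load_model,
    component_planes,
)
from mrci.io_preprocess import CHANNEL_ORDER

subjects, _ = generate_cohort(PhantomSpec(), n_lgg=3, n_hgg=4, seed=7)

features = cohort_feature_matrix([vs for vs, _ in subjects], stride=5)
print(f"training samples: {features.n_samples} "
      f"(one per 125 voxels inside each brain mask)")

codebook, labeling = train_two_level(features, K=6, kmeans_seed=0)

qe = codebook.quantization_error_trace
print(f"quantization error: {qe[0]:.4f} (epoch 1) -> {qe[-1]:.4f} (final)")
print(f"second-level inertia at K={labeling.K}: {labeling.inertia:.4f}")
print(f"protoclusters per class: "
      f"{[int((labeling.unit_class == k).sum()) for k in range(1, 7)]}")

path = Path("scratch/model_k6.json")
save_model(path, codebook, labeling, meta={"example": "02"})
cb2, lab2, meta = load_model(path)
assert (cb2.weights == codebook.weights).all()
print(f"model bundle saved to {path} and reloaded losslessly")

# Component planes: each channel's weight over the 20x20 lattice, plus the
# lattice edges where the class label changes (white borders in figures).
grids, borders = component_planes(codebook, labeling, CHANNEL_ORDER)
print(f"component planes: {list(grids)}; {len(borders)} class-border edges")
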