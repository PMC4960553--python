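"""End-to-end convenience layer: cohort -> trained model -> labeled volumes.

Ties the preprocessing, two-level clustering and labeling stages together
the way a study would run them: normalize every subject within its brain
mask, sample one voxel in every 125, stack the cohort, train the 400-unit
batch SOM, partition the codebook into K classes, then label any subject
(training or new) with its nearest protocluster's class.
"""

from __future__ import annotations

import numpy as np

from .clustering import (
    ProtoclusterLabeling,
    SOMCodebook,
    SOMConfig,
    init_som,
    kmeanspp_cluster,
    train_blsom,
)
from .io_preprocess import (
    FeatureMatrix,
    VolumeSet,
    extract_training_features,
    normalize_intensities,
    stack_cohort_features,
)
from .labeling import MRcI, assign_labels


def cohort_feature_matrix(
    volume_sets: list[VolumeSet], stride: int = 5
) -> FeatureMatrix:
    """Normalize each subject and stack the lattice-sampled features."""
    per_subject = [
        extract_training_features(normalize_intensities(vs), stride=stride)
        for vs in volume_sets
    ]
    return stack_cohort_features(per_subject)


def train_two_level(
    features: FeatureMatrix,
    K: int,
    som_cfg: SOMConfig | None = None,
    kmeans_seed: int = 0,
    n_restarts: int = 25,
) -> tuple[SOMCodebook, ProtoclusterLabeling]:
    """Train the batch SOM then cluster its codebook into K classes."""
    cfg = som_cfg or SOMConfig()
    codebook = train_blsom(init_som(features, cfg), features, cfg)
    labeling = kmeanspp_cluster(codebook, K=K, seed=kmeans_seed, n_restarts=n_restarts)
    return codebook, labeling


def label_subject(
    vs: VolumeSet,
    codebook: SOMCodebook,
    labeling: ProtoclusterLabeling,
    model_id: str = "model",
) -> MRcI:
    """Create a subject's MRcI: normalize with its own within-mask z-score,
    then assign every in-mask voxel its nearest protocluster's class."""
    nvs = normalize_intensities(vs)
    return assign_labels(nvs, codebook, labeling, model_id=model_id)
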