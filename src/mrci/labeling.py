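"""MR-based clustered images (MRcIs) and class-ratio features.

An MRcI assigns every in-brain voxel the class of its nearest protocluster,
giving a K-class integer label volume (0 = background). Within the tumor
ROI, the fraction of each class (on a common-log scale) is the feature
vector used for grading; classes whose fraction differs significantly
between grades form the H (high-grade-enriched) and L (low-grade-enriched)
groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ProtoclusterLabeling, SOMCodebook, bmus
from .errors import (
    EmptyRoiError,
    GradeError,
    GridMismatchError,
    LatticeMismatchError,
    MaskContainmentError,
)
from .io_preprocess import CHANNEL_ORDER, NormalizedVolumeSet
from .stats import WMWResult, wmw_exact


@dataclass
class MRcI:
    """Voxel-wise K-class label volume for one subject."""

    labels: np.ndarray  # uint16, 0 outside brain mask, 1..K inside
    K: int
    model_id: str
    subject_id: str


@dataclass
class ClassRatioFeatures:
    """Per-subject in-ROI class composition and its log10 transform."""

    subject_id: str
    K: int
    counts: np.ndarray
    ratios: np.ndarray
    log_ratios: np.ndarray
    grade: str  # "LGG" | "HGG" | "unknown"


@dataclass
class ClassGrouping:
    """L/N/H assignment per class with the supporting test results."""

    group: dict[int, str]  # class -> "L" | "N" | "H"
    tests: dict[int, WMWResult]
    alpha: float
    threshold: float  # alpha / K actually applied


def assign_labels(
    nvs: NormalizedVolumeSet,
    codebook: SOMCodebook,
    labeling: ProtoclusterLabeling,
    model_id: str = "model",
) -> MRcI:
    """Label every in-mask voxel with the class of its nearest protocluster."""
    if labeling.unit_class.shape[0] != codebook.n_units:
        raise LatticeMismatchError("labeling does not match the codebook lattice")
    mask = nvs.brain_mask
    stacked = nvs.stacked()
    feats = stacked[mask]
    if feats.shape[1] != codebook.n_features:
        raise GridMismatchError("channel count does not match the codebook")
    units = bmus(codebook, feats)
    labels = np.zeros(nvs.shape, dtype=np.uint16)
    labels[mask] = labeling.unit_class[units].astype(np.uint16)
    return MRcI(labels=labels, K=labeling.K, model_id=model_id, subject_id=nvs.subject_id)


def class_ratios(
    mrci: MRcI,
    roi_mask: np.ndarray,
    grade: str = "unknown",
    zero_floor: float | None = None,
) -> ClassRatioFeatures:
    """In-ROI per-class counts, fractions and common-log fractions.

    A class absent from the ROI would give log10(0); its ratio is floored at
    half a count, 1/(2*|ROI|), before the log (``zero_floor`` overrides).
    """
    roi = np.asarray(roi_mask) != 0
    if roi.shape != mrci.labels.shape:
        raise GridMismatchError("ROI grid does not match the label volume")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise EmptyRoiError("ROI selects no voxels")
    roi_labels = mrci.labels[roi]
    if (roi_labels == 0).any():
        raise MaskContainmentError("ROI contains background (out-of-brain) voxels")
    counts = np.bincount(roi_labels, minlength=mrci.K + 1)[1:].astype(np.int64)
    ratios = counts / n_roi
    floor = zero_floor if zero_floor is not None else 1.0 / (2 * n_roi)
    log_ratios = np.log10(np.where(ratios > 0, ratios, floor))
    return ClassRatioFeatures(
        subject_id=mrci.subject_id,
        K=mrci.K,
        counts=counts,
        ratios=ratios,
        log_ratios=log_ratios,
        grade=grade,
    )


def group_classes(
    cohort: list[ClassRatioFeatures],
    alpha: float = 0.05,
    seed: int = 0,
) -> ClassGrouping:
    """Assign each class to L, N or H from grade-wise log-ratio comparisons.

    Per class, a two-sided exact Wilcoxon–Mann–Whitney test compares the
    log-ratios between LGG and HGG subjects; a class is H when p < alpha/K
    with the higher median in HGG, L when p < alpha/K with the higher median
    in LGG, and N otherwise. Output is invariant to subject order.
    """
    if not cohort:
        raise GradeError("empty cohort")
    K = cohort[0].K
    if any(f.K != K for f in cohort):
        raise GradeError("inconsistent K across subjects")
    lgg = sorted((f for f in cohort if f.grade == "LGG"), key=lambda f: f.subject_id)
    hgg = sorted((f for f in cohort if f.grade == "HGG"), key=lambda f: f.subject_id)
    if not lgg or not hgg:
        raise GradeError("both grades must be represented")
    threshold = alpha / K
    group: dict[int, str] = {}
    tests: dict[int, WMWResult] = {}
    for k in range(1, K + 1):
        a = np.array([f.log_ratios[k - 1] for f in lgg])
        b = np.array([f.log_ratios[k - 1] for f in hgg])
        res = wmw_exact(a, b, seed=seed + k)
        tests[k] = res
        if res.p_two_sided < threshold:
            group[k] = "H" if np.median(b) > np.median(a) else "L"
        else:
            group[k] = "N"
    return ClassGrouping(group=group, tests=tests, alpha=alpha, threshold=threshold)


def radar_chart_data(
    codebook: SOMCodebook,
    labeling: ProtoclusterLabeling,
    channel_order: tuple[str, ...] = CHANNEL_ORDER,
) -> dict[int, np.ndarray]:
    """Per-class mean protocluster weight profile (one value per channel).

    This is the data behind the per-class radar charts: the average MR
    signature of the protoclusters belonging to each class.
    """
    if labeling.unit_class.shape[0] != codebook.n_units:
        raise LatticeMismatchError("labeling does not match the codebook lattice")
    profiles: dict[int, np.ndarray] = {}
    for k in range(1, labeling.K + 1):
        sel = labeling.unit_class == k
        profiles[k] = codebook.weights[sel].mean(axis=0)
    return profiles


def per_class_voxel_values(
    mrci: MRcI, nvs: NormalizedVolumeSet, region_mask: np.ndarray | None = None
) -> dict[int, np.ndarray]:
    """Normalized intensities of every voxel, grouped by MRcI class.

    Generic export behind scatter-matrix plots and region-restricted
    intensity comparisons (e.g. within an enhancing-tumor mask); pass
    ``region_mask`` to restrict, default is the whole brain mask.
    """
    mask = nvs.brain_mask if region_mask is None else (np.asarray(region_mask) != 0)
    if mask.shape != mrci.labels.shape:
        raise GridMismatchError("region grid does not match the label volume")
    stacked = nvs.stacked()
    out: dict[int, np.ndarray] = {}
    for k in range(1, mrci.K + 1):
        sel = mask & (mrci.labels == k)
        out[k] = stacked[sel]
    return out
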