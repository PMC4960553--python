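"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mrci.clustering import SOMCodebook
from mrci.io_preprocess import CHANNEL_ORDER, FeatureMatrix, VolumeSet


def feature_matrix(X: np.ndarray, subject: str = "s") -> FeatureMatrix:
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(values=X, source=[(subject, (i, 0, 0)) for i in range(len(X))])


def flat_codebook(X: np.ndarray) -> SOMCodebook:
    """Wrap arbitrary vectors as an n x 1 'codebook' for unit-level tests."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    return SOMCodebook(
        weights=X,
        grid_rows=n,
        grid_cols=1,
        unit_coords=np.stack([np.arange(n), np.zeros(n, dtype=int)], axis=1),
    )


def make_volume_set(
    shape=(10, 10, 10),
    rng: np.random.Generator | None = None,
    subject_id: str = "s1",
    brain_mask: np.ndarray | None = None,
    roi_mask: np.ndarray | None = None,
) -> VolumeSet:
    rng = rng or np.random.default_rng(0)
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    if roi_mask is None:
        roi_mask = np.zeros(shape, dtype=bool)
        roi_mask[tuple(s // 2 for s in shape)] = True
        roi_mask &= brain_mask
    channels = {c: rng.normal(100, 10, size=shape) for c in CHANNEL_ORDER}
    return VolumeSet(
        subject_id=subject_id,
        channels=channels,
        brain_mask=brain_mask,
        roi_mask=roi_mask,
    )


def exhaustive_min_sse(X: np.ndarray, K: int) -> float:
    """Brute-force optimal K-means SSE by enumerating all K^n assignments."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    A = np.array(list(itertools.product(range(K), repeat=n)), dtype=np.int8)
    total = (X**2).sum()
    explained = np.zeros(len(A))
    valid = np.ones(len(A), dtype=bool)
    for k in range(K):
        mask = A == k
        nk = mask.sum(axis=1)
        valid &= nk > 0
        S = mask @ X
        explained += np.where(nk > 0, (S**2).sum(axis=1) / np.maximum(nk, 1), 0.0)
    return float(total - explained[valid].max())


@pytest.fixture(scope="session")
def separable_cohort():
    """Twenty subjects whose single feature separates the grades linearly."""
    from mrci.labeling import ClassRatioFeatures

    rng = np.random.default_rng(42)
    cohort = []
    for i in range(20):
        grade = "HGG" if i >= 10 else "LGG"
        base = 1.0 if grade == "HGG" else -1.0
        lr = np.array([base + rng.normal(0, 0.1), -base + rng.normal(0, 0.1), 0.0])
        cohort.append(
            ClassRatioFeatures(
                subject_id=f"s{i:02d}", K=3, counts=np.zeros(3, dtype=int),
                ratios=10.0**lr, log_ratios=lr, grade=grade,
            )
        )
    return cohort
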