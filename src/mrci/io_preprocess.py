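"""Volume I/O, within-mask intensity normalization, and feature extraction.

A subject is four co-registered scalar MR volumes (t1, t1ce, t2, flair) on a
common voxel grid, a binary whole-brain mask and a binary tumor ROI mask.
Clustering features are the four z-normalized intensities sampled on a sparse
axis-aligned lattice (one voxel in every ``stride**3``) inside the brain mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

from .errors import (
    ChannelOrderError,
    DegenerateChannelError,
    EmptyInputError,
    EmptyMaskError,
    EmptySampleError,
    GridMismatchError,
    MaskContainmentError,
    NonVolumeError,
)

#: Fixed channel order used everywhere downstream.
CHANNEL_ORDER: tuple[str, ...] = ("t1", "t1ce", "t2", "flair")


@dataclass
class VolumeSet:
    """One subject's co-registered multi-channel volumes plus masks.

    Channels are stored float64 in :data:`CHANNEL_ORDER`; masks are boolean.
    All arrays share one shape; voxel indices are 0-based ``(i, j, k)``.
    """

    subject_id: str
    channels: dict[str, np.ndarray]
    brain_mask: np.ndarray
    roi_mask: np.ndarray
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask) != 0
        self.roi_mask = np.asarray(self.roi_mask) != 0
        shape = self.brain_mask.shape
        if len(shape) != 3:
            raise NonVolumeError(f"brain mask is {len(shape)}D, expected 3D")
        if tuple(self.channels) != CHANNEL_ORDER:
            raise ChannelOrderError(
                f"channels must be {CHANNEL_ORDER}, got {tuple(self.channels)}"
            )
        for name, vol in self.channels.items():
            vol = np.asarray(vol, dtype=np.float64)
            if vol.ndim != 3:
                raise NonVolumeError(f"channel {name!r} is {vol.ndim}D, expected 3D")
            if vol.shape != shape:
                raise GridMismatchError(
                    f"channel {name!r} shape {vol.shape} != mask shape {shape}"
                )
            self.channels[name] = vol
        if self.roi_mask.shape != shape:
            raise GridMismatchError(
                f"roi mask shape {self.roi_mask.shape} != brain mask shape {shape}"
            )
        if not self.brain_mask.any():
            raise EmptyMaskError("brain mask has no voxels")
        if (self.roi_mask & ~self.brain_mask).any():
            n = int((self.roi_mask & ~self.brain_mask).sum())
            raise MaskContainmentError(f"{n} ROI voxel(s) lie outside the brain mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.brain_mask.shape

    def stacked(self) -> np.ndarray:
        """Return an (nx, ny, nz, 4) stack in channel order."""
        return np.stack([self.channels[c] for c in CHANNEL_ORDER], axis=-1)


@dataclass
class NormalizedVolumeSet(VolumeSet):
    """A :class:`VolumeSet` whose channels are z-scored within the brain mask.

    Out-of-mask voxels carry NaN sentinels; downstream code must index through
    the mask, never read sentinels. ``normalization_params`` maps channel name
    to the (mean, sd) removed, so raw intensities can be recovered.
    """

    normalization_params: dict[str, tuple[float, float]] = field(default_factory=dict)


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise NonVolumeError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return np.asarray(data, dtype=np.float64), np.asarray(img.affine)


def load_volume_set(
    channel_paths: Mapping[str, str | Path],
    brain_mask_path: str | Path,
    roi_mask_path: str | Path,
    subject_id: str,
) -> VolumeSet:
    """Read one subject's four channels and two masks from NIfTI files.

    ``channel_paths`` must provide exactly the keys in :data:`CHANNEL_ORDER`.
    Masks are binarized at nonzero. All files must share one grid (shape and
    affine); violations raise the specific error, not a generic one.
    """
    if set(channel_paths) != set(CHANNEL_ORDER):
        raise ChannelOrderError(
            f"need channels {CHANNEL_ORDER}, got {sorted(channel_paths)}"
        )
    channels: dict[str, np.ndarray] = {}
    ref_affine: np.ndarray | None = None
    ref_shape: tuple[int, ...] | None = None
    for name in CHANNEL_ORDER:
        data, affine = _load_nifti(channel_paths[name])
        if ref_affine is None:
            ref_affine, ref_shape = affine, data.shape
        else:
            if data.shape != ref_shape:
                raise GridMismatchError(
                    f"channel {name!r} shape {data.shape} != {ref_shape}"
                )
            if not np.allclose(affine, ref_affine, atol=1e-4):
                raise GridMismatchError(f"channel {name!r} affine differs")
        channels[name] = data
    brain, baff = _load_nifti(brain_mask_path)
    roi, raff = _load_nifti(roi_mask_path)
    for nm, arr, aff in (("brain mask", brain, baff), ("roi mask", roi, raff)):
        if arr.shape != ref_shape:
            raise GridMismatchError(f"{nm} shape {arr.shape} != {ref_shape}")
        if not np.allclose(aff, ref_affine, atol=1e-4):
            raise GridMismatchError(f"{nm} affine differs")
    voxel_size = np.sqrt((np.asarray(ref_affine)[:3, :3] ** 2).sum(axis=0))
    return VolumeSet(
        subject_id=subject_id,
        channels=channels,
        brain_mask=brain != 0,
        roi_mask=roi != 0,
        voxel_size_mm=voxel_size,
        affine=ref_affine,
    )


def save_volume_set(vs: VolumeSet, out_dir: str | Path) -> dict[str, Path]:
    """Write a subject's channels and masks as NIfTI under ``out_dir``.

    Masks and label volumes are written as unsigned integers. Returns the
    written paths keyed by channel / mask name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in CHANNEL_ORDER:
        p = out / f"{vs.subject_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(vs.channels[name].astype(np.float32), vs.affine), p)
        paths[name] = p
    for nm, arr in (("brain_mask", vs.brain_mask), ("roi_mask", vs.roi_mask)):
        p = out / f"{vs.subject_id}_{nm}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.uint8), vs.affine), p)
        paths[nm] = p
    return paths


def normalize_intensities(vs: VolumeSet) -> NormalizedVolumeSet:
    """Z-score each channel within the brain mask (population variance).

    Within the mask every channel ends with mean 0 and sd 1; voxels outside
    the mask are set to NaN. The (mean, sd) pair per channel is recorded in
    ``normalization_params``. A channel constant within the mask raises
    :class:`DegenerateChannelError`.
    """
    mask = vs.brain_mask
    channels: dict[str, np.ndarray] = {}
    params: dict[str, tuple[float, float]] = {}
    for name in CHANNEL_ORDER:
        vals = vs.channels[name][mask]
        mean = float(vals.mean())
        sd = float(vals.std())  # population (divisor n)
        if sd == 0.0:
            raise DegenerateChannelError(f"channel {name!r} constant within mask")
        out = np.full(vs.shape, np.nan)
        out[mask] = (vals - mean) / sd
        channels[name] = out
        params[name] = (mean, sd)
    return NormalizedVolumeSet(
        subject_id=vs.subject_id,
        channels=channels,
        brain_mask=mask.copy(),
        roi_mask=vs.roi_mask.copy(),
        voxel_size_mm=np.asarray(vs.voxel_size_mm).copy(),
        affine=np.asarray(vs.affine).copy(),
        normalization_params=params,
    )


@dataclass
class FeatureMatrix:
    """Sampled voxel features: one row per voxel, 4 columns in channel order.

    ``source`` records (subject_id, (i, j, k)) per row so any row can be
    traced back to its voxel.
    """

    values: np.ndarray
    source: list[tuple[str, tuple[int, int, int]]]
    channel_order: tuple[str, ...] = CHANNEL_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_order):
            raise ChannelOrderError(
                f"feature matrix must be (n, {len(self.channel_order)}), "
                f"got {self.values.shape}"
            )
        if len(self.source) != self.values.shape[0]:
            raise EmptyInputError("source length != row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def lattice_mask(shape: Sequence[int], stride: int, offset: Sequence[int] = (0, 0, 0)) -> np.ndarray:
    """Boolean mask of the sampling lattice {(i,j,k) : i=j=k=offset (mod stride)}."""
    out = np.zeros(tuple(shape), dtype=bool)
    out[offset[0]::stride, offset[1]::stride, offset[2]::stride] = True
    return out


def extract_training_features(
    nvs: NormalizedVolumeSet,
    stride: int = 5,
    offset: Sequence[int] = (0, 0, 0),
) -> FeatureMatrix:
    """Sample normalized intensities on the sparse lattice inside the mask.

    With the default ``stride=5`` one voxel in every 125 is sampled. Rows are
    in lexicographic voxel-index order, which makes the output deterministic.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    sel = lattice_mask(nvs.shape, stride, offset) & nvs.brain_mask
    idx = np.argwhere(sel)  # lexicographic (i, j, k) order
    if idx.shape[0] == 0:
        raise EmptySampleError("no lattice point inside the brain mask")
    stacked = nvs.stacked()
    values = stacked[sel]  # same lexicographic order as argwhere
    source = [(nvs.subject_id, (int(i), int(j), int(k))) for i, j, k in idx]
    return FeatureMatrix(values=values, source=source)


def stack_cohort_features(per_subject: list[FeatureMatrix]) -> FeatureMatrix:
    """Row-wise concatenation of per-subject feature matrices.

    Subject order and per-row provenance are preserved; all inputs must share
    the channel order.
    """
    if not per_subject:
        raise EmptyInputError("no feature matrices to stack")
    order = per_subject[0].channel_order
    for fm in per_subject[1:]:
        if fm.channel_order != order:
            raise ChannelOrderError(
                f"channel order mismatch: {fm.channel_order} != {order}"
            )
    values = np.concatenate([fm.values for fm in per_subject], axis=0)
    source: list[tuple[str, tuple[int, int, int]]] = []
    for fm in per_subject:
        source.extend(fm.source)
    return FeatureMatrix(values=values, source=source, channel_order=order)
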