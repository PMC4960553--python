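"""Seeded phantom cohorts: multi-channel brain volumes with known voxel classes.

Each phantom is an ellipsoidal "brain" built from concentric tissue shells
(white matter core, gray matter shell, CSF rim) plus an ellipsoidal tumor
ROI whose voxel classes are drawn from a grade-dependent mixture: low-grade
tumors are dominated by a T2-bright signature, high-grade tumors add a
contrast-enhancing (T1ce-bright) component that low-grade tumors lack, so
grade information lives only in the ROI composition. Channel intensities
are the class signature plus Gaussian noise, optionally modulated by a
smooth multiplicative bias field. Everything is determined by the spec,
the grade and the RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MaskContainmentError
from .io_preprocess import CHANNEL_ORDER, VolumeSet, save_volume_set

#: default class signatures, rows in (t1, t1ce, t2, flair) order
DEFAULT_CLASS_NAMES = ("csf", "gm", "wm", "edema", "lgg_like", "enhancing")
DEFAULT_SIGNATURES = np.array(
    [
        [20.0, 20.0, 130.0, 10.0],   # csf: long T2, suppressed FLAIR
        [85.0, 85.0, 85.0, 90.0],    # gray matter
        [115.0, 115.0, 60.0, 70.0],  # white matter
        [60.0, 60.0, 115.0, 120.0],  # edema: T2/FLAIR bright
        [50.0, 52.0, 122.0, 100.0],  # low-grade-like tumor: T2 bright
        [70.0, 140.0, 80.0, 85.0],   # enhancing tumor: T1ce bright
    ]
)


def _min_pairwise_distance(signatures: np.ndarray) -> float:
    d = np.sqrt(((signatures[:, None, :] - signatures[None, :, :]) ** 2).sum(-1))
    return float(d[np.triu_indices_from(d, k=1)].min())


@dataclass
class PhantomSpec:
    """Geometry, signatures, noise and grade mixtures of a phantom cohort.

    The default noise_sd places the closest signature pair exactly
    ``min_separation_sd`` noise standard deviations apart. Mixture vectors
    are per-grade probabilities over the tissue classes inside the ROI;
    the enhancing class carries weight only in the HGG mixture.
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    signatures: np.ndarray = field(default_factory=lambda: DEFAULT_SIGNATURES.copy())
    noise_sd: float | None = None
    min_separation_sd: float = 3.0
    brain_semiaxes_frac: tuple[float, float, float] = (0.42, 0.42, 0.42)
    wm_radius: float = 0.66  # normalized ellipsoid radius of the WM core
    gm_radius: float = 0.90  # GM shell outer radius; CSF beyond
    roi_center_frac: tuple[float, float, float] = (0.6, 0.5, 0.5)
    roi_semiaxes_frac: tuple[float, float, float] = (0.26, 0.24, 0.24)
    mixtures: dict[str, np.ndarray] = field(default_factory=lambda: {
        # over (csf, gm, wm, edema, lgg_like, enhancing)
        "LGG": np.array([0.0, 0.0, 0.10, 0.30, 0.60, 0.0]),
        "HGG": np.array([0.0, 0.0, 0.10, 0.30, 0.30, 0.30]),
    })
    bias_amplitude: float = 0.0

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        G = self.signatures.shape[0]
        if G < 2 or self.signatures.shape[1] != len(CHANNEL_ORDER):
            raise ValueError("signatures must be (G >= 2, 4)")
        if len(self.class_names) != G:
            raise ValueError("one name per class required")
        sep = _min_pairwise_distance(self.signatures)
        if self.noise_sd is None:
            self.noise_sd = sep / self.min_separation_sd
        if self.noise_sd > 0 and sep < self.min_separation_sd * self.noise_sd - 1e-9:
            raise ValueError(
                f"signatures separated by {sep:.3g} < "
                f"{self.min_separation_sd} x noise_sd ({self.noise_sd:.3g})"
            )
        for grade, mix in self.mixtures.items():
            mix = np.asarray(mix, dtype=float)
            if mix.shape != (G,) or (mix < 0).any() or abs(mix.sum() - 1) > 1e-9:
                raise ValueError(f"invalid mixture for {grade}")
            self.mixtures[grade] = mix

    @property
    def n_classes(self) -> int:
        return self.signatures.shape[0]


@dataclass
class PhantomTruth:
    """Ground truth for one phantom subject."""

    class_volume: np.ndarray  # int, 0..G-1 inside brain, -1 outside
    grade: str
    realized_mixture: np.ndarray  # fractions over G classes inside the ROI


def _ellipsoid_rho(shape: tuple[int, int, int], center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return np.sqrt(rho2)


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (random quadratic, |.|<=1)."""
    if amplitude == 0.0:
        return np.ones(shape)
    coords = np.meshgrid(
        *(np.linspace(-1, 1, s) for s in shape), indexing="ij"
    )
    coefs = rng.uniform(-1, 1, size=(3, 3))
    poly = np.zeros(shape)
    for i, x in enumerate(coords):
        poly += coefs[i, 0] * x + coefs[i, 1] * x**2
    poly += coefs[0, 2] * coords[0] * coords[1] + coefs[1, 2] * coords[1] * coords[2]
    poly /= max(np.abs(poly).max(), 1e-12)
    return 1.0 + amplitude * poly


def generate_subject(
    spec: PhantomSpec,
    grade: str,
    rng: np.random.Generator,
    subject_id: str = "phantom",
) -> tuple[VolumeSet, PhantomTruth]:
    """Build one phantom subject with its voxel-level ground truth.

    Tissue shells are deterministic given the spec; ROI classes are
    multinomial draws from the grade's mixture; intensities add
    ``N(0, noise_sd)`` per channel.
    """
    if grade not in spec.mixtures:
        raise ValueError(f"no mixture defined for grade {grade!r}")
    shape = spec.shape
    center = (np.asarray(shape) - 1) / 2.0
    brain_ax = np.asarray(spec.brain_semiaxes_frac) * np.asarray(shape)
    rho = _ellipsoid_rho(shape, center, brain_ax)
    brain = rho <= 1.0

    roi_center = np.asarray(spec.roi_center_frac) * (np.asarray(shape) - 1)
    roi_ax = np.asarray(spec.roi_semiaxes_frac) * np.asarray(shape)
    roi = _ellipsoid_rho(shape, roi_center, roi_ax) <= 1.0
    if (roi & ~brain).any():
        raise MaskContainmentError("ROI extends outside the brain ellipsoid")

    classes = np.full(shape, -1, dtype=np.int64)
    classes[brain] = 0  # csf rim
    classes[brain & (rho <= spec.gm_radius)] = 1  # gray matter
    classes[brain & (rho <= spec.wm_radius)] = 2  # white matter
    mix = spec.mixtures[grade]
    n_roi = int(roi.sum())
    classes[roi] = rng.choice(spec.n_classes, size=n_roi, p=mix)
    realized = np.bincount(classes[roi], minlength=spec.n_classes) / n_roi

    noise = rng.normal(0.0, spec.noise_sd, size=shape + (spec.signatures.shape[1],))
    bias = _bias_field(shape, spec.bias_amplitude, rng)
    intensity = np.zeros(shape + (len(CHANNEL_ORDER),))
    inside = classes >= 0
    intensity[inside] = spec.signatures[classes[inside]]
    intensity += noise
    intensity *= bias[..., None]

    vs = VolumeSet(
        subject_id=subject_id,
        channels={c: intensity[..., j] for j, c in enumerate(CHANNEL_ORDER)},
        brain_mask=brain,
        roi_mask=roi,
    )
    truth = PhantomTruth(class_volume=classes, grade=grade, realized_mixture=realized)
    return vs, truth


def generate_cohort(
    spec: PhantomSpec,
    n_lgg: int = 15,
    n_hgg: int = 21,
    seed: int = 0,
) -> tuple[list[tuple[VolumeSet, PhantomTruth]], pd.DataFrame]:
    """Generate an independent cohort; defaults give 15 LGG + 21 HGG subjects.

    Every subject draws from its own child generator of ``seed``, so the
    cohort is reproducible and subjects are independent. Returns the list of
    (VolumeSet, PhantomTruth) plus a manifest table.
    """
    if n_lgg + n_hgg < 2:
        raise ValueError("need at least 2 subjects")
    subjects: list[tuple[VolumeSet, PhantomTruth]] = []
    rows = []
    grades = ["LGG"] * n_lgg + ["HGG"] * n_hgg
    for i, grade in enumerate(grades):
        sid = f"{grade.lower()}{i + 1:02d}"
        rng = np.random.default_rng([seed, i])
        vs, truth = generate_subject(spec, grade, rng, subject_id=sid)
        subjects.append((vs, truth))
        rows.append({
            "subject_id": sid,
            "grade": grade,
            "n_brain_voxels": int(vs.brain_mask.sum()),
            "n_roi_voxels": int(vs.roi_mask.sum()),
        })
    return subjects, pd.DataFrame(rows)


def write_cohort(
    subjects: list[tuple[VolumeSet, PhantomTruth]],
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write NIfTI volumes, truth labels and the manifest CSV to disk."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for vs, truth in subjects:
        save_volume_set(vs, out)
        truth_img = nib.Nifti1Image(
            (truth.class_volume + 1).astype(np.uint16), vs.affine
        )  # shift so 0 = outside brain
        nib.save(truth_img, out / f"{vs.subject_id}_truth.nii.gz")
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
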