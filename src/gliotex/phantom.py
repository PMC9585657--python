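"""Synthetic textured tumor phantoms.

The generator emulates the statistical structure the radiomics pipeline
assumes, not brain anatomy: each synthetic patient is a pair of co-registered
MR-like channels (tags ``T1C`` and ``T2``) containing an ellipsoidal "tumor"
on a smooth background, with one shared binary ROI mask. Within the mask,
intensities are a class-conditional Gaussian random field — white noise
convolved with a Gaussian kernel whose width is the class's spatial
correlation length — passed through a monotone sinh–arcsinh transform that
induces the class's histogram skew, re-standardized so the configured tumor
mean and field amplitude are preserved, and degraded with additive white
noise. The two channels share the same underlying white noise up to a
configurable correlation coefficient, so they are related but not redundant.

Class differences in correlation length, amplitude and skew are the knobs
that create (or, when equal, remove) a texture signal for the downstream
classifier; the defaults reproduce the study conditions of an imbalanced
100-patient cohort with 17 positive ("mutant") cases.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageVolume, ROIMask, write_manifest, write_mask, write_volume

POSITIVE_LABEL = "mutant"
NEGATIVE_LABEL = "wild"


@dataclasses.dataclass
class TextureParams:
    """Per-class texture knobs of the Gaussian random field.

    corr_length_mm : spatial correlation length (Gaussian kernel sigma), > 0
    amplitude : field standard deviation in intensity units, >= 0
    skew : sinh–arcsinh skew parameter (0 = symmetric histogram)
    """

    corr_length_mm: float = 1.0
    amplitude: float = 1.0
    skew: float = 0.0

    def __post_init__(self) -> None:
        if self.corr_length_mm <= 0:
            raise ValueError("correlation length must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def default_texture_params() -> dict[str, TextureParams]:
    """Study-condition class textures: coarse, right-skewed positive class
    (4 mm correlation length) vs fine-grained negative class (1 mm)."""
    return {
        NEGATIVE_LABEL: TextureParams(corr_length_mm=1.0, amplitude=1.0, skew=0.0),
        POSITIVE_LABEL: TextureParams(corr_length_mm=4.0, amplitude=1.0, skew=0.5),
    }


@dataclasses.dataclass
class PhantomSpec:
    """Configuration of one phantom cohort (defaults = study conditions)."""

    n_patients: int = 100
    n_class_positive: int = 17
    volume_shape: tuple[int, int, int] = (20, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range_mm: tuple[float, float] = (8.0, 16.0)
    texture_params_per_class: dict[str, TextureParams] | None = None
    channel_coupling: float = 0.5
    noise_sd: float = 0.2
    tumor_mean: float = 120.0
    background_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_class_positive < self.n_patients:
            raise ValueError(
                f"need 0 < n_class_positive < n_patients, got "
                f"{self.n_class_positive}/{self.n_patients}"
            )
        if any(n < 8 for n in self.volume_shape):
            raise ValueError(f"degenerate volume shape {self.volume_shape}: every axis >= 8")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        rmin, rmax = self.tumor_radius_range_mm
        if not 0 < rmin <= rmax:
            raise ValueError(f"bad tumor radius range {self.tumor_radius_range_mm}")
        if not -1.0 <= self.channel_coupling <= 1.0:
            raise ValueError("channel coupling must be in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.texture_params_per_class is None:
            self.texture_params_per_class = default_texture_params()
        for label in (NEGATIVE_LABEL, POSITIVE_LABEL):
            if label not in self.texture_params_per_class:
                raise ValueError(f"texture_params_per_class missing class {label!r}")
        # the tumor must fit: each semi-axis is capped at 45% of the axis extent,
        # so the smallest admissible radius must not exceed any cap
        extents = [n * s for n, s in zip(self.volume_shape, self.spacing_mm)]
        caps = [0.45 * e for e in extents]
        if rmin > min(caps):
            raise ValueError(
                f"minimum tumor radius {rmin} mm exceeds volume (caps {caps} mm)"
            )


@dataclasses.dataclass
class PhantomPatient:
    patient_id: str
    volumes: dict[str, ImageVolume]
    mask: ROIMask
    label: str


@dataclasses.dataclass
class PhantomCohort:
    spec: PhantomSpec
    patients: list[PhantomPatient]

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "label": [p.label for p in self.patients],
            }
        )


def _skewed_unit_field(z: np.ndarray, skew: float) -> np.ndarray:
    """Monotone sinh–arcsinh transform, re-standardized to mean 0, sd 1."""
    t = np.sinh(np.arcsinh(z) + skew) if skew != 0.0 else z
    sd = t.std()
    if sd == 0:
        return np.zeros_like(t)
    return (t - t.mean()) / sd


def _correlated_field(
    white: np.ndarray, corr_length_mm: float, spacing_mm: tuple, skew: float
) -> np.ndarray:
    """Gaussian random field with unit variance: smoothed white noise + skew."""
    sigma_vox = [corr_length_mm / s for s in spacing_mm]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="mirror")
    sd = f.std()
    if sd > 0:
        f = f / sd
    return _skewed_unit_field(f, skew)


def _ellipsoid_mask(
    shape: tuple, spacing_mm: tuple, center_mm: np.ndarray, semi_axes_mm: np.ndarray
) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing_mm)], indexing="ij"
    )
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semi_axes_mm))
    return q <= 1.0


def _patient_volumes(
    spec: PhantomSpec, params: TextureParams, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """One patient's two channels plus the shared tumor mask."""
    shape = spec.volume_shape
    spacing = spec.spacing_mm
    extents = np.array([n * s for n, s in zip(shape, spacing)])

    rmin, rmax = spec.tumor_radius_range_mm
    semi = rng.uniform(rmin, rmax, size=3)
    semi = np.minimum(semi, 0.45 * extents)
    margin = np.array(spacing)  # one voxel inside the border
    lo = semi + margin
    hi = extents - semi - margin
    center = np.array([rng.uniform(l, h) if h > l else 0.5 * e
                       for l, h, e in zip(lo, hi, extents)])
    mask = _ellipsoid_mask(shape, spacing, center, semi)

    # the correlated field only matters inside the mask: work on the mask
    # bounding box padded by the smoothing support
    sigma_vox = [params.corr_length_mm / s for s in spacing]
    pads = [int(np.ceil(4 * sv)) + 1 for sv in sigma_vox]
    nz = np.nonzero(mask)
    box = tuple(
        slice(max(0, int(z.min()) - p), min(n, int(z.max()) + p + 1))
        for z, p, n in zip(nz, pads, shape)
    )
    box_shape = tuple(s.stop - s.start for s in box)
    mask_box = mask[box]

    # shared-structure white noise: channel 2 = rho*w1 + sqrt(1-rho^2)*w2
    rho = spec.channel_coupling
    w1 = rng.standard_normal(box_shape)
    w2 = rng.standard_normal(box_shape)
    whites = {"T1C": w1, "T2": rho * w1 + np.sqrt(1.0 - rho**2) * w2}

    # smooth "brain" background: a broad Gaussian blob with a per-patient,
    # per-channel jittered center and width (smooth, anatomy-free)
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    channels: dict[str, np.ndarray] = {}
    for tag, white in whites.items():
        blob_center = extents * rng.uniform(0.4, 0.6, size=3)
        blob_width = extents * rng.uniform(0.5, 0.8, size=3)
        r2 = sum(((g - c) / w) ** 2 for g, c, w in zip(grids, blob_center, blob_width))
        img = spec.background_mean + 3.0 * np.exp(-0.5 * r2)
        tumor = _correlated_field(white, params.corr_length_mm, spacing, params.skew)
        img[mask] = spec.tumor_mean + params.amplitude * tumor[mask_box]
        img += spec.noise_sd * rng.standard_normal(shape)
        channels[tag] = img
    return channels, mask


def generate_phantom_cohort(spec: PhantomSpec) -> PhantomCohort:
    """Generate a full phantom cohort, deterministic under ``spec.seed``.

    Labels are assigned by a seeded permutation with exactly
    ``spec.n_class_positive`` positive ("mutant") patients; every patient
    gets two channels and one shared nonempty mask.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.array(
        [POSITIVE_LABEL] * spec.n_class_positive
        + [NEGATIVE_LABEL] * (spec.n_patients - spec.n_class_positive)
    )
    labels = labels[rng.permutation(spec.n_patients)]
    width = max(3, len(str(spec.n_patients)))
    patients = []
    for idx, label in enumerate(labels):
        params = spec.texture_params_per_class[label]
        channels, mask = _patient_volumes(spec, params, rng)
        pid = f"P{idx:0{width}d}"
        volumes = {
            tag: ImageVolume(vox, spec.spacing_mm, tag) for tag, vox in channels.items()
        }
        patients.append(
            PhantomPatient(pid, volumes, ROIMask(mask.astype(np.uint8), spec.spacing_mm), label)
        )
    return PhantomCohort(spec, patients)


def generate_tumor_slice(
    class_params: TextureParams,
    shape: tuple[int, int] = (64, 64),
    spacing_mm: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
    radius_frac: float = 0.35,
    tumor_mean: float = 120.0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One 2D textured tumor slice plus its elliptical mask (a unit fixture).

    Returns ``(pixels, mask)``. Raises for slices smaller than 8x8 or a
    radius fraction that produces an empty mask.
    """
    if shape[0] < 8 or shape[1] < 8:
        raise ValueError(f"slice shape {shape} smaller than 8x8")
    extents = np.array([n * s for n, s in zip(shape, spacing_mm)])
    semi = radius_frac * extents
    center = 0.5 * extents
    mask = _ellipsoid_mask(shape, spacing_mm, center, semi)
    if not mask.any():
        raise ValueError("configuration yields an empty mask")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    field = _correlated_field(white, class_params.corr_length_mm, spacing_mm,
                              class_params.skew)
    pixels = np.full(shape, 100.0)
    pixels[mask] = tumor_mean + class_params.amplitude * field[mask]
    if noise_sd > 0:
        pixels += noise_sd * rng.standard_normal(shape)
    return pixels, mask


def write_cohort(cohort: PhantomCohort, outdir: str | Path) -> Path:
    """Write NIfTI volumes/masks plus the manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        paths = {}
        for tag, key in (("T1C", "path_t1c"), ("T2", "path_t2w")):
            path = outdir / f"{p.patient_id}_{tag}.nii.gz"
            write_volume(p.volumes[tag], path)
            paths[key] = str(path)
        mask_path = outdir / f"{p.patient_id}_mask.nii.gz"
        write_mask(p.mask, mask_path)
        rows.append(
            {
                "patient_id": p.patient_id,
                **paths,
                "path_mask": str(mask_path),
                "label": p.label,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest_path = outdir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    return manifest_path
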