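"""Synthetic multi-modal MR phantoms with phenotype-dependent tumor texture.

Real low-grade-glioma cohorts with molecular labels are not publicly
deposited, so every downstream stage of the pipeline (patch sampling, CNN
segmentation, multi-scale deep-feature pooling, Fisher encoding, SVM
classification) is exercised on phantoms generated here.  A phantom is a
co-registered multi-channel 3-D volume containing one ellipsoidal "tumor"
whose internal texture statistics depend on the binary phenotype class:
class 0 tumors have a longer spatial correlation length (smoother texture)
than class 1 tumors.  That single scalar contrast is what the deep filter
responses must pick up for phenotype prediction to beat chance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "LabeledVolume",
    "generate_phantom",
    "generate_cohort",
]

#: half-width of the default 33x33 training patch; tumors keep this margin
#: from the in-plane volume borders so every tumor voxel is a legal patch center.
PATCH_HALF_WIDTH = 16


class PhantomConfigError(ValueError):
    """Raised when a PhantomConfig cannot produce a valid phantom."""


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom cohort.

    Parameters
    ----------
    volume_shape:
        Voxels per axis as ``(z, y, x)``; axial slices are indexed by z.
    n_channels:
        Number of co-registered modalities (1 or 2, e.g. T2-FLAIR and
        post-contrast T1).
    tumor_radius_range:
        In-plane ellipsoid semi-axis bounds in voxels, ``(min, max)``.
    tumor_contrast:
        Intensity offset of tumor over background (arbitrary units).
    texture_corr_length:
        Gaussian correlation length of the intratumoral texture field per
        class, ``(class 0, class 1)`` in voxels.  Class 0 larger means
        class 0 is smoother; class 1 tumors look internally busier.
    texture_sd:
        Standard deviation of the (unit-variance-normalised then scaled)
        texture field, intensity units.
    noise_sd:
        Additive white Gaussian noise everywhere, intensity units.
    background_level:
        Mean intensity of non-tumor tissue.
    seed:
        Base seed; per-case streams are spawned from it deterministically.
    """

    volume_shape: tuple[int, int, int] = (8, 64, 64)
    n_channels: int = 2
    tumor_radius_range: tuple[int, int] = (8, 12)
    tumor_contrast: float = 4.0
    texture_corr_length: tuple[float, float] = (3.0, 1.0)
    texture_sd: float = 1.0
    noise_sd: float = 0.3
    background_level: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        nz, ny, nx = self.volume_shape
        rmin, rmax = self.tumor_radius_range
        if self.n_channels not in (1, 2):
            raise PhantomConfigError("n_channels must be 1 or 2")
        if not (1 <= rmin <= rmax):
            raise PhantomConfigError("tumor_radius_range must satisfy 1 <= min <= max")
        # in-plane: the ellipsoid plus a patch half-width margin must fit
        for extent in (ny, nx):
            if 2 * (rmax + PATCH_HALF_WIDTH) >= extent:
                raise PhantomConfigError(
                    f"max radius {rmax} + patch margin {PATCH_HALF_WIDTH} does not fit "
                    f"in in-plane extent {extent}"
                )
        if nz < 3:
            raise PhantomConfigError("volume needs at least 3 axial slices")
        if min(self.texture_corr_length) <= 0:
            raise PhantomConfigError("texture_corr_length must be strictly positive")
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be >= 0")


@dataclass
class LabeledVolume:
    """A multi-channel volume with a binary tumor mask and a phenotype label.

    ``intensities`` has axes ``(channel, z, y, x)``; ``mask`` has the same
    spatial shape with nonzero = tumor.  ``diagnosis_time`` is an ordinal
    used by the time-based train/test split.
    """

    intensities: np.ndarray
    mask: np.ndarray
    label: int
    case_id: str
    diagnosis_time: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be (channel, z, y, x)")
        if self.mask.shape != self.intensities.shape[1:]:
            raise ValueError(
                f"mask shape {self.mask.shape} incongruent with intensity "
                f"spatial shape {self.intensities.shape[1:]}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if not np.any(self.mask):
            raise ValueError("mask must contain at least one foreground voxel")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return d2 <= 1.0


def _texture_field(shape, corr_length, rng) -> np.ndarray:
    """Unit-variance smoothed white-noise field with isotropic correlation."""
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=corr_length, mode="wrap")
    sd = smooth.std()
    if sd == 0:  # pragma: no cover - degenerate only for absurd shapes
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def generate_phantom(
    config: PhantomConfig,
    label: int,
    seed: int,
    case_id: str = "case",
    diagnosis_time: int = 0,
) -> LabeledVolume:
    """Generate one phantom of the given phenotype class.

    The tumor is an axis-aligned ellipsoid at a random interior position;
    its intensity is ``background_level + tumor_contrast`` plus a
    zero-mean texture field whose correlation length is set by the class.
    Gaussian noise of ``noise_sd`` is added everywhere.  Identical
    ``(config, label, seed)`` always yields a bit-identical volume.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng(seed)
    nz, ny, nx = config.volume_shape
    rmin, rmax = config.tumor_radius_range

    r_inplane = float(rng.uniform(rmin, rmax))
    # z semi-axis scaled down: axial voxel count is typically much smaller
    rz = max(1.0, min(r_inplane, nz / 2.0 - 1.0))
    margin = PATCH_HALF_WIDTH
    cy = rng.uniform(r_inplane + margin, ny - 1 - r_inplane - margin)
    cx = rng.uniform(r_inplane + margin, nx - 1 - r_inplane - margin)
    cz = rng.uniform(rz, nz - 1 - rz)

    mask = _ellipsoid_mask((nz, ny, nx), (cz, cy, cx), (rz, r_inplane, r_inplane))
    corr = config.texture_corr_length[label]

    channels = np.empty((config.n_channels, nz, ny, nx))
    for c in range(config.n_channels):
        vol = np.full((nz, ny, nx), config.background_level, dtype=np.float64)
        vol[mask] += config.tumor_contrast
        texture = _texture_field((nz, ny, nx), corr, rng) * config.texture_sd
        vol[mask] += texture[mask]
        if config.noise_sd > 0:
            vol += rng.normal(0.0, config.noise_sd, size=(nz, ny, nx))
        channels[c] = vol

    return LabeledVolume(
        intensities=channels,
        mask=mask.astype(np.uint8),
        label=int(label),
        case_id=case_id,
        diagnosis_time=diagnosis_time,
    )


def generate_cohort(
    n_per_class: int, config: PhantomConfig, seed: int | None = None
) -> list[LabeledVolume]:
    """Generate ``2 * n_per_class`` phantoms with alternating labels.

    Case ids are unique, and ``diagnosis_time`` equals the case index so a
    time-based split is available deterministically.  Per-case seeds are
    spawned from ``seed`` (default: ``config.seed``) so distinct cases are
    statistically independent while the whole cohort is reproducible.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = config.seed if seed is None else seed
    n_total = 2 * n_per_class
    children = np.random.SeedSequence(base).spawn(n_total)
    cohort = []
    for i in range(n_total):
        label = i % 2
        case_seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
        cohort.append(
            generate_phantom(
                config,
                label=label,
                seed=case_seed,
                case_id=f"case{i:03d}",
                diagnosis_time=i,
            )
        )
    return cohort


def highfreq_energy(volume: LabeledVolume, channel: int = 0) -> float:
    """Mean squared first difference of in-mask intensities along y and x.

    This is the scalar texture statistic that separates the phenotype
    classes by construction: a shorter correlation length raises it.
    """
    img = volume.intensities[channel]
    m = volume.mask.astype(bool)
    total = 0.0
    count = 0
    for axis in (1, 2):
        d = np.diff(img, axis=axis)
        valid = np.logical_and(
            np.take(m, range(0, m.shape[axis] - 1), axis=axis),
            np.take(m, range(1, m.shape[axis]), axis=axis),
        )
        total += float((d[valid] ** 2).sum())
        count += int(valid.sum())
    return total / max(count, 1)


def config_to_dict(config: PhantomConfig) -> dict:
    return dataclasses.asdict(config)
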