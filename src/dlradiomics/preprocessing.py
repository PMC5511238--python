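"""Patch normalization and unbalanced patch sampling for CNN training.

Training patches are 33x33 axial windows labeled by the class of their
center voxel (tumor vs non-tumor).  Because tumor occupies a small
fraction of the volume, sampling is deliberately unbalanced: by default
roughly 40% of drawn patches are centered on tumor voxels.  Each patch is
standardized per channel to zero mean, unit variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import LabeledVolume

__all__ = ["PatchSet", "normalize_patch", "sample_patches", "DegeneratePatchError"]


class DegeneratePatchError(ValueError):
    """A patch channel is constant and cannot be standardized."""


@dataclass
class PatchSet:
    """Normalized training patches with center-voxel labels and provenance.

    ``patches`` is ``(n, channel, p, p)`` float; ``labels`` is the binary
    class of each center voxel; ``centers`` records ``(case_id, z, y, x)``
    per patch.
    """

    patches: np.ndarray
    labels: np.ndarray
    centers: list[tuple[str, int, int, int]]

    def __len__(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_size(self) -> int:
        return self.patches.shape[-1]


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Standardize each channel of one patch to mean 0, variance 1.

    Raises :class:`DegeneratePatchError` for a constant channel; callers
    drop such patches and log them.  Idempotent up to float tolerance.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim == 2:
        patch = patch[None]
    out = np.empty_like(patch)
    for c in range(patch.shape[0]):
        sd = patch[c].std()
        if sd == 0:
            raise DegeneratePatchError(f"channel {c} is constant")
        out[c] = (patch[c] - patch[c].mean()) / sd
    return out


def _eligible_centers(mask2d: np.ndarray, half: int) -> np.ndarray:
    """Boolean map of voxels whose full patch support lies inside the slice."""
    ok = np.zeros_like(mask2d, dtype=bool)
    ok[half : mask2d.shape[0] - half, half : mask2d.shape[1] - half] = True
    return ok


def sample_patches(
    volumes: list[LabeledVolume],
    n_total: int,
    tumor_fraction: float = 0.4,
    patch_size: int = 33,
    seed: int = 0,
) -> PatchSet:
    """Draw ``n_total`` normalized patches with an unbalanced class mix.

    ``round(n_total * tumor_fraction)`` patches get tumor-voxel centers,
    the remainder non-tumor centers.  Within each class, centers are drawn
    uniformly without replacement from all eligible voxels (those whose
    full ``patch_size`` support fits in the slice), stratified across
    cases proportionally to each case's eligible-voxel count.  Constant
    (degenerate) patches are dropped with a warning and redrawn from the
    remaining pool when possible.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    half = patch_size // 2
    rng = np.random.default_rng(seed)

    n_tumor = int(round(n_total * tumor_fraction))
    n_back = n_total - n_tumor

    # per-case eligible coordinate arrays for each class
    pools: dict[int, list[tuple[LabeledVolume, np.ndarray]]] = {0: [], 1: []}
    for vol in volumes:
        if not np.any(vol.mask):
            raise ValueError(f"case {vol.case_id} has an empty mask")
        mask = vol.mask.astype(bool)
        for cls in (0, 1):
            coords = []
            for z in range(vol.spatial_shape[0]):
                sl = mask[z]
                inside = _eligible_centers(sl, half)
                sel = inside & (sl if cls == 1 else ~sl)
                ys, xs = np.nonzero(sel)
                if ys.size:
                    coords.append(
                        np.column_stack([np.full(ys.size, z), ys, xs])
                    )
            if coords:
                pools[cls].append((vol, np.concatenate(coords)))
            elif cls == 1:
                warnings.warn(
                    f"case {vol.case_id}: no eligible tumor centers; skipped",
                    stacklevel=2,
                )

    patches, labels, centers = [], [], []
    for cls, n_want in ((1, n_tumor), (0, n_back)):
        if n_want == 0:
            continue
        if not pools[cls]:
            raise ValueError(f"no case provides eligible class-{cls} centers")
        sizes = np.array([c.shape[0] for _, c in pools[cls]], dtype=float)
        # proportional allocation with largest-remainder rounding
        quota = sizes / sizes.sum() * n_want
        alloc = np.floor(quota).astype(int)
        rem = n_want - alloc.sum()
        order = np.argsort(-(quota - alloc))
        alloc[order[:rem]] += 1
        alloc = np.minimum(alloc, sizes.astype(int))
        short = n_want - alloc.sum()
        if short > 0:
            warnings.warn(
                f"only {alloc.sum()} eligible class-{cls} centers available, "
                f"requested {n_want}",
                stacklevel=2,
            )
        for (vol, coords), k in zip(pools[cls], alloc):
            idx = rng.choice(coords.shape[0], size=int(k), replace=False)
            for z, y, x in coords[idx]:
                raw = vol.intensities[:, z, y - half : y + half + 1, x - half : x + half + 1]
                try:
                    patches.append(normalize_patch(raw))
                except DegeneratePatchError:
                    warnings.warn(
                        f"degenerate patch at {vol.case_id} ({z},{y},{x}) dropped",
                        stacklevel=2,
                    )
                    continue
                labels.append(cls)
                centers.append((vol.case_id, int(z), int(y), int(x)))

    if not patches:
        raise ValueError("no patches could be sampled")
    return PatchSet(
        patches=np.stack(patches),
        labels=np.asarray(labels, dtype=np.int64),
        centers=centers,
    )
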