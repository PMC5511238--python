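"""Whole-volume tumor segmentation: dense inference, post-processing, scoring.

Inference is slice-wise (axial): each slice is standardized per channel,
zero-padded by half a patch, and pushed through the network in fully
convolutional mode.  Pooling subsamples the logit grid, so the class-1
probability map is upsampled back to voxel resolution with bicubic
interpolation.  Post-processing keeps the largest connected component per
slice and smooths the binary stack with a 3x3x3 box filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter, zoom
from skimage.measure import label as cc_label

from .network import ConvNet, _softmax
from .phantom import LabeledVolume

__all__ = [
    "SegmentationResult",
    "segment_volume",
    "postprocess_mask",
    "segmentation_metrics",
]


@dataclass
class SegmentationResult:
    probability_map: np.ndarray  # (z, y, x) in [0, 1]
    mask: np.ndarray  # (z, y, x) binary, post-processed

    def __post_init__(self) -> None:
        if self.probability_map.shape != self.mask.shape:
            raise ValueError("probability map and mask shapes differ")


def _standardize_slice(sl: np.ndarray) -> np.ndarray:
    """Per-channel zero-mean unit-variance standardization of one slice."""
    out = np.empty_like(sl, dtype=np.float64)
    for c in range(sl.shape[0]):
        sd = sl[c].std()
        out[c] = (sl[c] - sl[c].mean()) / sd if sd > 0 else 0.0
    return out


def segment_volume(
    net: ConvNet, volume: LabeledVolume, threshold: float = 0.5
) -> SegmentationResult:
    """Dense per-voxel tumor probability plus the post-processed mask."""
    if volume.n_channels != net.spec.n_input_channels:
        raise ValueError(
            f"volume has {volume.n_channels} channels, network expects "
            f"{net.spec.n_input_channels}"
        )
    half = net.spec.patch_size // 2
    nz, ny, nx = volume.spatial_shape
    prob = np.empty((nz, ny, nx))
    stride = net.stride
    for z in range(nz):
        sl = _standardize_slice(volume.intensities[:, z])
        padded = np.pad(sl, ((0, 0), (half, half), (half, half)))
        logits = net.dense_logits(padded)  # (2, h', w') at `stride`
        pmap = _softmax(logits.reshape(2, -1).T).T.reshape(logits.shape)[1]
        if stride > 1:
            pmap = zoom(pmap, stride, order=3)
        h, w = pmap.shape
        if h < ny or w < nx:
            pmap = np.pad(pmap, ((0, max(0, ny - h)), (0, max(0, nx - w))), mode="edge")
        prob[z] = np.clip(pmap[:ny, :nx], 0.0, 1.0)
    mask = postprocess_mask(prob, threshold=threshold)
    return SegmentationResult(probability_map=prob, mask=mask)


def postprocess_mask(probability_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Largest per-slice connected component, then 3x3x3 box smoothing.

    Per axial slice, only the largest 4-connected component of
    ``{p >= threshold}`` is kept.  The resulting binary stack is convolved
    with a 3x3x3 box kernel and re-thresholded at 0.5, which removes
    isolated voxels (smoothed value 1/27) and rounds ragged borders.
    An empty result is allowed.
    """
    pm = np.asarray(probability_map, dtype=np.float64)
    if pm.min() < 0 or pm.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    binary = pm >= threshold
    kept = np.zeros_like(binary)
    for z in range(binary.shape[0]):
        labels = cc_label(binary[z], connectivity=1)
        if labels.max() == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        kept[z] = labels == (int(np.argmax(sizes)) + 1)
    smoothed = uniform_filter(kept.astype(np.float64), size=3, mode="constant")
    return (smoothed > 0.5 - 1e-12).astype(np.uint8)


def segmentation_metrics(pred_mask: np.ndarray, truth_mask: np.ndarray):
    """(DSC, PPV, sensitivity) of a predicted vs ground-truth binary mask.

    DSC = 2|P∩T| / (|P|+|T|); PPV = |P∩T|/|P|; sensitivity = |P∩T|/|T|.
    An empty denominator yields 0 with a warning rather than NaN.
    """
    p = np.asarray(pred_mask).astype(bool)
    t = np.asarray(truth_mask).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    inter = int(np.logical_and(p, t).sum())
    np_, nt = int(p.sum()), int(t.sum())

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name}: empty denominator, returning 0", stacklevel=3)
            return 0.0
        return num / den

    dsc = _ratio(2 * inter, np_ + nt, "DSC")
    ppv = _ratio(inter, np_, "PPV")
    sens = _ratio(inter, nt, "sensitivity")
    return dsc, ppv, sens
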