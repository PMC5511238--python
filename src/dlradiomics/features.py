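"""Multi-scale tumor ROIs and pooled last-conv-layer filter responses.

For every axial slice that intersects the tumor mask, the mask bounding
box is cropped, out-of-mask voxels are zeroed to isolate the tumor
signal, and the crop is resampled at ``n_scales`` ratios spanning
``scale_range`` (geometric spacing, endpoints included; bicubic
interpolation).  Each scaled ROI is pushed through the network's
convolutional stack and the post-ReLU feature map of every last-layer
filter is flattened and appended — slice-major, then scale, then
row-major pixels — giving one long scalar response sequence per filter
with identical length T across filters.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .network import ConvNet
from .phantom import LabeledVolume

__all__ = [
    "ScaledRoi",
    "ScaledRoiSet",
    "FilterResponseSet",
    "scale_ratios",
    "multiscale_rois",
    "extract_filter_responses",
]


@dataclass
class ScaledRoi:
    slice_index: int
    scale: float
    image: np.ndarray  # (channel, h, w)


@dataclass
class ScaledRoiSet:
    case_id: str
    rois: list[ScaledRoi]
    ratios: np.ndarray

    def __len__(self) -> int:
        return len(self.rois)


@dataclass
class FilterResponseSet:
    """Per-case ragged-to-rectangular pool of deep filter responses.

    ``responses`` is (F, T): for each of the F last-conv filters, the
    scalar activations pooled over all (slice, scale) ROI images in a
    fixed order.  T is identical across filters because every filter
    shares the spatial grid of each feature map.
    """

    case_id: str
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a (F, T) array")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    @property
    def n_filters(self) -> int:
        return self.responses.shape[0]

    @property
    def length(self) -> int:
        return self.responses.shape[1]


def scale_ratios(n_scales: int = 10, scale_range=(0.5, 2.0)) -> np.ndarray:
    """Geometrically spaced resampling ratios including both endpoints."""
    lo, hi = scale_range
    if not 0 < lo < hi:
        raise ValueError("scale_range must satisfy 0 < low < high")
    if n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    return np.geomspace(lo, hi, n_scales)


def _pad_to(img: np.ndarray, size: int) -> np.ndarray:
    """Zero-pad (C, h, w) symmetrically so both spatial dims are >= size."""
    c, h, w = img.shape
    ph, pw = max(0, size - h), max(0, size - w)
    return np.pad(
        img,
        ((0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)),
    )


def multiscale_rois(
    volume: LabeledVolume,
    mask: np.ndarray | None = None,
    n_scales: int = 10,
    scale_range=(0.5, 2.0),
    min_size: int = 8,
) -> ScaledRoiSet:
    """Build the scaled tumor-ROI image set for one case.

    ``mask`` defaults to the volume's own (ground-truth) mask; pass a
    predicted mask for fully automatic operation.  Each in-mask crop is
    standardized per channel over its in-mask pixels before zeroing the
    outside, so ROI intensities live on the scale the network was trained
    on.  A (slice, scale) whose resampled crop cannot reach ``min_size``
    even with padding never occurs (padding always can), but empty masks
    raise.
    """
    m = (volume.mask if mask is None else np.asarray(mask)).astype(bool)
    if m.shape != volume.spatial_shape:
        raise ValueError("mask shape incongruent with volume")
    if not m.any():
        raise ValueError(f"case {volume.case_id}: empty mask, no ROI")
    ratios = scale_ratios(n_scales, scale_range)

    rois: list[ScaledRoi] = []
    for z in range(volume.spatial_shape[0]):
        sl_mask = m[z]
        if not sl_mask.any():
            continue
        ys, xs = np.nonzero(sl_mask)
        y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
        crop_mask = sl_mask[y0:y1, x0:x1]
        crop = volume.intensities[:, z, y0:y1, x0:x1].astype(np.float64).copy()
        for c in range(crop.shape[0]):
            vals = crop[c][crop_mask]
            sd = vals.std()
            crop[c] = (crop[c] - vals.mean()) / sd if sd > 0 else 0.0
        crop *= crop_mask  # zero out-of-mask voxels: isolate tumor signal
        for r in ratios:
            h = max(1, int(round(crop.shape[1] * r)))
            w = max(1, int(round(crop.shape[2] * r)))
            scaled = resize(
                crop,
                (crop.shape[0], h, w),
                order=3,
                mode="constant",
                anti_aliasing=r < 1.0,
                preserve_range=True,
            )
            rois.append(ScaledRoi(slice_index=z, scale=float(r), image=_pad_to(scaled, min_size)))
    if not rois:
        raise ValueError(f"case {volume.case_id}: no usable (slice, scale) ROI")
    return ScaledRoiSet(case_id=volume.case_id, rois=rois, ratios=ratios)


def extract_filter_responses(net: ConvNet, roi_set: ScaledRoiSet) -> FilterResponseSet:
    """Pool post-ReLU last-conv responses over all ROIs of one case.

    ROIs differ in spatial size, so each filter's 2-D map is flattened
    row-major and concatenated in ROI order (slice-major, then scale).
    All filters see the same grid, hence equal sequence lengths.  An
    untrained network is allowed — responses are valid, just uninformative.
    """
    if len(roi_set) == 0:
        raise ValueError("empty ROI set")
    min_in = net.min_feature_input()
    chunks: list[np.ndarray] = []
    for roi in roi_set.rois:
        img = _pad_to(roi.image, min_in)
        maps = net.last_conv_maps(img)  # (F, h, w)
        chunks.append(maps.reshape(maps.shape[0], -1))
    responses = np.concatenate(chunks, axis=1)
    return FilterResponseSet(case_id=roi_set.case_id, responses=responses)
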