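"""Flat pipeline configuration with strict (typo-safe) YAML loading."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline in one flat record.

    Defaults mirror the reference operating point: 33x33 patches with
    ~40% tumor centers, a 6-conv network with 4096-neuron fc layers and
    128 last-conv filters, 10 ROI scales spanning ratio 0.5-2, a
    64-component GMM fitted on a 30-case encoder subset, t-test alpha
    0.05, and a linear SVM with box constraint 1.
    """

    # patch sampling
    patch_size: int = 33
    tumor_patch_fraction: float = 0.4
    n_patches: int = 5000
    # network
    n_conv_layers: int = 6
    conv_filters: tuple[int, ...] | None = None  # default derived below
    fc_neurons: int = 4096
    last_conv_filters: int = 128
    dropout_rate: float = 0.5
    n_channels: int = 2
    # SGD
    learning_rate: float = 0.005
    momentum: float = 0.9
    batch_size: int = 128
    n_epochs: int = 30
    # segmentation
    mask_threshold: float = 0.5
    # deep features
    n_scales: int = 10
    scale_range: tuple[float, float] = (0.5, 2.0)
    roi_mask: str = "truth"  # "truth" or "predicted"
    # Fisher encoding
    gmm_components: int = 64
    encoder_fit_cases: int = 30
    # selection / classification
    ttest_alpha: float = 0.05
    m_features: int = 100
    svm_c: float = 1.0
    classify_mode: str = "loocv"  # or "timesplit"
    time_cutoff: float | None = None
    # phantom cohort (simulate stage)
    n_per_class: int = 5
    volume_shape: tuple[int, int, int] = (8, 64, 64)
    tumor_radius_range: tuple[int, int] = (8, 12)
    tumor_contrast: float = 4.0
    texture_corr_length: tuple[float, float] = (3.0, 1.0)
    texture_sd: float = 1.0
    noise_sd: float = 0.3
    background_level: float = 1.0
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ConfigError("patch_size must be odd and >= 3")
        for name in (
            "n_patches",
            "n_conv_layers",
            "fc_neurons",
            "last_conv_filters",
            "n_scales",
            "gmm_components",
            "encoder_fit_cases",
            "m_features",
            "batch_size",
            "n_epochs",
            "n_per_class",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.scale_range
        if not lo < hi:
            raise ConfigError("scale_range must satisfy low < high")
        if self.roi_mask not in ("truth", "predicted"):
            raise ConfigError("roi_mask must be 'truth' or 'predicted'")
        if self.classify_mode not in ("loocv", "timesplit"):
            raise ConfigError("classify_mode must be 'loocv' or 'timesplit'")

    def resolved_conv_filters(self) -> tuple[int, ...]:
        """Per-layer conv widths; the last is always last_conv_filters."""
        if self.conv_filters is not None:
            filt = tuple(self.conv_filters)
            if len(filt) != self.n_conv_layers:
                raise ConfigError("conv_filters length must equal n_conv_layers")
            return filt
        base = (64, 64, 128, 128, 128, 128)
        if self.n_conv_layers <= len(base):
            filt = base[: self.n_conv_layers]
        else:
            filt = base + (128,) * (self.n_conv_layers - len(base))
        return filt[:-1] + (self.last_conv_filters,)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash used in stage log lines."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


_TUPLE_FIELDS = {
    "conv_filters",
    "scale_range",
    "volume_shape",
    "tumor_radius_range",
    "texture_corr_length",
}


def load_config(path) -> PipelineConfig:
    """Load a flat YAML mapping into a PipelineConfig; unknown keys error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must be a flat key/value mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(raw):
        if raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)
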