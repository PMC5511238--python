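"""Patch-based convolutional network for pixel-wise tumor classification.

The network follows the BRATS-winning patch-classification design: a stack
of 3x3 valid convolutions with ReLU and occasional 2x2 max-pooling,
followed by two fully connected layers (with dropout) and a 2-way softmax.
A 33x33 patch centered on a voxel is classified as tumor / non-tumor.

Everything here is plain NumPy.  Fully connected layers are represented as
convolutions whose kernel covers the entire remaining spatial extent, so
the very same weights support two inference modes:

* patch mode — a batch of 33x33 patches yields one logit pair each;
* dense (fully convolutional) mode — a whole padded slice yields a
  subsampled logit map (stride ``2**n_pools``), which the segmentation
  stage upsamples back to voxel resolution with bicubic interpolation.

The post-ReLU feature maps of the last convolutional layer are exposed for
the radiomics stage, which pools their scalar responses over multi-scale
tumor ROIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "NetworkSpec",
    "SgdConfig",
    "ConvNet",
    "build_network",
    "train_network",
    "NetworkSpecError",
]


class NetworkSpecError(ValueError):
    """The requested architecture cannot operate on the given patch size."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``conv_filters`` lists the output width of each convolutional layer;
    its last entry is the number of deep filters F whose responses feed
    the Fisher encoding (128 at defaults).  ``fc_neurons`` is the width of
    both fully connected layers (4096 at defaults, 256 in the shallow
    ablation).  2x2 max-pooling is inserted after every second
    convolution while the spatial extent stays large enough; the
    receptive field of the convolutional stack must not exceed the patch.
    """

    n_conv_layers: int = 6
    conv_filters: tuple[int, ...] = (64, 64, 128, 128, 128, 128)
    kernel_size: int = 3
    n_fc_layers: int = 2
    fc_neurons: int = 4096
    dropout_rate: float = 0.5
    n_input_channels: int = 2
    n_classes: int = 2
    patch_size: int = 33

    def __post_init__(self) -> None:
        if len(self.conv_filters) != self.n_conv_layers:
            raise NetworkSpecError(
                f"conv_filters has {len(self.conv_filters)} entries for "
                f"{self.n_conv_layers} conv layers"
            )
        if self.kernel_size % 2 == 0 or self.kernel_size < 3:
            raise NetworkSpecError("kernel_size must be odd and >= 3")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise NetworkSpecError("dropout_rate must be in [0, 1)")
        if min(self.conv_filters) < 1 or self.fc_neurons < 1:
            raise NetworkSpecError("layer widths must be positive")

    @property
    def n_filters(self) -> int:
        """Width of the last convolutional layer (deep filters F)."""
        return self.conv_filters[-1]


@dataclass(frozen=True)
class SgdConfig:
    learning_rate: float = 0.005
    momentum: float = 0.9
    batch_size: int = 128
    n_epochs: int = 30


# ---------------------------------------------------------------------------
# layers


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H-kh+1, W-kw+1, C*kh*kw) patch matrix."""
    v = sliding_window_view(x, (kh, kw), axis=(2, 3))
    n, c, h2, w2 = v.shape[:4]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, h2, w2, c * kh * kw
    )


class Conv:
    """Valid 2-D convolution (cross-correlation) with bias."""

    def __init__(self, in_ch, out_ch, kh, kw, rng=None, dtype=np.float32):
        self.in_ch, self.out_ch, self.kh, self.kw = in_ch, out_ch, kh, kw
        fan_in = in_ch * kh * kw
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        if rng is None:
            self.W = np.zeros((out_ch, in_ch, kh, kw), dtype=dtype)
        else:
            self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, kh, kw)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self._cols = None
        self._x_shape = None
        #: set False on the first layer during training: its input gradient
        #: is never consumed and is the single most expensive backward step
        self.input_grad = True

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.W.dtype)
        if x.shape[2] < self.kh or x.shape[3] < self.kw:
            raise NetworkSpecError(
                f"input spatial {x.shape[2:]} smaller than kernel ({self.kh},{self.kw})"
            )
        cols = _im2col(x, self.kh, self.kw)
        if train:
            self._cols = cols
            self._x_shape = x.shape
        y = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        return y.transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray):
        n, o, h2, w2 = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, o)
        self.dW = (dyf.T @ self._cols.reshape(-1, self._cols.shape[-1])).reshape(
            self.W.shape
        )
        self.db = dyf.sum(axis=0)
        self._cols = None
        if not self.input_grad:
            return None
        if h2 == 1 and w2 == 1:
            # kernel covers the whole input (fc-as-conv): dx is a plain matmul
            dx = dyf @ self.W.reshape(o, -1)
            return dx.reshape(n, self.in_ch, self.kh, self.kw)
        # full correlation of dy with the flipped kernels gives dx
        pad = ((0, 0), (0, 0), (self.kh - 1,) * 2, (self.kw - 1,) * 2)
        dyp = np.pad(dy, pad)
        cols = _im2col(dyp, self.kh, self.kw)
        wf = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.in_ch, -1)
        dx = cols @ wf.T
        return dx.transpose(0, 3, 1, 2)

    @property
    def grads(self):
        return [self.dW, self.db]

    def out_size(self, h: int, w: int):
        return h - self.kh + 1, w - self.kw + 1


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask

    def out_size(self, h, w):
        return h, w


class MaxPool2:
    """2x2 max-pooling with stride 2; odd trailing rows/cols are cropped."""

    params: list = []
    grads: list = []

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        if h2 < 1 or w2 < 1:
            raise NetworkSpecError("input too small for 2x2 pooling")
        xc = x[:, :, : 2 * h2, : 2 * w2]
        v = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2, w2, 4
        )
        if train:
            self._x_shape = x.shape
            self._arg = v.argmax(axis=-1)
        return v.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._x_shape
        h2, w2 = dy.shape[2], dy.shape[3]
        flat = np.zeros((n, c, h2, w2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=dy.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            flat.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2)
        )
        return dx

    def out_size(self, h, w):
        return h // 2, w // 2


class Dropout:
    params: list = []
    grads: list = []

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            return x
        self._mask = ((rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def out_size(self, h, w):
        return h, w


# ---------------------------------------------------------------------------
# network


class ConvNet:
    """The assembled network: conv stack, then fc-as-conv head.

    ``feature_cutoff`` marks the end of the convolutional stack (just
    after the last conv's ReLU); :meth:`last_conv_maps` runs only that
    prefix and returns the F post-ReLU feature maps.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = seed
        self.dtype = np.dtype(dtype)
        self.training_log: list[dict] = []
        self.trained = False
        rng = np.random.default_rng(seed)

        k = spec.kernel_size
        s = spec.patch_size
        rf, jump = 1, 1
        layers: list = []
        in_ch = spec.n_input_channels
        self._n_pools = 0
        for i, width in enumerate(spec.conv_filters):
            if s < k:
                raise NetworkSpecError(
                    f"conv layer {i}: spatial extent {s} below kernel {k}"
                )
            layers.append(Conv(in_ch, width, k, k, rng, dtype=self.dtype))
            layers.append(ReLU())
            s -= k - 1
            rf += (k - 1) * jump
            in_ch = width
            if i % 2 == 1 and s >= 8:
                layers.append(MaxPool2())
                s //= 2
                rf += jump
                jump *= 2
                self._n_pools += 1
        if rf > spec.patch_size:
            raise NetworkSpecError(
                f"receptive field {rf} exceeds patch size {spec.patch_size}"
            )
        self.receptive_field = rf
        self.feature_cutoff = len(layers)
        self._fc_entry_size = s

        for j in range(spec.n_fc_layers):
            kk = s if j == 0 else 1
            layers.append(Conv(in_ch, spec.fc_neurons, kk, kk, rng, dtype=self.dtype))
            layers.append(ReLU())
            layers.append(Dropout(spec.dropout_rate))
            in_ch = spec.fc_neurons
        layers.append(Conv(in_ch, spec.n_classes, 1, 1, rng, dtype=self.dtype))
        self.layers = layers

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return sum(p.size for lay in self.layers for p in lay.params)

    @property
    def n_filters(self) -> int:
        return self.spec.n_filters

    @property
    def stride(self) -> int:
        """Output subsampling factor of dense inference (2**n_pools)."""
        return 2**self._n_pools

    def min_feature_input(self) -> int:
        """Smallest square input on which the conv stack yields a 1x1 map."""
        for s in range(self.spec.kernel_size, 4 * self.spec.patch_size):
            t = s
            ok = True
            for lay in self.layers[: self.feature_cutoff]:
                if isinstance(lay, Conv):
                    t = t - lay.kh + 1
                elif isinstance(lay, MaxPool2):
                    t //= 2
                if t < 1:
                    ok = False
                    break
            if ok:
                return s
        raise NetworkSpecError("no feasible input size")  # pragma: no cover

    # -- inference -----------------------------------------------------

    def _run(self, x: np.ndarray, upto: int | None = None, train: bool = False, rng=None):
        for lay in self.layers[:upto]:
            if isinstance(lay, Dropout):
                x = lay.forward(x, train=train, rng=rng)
            else:
                x = lay.forward(x, train=train)
        return x

    def forward_patches(self, patches: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (n, n_classes), for a patch batch."""
        logits = self._run(np.asarray(patches, dtype=np.float64))
        if logits.shape[2] != 1 or logits.shape[3] != 1:
            raise NetworkSpecError(
                f"patch spatial shape leaves a {logits.shape[2:]} logit map; "
                f"expected 1x1 — wrong patch size?"
            )
        return _softmax(logits[:, :, 0, 0].astype(np.float64))

    def dense_logits(self, image: np.ndarray) -> np.ndarray:
        """Fully convolutional logit map for one (C, H, W) image.

        The output grid is subsampled by :attr:`stride`; position (i, j)
        corresponds to the patch whose top-left corner sits at
        ``(i*stride, j*stride)`` in the input.
        """
        return self._run(image[None])[0].astype(np.float64)

    def last_conv_maps(self, image: np.ndarray) -> np.ndarray:
        """Post-ReLU feature maps (F, h, w) of the last conv layer."""
        return self._run(image[None], upto=self.feature_cutoff)[0].astype(np.float64)

    # -- persistence ----------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, lay in enumerate(self.layers):
            if isinstance(lay, Conv):
                arrays[f"W{i}"] = lay.W
                arrays[f"b{i}"] = lay.b
        meta = {
            "spec": {
                "n_conv_layers": self.spec.n_conv_layers,
                "conv_filters": list(self.spec.conv_filters),
                "kernel_size": self.spec.kernel_size,
                "n_fc_layers": self.spec.n_fc_layers,
                "fc_neurons": self.spec.fc_neurons,
                "dropout_rate": self.spec.dropout_rate,
                "n_input_channels": self.spec.n_input_channels,
                "n_classes": self.spec.n_classes,
                "patch_size": self.spec.patch_size,
            },
            "seed": self.seed,
            "trained": self.trained,
            "dtype": self.dtype.name,
            "training_log": self.training_log,
        }
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ConvNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            spec = NetworkSpec(
                **{**meta["spec"], "conv_filters": tuple(meta["spec"]["conv_filters"])}
            )
            net = cls(spec, seed=meta["seed"], dtype=np.dtype(meta.get("dtype", "float32")))
            for i, lay in enumerate(net.layers):
                if isinstance(lay, Conv):
                    lay.W = data[f"W{i}"]
                    lay.b = data[f"b{i}"]
            net.trained = meta["trained"]
            net.training_log = meta["training_log"]
        return net


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_network(spec: NetworkSpec, seed: int = 0) -> ConvNet:
    """Construct an untrained network with seeded He-initialised weights."""
    return ConvNet(spec, seed=seed)


def train_network(
    net: ConvNet,
    patch_set,
    sgd: SgdConfig | None = None,
    seed: int = 0,
) -> ConvNet:
    """Train by minibatch SGD with momentum on softmax cross-entropy.

    The patch set must contain both classes.  Training is deterministic
    for a fixed seed: shuffling, dropout masks and initial weights are all
    driven by seeded generators.  Per-epoch mean loss and accuracy are
    appended to ``net.training_log``.
    """
    sgd = sgd or SgdConfig()
    x = np.asarray(patch_set.patches, dtype=net.dtype)
    y = np.asarray(patch_set.labels, dtype=np.int64)
    if x.shape[0] == 0:
        raise ValueError("empty patch set")
    if np.unique(y).size < 2:
        raise ValueError("patch set must contain both classes")

    rng = np.random.default_rng(seed)
    n = x.shape[0]
    first_conv = next(lay for lay in net.layers if isinstance(lay, Conv))
    first_conv.input_grad = False
    velocities = {}
    for epoch in range(sgd.n_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, sgd.batch_size):
            idx = order[start : start + sgd.batch_size]
            xb, yb = x[idx], y[idx]
            logits = net._run(xb, train=True, rng=rng)[:, :, 0, 0]
            probs = _softmax(logits)
            eps = 1e-12
            losses.append(float(-np.log(probs[np.arange(len(yb)), yb] + eps).mean()))
            correct += int((probs.argmax(axis=1) == yb).sum())
            dlogit = probs.copy()
            dlogit[np.arange(len(yb)), yb] -= 1.0
            dlogit /= len(yb)
            grad = dlogit[:, :, None, None]
            for lay in reversed(net.layers):
                grad = lay.backward(grad)
            for li, lay in enumerate(net.layers):
                for pi, (p, g) in enumerate(zip(lay.params, lay.grads)):
                    key = (li, pi)
                    v = velocities.get(key)
                    if v is None:
                        v = np.zeros_like(p)
                    v *= sgd.momentum
                    v -= sgd.learning_rate * g
                    p += v
                    velocities[key] = v
        net.training_log.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "accuracy": correct / n,
            }
        )
    first_conv.input_grad = True
    net.trained = True
    return net
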