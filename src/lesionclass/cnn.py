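"""Reference CNN operators, the 16-layer VGG16-style network builder, a
desk-scale NumPy training engine, and embedding extraction.

The network follows the VGG16 recipe: five blocks of 3x3 / stride-1 /
zero-padded convolutions (2, 2, 3, 3, 3 layers; 64, 128, 256, 512, 512
filters), each block closed by a 2x2 / stride-2 max pool; then three fully
connected layers (4096, 4096, K) and a softmax — 16 trainable layers in
total (13 conv + 3 FC), with dropout after FC6 and FC7.  Weight fillers:
conv weights fan-in-scaled uniform ("reference" filler) with constant bias
0.2; FC6/FC7 Gaussian sd 0.005 with bias 1; FC8 Gaussian sd 0.01 with bias
0.

Tensors are (n, c, h, w) float arrays — batch, channels, spatial.  The
reference operators (:func:`conv2d`, :func:`maxpool`, :func:`relu`,
:func:`softmax`, :func:`multinomial_log_loss`) define the exact semantics
the batched training engine must reproduce; tests hold the engine to them.

Training is plain momentum SGD on the multinomial logistic loss with
hand-derived layer gradients, fully seeded.  A ``width_mult`` config scales
channel widths down for desk-scale experiments while keeping the block
structure; the 256x256x3 full recipe stays the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import rescale as _sk_rescale
from skimage.transform import resize as _sk_resize

from .errors import (DegenerateTrainingError, ParameterError, StateError)

# ---------------------------------------------------------------------------
# reference operators
# ---------------------------------------------------------------------------


def conv2d(plane: np.ndarray, kernel: np.ndarray, flip: bool = False
           ) -> np.ndarray:
    """2-D convolution/cross-correlation of a single plane, 'same' output.

    With ``flip=False`` this is the cross-correlation
    ``out(i,j) = sum_{n,m} Bp(i+n, j+m) K(n,m)`` over the zero-padded input
    ``Bp`` (pad ``(kh-1)//2`` before / ``kh//2`` after per axis); with
    ``flip=True`` the kernel is rotated 180 degrees first, giving the
    convolution proper.  The two agree when one rotates the kernel.
    """
    plane = np.asarray(plane, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise ParameterError("empty kernel")
    if kernel.ndim != 2 or plane.ndim != 2:
        raise ParameterError("conv2d expects 2-D plane and kernel")
    kh, kw = kernel.shape
    if flip:
        kernel = kernel[::-1, ::-1]
    padded = np.pad(plane, (((kh - 1) // 2, kh // 2),
                            ((kw - 1) // 2, kw // 2)))
    windows = sliding_window_view(padded, (kh, kw))
    return np.einsum("ijnm,nm->ij", windows, kernel)


def maxpool(x: np.ndarray, kernel: int = 2, stride: int = 2) -> np.ndarray:
    """Non-overlapping max pooling over the trailing two (spatial) axes.

    Odd trailing rows/columns are dropped (floor semantics); with the
    default 2x2 / stride 2, each output plane keeps 25% of the input
    elements.
    """
    x = np.asarray(x, dtype=float)
    if kernel != stride:
        raise ParameterError("only kernel == stride pooling is supported")
    h, w = x.shape[-2], x.shape[-1]
    if h < kernel or w < kernel:
        raise ParameterError("spatial dims smaller than pooling kernel")
    ho, wo = h // kernel, w // kernel
    trimmed = x[..., :ho * kernel, :wo * kernel]
    blocks = trimmed.reshape(*x.shape[:-2], ho, kernel, wo, kernel)
    return blocks.max(axis=(-3, -1))


def relu(x: np.ndarray, leaky_slope: float = 0.0) -> np.ndarray:
    """Rectified linear unit; ``leaky_slope`` a multiplies x where x <= 0."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, leaky_slope * x)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax: outputs are positive and each row sums to one."""
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def multinomial_log_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class.

    ``probs`` is (N, K) with rows on the probability simplex; ``labels``
    are integer class ids in [0, K).  Never negative; zero iff every true
    class receives probability one.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n, k = probs.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ParameterError(f"labels must lie in [0, {k})")
    p = np.clip(probs[np.arange(n), labels], 1e-300, None)
    return float(-np.log(p).mean())


# ---------------------------------------------------------------------------
# declarative network specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | relu | maxpool | fc | dropout | softmax
    kernel: tuple[int, int] | None = None
    stride: int = 1
    zero_padding: int = 0
    out_channels: int | None = None
    weight_filler: str = "reference"  # "reference" | "gaussian"
    filler_sd: float = 0.0  # sd for the gaussian filler
    bias_filler: float = 0.0  # constant bias value
    dropout_p: float = 0.0
    leaky_slope: float = 0.0

    def __post_init__(self):
        if self.kind == "conv":
            if self.kernel != (3, 3) or self.stride != 1 or self.zero_padding != 1:
                raise ParameterError(
                    "conv layers are fixed to 3x3 / stride 1 / zero padding "
                    "that preserves spatial size")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ParameterError("dropout_p must be in [0, 1)")


@dataclass(frozen=True)
class NetworkSpec:
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int]  # (h, w, d)
    num_classes: int

    def count(self, kind: str) -> int:
        return sum(1 for l in self.layers if l.kind == kind)

    @property
    def trainable_layers(self) -> int:
        return self.count("conv") + self.count("fc")


#: VGG16 block plan: (conv layers per block, filters per block)
VGG16_BLOCKS = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))
FC_WIDTH = 4096


def build_lesion_net(input_shape: tuple[int, int, int] = (256, 256, 3),
                     K: int = 2, width_mult: float = 1.0,
                     dropout_p: float = 0.5,
                     filler_profile: str = "gaussian") -> NetworkSpec:
    """Build the 16-layer lesion-classification network specification.

    ``width_mult`` scales conv and hidden FC widths (minimum 1 channel) for
    reduced desk-scale profiles; the block structure, kernel geometry and
    layer counts are invariant.  Spatial dims must be divisible by 32 (five
    pooling halvings).

    ``filler_profile`` selects the initialisation: ``"gaussian"`` (default)
    uses the small-variance Gaussian FC fillers (FC6/FC7: sd 0.005, bias 1;
    FC8: sd 0.01, bias 0) with constant 0.2 conv biases, while
    ``"reference"`` uses the fan-in-scaled uniform filler with zero bias on
    every trainable layer — the profile desk-scale training uses, because
    the near-zero-variance Gaussian FC init cannot break symmetry at
    reduced width and sample budget.
    """
    h, w, d = input_shape
    if h % 32 or w % 32:
        raise ParameterError("input spatial dims must be divisible by 32")
    if K < 2:
        raise ParameterError("need at least two classes")
    if filler_profile not in ("gaussian", "reference"):
        raise ParameterError(f"unknown filler profile {filler_profile!r}")
    gauss = filler_profile == "gaussian"
    scale = lambda c: max(1, int(round(c * width_mult)))
    layers: list[LayerSpec] = []
    for n_conv, filters in VGG16_BLOCKS:
        for _ in range(n_conv):
            layers.append(LayerSpec(kind="conv", kernel=(3, 3), stride=1,
                                    zero_padding=1, out_channels=scale(filters),
                                    weight_filler="reference",
                                    bias_filler=0.2 if gauss else 0.0))
            layers.append(LayerSpec(kind="relu"))
        layers.append(LayerSpec(kind="maxpool", kernel=(2, 2), stride=2))
    fc_width = scale(FC_WIDTH)
    for _ in range(2):  # FC6, FC7
        layers.append(LayerSpec(
            kind="fc", out_channels=fc_width,
            weight_filler="gaussian" if gauss else "reference",
            filler_sd=0.005, bias_filler=1.0 if gauss else 0.0))
        layers.append(LayerSpec(kind="relu"))
        layers.append(LayerSpec(kind="dropout", dropout_p=dropout_p))
    layers.append(LayerSpec(
        kind="fc", out_channels=K,
        weight_filler="gaussian" if gauss else "reference",
        filler_sd=0.01, bias_filler=0.0))
    layers.append(LayerSpec(kind="softmax"))
    return NetworkSpec(layers=tuple(layers), input_shape=input_shape,
                       num_classes=K)


def propagate_shapes(spec: NetworkSpec) -> list[tuple]:
    """Symbolic shape trace: the (c, h, w) / (d,) shape after every layer."""
    h, w, d = spec.input_shape
    shape: tuple = (d, h, w)
    trace = []
    for layer in spec.layers:
        if layer.kind == "conv":
            shape = (layer.out_channels, shape[1], shape[2])
        elif layer.kind == "maxpool":
            shape = (shape[0], shape[1] // 2, shape[2] // 2)
        elif layer.kind == "fc":
            shape = (layer.out_channels,)
        # relu / dropout / softmax preserve shape
        trace.append(shape)
    return trace


# ---------------------------------------------------------------------------
# runtime layers (forward + hand-derived backward)
# ---------------------------------------------------------------------------


class _ConvLayer:
    def __init__(self, spec: LayerSpec, in_channels: int,
                 rng: np.random.Generator):
        co, ci = spec.out_channels, in_channels
        kh, kw = spec.kernel
        fan_in = ci * kh * kw
        if spec.weight_filler == "gaussian":
            self.W = rng.normal(0.0, spec.filler_sd,
                                size=(co, ci, kh, kw)).astype(np.float32)
        else:  # fan-in-scaled uniform reference filler (He limit, ReLU gain)
            lim = np.sqrt(6.0 / fan_in)
            self.W = rng.uniform(-lim, lim,
                                 size=(co, ci, kh, kw)).astype(np.float32)
        self.b = np.full(co, spec.bias_filler, dtype=np.float32)
        self.params = ("W", "b")

    def forward(self, x, train):
        self._x = x if train else None
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))
        y = np.tensordot(win, self.W, axes=([1, 4, 5], [1, 2, 3]))
        return y.transpose(0, 3, 1, 2) + self.b[None, :, None, None]

    def backward(self, dy):
        x = self._x
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))
        # dW[o,c,u,v] = sum_{n,i,j} x_pad[n,c,i+u,j+v] dy[n,o,i,j]
        self.dW = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3])
                               ).astype(np.float32)
        self.db = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dwin = sliding_window_view(dyp, (3, 3), axis=(2, 3))
        Wf = self.W[:, :, ::-1, ::-1]
        dx = np.tensordot(dwin, Wf, axes=([1, 4, 5], [0, 2, 3]))
        return dx.transpose(0, 3, 1, 2).astype(np.float32)


class _ReLULayer:
    params = ()

    def __init__(self, spec: LayerSpec):
        self.slope = spec.leaky_slope

    def forward(self, x, train):
        y = np.where(x > 0, x, self.slope * x)
        if train:
            self._pos = x > 0
        return y

    def backward(self, dy):
        return np.where(self._pos, dy, self.slope * dy)


class _MaxPoolLayer:
    params = ()

    def forward(self, x, train):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        blocks = x[:, :, :2 * ho, :2 * wo].reshape(n, c, ho, 2, wo, 2)
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._in_shape
        ho, wo = h // 2, w // 2
        dflat = np.zeros((n, c, ho, wo, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], dy[..., None],
                          axis=-1)
        dx = np.zeros((n, c, h, w), dtype=dy.dtype)
        dx[:, :, :2 * ho, :2 * wo] = (
            dflat.reshape(n, c, ho, wo, 2, 2)
                 .transpose(0, 1, 2, 4, 3, 5)
                 .reshape(n, c, 2 * ho, 2 * wo))
        return dx


class _FCLayer:
    def __init__(self, spec: LayerSpec, in_dim: int,
                 rng: np.random.Generator):
        out = spec.out_channels
        if spec.weight_filler == "gaussian":
            self.W = rng.normal(0.0, spec.filler_sd,
                                size=(in_dim, out)).astype(np.float32)
        else:
            lim = np.sqrt(6.0 / in_dim)
            self.W = rng.uniform(-lim, lim, size=(in_dim, out)
                                 ).astype(np.float32)
        self.b = np.full(out, spec.bias_filler, dtype=np.float32)
        self.params = ("W", "b")

    def forward(self, x, train):
        self._in_shape = x.shape
        x2 = x.reshape(x.shape[0], -1)
        if train:
            self._x = x2
        return x2 @ self.W + self.b

    def backward(self, dy):
        self.dW = (self._x.T @ dy).astype(np.float32)
        self.db = dy.sum(axis=0).astype(np.float32)
        return (dy @ self.W.T).reshape(self._in_shape).astype(np.float32)


class _DropoutLayer:
    params = ()

    def __init__(self, spec: LayerSpec):
        self.p = spec.dropout_p

    def forward(self, x, train, rng=None):
        if not train or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _SoftmaxLayer:
    params = ()

    def forward(self, x, train):
        return softmax(x)

    def backward(self, dy):  # pragma: no cover - loss bypasses softmax
        raise StateError("softmax backward is fused into the loss")


# ---------------------------------------------------------------------------
# network runtime, training, embedding
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 25
    learning_rate: float = 0.001
    momentum: float = 0.9
    seed: int = 0
    shuffle: bool = True


class Network:
    """Runtime instantiation of a :class:`NetworkSpec` (seeded fillers)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.trained = False
        rng = np.random.default_rng(seed)
        h, w, d = spec.input_shape
        shape: tuple = (d, h, w)
        self.layers = []
        fc_seen = 0
        self.embed_index = None  # layer index whose output is the embedding
        for i, ls in enumerate(spec.layers):
            if ls.kind == "conv":
                self.layers.append(_ConvLayer(ls, shape[0], rng))
                shape = (ls.out_channels, shape[1], shape[2])
            elif ls.kind == "relu":
                self.layers.append(_ReLULayer(ls))
                if fc_seen == 2 and self.embed_index is None:
                    self.embed_index = i  # ReLU after FC7
            elif ls.kind == "maxpool":
                self.layers.append(_MaxPoolLayer())
                shape = (shape[0], shape[1] // 2, shape[2] // 2)
            elif ls.kind == "fc":
                in_dim = int(np.prod(shape))
                self.layers.append(_FCLayer(ls, in_dim, rng))
                shape = (ls.out_channels,)
                fc_seen += 1
            elif ls.kind == "dropout":
                self.layers.append(_DropoutLayer(ls))
            elif ls.kind == "softmax":
                self.layers.append(_SoftmaxLayer())
            else:
                raise ParameterError(f"unknown layer kind {ls.kind!r}")

    # -- forward passes -----------------------------------------------------

    def _forward(self, x, train=False, rng=None, stop_at=None):
        out = np.asarray(x, dtype=np.float32)
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _SoftmaxLayer) and train:
                break  # softmax is fused with the loss during training
            if isinstance(layer, _DropoutLayer):
                out = layer.forward(out, train, rng=rng)
            else:
                out = layer.forward(out, train)
            if stop_at is not None and i == stop_at:
                return out
        return out

    def predict_proba(self, images: np.ndarray, batch_size: int = 50
                      ) -> np.ndarray:
        """Class probabilities for (n, c, h, w) images, inference mode."""
        outs = [self._forward(images[i:i + batch_size])
                for i in range(0, len(images), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def embed(self, images: np.ndarray, batch_size: int = 50) -> np.ndarray:
        """Case-representation embedding: post-ReLU FC7 activations.

        Deterministic (dropout off); requires a trained network.
        """
        if not self.trained:
            raise StateError("network must be trained before embedding")
        outs = [self._forward(images[i:i + batch_size],
                              stop_at=self.embed_index)
                for i in range(0, len(images), batch_size)]
        return np.concatenate(outs, axis=0)

    # -- training -----------------------------------------------------------

    def _loss_and_grads(self, xb, yb, rng):
        logits = self._forward(xb, train=True, rng=rng)
        probs = softmax(logits)
        loss = multinomial_log_loss(probs, yb)
        n = len(yb)
        dlogits = probs.copy()
        dlogits[np.arange(n), yb] -= 1.0
        d = (dlogits / n).astype(np.float32)
        for layer in reversed(self.layers):
            if isinstance(layer, _SoftmaxLayer):
                continue
            d = layer.backward(d)
        return loss

    def fit(self, images: np.ndarray, labels: np.ndarray,
            config: TrainConfig | None = None) -> list[float]:
        """Momentum-SGD minimisation of the multinomial logistic loss.

        Returns the per-epoch mean training loss.  Dropout is active only
        here; everything (shuffling, dropout masks) flows from the config
        seed.
        """
        config = config or TrainConfig()
        images = np.asarray(images, dtype=np.float32)
        labels = np.asarray(labels, dtype=int)
        if len(images) == 0 or len(np.unique(labels)) < 2:
            raise DegenerateTrainingError(
                "training needs a non-empty, two-class dataset")
        rng = np.random.default_rng(config.seed)
        velocity = {}
        for li, layer in enumerate(self.layers):
            for p in layer.params:
                velocity[(li, p)] = np.zeros_like(getattr(layer, p))
        history = []
        idx = np.arange(len(images))
        for _ in range(config.epochs):
            if config.shuffle:
                rng.shuffle(idx)
            losses = []
            for s in range(0, len(idx), config.batch_size):
                batch = idx[s:s + config.batch_size]
                loss = self._loss_and_grads(images[batch], labels[batch], rng)
                losses.append(loss)
                for li, layer in enumerate(self.layers):
                    for p in layer.params:
                        g = getattr(layer, "d" + p)
                        v = velocity[(li, p)]
                        v *= config.momentum
                        v -= config.learning_rate * g
                        getattr(layer, p)[...] += v
            history.append(float(np.mean(losses)))
        self.trained = True
        return history


def train(spec: NetworkSpec, images: np.ndarray, labels: np.ndarray,
          config: TrainConfig | None = None) -> tuple[Network, list[float]]:
    """Build a seeded network from ``spec`` and fit it; returns
    ``(network, loss history)``."""
    config = config or TrainConfig()
    net = Network(spec, seed=config.seed)
    history = net.fit(images, labels, config)
    return net, history


# ---------------------------------------------------------------------------
# HDF5 bundles and data preparation
# ---------------------------------------------------------------------------


def save_bundle(path: str, images: np.ndarray, labels: np.ndarray) -> None:
    """Write an HDF5 training bundle: ``images`` (n, 3, h, w) float in
    [0, 1] and integer ``labels`` (0=benign, 1=malignant)."""
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if images.ndim != 4 or images.shape[0] != labels.shape[0]:
        raise ParameterError("images must be (n, c, h, w) matching labels")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("images", data=images)
        fh.create_dataset("labels", data=labels)


def load_bundle(path: str) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as fh:
        return fh["images"][...], fh["labels"][...]


def images_to_tensor(images: list[np.ndarray],
                     size: tuple[int, int] | None = None) -> np.ndarray:
    """Stack (h, w, 3) float images into an (n, 3, h, w) tensor, rescaling
    to ``size`` when given."""
    planes = []
    for img in images:
        if size is not None and img.shape[:2] != size:
            img = _sk_resize(img, size, anti_aliasing=True)
        planes.append(np.moveaxis(img, -1, 0))
    return np.asarray(planes, dtype=np.float32)


# ---------------------------------------------------------------------------
# label-preserving data augmentation
# ---------------------------------------------------------------------------


def rotate90(image: np.ndarray, k: int = 1) -> np.ndarray:
    """Rotate an (h, w, c) image by k*90 degrees; k=4 is the identity."""
    return np.rot90(image, k=k, axes=(0, 1)).copy()


def flip(image: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mirror along rows (axis=0) or columns (axis=1)."""
    return np.flip(image, axis=axis).copy()


def rescale(image: np.ndarray, factor: float) -> np.ndarray:
    """Spatially rescale, clipping intensities back to [0, 1]."""
    out = _sk_rescale(image, factor, channel_axis=-1, anti_aliasing=True)
    return np.clip(out, 0.0, 1.0)


def crop(image: np.ndarray, top: int, left: int, height: int, width: int
         ) -> np.ndarray:
    if top < 0 or left < 0 or top + height > image.shape[0] \
            or left + width > image.shape[1]:
        raise ParameterError("crop window outside image bounds")
    return image[top:top + height, left:left + width].copy()


def translate(image: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift by (dr, dc) pixels, zero-filling the vacated border."""
    out = np.zeros_like(image)
    h, w = image.shape[:2]
    r0, r1 = max(dr, 0), min(h + dr, h)
    c0, c1 = max(dc, 0), min(w + dc, w)
    out[r0:r1, c0:c1] = image[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out
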