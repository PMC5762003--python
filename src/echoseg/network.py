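"""Self-normalizing encoder-decoder segmentation networks.

Implements the SELU activation, alpha (SELU-)dropout, and a family of
U-Net-style encoder-decoder architectures in pure NumPy with hand-written
forward and backward passes:

``sunet``
    SELU activations only, no normalization layers.
``sunet_dropout``
    As ``sunet`` plus alpha dropout after each activation.
``unet``
    Every SELU replaced by batch normalization + ReLU.
``unet_dc``
    As ``unet``, with the final-block convolutions dilated.

Each block applies two convolutions (kernel 2x2 by default) with a
"same"-style asymmetric padding (extra row/column on the bottom/right).
Downsampling is 2x2 max pooling with stride 2; upsampling is a 2x2
transposed convolution with stride 2, followed by concatenation with the
encoder feature maps of the same size.  The last decoder block carries an
extra convolution + activation.  A 1x1 convolution and a logistic sigmoid
produce a single-channel probability map.

Everything runs on CPU.  Layers are stateful: ``forward`` caches what
``backward`` needs, so a model instance is single-threaded by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SELU_LAMBDA",
    "SELU_ALPHA",
    "selu",
    "alpha_dropout",
    "NetworkSpec",
    "Model",
    "build_model",
    "predict",
    "padded_shape",
    "save_checkpoint",
    "load_checkpoint",
]

#: Fixed scale constant of the scaled exponential linear unit.
SELU_LAMBDA = 1.0507
#: Fixed alpha constant of the scaled exponential linear unit.
SELU_ALPHA = 1.6733
#: Negative saturation value lambda * (-alpha): the infimum of SELU.
SELU_SATURATION = -SELU_LAMBDA * SELU_ALPHA

VARIANTS = ("sunet", "sunet_dropout", "unet", "unet_dc")

#: Float dtype for all parameters/activations; float64 only for gradient checks.
DTYPE = "float32"


def _dt():
    return np.dtype(DTYPE)


def selu(x):
    """Scaled exponential linear unit, elementwise.

    ``lambda * x`` for ``x > 0`` and ``lambda * alpha * (exp(x) - 1)`` for
    ``x <= 0``, with the fixed constants ``lambda = 1.0507`` and
    ``alpha = 1.6733``.  Continuous, strictly increasing, bounded below by
    ``-lambda * alpha``.
    """
    x = np.asarray(x)
    return np.where(
        x > 0,
        SELU_LAMBDA * x,
        SELU_LAMBDA * (SELU_ALPHA * np.exp(np.minimum(x, 0.0)) - SELU_ALPHA),
    )


def _selu_grad(x, y):
    """d selu / dx given input x and output y (avoids recomputing exp)."""
    return np.where(x > 0, SELU_LAMBDA, y - SELU_SATURATION)


def alpha_dropout(t, rate, training=True, seed=None, rng=None):
    """Dropout matched to SELU's self-normalizing fixed point.

    Dropped units are set to the negative saturation value ``-lambda*alpha``
    (not zero), then an affine correction restores the input mean and
    variance for standard-normal inputs.

    Parameters
    ----------
    t : array_like
    rate : float
        Drop probability, in [0, 1).
    training : bool
        When False the input is returned unchanged.
    seed : int, optional
        Seeds a fresh generator; ignored if ``rng`` is given.
    rng : numpy.random.Generator, optional
    """
    t = np.asarray(t)
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if not training or rate == 0.0:
        return t
    if rng is None:
        rng = np.random.default_rng(seed)
    q = 1.0 - rate
    sat = SELU_SATURATION
    # Affine correction from Klambauer et al.: keeps mean 0 / variance 1.
    a = (q + sat * sat * q * rate) ** -0.5
    b = -a * rate * sat
    mask = rng.random(t.shape) >= rate
    return a * np.where(mask, t, sat) + b


def _alpha_dropout_train(t, rate, rng):
    """Training-mode alpha dropout returning (output, mask, scale a)."""
    q = 1.0 - rate
    sat = SELU_SATURATION
    a = (q + sat * sat * q * rate) ** -0.5
    b = -a * rate * sat
    mask = rng.random(t.shape) >= rate
    return a * np.where(mask, t, sat) + b, mask, a


@dataclass
class NetworkSpec:
    """Architecture description.

    ``depth`` counts pooling levels; ``channels`` is constant across all
    blocks and defaults to 64 (128 for the dilated ``unet_dc`` variant).
    ``dilation_rate`` only affects ``unet_dc`` (final-block convolutions).
    ``kernel_size`` defaults to the published 2x2.
    """

    variant: str = "sunet"
    depth: int = 4
    channels: int | None = None
    dropout_rate: float = 0.5
    dilation_rate: int = 2
    kernel_size: int = 2
    in_shape: tuple[int, int] | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.channels is None:
            self.channels = 128 if self.variant == "unet_dc" else 64
        if self.channels < 1:
            raise ValueError("channels must be >= 1")

    @property
    def uses_selu(self) -> bool:
        return self.variant in ("sunet", "sunet_dropout")

    def to_json(self) -> str:
        d = asdict(self)
        if d["in_shape"] is not None:
            d["in_shape"] = list(d["in_shape"])
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        if d.get("in_shape") is not None:
            d["in_shape"] = tuple(d["in_shape"])
        return cls(**d)


def padded_shape(shape, depth):
    """Smallest (H, W) >= shape with both sides multiples of 2**depth."""
    m = 1 << depth
    return tuple(int(np.ceil(s / m)) * m for s in shape)


# ---------------------------------------------------------------------------
# layers (NHWC layout throughout)
# ---------------------------------------------------------------------------


class Conv2d:
    """2-D convolution, "same" output size, asymmetric bottom/right padding."""

    def __init__(self, cin, cout, k=2, dilation=1, init="selu", rng=None, name=""):
        self.k, self.dilation, self.name = k, dilation, name
        fan_in = k * k * cin
        if init == "selu":
            std = 1.0 / np.sqrt(fan_in)  # SNN-recommended init
        else:
            std = np.sqrt(2.0 / fan_in)  # He init for ReLU variants
        self.W = rng.normal(0.0, std, size=(k, k, cin, cout)).astype(_dt())
        self.b = np.zeros(cout, dtype=_dt())
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        eff = dilation * (k - 1)
        self._pad_before = eff // 2
        self._pad_after = eff - self._pad_before

    def params(self):
        return [(self.name + ".W", self.W, self.dW, True), (self.name + ".b", self.b, self.db, False)]

    def forward(self, x):
        pb, pa = self._pad_before, self._pad_after
        xp = np.pad(x, ((0, 0), (pb, pa), (pb, pa), (0, 0)))
        self._xp, self._xshape = xp, x.shape
        N, H, W, _ = x.shape
        d = self.dilation
        out = np.empty((N, H, W, self.W.shape[3]), dtype=_dt())
        out[:] = self.b
        for di in range(self.k):
            for dj in range(self.k):
                out += xp[:, di * d : di * d + H, dj * d : dj * d + W, :] @ self.W[di, dj]
        return out

    def backward(self, dout):
        N, H, W, _ = self._xshape
        d = self.dilation
        xp = self._xp
        dxp = np.zeros_like(xp)
        self.db[:] = dout.sum(axis=(0, 1, 2))
        dflat = dout.reshape(-1, dout.shape[-1])
        for di in range(self.k):
            for dj in range(self.k):
                sl = np.s_[:, di * d : di * d + H, dj * d : dj * d + W, :]
                self.dW[di, dj] = xp[sl].reshape(-1, xp.shape[-1]).T @ dflat
                dxp[sl] += dout @ self.W[di, dj].T
        pb = self._pad_before
        self._xp = None
        return dxp[:, pb : pb + H, pb : pb + W, :]


class ConvTranspose2d:
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, cin, cout, init="selu", rng=None, name=""):
        self.name = name
        fan_in = cin  # each output pixel sees exactly one input pixel
        std = 1.0 / np.sqrt(fan_in) if init == "selu" else np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(2, 2, cin, cout)).astype(_dt())
        self.b = np.zeros(cout, dtype=_dt())
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.name + ".W", self.W, self.dW, True), (self.name + ".b", self.b, self.db, False)]

    def forward(self, x):
        self._x = x
        N, H, W, _ = x.shape
        out = np.empty((N, 2 * H, 2 * W, self.W.shape[3]), dtype=_dt())
        for di in range(2):
            for dj in range(2):
                out[:, di::2, dj::2, :] = x @ self.W[di, dj]
        out += self.b
        return out

    def backward(self, dout):
        x = self._x
        xflat = x.reshape(-1, x.shape[-1])
        dx = np.zeros_like(x)
        self.db[:] = dout.sum(axis=(0, 1, 2))
        for di in range(2):
            for dj in range(2):
                sl = dout[:, di::2, dj::2, :]
                self.dW[di, dj] = xflat.T @ sl.reshape(-1, sl.shape[-1])
                dx += sl @ self.W[di, dj].T
        self._x = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2; input sides must be even."""

    def forward(self, x):
        N, H, W, C = x.shape
        xr = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, C, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        N, H, W, C = self._shape
        dxr = np.zeros((N, H // 2, W // 2, C, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        return dxr.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(N, H, W, C)


class SELUAct:
    def forward(self, x, training):
        y = np.where(
            x > 0, SELU_LAMBDA * x, SELU_LAMBDA * SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0)
        ).astype(_dt())
        self._x, self._y = x, y
        return y

    def backward(self, dout):
        dx = dout * _selu_grad(self._x, self._y)
        self._x = self._y = None
        return dx

    def params(self):
        return []


class ReLUAct:
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class BatchNorm:
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c, momentum=0.9, eps=1e-5, name=""):
        self.gamma = np.ones(c, dtype=_dt())
        self.beta = np.zeros(c, dtype=_dt())
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=_dt())
        self.running_var = np.ones(c, dtype=_dt())
        self.momentum, self.eps, self.name = momentum, eps, name

    def params(self):
        return [
            (self.name + ".gamma", self.gamma, self.dgamma, False),
            (self.name + ".beta", self.beta, self.dbeta, False),
        ]

    def state(self):
        return [(self.name + ".running_mean", self.running_mean), (self.name + ".running_var", self.running_var)]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean[:] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[:] = self.momentum * self.running_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[1] * x.shape[2]
            return self.gamma * xhat + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * (x - self.running_mean) * inv + self.beta

    def backward(self, dout):
        xhat, inv, m = self._xhat, self._inv, self._m
        self.dgamma[:] = (dout * xhat).sum(axis=(0, 1, 2))
        self.dbeta[:] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma
        dx = (inv / m) * (
            m * dxhat - dxhat.sum(axis=(0, 1, 2)) - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
        )
        self._xhat = None
        return dx.astype(_dt())


class AlphaDropoutLayer:
    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._a = None
            return x
        out, mask, a = _alpha_dropout_train(x, self.rate, rng)
        self._mask, self._a = mask, a
        return out.astype(_dt())

    def backward(self, dout):
        if self._a is None:
            return dout
        return dout * (self._a * self._mask)

    def params(self):
        return []


class _Unit:
    """conv -> [batchnorm] -> activation -> [alpha dropout]."""

    def __init__(self, cin, cout, spec: NetworkSpec, rng, name, dilation=1):
        init = "selu" if spec.uses_selu else "relu"
        self.conv = Conv2d(cin, cout, k=spec.kernel_size, dilation=dilation, init=init, rng=rng, name=name + ".conv")
        self.bn = None if spec.uses_selu else BatchNorm(cout, name=name + ".bn")
        self.act = SELUAct() if spec.uses_selu else ReLUAct()
        self.drop = AlphaDropoutLayer(spec.dropout_rate) if spec.variant == "sunet_dropout" else None

    def forward(self, x, training, rng):
        h = self.conv.forward(x)
        if self.bn is not None:
            h = self.bn.forward(h, training)
        h = self.act.forward(h, training)
        if self.drop is not None:
            h = self.drop.forward(h, training, rng)
        return h

    def backward(self, dout):
        if self.drop is not None:
            dout = self.drop.backward(dout)
        dout = self.act.backward(dout)
        if self.bn is not None:
            dout = self.bn.backward(dout)
        return self.conv.backward(dout)

    def params(self):
        p = self.conv.params()
        if self.bn is not None:
            p += self.bn.params()
        return p


class Model:
    """Encoder-decoder segmentation model (acts as the ModelParameters store).

    ``forward`` pads the input to a multiple of ``2**depth``, runs the
    network and crops the probability map back to the input frame.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(seed + 101)
        c, d = spec.channels, spec.depth
        init = "selu" if spec.uses_selu else "relu"

        self.enc_blocks = []
        cin = 1
        for lev in range(d):
            blk = [
                _Unit(cin, c, spec, rng, f"enc{lev}.0"),
                _Unit(c, c, spec, rng, f"enc{lev}.1"),
            ]
            self.enc_blocks.append(blk)
            cin = c
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottom = [_Unit(cin, c, spec, rng, "bottom.0"), _Unit(c, c, spec, rng, "bottom.1")]

        self.upconvs = []
        self.dec_blocks = []
        for lev in reversed(range(d)):
            self.upconvs.append(ConvTranspose2d(c, c, init=init, rng=rng, name=f"up{lev}"))
            dil = spec.dilation_rate if (spec.variant == "unet_dc" and lev == 0) else 1
            blk = [
                _Unit(2 * c, c, spec, rng, f"dec{lev}.0", dilation=dil),
                _Unit(c, c, spec, rng, f"dec{lev}.1", dilation=dil),
            ]
            if lev == 0:  # last block carries an extra convolution + activation
                blk.append(_Unit(c, c, spec, rng, f"dec{lev}.2", dilation=dil))
            self.dec_blocks.append(blk)

        self.head = Conv2d(c, 1, k=1, init=init, rng=rng, name="head")

    # -- parameter access ---------------------------------------------------

    def params(self):
        """List of (name, array, grad, is_kernel) for every learnable array."""
        out = []
        for blk in self.enc_blocks:
            for u in blk:
                out += u.params()
        for u in self.bottom:
            out += u.params()
        for up, blk in zip(self.upconvs, self.dec_blocks):
            out += up.params()
            for u in blk:
                out += u.params()
        out += self.head.params()
        return out

    def state_arrays(self):
        """Non-learnable state (batch-norm running statistics)."""
        out = []
        for blk in self.enc_blocks + [self.bottom] + self.dec_blocks:
            for u in blk:
                if u.bn is not None:
                    out += u.bn.state()
        return out

    def n_normalization_params(self):
        return sum(p[1].size for p in self.params() if ".bn." in p[0]) + sum(
            a.size for _, a in self.state_arrays()
        )

    def l2_penalty(self):
        """Sum of squared convolution-kernel weights (biases/BN excluded)."""
        return float(sum(np.sum(arr.astype(np.float64) ** 2) for _, arr, _, k in self.params() if k))

    # -- forward / backward -------------------------------------------------

    def forward(self, images, training=False, capture_last_selu=False):
        """images: (N, H, W) float array -> probabilities (N, H, W) in [0,1]."""
        images = np.asarray(images, dtype=_dt())
        if images.ndim != 3:
            raise ValueError(f"expected batch of 2-D images, got shape {images.shape}")
        N, H, W = images.shape
        m = 1 << self.spec.depth
        if H < m or W < m:
            raise ValueError(f"input shape {(H, W)} smaller than 2^depth = {m}")
        PH, PW = padded_shape((H, W), self.spec.depth)
        x = np.zeros((N, PH, PW, 1), dtype=_dt())
        x[:, :H, :W, 0] = images
        self._in_shape = (N, H, W, PH, PW)

        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for u in blk:
                x = u.forward(x, training, self._drop_rng)
            skips.append(x)
            x = pool.forward(x)
        for u in self.bottom:
            x = u.forward(x, training, self._drop_rng)
        self._skip_ch = skips[0].shape[-1]
        for up, blk, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=-1)
            for u in blk:
                x = u.forward(x, training, self._drop_rng)
        self.last_activation = x if capture_last_selu else None
        z = np.clip(self.head.forward(x)[..., 0], -60.0, 60.0)
        p = 1.0 / (1.0 + np.exp(-z))
        self._p = p
        return p[:, :H, :W].astype(_dt())

    def backward(self, dprobs):
        """dprobs: gradient wrt the cropped probability map (N, H, W)."""
        N, H, W, PH, PW = self._in_shape
        p = self._p
        dp = np.zeros((N, PH, PW), dtype=_dt())
        dp[:, :H, :W] = dprobs
        dz = (dp * p * (1.0 - p))[..., None].astype(_dt())
        dx = self.head.backward(dz)
        skip_grads = []  # collected shallowest level first
        for up, blk in zip(reversed(self.upconvs), reversed(self.dec_blocks)):
            for u in reversed(blk):
                dx = u.backward(dx)
            dskip, dx = dx[..., : self._skip_ch], dx[..., self._skip_ch :]
            dx = up.backward(dx)
            skip_grads.append(dskip)
        for u in reversed(self.bottom):
            dx = u.backward(dx)
        for blk, pool, dskip in zip(reversed(self.enc_blocks), reversed(self.pools), reversed(skip_grads)):
            dx = pool.backward(dx) + dskip
            for u in reversed(blk):
                dx = u.backward(dx)
        return dx


def build_model(spec: NetworkSpec, seed: int = 0) -> Model:
    """Construct a model with seeded parameter initialization.

    SELU variants use normal(0, 1/fan_in) initialization and contain no
    normalization parameters; ReLU variants use He initialization with
    batch normalization after every convolution.
    """
    if spec.in_shape is not None:
        m = 1 << spec.depth
        if min(spec.in_shape) < m:
            raise ValueError(f"in_shape {spec.in_shape} smaller than 2^depth = {m}")
    return Model(spec, seed)


def predict(model: Model, images, spacing=None):
    """Inference-mode forward pass.

    Returns per-pixel foreground probabilities with the same (N, H, W)
    shape as the input batch; dropout is off and batch normalization uses
    running statistics, so the output is batch-composition independent for
    SELU variants and deterministic for all variants.
    """
    images = np.asarray(images, dtype=_dt())
    squeeze = images.ndim == 2
    if squeeze:
        images = images[None]
    if model.spec.in_shape is not None and tuple(images.shape[1:]) != tuple(model.spec.in_shape):
        raise ValueError(
            f"input shape {tuple(images.shape[1:])} does not match spec in_shape "
            f"{tuple(model.spec.in_shape)}"
        )
    probs = model.forward(images, training=False)
    return probs[0] if squeeze else probs


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: Model, path):
    """Single-archive checkpoint: parameter arrays keyed by block name plus
    the NetworkSpec as JSON."""
    arrays = {name: arr for name, arr, _, _ in model.params()}
    arrays.update({name: arr for name, arr in model.state_arrays()})
    arrays["__spec__"] = np.frombuffer(model.spec.to_json().encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Model:
    with np.load(path) as data:
        spec = NetworkSpec.from_json(bytes(data["__spec__"].tobytes()).decode())
        model = Model(spec, seed=0)
        for name, arr, _, _ in model.params():
            arr[:] = data[name]
        for name, arr in model.state_arrays():
            arr[:] = data[name]
    return model
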