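"""The SMAFNet architecture.

SMAFNet (spectral multi-scale attention fusion network) classifies a raw NIR
absorbance vector as pure vs adulterated through four stages:

1. **SPM** (spectral preprocessing module): one valid 1-D convolution
   (default kernel 16, 64 channels, so an L-point spectrum becomes
   L - 15 positions) followed by max-pooling — a learned noise-suppressing
   front end that replaces classical preprocessing.
2. **MSFEM** (multi-scale feature extraction module): n parallel branches
   (default kernels [1, 5, 9]), each a stack of d feature extraction blocks
   (FEB = same-padded convolution -> ReLU -> squeeze-and-excitation channel
   attention -> max-pool).  Same padding keeps every branch length-aligned,
   so maps from different receptive fields can later be fused element-wise.
3. **CSAFM** (cross-scale attention fusion module): for every reference scale
   r, each partner scale j is concatenated with it channel-wise, pushed
   through a two-convolution sigmoid gate to produce attention weights
   a_j in (0,1), and the recalibrated partners a_j * X_j are summed onto X_r:
   F_r = X_r + sum_{j != r} a_j * X_j.  Each ordered pair (r, j) owns its own
   gate parameters.
4. **Head**: all F_r flattened and concatenated, one hidden dense layer with
   ReLU, then a single sigmoid unit giving P(adulterated).

The forward pass works on any batch shaped (B, 1, L); ``backward`` consumes
the gradient of the loss with respect to the pre-sigmoid logit, which keeps
binary cross-entropy numerically exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import Conv1d, Dense, MaxPool1d, ReLU, Sigmoid, SqueezeExcite, sigmoid

__all__ = [
    "SPMConfig",
    "MSFEMConfig",
    "CSAFMConfig",
    "SMAFNetConfig",
    "SMAFNet",
    "init_model",
    "save_checkpoint",
    "load_checkpoint",
]

_ALLOWED_KERNELS = (1, 3, 5, 7, 9, 11)


@dataclass(frozen=True)
class SPMConfig:
    kernel_size: int = 16
    out_channels: int = 64
    pool_size: int = 2
    pool_stride: int = 2

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.out_channels < 1:
            raise ValueError("kernel size and channel count must be >= 1")


@dataclass(frozen=True)
class MSFEMConfig:
    kernel_sizes: tuple[int, ...] = (1, 5, 9)
    depth: int = 2
    channels: int = 64
    se_reduction: int = 8
    pool_size: int = 2
    pool_stride: int = 2

    def __post_init__(self) -> None:
        if not 1 <= len(self.kernel_sizes) <= 3:
            raise ValueError("between 1 and 3 parallel scales are supported")
        bad = set(self.kernel_sizes) - set(_ALLOWED_KERNELS)
        if bad:
            raise ValueError(f"kernel sizes must be odd and <= 11, got {sorted(bad)}")
        if not 1 <= self.depth <= 3:
            raise ValueError("depth must be 1, 2 or 3")
        if self.channels % self.se_reduction != 0:
            raise ValueError("channels must be divisible by se_reduction")


@dataclass(frozen=True)
class CSAFMConfig:
    hidden_channels: int | None = None  # None -> same as MSFEM channels
    kernel_size: int = 1

    def __post_init__(self) -> None:
        if self.hidden_channels is not None and self.hidden_channels < 1:
            raise ValueError("hidden_channels must be >= 1")


@dataclass(frozen=True)
class SMAFNetConfig:
    input_length: int = 267
    spm: SPMConfig = field(default_factory=SPMConfig)
    msfem: MSFEMConfig = field(default_factory=MSFEMConfig)
    csafm: CSAFMConfig = field(default_factory=CSAFMConfig)
    head_hidden: int = 128

    def fused_length(self) -> int:
        """Temporal length of each fused map after SPM and d FEB poolings."""
        t = self.input_length - self.spm.kernel_size + 1
        t = (t - self.spm.pool_size) // self.spm.pool_stride + 1
        for _ in range(self.msfem.depth):
            t = (t - self.msfem.pool_size) // self.msfem.pool_stride + 1
        if t < 1:
            raise ValueError("input too short for this architecture")
        return t

    def flat_features(self) -> int:
        n = len(self.msfem.kernel_sizes)
        return n * self.msfem.channels * self.fused_length()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SMAFNetConfig":
        d = dict(d)
        spm = SPMConfig(**d.pop("spm", {}))
        ms = d.pop("msfem", {})
        if "kernel_sizes" in ms:
            ms["kernel_sizes"] = tuple(ms["kernel_sizes"])
        msfem = MSFEMConfig(**ms)
        csafm = CSAFMConfig(**d.pop("csafm", {}))
        return cls(spm=spm, msfem=msfem, csafm=csafm, **d)


class _FEB:
    """Feature extraction block: same-pad conv -> ReLU -> SE -> max-pool."""

    def __init__(self, in_ch: int, cfg: MSFEMConfig, kernel: int, rng: np.random.Generator):
        self.conv = Conv1d(in_ch, cfg.channels, kernel, padding="same", rng=rng)
        self.relu = ReLU()
        self.se = SqueezeExcite(cfg.channels, cfg.se_reduction, rng=rng)
        self.pool = MaxPool1d(cfg.pool_size, cfg.pool_stride)
        self._stages = (self.conv, self.relu, self.se, self.pool)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for stage in self._stages:
            x = stage.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for stage in reversed(self._stages):
            g = stage.backward(g)
        return g

    def layers(self):
        return {"conv": self.conv, "se": self.se}


class _FusionGate:
    """CSAFM attention gate for one ordered (reference, partner) pair."""

    def __init__(self, channels: int, cfg: CSAFMConfig, rng: np.random.Generator):
        hidden = cfg.hidden_channels or channels
        self.conv1 = Conv1d(2 * channels, hidden, cfg.kernel_size, padding="same", rng=rng)
        self.relu = ReLU()
        self.conv2 = Conv1d(hidden, channels, cfg.kernel_size, padding="same", rng=rng)
        self.sig = Sigmoid()
        self.channels = channels

    def attention(self, x_ref: np.ndarray, x_j: np.ndarray) -> np.ndarray:
        z = np.concatenate([x_ref, x_j], axis=1)
        return self.sig.forward(self.conv2.forward(self.relu.forward(self.conv1.forward(z))))

    def forward(self, x_ref: np.ndarray, x_j: np.ndarray) -> np.ndarray:
        self._xj = x_j
        self._a = self.attention(x_ref, x_j)
        return self._a * x_j

    def backward(self, g_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradient w.r.t. (x_ref, x_j) given the gradient of a_j * x_j."""
        ga = g_out * self._xj
        gz = self.conv1.backward(self.relu.backward(self.conv2.backward(self.sig.backward(ga))))
        c = self.channels
        g_ref = gz[:, :c]
        g_j = gz[:, c:] + g_out * self._a
        return g_ref, g_j


class SMAFNet:
    """A fully built network: configuration plus all learnable arrays.

    Construct through :func:`init_model` for seeded, reproducible weights.
    """

    def __init__(self, config: SMAFNetConfig, rng: np.random.Generator, seed: int | None = None):
        self.config = config
        self.seed = seed
        cfg = config
        self.spm_conv = Conv1d(
            1, cfg.spm.out_channels, cfg.spm.kernel_size, padding="valid", rng=rng
        )
        # The preprocessing convolution starts as zero-sum (difference) filters:
        # absorbance spectra carry a large common offset that dwarfs the trace
        # adulteration signal, and a front end that is blind to that offset at
        # initialization is what lets gradient descent find the signal at all.
        # Training is free to move the taps away from zero-sum.
        self.spm_conv.W -= self.spm_conv.W.mean(axis=2, keepdims=True)
        self.spm_pool = MaxPool1d(cfg.spm.pool_size, cfg.spm.pool_stride)
        self.branches = [
            [
                _FEB(
                    cfg.spm.out_channels if d == 0 else cfg.msfem.channels,
                    cfg.msfem,
                    k,
                    rng,
                )
                for d in range(cfg.msfem.depth)
            ]
            for k in cfg.msfem.kernel_sizes
        ]
        n = len(cfg.msfem.kernel_sizes)
        self.gates = {
            (r, j): _FusionGate(cfg.msfem.channels, cfg.csafm, rng)
            for r in range(n)
            for j in range(n)
            if j != r
        }
        flat = cfg.flat_features()
        self.fc1 = Dense(flat, cfg.head_hidden, rng=rng)
        self.head_relu = ReLU()
        self.fc2 = Dense(cfg.head_hidden, 1, rng=rng)

    # ---- parameter bookkeeping -------------------------------------------

    def _named_layers(self):
        yield "spm.conv", self.spm_conv
        for b, branch in enumerate(self.branches):
            for d, feb in enumerate(branch):
                for name, layer in feb.layers().items():
                    yield f"msfem.b{b}.d{d}.{name}", layer
        for (r, j), gate in sorted(self.gates.items()):
            yield f"csafm.r{r}j{j}.conv1", gate.conv1
            yield f"csafm.r{r}j{j}.conv2", gate.conv2
        yield "head.fc1", self.fc1
        yield "head.fc2", self.fc2

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{path}.{k}": v
            for path, layer in self._named_layers()
            for k, v in layer.parameters().items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{path}.{k}": v
            for path, layer in self._named_layers()
            for k, v in layer.gradients().items()
        }

    def zero_grad(self) -> None:
        for g in self.gradients().values():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())

    # ---- forward / backward ----------------------------------------------

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Pre-sigmoid logits for a batch shaped (B, 1, L) or (B, L)."""
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected spectra of length {self.config.input_length}, got {x.shape[2]}"
            )
        s0 = self.spm_pool.forward(self.spm_conv.forward(x))
        feats = []
        for branch in self.branches:
            h = s0
            for feb in branch:
                h = feb.forward(h)
            feats.append(h)
        self._feats = feats
        fused = []
        for r in range(len(feats)):
            f_r = feats[r].copy()
            for j in range(len(feats)):
                if j != r:
                    f_r += self.gates[(r, j)].forward(feats[r], feats[j])
            fused.append(f_r)
        self._batch = x.shape[0]
        flat = np.concatenate([f.reshape(self._batch, -1) for f in fused], axis=1)
        h = self.head_relu.forward(self.fc1.forward(flat))
        return self.fc2.forward(h)[:, 0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """P(adulterated) for each spectrum in the batch; values in (0, 1)."""
        return sigmoid(self.forward_logits(x))

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Hard class labels (1 = adulterated) at the given threshold."""
        return (self.forward(x) >= threshold).astype(np.int64)

    def backward(self, grad_logits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logit); accumulates parameter gradients."""
        g = self.fc2.backward(grad_logits[:, None])
        g_flat = self.fc1.backward(self.head_relu.backward(g))
        n = len(self.branches)
        c = self.config.msfem.channels
        t = self._feats[0].shape[2]
        per = c * t
        g_feats = [np.zeros_like(f) for f in self._feats]
        for r in range(n):
            g_fr = g_flat[:, r * per : (r + 1) * per].reshape(self._batch, c, t)
            g_feats[r] += g_fr  # identity path of Eq (4)
            for j in range(n):
                if j != r:
                    g_ref, g_j = self.gates[(r, j)].backward(g_fr)
                    g_feats[r] += g_ref
                    g_feats[j] += g_j
        g_s0 = None
        for branch, g_b in zip(self.branches, g_feats):
            for feb in reversed(branch):
                g_b = feb.backward(g_b)
            g_s0 = g_b if g_s0 is None else g_s0 + g_b
        self.spm_conv.backward(self.spm_pool.backward(g_s0))


def init_model(config: SMAFNetConfig, seed: int = 0) -> SMAFNet:
    """Deterministically initialize a SMAFNet from a seed."""
    rng = np.random.default_rng(seed)
    return SMAFNet(config, rng, seed=seed)


def save_checkpoint(model: SMAFNet, path: str | Path) -> None:
    """Serialize config + weights + init seed into one ``.npz`` file."""
    meta = json.dumps({"config": model.config.to_dict(), "seed": model.seed}, sort_keys=True)
    np.savez(path, __meta__=np.array(meta), **model.parameters())


def load_checkpoint(path: str | Path) -> SMAFNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        model = init_model(SMAFNetConfig.from_dict(meta["config"]), seed=meta["seed"] or 0)
        params = model.parameters()
        for name, arr in params.items():
            arr[...] = data[name]
    return model
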