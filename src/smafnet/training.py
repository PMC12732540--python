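"""Training loop (binary cross-entropy + Adam) and the architecture sweep.

Optimization follows the study protocol: Adam with initial learning rate
0.001, beta1 = 0.9, beta2 = 0.999, epsilon = 1e-8, minimizing binary
cross-entropy on the single-logit sigmoid output.  Epoch count and batch size
are free configuration values (defaults 200 and 16, sized for a ~109-sample
calibration set); there is no learning-rate schedule.  Runs are bit-
reproducible at a fixed seed: the seed fixes both weight initialization and
the per-epoch shuffle stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import compute_metrics, confusion_matrix
from .model import SMAFNet, SMAFNetConfig, init_model
from .nn import sigmoid
from .spectra import SpectraSet

__all__ = ["TrainConfig", "TrainHistory", "Adam", "train_model", "sweep_configs"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epsilon) <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning rate, epsilon, epochs and batch size must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


class Adam:
    """Adaptive moment estimation over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bias1 = 1.0 - c.beta1**self.t
        bias2 = 1.0 - c.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = c.beta1 * self.m[k] + (1.0 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1.0 - c.beta2) * g * g
            m_hat = self.m[k] / bias1
            v_hat = self.v[k] / bias2
            p -= c.learning_rate * m_hat / (np.sqrt(v_hat) + c.epsilon)


def bce_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits).

    Working on logits keeps log(sigmoid) exact:
    loss_i = softplus(z_i) - y_i * z_i, gradient (sigmoid(z_i) - y_i) / B.
    """
    z = logits
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad


def train_model(
    cfg: SMAFNetConfig,
    tcfg: TrainConfig,
    train: SpectraSet,
    val: SpectraSet | None = None,
) -> tuple[SMAFNet, TrainHistory]:
    """Train a freshly initialized SMAFNet on a calibration set.

    Returns the trained model and the per-epoch history (training loss, and
    validation ACC/F1 when a validation set is supplied).
    """
    y = train.labels.astype(float)
    if len(set(train.labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    if train.n_wavelengths != cfg.input_length:
        raise ValueError(
            f"config expects L={cfg.input_length}, data has L={train.n_wavelengths}"
        )

    model = init_model(cfg, seed=tcfg.seed)
    opt = Adam(model.parameters(), tcfg)
    rng = np.random.default_rng(tcfg.seed)
    x = train.absorbance
    n = x.shape[0]
    history = TrainHistory()

    for _ in range(tcfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            model.zero_grad()
            logits = model.forward_logits(x[idx])
            loss, grad = bce_loss(logits, y[idx])
            model.backward(grad)
            opt.step(model.gradients())
            epoch_loss += loss * idx.size
        history.train_loss.append(epoch_loss / n)
        if val is not None:
            cm = confusion_matrix(val.labels, model.predict(val.absorbance))
            rep = compute_metrics(cm)
            history.val_acc.append(rep.acc)
            history.val_f1.append(rep.f1 if rep.f1 is not None else float("nan"))
    return model, history


def sweep_configs(
    grid: list[SMAFNetConfig],
    tcfg: TrainConfig,
    train: SpectraSet,
    val: SpectraSet,
) -> pd.DataFrame:
    """Train every architecture in ``grid`` with one common seed and rank them.

    Mirrors the study's module-selection procedure (kernel set, scale count,
    depth): each candidate trains from the same seeded initialization stream
    and is scored by validation ACC then F1, descending.
    """
    if not grid:
        raise ValueError("empty configuration grid")
    rows = []
    for cfg in grid:
        model, _ = train_model(cfg, tcfg, train, val)
        cm = confusion_matrix(val.labels, model.predict(val.absorbance))
        rep = compute_metrics(cm).rounded()
        rows.append(
            {
                "kernel_sizes": tuple(cfg.msfem.kernel_sizes),
                "n_scales": len(cfg.msfem.kernel_sizes),
                "depth": cfg.msfem.depth,
                "acc": rep.acc,
                "f1": rep.f1,
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(["acc", "f1"], ascending=False, kind="stable").reset_index(
        drop=True
    )


def config_grid(
    kernel_sets: list[tuple[int, ...]],
    depths: list[int],
    base: SMAFNetConfig | None = None,
) -> list[SMAFNetConfig]:
    """Expand kernel sets x depths into full configs around a base config."""
    base = base or SMAFNetConfig()
    return [
        replace(base, msfem=replace(base.msfem, kernel_sizes=tuple(ks), depth=d))
        for ks in kernel_sets
        for d in depths
    ]
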