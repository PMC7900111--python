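"""A compact 2D fully-convolutional segmentation network with dilated convolutions.

The model maps an S·k-channel 2.5D slab to a per-pixel probability map for
the slab's center slice.  Architecturally it is a small encoder of
same-resolution 3×3 convolutions followed by a dilated-convolution pyramid
head (parallel 3×3 branches at several atrous rates, concatenated), giving
a large receptive field without downsampling, and a 1×1 logit head with a
sigmoid output.  Depth/width scale through :class:`NetworkConfig`.

Forward and backward passes are written directly on numpy (im2col /
col2im + GEMM) so training is deterministic, dependency-light and fast
enough on a single CPU at desk scale; the optimizer is Adam.  Training
draws a fresh availability pattern per sample via the input-level dropout
policy and applies zero-fill + 1/(1-p) reweighting before the forward
pass, exactly as at inference.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ild import DropoutPolicy, apply_input_dropout, sample_pattern
from .volumes import MultisequenceStudy, extract_slab, normalize_study

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "SegmentationModel",
    "build_network",
    "train",
]

_DTYPE = np.float32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    in_channels must equal S·k of the slabs the model will see
    (4 sequences × 5 slices = 20 by default).
    """

    in_channels: int = 20
    base_width: int = 16
    n_stages: int = 1
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.base_width < 1 or self.n_stages < 0:
            raise ValueError("in_channels, base_width >= 1 and n_stages >= 0 required")
        if not self.dilation_rates or any(d < 1 for d in self.dilation_rates):
            raise ValueError("dilation_rates must be nonempty, all >= 1")
        object.__setattr__(self, "dilation_rates", tuple(int(d) for d in self.dilation_rates))


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    loss_name is one of ``"bce"``, ``"dice"``, ``"bce_dice"`` (weighted
    cross-entropy plus soft Dice, the default: pure cross-entropy is
    degenerate for small lesions).  foreground_weight multiplies the
    positive-class cross-entropy term.
    """

    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 3e-3
    loss_name: str = "bce_dice"
    foreground_weight: float = 4.0
    dropout_policy: DropoutPolicy = field(default_factory=DropoutPolicy)
    validation_fraction: float = 0.1
    slab_half_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.foreground_weight <= 0:
            raise ValueError("foreground_weight must be > 0")
        if self.loss_name not in ("bce", "dice", "bce_dice"):
            raise ValueError(f"unknown loss {self.loss_name!r}")


# ---------------------------------------------------------------------------
# Layers


class _Conv2d:
    """Same-padding 2D convolution with dilation, im2col + GEMM."""

    def __init__(self, cin: int, cout: int, ksize: int, dilation: int,
                 rng: np.random.Generator):
        fan_in = cin * ksize * ksize
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(cout, cin, ksize, ksize)).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.ksize = ksize
        self.dilation = dilation
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @property
    def pad(self) -> int:
        return self.dilation * (self.ksize - 1) // 2

    def _offsets(self) -> list[tuple[int, int]]:
        taps = [i * self.dilation for i in range(self.ksize)]
        return [(di, dj) for di in taps for dj in taps]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, cin, H, W = x.shape
        self._shape = x.shape
        if self.ksize == 1:
            cols = x.reshape(B, cin, H * W)
        else:
            p = self.pad
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            views = [xp[:, :, di:di + H, dj:dj + W] for di, dj in self._offsets()]
            cols = np.stack(views, axis=2).reshape(B, cin * self.ksize**2, H * W)
        self._cols = cols
        w2 = self.w.reshape(self.w.shape[0], -1)
        out = np.matmul(w2, cols) + self.b[:, None]
        return out.reshape(B, -1, H, W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, cin, H, W = self._shape
        cout = self.w.shape[0]
        dout2 = dout.reshape(B, cout, H * W)
        cols = self._cols
        self.dw += np.matmul(dout2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.w.shape)
        self.db += dout2.sum(axis=(0, 2))
        w2 = self.w.reshape(cout, -1)
        dcols = np.matmul(w2.T, dout2)  # (B, cin*k^2, H*W)
        if self.ksize == 1:
            return dcols.reshape(B, cin, H, W)
        p = self.pad
        dcols = dcols.reshape(B, cin, self.ksize**2, H, W)
        gxp = np.zeros((B, cin, H + 2 * p, W + 2 * p), dtype=_DTYPE)
        for t, (di, dj) in enumerate(self._offsets()):
            gxp[:, :, di:di + H, dj:dj + W] += dcols[:, :, t]
        return gxp[:, :, p:p + H, p:p + W] if p else gxp

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


# ---------------------------------------------------------------------------
# Model


class SegmentationModel:
    """Slab -> center-slice probability map; see module docstring."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.base_width
        self.stem = _Conv2d(config.in_channels, w, 3, 1, rng)
        self.stem_act = _ReLU()
        self.stages = [_Conv2d(w, w, 3, 1, rng) for _ in range(config.n_stages)]
        self.stage_acts = [_ReLU() for _ in range(config.n_stages)]
        self.branches = [_Conv2d(w, w, 3, d, rng) for d in config.dilation_rates]
        self.pyramid_act = _ReLU()
        self.head = _Conv2d(w * len(config.dilation_rates), 1, 1, 1, rng)

    # -- plumbing

    def _layers(self):
        return [self.stem, *self.stages, *self.branches, self.head]

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for p, g in self.params():
            g[...] = 0

    @property
    def model_id(self) -> str:
        c = self.config
        return f"segnet-c{c.in_channels}-w{c.base_width}-s{c.seed}"

    # -- forward / backward

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """x: (B, in_channels, H, W) -> logits (B, 1, H, W)."""
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        h = self.stem_act.forward(self.stem.forward(x))
        for conv, act in zip(self.stages, self.stage_acts):
            h = act.forward(conv.forward(h))
        self._branch_width = h.shape[1]
        cat = np.concatenate([b.forward(h) for b in self.branches], axis=1)
        a = self.pyramid_act.forward(cat)
        return self.head.forward(a)

    def backward(self, dlogits: np.ndarray) -> None:
        da = self.head.backward(dlogits)
        dcat = self.pyramid_act.backward(da)
        w = self._branch_width
        dh = np.zeros_like(dcat[:, :w])
        for i, b in enumerate(self.branches):
            dh += b.backward(dcat[:, i * w:(i + 1) * w])
        for conv, act in zip(reversed(self.stages), reversed(self.stage_acts)):
            dh = conv.backward(act.backward(dh))
        self.stem.backward(self.stem_act.backward(dh))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities in the open interval (0, 1)."""
        z = self.forward_logits(x)
        p = _sigmoid(z)
        return np.clip(p, 1e-7, 1.0 - 1e-7)

    # -- persistence

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.params())}
        np.savez(str(path), config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        with np.load(str(path), allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["config"]))
            cfg_dict["dilation_rates"] = tuple(cfg_dict["dilation_rates"])
            model = cls(NetworkConfig(**cfg_dict))
            for i, (p, _) in enumerate(model.params()):
                p[...] = data[f"p{i}"]
        return model


def build_network(config: NetworkConfig) -> SegmentationModel:
    """Deterministically initialize a model from its config."""
    return SegmentationModel(config)


# ---------------------------------------------------------------------------
# Loss and optimizer


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _loss_and_grad(logits: np.ndarray, target: np.ndarray, cfg: TrainConfig):
    """Weighted BCE-with-logits and/or soft Dice; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    y = target.astype(np.float64)
    n = z.size
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    loss = 0.0
    dz = np.zeros_like(z)
    wp = cfg.foreground_weight
    if cfg.loss_name in ("bce", "bce_dice"):
        softplus_negz = np.logaddexp(0.0, -z)
        softplus_z = np.logaddexp(0.0, z)
        loss += float(np.sum(wp * y * softplus_negz + (1 - y) * softplus_z) / n)
        dz += (-wp * y * (1 - p) + (1 - y) * p) / n
    if cfg.loss_name in ("dice", "bce_dice"):
        eps = 1.0
        inter = np.sum(p * y)
        denom = np.sum(p) + np.sum(y) + eps
        dice = (2 * inter + eps) / denom
        loss += float(1.0 - dice)
        dp = -(2 * y * denom - (2 * inter + eps)) / denom**2
        dz += dp * p * (1 - p)
    return loss, dz.astype(_DTYPE)


class _Adam:
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


# ---------------------------------------------------------------------------
# Training loop


def _study_batches(order, batch_size):
    for i in range(0, len(order), batch_size):
        yield order[i:i + batch_size]


def _make_batch(items, cfg: TrainConfig, rng, policy: DropoutPolicy | None,
                pattern_log: list[str] | None = None):
    xs, ys = [], []
    for study, z in items:
        slab = extract_slab(study, z, cfg.slab_half_width)
        if policy is not None:
            pattern = sample_pattern(policy, study.n_sequences, rng)
            slab = apply_input_dropout(slab, pattern)
            if pattern_log is not None:
                pattern_log.append(pattern.to_string())
        xs.append(slab.values)
        ys.append(study.ground_truth[:, :, z])
    return np.stack(xs), np.stack(ys)[:, None].astype(_DTYPE)


def train(
    model: SegmentationModel,
    studies: Sequence[MultisequenceStudy],
    cfg: TrainConfig,
) -> tuple[SegmentationModel, dict]:
    """Train in place; returns (model, history).

    Per step: slabs are drawn, a fresh availability pattern is sampled from
    the dropout policy, zero-fill + 1/(1-p) reweighting is applied, and the
    loss against the center-slice ground truth is minimized with Adam.
    History records per-epoch train/validation loss and the histogram of
    sampled patterns.  Fully seeded and deterministic.
    """
    if not studies:
        raise ValueError("need at least one training study")
    for st in studies:
        if not st.ground_truth.any():
            raise ValueError(f"study {st.subject_id} has an empty ground truth")

    rng = np.random.default_rng(cfg.seed)
    normalized = [normalize_study(s) for s in studies]
    n_val = int(round(cfg.validation_fraction * len(normalized)))
    if 0 < n_val < len(normalized):
        perm = rng.permutation(len(normalized))
        val_set = [normalized[i] for i in perm[:n_val]]
        train_set = [normalized[i] for i in perm[n_val:]]
    else:
        train_set, val_set = list(normalized), list(normalized)

    pairs = [(s, z) for s in train_set for z in range(s.n_slices)]
    val_pairs = [(s, z) for s in val_set for z in range(s.n_slices)]
    optimizer = _Adam(model.params(), lr=cfg.learning_rate)
    history: dict = {"train_loss": [], "val_loss": [], "pattern_histogram": {}}
    pattern_log: list[str] = []

    for epoch in range(cfg.epochs):
        order = [pairs[i] for i in rng.permutation(len(pairs))]
        losses = []
        for batch in _study_batches(order, cfg.batch_size):
            x, y = _make_batch(batch, cfg, rng, cfg.dropout_policy, pattern_log)
            model.zero_grad()
            logits = model.forward_logits(x)
            loss, dz = _loss_and_grad(logits, y, cfg)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}; lower the learning "
                    "rate or check input normalization"
                )
            model.backward(dz)
            optimizer.step()
            losses.append(loss)
        # validation under the all-available pattern (identity dropout)
        vlosses = []
        for batch in _study_batches(val_pairs, cfg.batch_size):
            x, y = _make_batch(batch, cfg, rng, None)
            logits = model.forward_logits(x)
            vloss, _ = _loss_and_grad(logits, y, cfg)
            vlosses.append(vloss)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(np.mean(vlosses)))

    hist: dict[str, int] = {}
    for pat in pattern_log:
        hist[pat] = hist.get(pat, 0) + 1
    history["pattern_histogram"] = hist
    return model, history
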