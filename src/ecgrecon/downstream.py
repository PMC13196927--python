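"""Diagnostic-utility probe: frozen 1-D SE-residual backbone + linear head.

The probe asks whether reconstructed signals still carry disease-specific
information: a feature backbone is trained (briefly) on real 12-lead signals
with multi-hot condition labels, then frozen; a lightweight linear head is
fitted on features of the signals under evaluation (e.g. VAE reconstructions)
with per-label binary cross-entropy; per-condition AUROC and the Youden
operating point are reported.

The backbone is a squeeze-and-excitation residual bottleneck network:
1x1 reduce, k x 1, 1x1 expand convolutions with batch normalization and
sigmoid-weighted (Swish) activations, SAME padding, channel-wise SE gating,
stagewise downsampling and global average pooling.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .metrics import auroc, youden_threshold
from .nn import AdamW, BatchNorm1d, Conv1d, Linear, Module, SqueezeExcite, Tensor
from .records import EcgRecord


@dataclass(frozen=True)
class BackboneConfig:
    channels: tuple[int, ...] = (16, 32, 64)   # one entry per stage
    kernel_size: int = 7
    se_reduction: int = 4
    blocks_per_stage: int = 1
    global_average_pool: bool = True

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd (SAME padding)")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")

    @property
    def stages(self) -> int:
        return len(self.channels)

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]


class BottleneckBlock(Module):
    """1x1 reduce -> k x 1 -> 1x1 expand with BN/Swish, SE gating, skip."""

    def __init__(self, in_ch: int, out_ch: int, k: int, se_reduction: int,
                 *, stride: int = 1, rng, dtype=np.float32):
        mid = max(out_ch // 2, 4)
        self.conv_reduce = Conv1d(in_ch, mid, 1, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm1d(mid, dtype=dtype)
        self.conv_mid = Conv1d(mid, mid, k, stride=stride, padding=k // 2,
                               rng=rng, dtype=dtype)
        self.bn2 = BatchNorm1d(mid, dtype=dtype)
        self.conv_expand = Conv1d(mid, out_ch, 1, rng=rng, dtype=dtype)
        self.bn3 = BatchNorm1d(out_ch, dtype=dtype)
        self.se = SqueezeExcite(out_ch, se_reduction, rng=rng, dtype=dtype)
        self.skip = None
        if in_ch != out_ch or stride != 1:
            self.skip = Conv1d(in_ch, out_ch, 1, stride=stride, padding=0,
                               rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv_reduce(x)).silu()
        h = self.bn2(self.conv_mid(h)).silu()
        h = self.se(self.bn3(self.conv_expand(h)))
        identity = x if self.skip is None else self.skip(x)
        return (identity + h).silu()


class Backbone(Module):
    """Deterministic-at-inference map from [12 x T] to an F-vector."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.config = cfg
        self.dtype = dtype
        self.training = True
        self.stem = Conv1d(12, cfg.channels[0], cfg.kernel_size, rng=rng,
                           dtype=dtype)
        self.bn_stem = BatchNorm1d(cfg.channels[0], dtype=dtype)
        self.blocks = []
        in_ch = cfg.channels[0]
        for stage, ch in enumerate(cfg.channels):
            for b in range(cfg.blocks_per_stage):
                stride = 2 if (b == 0 and stage > 0) else 1
                self.blocks.append(BottleneckBlock(
                    in_ch, ch, cfg.kernel_size, cfg.se_reduction,
                    stride=stride, rng=rng, dtype=dtype))
                in_ch = ch

    def forward_t(self, x: Tensor) -> Tensor:
        h = self.bn_stem(self.stem(x)).silu()
        for blk in self.blocks:
            h = blk(h)
        if self.config.global_average_pool:
            h = h.mean(axis=2)  # [N, F]
        return h

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode features (running BN statistics, no grad)."""
        x = np.asarray(x, dtype=self.dtype)
        single = x.ndim == 2
        if single:
            x = x[None]
        was = self.training
        self.set_training(False)
        out = self.forward_t(Tensor(x)).data
        self.set_training(was)
        return out[0] if single else out

    def parameter_hash(self) -> str:
        h = hashlib.sha256()
        for a in self.state_arrays():
            h.update(np.ascontiguousarray(a, dtype=np.float64).tobytes())
        return h.hexdigest()


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> Backbone:
    return Backbone(cfg, seed=seed)


def _signals(records, dtype) -> np.ndarray:
    x = np.stack([np.asarray(r.signal, dtype=dtype) for r in records])
    return x


def pretrain_backbone(backbone: Backbone, records: list[EcgRecord],
                      epochs: int = 5, lr: float = 1e-3, batch_size: int = 16,
                      seed: int = 0) -> list[float]:
    """Brief supervised pretraining of the backbone on labelled 12-lead
    signals (multi-label BCE through a temporary linear head).  Returns the
    per-epoch mean loss trace; the temporary head is discarded."""
    K = len(records[0].label_names)
    if K == 0:
        raise ValueError("records carry no labels")
    rng = np.random.default_rng(seed)
    head = Linear(backbone.config.feature_dim, K,
                  rng=np.random.default_rng(seed + 1), dtype=backbone.dtype)
    x = _signals(records, backbone.dtype)
    y = np.stack([r.labels for r in records]).astype(backbone.dtype)
    params = backbone.parameters() + head.parameters()
    opt = AdamW(params, lr=lr, weight_decay=1e-4)
    backbone.set_training(True)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(len(x))
        epoch_losses = []
        for i in range(0, len(x), batch_size):
            idx = order[i:i + batch_size]
            feats = backbone.forward_t(Tensor(x[idx]))
            logits = head(feats)
            yb = Tensor(y[idx])
            # stable BCE-with-logits: softplus(z) - z*y, averaged
            loss = (logits.softplus() - logits * yb).mean()
            for p in params:
                p.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        losses.append(float(np.mean(epoch_losses)))
    backbone.set_training(False)
    return losses


def extract_features(backbone: Backbone, records: list[EcgRecord],
                     batch_size: int = 32) -> np.ndarray:
    x = _signals(records, backbone.dtype)
    feats = [backbone(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(feats, axis=0).astype(np.float64)


# ---------------------------------------------------------------------------
# linear head
# ---------------------------------------------------------------------------

@dataclass
class LinearHead:
    weight: np.ndarray  # [F x K]
    bias: np.ndarray    # [K]

    def scores(self, features: np.ndarray) -> np.ndarray:
        z = features @ self.weight + self.bias
        return 1.0 / (1.0 + np.exp(-z))


def fit_head(features: np.ndarray, labels: np.ndarray, epochs: int = 300,
             lr: float = 0.1, seed: int = 0) -> LinearHead:
    """Single affine map F -> K trained with per-label sigmoid BCE by
    full-batch gradient descent; deterministic under the seed (zero init, the
    seed only fixes any future stochastic extension)."""
    features = np.asarray(features, float)
    labels = np.atleast_2d(np.asarray(labels, float))
    if labels.shape[0] != features.shape[0]:
        labels = labels.T
    n, F = features.shape
    K = labels.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not any(0 < labels[:, k].sum() < n for k in range(K)):
        raise ValueError("every label is single-class; head cannot be fit")
    # standardize features for conditioning; fold into weights afterwards
    mu = features.mean(axis=0)
    sd = features.std(axis=0) + 1e-8
    Xs = (features - mu) / sd
    W = np.zeros((F, K))
    b = np.zeros(K)
    for _ in range(epochs):
        p = 1.0 / (1.0 + np.exp(-(Xs @ W + b)))
        err = (p - labels) / n
        W -= lr * (Xs.T @ err)
        b -= lr * err.sum(axis=0)
    return LinearHead(weight=W / sd[:, None], bias=b - (mu / sd) @ W)


@dataclass
class ProbeResult:
    table: "object"     # pandas DataFrame: label, auroc, sensitivity, specificity, threshold
    macro_auroc: float

    def __repr__(self):
        return f"ProbeResult(macro_auroc={self.macro_auroc:.4f})\n{self.table}"


def probe(backbone: Backbone, head: LinearHead, records: list[EcgRecord],
          labels: np.ndarray | None = None) -> ProbeResult:
    """Per-label AUROC / Youden sensitivity / specificity of head scores on
    backbone features; single-class labels are flagged undefined (NaN) and
    excluded from the macro average."""
    import pandas as pd

    if not records:
        raise ValueError("no records to probe")
    if labels is None:
        labels = np.stack([r.labels for r in records])
    label_names = records[0].label_names
    feats = extract_features(backbone, records)
    scores = head.scores(feats)
    rows = []
    defined = []
    for k, name in enumerate(label_names):
        yk = labels[:, k]
        if len(np.unique(yk)) != 2:
            rows.append({"label": name, "auroc": np.nan, "sensitivity": np.nan,
                         "specificity": np.nan, "threshold": np.nan})
            continue
        a = auroc(scores[:, k], yk)
        thr, sens, spec = youden_threshold(scores[:, k], yk)
        rows.append({"label": name, "auroc": a, "sensitivity": sens,
                     "specificity": spec, "threshold": thr})
        defined.append(a)
    macro = float(np.mean(defined)) if defined else float("nan")
    return ProbeResult(table=pd.DataFrame(rows), macro_auroc=macro)


def zero_fill_records(records: list[EcgRecord], mask) -> list[EcgRecord]:
    """Replace all dropped leads with zeros (the reduced-lead control arm)."""
    from .maskvae import mask_leads

    return [r.with_signal(mask_leads(r.signal, mask)) for r in records]
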