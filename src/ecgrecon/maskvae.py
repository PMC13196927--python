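"""Masked-input variational autoencoder for reduced-lead ECG reconstruction.

The task: given a 12-lead segment x with 9 leads zeroed out (simulating a
3-lead wearable recording, typically retaining II, V1, V5), reconstruct the
full 12-lead signal.  The encoder maps the masked 12-channel input through
strided residual convolution stages to a compressed grid of width T' = T/2^s,
where two 1x1 convolution heads emit the posterior parameters mu and
log sigma^2 of a diagonal Gaussian over a d-dimensional latent per time
position.  A latent sample z = mu + sigma * eps (reparameterization trick)
feeds a mirrored decoder whose lowest-resolution stage carries multi-head
self-attention over time, restoring the [12 x T] signal.

Training maximizes the evidence lower bound: per-element MSE reconstruction
plus beta times the closed-form KL divergence of the posterior from the unit
Gaussian prior.  A perceptual term (feature-space MSE under a pluggable
embedder) can be added with its own weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .leads import CANONICAL_LEADS, lead_indices
from .nn import Conv1d, GroupNorm, Module, SelfAttention1d, Tensor

LOGVAR_MIN, LOGVAR_MAX = -30.0, 20.0

DEFAULT_RETAINED = ("II", "V1", "V5")

#: Mask presets named by the retained leads of each experiment arm.
MASK_PRESETS: dict[str, tuple[str, ...]] = {
    "II,V1,V5": ("II", "V1", "V5"),
    "I,II,V3": ("I", "II", "V3"),
    "I": ("I",),
}


@dataclass(frozen=True)
class LeadMask:
    """Binary retain/drop pattern over the 12 canonical leads (1 = dropped)."""

    drop_flags: np.ndarray

    def __post_init__(self):
        flags = np.asarray(self.drop_flags, dtype=np.int8)
        if flags.shape != (12,):
            raise ValueError("drop_flags must have length 12")
        if not np.isin(flags, (0, 1)).all():
            raise ValueError("drop_flags must be binary")
        if flags.sum() == 0 or flags.sum() == 12:
            raise ValueError("mask needs at least one retained and one dropped lead")
        object.__setattr__(self, "drop_flags", flags)

    @classmethod
    def from_retained(cls, retained) -> "LeadMask":
        if isinstance(retained, str):
            retained = tuple(s.strip() for s in retained.split(","))
        flags = np.ones(12, dtype=np.int8)
        flags[lead_indices(retained)] = 0
        return cls(flags)

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.drop_flags == 0)

    @property
    def dropped_indices(self) -> np.ndarray:
        return np.flatnonzero(self.drop_flags == 1)

    @property
    def retained_names(self) -> tuple[str, ...]:
        return tuple(CANONICAL_LEADS[i] for i in self.retained_indices)


def mask_leads(x: np.ndarray, mask: LeadMask) -> np.ndarray:
    """x * (1 - M): retained rows pass through, dropped rows become zero."""
    x = np.asarray(x)
    if x.shape[-2] != 12:
        raise ValueError(f"expected 12 leads on the channel axis, got {x.shape}")
    keep = (1 - mask.drop_flags).astype(x.dtype)
    return x * keep[..., :, None]


@dataclass(frozen=True)
class ModelConfig:
    in_leads: int = 12
    base_channels: int = 128
    bottleneck_channels: int = 512
    n_down_stages: int = 3
    latent_dim: int = 4
    attention_heads: int = 4
    groupnorm_groups: int = 8
    residual_blocks_per_stage: int = 2

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.bottleneck_channels % self.attention_heads:
            raise ValueError("bottleneck must be divisible by attention_heads")

    @property
    def down_factor(self) -> int:
        return 2 ** self.n_down_stages

    def channel_plan(self) -> list[int]:
        """Geometric widening base -> bottleneck, rounded to the group size."""
        g = self.groupnorm_groups
        plan = [self.base_channels]
        for i in range(1, self.n_down_stages):
            ch = self.base_channels * (self.bottleneck_channels
                                       / self.base_channels) ** (i / self.n_down_stages)
            plan.append(max(g, int(round(ch / g)) * g))
        plan.append(self.bottleneck_channels)
        return plan


@dataclass(frozen=True)
class LatentState:
    """Posterior parameters and the reparameterized sample on the T' grid."""

    mu: np.ndarray
    log_var: np.ndarray
    eps: np.ndarray
    z: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.z is None:
            object.__setattr__(
                self, "z", self.mu + np.exp(self.log_var / 2.0) * self.eps)


def reparameterize(mu: np.ndarray, log_var: np.ndarray, seed: int) -> LatentState:
    """Draw eps ~ N(0, I) under seed and form z = mu + sigma * eps."""
    mu = np.asarray(mu, dtype=np.float64)
    log_var = np.asarray(log_var, dtype=np.float64)
    if mu.shape != log_var.shape:
        raise ValueError("mu and log_var must share a shape")
    eps = np.random.default_rng(seed).standard_normal(mu.shape)
    return LatentState(mu=mu, log_var=log_var, eps=eps)


class ResBlock1d(Module):
    """conv - groupnorm - SiLU - conv - groupnorm, plus identity skip."""

    def __init__(self, channels: int, groups: int, *, rng, dtype):
        self.conv1 = Conv1d(channels, channels, 3, rng=rng, dtype=dtype)
        self.norm1 = GroupNorm(groups, channels, dtype=dtype)
        self.conv2 = Conv1d(channels, channels, 3, rng=rng, dtype=dtype)
        self.norm2 = GroupNorm(groups, channels, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).silu()
        h = self.norm2(self.conv2(h))
        return x + h


class VaeModel(Module):
    """Encoder/decoder pair; parameter shapes are a pure function of config."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        cfg = config
        self.config = cfg
        self.dtype = dtype
        plan = cfg.channel_plan()
        g = cfg.groupnorm_groups
        nres = cfg.residual_blocks_per_stage

        # encoder
        self.enc_stem = Conv1d(cfg.in_leads, plan[0], 7, rng=rng, dtype=dtype)
        self.enc_blocks = []
        self.enc_down = []
        for i in range(cfg.n_down_stages):
            self.enc_blocks.extend(
                ResBlock1d(plan[i], g, rng=rng, dtype=dtype) for _ in range(nres))
            self.enc_down.append(Conv1d(plan[i], plan[i + 1], 3, stride=2,
                                        padding=1, rng=rng, dtype=dtype))
        self.enc_mid = ResBlock1d(plan[-1], g, rng=rng, dtype=dtype)
        self.mu_head = Conv1d(plan[-1], cfg.latent_dim, 1, rng=rng, dtype=dtype)
        self.logvar_head = Conv1d(plan[-1], cfg.latent_dim, 1, rng=rng, dtype=dtype)

        # decoder
        self.dec_in = Conv1d(cfg.latent_dim, plan[-1], 1, rng=rng, dtype=dtype)
        self.dec_mid = ResBlock1d(plan[-1], g, rng=rng, dtype=dtype)
        self.attn_norm = GroupNorm(g, plan[-1], dtype=dtype)
        self.attn = SelfAttention1d(plan[-1], cfg.attention_heads, rng=rng,
                                    dtype=dtype)
        self.dec_up = []
        self.dec_blocks = []
        for i in reversed(range(cfg.n_down_stages)):
            self.dec_up.append(Conv1d(plan[i + 1], plan[i], 3, rng=rng, dtype=dtype))
            self.dec_blocks.extend(
                ResBlock1d(plan[i], g, rng=rng, dtype=dtype) for _ in range(nres))
        self.out_norm = GroupNorm(g, plan[0], dtype=dtype)
        self.out_conv = Conv1d(plan[0], cfg.in_leads, 7, rng=rng, dtype=dtype)

    # -- graph-building forward passes ------------------------------------

    def encode_t(self, x: Tensor) -> tuple[Tensor, Tensor]:
        T = x.shape[-1]
        if T % self.config.down_factor:
            raise ValueError(
                f"T={T} not divisible by 2^{self.config.n_down_stages}")
        h = self.enc_stem(x)
        nres = self.config.residual_blocks_per_stage
        for i, down in enumerate(self.enc_down):
            for blk in self.enc_blocks[i * nres:(i + 1) * nres]:
                h = blk(h)
            h = down(h).silu()
        h = self.enc_mid(h)
        mu = self.mu_head(h)
        log_var = self.logvar_head(h).clip(LOGVAR_MIN, LOGVAR_MAX)
        return mu, log_var  # [N, d, T']

    def decode_t(self, z: Tensor) -> Tensor:
        h = self.dec_in(z)
        h = self.dec_mid(h)
        h = h + self.attn(self.attn_norm(h))
        nres = self.config.residual_blocks_per_stage
        for i, up in enumerate(self.dec_up):
            h = up(h.repeat_time(2)).silu()
            for blk in self.dec_blocks[i * nres:(i + 1) * nres]:
                h = blk(h)
        return self.out_conv(self.out_norm(h).silu())

    # -- numpy-facing API ---------------------------------------------------

    def _to_batch(self, x: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            return x[None], True
        return x, False

    def encode(self, x_masked: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters for masked input [12 x T] -> two [T' x d]."""
        xb, single = self._to_batch(x_masked)
        mu, log_var = self.encode_t(Tensor(xb))
        mu = np.swapaxes(mu.data, -1, -2)
        log_var = np.swapaxes(log_var.data, -1, -2)
        return (mu[0], log_var[0]) if single else (mu, log_var)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode [T' x d] (or batched) latents to [12 x T]."""
        z = np.asarray(z, dtype=self.dtype)
        single = z.ndim == 2
        if single:
            z = z[None]
        if z.shape[-1] != self.config.latent_dim:
            raise ValueError(
                f"latent width {z.shape[-1]} != d={self.config.latent_dim}")
        out = self.decode_t(Tensor(np.swapaxes(z, -1, -2))).data
        return out[0] if single else out


def pad_to_multiple(x: np.ndarray, factor: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Symmetric edge-pad the time axis up to the next multiple of factor."""
    T = x.shape[-1]
    rem = (-T) % factor
    lo, hi = rem // 2, rem - rem // 2
    if rem == 0:
        return x, (0, 0)
    pad = [(0, 0)] * (x.ndim - 1) + [(lo, hi)]
    return np.pad(x, pad, mode="edge"), (lo, hi)


def reconstruct(model: VaeModel, x: np.ndarray, mask: LeadMask,
                seed: int | None = None, passthrough: bool = False) -> np.ndarray:
    """Mask, encode, decode; inference uses the posterior mean unless a seed
    requests a stochastic latent.  With passthrough, retained leads are copied
    from the input and only dropped leads come from the decoder."""
    x = np.asarray(x, dtype=np.float64)
    xm = mask_leads(x, mask)
    xp, (lo, hi) = pad_to_multiple(xm, model.config.down_factor)
    mu, log_var = model.encode(xp)
    z = mu if seed is None else reparameterize(mu, log_var, seed).z
    out = model.decode(z).astype(np.float64)
    T = xp.shape[-1]
    out = out[..., lo:T - hi]
    if passthrough:
        out = out.copy()
        out[..., mask.retained_indices, :] = x[..., mask.retained_indices, :]
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def recon_loss_t(x: Tensor, x_hat: Tensor, reduction: str = "mean") -> Tensor:
    diff = x_hat - x
    sq = diff * diff
    if reduction == "mean":
        return sq.mean()
    if reduction == "sum_per_sample":
        # squared norm per sample, averaged over the batch
        n = sq.shape[0] if sq.ndim == 3 else 1
        return sq.sum() * (1.0 / n)
    raise ValueError(f"unknown reduction {reduction!r}")


def kl_divergence_t(mu: Tensor, log_var: Tensor) -> Tensor:
    """Closed-form KL(N(mu, sigma^2) || N(0, I)): summed over latent
    coordinates, averaged over batch and time positions.  Expects the latent
    axis in position -2 ([N, d, T'] layout) or 1-D inputs."""
    term = 1.0 + log_var - mu * mu - log_var.exp()
    if term.ndim == 1:
        return term.sum() * (-0.5)
    axis = -2
    per_pos = term.sum(axis=axis) * (-0.5)
    return per_pos.mean()


def recon_loss(x: np.ndarray, x_hat: np.ndarray, reduction: str = "mean") -> float:
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(recon_loss_t(Tensor(x), Tensor(x_hat), reduction).data)


def kl_divergence(mu: np.ndarray, log_var: np.ndarray) -> float:
    """Closed-form KL for [T' x d] / [N x T' x d] posterior parameter arrays."""
    mu, log_var = np.asarray(mu, float), np.asarray(log_var, float)
    if mu.shape != log_var.shape:
        raise ValueError("mu and log_var must share a shape")
    term = 1.0 + log_var - mu ** 2 - np.exp(log_var)
    if term.ndim == 1:
        return float(-0.5 * term.sum())
    return float(np.mean(-0.5 * term.sum(axis=-1)))


def total_loss(x: np.ndarray, x_hat: np.ndarray, mu: np.ndarray,
               log_var: np.ndarray, beta: float = 1e-4,
               perceptual_weight: float = 0.0, embedder=None,
               reduction: str = "mean") -> tuple[float, dict[str, float]]:
    """ELBO-style training objective: recon + beta*KL (+ perceptual term)."""
    if beta < 0 or perceptual_weight < 0:
        raise ValueError("beta and perceptual_weight must be >= 0")
    if perceptual_weight > 0 and embedder is None:
        raise ValueError("perceptual_weight > 0 requires an embedder")
    components = {
        "recon": recon_loss(x, x_hat, reduction),
        "kl": kl_divergence(mu, log_var),
    }
    total = components["recon"] + beta * components["kl"]
    if perceptual_weight > 0:
        fx = np.asarray(embedder(x), float)
        fy = np.asarray(embedder(x_hat), float)
        components["perceptual"] = float(np.mean((fx - fy) ** 2))
        total += perceptual_weight * components["perceptual"]
    return float(total), components
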