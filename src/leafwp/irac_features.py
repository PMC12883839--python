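"""Multi-branch convolution/self-attention feature extractor for 1-D spectra.

The extractor is an Inception-ResNet-style backbone adapted to spectral
vectors: an input batch norm and a stem convolution feed three parallel
branches with kernel sizes 3/5/7 (multi-scale local absorption features);
branch outputs are concatenated along channels, fused by a 1x1 convolution
and added back to the stem (residual connection) before flattening.

Selected branches replace their plain convolution with a dual-path block
that computes, in parallel,

* a convolution path: 1x1 pointwise -> depthwise (kernel k) -> 1x1
  pointwise (a depthwise-separable convolution), capturing fine-grained
  neighbouring-band structure, and
* a self-attention path: 1x1 projections to query/key/value, dot-product
  scores over the 176 positions plus a learnable positional-encoding table,
  softmax weighting of the values — capturing long-range dependencies
  between distant wavelengths;

fused as  alpha * attention + beta * convolution  with learnable scalars
alpha and beta (both initialized to 1), so the network can rebalance local
versus global evidence during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .spectral_core import DEFAULT_N_BANDS, SpectraSet

__all__ = ["IRACConfig", "ACmixBlock", "IRACExtractor", "build_irac", "extract_features"]


@dataclass
class IRACConfig:
    """Architecture hyperparameters of the extractor.

    channels is shared by every stage (the dual-path block requires equal
    input and output channels); feature_dim is the flattened output length
    channels * seq_len and is derived, not set.
    """

    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    channels: int = 8
    n_heads: int = 1
    seq_len: int = DEFAULT_N_BANDS
    acmix_enabled: bool = True
    #: which branches use the dual-path block when enabled; by default the
    #: two largest-kernel branches (long-range context helps most there).
    acmix_branches: tuple[bool, ...] = (False, True, True)

    def __post_init__(self) -> None:
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd")
        if len(self.acmix_branches) != len(self.kernel_sizes):
            raise ValueError("acmix_branches must match kernel_sizes in length")
        if self.channels % self.n_heads != 0:
            raise ValueError("channels must be divisible by n_heads")

    @property
    def feature_dim(self) -> int:
        return self.channels * self.seq_len


class ACmixBlock(nn.Module):
    """Dual-path (self-attention + separable convolution) block, shape-preserving.

    Input and output are both (B, C, L). ``attention_path`` and
    ``conv_path`` are exposed separately; ``forward`` returns
    alpha * attention_path(x) + beta * conv_path(x).
    """

    def __init__(self, channels: int, kernel: int, seq_len: int, n_heads: int, rng):
        super().__init__()
        if channels % n_heads != 0:
            raise ValueError("channels must be divisible by n_heads")
        self.channels = channels
        self.n_heads = n_heads
        self.seq_len = seq_len
        # attention path projections (1x1 convolutions)
        self.q_proj = nn.Conv1d(channels, channels, 1, rng)
        self.k_proj = nn.Conv1d(channels, channels, 1, rng)
        self.v_proj = nn.Conv1d(channels, channels, 1, rng)
        # learnable positional-encoding table added inside the attention score
        self.pos_table = nn.Tensor(np.zeros((n_heads, seq_len, seq_len)), requires_grad=True)
        # convolution path: pointwise -> depthwise -> pointwise
        self.pw_in = nn.Conv1d(channels, channels, 1, rng)
        self.dw = nn.DepthwiseConv1d(channels, kernel, rng)
        self.pw_out = nn.Conv1d(channels, channels, 1, rng)
        # learnable fusion scalars
        self.alpha = nn.Tensor(np.array(1.0), requires_grad=True)
        self.beta = nn.Tensor(np.array(1.0), requires_grad=True)

    def attention_path(self, x: nn.Tensor) -> nn.Tensor:
        B, C, L = x.shape
        h = self.n_heads
        d = C // h
        q = self.q_proj(x).reshape(B, h, d, L)
        k = self.k_proj(x).reshape(B, h, d, L)
        v = self.v_proj(x).reshape(B, h, d, L)
        # scores[b,h,i,j]: similarity of position i's query with position j's key
        scores = q.transpose(0, 1, 3, 2) @ k * (1.0 / np.sqrt(d))
        scores = scores + self.pos_table.reshape(1, h, L, L)
        attn = nn.softmax(scores, axis=-1)  # rows sum to 1 over source positions
        out = v @ attn.transpose(0, 1, 3, 2)  # (B,h,d,L)
        return out.reshape(B, C, L)

    def conv_path(self, x: nn.Tensor) -> nn.Tensor:
        return self.pw_out(self.dw(self.pw_in(x)))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.channels or x.shape[2] != self.seq_len:
            raise ValueError(
                f"expected (B, {self.channels}, {self.seq_len}), got {x.shape}"
            )
        return self.alpha * self.attention_path(x) + self.beta * self.conv_path(x)


class _ConvBranch(nn.Module):
    """A plain convolution branch (the block the dual-path variant replaces)."""

    def __init__(self, channels: int, kernel: int, rng):
        super().__init__()
        self.conv = nn.Conv1d(channels, channels, kernel, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.conv(x)


class IRACExtractor(nn.Module):
    """Input BN -> stem conv -> three multi-scale branches -> fuse -> residual -> flatten."""

    def __init__(self, cfg: IRACConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        C = cfg.channels
        self.input_bn = nn.BatchNorm1d(1)
        self.stem = nn.Conv1d(1, C, 3, rng)
        self.stem_bn = nn.BatchNorm1d(C)
        branches = []
        for kernel, use_acmix in zip(cfg.kernel_sizes, cfg.acmix_branches):
            if cfg.acmix_enabled and use_acmix:
                branches.append(ACmixBlock(C, kernel, cfg.seq_len, cfg.n_heads, rng))
            else:
                branches.append(_ConvBranch(C, kernel, rng))
        self.branches = branches
        for i, b in enumerate(branches):
            setattr(self, f"branch_{i}", b)
        self.fuse = nn.Conv1d(C * len(branches), C, 1, rng)
        self.fuse_bn = nn.BatchNorm1d(C)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.ndim != 3 or x.shape[1] != 1 or x.shape[2] != self.cfg.seq_len:
            raise ValueError(
                f"expected input (B, 1, {self.cfg.seq_len}), got {x.shape}"
            )
        B = x.shape[0]
        stem = self.stem_bn(self.stem(self.input_bn(x))).relu()
        outs = [b(stem).relu() for b in self.branches]
        fused = self.fuse_bn(self.fuse(nn.concat(outs, axis=1)))
        res = (fused + stem).relu()  # residual join with the stem features
        return res.reshape(B, self.cfg.feature_dim)


def build_irac(cfg: IRACConfig, seed: int = 0) -> IRACExtractor:
    """Construct a seeded extractor; `acmix_enabled=False` gives the plain
    Inception-ResNet baseline (strictly fewer parameters)."""
    return IRACExtractor(cfg, np.random.default_rng(seed))


def extract_features(extractor: IRACExtractor, spectra: np.ndarray | SpectraSet) -> np.ndarray:
    """Deterministic (inference-mode) feature matrix (n_samples, feature_dim)."""
    x = spectra.spectra if isinstance(spectra, SpectraSet) else np.asarray(spectra, dtype=float)
    if x.ndim != 2 or x.shape[1] != extractor.cfg.seq_len:
        raise ValueError(
            f"spectra must be (n, {extractor.cfg.seq_len}), got {x.shape}"
        )
    was_training = extractor.training
    extractor.eval()
    out = extractor(nn.Tensor(x[:, None, :])).data
    if was_training:
        extractor.train()
    return out
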