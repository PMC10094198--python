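"""The multi-task ECG network.

Architecture (hard parameter sharing): a trunk of squeeze-and-excitation
residual blocks extracts a feature sequence shared by both tasks; a
contextual-transformer (CoT) attention block fuses a convolutional static
context of the keys with a dynamically computed attention-weighted value
map; a bidirectional GRU summarizes the sequence from both temporal
directions; two independent fully connected heads score the main and the
auxiliary label spaces.  The CoT and Bi-GRU stages can be toggled off for
ablation runs, and optionally duplicated per task (``per_task_branch``).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat
from .nn import BatchNorm1d, BiGRU, Conv1d, Dropout, Linear, Module

__all__ = ["ModelConfig", "CotState", "SEBlock", "CoTBlock", "MultiTaskECGNet"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_kernel=7`` and ``dropout=0.2`` are the reference settings for the
    trunk; the trunk depth and widths are free choices (the default keeps a
    15000-sample input down to a sequence length a GRU handles comfortably).
    """

    in_leads: int = 12
    n_main_classes: int = 9
    n_aux_classes: int = 5
    block_channels: tuple[int, ...] = (64, 128, 128, 256)
    block_strides: tuple[int, ...] | None = None  # default: stride 2 per block
    conv_kernel: int = 7
    dropout: float = 0.2
    se_reduction: int = 16
    cot_kernel: int = 3
    gru_hidden: int = 128
    use_cot: bool = True
    use_bigru: bool = True
    per_task_branch: bool = False

    def __post_init__(self):
        if self.block_strides is None:
            self.block_strides = tuple(2 for _ in self.block_channels)
        self.block_channels = tuple(self.block_channels)
        self.block_strides = tuple(self.block_strides)
        if len(self.block_strides) != len(self.block_channels):
            raise ValueError("block_strides and block_channels lengths differ")
        for k in (self.conv_kernel, self.cot_kernel):
            if k % 2 != 1 or k < 1:
                raise ValueError("kernel sizes must be odd and positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for name in ("in_leads", "n_main_classes", "n_aux_classes",
                     "se_reduction", "gru_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class CotState:
    """Named intermediate tensors of the CoT block, for inspection/oracles."""

    E: np.ndarray
    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    K1: np.ndarray
    A: np.ndarray
    K2: np.ndarray
    D: np.ndarray


class SEBlock(Module):
    """Residual block: two conv-BN-ReLU stages with dropout, then an SE gate.

    Squeeze: global mean over time per channel.  Excitation: bottleneck of
    two fully connected maps (ReLU, then logistic) producing one gate per
    channel, applied multiplicatively.  The shortcut is a pointwise strided
    convolution whenever the shape changes.
    """

    def __init__(self, in_ch: int, out_ch: int, cfg: ModelConfig, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_ch = in_ch
        k = cfg.conv_kernel
        self.conv1 = Conv1d(in_ch, out_ch, k, rng, stride=stride)
        self.bn1 = BatchNorm1d(out_ch)
        self.conv2 = Conv1d(out_ch, out_ch, k, rng)
        self.bn2 = BatchNorm1d(out_ch)
        self.drop1 = Dropout(cfg.dropout, rng)
        self.drop2 = Dropout(cfg.dropout, rng)
        bott = max(1, out_ch // cfg.se_reduction)
        self.fc1 = Linear(out_ch, bott, rng)
        self.fc2 = Linear(bott, out_ch, rng)
        if in_ch != out_ch or stride != 1:
            self.shortcut = Conv1d(in_ch, out_ch, 1, rng, stride=stride, padding=0)
        else:
            self.shortcut = None
        self.stride = stride

    def se_gate(self, x: Tensor) -> Tensor:
        """Per-channel gates in (0,1): mean -> FC -> ReLU -> FC -> logistic."""
        squeezed = x.mean(axis=2)  # (N, C)
        return self.fc2(self.fc1(squeezed).relu()).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"channel mismatch: got {x.shape[1]}, block expects {self.in_ch}")
        h = self.drop1(self.bn1(self.conv1(x)).relu())
        h = self.drop2(self.bn2(self.conv2(h)).relu())
        gate = self.se_gate(h)
        h = h * gate.reshape(gate.shape[0], gate.shape[1], 1)
        res = self.shortcut(x) if self.shortcut is not None else x
        return h + res


class CoTBlock(Module):
    """Contextual-transformer attention over a (N, C, T) feature sequence.

    With input E: Q = E and K = E; V = W(E) with W a learned pointwise
    embedding; the static context K1 is a kernel-``cot_kernel`` convolution
    of K; the attention map A is two successive pointwise transforms (ReLU
    between) of the channel concatenation [K1, Q]; the dynamic context is
    K2 = V * A (element-wise); the output fuses [K1, K2] through a pointwise
    projection back to C channels, so the block is shape-preserving.
    """

    def __init__(self, channels: int, cot_kernel: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.key_conv = Conv1d(channels, channels, cot_kernel, rng)       # K -> K1
        self.value_embed = Conv1d(channels, channels, 1, rng, padding=0)  # W
        self.attn1 = Conv1d(2 * channels, channels, 1, rng, padding=0)    # W_sigma
        self.attn2 = Conv1d(channels, channels, 1, rng, padding=0)        # W_theta
        self.proj = Conv1d(2 * channels, channels, 1, rng, padding=0)

    def __call__(self, e: Tensor, return_state: bool = False):
        if not np.isfinite(e.data).all():
            raise ValueError("CoT block received non-finite input")
        q = e
        k = e
        v = self.value_embed(e)
        k1 = self.key_conv(k)
        a = self.attn2(self.attn1(concat([k1, q], axis=1)).relu())
        k2 = v * a
        fused = concat([k1, k2], axis=1)
        d = self.proj(fused)
        if return_state:
            state = CotState(E=e.data, Q=q.data, K=k.data, V=v.data,
                             K1=k1.data, A=a.data, K2=k2.data, D=fused.data)
            return d, state
        return d


class _TaskBranch(Module):
    """CoT + Bi-GRU + head for one task (used when per_task_branch=True)."""

    def __init__(self, channels: int, cfg: ModelConfig, n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cot = CoTBlock(channels, cfg.cot_kernel, rng) if cfg.use_cot else None
        if cfg.use_bigru:
            self.bigru = BiGRU(channels, cfg.gru_hidden, rng)
            head_in = 2 * cfg.gru_hidden
        else:
            self.bigru = None
            head_in = channels
        self.head = Linear(head_in, n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if self.cot is not None:
            x = self.cot(x)
        if self.bigru is not None:
            feat = self.bigru(x.transpose(0, 2, 1))
        else:
            feat = x.mean(axis=2)
        return self.head(feat)


class MultiTaskECGNet(Module):
    """Shared SE-ResNet trunk with two task heads.

    By default (per the hard-parameter-sharing reading of the architecture
    diagram) the CoT block and the Bi-GRU are shared and only the two fully
    connected heads are task-specific; ``per_task_branch=True`` duplicates
    CoT and Bi-GRU per task instead.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        blocks = []
        in_ch = cfg.in_leads
        for out_ch, stride in zip(cfg.block_channels, cfg.block_strides):
            blocks.append(SEBlock(in_ch, out_ch, cfg, stride, rng))
            in_ch = out_ch
        self.blocks = blocks
        trunk_ch = in_ch
        if cfg.per_task_branch:
            self.main_branch = _TaskBranch(trunk_ch, cfg, cfg.n_main_classes, rng)
            self.aux_branch = _TaskBranch(trunk_ch, cfg, cfg.n_aux_classes, rng)
            self.cot = self.bigru = None
            self.main_head = self.aux_head = None
        else:
            self.cot = CoTBlock(trunk_ch, cfg.cot_kernel, rng) if cfg.use_cot else None
            if cfg.use_bigru:
                self.bigru = BiGRU(trunk_ch, cfg.gru_hidden, rng)
                head_in = 2 * cfg.gru_hidden
            else:
                self.bigru = None
                head_in = trunk_ch
            self.main_head = Linear(head_in, cfg.n_main_classes, rng)
            self.aux_head = Linear(head_in, cfg.n_aux_classes, rng)
            self.main_branch = self.aux_branch = None

    def trunk(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x

    def trunk_parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for block in self.blocks:
            params.extend(block.parameters())
        return params

    def forward(self, batch: np.ndarray | Tensor) -> tuple[Tensor, Tensor]:
        """Score a (N, leads, T) batch; returns (main scores, aux scores)."""
        x = batch if isinstance(batch, Tensor) else Tensor(batch)
        if x.ndim != 3:
            raise ValueError("expected a (batch, leads, time) array")
        if x.shape[1] != self.cfg.in_leads:
            raise ValueError(
                f"lead mismatch: got {x.shape[1]}, config has {self.cfg.in_leads}")
        feat = self.trunk(x)
        if self.cfg.per_task_branch:
            return self.main_branch(feat), self.aux_branch(feat)
        if self.cot is not None:
            feat = self.cot(feat)
        if self.bigru is not None:
            pooled = self.bigru(feat.transpose(0, 2, 1))
        else:
            pooled = feat.mean(axis=2)
        return self.main_head(pooled), self.aux_head(pooled)

    __call__ = forward

    def predict_proba(self, batch: np.ndarray,
                      batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
        """Per-class probabilities in eval mode, mini-batched."""
        was_training = self.training
        self.eval()
        mains, auxs = [], []
        for start in range(0, len(batch), batch_size):
            m, a = self.forward(np.asarray(batch[start:start + batch_size]))
            mains.append(1.0 / (1.0 + np.exp(-m.data)))
            auxs.append(1.0 / (1.0 + np.exp(-a.data)))
        if was_training:
            self.train()
        return np.concatenate(mains), np.concatenate(auxs)
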