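"""Teacher and Student network architectures.

Both networks share the same symmetric encoder-decoder skeleton (two 3x3
convolutions + ReLU per stage, 2x2 max-pool down, 2x2 transpose-conv up,
channel doubling per stage, four downsamplings by default).  They differ
in exactly one structural aspect:

* the **Teacher** is an auto-encoder *without* skip connections; its dense
  head reconstructs the input (through a sigmoid) and a classification
  head on the globally-pooled bottleneck predicts pathology;
* the **Student** is a U-Net *with* skip concatenations at every stage;
  its dense head emits per-pixel segmentation logits, plus the same
  auxiliary classification head.

Because the stage widths are identical, the flattened bottlenecks of a
teacher and a student built from one :class:`NetConfig` have equal length
— the precondition for comparing their latent distributions with a KL
divergence during distillation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Conv2d, ConvBlock, ConvTranspose2d, Linear, MaxPool2d, Parameter
from .nn.layers import DTYPE, sigmoid


class NetConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyper-parameters shared by teacher and student.

    ``in_size`` must be divisible by ``2**depth``.  The default depth of 4
    gives four downsamplings; the desk-scale default is 64-pixel tiles with
    8 base channels, the mammogram-scale preset 1024 pixels with 64.
    """

    in_size: int = 64
    base_channels: int = 8
    depth: int = 4
    num_classes: int = 2

    def __post_init__(self):
        if self.in_size % (2 ** self.depth) != 0:
            raise NetConfigError(
                f"in_size={self.in_size} not divisible by 2**depth={2 ** self.depth}")
        if self.base_channels < 1 or self.depth < 1:
            raise NetConfigError("base_channels and depth must be >= 1")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** self.depth

    @property
    def bottleneck_side(self) -> int:
        return self.in_size // 2 ** self.depth

    @property
    def bottleneck_len(self) -> int:
        return self.bottleneck_channels * self.bottleneck_side ** 2


@dataclass
class TeacherOutput:
    reconstruction: np.ndarray      # sigmoid of the dense head, input-shaped
    recon_logits: np.ndarray        # dense head before sigmoid
    class_logits: np.ndarray        # (batch, num_classes)
    bottleneck: np.ndarray          # (batch, bottleneck_len) flattened code


@dataclass
class StudentOutput:
    seg_logits: np.ndarray          # per-pixel logits, input-shaped
    class_logits: np.ndarray
    bottleneck: np.ndarray


PRESETS = {
    "desk": NetConfig(in_size=64, base_channels=8, depth=4),
    "mammogram": NetConfig(in_size=1024, base_channels=64, depth=4),
}


class EncoderDecoder:
    """Shared encoder-decoder graph; ``skips`` toggles U-Net concatenation."""

    def __init__(self, cfg: NetConfig, skips: bool, seed: int = 0):
        self.cfg = cfg
        self.skips = bool(skips)
        rng = np.random.default_rng(seed)
        base, depth = cfg.base_channels, cfg.depth

        self.enc_blocks, self.pools = [], []
        cin = 1
        for d in range(depth):
            cout = base * 2 ** d
            self.enc_blocks.append(ConvBlock(cin, cout, rng, f"enc{d}"))
            self.pools.append(MaxPool2d())
            cin = cout
        self.mid = ConvBlock(cin, base * 2 ** depth, rng, "mid")

        self.ups, self.dec_blocks = [], []
        for d in reversed(range(depth)):
            c_up_in = base * 2 ** (d + 1)
            c_out = base * 2 ** d
            self.ups.append(ConvTranspose2d(c_up_in, c_out, rng, f"up{d}"))
            c_block_in = c_out * 2 if self.skips else c_out
            self.dec_blocks.append(ConvBlock(c_block_in, c_out, rng, f"dec{d}"))
        self.out_conv = Conv2d(base, 1, 1, rng, "head")
        self.fc = Linear(cfg.bottleneck_channels, cfg.num_classes, rng, "cls")
        self._cache: dict | None = None

    # -- introspection ------------------------------------------------------

    def topology(self, include_class_head: bool = True) -> list[tuple]:
        """Structural fingerprint: (kind, cin, cout) per weighted layer."""
        items: list[tuple] = []
        for blk in self.enc_blocks + [self.mid]:
            for lyr in blk.layers:
                if isinstance(lyr, Conv2d):
                    items.append(("conv3", lyr.cin, lyr.cout))
        for up, blk in zip(self.ups, self.dec_blocks):
            items.append(("upconv", up.cin, up.cout))
            for lyr in blk.layers:
                if isinstance(lyr, Conv2d):
                    items.append(("conv3", lyr.cin, lyr.cout))
        items.append(("conv1", self.out_conv.cin, self.out_conv.cout))
        if include_class_head:
            items.append(("linear", self.fc.W.data.shape[1], self.fc.W.data.shape[0]))
        return items

    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for blk in self.enc_blocks:
            ps += blk.parameters()
        ps += self.mid.parameters()
        for up, blk in zip(self.ups, self.dec_blocks):
            ps += up.parameters() + blk.parameters()
        ps += self.out_conv.parameters() + self.fc.parameters()
        return ps

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name} in checkpoint")
            if state[p.name].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {p.name}: checkpoint "
                    f"{state[p.name].shape} vs model {p.data.shape}")
            p.data[...] = state[p.name]

    def checksum(self) -> int:
        """Order-stable hash of every parameter's exact bytes."""
        import hashlib

        h = hashlib.sha256()
        for p in self.parameters():
            h.update(p.name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return int.from_bytes(h.digest()[:8], "big")

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> dict:
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        x = np.ascontiguousarray(x, dtype=DTYPE)
        B = x.shape[0]
        if x.shape[2] != self.cfg.in_size or x.shape[3] != self.cfg.in_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} does not match "
                f"configured in_size={self.cfg.in_size}")

        skips: list[np.ndarray] = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        mid_out = self.mid.forward(h)

        h = mid_out
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h)
            if self.skips:
                h = np.concatenate([h, skip], axis=1)
            h = blk.forward(h)
        dense = self.out_conv.forward(h)

        gap = mid_out.mean(axis=(2, 3))
        class_logits = self.fc.forward(gap)
        self._cache = {"B": B, "mid_shape": mid_out.shape}
        return {
            "dense_logits": dense[:, 0],
            "class_logits": class_logits,
            "bottleneck_map": mid_out,
            "bottleneck_flat": mid_out.reshape(B, -1),
        }

    def backward(self, g_dense: np.ndarray | None = None,
                 g_class: np.ndarray | None = None,
                 g_bottleneck_flat: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients for a weighted sum of heads.

        Each argument is the gradient of the scalar loss with respect to
        the corresponding forward output; ``None`` means that head does
        not participate.
        """
        B = self._cache["B"]
        mid_shape = self._cache["mid_shape"]
        g_mid = np.zeros(mid_shape, dtype=DTYPE)

        if g_dense is not None:
            g = self.out_conv.backward(
                np.ascontiguousarray(g_dense, dtype=DTYPE).reshape(B, 1, *g_dense.shape[-2:]))
            n_skip_grads: list[np.ndarray] = []
            for up, blk in zip(reversed(self.ups), reversed(self.dec_blocks)):
                g = blk.backward(g)
                if self.skips:
                    c = up.cout
                    g, g_skip = g[:, :c], g[:, c:]
                    n_skip_grads.append(g_skip)
                g = up.backward(g)
            g_mid += g
        else:
            n_skip_grads = [None] * len(self.ups) if self.skips else []

        if g_class is not None:
            g_gap = self.fc.backward(np.ascontiguousarray(g_class, dtype=DTYPE))
            hw = mid_shape[2] * mid_shape[3]
            g_mid += (g_gap / hw)[:, :, None, None]

        if g_bottleneck_flat is not None:
            g_mid += np.ascontiguousarray(
                g_bottleneck_flat, dtype=DTYPE).reshape(mid_shape)

        g = self.mid.backward(g_mid)
        # n_skip_grads was collected shallowest-first; the encoder backward
        # walks deepest-first, so reverse the pairing
        skip_grads = list(reversed(n_skip_grads))
        for i, (blk, pool) in enumerate(zip(reversed(self.enc_blocks),
                                            reversed(self.pools))):
            g = pool.backward(g)
            if self.skips and i < len(skip_grads) and skip_grads[i] is not None:
                g = g + skip_grads[i]
            g = blk.backward(g)


class Teacher:
    """Auto-encoder teacher: reconstruction + pathology classification."""

    skip_connections = False

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        self.net = EncoderDecoder(cfg, skips=False, seed=seed)

    def forward(self, x: np.ndarray) -> TeacherOutput:
        out = self.net.forward(x)
        return TeacherOutput(
            reconstruction=sigmoid(out["dense_logits"]),
            recon_logits=out["dense_logits"],
            class_logits=out["class_logits"],
            bottleneck=out["bottleneck_flat"],
        )

    __call__ = forward

    def parameters(self):
        return self.net.parameters()

    def state_dict(self):
        return self.net.state_dict()

    def load_state_dict(self, state):
        self.net.load_state_dict(state)

    def checksum(self):
        return self.net.checksum()


class Student:
    """U-Net student: segmentation + auxiliary pathology classification."""

    skip_connections = True

    def __init__(self, cfg: NetConfig, seed: int = 0, skips: bool = True):
        self.cfg = cfg
        self.skip_connections = bool(skips)
        self.net = EncoderDecoder(cfg, skips=skips, seed=seed)

    def forward(self, x: np.ndarray) -> StudentOutput:
        out = self.net.forward(x)
        return StudentOutput(
            seg_logits=out["dense_logits"],
            class_logits=out["class_logits"],
            bottleneck=out["bottleneck_flat"],
        )

    __call__ = forward

    def parameters(self):
        return self.net.parameters()

    def state_dict(self):
        return self.net.state_dict()

    def load_state_dict(self, state):
        self.net.load_state_dict(state)

    def checksum(self):
        return self.net.checksum()


def build_teacher(cfg: NetConfig, seed: int = 0) -> Teacher:
    """Construct a teacher with seeded (reproducible) initialization."""
    return Teacher(cfg, seed=seed)


def build_student(cfg: NetConfig, seed: int = 0, skips: bool = True) -> Student:
    """Construct a student; ``skips=False`` degrades it to the teacher's
    skipless topology (used by the auto-encoder ablation arms)."""
    return Student(cfg, seed=seed, skips=skips)


def save_checkpoint(path: str, model: Teacher | Student) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(path: str, model: Teacher | Student) -> None:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})


def make_optimizer(model: Teacher | Student, lr: float = 1e-3) -> Adam:
    return Adam(model.parameters(), lr=lr)
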