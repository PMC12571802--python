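"""The radial-to-aortic sequence model.

The network G maps a normalized radial pressure sequence x(0..N) to a
normalized aortic estimate of identical length, with y^(n) depending only
on x(0..n): a stack of causal dilated convolutional residual blocks
(dilation 2^l at level l) with an attention stage inside each block, and a
1x1 convolution head that collapses the last level's channels to the
scalar pressure output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from ..errors import ValidationError
from .functional import receptive_field
from .layers import CausalConv1d, Param, ResidualBlock

logger = logging.getLogger("capwave")

ATTENTION_VARIANTS = ("channel", "temporal", "none")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``k`` is the convolution kernel size, ``num_levels`` the number of
    residual levels (dilation 2^l at level l), ``channels`` either one
    width shared by all levels or an explicit per-level list.  Stride is
    fixed at 1.  ``attention='none'`` reduces the architecture to the
    baseline TCN.
    """

    k: int = 2
    num_levels: int = 7
    channels: int | tuple[int, ...] = 16
    dropout: float = 0.2
    attention: str = "channel"
    attention_reduction: int = 4
    init_sd: float | None = None  # None -> He-scaled per layer

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"kernel size must be >= 1, got {self.k}")
        if self.num_levels < 1:
            raise ValidationError(f"num_levels must be >= 1, got {self.num_levels}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.attention not in ATTENTION_VARIANTS:
            raise ValidationError(f"attention must be one of {ATTENTION_VARIANTS}")
        if self.attention_reduction < 1:
            raise ValidationError("attention_reduction must be >= 1")
        if self.init_sd is not None and not self.init_sd > 0:
            raise ValidationError("init_sd must be positive or None (He-scaled)")
        if isinstance(self.channels, (list, tuple)):
            object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
            if len(self.channels) != self.num_levels:
                raise ValidationError("channels list must have num_levels entries")
            if any(c < 1 for c in self.channels):
                raise ValidationError("channel widths must be >= 1")
        elif int(self.channels) < 1:
            raise ValidationError("channel width must be >= 1")

    @property
    def channel_widths(self) -> tuple[int, ...]:
        if isinstance(self.channels, tuple):
            return self.channels
        return (int(self.channels),) * self.num_levels

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.k, self.num_levels)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        if isinstance(d.get("channels"), list):
            d["channels"] = tuple(d["channels"])
        return cls(**d)


class TCNAttention:
    """Stacked causal residual blocks with attention, plus a 1x1 output head.

    Parameters are initialized from zero-mean Gaussians using ``seed``
    (He-scaled per layer by default, or a fixed SD via ``config.init_sd``);
    the same seed also drives dropout, so training runs are reproducible.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self._rng = rng
        widths = config.channel_widths
        self.blocks: list[ResidualBlock] = []
        c_in = 1
        for level, c_out in enumerate(widths):
            self.blocks.append(ResidualBlock(
                c_in, c_out, config.k, 2 ** level, config.dropout,
                config.attention, config.attention_reduction, rng,
                name=f"block{level}", init_sd=config.init_sd,
            ))
            c_in = c_out
        self.head = CausalConv1d(c_in, 1, 1, 1, rng, name="head",
                                 weight_norm=False, init_sd=config.init_sd)
        self._warned_short_rf = False

    # -- parameter plumbing --------------------------------------------------
    def params(self) -> list[Param]:
        ps: list[Param] = []
        for block in self.blocks:
            ps.extend(block.params())
        ps.extend(self.head.params())
        return ps

    def named_params(self) -> dict[str, Param]:
        return {p.name: p for p in self.params()}

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    @property
    def receptive_field(self) -> int:
        return self.config.receptive_field

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map a normalized radial sequence to a normalized aortic estimate."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 1 or x.size == 0:
            raise ValidationError("model input must be a non-empty 1-D sequence")
        if self.receptive_field < x.size and not self._warned_short_rf:
            logger.warning(
                "receptive field %d is shorter than the input length %d; "
                "outputs use at most the last %d samples of history",
                self.receptive_field, x.size, self.receptive_field,
            )
            self._warned_short_rf = True
        h = x[None, :]
        for block in self.blocks:
            h = block.forward(h, training=training)
        y = self.head.forward(h, training=training)
        return y[0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients for the last forward pass; returns
        the gradient with respect to the input sequence."""
        g = self.head.backward(np.asarray(gy, dtype=np.float64)[None, :])
        for block in reversed(self.blocks):
            g = block.backward(g)
        return g[0]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)
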