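"""Amplitude normalization of pressure sequences.

Four per-sequence candidate schemes are provided (min-max to [0, 1],
z-score with population SD, mean normalization to [-0.5, 0.5], and unit L2
norm), plus the pipeline default: a *global* fixed-constant min-max map

    x~ = (x - a) / b,   a = 45 mmHg, b = 135 mmHg,

applied identically to radial inputs and aortic targets so both live on one
scale, with an exact affine inverse back to mmHg.  The per-sequence schemes
recompute their statistics per record and therefore cannot be inverted
consistently across a dataset; the fixed-constant map can, which is why it
is the scheme trained models embed in their checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "METHODS",
    "NormalizationScheme",
    "normalize",
    "global_minmax",
    "global_minmax_inverse",
]

METHODS = ("minmax", "zscore", "mean", "unitnorm", "global_minmax")

DEFAULT_A = 45.0   # mmHg offset of the global map
DEFAULT_B = 135.0  # mmHg scale of the global map


@dataclass(frozen=True)
class NormalizationScheme:
    """A named normalization method; ``a``/``b`` apply to ``global_minmax`` only."""

    method: str = "global_minmax"
    a: float = DEFAULT_A
    b: float = DEFAULT_B

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown normalization method {self.method!r}")
        if not self.b > 0:
            raise ValidationError(f"scale b must be > 0, got {self.b}")

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.method == "global_minmax":
            return global_minmax(x, self.a, self.b)
        return normalize(x, self.method)

    def invert(self, x_norm: np.ndarray) -> np.ndarray:
        if self.method != "global_minmax":
            raise ValidationError(
                f"{self.method!r} recomputes per-sequence statistics and has no "
                "dataset-consistent inverse; use method='global_minmax'"
            )
        return global_minmax_inverse(x_norm, self.a, self.b)


def _as_sequence(x, min_len: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < min_len:
        raise ValidationError(f"expected a 1-D sequence of length >= {min_len}")
    return x


def normalize(x, method: str) -> np.ndarray:
    """Apply one of the per-sequence normalizations.

    ``minmax``   maps to [0, 1]: (x - min) / (max - min)
    ``zscore``   standardizes to mean 0, population SD 1 (divisor N)
    ``mean``     maps to [-0.5, 0.5]: (x - mean) / (max - min)
    ``unitnorm`` scales to unit L2 norm

    Constant sequences (minmax/mean/zscore) and the zero sequence
    (unitnorm) are degenerate and rejected.
    """
    x = _as_sequence(x)
    if method == "minmax":
        span = x.max() - x.min()
        if span == 0:
            raise DegenerateInputError("constant sequence under min-max normalization")
        return (x - x.min()) / span
    if method == "zscore":
        sd = x.std()  # population SD, divisor N
        if sd == 0:
            raise DegenerateInputError("constant sequence under z-score normalization")
        return (x - x.mean()) / sd
    if method == "mean":
        span = x.max() - x.min()
        if span == 0:
            raise DegenerateInputError("constant sequence under mean normalization")
        return (x - x.mean()) / span
    if method == "unitnorm":
        nrm = np.linalg.norm(x)
        if nrm == 0:
            raise DegenerateInputError("zero sequence under unit-norm scaling")
        return x / nrm
    if method == "global_minmax":
        return global_minmax(x)
    raise ValidationError(f"unknown normalization method {method!r}")


def global_minmax(x, a: float = DEFAULT_A, b: float = DEFAULT_B) -> np.ndarray:
    """Fixed-constant map x~ = (x - a) / b, shared by inputs and targets.

    Out-of-range results (outside [0, 1]) pass through unchanged — the
    constants are fixed precisely so new records never change the scale.
    """
    if not b > 0:
        raise ValidationError(f"scale b must be > 0, got {b}")
    return (np.asarray(x, dtype=np.float64) - a) / b


def global_minmax_inverse(x_norm, a: float = DEFAULT_A, b: float = DEFAULT_B) -> np.ndarray:
    """Exact inverse of :func:`global_minmax`: x = a + b * x~."""
    if not b > 0:
        raise ValidationError(f"scale b must be > 0, got {b}")
    return a + b * np.asarray(x_norm, dtype=np.float64)
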