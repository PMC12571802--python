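"""Causal dilated convolution primitives and receptive-field arithmetic.

A causal dilated convolution computes

    F(n) = sum_{i=0..k-1} f(i) * x(n - d*i),    x(t) = 0 for t < 0,

so the output at time n depends only on inputs at times <= n.  Length
preservation is achieved by padding p = (k-1)*d zeros on each side,
convolving, and chomping the trailing p samples — which is arithmetically
identical to zero-padding the left side only.
"""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError

__all__ = ["causal_dilated_conv", "chomp", "receptive_field", "min_layers"]


def chomp(x, p: int) -> np.ndarray:
    """Remove the last ``p`` elements (the excess causal padding)."""
    x = np.asarray(x)
    p = int(p)
    if p < 0:
        raise ValidationError(f"chomp length must be >= 0, got {p}")
    if p > x.shape[-1]:
        raise ValidationError(f"cannot chomp {p} elements from length {x.shape[-1]}")
    return x[..., : x.shape[-1] - p]


def causal_dilated_conv(x, f, d: int = 1) -> np.ndarray:
    """Single-channel causal dilated convolution with length preservation.

    Pads ``p = (k-1)*d`` zeros on each side, runs the dilated filter over
    the padded sequence, and chomps ``p`` samples from the right, so the
    output has the input's length and equals the direct sum
    ``F(n) = sum_i f(i) x(n - d*i)``.
    """
    x = np.asarray(x, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 1 or f.size == 0:
        raise ValidationError("filter must be a non-empty 1-D array")
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("input must be a non-empty 1-D sequence")
    d = int(d)
    if d < 1:
        raise ValidationError(f"dilation must be >= 1, got {d}")
    k = f.size
    p = (k - 1) * d
    # dilated kernel: tap i sits at lag d*i
    g = np.zeros(p + 1)
    g[::d] = f
    padded = np.pad(x, p)
    full = np.convolve(padded, g, mode="valid")  # length N + p
    return chomp(full, p)


def receptive_field(k: int, L: int) -> int:
    """Receptive field of an L-level stack with dilations 2^l:
    R = 1 + (k-1)(2^L - 1)."""
    k, L = int(k), int(L)
    if k < 1:
        raise ValidationError(f"kernel size must be >= 1, got {k}")
    if L < 0:
        raise ValidationError(f"level count must be >= 0, got {L}")
    return 1 + (k - 1) * ((1 << L) - 1)


def min_layers(N: int, k: int) -> int:
    """Smallest L with receptive_field(k, L) >= N (full-history coverage)."""
    N, k = int(N), int(k)
    if N < 1:
        raise ValidationError(f"input length must be >= 1, got {N}")
    if k <= 1:
        raise ValidationError("kernel size must be >= 2 for the receptive field to grow")
    L = 0
    while receptive_field(k, L) < N:
        L += 1
    return L
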