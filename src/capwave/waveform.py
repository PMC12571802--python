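"""Uniformly sampled arterial pressure time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass(eq=False)
class PressureWaveform:
    """A pressure signal in mmHg sampled uniformly at ``fs`` samples/s.

    Parameters
    ----------
    values
        1-D array of pressures in mmHg.
    fs
        Sampling rate in samples per second (128 Hz for radial tonometry
        acquired with a SphygmoCor-class device).
    """

    values: np.ndarray
    fs: float = 128.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("waveform values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("waveform contains non-finite samples")
        if not (self.fs > 0):
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    # Clinical point features -------------------------------------------------
    @property
    def sbp(self) -> float:
        """Systolic pressure: waveform maximum (mmHg)."""
        return float(self.values.max())

    @property
    def dbp(self) -> float:
        """Diastolic pressure: waveform minimum (mmHg)."""
        return float(self.values.min())

    @property
    def map(self) -> float:
        """Mean arterial pressure: time average over the record (mmHg)."""
        return float(self.values.mean())

    def copy(self) -> "PressureWaveform":
        return PressureWaveform(self.values.copy(), self.fs)
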