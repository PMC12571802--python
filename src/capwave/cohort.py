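"""Synthetic paired radial/aortic pressure cohort generator.

The measurement cohort this package targets is not public, so every
downstream stage (normalization, model, training, evaluation) is exercised
against simulated subjects that reproduce the published cohort statistics:

* heart rate 67.5 +/- 9.8 bpm, radial SBP 119.8 +/- 15.0 mmHg, radial DBP
  75.1 +/- 9.8 mmHg;
* pulse pressure amplification: radial-minus-aortic SBP difference
  14.59 +/- 5.95 mmHg on [0, 43] mmHg;
* near-equal diastolic pressures: aortic-minus-radial DBP difference
  1.40 +/- 1.02 mmHg on [0.20, 14] mmHg.

Each subject gets a physiologic aortic beat template (systolic upstroke,
dicrotic wave, exponential diastolic decay); the radial waveform is derived
through a single-tube transmission-line (tube-load) model

    H(w) = (1 + G) e^{-i w tau} / (1 + G e^{-2 i w tau})

with reflection coefficient ``G`` and tube delay ``tau``, which produces the
pulse-pressure amplification phenomenon, and is then affinely recalibrated
so the radial SBP/DBP match the sampled cuff-style targets exactly.  The
aortic waveform is generated first and the radial waveform derived from it,
so the learning task (radial -> aortic) always has a well-defined target.

All truncated-normal location parameters are calibrated (by root finding)
so the *truncated* distributions have exactly the specified means; without
this the hard range limits — most visibly the [0.20, 14] mmHg bound on the
diastolic difference — would bias the realized cohort means away from the
published values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError
from .waveform import PressureWaveform

__all__ = [
    "CohortSpec",
    "ShapeParams",
    "SubjectParams",
    "PairedRecord",
    "Cohort",
    "sample_subject",
    "aortic_beat_shape",
    "tube_load_transfer",
    "generate_pair",
    "generate_cohort",
]

# Physiologic truncation bounds for the marginal draws (plausibility limits;
# the published cohort reports only means and SDs).
HR_BOUNDS = (40.0, 120.0)        # bpm
SBP_BOUNDS = (80.0, 200.0)       # mmHg, radial systolic
DBP_BOUNDS = (40.0, 110.0)       # mmHg, radial diastolic
PULSE_GAP = 20.0                 # enforced radial pulse pressure floor: DBP < SBP - 20
SBP_DBP_RHO = 0.7                # Gaussian-copula correlation between SBP and DBP draws
MIN_AORTIC_PP = 1.0              # mmHg; redraw amplification terms below this
TUBE_DELAY_RANGE = (0.03, 0.06)  # s
REFLECTION_RANGE = (0.3, 0.7)    # dimensionless


def _pair(name: str, value: tuple[float, float]) -> tuple[float, float]:
    m, s = float(value[0]), float(value[1])
    if not s > 0:
        raise ValidationError(f"{name}: SD must be > 0, got {s}")
    return (m, s)


def _interval(name: str, value: tuple[float, float]) -> tuple[float, float]:
    lo, hi = float(value[0]), float(value[1])
    if not lo <= hi:
        raise ValidationError(f"{name}: interval must satisfy lo <= hi, got {value}")
    return (lo, hi)


@dataclass(frozen=True)
class CohortSpec:
    """Distribution parameters the simulator samples subjects from.

    Defaults reproduce the published cohort statistics (means +/- SD and
    hard ranges); ``noise_sd`` is additive Gaussian measurement noise in
    mmHg applied after feature bookkeeping, so stored subject features
    always describe the noise-free waveforms.
    """

    hr_mean_sd: tuple[float, float] = (67.5, 9.8)
    sbp_mean_sd: tuple[float, float] = (119.8, 15.0)
    dbp_mean_sd: tuple[float, float] = (75.1, 9.8)
    sbp_amp_mean_sd: tuple[float, float] = (14.59, 5.95)
    sbp_amp_range: tuple[float, float] = (0.0, 43.0)
    dbp_diff_mean_sd: tuple[float, float] = (1.40, 1.02)
    dbp_diff_range: tuple[float, float] = (0.20, 14.0)
    fs: float = 128.0
    beats_per_record: int = 8
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("hr_mean_sd", "sbp_mean_sd", "dbp_mean_sd",
                     "sbp_amp_mean_sd", "dbp_diff_mean_sd"):
            object.__setattr__(self, name, _pair(name, getattr(self, name)))
        for name in ("sbp_amp_range", "dbp_diff_range"):
            object.__setattr__(self, name, _interval(name, getattr(self, name)))
        if not self.fs > 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if int(self.beats_per_record) < 1:
            raise ValidationError("beats_per_record must be >= 1")
        object.__setattr__(self, "beats_per_record", int(self.beats_per_record))
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


@dataclass(frozen=True)
class ShapeParams:
    """Dimensionless aortic beat morphology knobs (times as beat fractions)."""

    peak_time: float = 0.30       # systolic peak location
    decay_tau: float = 0.17       # diastolic exponential decay constant
    dicrotic_amp: float = 0.12    # dicrotic wave amplitude (relative to pulse height)
    dicrotic_frac: float = 0.20   # dicrotic peak delay after the systolic peak
    dicrotic_width: float = 0.04  # dicrotic wave Gaussian width

    def __post_init__(self) -> None:
        if not (self.peak_time > 0 and self.decay_tau > 0 and self.dicrotic_width > 0):
            raise ValidationError(
                "degenerate beat shape: peak_time, decay_tau and dicrotic_width "
                "must all be > 0"
            )
        if self.dicrotic_amp < 0 or self.dicrotic_frac < 0:
            raise ValidationError("dicrotic amplitude/delay must be >= 0")


@dataclass(frozen=True)
class SubjectParams:
    """One simulated subject: pressures in mmHg, heart rate in bpm."""

    heart_rate: float
    radial_sbp: float
    radial_dbp: float
    aortic_sbp: float
    aortic_dbp: float
    tube_delay: float
    reflection_coeff: float
    shape_params: ShapeParams = field(default_factory=ShapeParams)

    def __post_init__(self) -> None:
        if not self.radial_dbp < self.radial_sbp:
            raise ValidationError("radial DBP must be below radial SBP")
        if not self.aortic_dbp < self.aortic_sbp:
            raise ValidationError("aortic DBP must be below aortic SBP")
        if not 0 <= abs(self.reflection_coeff) < 1:
            raise ValidationError("|reflection_coeff| must be < 1")


@dataclass(eq=False)
class PairedRecord:
    """Aligned radial (model input) and aortic (model target) waveforms."""

    radial: PressureWaveform
    aortic: PressureWaveform
    subject: SubjectParams
    record_id: str

    def __post_init__(self) -> None:
        if self.radial.n_samples != self.aortic.n_samples:
            raise ValidationError("radial and aortic waveforms must have equal length")
        if self.radial.fs != self.aortic.fs:
            raise ValidationError("radial and aortic waveforms must share one fs")


@dataclass(eq=False)
class Cohort:
    """A generated cohort plus the provenance needed to regenerate it."""

    records: list[PairedRecord]
    spec: CohortSpec
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PairedRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


# --------------------------------------------------------------------------
# Moment-matched truncated-normal sampling
# --------------------------------------------------------------------------

def _trunc_mean(mu, sd: float, lo, hi):
    a = (np.asarray(lo) - mu) / sd
    b = (np.asarray(hi) - mu) / sd
    return stats.truncnorm.mean(a, b, loc=mu, scale=sd)


@lru_cache(maxsize=None)
def _matched_loc(target: float, sd: float, lo: float, hi: float) -> float:
    """Location mu such that N(mu, sd) truncated to [lo, hi] has mean `target`."""
    if not lo < target < hi:
        raise ValidationError(
            f"target mean {target} must lie strictly inside the range [{lo}, {hi}]"
        )
    return float(optimize.brentq(
        lambda mu: _trunc_mean(mu, sd, lo, hi) - target,
        lo - 10.0 * sd, hi + 10.0 * sd, xtol=1e-10,
    ))


def _trunc_draw(rng: np.random.Generator, mu, sd, lo, hi) -> float:
    """Inverse-CDF draw from a truncated normal (exactly one uniform consumed)."""
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(stats.truncnorm.ppf(rng.uniform(), a, b, loc=mu, scale=sd))


@lru_cache(maxsize=None)
def _dbp_shift(sbp_mean: float, sbp_sd: float, dbp_mean: float, dbp_sd: float) -> float:
    """Offset added to the conditional DBP mean so the realized DBP marginal
    mean equals `dbp_mean` despite truncation to [40, min(110, SBP-20)]."""
    mu_sbp = _matched_loc(sbp_mean, sbp_sd, *SBP_BOUNDS)
    a = (SBP_BOUNDS[0] - mu_sbp) / sbp_sd
    b = (SBP_BOUNDS[1] - mu_sbp) / sbp_sd
    s = np.linspace(*SBP_BOUNDS, 801)
    w = stats.truncnorm.pdf(s, a, b, loc=mu_sbp, scale=sbp_sd)
    w = w / w.sum()
    cond_sd = dbp_sd * np.sqrt(1.0 - SBP_DBP_RHO ** 2)
    cond_mu = dbp_mean + SBP_DBP_RHO * (dbp_sd / sbp_sd) * (s - sbp_mean)
    hi = np.minimum(DBP_BOUNDS[1], s - PULSE_GAP)

    def realized_mean(delta: float) -> float:
        return float(np.sum(w * _trunc_mean(cond_mu + delta, cond_sd, DBP_BOUNDS[0], hi)))

    return float(optimize.brentq(lambda d: realized_mean(d) - dbp_mean, -20.0, 20.0,
                                 xtol=1e-9))


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def sample_subject(spec: CohortSpec, rng: np.random.Generator) -> SubjectParams:
    """Draw one subject's hemodynamic parameters.

    Heart rate, radial SBP and radial DBP come from truncated normals with
    the cohort moments (HR on [40, 120] bpm, SBP on [80, 200] mmHg, DBP on
    [40, 110] mmHg with DBP < SBP - 20).  The systolic amplification and
    diastolic difference come from truncated normals over their stated
    ranges; the pair is redrawn if it would leave an aortic pulse pressure
    below 1 mmHg.  Tube delay is uniform on [0.03, 0.06] s and the
    reflection coefficient uniform on [0.3, 0.7].
    """
    if not isinstance(spec, CohortSpec):
        raise ValidationError("spec must be a CohortSpec")

    hr_m, hr_s = spec.hr_mean_sd
    sbp_m, sbp_s = spec.sbp_mean_sd
    dbp_m, dbp_s = spec.dbp_mean_sd

    hr = _trunc_draw(rng, _matched_loc(hr_m, hr_s, *HR_BOUNDS), hr_s, *HR_BOUNDS)
    sbp = _trunc_draw(rng, _matched_loc(sbp_m, sbp_s, *SBP_BOUNDS), sbp_s, *SBP_BOUNDS)

    cond_sd = dbp_s * np.sqrt(1.0 - SBP_DBP_RHO ** 2)
    cond_mu = (dbp_m + SBP_DBP_RHO * (dbp_s / sbp_s) * (sbp - sbp_m)
               + _dbp_shift(sbp_m, sbp_s, dbp_m, dbp_s))
    dbp = _trunc_draw(rng, cond_mu, cond_sd,
                      DBP_BOUNDS[0], min(DBP_BOUNDS[1], sbp - PULSE_GAP))

    amp_m, amp_s = spec.sbp_amp_mean_sd
    diff_m, diff_s = spec.dbp_diff_mean_sd
    mu_amp = _matched_loc(amp_m, amp_s, *spec.sbp_amp_range)
    mu_diff = _matched_loc(diff_m, diff_s, *spec.dbp_diff_range)
    for _ in range(1000):
        dsbp = _trunc_draw(rng, mu_amp, amp_s, *spec.sbp_amp_range)
        ddbp = _trunc_draw(rng, mu_diff, diff_s, *spec.dbp_diff_range)
        if (sbp - dsbp) - (dbp + ddbp) >= MIN_AORTIC_PP:
            break
    else:  # pragma: no cover - probability ~0 under the defaults
        raise ValidationError("could not sample a physiologic amplification pair")

    shape = ShapeParams(
        peak_time=rng.uniform(0.25, 0.35),
        decay_tau=rng.uniform(0.12, 0.22),
        dicrotic_amp=rng.uniform(0.08, 0.18),
        dicrotic_frac=rng.uniform(0.15, 0.25),
        dicrotic_width=rng.uniform(0.03, 0.05),
    )
    return SubjectParams(
        heart_rate=hr,
        radial_sbp=sbp,
        radial_dbp=dbp,
        aortic_sbp=sbp - dsbp,
        aortic_dbp=dbp + ddbp,
        tube_delay=rng.uniform(*TUBE_DELAY_RANGE),
        reflection_coeff=rng.uniform(*REFLECTION_RANGE),
        shape_params=shape,
    )


def aortic_beat_shape(subject: SubjectParams, fs: float,
                      n_samples_per_beat: int) -> np.ndarray:
    """Unit-amplitude aortic beat template on [0, 1].

    Starts at 0 (end-diastole), rises along a half-cosine upstroke to a
    single dominant systolic peak at ``peak_time`` (within the first 40% of
    the beat), decays exponentially with constant ``decay_tau`` through
    diastole, carries a secondary dicrotic bump, and is rescaled so
    max = 1 and min = 0 exactly.
    """
    if n_samples_per_beat < 16:
        raise ValidationError("n_samples_per_beat must be >= 16")
    p = subject.shape_params
    t = np.arange(n_samples_per_beat) / n_samples_per_beat
    rising = t <= p.peak_time
    base = np.where(
        rising,
        0.5 * (1.0 - np.cos(np.pi * np.minimum(t, p.peak_time) / p.peak_time)),
        np.exp(-(t - p.peak_time) / p.decay_tau),
    )
    td = p.peak_time + p.dicrotic_frac
    s = base + p.dicrotic_amp * np.exp(-0.5 * ((t - td) / p.dicrotic_width) ** 2)
    s = s - s.min()
    s = s / s.max()
    return s


def tube_load_transfer(aortic: PressureWaveform, tube_delay: float,
                       reflection_coeff: float) -> PressureWaveform:
    """Propagate a (beat-periodic) aortic waveform down a uniform tube.

    Applies the single-tube transmission model
    ``H(w) = (1 + G) e^{-i w tau} / (1 + G e^{-2 i w tau})`` in the
    frequency domain via the discrete Fourier transform (the record is
    treated as periodic).  Only the *shape* of the output is consumed
    downstream — the radial waveform is affinely recalibrated to its
    sampled SBP/DBP targets afterwards.
    """
    g = float(reflection_coeff)
    tau = float(tube_delay)
    if abs(g) >= 1.0:
        raise ValidationError(f"|reflection_coeff| must be < 1 (got {g}): unstable tube")
    if tau < 0:
        raise ValidationError("tube_delay must be >= 0")
    x = aortic.values
    n = x.size
    omega = 2.0 * np.pi * np.fft.rfftfreq(n, d=1.0 / aortic.fs)
    e = np.exp(-1j * omega * tau)
    h = (1.0 + g) * e / (1.0 + g * e ** 2)
    y = np.fft.irfft(np.fft.rfft(x) * h, n=n)
    return PressureWaveform(y, aortic.fs)


def generate_pair(subject: SubjectParams, spec: CohortSpec,
                  rng: np.random.Generator, record_id: str = "r0") -> PairedRecord:
    """Build one subject's aligned aortic/radial record.

    The aortic waveform is ``aDBP + (aSBP - aDBP) * shape`` tiled for
    ``beats_per_record`` identical beats of duration 60/HR seconds; the
    radial waveform is the tube-load output affinely rescaled so its max and
    min equal the sampled radial SBP/DBP exactly.  Gaussian measurement
    noise (``spec.noise_sd`` mmHg) is added after the calibration, so the
    stored subject parameters describe the noise-free waveforms.
    """
    n_beat = int(round(spec.fs * 60.0 / subject.heart_rate))
    shape = aortic_beat_shape(subject, spec.fs, n_beat)
    tiled = np.tile(shape, spec.beats_per_record)
    aortic = PressureWaveform(
        subject.aortic_dbp + (subject.aortic_sbp - subject.aortic_dbp) * tiled,
        spec.fs,
    )
    raw = tube_load_transfer(aortic, subject.tube_delay, subject.reflection_coeff)
    r = raw.values
    span = r.max() - r.min()
    radial_vals = (subject.radial_dbp
                   + (subject.radial_sbp - subject.radial_dbp) * (r - r.min()) / span)
    aortic_vals = aortic.values
    if spec.noise_sd > 0:
        radial_vals = radial_vals + rng.normal(0.0, spec.noise_sd, radial_vals.size)
        aortic_vals = aortic_vals + rng.normal(0.0, spec.noise_sd, aortic_vals.size)
    return PairedRecord(
        radial=PressureWaveform(radial_vals, spec.fs),
        aortic=PressureWaveform(aortic_vals, spec.fs),
        subject=subject,
        record_id=record_id,
    )


def generate_cohort(n: int, spec: CohortSpec | None = None, seed: int = 0) -> Cohort:
    """Generate ``n`` independent paired records, reproducible from ``seed``."""
    if n <= 0:
        raise ValidationError(f"cohort size must be positive, got {n}")
    spec = spec if spec is not None else CohortSpec()
    if not isinstance(spec, CohortSpec):
        raise ValidationError("spec must be a CohortSpec")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        subject = sample_subject(spec, rng)
        records.append(generate_pair(subject, spec, rng, record_id=f"rec{i:05d}"))
    return Cohort(records=records, spec=spec, seed=int(seed))
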