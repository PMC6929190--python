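"""Synthetic cardiac signals with analytically known fiducial points.

Every beat is a sum of Gaussian waves placed inside one beat period.  For ECG
the five waves are P, Q, R, S and T; for PPG a positive systolic wave P and a
negative valley wave V after it.  Because the waves are Gaussians, the exact
sample index of every peak — and of every onset/offset, defined as the wave
center minus/plus three standard deviations — is known in closed form, which
makes the generator suitable as ground truth for the fiducial detector.

The generator is not a physiological simulator: it produces a strictly
periodic, noiseless morphology to which white noise, sinusoidal baseline
wander and mains interference can be added.  All randomness flows through
explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .signal import Signal


@dataclass(frozen=True)
class Wave:
    """One Gaussian component of a beat: center/width in seconds, amplitude in mV."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ParameterError(f"wave width must be > 0, got {self.width}")

    @property
    def onset(self) -> float:
        """Start of the wave, center - 3 sigma (covers >99% of the energy)."""
        return self.center - 3.0 * self.width

    @property
    def offset(self) -> float:
        """End of the wave, center + 3 sigma."""
        return self.center + 3.0 * self.width


@dataclass(frozen=True)
class BeatTemplate:
    """Per-subject beat morphology.

    ``waves`` maps wave names to :class:`Wave` components.  ECG templates carry
    P, Q, R, S, T (centers strictly ordered within the beat); PPG templates
    carry P (systolic peak) and V (valley, negative amplitude).
    """

    waves: dict[str, Wave]
    heart_rate: float = 60.0
    kind: str = "ecg"

    def __post_init__(self):
        if not 30.0 <= self.heart_rate <= 200.0:
            raise ParameterError(f"heart_rate must be in [30, 200] bpm, got {self.heart_rate}")
        if self.kind == "ecg":
            order = ["P", "Q", "R", "S", "T"]
            if list(self.waves) != order and set(self.waves) == set(order):
                object.__setattr__(self, "waves", {k: self.waves[k] for k in order})
            if set(self.waves) != set(order):
                raise ParameterError(f"ECG template needs waves {order}, got {list(self.waves)}")
            centers = [self.waves[k].center for k in order]
            if not all(a < b for a, b in zip(centers, centers[1:])):
                raise ParameterError("ECG wave centers must be strictly ordered P<Q<R<S<T")
        elif self.kind == "ppg":
            if set(self.waves) != {"P", "V"}:
                raise ParameterError("PPG template needs waves P and V")
            if not self.waves["P"].center < self.waves["V"].center:
                raise ParameterError("PPG systolic peak must precede the valley")
        else:
            raise ParameterError(f"template kind must be 'ecg' or 'ppg', got {self.kind!r}")

    @property
    def period(self) -> float:
        """Beat period in seconds."""
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination: white noise, baseline wander, mains interference."""

    white_sd: float = 0.0
    baseline_amp: float = 0.0
    baseline_freq: float = 0.3
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0
    seed: int = 0

    def __post_init__(self):
        for name in ("white_sd", "baseline_amp", "powerline_amp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("baseline_freq", "powerline_freq"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def silent(self) -> bool:
        return self.white_sd == 0 and self.baseline_amp == 0 and self.powerline_amp == 0


# Lead-I-like default morphology at 60 bpm: R at 0.37 s with 1.0 mV, small
# narrow Q/S flanks, low broad P and T.  Gaussian tails of neighbouring waves
# at each center are < 0.005 mV, so analytic fiducials match signal extrema.
def default_ecg_template(heart_rate: float = 60.0) -> BeatTemplate:
    """Default single-beat ECG morphology (amplitudes in mV, times in seconds)."""
    return BeatTemplate(
        waves={
            "P": Wave(0.200, 0.020, 0.15),
            "Q": Wave(0.345, 0.008, -0.12),
            "R": Wave(0.370, 0.007, 1.00),
            "S": Wave(0.395, 0.008, -0.18),
            "T": Wave(0.600, 0.040, 0.30),
        },
        heart_rate=heart_rate,
        kind="ecg",
    )


def default_ppg_template(heart_rate: float = 60.0) -> BeatTemplate:
    """Default PPG morphology: systolic peak plus a later negative valley wave."""
    return BeatTemplate(
        waves={
            "P": Wave(0.300, 0.045, 1.00),
            "V": Wave(0.620, 0.050, -0.25),
        },
        heart_rate=heart_rate,
        kind="ppg",
    )


def _beat_waveform(template: BeatTemplate, n: int, fs: float) -> np.ndarray:
    """Clean periodic waveform of ``n`` samples built from the template."""
    t = np.arange(n) / fs
    phase = np.mod(t, template.period)
    x = np.zeros(n)
    for w in template.waves.values():
        x += w.amplitude * np.exp(-0.5 * ((phase - w.center) / w.width) ** 2)
    return x


def _noise(spec: NoiseSpec, n: int, fs: float) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n) / fs
    out = np.zeros(n)
    if spec.white_sd > 0:
        out += rng.normal(0.0, spec.white_sd, size=n)
    if spec.baseline_amp > 0:
        out += spec.baseline_amp * np.sin(2 * np.pi * spec.baseline_freq * t)
    if spec.powerline_amp > 0:
        out += spec.powerline_amp * np.sin(2 * np.pi * spec.powerline_freq * t)
    return out


def _fiducial_table(template: BeatTemplate, n: int, fs: float) -> list[dict[str, int]]:
    """Exact fiducial sample indices for every complete beat in ``n`` samples."""
    period = template.period
    n_beats = int(np.floor(n / (period * fs) + 1e-9))
    beats = []
    if template.kind == "ecg":
        points = {name: w.center for name, w in template.waves.items()}
        points["PB"] = template.waves["P"].onset
        points["PE"] = template.waves["P"].offset
        points["TB"] = template.waves["T"].onset
        points["TE"] = template.waves["T"].offset
    else:
        points = {
            "P": template.waves["P"].center,
            "V": template.waves["V"].center,
            "PS": template.waves["P"].onset,
            "PD": template.waves["P"].offset,
            "VS": template.waves["V"].onset,
            "VD": template.waves["V"].offset,
        }
    for b in range(n_beats):
        beat = {name: int(round((b * period + t0) * fs)) for name, t0 in points.items()}
        if all(0 <= i < n for i in beat.values()):
            beats.append(beat)
    return beats


def _make(template, duration, fs, noise, kind) -> tuple[Signal, list[dict[str, int]]]:
    if duration <= 0 or fs <= 0:
        raise ParameterError("duration and fs must be positive")
    n = int(round(duration * fs))
    if n < template.period * fs:
        raise ParameterError(
            f"duration {duration} s is shorter than one beat period {template.period} s"
        )
    x = _beat_waveform(template, n, fs)
    if noise is not None and not noise.silent:
        x = x + _noise(noise, n, fs)
    return Signal(x, fs, kind=kind), _fiducial_table(template, n, fs)


def make_ecg(
    template: BeatTemplate | None = None,
    duration: float = 10.0,
    fs: float = 500.0,
    noise: NoiseSpec | None = None,
) -> tuple[Signal, list[dict[str, int]]]:
    """Generate a periodic sum-of-Gaussians ECG plus exact per-beat fiducials.

    Returns the signal and, per complete beat, the sample indices of P, Q, R,
    S, T centers and of the analytic onsets/offsets PB, PE, TB, TE (center
    +- 3 sigma).  Deterministic given the noise seed.
    """
    template = template if template is not None else default_ecg_template()
    if template.kind != "ecg":
        raise ParameterError("make_ecg needs an ECG template")
    return _make(template, duration, fs, noise, "ecg")


def make_ppg(
    template: BeatTemplate | None = None,
    duration: float = 10.0,
    fs: float = 500.0,
    noise: NoiseSpec | None = None,
) -> tuple[Signal, list[dict[str, int]]]:
    """Generate a periodic PPG plus exact per-beat fiducials (P, V, PS, PD, VS, VD)."""
    template = template if template is not None else default_ppg_template()
    if template.kind != "ppg":
        raise ParameterError("make_ppg needs a PPG template")
    return _make(template, duration, fs, noise, "ppg")


def make_population(
    n_subjects: int,
    jitter: float = 0.05,
    seed: int = 0,
    base: BeatTemplate | None = None,
) -> list[BeatTemplate]:
    """Draw ``n_subjects`` beat templates around a base morphology.

    Amplitudes, widths, heart rate and the wave positions *relative to the
    anchor wave* (R for ECG, P for PPG) receive independent multiplicative
    jitter ~ N(1, jitter); jittering relative offsets rather than absolute
    centers preserves the wave ordering for every draw.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    if jitter < 0:
        raise ParameterError("jitter must be >= 0")
    base = base if base is not None else default_ecg_template()
    anchor = "R" if base.kind == "ecg" else "P"
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        def j():
            return max(0.2, 1.0 + jitter * rng.standard_normal())

        hr = float(np.clip(base.heart_rate * j(), 30.0, 200.0))
        c_anchor = base.waves[anchor].center * j()
        waves = {}
        for name, w in base.waves.items():
            if name == anchor:
                c = c_anchor
            else:
                c = c_anchor + (w.center - base.waves[anchor].center) * j()
            waves[name] = Wave(c, w.width * j(), w.amplitude * j())
        out.append(BeatTemplate(waves=waves, heart_rate=hr, kind=base.kind))
    return out


def make_ksparse(
    n: int,
    k: int,
    amplitude_range: tuple[float, float] = (0.5, 1.5),
    seed: int = 0,
) -> np.ndarray:
    """Coefficient vector of length ``n`` with exactly ``k`` nonzeros.

    Support drawn uniformly without replacement; magnitudes uniform in
    ``amplitude_range`` with random signs.
    """
    if not 1 <= k <= n:
        raise ParameterError(f"need 1 <= k <= n, got k={k}, n={n}")
    lo, hi = amplitude_range
    if not 0 < lo <= hi:
        raise ParameterError("amplitude_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    support = rng.choice(n, size=k, replace=False)
    theta = np.zeros(n)
    theta[support] = rng.uniform(lo, hi, size=k) * rng.choice([-1.0, 1.0], size=k)
    return theta
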