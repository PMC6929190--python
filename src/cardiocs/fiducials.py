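"""Wavelet-assisted fiducial-point detection for ECG and PPG beats.

R peaks are located as modulus maxima of a mid-scale undecimated wavelet
detail band (about 15-30 Hz at 500 Hz, where QRS energy concentrates) above
an adaptive threshold — a fraction of the band's maximum — with a refractory
window, then refined to the local extremum of the raw signal.  The remaining
ECG points are found in physiology-motivated windows around each R: Q and S
as the nearest local minima within +-60 ms, P as the maximum in (-280, -80) ms,
T as the maximum in (80, 450) ms.  Wave onsets/offsets (PB/PE, TB/TE) are the
nearest samples where the wave falls below a fraction (default 10%) of its
peak amplitude relative to the local baseline (the record median).

PPG systolic peaks are detected directly with the same adaptive-threshold /
refractory rule, the valley V as the minimum between consecutive peaks, and
PS/PD, VS/VD by the same fractional-crossing rule.

Every threshold is relative, so detection is invariant to amplitude scaling.
Beats whose search windows fall outside the record are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
import scipy.signal

from .errors import DetectionError
from .signal import Signal

ECG_ORDER = ("PB", "P", "PE", "Q", "R", "S", "TB", "T", "TE")


@dataclass(frozen=True)
class FiducialConfig:
    """Detection windows (seconds) and relative thresholds."""

    peak_threshold_frac: float = 0.3
    refractory: float = 0.25
    qs_window: float = 0.06
    p_window: tuple[float, float] = (-0.28, -0.08)
    t_window: tuple[float, float] = (0.08, 0.45)
    onset_frac: float = 0.10
    wavelet: str = "coif3"


@dataclass
class FiducialSet:
    """Per-beat fiducial sample indices.

    ECG beats carry P, Q, R, S, T plus onsets/offsets PB, PE, TB, TE with the
    ordering PB <= P <= PE <= Q <= R <= S <= TB <= T <= TE; PPG beats carry
    P, V, PS, PD, VS, VD with PS <= P <= PD and VS <= V <= VD.
    """

    beats: list[dict[str, int]]
    fs: float
    kind: str = "ecg"
    #: mean anchor-to-anchor interval (seconds) over *all* detected peaks,
    #: including edge beats too incomplete to yield a fiducial dict
    anchor_interval: float | None = None

    def __post_init__(self):
        for beat in self.beats:
            if self.kind == "ecg":
                seq = [beat[k] for k in ECG_ORDER]
                if not all(a <= b for a, b in zip(seq, seq[1:])):
                    raise DetectionError(f"ECG fiducial ordering violated: {beat}")
            else:
                if not beat["PS"] <= beat["P"] <= beat["PD"]:
                    raise DetectionError(f"PPG P-wave ordering violated: {beat}")
                if not beat["VS"] <= beat["V"] <= beat["VD"]:
                    raise DetectionError(f"PPG valley ordering violated: {beat}")

    def __len__(self) -> int:
        return len(self.beats)

    def indices(self, name: str) -> np.ndarray:
        return np.array([b[name] for b in self.beats], dtype=int)


def _qrs_band_envelope(x: np.ndarray, fs: float, wavelet: str) -> np.ndarray:
    """|detail| of the undecimated wavelet level whose band covers ~15-30 Hz."""
    level = max(1, int(round(np.log2(fs / 22.5))))
    pad = (-len(x)) % 2**level
    xp = np.pad(x, (0, pad), mode="edge")
    coeffs = pywt.swt(xp, wavelet, level=level, trim_approx=True, norm=True)
    detail = coeffs[1]  # deepest detail level
    return np.abs(detail[: len(x)])


def _detect_anchor_peaks(
    x: np.ndarray, fs: float, cfg: FiducialConfig, use_wavelet: bool
) -> np.ndarray:
    """Adaptive-threshold peak detection with a refractory window."""
    env = _qrs_band_envelope(x, fs, cfg.wavelet) if use_wavelet else x - np.median(x)
    span = float(env.max())
    if span <= 0:
        raise DetectionError("flat signal: no peaks found")
    distance = max(1, int(round(cfg.refractory * fs)))
    peaks, _ = scipy.signal.find_peaks(env, height=cfg.peak_threshold_frac * span, distance=distance)
    if peaks.size == 0:
        raise DetectionError("no peaks above the adaptive threshold")
    if not use_wavelet:
        return peaks
    # refine each envelope maximum to the raw-signal extremum nearby
    half = max(1, int(round(0.04 * fs)))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # re-apply the refractory rule after refinement
    keep = [int(refined[0])]
    for p in refined[1:]:
        if p - keep[-1] >= distance:
            keep.append(int(p))
        elif x[p] > x[keep[-1]]:
            keep[-1] = int(p)
    return np.asarray(keep, dtype=int)


def _cross_left(x, peak, baseline, frac, limit) -> int:
    """Walk left from a wave peak to the fractional-amplitude crossing."""
    amp = x[peak] - baseline
    i = peak
    while i > limit:
        if abs(x[i - 1] - baseline) <= frac * abs(amp):
            return i - 1
        i -= 1
    return limit


def _cross_right(x, peak, baseline, frac, limit) -> int:
    amp = x[peak] - baseline
    i = peak
    while i < limit:
        if abs(x[i + 1] - baseline) <= frac * abs(amp):
            return i + 1
        i += 1
    return limit


def detect_ecg_fiducials(signal: Signal, config: FiducialConfig | None = None) -> FiducialSet:
    """Locate P, Q, R, S, T and the P/T onsets and offsets for every beat.

    Expects a denoised signal with at least one full beat; raises
    :class:`DetectionError` when no R peak is found.
    """
    cfg = config if config is not None else FiducialConfig()
    x, fs = signal.samples, signal.fs
    r_peaks = _detect_anchor_peaks(x, fs, cfg, use_wavelet=True)
    baseline = float(np.median(x))
    s = lambda sec: int(round(sec * fs))
    beats = []
    for r in r_peaks:
        lo_p, hi_p = r + s(cfg.p_window[0]), r + s(cfg.p_window[1])
        lo_t, hi_t = r + s(cfg.t_window[0]), r + s(cfg.t_window[1])
        left_edge = r + s(cfg.p_window[0] - 0.07)
        right_edge = r + s(cfg.t_window[1] + 0.15)
        if left_edge < 0 or right_edge >= len(x):
            continue  # incomplete beat at a record edge
        q = r - s(cfg.qs_window) + int(np.argmin(x[r - s(cfg.qs_window) : r]))
        s_pt = r + 1 + int(np.argmin(x[r + 1 : r + s(cfg.qs_window) + 1]))
        p = lo_p + int(np.argmax(x[lo_p : hi_p + 1]))
        t = lo_t + int(np.argmax(x[lo_t : hi_t + 1]))
        beat = {
            "R": int(r), "Q": int(q), "S": int(s_pt), "P": int(p), "T": int(t),
            "PB": _cross_left(x, p, baseline, cfg.onset_frac, left_edge),
            "PE": _cross_right(x, p, baseline, cfg.onset_frac, q - 1),
            "TB": _cross_left(x, t, baseline, cfg.onset_frac, s_pt + 1),
            "TE": _cross_right(x, t, baseline, cfg.onset_frac, right_edge),
        }
        beats.append(beat)
    if not beats:
        raise DetectionError(
            f"no complete beat detected in signal {signal.subject_id or '<unnamed>'}"
        )
    interval = float(np.mean(np.diff(r_peaks))) / fs if r_peaks.size >= 2 else None
    return FiducialSet(beats=beats, fs=fs, kind="ecg", anchor_interval=interval)


def detect_ppg_fiducials(signal: Signal, config: FiducialConfig | None = None) -> FiducialSet:
    """Locate the systolic peak P, valley V, and their onsets/offsets per beat.

    V is the minimum between consecutive systolic peaks, so the last
    (successor-less) peak yields no beat.
    """
    cfg = config if config is not None else FiducialConfig()
    x, fs = signal.samples, signal.fs
    peaks = _detect_anchor_peaks(x, fs, cfg, use_wavelet=False)
    if peaks.size < 2:
        raise DetectionError("need at least two systolic peaks to delimit a PPG beat")
    baseline = float(np.median(x))
    beats = []
    for p, p_next in zip(peaks[:-1], peaks[1:]):
        v = p + 1 + int(np.argmin(x[p + 1 : p_next]))
        left_edge = max(0, p - int(round(0.35 * fs)))
        beat = {
            "P": int(p), "V": int(v),
            "PS": _cross_left(x, p, baseline, cfg.onset_frac, left_edge),
            "PD": _cross_right(x, p, baseline, cfg.onset_frac, v - 1),
            "VS": _cross_left(x, v, baseline, cfg.onset_frac, p + 1),
            "VD": _cross_right(x, v, baseline, cfg.onset_frac, p_next - 1),
        }
        beats.append(beat)
    interval = float(np.mean(np.diff(peaks))) / fs
    return FiducialSet(beats=beats, fs=fs, kind="ppg", anchor_interval=interval)
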