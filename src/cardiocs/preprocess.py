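"""Wavelet denoising of raw cardiac signals.

The denoiser is a multilevel DWT (coif3 by default) with universal soft
thresholding of the detail coefficients: the noise scale is estimated from
the finest detail level as sigma = median(|d1|) / 0.6745 and every detail
level is shrunk by t = sigma * sqrt(2 ln n).  Optionally the deepest
approximation is zeroed, which removes baseline wander below roughly
fs / 2^(levels+1) Hz (< 1 Hz at 500 Hz with the default 8 levels) and stands
in for an analog high-pass stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ParameterError
from .signal import Signal


@dataclass(frozen=True)
class DenoiseConfig:
    wavelet_name: str = "coif3"
    levels: int = 8
    threshold_rule: str = "universal"
    threshold_mode: str = "soft"  # or "hard"
    remove_baseline: bool = False

    def __post_init__(self):
        if self.levels < 1:
            raise ParameterError("levels must be >= 1")
        if self.threshold_rule != "universal":
            raise ParameterError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_mode not in ("soft", "hard"):
            raise ParameterError("threshold_mode must be 'soft' or 'hard'")


def denoise(signal: Signal, config: DenoiseConfig | None = None) -> Signal:
    """Wavelet-threshold denoise; output has the input's length."""
    cfg = config if config is not None else DenoiseConfig()
    x = signal.samples
    if x.size < 2**cfg.levels:
        raise ParameterError(
            f"signal of {x.size} samples is too short for {cfg.levels} decomposition levels"
        )
    # clip the depth to what the record length supports without boundary artifacts
    levels = min(cfg.levels, pywt.dwt_max_level(x.size, cfg.wavelet_name))
    levels = max(1, levels)
    coeffs = pywt.wavedec(x, cfg.wavelet_name, level=levels, mode="symmetric")
    d1 = coeffs[-1]
    sigma = float(np.median(np.abs(d1))) / 0.6745
    t = sigma * np.sqrt(2.0 * np.log(x.size))
    out = [coeffs[0]]
    if cfg.remove_baseline:
        out[0] = np.zeros_like(coeffs[0])
    for d in coeffs[1:]:
        out.append(pywt.threshold(d, t, mode=cfg.threshold_mode) if t > 0 else d)
    y = pywt.waverec(out, cfg.wavelet_name, mode="symmetric")[: x.size]
    return signal.with_samples(y)
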