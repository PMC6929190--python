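"""In-memory container for a single-channel sampled biosignal."""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

VALID_KINDS = ("ecg", "ppg", "generic")


class Signal:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : array-like
        Sample values; mV for ECG, arbitrary units for PPG.
    fs : float
        Sampling rate in Hz (strictly positive).
    subject_id : str, optional
        Identity label used by the identification stage.
    kind : {"ecg", "ppg", "generic"}
    """

    def __init__(self, samples, fs, subject_id: str | None = None, kind: str = "generic"):
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ParameterError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ParameterError("samples must be finite")
        if not np.isscalar(fs) or not np.isfinite(fs) or fs <= 0:
            raise ParameterError(f"fs must be a positive scalar, got {fs!r}")
        if kind not in VALID_KINDS:
            raise ParameterError(f"kind must be one of {VALID_KINDS}, got {kind!r}")
        self.samples = samples
        self.fs = float(fs)
        self.subject_id = subject_id
        self.kind = kind

    def __len__(self) -> int:
        return self.samples.size

    def __repr__(self) -> str:
        return (
            f"Signal(n={self.samples.size}, fs={self.fs:g} Hz, kind={self.kind!r},"
            f" subject_id={self.subject_id!r})"
        )

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples) -> "Signal":
        """Copy of this signal with the sample array replaced."""
        return Signal(samples, self.fs, subject_id=self.subject_id, kind=self.kind)
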