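"""Distance/amplitude feature vectors for biometric identification.

Each beat yields a fixed-length named vector: 21 entries for ECG (15
distances + 6 amplitudes) and 12 for PPG (8 + 4).  Distance features are
absolute index differences converted to seconds and divided by the record's
mean RR interval (mean P-P for PPG), which removes the heart-rate dependence;
amplitude features are signed sample-value differences, value at the first
named point minus value at the second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .fiducials import FiducialSet
from .signal import Signal

logger = logging.getLogger(__name__)

ECG_DISTANCE_PAIRS = [
    ("R", "Q"), ("R", "S"), ("R", "P"), ("R", "PB"), ("R", "PE"),
    ("R", "T"), ("R", "TB"), ("R", "TE"), ("PB", "PE"), ("TB", "TE"),
    ("Q", "P"), ("S", "T"), ("P", "T"), ("Q", "PB"), ("S", "TE"),
]
ECG_AMPLITUDE_PAIRS = [
    ("Q", "R"), ("S", "R"), ("PB", "P"), ("P", "Q"), ("T", "TB"), ("T", "S"),
]
PPG_DISTANCE_PAIRS = [
    ("P", "PS"), ("P", "PD"), ("P", "V"), ("P", "VS"), ("P", "VD"),
    ("VS", "VD"), ("PD", "V"), ("PD", "VD"),
]
PPG_AMPLITUDE_PAIRS = [("PS", "P"), ("P", "PD"), ("V", "VS"), ("PD", "V")]


def feature_names(kind: str) -> list[str]:
    """Ordered feature names: distances first, then amplitudes."""
    if kind == "ecg":
        dist, amp = ECG_DISTANCE_PAIRS, ECG_AMPLITUDE_PAIRS
    elif kind == "ppg":
        dist, amp = PPG_DISTANCE_PAIRS, PPG_AMPLITUDE_PAIRS
    else:
        raise ParameterError(f"kind must be 'ecg' or 'ppg', got {kind!r}")
    return [f"d_{a}-{b}" for a, b in dist] + [f"a_{a}-{b}" for a, b in amp]


@dataclass
class FeatureVector:
    """One beat's named features (21 for ECG, 12 for PPG)."""

    names: list[str]
    values: np.ndarray
    kind: str
    subject_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = 21 if self.kind == "ecg" else 12
        if len(self.names) != expected or self.values.size != expected:
            raise DataError(f"{self.kind} feature vector must have {expected} entries")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature values must be finite")


def mean_rr(fiducials: FiducialSet) -> float:
    """Mean beat-to-beat interval in seconds (R-R for ECG, P-P for PPG).

    Prefers the detector's anchor interval, which also counts edge beats too
    incomplete to carry a full fiducial set.
    """
    if fiducials.anchor_interval is not None:
        return float(fiducials.anchor_interval)
    anchor = "R" if fiducials.kind == "ecg" else "P"
    idx = fiducials.indices(anchor)
    if idx.size < 2:
        raise DataError("need at least two beats to estimate the mean RR interval")
    return float(np.mean(np.diff(np.sort(idx)))) / fiducials.fs


def extract_features(
    fiducials: FiducialSet,
    signal: Signal,
    aggregate: str = "per-beat",
) -> list[FeatureVector]:
    """Assemble the named feature vectors, one per complete beat.

    ``aggregate="mean"`` returns a single vector averaging all beats.  Beats
    with a missing or non-finite fiducial are excluded (counted in the log).
    """
    if aggregate not in ("per-beat", "mean"):
        raise ParameterError("aggregate must be 'per-beat' or 'mean'")
    kind = fiducials.kind
    if kind == "ecg":
        dist_pairs, amp_pairs = ECG_DISTANCE_PAIRS, ECG_AMPLITUDE_PAIRS
    else:
        dist_pairs, amp_pairs = PPG_DISTANCE_PAIRS, PPG_AMPLITUDE_PAIRS
    required = {p for pair in dist_pairs + amp_pairs for p in pair}
    names = feature_names(kind)
    rr = mean_rr(fiducials)
    x, fs = signal.samples, signal.fs

    vectors, skipped = [], 0
    for beat in fiducials.beats:
        if not required <= beat.keys() or not all(
            0 <= beat[p] < len(x) for p in required
        ):
            skipped += 1
            continue
        dist = [abs(beat[a] - beat[b]) / fs / rr for a, b in dist_pairs]
        amp = [float(x[beat[a]] - x[beat[b]]) for a, b in amp_pairs]
        vectors.append(
            FeatureVector(names=names, values=np.array(dist + amp), kind=kind,
                          subject_id=signal.subject_id)
        )
    if skipped:
        logger.warning("%d beat(s) had incomplete fiducials and were excluded", skipped)
    if not vectors:
        raise DataError("no complete beat produced a feature vector")
    if aggregate == "mean":
        mean = np.mean([v.values for v in vectors], axis=0)
        return [FeatureVector(names=names, values=mean, kind=kind,
                              subject_id=signal.subject_id)]
    return vectors


def features_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """One row per beat, named feature columns plus the subject label."""
    if not vectors:
        raise DataError("no feature vectors")
    rows = [dict(zip(v.names, v.values), subject_id=v.subject_id) for v in vectors]
    return pd.DataFrame(rows)
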