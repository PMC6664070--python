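"""Band-pass filtering, trial windowing, and the inter-subject set protocol.

The cross-subject protocol partitions each subject's 280 trials into 10
contiguous, equal subsets and pairs subset i of the training subject with
subset i of the test subject: 10 directed "inter-subject sets" of 28 train +
28 test trials.  Reversing the subject roles is a distinct experiment.

Pipeline order is fixed: filter the full trial, then extract the analysis
window — filtering after windowing would smear edge transients into the
short epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import Trial, TrialSet

__all__ = [
    "FilterSpec",
    "InterSubjectSet",
    "bandpass",
    "extract_window",
    "split_into_sets",
    "build_intersubject_sets",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass design: 8-40 Hz, order 10, zero-phase."""

    low_hz: float = 8.0
    high_hz: float = 40.0
    order: int = 10
    family: str = "butterworth"

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.family != "butterworth":
            raise ValueError("only Butterworth filters are supported")

    def sos(self, sample_rate: float) -> np.ndarray:
        nyq = sample_rate / 2.0
        if self.high_hz >= nyq:
            raise ValueError(
                f"high corner {self.high_hz} Hz >= Nyquist {nyq} Hz"
            )
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass",
            fs=sample_rate, output="sos",
        )


def bandpass(trials: TrialSet, spec: FilterSpec = FilterSpec()) -> TrialSet:
    """Zero-phase (forward-backward) band-pass of every trial and baseline.

    Realized as cascaded second-order sections; the contract is the magnitude
    response (unity in-band, strong stop-band rejection), not coefficient
    values.  The forward-backward pass doubles the effective order and
    cancels group delay, keeping the cue alignment intact.
    """
    sos = spec.sos(trials.sample_rate)

    def apply(m: np.ndarray) -> np.ndarray:
        # cap the edge padding for short segments (e.g. 0.5 s baselines)
        padlen = min(3 * (2 * sos.shape[0] + 1), m.shape[-1] - 1)
        return sps.sosfiltfilt(sos, m, axis=-1, padlen=padlen)

    return trials.map_data(apply)


def extract_window(trial: Trial, start_s: float = 0.5, dur_s: float = 2.5) -> Trial:
    """Half-open sample window [round(start*fs), round((start+dur)*fs))."""
    fs = trial.sample_rate
    a = int(round(start_s * fs))
    b = int(round((start_s + dur_s) * fs))
    if a < 0 or b > trial.n_samples or b <= a:
        raise IndexError(
            f"window [{a}, {b}) outside trial of {trial.n_samples} samples"
        )
    return trial.with_data(trial.data[:, a:b])


def window_trials(trials: TrialSet, start_s: float = 0.5, dur_s: float = 2.5) -> TrialSet:
    return TrialSet(extract_window(t, start_s, dur_s) for t in trials)


def split_into_sets(X: TrialSet, n_sets: int = 10) -> list[TrialSet]:
    """Contiguous, disjoint, equal-size partition in recorded order."""
    n = len(X)
    if n % n_sets:
        raise ValueError(f"{n} trials not divisible into {n_sets} sets")
    size = n // n_sets
    subsets = [X[i * size : (i + 1) * size] for i in range(n_sets)]
    for i, s in enumerate(subsets):
        counts = s.class_counts()
        if len(set(counts.values())) > 1:
            log.info("subset %d class-imbalanced: %s", i + 1, counts)
    return subsets


@dataclass(frozen=True)
class InterSubjectSet:
    """One directed protocol set: train on subject X's subset, test on Y's."""

    train: TrialSet
    test: TrialSet
    set_index: int  # 1-based

    def __post_init__(self) -> None:
        if set(self.train.subject_ids) & set(self.test.subject_ids):
            raise ValueError("train and test subjects must differ")
        if len(self.train) != len(self.test):
            raise ValueError("train/test subsets must be equal-sized")


def build_intersubject_sets(
    X: TrialSet, Y: TrialSet, n_sets: int = 10
) -> list[InterSubjectSet]:
    """Pair subset i of X (train) with subset i of Y (test), i = 1..n_sets."""
    if len(X) != len(Y):
        raise ValueError("both subjects need the same trial count")
    xs = split_into_sets(X, n_sets)
    ys = split_into_sets(Y, n_sets)
    return [
        InterSubjectSet(x, y, i + 1) for i, (x, y) in enumerate(zip(xs, ys))
    ]
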