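"""Core data containers: montage, head model, trials.

A :class:`Trial` is one labeled multichannel epoch (channels x samples, in
microvolts) together with its pre-cue baseline segment; a :class:`TrialSet` is
an ordered, shape-homogeneous collection of trials and is the currency passed
between every pipeline stage.  The :class:`HeadModel` carries the forward
operator ``G`` (lead field) that maps dipolar cortical source currents to
scalp electrode potentials, ``M = G J + E``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["Montage", "HeadModel", "Trial", "TrialSet"]


@dataclass(frozen=True)
class Montage:
    """Electrode montage: channel names and 3D positions (unit-sphere scale)."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (q, 3)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(names) < 2:
            raise ValueError("montage needs at least 2 channels")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if pos.shape != (len(names), 3):
            raise ValueError(f"positions shape {pos.shape} != ({len(names)}, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def subset(self, indices: Sequence[int]) -> "Montage":
        idx = list(indices)
        return Montage(
            tuple(self.channel_names[i] for i in idx), self.positions[idx]
        )


@dataclass(frozen=True)
class HeadModel:
    """Distributed-dipole forward model.

    ``lead_field`` is the q-channels x r-sources matrix G (microvolt per unit
    dipole moment); each source carries a fixed unit orientation, normal-ish
    to the local surface of the source shell.
    """

    source_positions: np.ndarray  # (r, 3)
    source_orientations: np.ndarray  # (r, 3), unit rows
    lead_field: np.ndarray  # (q, r)
    montage: Montage

    def __post_init__(self) -> None:
        pos = np.asarray(self.source_positions, dtype=float)
        ori = np.asarray(self.source_orientations, dtype=float)
        G = np.asarray(self.lead_field, dtype=float)
        object.__setattr__(self, "source_positions", pos)
        object.__setattr__(self, "source_orientations", ori)
        object.__setattr__(self, "lead_field", G)
        r = pos.shape[0]
        if pos.shape != (r, 3) or ori.shape != (r, 3):
            raise ValueError("source positions/orientations must be (r, 3)")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("source orientations must have unit norm")
        if G.shape != (self.montage.n_channels, r):
            raise ValueError(
                f"lead field shape {G.shape} != ({self.montage.n_channels}, {r})"
            )
        if not np.all(np.isfinite(G)):
            raise ValueError("lead field must be finite")

    @property
    def n_channels(self) -> int:
        return self.montage.n_channels

    @property
    def n_sources(self) -> int:
        return self.source_positions.shape[0]

    def restrict_channels(self, indices: Sequence[int]) -> "HeadModel":
        idx = list(indices)
        return HeadModel(
            self.source_positions,
            self.source_orientations,
            self.lead_field[idx],
            self.montage.subset(idx),
        )


@dataclass(frozen=True)
class Trial:
    """One labeled epoch: data (q x tau), pre-cue baseline (q x tau_b), both in uV."""

    data: np.ndarray
    label: int
    subject_id: str
    baseline: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        base = np.asarray(self.baseline, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "baseline", base)
        if data.ndim != 2 or data.shape[1] < 1:
            raise ValueError("trial data must be (q, tau) with tau > 0")
        if base.ndim != 2 or base.shape[1] < 1:
            raise ValueError("baseline must be (q, tau_b) with tau_b > 0")
        if base.shape[0] != data.shape[0]:
            raise ValueError("baseline channel count differs from data")
        if not np.all(np.isfinite(data)):
            raise ValueError("trial data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, baseline: np.ndarray | None = None) -> "Trial":
        return replace(self, data=data, baseline=self.baseline if baseline is None else baseline)

    def restrict_channels(self, indices: Sequence[int]) -> "Trial":
        idx = list(indices)
        return replace(self, data=self.data[idx], baseline=self.baseline[idx])


class TrialSet:
    """Ordered collection of trials sharing channel count, length and rate."""

    def __init__(self, trials: Iterable[Trial]):
        self.trials: list[Trial] = list(trials)
        if not self.trials:
            raise ValueError("TrialSet cannot be empty")
        t0 = self.trials[0]
        for t in self.trials:
            if t.n_channels != t0.n_channels or t.n_samples != t0.n_samples:
                raise ValueError("all trials must share (q, tau)")
            if t.sample_rate != t0.sample_rate:
                raise ValueError("all trials must share the sample rate")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return TrialSet(self.trials[i])
        return self.trials[i]

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def n_samples(self) -> int:
        return self.trials[0].n_samples

    @property
    def sample_rate(self) -> float:
        return self.trials[0].sample_rate

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=int)

    @property
    def subject_ids(self) -> list[str]:
        return [t.subject_id for t in self.trials]

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def of_class(self, label: int) -> "TrialSet":
        sel = [t for t in self.trials if t.label == label]
        if not sel:
            raise ValueError(f"no trials with label {label}")
        return TrialSet(sel)

    def select(self, indices: Sequence[int]) -> "TrialSet":
        return TrialSet(self.trials[i] for i in indices)

    def restrict_channels(self, indices: Sequence[int]) -> "TrialSet":
        idx = list(indices)
        return TrialSet(t.restrict_channels(idx) for t in self.trials)

    def data_array(self) -> np.ndarray:
        """Stack trial data into (n_trials, q, tau)."""
        return np.stack([t.data for t in self.trials])

    def baseline_array(self) -> np.ndarray:
        return np.stack([t.baseline for t in self.trials])

    def map_data(self, func) -> "TrialSet":
        """Apply ``func(matrix) -> matrix`` to every trial's data and baseline."""
        return TrialSet(
            replace(t, data=func(t.data), baseline=func(t.baseline))
            for t in self.trials
        )

    def __add__(self, other: "TrialSet") -> "TrialSet":
        return TrialSet(self.trials + other.trials)
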