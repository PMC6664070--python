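"""Toy forward model and synthetic two-subject motor-imagery EEG.

The generator emulates the structure of a two-class, 280-trials-per-subject
motor-imagery recording: 118 electrodes on the upper unit hemisphere, 600
dipolar sources on an inner shell, class-specific compact source patches
carrying a band-limited oscillation (default 10-13 Hz, inside the 8-40 Hz
analysis band), additive Gaussian sensor noise, and a signal-free pre-cue
baseline segment per trial.  A ``shared_fraction`` knob controls how much of
the two subjects' class-specific active source sets coincide — the
"inter-subject associativity" that the downstream pipeline is designed to
detect.

Lead-field kernel (fixed, documented):
    g(c, s) = (o_s . u_cs) / (||p_c - p_s||^2 + eps),   u_cs = (p_c - p_s)/||p_c - p_s||
with eps = 0.01.  This is a distance-decay dipole-projection kernel: nearby,
radially oriented sources dominate the closest electrodes, neighboring
sources produce correlated scalp topographies, and with r > q the inverse
problem stays under-determined — the regime MEM regularization targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import HeadModel, Montage, Trial, TrialSet

__all__ = ["SynthConfig", "build_toy_headmodel", "simulate_subject_pair", "default_active_sets"]

_KERNEL_EPS = 0.01
SOURCE_SHELL_RADIUS = 0.8


def _fibonacci_hemisphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Quasi-uniform points on the upper hemisphere (z >= 0)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = (i + 0.5) / n  # upper hemisphere only
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z**2)
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return radius * pts


def build_toy_headmodel(
    n_channels: int = 118, n_sources: int = 600, rng_seed: int = 0
) -> HeadModel:
    """Desk-scale forward model: electrodes on the unit upper hemisphere,
    sources on an inner shell (radius 0.8) with radial-plus-jitter unit
    orientations, and the documented distance-decay lead-field kernel.
    """
    if n_channels < 2 or n_sources < 1:
        raise ValueError("n_channels must be >= 2 and n_sources >= 1")
    rng = np.random.default_rng(rng_seed)
    elec = _fibonacci_hemisphere(n_channels, 1.0)
    src = _fibonacci_hemisphere(n_sources, SOURCE_SHELL_RADIUS)
    radial = src / np.linalg.norm(src, axis=1, keepdims=True)
    ori = radial + 0.15 * rng.standard_normal(src.shape)
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)

    diff = elec[:, None, :] - src[None, :, :]  # (q, r, 3)
    dist = np.linalg.norm(diff, axis=2)
    unit = diff / dist[..., None]
    proj = np.einsum("qrk,rk->qr", unit, ori)
    G = proj / (dist**2 + _KERNEL_EPS)

    names = tuple(f"E{i:03d}" for i in range(n_channels))
    return HeadModel(src, ori, G, Montage(names, elec))


@dataclass
class SynthConfig:
    """Stated world of the synthetic experiment.

    Defaults mirror the emulated recording: 2 subjects, 140 trials per class
    (280 per subject), 3.5 s trials at 100 Hz with a 0.5 s pre-cue baseline,
    mu-band (10-13 Hz) oscillatory sources.  ``active_source_sets`` may pin
    the active source indices explicitly as
    ``{class_label: {subject_index: [indices]}}``; otherwise compact patches
    are drawn from ``rng_seed`` with ``shared_fraction`` of each class's
    patch common to both subjects.
    """

    n_subjects: int = 2
    n_trials_per_class: int = 140
    classes: tuple[int, int] = (1, 2)
    active_source_sets: dict | None = None
    n_active_per_class: int = 8
    shared_fraction: float = 1.0
    source_amplitude: float = 1.0  # uV * moment
    target_snr: float | None = None  # overrides amplitude when set
    oscillation_band: tuple[float, float] = (10.0, 13.0)
    equalize_power: bool = True  # normalize each patch's scalp topography
    noise_sd: float = 1.0  # uV
    sample_rate: float = 100.0
    trial_dur_s: float = 3.5
    baseline_dur_s: float = 0.5
    cue_onset_s: float = 0.5  # signal occupies [cue_onset, trial_dur - 0.5]
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.n_trials_per_class < 1 or self.n_subjects < 1:
            raise ValueError("counts must be positive")
        if self.n_active_per_class < 1:
            raise ValueError("n_active_per_class must be >= 1")


def _patch(head: HeadModel, seed_source: int, size: int) -> list[int]:
    """Compact patch: the seed source plus its nearest neighbors."""
    d = np.linalg.norm(head.source_positions - head.source_positions[seed_source], axis=1)
    return np.argsort(d, kind="stable")[:size].tolist()


def default_active_sets(head: HeadModel, cfg: SynthConfig) -> dict:
    """Draw per-(class, subject) active source sets honoring shared_fraction.

    Each class gets a compact shared patch; the non-shared remainder of each
    subject's set is a disjoint subject-specific patch drawn well away from
    the other patches.  Returns {class: {subject: sorted index list}}.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n_shared = int(round(cfg.shared_fraction * cfg.n_active_per_class))
    n_own = cfg.n_active_per_class - n_shared
    taken: set[int] = set()
    out: dict = {}

    def far_seed() -> int:
        # seed far from everything already used, with random tie-breaking
        cand = rng.permutation(head.n_sources)
        if not taken:
            return int(cand[0])
        taken_pos = head.source_positions[sorted(taken)]
        d = np.linalg.norm(
            head.source_positions[cand][:, None, :] - taken_pos[None, :, :], axis=2
        ).min(axis=1)
        return int(cand[np.argmax(d)])

    for cls in cfg.classes:
        shared = _patch(head, far_seed(), n_shared) if n_shared else []
        taken.update(shared)
        out[cls] = {}
        for subj in range(cfg.n_subjects):
            own = _patch(head, far_seed(), n_own) if n_own else []
            taken.update(own)
            out[cls][subj] = sorted(set(shared) | set(own))
    return out


def _oscillation(n_sig: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    """Amplitude-modulated sinusoid, random frequency in band, random phase."""
    f = rng.uniform(*band)
    phi = rng.uniform(0, 2 * np.pi)
    t = np.arange(n_sig) / fs
    envelope = np.hanning(n_sig)
    return envelope * np.sin(2 * np.pi * f * t + phi)


def _signal_window(cfg: SynthConfig) -> tuple[int, int]:
    fs = cfg.sample_rate
    start = int(round(cfg.cue_onset_s * fs))
    stop = int(round((cfg.trial_dur_s - 0.5) * fs))
    return start, stop


def _class_topography(head: HeadModel, indices, equalize: bool = True) -> np.ndarray:
    """Summed scalp topography of a patch, normalized to the mean single-
    column lead-field norm.  The normalization equalizes signal power across
    (class, subject) patches so that class membership is encoded in the
    spatial pattern, not in overall amplitude — an amplitude imbalance would
    be a trivially transferable cue unrelated to associativity."""
    col = head.lead_field[:, list(indices)].sum(axis=1)
    norm = np.linalg.norm(col)
    if not equalize or norm == 0:
        return col
    scale = float(np.mean(np.linalg.norm(head.lead_field, axis=0)))
    return col * (scale / norm)


def _mean_signal_power(head: HeadModel, cfg: SynthConfig, active: dict) -> float:
    """Expected per-sample, per-channel signal power over the active window
    at unit source amplitude (analytic over phase/envelope, averaged over
    the frequency draw only implicitly — the envelope dominates)."""
    start, stop = _signal_window(cfg)
    n_sig = stop - start
    env2 = np.mean(np.hanning(n_sig) ** 2) * 0.5  # E[sin^2] over phase
    powers = []
    for cls in cfg.classes:
        for subj in range(cfg.n_subjects):
            col = _class_topography(head, active[cls][subj], cfg.equalize_power)
            powers.append(np.mean(col**2) * env2)
    return float(np.mean(powers))


def simulate_subject_pair(
    head: HeadModel, cfg: SynthConfig
) -> tuple[TrialSet, TrialSet]:
    """Simulate two subjects' labeled trial sets from the forward model.

    Every trial is ``G J(t) + E(t)`` where J(t) is nonzero only on the
    (class, subject) active set and carries one coherent band-limited
    oscillation per trial; E(t) is iid Gaussian with sd ``noise_sd``.
    Baselines contain noise only.
    """
    if cfg.n_subjects != 2:
        raise ValueError("simulate_subject_pair generates exactly 2 subjects")
    active = cfg.active_source_sets or default_active_sets(head, cfg)
    for cls in cfg.classes:
        for subj in range(cfg.n_subjects):
            idx = active.get(cls, {}).get(subj)
            if not idx:
                raise ValueError(f"empty active set for class {cls}, subject {subj}")
            if max(idx) >= head.n_sources:
                raise ValueError("active source index out of range")

    amplitude = cfg.source_amplitude
    if cfg.target_snr is not None:
        p_sig = _mean_signal_power(head, cfg, active)
        if p_sig <= 0:
            raise ValueError("degenerate active sets: zero mean signal power")
        noise_p = cfg.noise_sd**2
        if noise_p == 0:
            raise ValueError("target_snr requires noise_sd > 0")
        amplitude = float(np.sqrt(cfg.target_snr * noise_p / p_sig))

    rng = np.random.default_rng(cfg.rng_seed)
    fs = cfg.sample_rate
    tau = int(round(cfg.trial_dur_s * fs))
    tau_b = int(round(cfg.baseline_dur_s * fs))
    start, stop = _signal_window(cfg)

    subjects: list[TrialSet] = []
    for subj in range(2):
        trials: list[Trial] = []
        for cls in cfg.classes:
            gsum = _class_topography(head, active[cls][subj], cfg.equalize_power)
            for _ in range(cfg.n_trials_per_class):
                data = cfg.noise_sd * rng.standard_normal((head.n_channels, tau))
                osc = amplitude * _oscillation(stop - start, fs, cfg.oscillation_band, rng)
                data[:, start:stop] += np.outer(gsum, osc)
                baseline = cfg.noise_sd * rng.standard_normal((head.n_channels, tau_b))
                trials.append(
                    Trial(data, cls, f"S{subj + 1}", baseline, fs)
                )
        # interleave classes so contiguous protocol subsets stay balanced
        order = np.argsort(
            np.r_[
                np.arange(cfg.n_trials_per_class) * 2,
                np.arange(cfg.n_trials_per_class) * 2 + 1,
            ],
            kind="stable",
        )
        subjects.append(TrialSet([trials[i] for i in order]))
    return subjects[0], subjects[1]
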