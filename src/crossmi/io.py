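"""HDF5 trial-set container and a plain epoch-array import adapter.

Layout of the HDF5 container (one file per subject or pooled set):

    /trials        (n, q, tau)  float64, uV
    /labels        (n,)         int
    /subject_ids   (n,)         UTF-8 strings
    /baseline      (n, q, tau_b) float64
    /sample_rate   scalar
    /montage/names     (q,) strings        [optional]
    /montage/positions (q, 3) float64      [optional]

Data arrays round-trip bit-exactly.  The import adapter reads a plain
array file (.npy) plus a JSON sidecar carrying labels/rate metadata, for
epochs exported from standard EEG toolchains; native EDF/BrainVision parsing
is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import Montage, Trial, TrialSet

__all__ = ["save_trialset", "load_trialset", "load_epochs"]


def save_trialset(
    path, trials: TrialSet, montage: Montage | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=trials.data_array())
        f.create_dataset("labels", data=trials.labels)
        f.create_dataset(
            "subject_ids",
            data=np.array(trials.subject_ids, dtype=h5py.string_dtype()),
        )
        f.create_dataset("baseline", data=trials.baseline_array())
        f["sample_rate"] = float(trials.sample_rate)
        if montage is not None:
            grp = f.create_group("montage")
            grp.create_dataset(
                "names",
                data=np.array(montage.channel_names, dtype=h5py.string_dtype()),
            )
            grp.create_dataset("positions", data=montage.positions)


def load_trialset(path) -> tuple[TrialSet, Montage | None]:
    with h5py.File(path, "r") as f:
        data = f["trials"][...]
        labels = f["labels"][...]
        sids = [s.decode() if isinstance(s, bytes) else s for s in f["subject_ids"][...]]
        base = f["baseline"][...]
        fs = float(f["sample_rate"][()])
        montage = None
        if "montage" in f:
            names = tuple(
                s.decode() if isinstance(s, bytes) else s
                for s in f["montage/names"][...]
            )
            montage = Montage(names, f["montage/positions"][...])
    trials = TrialSet(
        Trial(data[i], int(labels[i]), sids[i], base[i], fs)
        for i in range(data.shape[0])
    )
    return trials, montage


def load_epochs(array_path, sidecar_path) -> TrialSet:
    """Import adapter: (n, q, tau) array in .npy plus a JSON sidecar.

    Sidecar keys: ``labels`` (n ints), ``subject_id`` (string or n strings),
    ``sample_rate`` (Hz), ``baseline_samples`` (int: the first samples of
    each epoch form the pre-cue baseline).
    """
    arr = np.load(array_path)
    if arr.ndim != 3:
        raise ValueError("epoch array must be (n_trials, q, tau)")
    meta = json.loads(Path(sidecar_path).read_text())
    labels = meta["labels"]
    if len(labels) != arr.shape[0]:
        raise ValueError("labels length mismatch")
    sid = meta["subject_id"]
    sids = [sid] * arr.shape[0] if isinstance(sid, str) else list(sid)
    fs = float(meta["sample_rate"])
    nb = int(meta["baseline_samples"])
    if not 0 < nb < arr.shape[2]:
        raise ValueError("baseline_samples must split the epoch")
    return TrialSet(
        Trial(arr[i, :, nb:], int(labels[i]), sids[i], arr[i, :, :nb], fs)
        for i in range(arr.shape[0])
    )
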