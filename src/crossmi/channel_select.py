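"""Automated inter-subject associative channel selection.

Maps each class's most active localized sources to nearby electrodes
(radial scalp projection + Euclidean radius) and takes the per-class union
as the selected channel set.  This replaces manual inspection of source
maps with an explicit, deterministic criterion: an energy quantile picks the
active sources, a distance radius picks the electrodes above them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .containers import HeadModel
from .wmem import SourceEstimate

__all__ = [
    "ChannelSelection",
    "active_sources",
    "sources_to_channels",
    "select_channels",
]

log = logging.getLogger(__name__)

DEFAULT_ENERGY_QUANTILE = 0.95
DEFAULT_RADIUS = 0.25  # in head-radius units (electrode shell radius 1)


@dataclass
class ChannelSelection:
    """Per-class and union channel index sets plus the parameters used."""

    per_class: dict[int, np.ndarray]
    union: np.ndarray
    energy_quantile: float
    radius: float

    def counts(self) -> dict:
        """Table-style counts: one entry per class plus the union total."""
        out = {f"class_{c}": int(len(v)) for c, v in self.per_class.items()}
        out["total"] = int(len(self.union))
        return out

    def to_json(self) -> str:
        payload = {
            **{f"class_{c}": v.tolist() for c, v in self.per_class.items()},
            "union": self.union.tolist(),
            "params": {
                "energy_quantile": self.energy_quantile,
                "radius": self.radius,
            },
        }
        return json.dumps(payload, indent=2)


def active_sources(
    est: SourceEstimate, energy_quantile: float = DEFAULT_ENERGY_QUANTILE
) -> np.ndarray:
    """Sources in the top (1 - quantile) tail of the nonzero-energy map.

    Deterministic tie-break toward the lower source index; empty only when
    the estimate is identically zero.
    """
    if not (0.0 <= energy_quantile < 1.0):
        raise ValueError("energy_quantile must be in [0, 1)")
    e = np.asarray(est.energy, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("energy map must be finite")
    nz = np.flatnonzero(e > 0)
    if nz.size == 0:
        log.warning("active_sources: all-zero energy map, empty selection")
        return np.array([], dtype=int)
    # round before ceil: (1 - 0.95) * 600 is 30.000000000000004 in floats
    k = max(1, int(np.ceil(np.round((1.0 - energy_quantile) * nz.size, 9))))
    order = nz[np.lexsort((nz, -e[nz]))]
    return np.sort(order[:k])


def sources_to_channels(
    sources, head: HeadModel, radius: float = DEFAULT_RADIUS
) -> np.ndarray:
    """Electrodes within ``radius`` of the scalp projection of any source.

    Sources are projected radially onto the electrode shell (mean electrode
    radius).  If the radius captures no electrode at all, the single nearest
    electrode of each source is selected instead, so a non-empty source set
    always yields at least one channel.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    src = np.asarray(list(sources), dtype=int)
    if src.size == 0:
        return np.array([], dtype=int)
    elec = head.montage.positions
    shell = float(np.mean(np.linalg.norm(elec, axis=1)))
    pos = head.source_positions[src]
    proj = pos / np.linalg.norm(pos, axis=1, keepdims=True) * shell
    d = np.linalg.norm(elec[:, None, :] - proj[None, :, :], axis=2)  # (q, m)
    sel = np.flatnonzero((d <= radius).any(axis=1))
    if sel.size == 0:
        sel = np.unique(np.argmin(d, axis=0))
    return np.sort(sel)


def select_channels(
    est_class1: SourceEstimate,
    est_class2: SourceEstimate,
    head: HeadModel,
    energy_quantile: float = DEFAULT_ENERGY_QUANTILE,
    radius: float = DEFAULT_RADIUS,
) -> ChannelSelection:
    """Per-class active-source channels and their union.

    The union of the two class-specific channel sets is the operating channel
    set for the subject pair; per-class counts are logged in the same
    class-1 / class-2 / total layout used to report montage reductions.
    """
    per_class: dict[int, np.ndarray] = {}
    for cls, est in ((1, est_class1), (2, est_class2)):
        ch = sources_to_channels(
            active_sources(est, energy_quantile), head, radius
        )
        per_class[cls] = ch
    union = np.union1d(per_class[1], per_class[2])
    if union.size == 0:
        raise ValueError("channel selection is empty; pipeline cannot proceed")
    sel = ChannelSelection(per_class, union, energy_quantile, radius)
    log.info("selected channels: %s", sel.counts())
    return sel
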