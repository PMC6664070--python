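"""Cross-subject evaluation harness: run directed pairs, tabulate results.

Thin protocol layer over :class:`crossmi.model.CrossSubjectMI`: one
``run_pair`` per directed subject pair (10 sets of 28 train / 28 test trials
at the default scale), and a ``summarize`` that aggregates per-pair rows
into the grand mean-of-means +/- SD-of-means table with medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HeadModel, TrialSet
from .model import CrossSubjectMI, CrossSubjectMIResults, ExperimentConfig

__all__ = ["ResultRow", "run_pair", "summarize"]


@dataclass
class ResultRow:
    """One directed pair's protocol outcome."""

    pair_id: str
    accuracies: np.ndarray  # per-set, percent
    mean: float
    sd: float
    channel_counts: list[int]
    channel_case: str
    method: str
    results: CrossSubjectMIResults

    def __post_init__(self) -> None:
        finite = self.accuracies[np.isfinite(self.accuracies)]
        if finite.size and not (
            np.isclose(self.mean, finite.mean(), atol=1e-9)
            and np.isclose(
                self.sd, np.std(finite, ddof=1) if finite.size > 1 else 0.0,
                atol=1e-9,
            )
        ):
            raise ValueError("stored mean/sd inconsistent with accuracies")


def run_pair(
    X: TrialSet,
    Y: TrialSet,
    config: ExperimentConfig | None = None,
    head: HeadModel | None = None,
) -> ResultRow:
    """Run the directed X(train) -> Y(test) protocol and return its row."""
    res = CrossSubjectMI(X, Y, head=head, config=config).fit()
    return ResultRow(
        res.pair_id,
        res.accuracies,
        res.mean_accuracy,
        res.sd_accuracy,
        res.channel_counts(),
        res.model.config.channel_case,
        res.model.config.method,
        res,
    )


def summarize(rows: list[ResultRow]) -> dict:
    """Aggregate pair rows: per-pair table + grand mean/SD/median of means.

    The grand statistics follow the mean-of-means convention: the mean of
    the per-pair mean accuracies, their SD (n-1 denominator), and their
    median, grouped by (channel_case, method).
    """
    if not rows:
        raise ValueError("need at least one result row")
    table = pd.DataFrame(
        {
            "pair": [r.pair_id for r in rows],
            "case": [r.channel_case for r in rows],
            "method": [r.method for r in rows],
            "mean": [r.mean for r in rows],
            "sd": [r.sd for r in rows],
            "n_channels": [int(np.mean(r.channel_counts)) for r in rows],
        }
    ).sort_values(["case", "method", "pair"], kind="stable").reset_index(drop=True)
    means = np.array([r.mean for r in rows], dtype=float)
    grand = {
        "grand_mean": float(means.mean()),
        "grand_sd": float(np.std(means, ddof=1)) if means.size > 1 else 0.0,
        "median": float(np.median(means)),
    }
    by_group = {
        f"{case}/{method}": {
            "mean": float(g["mean"].mean()),
            "sd": float(g["mean"].std(ddof=1)) if len(g) > 1 else 0.0,
            "median": float(g["mean"].median()),
        }
        for (case, method), g in table.groupby(["case", "method"])
    }
    return {"table": table, **grand, "by_group": by_group}
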