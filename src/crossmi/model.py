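"""Cross-subject motor-imagery model: fit on one subject, test on another.

`CrossSubjectMI` is the modelling object for one *directed* subject pair:
subject X supplies the training trials, subject Y the test trials.  Its
``fit()`` runs the full protocol — partition both subjects' trials into
``n_sets`` contiguous subsets, pair them one-to-one, and for every set
(optionally) select channels by joint wMEM source localization, fit CSP or
RCSP spatial filters and the subband-entropy classifier on the training
half, and score the test half — returning a `CrossSubjectMIResults` with the
per-set accuracies, their mean +/- SD, the channels used, and a summary()
table.

Train/test separation: spatial filters, the beta/gamma choice (internal
stratified splits of the training half) and classifier weights see training
trials only.  Channel selection in the "selected" case deliberately uses the
combined class-specific trials of both subjects — it is label-aware and
subject-joint by design (that joint localization is what operationalizes
inter-subject associativity), but it never sees test labels' mapping to
predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .channel_select import select_channels
from .containers import HeadModel, TrialSet
from .features import feature_matrix, predict, train_classifier
from .preprocess import InterSubjectSet, build_intersubject_sets, split_into_sets
from .spatial_filter import (
    BETA_GRID,
    GAMMA_GRID,
    SpatialFilterBank,
    fit_csp,
    fit_rcsp,
)
from .wmem import localize

__all__ = ["ExperimentConfig", "SetResult", "CrossSubjectMI", "CrossSubjectMIResults"]

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Knobs of one directed cross-subject experiment."""

    channel_case: str = "all"  # "all" | "selected"
    method: str = "csp"  # "csp" | "rcsp"
    n_sets: int = 10
    seed: int = 0
    # RCSP regularization: fixed values, or grids searched on internal splits
    beta: float | None = None
    gamma: float | None = None
    beta_grid: tuple = BETA_GRID
    gamma_grid: tuple = GAMMA_GRID
    inner_folds: int = 2
    # channel selection / wMEM
    energy_quantile: float = 0.95
    radius: float = 0.25
    wmem_levels: int | None = None
    wmem_K: int = 20
    refit_selection_per_set: bool = True
    # classifier
    hidden: int = 10
    zscore: bool = False

    def __post_init__(self) -> None:
        if self.channel_case not in ("all", "selected"):
            raise ValueError("channel_case must be 'all' or 'selected'")
        if self.method not in ("csp", "rcsp"):
            raise ValueError("method must be 'csp' or 'rcsp'")
        for g in (*self.beta_grid, *self.gamma_grid):
            if not 0.0 <= g <= 1.0:
                raise ValueError("beta/gamma grids must lie in [0, 1]")


@dataclass
class SetResult:
    """One protocol set's outcome and fitted artifacts."""

    set_index: int
    accuracy: float  # percent
    n_test: int
    channels: np.ndarray
    beta: float
    gamma: float
    bank: SpatialFilterBank
    classifier: object
    error: str | None = None


def _subseed(seed: int, set_index: int) -> int:
    return int((seed * 100003 + set_index * 7919 + 1) % (2**31 - 1))


class CrossSubjectMI:
    """Directed cross-subject motor-imagery classification model.

    Parameters
    ----------
    train_subject, test_subject : preprocessed (band-passed, windowed)
        TrialSets of the two subjects; equal trial counts divisible by
        ``config.n_sets``.
    head : HeadModel, required for ``channel_case='selected'`` (wMEM channel
        selection needs the forward model).
    config : ExperimentConfig.
    """

    def __init__(
        self,
        train_subject: TrialSet,
        test_subject: TrialSet,
        head: HeadModel | None = None,
        config: ExperimentConfig | None = None,
    ):
        self.train_subject = train_subject
        self.test_subject = test_subject
        self.head = head
        self.config = config or ExperimentConfig()
        if self.config.channel_case == "selected" and head is None:
            raise ValueError("channel_case='selected' requires a head model")
        if len(train_subject) != len(test_subject):
            raise ValueError("subjects must have equal trial counts")

    # -- pieces -------------------------------------------------------------

    def _select_channels(self, iset: InterSubjectSet) -> np.ndarray:
        cfg = self.config
        if cfg.channel_case == "all":
            return np.arange(self.train_subject.n_channels)
        combined = iset.train + iset.test
        est1 = localize(
            combined, 1, self.head, levels=cfg.wmem_levels, K_target=cfg.wmem_K
        )
        est2 = localize(
            combined, 2, self.head, levels=cfg.wmem_levels, K_target=cfg.wmem_K
        )
        sel = select_channels(
            est1, est2, self.head, cfg.energy_quantile, cfg.radius
        )
        return sel.union

    def _generic_trials(self, set_index: int, channels, label: int) -> list:
        """Generic (Eq.-style) trials: the training subject's class trials
        from all protocol sets other than the current one."""
        subsets = split_into_sets(self.train_subject, self.config.n_sets)
        out = []
        for i, sub in enumerate(subsets):
            if i + 1 == set_index:
                continue
            for t in sub:
                if t.label == label:
                    out.append(t.restrict_channels(channels))
        return out

    def _fit_bank(
        self, train: TrialSet, set_index: int, channels, seed: int
    ) -> tuple[SpatialFilterBank, float, float]:
        cfg = self.config
        c1, c2 = train.of_class(1), train.of_class(2)
        if cfg.method == "csp":
            return fit_csp(c1, c2), 0.0, 0.0
        g1 = self._generic_trials(set_index, channels, 1)
        g2 = self._generic_trials(set_index, channels, 2)
        if cfg.beta is not None and cfg.gamma is not None:
            beta, gamma = cfg.beta, cfg.gamma
        else:
            beta, gamma = self._search_beta_gamma(train, g1, g2, seed)
        return fit_rcsp(c1, c2, g1, g2, beta, gamma), beta, gamma

    def _search_beta_gamma(self, train, g1, g2, seed):
        """Pick (beta, gamma) by mean accuracy over internal stratified
        splits of the training trials; ties break toward less regularization."""
        from sklearn.model_selection import StratifiedKFold

        cfg = self.config
        y = train.labels
        skf = StratifiedKFold(
            n_splits=cfg.inner_folds, shuffle=True, random_state=seed
        )
        folds = list(skf.split(np.zeros(len(y)), y))
        best = (-1.0, 0.0, 0.0)
        for beta in cfg.beta_grid:
            for gamma in cfg.gamma_grid:
                accs = []
                for tr_idx, va_idx in folds:
                    tr, va = train.select(tr_idx), train.select(va_idx)
                    try:
                        bank = fit_rcsp(
                            tr.of_class(1), tr.of_class(2), g1, g2, beta, gamma
                        )
                        clf = train_classifier(
                            feature_matrix(tr, bank), tr.labels,
                            seed=seed, hidden=cfg.hidden, zscore=cfg.zscore,
                        )
                        pred, _ = predict(clf, feature_matrix(va, bank))
                        accs.append(np.mean(pred == va.labels))
                    except ValueError:
                        accs.append(0.0)
                score = float(np.mean(accs))
                if score > best[0] + 1e-12:
                    best = (score, beta, gamma)
        return best[1], best[2]

    def _run_set(self, iset: InterSubjectSet) -> SetResult:
        cfg = self.config
        seed = _subseed(cfg.seed, iset.set_index)
        channels = self._select_channels(iset)
        train = iset.train.restrict_channels(channels)
        test = iset.test.restrict_channels(channels)
        bank, beta, gamma = self._fit_bank(train, iset.set_index, channels, seed)
        clf = train_classifier(
            feature_matrix(train, bank), train.labels,
            seed=seed, hidden=cfg.hidden, zscore=cfg.zscore,
        )
        pred, _ = predict(clf, feature_matrix(test, bank))
        acc = 100.0 * float(np.mean(pred == test.labels))
        return SetResult(
            iset.set_index, acc, len(test), channels, beta, gamma, bank, clf
        )

    # -- fit ----------------------------------------------------------------

    def fit(self) -> "CrossSubjectMIResults":
        cfg = self.config
        sets = build_intersubject_sets(
            self.train_subject, self.test_subject, cfg.n_sets
        )
        shared_channels: np.ndarray | None = None
        results: list[SetResult] = []
        for iset in sets:
            try:
                if (
                    cfg.channel_case == "selected"
                    and not cfg.refit_selection_per_set
                ):
                    if shared_channels is None:
                        log.warning(
                            "fast mode: reusing set-1 channel selection for all sets"
                        )
                        shared_channels = self._select_channels(sets[0])
                    iset_res = self._run_set_with_channels(iset, shared_channels)
                else:
                    iset_res = self._run_set(iset)
            except Exception as exc:  # record, exclude, flag
                log.error("set %d failed: %s", iset.set_index, exc)
                iset_res = SetResult(
                    iset.set_index, float("nan"), len(iset.test),
                    np.array([], dtype=int), 0.0, 0.0, None, None, str(exc),
                )
            results.append(iset_res)
        return CrossSubjectMIResults(self, results)

    def _run_set_with_channels(self, iset, channels) -> SetResult:
        cfg = self.config
        seed = _subseed(cfg.seed, iset.set_index)
        train = iset.train.restrict_channels(channels)
        test = iset.test.restrict_channels(channels)
        bank, beta, gamma = self._fit_bank(train, iset.set_index, channels, seed)
        clf = train_classifier(
            feature_matrix(train, bank), train.labels,
            seed=seed, hidden=cfg.hidden, zscore=cfg.zscore,
        )
        pred, _ = predict(clf, feature_matrix(test, bank))
        acc = 100.0 * float(np.mean(pred == test.labels))
        return SetResult(
            iset.set_index, acc, len(test), np.asarray(channels), beta, gamma,
            bank, clf,
        )


class CrossSubjectMIResults:
    """Per-set accuracies and fitted artifacts of one directed pair."""

    def __init__(self, model: CrossSubjectMI, per_set: list[SetResult]):
        self.model = model
        self.per_set = per_set

    @property
    def pair_id(self) -> str:
        a = self.model.train_subject[0].subject_id
        b = self.model.test_subject[0].subject_id
        return f"{a}-{b}"

    @property
    def accuracies(self) -> np.ndarray:
        """Per-set accuracies in percent (NaN for failed sets)."""
        return np.array([s.accuracy for s in self.per_set])

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        """SD across sets, n-1 denominator."""
        a = self.accuracies
        a = a[np.isfinite(a)]
        return float(np.std(a, ddof=1)) if a.size > 1 else 0.0

    @property
    def n_failed(self) -> int:
        return int(np.sum(~np.isfinite(self.accuracies)))

    def channel_counts(self) -> list[int]:
        return [len(s.channels) for s in self.per_set]

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Cross-subject motor-imagery results",
            "===================================",
            f"pair (train-test):  {self.pair_id}",
            f"method:             {cfg.method.upper()}  |  channels: {cfg.channel_case}",
            f"sets:               {cfg.n_sets}  ({len(self.per_set[0].channels)}"
            f" channels in set 1)" if self.per_set else "",
            "",
            f"{'set':>4} {'acc %':>8} {'n_ch':>6} {'beta':>7} {'gamma':>7}",
        ]
        for s in self.per_set:
            if s.error:
                lines.append(f"{s.set_index:>4} {'FAILED':>8}  ({s.error})")
            else:
                lines.append(
                    f"{s.set_index:>4} {s.accuracy:>8.2f} {len(s.channels):>6}"
                    f" {s.beta:>7.3f} {s.gamma:>7.3f}"
                )
        lines += [
            "",
            f"mean +/- SD:        {self.mean_accuracy:.2f} +/- {self.sd_accuracy:.2f} %",
        ]
        if self.n_failed:
            lines.append(f"failed sets:        {self.n_failed}")
        return "\n".join(lines)

    def plot_accuracies(self, ax=None):
        """Bar plot of per-set accuracies with the mean as a line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        acc = self.accuracies
        ax.bar(np.arange(1, len(acc) + 1), acc)
        ax.axhline(self.mean_accuracy, color="k", ls="--", label="mean")
        ax.axhline(50, color="gray", ls=":", label="chance")
        ax.set_xlabel("protocol set")
        ax.set_ylabel("accuracy [%]")
        ax.set_title(self.pair_id)
        ax.legend()
        return ax
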