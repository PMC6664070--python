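"""Common spatial patterns (CSP) and covariance-regularized CSP (RCSP).

CSP finds spatial filters that maximize the variance of one class while
minimizing the other's: whiten the composite covariance S1 + S2, then
eigendecompose the whitened class-1 covariance.  Because the two whitened
class covariances sum to the identity, the leading filters favor class 1 and
the trailing filters favor class 2; four components (two per class) are
retained.

RCSP shrinks each class's covariance estimate two ways before filtering:
beta mixes in "generic" trials from outside the training split, gamma
shrinks toward a scaled identity,

    Omega_c(beta) = [(1-beta) S_c + beta S^_c] / [(1-beta) M + beta M^]
    Sigma_c(beta, gamma) = (1-gamma) Omega_c(beta)
                           + (gamma / N) trace[Omega_c(beta)] I,

with S_c, S^_c sums of unit-trace per-trial covariances over the M class
trials and M^ generic trials.  beta = gamma = 0 recovers plain CSP exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TrialSet

__all__ = [
    "BETA_GRID",
    "GAMMA_GRID",
    "SpatialFilterBank",
    "trial_covariance",
    "mean_class_covariance",
    "regularized_class_covariance",
    "fit_filters",
    "fit_csp",
    "fit_rcsp",
    "project_and_retain",
]

# regularization grids swept by the evaluation harness
BETA_GRID = (0.0, 0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
GAMMA_GRID = (0.0, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

N_RETAINED = 4  # two components per class


def trial_covariance(E: np.ndarray) -> np.ndarray:
    """Per-trial spatial covariance normalized to unit trace: EE'/tr(EE')."""
    E = np.asarray(E, dtype=float)
    C = E @ E.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("zero trial: covariance undefined")
    return C / tr


def _cov_sum(trials) -> tuple[np.ndarray, int]:
    mats = [trial_covariance(t.data if hasattr(t, "data") else t) for t in trials]
    if not mats:
        raise ValueError("no trials")
    return np.sum(mats, axis=0), len(mats)


def mean_class_covariance(trials) -> np.ndarray:
    """Mean unit-trace covariance across a class's trials."""
    S, m = _cov_sum(trials)
    return S / m


def regularized_class_covariance(
    class_trials,
    generic_trials=None,
    beta: float = 0.0,
    gamma: float = 0.0,
) -> np.ndarray:
    """Sigma_c(beta, gamma): generic-trial mixing then identity shrinkage."""
    if not (0.0 <= beta <= 1.0 and 0.0 <= gamma <= 1.0):
        raise ValueError("beta and gamma must be in [0, 1]")
    S_c, M = _cov_sum(class_trials)
    if beta > 0.0:
        if not generic_trials:
            raise ValueError("beta > 0 requires generic trials")
        S_hat, M_hat = _cov_sum(generic_trials)
    else:
        S_hat, M_hat = np.zeros_like(S_c), 0
    omega = ((1.0 - beta) * S_c + beta * S_hat) / ((1.0 - beta) * M + beta * M_hat)
    N = omega.shape[0]
    return (1.0 - gamma) * omega + (gamma / N) * np.trace(omega) * np.eye(N)


@dataclass
class SpatialFilterBank:
    """RCSP projection with its provenance.

    ``W`` rows are spatial filters ordered by descending whitened class-1
    eigenvalue; rows (0, 1) favor class 1 and rows (-2, -1) favor class 2.
    """

    W: np.ndarray  # (N, N)
    composite_eigenvalues: np.ndarray  # (N,), descending
    class1_eigenvalues: np.ndarray  # (N,), descending, in [0, 1]
    beta: float
    gamma: float

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]

    @property
    def retained_indices(self) -> tuple[int, int, int, int]:
        n = self.W.shape[0]
        return (0, 1, n - 2, n - 1)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (sign convention)."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _eigh_descending(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(-vals, kind="stable")
    return vals[order], _fix_signs(vecs[:, order])


def fit_filters(
    Sigma_1: np.ndarray,
    Sigma_2: np.ndarray,
    beta: float = 0.0,
    gamma: float = 0.0,
    eig_floor_rel: float = 1e-10,
) -> SpatialFilterBank:
    """Two-step CSP factorization of a class-covariance pair.

    Eigendecompose the composite Sigma_1 + Sigma_2 = U L U' (descending),
    whiten with P = L^-1/2 U', eigendecompose the whitened class-1 covariance
    P Sigma_1 P' = B D B' (descending), and return W = B' P.  Then
    W Sigma_1 W' = D and W Sigma_2 W' = I - D are both diagonal.
    """
    C = np.asarray(Sigma_1, float) + np.asarray(Sigma_2, float)
    lam, U = _eigh_descending(C)
    top = lam[0]
    if top <= 0:
        raise ValueError("composite covariance is not positive")
    floor = eig_floor_rel * top
    if np.all(lam < floor):
        raise ValueError("composite covariance singular beyond floor")
    lam = np.maximum(lam, floor)
    P = (U / np.sqrt(lam)).T  # Lambda^(-1/2) U'
    Wc1 = P @ Sigma_1 @ P.T
    d, B = _eigh_descending(0.5 * (Wc1 + Wc1.T))
    W = B.T @ P
    return SpatialFilterBank(W, lam, d, beta, gamma)


def fit_csp(class1: TrialSet, class2: TrialSet) -> SpatialFilterBank:
    """Plain CSP from the mean unit-trace class covariances."""
    return fit_filters(
        mean_class_covariance(class1), mean_class_covariance(class2)
    )


def fit_rcsp(
    class1: TrialSet,
    class2: TrialSet,
    generic1=None,
    generic2=None,
    beta: float = 0.0,
    gamma: float = 0.0,
) -> SpatialFilterBank:
    """RCSP: regularize each class covariance, then the CSP factorization."""
    S1 = regularized_class_covariance(class1, generic1, beta, gamma)
    S2 = regularized_class_covariance(class2, generic2, beta, gamma)
    return fit_filters(S1, S2, beta, gamma)


def project_and_retain(E: np.ndarray, bank: SpatialFilterBank) -> np.ndarray:
    """Project a trial and keep the two outermost components per side.

    Returns the (4, P) matrix of rows (0, 1, -2, -1) of W E — the most
    class-1- and most class-2-discriminative spatially filtered signals.
    """
    E = np.asarray(E, dtype=float)
    if E.shape[0] != bank.n_channels:
        raise ValueError(
            f"trial has {E.shape[0]} channels, bank expects {bank.n_channels}"
        )
    X = bank.W @ E
    return X[list(bank.retained_indices)]
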