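"""Wavelet-domain maximum-entropy-on-the-mean (wMEM) source localization.

The EEG inverse problem M = G J + E is ill-posed (more sources than
channels).  MEM regularizes it by treating the source amplitudes as a random
vector with a *reference* law mu and choosing, among all densities f*mu that
reproduce the observed data on average, the one of maximum relative entropy
(minimum KL divergence to mu).  The wavelet variant applies this
independently to every (scale, translation) coefficient of the discrete
wavelet transform of the averaged data: each "box" contributes one q-vector
of whitened, noise-shrunk channel coefficients d*, and the solution is the
a-posteriori mean w* of the source coefficients.

The reference law is Bernoulli-Gaussian per cortical parcel: parcel k is
active with probability alpha_k, and when active its member sources follow a
zero-mean Gaussian with a spatially smoothed covariance Sigma_k.  This gives
the log-partition (free energy) in closed form,

    F*(xi) = sum_k ln[(1 - alpha_k) + alpha_k exp(xi_k' Sigma_k xi_k / 2)],

so the dual problem — maximize the concave
D(lambda) = lambda'd* - F*(G' lambda) - lambda' eta lambda / 2 over the
q-dimensional sensor-space multiplier lambda — is solved by quasi-Newton
iteration with the analytic gradient, and w* = dF*/dxi at xi = G' lambda*.

In the all-parcels-active limit (alpha_k -> 1) the prior is purely Gaussian
and w* collapses to the classical minimum-norm solution
Sigma_J G' (G Sigma_J G' + eta)^-1 d*, which serves as the oracle in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .containers import HeadModel, Trial, TrialSet
from .wavelet import WaveletStack, dwt_forward, dwt_inverse

__all__ = [
    "NoiseModel",
    "Parcellation",
    "MEMReference",
    "SourceEstimate",
    "average_trials",
    "estimate_noise_model",
    "soft_shrink",
    "prelocalize",
    "parcellate",
    "build_reference",
    "mem_solve",
    "localize",
]

log = logging.getLogger(__name__)

MAD_TO_SD = 1.4826  # consistency constant for Gaussian noise
EIG_FLOOR_REL = 1e-8


# ----------------------------------------------------------------- averaging

def average_trials(trials: TrialSet, class_label: int) -> Trial:
    """Pointwise ensemble average of one class's trials (data and baseline).

    Averaging suppresses trial-independent background fluctuations by
    ~1/sqrt(n), concentrating the class-locked source topography.
    """
    cls = trials.of_class(class_label)
    data = cls.data_array().mean(axis=0)
    base = cls.baseline_array().mean(axis=0)
    t0 = cls[0]
    return Trial(data, class_label, t0.subject_id, base, t0.sample_rate)


# --------------------------------------------------------------- noise model

@dataclass
class NoiseModel:
    """Baseline covariance, its inverse square root, per-channel thresholds."""

    covariance: np.ndarray  # (q, q)
    whitener: np.ndarray  # (q, q), Sigma^(-1/2) on the retained subspace
    tau: np.ndarray  # (q,) soft-shrinkage thresholds

    @property
    def n_channels(self) -> int:
        return self.covariance.shape[0]


def _inv_sqrt_psd(S: np.ndarray, floor_rel: float = EIG_FLOOR_REL) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    top = vals.max()
    if top <= 0:
        raise ValueError("covariance has no positive eigenvalues")
    vals = np.maximum(vals, floor_rel * top)
    return (vecs / np.sqrt(vals)) @ vecs.T


def estimate_noise_model(
    baselines,
    data: np.ndarray | None = None,
    wavelet: str = "db4",
    c: float = 1.0,
) -> NoiseModel:
    """Noise covariance + whitener from pooled baselines; universal thresholds.

    Parameters
    ----------
    baselines : iterable of (q, tau_b) matrices pooled column-wise.
    data : optional (q, tau) matrix whose finest-scale wavelet coefficients
        set the shrinkage thresholds (universal-threshold practice); when
        absent the pooled baseline is used instead.
    c : threshold scale factor, default 1 (tau_ch = c * sd_ch * sqrt(2 ln N)).

    The per-channel noise scale is the median estimator
    sd = 1.4826 * median(|finest detail coefficients|).
    """
    pooled = np.concatenate([np.asarray(b, float) for b in baselines], axis=1)
    q, n = pooled.shape
    if n < 32:
        raise ValueError("need at least 32 pooled baseline samples per channel")
    Sigma = np.cov(pooled)
    Sigma = np.atleast_2d(Sigma)
    W = _inv_sqrt_psd(Sigma)

    ref = np.asarray(data, float) if data is not None else pooled
    N = ref.shape[1]
    d1 = dwt_forward(ref, 1, wavelet).subband("d1")
    sd = MAD_TO_SD * np.median(np.abs(d1), axis=1)
    tau = c * sd * np.sqrt(2.0 * np.log(N))
    return NoiseModel(Sigma, W, tau)


def soft_shrink(w, tau):
    """Soft shrinkage delta_tau(w) = (1 - tau/|w|)_+ * w (elementwise)."""
    w = np.asarray(w, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    out = np.sign(w) * np.maximum(np.abs(w) - tau, 0.0)
    return out if out.ndim else float(out)


# ------------------------------------------------------------ prelocalization

def prelocalize(
    M_avg: np.ndarray, head: HeadModel, whitener: np.ndarray | None = None,
    energy: float = 0.95,
) -> np.ndarray:
    """Probability-like per-source contribution scores m_s in [0, 1].

    m_s is the squared norm of the projection of the (whitened) unit
    lead-field column of source s onto the dominant left-singular subspace of
    the (whitened) averaged data, the subspace rank chosen to capture the
    given energy fraction.
    """
    M = np.asarray(M_avg, float)
    G = head.lead_field
    if whitener is not None:
        M = whitener @ M
        G = whitener @ G
    if not np.any(M):
        log.warning("prelocalize: zero data, all scores are 0")
        return np.zeros(head.n_sources)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    cum = np.cumsum(s**2) / np.sum(s**2)
    rank = int(np.searchsorted(cum, energy) + 1)
    Ur = U[:, :rank]
    norms = np.linalg.norm(G, axis=0)
    norms[norms == 0] = 1.0
    proj = Ur.T @ (G / norms)
    return np.clip(np.sum(proj**2, axis=0), 0.0, 1.0)


# --------------------------------------------------------------- parcellation

@dataclass
class Parcellation:
    """K disjoint source parcels with activation probabilities."""

    parcels: list[np.ndarray]  # index arrays, pairwise disjoint
    alpha: np.ndarray  # (K,) in (0, 1)
    scores: np.ndarray  # (r,) pre-localization scores
    labels: np.ndarray  # (r,) parcel id per source, -1 = unassigned

    @property
    def n_parcels(self) -> int:
        return len(self.parcels)


def _source_adjacency(head: HeadModel, k: int = 6) -> list[np.ndarray]:
    tree = cKDTree(head.source_positions)
    _, nn = tree.query(head.source_positions, k=min(k + 1, head.n_sources))
    nn = np.atleast_2d(nn)[:, 1:]  # drop self
    neigh = [set() for _ in range(head.n_sources)]
    for s in range(head.n_sources):
        for t in nn[s]:
            neigh[s].add(int(t))
            neigh[int(t)].add(s)  # symmetrize
    return [np.array(sorted(x), dtype=int) for x in neigh]


def parcellate(
    head: HeadModel,
    scores: np.ndarray,
    K_target: int = 20,
    knn: int = 6,
    score_floor: float = 0.0,
) -> Parcellation:
    """Region growing around local maxima of the pre-localization scores.

    Seeds are the top-``K_target`` local maxima of ``scores`` on the
    k-nearest-neighbor source adjacency graph (ties broken toward the lower
    source index); regions grow by best-first accretion of adjacent
    unassigned sources until everything (above ``score_floor``) is assigned.
    Activation probabilities are the mean member score clipped to
    [0.05, 0.95].
    """
    if K_target < 1:
        raise ValueError("K_target must be >= 1")
    if K_target >= head.n_sources:
        raise ValueError("K_target must be < number of sources")
    scores = np.asarray(scores, dtype=float)
    neigh = _source_adjacency(head, knn)
    r = head.n_sources

    def beats(a: int, b: int) -> bool:
        # a dominates b (score, then lower-index tie-break)
        return (scores[a], -a) > (scores[b], -b)

    is_max = np.array(
        [all(beats(s, t) for t in neigh[s]) for s in range(r)]
    )
    seeds = np.flatnonzero(is_max)
    seeds = seeds[np.lexsort((seeds, -scores[seeds]))][:K_target]

    labels = np.full(r, -1, dtype=int)
    import heapq

    heap: list[tuple[float, int, int]] = []
    for pid, s in enumerate(seeds):
        heapq.heappush(heap, (-scores[s], int(s), pid))
    while heap:
        negscore, s, pid = heapq.heappop(heap)
        if labels[s] != -1 or -negscore < score_floor:
            continue
        labels[s] = pid
        for t in neigh[s]:
            if labels[t] == -1:
                heapq.heappush(heap, (-scores[t], int(t), pid))

    parcels = [np.flatnonzero(labels == pid) for pid in range(len(seeds))]
    parcels = [p for p in parcels if len(p)]
    alpha = np.array(
        [np.clip(scores[p].mean(), 0.05, 0.95) for p in parcels]
    )
    return Parcellation(parcels, alpha, scores, labels)


# ----------------------------------------------------------------- reference

@dataclass
class MEMReference:
    """Bernoulli-Gaussian reference law: per-parcel (alpha_k, Sigma_k).

    The active-state Gaussian is zero-mean with covariance
    sigma2_k * C_k where C_k = I + 0.5 * A (A = within-parcel adjacency),
    eigenvalue-clipped at 0.05 to stay positive definite.
    """

    parcels: list[np.ndarray]
    alpha: np.ndarray  # (K,), in (0, 1]
    covariances: list[np.ndarray]  # (p_k, p_k) each

    def __post_init__(self) -> None:
        if np.any(self.alpha <= 0) or np.any(self.alpha > 1):
            raise ValueError("alpha must be in (0, 1]")
        for S in self.covariances:
            if np.any(np.linalg.eigvalsh(S) <= 0):
                raise ValueError("active-state covariances must be PD")


def build_reference(
    head: HeadModel,
    parcellation: Parcellation,
    sigma2: float | np.ndarray = 1.0,
    neighbor_corr: float = 0.5,
    knn: int = 6,
) -> MEMReference:
    """Assemble the Bernoulli-Gaussian reference from a parcellation."""
    neigh = _source_adjacency(head, knn)
    sigma2 = np.broadcast_to(
        np.asarray(sigma2, dtype=float), (parcellation.n_parcels,)
    )
    covs = []
    for k, p in enumerate(parcellation.parcels):
        pos = {s: i for i, s in enumerate(p)}
        C = np.eye(len(p))
        for s in p:
            for t in neigh[s]:
                if t in pos:
                    C[pos[s], pos[t]] = neighbor_corr
        # clip eigenvalues: a high-degree node at corr 0.5 can break PD
        vals, vecs = np.linalg.eigh(C)
        C = (vecs * np.maximum(vals, 0.05)) @ vecs.T
        covs.append(sigma2[k] * C)
    return MEMReference(parcellation.parcels, parcellation.alpha.copy(), covs)


# -------------------------------------------------------------------- solver

@dataclass
class MEMSolution:
    """One box's solution: posterior source means and parcel activations."""

    w_star: np.ndarray  # (r,)
    alpha_post: np.ndarray  # (K,)
    converged: bool
    n_iter: int
    grad_norm: float
    dual_value: float


def _free_energy_terms(xi: np.ndarray, ref: MEMReference):
    """Per-parcel (F_k, p_k, Sigma_k xi_k) for the Bernoulli-Gaussian law."""
    F = np.empty(len(ref.parcels))
    p = np.empty(len(ref.parcels))
    sx = []
    for k, idx in enumerate(ref.parcels):
        xk = xi[idx]
        Sx = ref.covariances[k] @ xk
        u = 0.5 * float(xk @ Sx)
        a = ref.alpha[k]
        with np.errstate(divide="ignore"):
            F[k] = np.logaddexp(np.log1p(-a) if a < 1 else -np.inf, np.log(a) + u)
        p[k] = np.exp(np.log(a) + u - F[k])
        sx.append(Sx)
    return F, p, sx


def mem_solve(
    d_star: np.ndarray,
    G_w: np.ndarray,
    ref: MEMReference,
    eta: np.ndarray | float = 1.0,
    grad_tol: float = 1e-6,
    max_iter: int = 500,
) -> MEMSolution:
    """Solve one (scale, translation) box by maximizing the concave dual.

    Parameters
    ----------
    d_star : (q,) whitened, shrunk data coefficients.
    G_w : (q, r) whitened lead field.
    ref : Bernoulli-Gaussian reference law.
    eta : residual-noise covariance (scalar = multiple of identity).

    Returns the a-posteriori mean source coefficients
    w*_k = p_k(xi) Sigma_k xi_k with xi = G_w' lambda*, plus the posterior
    parcel activation probabilities p_k and convergence diagnostics.
    """
    d_star = np.asarray(d_star, dtype=float)
    q, r = G_w.shape
    if d_star.shape != (q,):
        raise ValueError("d_star must be a q-vector matching G_w")
    eta_mat = np.asarray(eta, dtype=float)
    if eta_mat.ndim == 0:
        eta_dot = lambda lam: float(eta_mat) * lam
    else:
        eta_dot = lambda lam: eta_mat @ lam

    def w_of_xi(xi):
        _, p, sx = _free_energy_terms(xi, ref)
        w = np.zeros(r)
        for k, idx in enumerate(ref.parcels):
            w[idx] = p[k] * sx[k]
        return w, p

    def negD_and_grad(lam):
        xi = G_w.T @ lam
        F, p, sx = _free_energy_terms(xi, ref)
        w = np.zeros(r)
        for k, idx in enumerate(ref.parcels):
            w[idx] = p[k] * sx[k]
        el = eta_dot(lam)
        D = float(lam @ d_star) - float(F.sum()) - 0.5 * float(lam @ el)
        grad = d_star - G_w @ w - el
        return -D, -grad

    res = optimize.minimize(
        negD_and_grad,
        np.zeros(q),
        jac=True,
        method="BFGS",
        options={"gtol": grad_tol, "maxiter": max_iter},
    )
    lam = res.x
    xi = G_w.T @ lam
    w, p = w_of_xi(xi)
    grad_norm = float(np.linalg.norm(res.jac))
    converged = bool(grad_norm <= max(grad_tol, 1e-5 * (1 + np.abs(res.fun))))
    if not converged:
        log.warning(
            "mem_solve: dual optimizer stopped with |grad| = %.3g after %d iterations",
            grad_norm, res.nit,
        )
    return MEMSolution(w, p, converged, int(res.nit), grad_norm, -float(res.fun))


def dual_value(lam, d_star, G_w, ref, eta=1.0):
    """D(lambda) = lambda'd* - F*(G'lambda) - lambda' eta lambda / 2."""
    lam = np.asarray(lam, dtype=float)
    xi = G_w.T @ lam
    F, _, _ = _free_energy_terms(xi, ref)
    eta_mat = np.asarray(eta, dtype=float)
    el = float(eta_mat) * lam if eta_mat.ndim == 0 else eta_mat @ lam
    return float(lam @ d_star) - float(F.sum()) - 0.5 * float(lam @ el)


# ------------------------------------------------------------------ pipeline

@dataclass
class SourceEstimate:
    """Wavelet-domain posterior source coefficients and energy maps."""

    w_star: np.ndarray  # (r, n_coeffs)
    energy: np.ndarray  # (r,) summed over all boxes
    per_scale_energy: dict[int, np.ndarray]
    parcellation: Parcellation
    solved_boxes: np.ndarray  # column indices actually solved
    skipped_fraction: float
    converged: np.ndarray  # bool per solved box
    stack_template: WaveletStack | None = None

    def time_courses(self) -> np.ndarray:
        """Inverse DWT of the posterior coefficients -> (r, tau) currents."""
        if self.stack_template is None:
            raise ValueError("no wavelet stack template stored")
        st = WaveletStack(
            self.w_star,
            self.stack_template.n_levels,
            self.stack_template.family,
            self.stack_template.original_length,
        )
        return dwt_inverse(st)


def localize(
    trials: TrialSet,
    class_label: int,
    head: HeadModel,
    levels: int | None = None,
    wavelet: str = "db4",
    K_target: int = 20,
    threshold_scale: float = 1.0,
    min_active_channels: int = 1,
) -> SourceEstimate:
    """Full wMEM pipeline on one class's trials.

    average -> DWT -> noise model -> per-channel soft shrinkage -> whitening
    -> pre-localization + parcellation (once, on the whitened average) ->
    per-box dual MEM solve (boxes that shrink to zero are skipped) ->
    energy map.

    ``levels`` defaults to floor(log2(tau)) - 2.
    """
    if head.n_channels != trials.n_channels:
        raise ValueError("head model and trials have different channel counts")
    avg = average_trials(trials, class_label)
    tau = avg.n_samples
    if levels is None:
        levels = max(1, int(np.floor(np.log2(tau))) - 2)

    stack = dwt_forward(avg.data, levels, wavelet)
    cls = trials.of_class(class_label)
    noise = estimate_noise_model(
        [t.baseline for t in cls], data=avg.data, wavelet=wavelet,
        c=threshold_scale,
    )
    # baseline covariance scales as 1/n under averaging of independent noise;
    # the thresholds are already on the averaged-data scale (data=avg.data)
    n_avg = len(cls)
    W = noise.whitener * np.sqrt(n_avg)
    tau_ch = noise.tau

    shrunk = soft_shrink(stack.coefficients, tau_ch[:, None])
    d_all = W @ shrunk
    G_w = W @ head.lead_field

    scores = prelocalize(avg.data, head, whitener=W)
    parc = parcellate(head, scores, K_target=K_target)
    if not np.any(shrunk):
        r = head.n_sources
        return SourceEstimate(
            np.zeros((r, stack.coefficients.shape[1])), np.zeros(r),
            {}, parc, np.array([], dtype=int), 1.0,
            np.array([], dtype=bool), stack,
        )

    # prior source variance set from the data/lead-field scale
    active_cols = np.flatnonzero(
        (np.abs(shrunk) > 0).sum(axis=0) >= min_active_channels
    )
    col_norm2 = np.mean(np.sum(G_w**2, axis=0))
    mean_d2 = np.mean(d_all[:, active_cols] ** 2)
    sigma2 = max(mean_d2 / max(col_norm2, 1e-30), 1e-30)
    ref = build_reference(head, parc, sigma2=sigma2)

    r = head.n_sources
    n_cols = stack.coefficients.shape[1]
    w_star = np.zeros((r, n_cols))
    flags = []
    for j in active_cols:
        sol = mem_solve(d_all[:, j], G_w, ref, eta=1.0)
        w_star[:, j] = sol.w_star
        flags.append(sol.converged)

    energy = np.sum(w_star**2, axis=1)
    tags = stack.scale_of_column()
    per_scale = {
        int(lev): np.sum(w_star[:, tags == lev] ** 2, axis=1)
        for lev in np.unique(tags)
    }
    return SourceEstimate(
        w_star, energy, per_scale, parc, active_cols,
        1.0 - len(active_cols) / n_cols, np.array(flags, dtype=bool), stack,
    )
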