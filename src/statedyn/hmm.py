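"""K-state hidden Markov model with full multivariate-normal emissions.

One group-level model is fit to the temporally concatenated, standardized
envelope data of all subjects: each state is a unique P-dimensional Gaussian
(mean vector + covariance matrix) and the latent state sequence follows a
first-order Markov chain. Inference is maximum-likelihood EM (Baum-Welch) with
k-means++ initialization, ridge-regularized covariances and best-of-n-restarts
selection; hard state time courses are obtained per subject with the Viterbi
algorithm. Forward-backward and Viterbi restart from the initial distribution
at every subject boundary, so no transition is ever counted across subjects.

All recursions use per-sample normalization (emission densities are max-shifted
in log space, then the forward/backward passes carry scaling constants), which
keeps T ~ 1e5 concatenated samples numerically stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from ._rng import substream
from .paths import StatePath

__all__ = [
    "HMMModel", "fit_hmm", "viterbi_decode", "decode_cohort", "forward_loglik",
    "match_states",
]

logger = logging.getLogger(__name__)


@dataclass
class HMMModel:
    """Point estimate of the state-space model.

    ``fit_log`` is the per-iteration total log-likelihood of the selected
    restart; EM guarantees it is non-decreasing (within rounding).
    """

    K: int
    means: np.ndarray        # (K, P)
    covariances: np.ndarray  # (K, P, P), symmetric positive-definite
    transitions: np.ndarray  # (K, K), row-stochastic
    initial: np.ndarray      # (K,), simplex
    fit_log: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None
    n_restarts: int = 1
    converged: bool = True
    covariance_type: str = "full"

    @property
    def n_parcels(self) -> int:
        return int(self.means.shape[1])

    def permute_states(self, perm: np.ndarray) -> "HMMModel":
        """Relabel states: new state i is old state perm[i]."""
        perm = np.asarray(perm)
        return HMMModel(
            K=self.K,
            means=self.means[perm],
            covariances=self.covariances[perm],
            transitions=self.transitions[np.ix_(perm, perm)],
            initial=self.initial[perm],
            fit_log=self.fit_log.copy(),
            seed=self.seed,
            n_restarts=self.n_restarts,
            converged=self.converged,
            covariance_type=self.covariance_type,
        )


# ---------------------------------------------------------------------------
# emission densities

def _chol_params(covariances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky factors and log-determinants per state; raises if not PD."""
    K = covariances.shape[0]
    chols = np.empty_like(covariances)
    logdets = np.empty(K)
    for k in range(K):
        try:
            chols[k] = np.linalg.cholesky(covariances[k])
        except np.linalg.LinAlgError as e:
            raise ValueError(f"state {k + 1} covariance is not positive-definite") from e
        logdets[k] = 2.0 * np.sum(np.log(np.diag(chols[k])))
    return chols, logdets


def _emission_logprob(X: np.ndarray, means: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    """(N, K) Gaussian log-densities of each sample under each state."""
    N, P = X.shape
    K = means.shape[0]
    chols, logdets = _chol_params(covariances)
    out = np.empty((N, K))
    const = P * np.log(2.0 * np.pi)
    for k in range(K):
        diff = X - means[k]
        z = scipy.linalg.solve_triangular(chols[k], diff.T, lower=True)
        quad = np.einsum("pn,pn->n", z, z)
        out[:, k] = -0.5 * (const + logdets[k] + quad)
    return out


# ---------------------------------------------------------------------------
# forward-backward on a batch of equal-length sequences

def _forward_backward_batch(logB: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward for S sequences of common length T.

    Returns (gamma (S,T,K), xi_sum (K,K) summed over sequences and time,
    gamma0_sum (K,), loglik total over sequences).
    """
    S, T, K = logB.shape
    shift = logB.max(axis=2, keepdims=True)
    B = np.exp(logB - shift)
    alpha = np.empty((S, T, K))
    c = np.empty((S, T))
    a = pi[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    beta = np.empty((S, T, K))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta[:, t + 1]
        beta[:, t] = (bb @ A.T) / c[:, t + 1, None]
        xi_sum += np.einsum("si,sj->ij", alpha[:, t], bb / c[:, t + 1, None]) * A
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, xi_sum, gamma[:, 0].sum(axis=0), loglik


def _group_by_length(boundaries: np.ndarray) -> dict[int, list[int]]:
    lengths = np.diff(boundaries)
    groups: dict[int, list[int]] = {}
    for i, L in enumerate(lengths):
        groups.setdefault(int(L), []).append(i)
    return groups


def _stack_group(X: np.ndarray, boundaries: np.ndarray, idx: list[int], T: int) -> np.ndarray:
    return np.stack([X[boundaries[i]: boundaries[i] + T] for i in idx])


# ---------------------------------------------------------------------------
# fitting

def _init_params(X, K, reg_ridge, rng):
    """k-means++ initialization: cluster centers as means, within-cluster
    covariances (ridge-floored), transitions from the label sequence."""
    km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(X)
    P = X.shape[1]
    means = km.cluster_centers_.copy()
    covariances = np.empty((K, P, P))
    for k in range(K):
        sel = X[labels == k]
        if sel.shape[0] > P + 1:
            covariances[k] = np.cov(sel, rowvar=False, ddof=0)
        else:
            covariances[k] = np.eye(P)
        covariances[k] += reg_ridge * np.eye(P)
    counts = np.ones((K, K))
    counts[labels[:-1], labels[1:]] += 1.0  # smoothed; boundary bleed is harmless at init
    A = counts / counts.sum(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)
    return means, covariances, A, pi


def fit_hmm(
    X: np.ndarray,
    boundaries: np.ndarray,
    K: int,
    *,
    n_restarts: int = 4,
    max_iter: int = 100,
    tol: float = 1e-6,
    reg: float = 1e-6,
    seed: int = 0,
    covariance_type: str = "full",
) -> HMMModel:
    """Fit the K-state Gaussian HMM by EM on concatenated standardized data.

    Parameters
    ----------
    X : (N, P) concatenated standardized matrix.
    boundaries : subject boundary index from the preprocessing step;
        forward-backward restarts from the initial distribution at each one.
    n_restarts : independent EM runs; the one with the best final
        log-likelihood is returned. Deterministic given ``seed``.
    tol : relative log-likelihood improvement threshold for convergence.
    reg : covariance ridge floor as a fraction of the mean data variance.
    covariance_type : "full" (default) or "diag".

    Returns the model; if no restart converges within ``max_iter`` the best
    model is still returned with ``converged=False`` and a warning.
    """
    X = np.asarray(X, dtype=float)
    N, P = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if N < K * (P + 2):
        raise ValueError(f"too few samples ({N}) for K={K}, P={P}")
    if covariance_type not in ("full", "diag"):
        raise ValueError("covariance_type must be 'full' or 'diag'")
    boundaries = np.asarray(boundaries, dtype=np.int64)
    reg_ridge = reg * float(np.mean(np.var(X, axis=0)))
    groups = _group_by_length(boundaries)
    stacks = {
        T: (_stack_group(X, boundaries, idx, T), len(idx)) for T, idx in groups.items()
    }

    best: HMMModel | None = None
    for r in range(n_restarts):
        rng = substream(seed, "hmm-restart", r)
        means, covariances, A, pi = _init_params(X, K, reg_ridge, rng)
        trace: list[float] = []
        converged = False
        for it in range(max_iter):
            logB_all = _emission_logprob(X, means, covariances)
            Ng = np.zeros(K)
            sum_x = np.zeros((K, P))
            sum_xx = np.zeros((K, P, P))
            xi_sum = np.zeros((K, K))
            g0 = np.zeros(K)
            loglik = 0.0
            n_seq = 0
            for T, idx in groups.items():
                logB = np.stack([logB_all[boundaries[i]: boundaries[i] + T] for i in idx])
                gamma, xi, gamma0, ll = _forward_backward_batch(logB, A, pi)
                loglik += ll
                xi_sum += xi
                g0 += gamma0
                n_seq += len(idx)
                g2 = gamma.reshape(-1, K)
                Xg = stacks[T][0].reshape(-1, P)
                Ng += g2.sum(axis=0)
                sum_x += g2.T @ Xg
                sum_xx += np.einsum("nk,np,nq->kpq", g2, Xg, Xg, optimize=True)
            means = sum_x / Ng[:, None]
            covariances = sum_xx / Ng[:, None, None] - np.einsum(
                "kp,kq->kpq", means, means
            )
            if covariance_type == "diag":
                covariances = np.stack([np.diag(np.diag(c)) for c in covariances])
            covariances = 0.5 * (covariances + covariances.transpose(0, 2, 1))
            covariances += reg_ridge * np.eye(P)[None]
            for k in range(K):
                ev_min = np.linalg.eigvalsh(covariances[k])[0]
                if ev_min < 0.5 * reg_ridge:
                    logger.warning(
                        "restart %d iter %d: covariance collapse in state %d; extra ridge",
                        r, it, k + 1,
                    )
                    covariances[k] += (reg_ridge - ev_min) * np.eye(P)
            if K > 1:
                A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
            pi = g0 / n_seq
            trace.append(loglik)
            if it > 0:
                prev = trace[-2]
                if loglik < prev - 1e-8 * max(1.0, abs(prev)):
                    logger.warning("restart %d: log-likelihood decreased at iter %d", r, it)
                if abs(loglik - prev) <= tol * abs(prev):
                    converged = True
                    break
        if not converged:
            warnings.warn(
                f"EM restart {r} did not converge in {max_iter} iterations",
                RuntimeWarning,
            )
        model = HMMModel(
            K=K, means=means, covariances=covariances, transitions=A
            if K > 1 else np.ones((1, 1)),
            initial=pi, fit_log=np.array(trace), seed=seed,
            n_restarts=n_restarts, converged=converged,
            covariance_type=covariance_type,
        )
        if best is None or model.fit_log[-1] > best.fit_log[-1]:
            best = model
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# decoding

def viterbi_decode(model: HMMModel, x: np.ndarray, subject_id: str | None = None) -> StatePath:
    """Most probable state sequence for one subject (log-space recursion).

    Ties are broken toward the lower state index (first argmax).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.n_parcels:
        raise ValueError(
            f"series has {x.shape[1] if x.ndim == 2 else '?'} columns, model expects {model.n_parcels}"
        )
    states = _viterbi_batch(model, x[None])[0]
    return StatePath(states=states + 1, K=model.K, subject_id=subject_id)


def _viterbi_batch(model: HMMModel, xs: np.ndarray) -> np.ndarray:
    """Viterbi over a (S, T, P) stack; returns (S, T) 0-based states."""
    S, T, P = xs.shape
    K = model.K
    with np.errstate(divide="ignore"):
        logA = np.log(model.transitions)
        logpi = np.log(model.initial)
    logB = _emission_logprob(xs.reshape(-1, P), model.means, model.covariances).reshape(S, T, K)
    delta = logpi[None, :] + logB[:, 0]
    psi = np.empty((S, T, K), dtype=np.int32)
    for t in range(1, T):
        cand = delta[:, :, None] + logA[None, :, :]  # (S, prev, next)
        psi[:, t] = cand.argmax(axis=1)              # first max = lower prev index
        delta = cand.max(axis=1) + logB[:, t]
    states = np.empty((S, T), dtype=np.int64)
    states[:, T - 1] = delta.argmax(axis=1)
    rows = np.arange(S)
    for t in range(T - 2, -1, -1):
        states[:, t] = psi[rows, t + 1, states[:, t + 1]]
    return states


def decode_cohort(
    model: HMMModel,
    X: np.ndarray,
    boundaries: np.ndarray,
    subject_ids: list[str] | None = None,
) -> list[StatePath]:
    """Viterbi-decode every subject of a concatenated standardized matrix.

    Each subject restarts from the initial distribution; path lengths equal
    series lengths. Equal-length subjects are decoded as one batch.
    """
    boundaries = np.asarray(boundaries, dtype=np.int64)
    n = len(boundaries) - 1
    if subject_ids is None:
        subject_ids = [f"sub{i + 1}" for i in range(n)]
    out: list[StatePath | None] = [None] * n
    for T, idx in _group_by_length(boundaries).items():
        stack = _stack_group(X, boundaries, idx, T)
        decoded = _viterbi_batch(model, stack)
        for j, i in enumerate(idx):
            out[i] = StatePath(states=decoded[j] + 1, K=model.K, subject_id=subject_ids[i])
    return out  # type: ignore[return-value]


def match_states(reference_means: np.ndarray, estimated_means: np.ndarray) -> np.ndarray:
    """Optimal state relabeling for evaluation against a reference model.

    HMM state labels are arbitrary (label switching); this returns the
    permutation ``perm`` maximizing the summed Pearson correlation between
    reference mean vectors and ``estimated_means[perm]``, via the Hungarian
    assignment.
    """
    from scipy.optimize import linear_sum_assignment

    R = np.corrcoef(reference_means, estimated_means)[
        : reference_means.shape[0], reference_means.shape[0]:
    ]
    _, perm = linear_sum_assignment(-R)
    return perm


def forward_loglik(model: HMMModel, x: np.ndarray) -> float:
    """Total data log-likelihood of one sequence (scaled forward pass)."""
    x = np.asarray(x, dtype=float)
    logB = _emission_logprob(x, model.means, model.covariances)[None]
    _, _, _, ll = _forward_backward_batch(logB, model.transitions, model.initial)
    return ll


def viterbi_path_loglik(model: HMMModel, path: StatePath, x: np.ndarray) -> float:
    """Joint log-probability of (path, data); <= forward_loglik by definition."""
    s = path.states - 1
    logB = _emission_logprob(np.asarray(x, dtype=float), model.means, model.covariances)
    with np.errstate(divide="ignore"):
        ll = np.log(model.initial[s[0]]) + logB[0, s[0]]
        ll += np.sum(np.log(model.transitions[s[:-1], s[1:]]))
    ll += logB[np.arange(1, len(s)), s[1:]].sum()
    return float(ll)
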