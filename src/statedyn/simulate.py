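"""Synthetic cohort generator with planted ground truth.

Generates everything the downstream pipeline consumes, with known answers:

1.  Latent dynamics: each subject's state sequence is a first-order Markov
    chain (transition matrix A, initial distribution pi).
2.  Envelopes: sample t is drawn from the multivariate normal of its state
    (mean vector + covariance matrix per state), on a positive baseline so
    amplitude values are effectively nonnegative (draws below zero - possible
    only in the extreme Gaussian tail - are clipped and counted).
3.  Behavior: the true temporal metrics of each subject's path are z-scored
    across the cohort and projected on the planted unit brain salience w to
    give a standardized brain latent b. The continuous sleep latent is

        s = rho * b + gamma_std * z(age) + delta * z(b * z(age)) + noise,

    where gamma_std = gamma_per_year * SD(age); by default the noise completes
    s to unit population variance so rho, gamma_std and delta are standardized
    effect sizes directly comparable with the second-level moderation betas.
    Each of the 7 sleep components is lambda_j * s + noise, discretized to the
    ordinal scale {0, 1, 2, 3} by within-cohort quartile cutpoints (higher =
    worse sleep). Each of the 13 cognitive scores is c_j * (-b) + noise, so a
    higher brain latent accompanies worse cognition.

Ages are uniform on [18, 88] years. All randomness flows from the scenario
seed through named substreams, so identical configs give bitwise-identical
cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .config import AGE_RANGE, AGE_SD, N_COG, N_SLEEP, ScenarioConfig
from .metrics import TemporalMetrics, metrics_matrix, temporal_metrics
from .paths import StatePath
from .preprocess import EnvelopeDataset

__all__ = [
    "GroundTruth", "simulate_state_sequence", "emit_envelopes", "simulate_cohort",
    "planted_rank1_blocks",
]

logger = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_paths: list[StatePath]
    true_metrics: pd.DataFrame            # subjects x 4K, NaN = missing
    true_salience_pair: tuple[np.ndarray, np.ndarray]  # (brain side, sleep side)
    true_coefficients: dict[str, float]   # rho, gamma (per year), gamma_std, delta
    latent_brain: np.ndarray              # standardized b per subject
    latent_sleep: np.ndarray              # continuous sleep latent s per subject
    ages: np.ndarray


def _check_stochastic(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(A < 0) or np.max(np.abs(A.sum(axis=1) - 1.0)) > 1e-12:
        raise ValueError("transition matrix must be row-stochastic with nonnegative entries")
    return A


def _sample_paths(A: np.ndarray, pi: np.ndarray, T: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, T) 0-based Markov chains, vectorized across chains."""
    K = A.shape[0]
    cumA = np.cumsum(A, axis=1)
    cum0 = np.cumsum(pi)
    states = np.empty((n, T), dtype=np.int64)
    states[:, 0] = np.searchsorted(cum0, rng.random(n), side="right").clip(max=K - 1)
    for t in range(1, T):
        u = rng.random(n)
        row = cumA[states[:, t - 1]]
        states[:, t] = (u[:, None] > row).sum(axis=1).clip(max=K - 1)
    return states


def simulate_state_sequence(A: np.ndarray, pi: np.ndarray, T: int, seed: int) -> StatePath:
    """One Markov chain of length T: first state from pi, transitions from A."""
    A = _check_stochastic(A)
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-12 or np.any(pi < 0):
        raise ValueError("initial distribution must be a simplex vector")
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = substream(seed, "state-sequence")
    states = _sample_paths(A, pi, T, 1, rng)[0]
    return StatePath(states=states + 1, K=A.shape[0])


def emit_envelopes(
    path: StatePath,
    means: np.ndarray,
    covs: np.ndarray,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw row t from the multivariate normal of state path[t].

    Negative draws (possible only far in the Gaussian tail for the shipped
    scenarios) are clipped to zero to respect the amplitude-envelope domain;
    clips are counted in the log.
    """
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covs, dtype=float)
    K, P = means.shape
    if path.K > K:
        raise ValueError("path states exceed the number of emission distributions")
    chols = np.empty_like(covs)
    for k in range(K):
        try:
            chols[k] = np.linalg.cholesky(covs[k])
        except np.linalg.LinAlgError as e:
            raise ValueError(f"state {k + 1} covariance is not positive-definite") from e
    if rng is None:
        rng = substream(0 if seed is None else seed, "envelopes")
    T = len(path)
    z = rng.standard_normal((T, P))
    out = np.empty((T, P))
    s = path.states - 1
    for k in range(K):
        rows = s == k
        if rows.any():
            out[rows] = means[k] + z[rows] @ chols[k].T
    n_neg = int((out < 0).sum())
    if n_neg:
        logger.info("clipped %d negative envelope draws to 0", n_neg)
        out = np.clip(out, 0.0, None)
    return out


def planted_rank1_blocks(
    n: int,
    u: np.ndarray,
    v: np.ndarray,
    rho: float,
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two blocks whose population cross-covariance is exactly rank-1.

    X has p = len(u) independent standard-normal columns; Y = rho * (X u) v' +
    noise, so cov(X, Y) = rho * u v'. This is the direct planted-salience
    construction used to validate PLS recovery: unlike the cohort channel
    (where the metric correlation structure transforms the singular vectors),
    the singular vectors here equal u and v exactly in population.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    rng = substream(seed, "rank1-blocks")
    X = rng.standard_normal((n, u.size))
    Y = rho * np.outer(X @ u, v) + noise_sd * rng.standard_normal((n, v.size))
    return X, Y


def _nan_zscore(df: pd.DataFrame) -> np.ndarray:
    """Column z-scores with NaNs ignored in the moments and set to 0 after
    (mean imputation on the standardized scale); used only to form the true
    brain latent when a rare subject misses a state."""
    X = df.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant metric column in the generated cohort")
    Z = (X - mu) / sd
    return np.nan_to_num(Z, nan=0.0)


def _z(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def simulate_cohort(
    config: ScenarioConfig, *, emit: bool = True
) -> tuple[EnvelopeDataset | None, pd.DataFrame, GroundTruth]:
    """Generate a full cohort: envelopes, behavioral table, ground truth.

    ``emit=False`` skips the envelope draws (paths, metrics and behavior only),
    which is what calibration studies that never touch the HMM need.

    The behavioral table has columns: subject_id, age, sex, sleep_1..sleep_7
    (ordinal 0-3), cog_1..cog_13 (continuous).
    """
    K, P, T, n = (
        config.n_states,
        config.n_parcels,
        config.samples_per_subject,
        config.n_subjects,
    )
    if n < 4 * K + 2:
        warnings.warn(
            f"n_subjects={n} < 4K+2={4 * K + 2}: PLS/regression will be ill-conditioned",
            UserWarning,
        )
    seed = config.seed
    subject_ids = [f"sub{i + 1:04d}" for i in range(n)]

    ages = substream(seed, "ages").uniform(*AGE_RANGE, size=n)
    sex = substream(seed, "sex").integers(0, 2, size=n)

    raw_paths = _sample_paths(
        config.transition_matrix, config.initial_dist, T, n, substream(seed, "paths")
    )
    true_paths = [
        StatePath(states=raw_paths[i] + 1, K=K, subject_id=subject_ids[i]) for i in range(n)
    ]

    dataset = None
    if emit:
        env_rng = substream(seed, "envelopes")
        series = [
            emit_envelopes(p, config.state_means, config.state_covs, rng=env_rng)
            for p in true_paths
        ]
        dataset = EnvelopeDataset(subjects=subject_ids, series=series, dt=config.dt)

    per_subject = [temporal_metrics(p, config.dt) for p in true_paths]
    true_metrics, _ = metrics_matrix(per_subject, drop_incomplete=False)
    Z = _nan_zscore(true_metrics)
    b = _z(Z @ config.brain_salience)

    rho, delta = config.effect_size, config.moderation_slope
    gamma_std = config.age_slope * AGE_SD
    za = _z(ages)
    inter = b * za
    inter = _z(inter) if inter.std(ddof=1) > 0 else inter
    if config.latent_noise_sd is not None:
        lat_sd = config.latent_noise_sd
    else:
        lat_sd = float(np.sqrt(max(1.0 - rho**2 - gamma_std**2 - delta**2, 0.05)))
    s = (
        rho * b
        + gamma_std * za
        + delta * inter
        + lat_sd * substream(seed, "latent-noise").standard_normal(n)
    )

    sleep_rng = substream(seed, "sleep-noise")
    sleep = np.empty((n, N_SLEEP), dtype=np.int64)
    for j in range(N_SLEEP):
        cont = config.sleep_weights[j] * s + config.noise_sd * sleep_rng.standard_normal(n)
        cuts = np.quantile(cont, [0.25, 0.5, 0.75])
        sleep[:, j] = np.searchsorted(cuts, cont, side="right")

    cog_rng = substream(seed, "cog-noise")
    cog = np.empty((n, N_COG))
    for j in range(N_COG):
        cog[:, j] = config.cognition_weights[j] * (-b) + config.noise_sd * cog_rng.standard_normal(n)

    behavior = pd.DataFrame({"subject_id": subject_ids, "age": ages, "sex": sex})
    for j in range(N_SLEEP):
        behavior[f"sleep_{j + 1}"] = sleep[:, j]
    for j in range(N_COG):
        behavior[f"cog_{j + 1}"] = cog[:, j]

    lam = config.sleep_weights
    truth = GroundTruth(
        true_paths=true_paths,
        true_metrics=true_metrics,
        true_salience_pair=(config.brain_salience.copy(), lam / np.linalg.norm(lam)),
        true_coefficients={
            "rho": rho,
            "gamma": config.age_slope,
            "gamma_std": gamma_std,
            "delta": delta,
        },
        latent_brain=b,
        latent_sleep=s,
        ages=ages,
    )
    return dataset, behavior, truth
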