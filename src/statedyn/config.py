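"""Scenario configuration for the synthetic cohort generator.

A scenario fixes everything the generator needs: the Markov dynamics (K states,
transition matrix, initial distribution), the per-state Gaussian envelope
emission parameters, and the planted brain-behavior structure - a unit brain
salience vector w over the 4K temporal metrics, sleep component weights (7,
PSQI-style ordinal components scored 0-3), cognitive score weights (13), a
standardized brain-behavior effect size rho, a per-year age slope gamma on the
sleep latent, and a moderation (brain x age interaction) slope delta.

Two ready-made scales are provided: a desk-scale scenario (K=3 states, 5
parcels) used throughout the tests, and a paper-scale scenario (K=8 states,
38 parcels) for demonstration runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["ScenarioConfig", "test_scenario", "paper_scale_scenario", "AGE_RANGE", "AGE_SD"]

AGE_RANGE = (18.0, 88.0)
#: population SD of uniform ages on AGE_RANGE; converts per-year slopes to
#: standardized ones
AGE_SD = (AGE_RANGE[1] - AGE_RANGE[0]) / np.sqrt(12.0)

N_SLEEP = 7
N_COG = 13


@dataclass
class ScenarioConfig:
    n_subjects: int
    n_parcels: int
    n_states: int
    samples_per_subject: int
    dt: float
    transition_matrix: np.ndarray   # (K, K) row-stochastic
    initial_dist: np.ndarray        # (K,) simplex
    state_means: np.ndarray         # (K, P)
    state_covs: np.ndarray          # (K, P, P) SPD
    brain_salience: np.ndarray      # (4K,), unit norm
    sleep_weights: np.ndarray       # (7,)
    cognition_weights: np.ndarray   # (13,)
    effect_size: float = 0.5        # rho: standardized brain -> sleep latent
    age_slope: float = -0.015       # gamma: per-year effect on the sleep latent
    moderation_slope: float = 0.0   # delta: standardized brain x age interaction
    noise_sd: float = 0.6           # per behavioral variable, before discretization
    latent_noise_sd: float | None = None  # None: complete sleep latent to unit variance
    seed: int = 0

    def __post_init__(self) -> None:
        K, P = self.n_states, self.n_parcels
        A = np.asarray(self.transition_matrix, dtype=float)
        if A.shape != (K, K) or np.any(A < 0) or np.max(np.abs(A.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition_matrix must be K x K row-stochastic (tol 1e-12)")
        self.transition_matrix = A
        pi = np.asarray(self.initial_dist, dtype=float)
        if pi.shape != (K,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("initial_dist must be a length-K simplex vector")
        self.initial_dist = pi
        self.state_means = np.asarray(self.state_means, dtype=float).reshape(K, P)
        covs = np.asarray(self.state_covs, dtype=float).reshape(K, P, P)
        for k in range(K):
            if np.linalg.eigvalsh(covs[k])[0] <= 0:
                raise ValueError(f"state {k + 1} covariance is not positive-definite")
        self.state_covs = covs
        w = np.asarray(self.brain_salience, dtype=float)
        if w.shape != (4 * K,) or abs(np.linalg.norm(w) - 1.0) > 1e-12:
            raise ValueError("brain_salience must be a unit vector of length 4K (tol 1e-12)")
        self.brain_salience = w
        self.sleep_weights = np.asarray(self.sleep_weights, dtype=float).reshape(N_SLEEP)
        self.cognition_weights = np.asarray(self.cognition_weights, dtype=float).reshape(N_COG)
        if self.samples_per_subject < 1 or self.n_subjects < 1 or self.dt <= 0:
            raise ValueError("n_subjects, samples_per_subject must be >= 1 and dt > 0")


def _sticky_transitions(K: int, stay: float) -> np.ndarray:
    if K == 1:
        return np.ones((1, 1))
    A = np.full((K, K), (1.0 - stay) / (K - 1))
    np.fill_diagonal(A, stay)
    return A


def _default_salience(K: int) -> np.ndarray:
    """Planted 'neural shift' pattern over the metric-major 4K feature vector:
    the first half of the states ('higher-order' analogue) load positively on
    occupancy and occurrence and negatively on interval length; the second half
    ('lower-order' analogue) load the opposite way."""
    sign = np.where(np.arange(K) < (K + 1) // 2, 1.0, -1.0)
    w = np.concatenate([sign, 0.3 * sign, sign, -sign])  # FO, MLT, NO, MIL blocks
    return w / np.linalg.norm(w)


# ordering follows the PSQI components: quality, latency, duration, efficiency,
# disturbance, medication use, daytime dysfunction; efficiency/duration/meds
# carry the strongest planted loadings, daytime dysfunction the weakest
_SLEEP_WEIGHTS = np.array([0.55, 0.50, 0.75, 0.80, 0.45, 0.70, 0.25])

# 13 cognitive scores; the first (fluid-intelligence analogue) loads strongest
_COG_WEIGHTS = np.array(
    [0.80, 0.60, 0.50, 0.50, 0.20, 0.25, 0.20, 0.30, 0.15, 0.40, 0.30, 0.35, 0.30]
)

#: baseline envelope amplitude; keeps Gaussian emissions effectively nonnegative
ENVELOPE_BASELINE = 6.0


def _state_emissions(K: int, P: int, separation: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    means = ENVELOPE_BASELINE + separation * np.eye(K, P)
    covs = np.empty((K, P, P))
    for k in range(K):
        scale = 0.7 + 0.1 * (k % 4)
        r = 0.05 * (k % 4)
        covs[k] = scale * ((1.0 - r) * np.eye(P) + r * np.ones((P, P)))
    return means, covs


def _scenario(n_subjects, n_parcels, K, T, dt, seed, stay, **kw) -> ScenarioConfig:
    means, covs = _state_emissions(K, n_parcels)
    return ScenarioConfig(
        n_subjects=n_subjects,
        n_parcels=n_parcels,
        n_states=K,
        samples_per_subject=T,
        dt=dt,
        transition_matrix=_sticky_transitions(K, stay),
        initial_dist=np.full(K, 1.0 / K),
        state_means=means,
        state_covs=covs,
        brain_salience=_default_salience(K),
        sleep_weights=_SLEEP_WEIGHTS.copy(),
        cognition_weights=_COG_WEIGHTS.copy(),
        seed=seed,
        **kw,
    )


def test_scenario(
    n_subjects: int = 200,
    samples_per_subject: int = 300,
    seed: int = 0,
    **kw,
) -> ScenarioConfig:
    """Desk-scale scenario: K = 3 states, 5 parcels, sticky chain (stay 0.8,
    mean dwell 0.5 s at dt = 0.1 s)."""
    return _scenario(n_subjects, 5, 3, samples_per_subject, 0.1, seed, 0.8, **kw)


def paper_scale_scenario(
    n_subjects: int = 100,
    samples_per_subject: int = 400,
    seed: int = 0,
    **kw,
) -> ScenarioConfig:
    """Paper-scale scenario: K = 8 states, 38 parcels."""
    return _scenario(n_subjects, 38, 8, samples_per_subject, 0.1, seed, 0.8, **kw)
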