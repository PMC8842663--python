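"""Covariance-maximizing partial least squares with a subject-permutation test.

Given two z-scored blocks X (n x p brain temporal metrics) and Y (n x q
behavioral scores), the paired latent variables are the singular vectors of the
cross-covariance matrix C = X'Y/(n-1): each component is a pair of unit weight
vectors ("saliences") whose latent scores have maximal covariance among
directions orthogonal to the earlier components. Significance is assessed by
shuffling the subject rows of Y (breaking the brain-behavior pairing while
preserving each block's internal covariance) and comparing each observed
singular value with its permuted counterparts. Interpretation uses "structure
loadings" - the Pearson correlation of each original variable with its latent
score - thresholded at |loading| > 0.2 by default; structure loadings are
bounded in [-1, 1], which makes an absolute cut-off meaningful, whereas raw
weights are not.

Sign convention: each component is flipped so that the mean of the Y-side
(behavioral) salience is nonnegative, so "higher behavioral latent" reads as
"higher behavioral scores" on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import numpy as np

from ._rng import substream
from .preprocess import zscore_columns

__all__ = [
    "PLSResult",
    "pls_fit",
    "structure_loadings",
    "pls_permutation_test",
    "threshold_loadings",
]


@dataclass
class PLSResult:
    """Fitted PLS decomposition (r = min(p, q) components).

    ``saliences_X``/``saliences_Y`` are orthonormal weight matrices; scores are
    the per-subject latent variables; ``perm_p`` is filled in by
    :func:`pls_permutation_test`.
    """

    saliences_X: np.ndarray          # (p, r)
    saliences_Y: np.ndarray          # (q, r)
    singular_values: np.ndarray      # (r,), nonincreasing
    scores_X: np.ndarray             # (n, r)
    scores_Y: np.ndarray             # (n, r)
    structure_loadings_X: np.ndarray  # (p, r), in [-1, 1]
    structure_loadings_Y: np.ndarray  # (q, r)
    perm_p: np.ndarray | None = None
    n_perm: int = 0
    seed: int | None = None
    x_names: list[str] | None = None
    y_names: list[str] | None = None
    subject_ids: list[str] | None = None

    @property
    def n_components(self) -> int:
        return int(self.singular_values.size)

    def first_significant(self, alpha: float = 0.05) -> int:
        """Index of the first component with permutation p < alpha (0 if the
        test was not run; raises if none is significant)."""
        if self.perm_p is None:
            return 0
        sig = np.where(self.perm_p < alpha)[0]
        if sig.size == 0:
            raise ValueError(f"no component significant at alpha={alpha}")
        return int(sig[0])


def _cross_cov(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return X.T @ Y / (X.shape[0] - 1)


def pls_fit(
    X: np.ndarray,
    Y: np.ndarray,
    *,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
    subject_ids: list[str] | None = None,
) -> PLSResult:
    """SVD of the cross-covariance between two blocks over the same subjects.

    Inputs are z-scored internally (idempotent if already standardized; a
    constant column raises, naming it). Warns when n <= max(p, q), where the
    decomposition is poorly conditioned.
    """
    X = zscore_columns(np.asarray(X, dtype=float), names=x_names)
    Y = zscore_columns(np.asarray(Y, dtype=float), names=y_names)
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of subjects")
    if n <= max(p, q):
        warnings.warn(
            f"n={n} <= max(p, q)={max(p, q)}: PLS is ill-conditioned", UserWarning
        )
    U, s, Vt = np.linalg.svd(_cross_cov(X, Y), full_matrices=False)
    V = Vt.T
    # component sign: mean of the behavioral salience >= 0
    flip = V.mean(axis=0) < 0
    U[:, flip] *= -1.0
    V[:, flip] *= -1.0
    scores_X = X @ U
    scores_Y = Y @ V
    res = PLSResult(
        saliences_X=U, saliences_Y=V, singular_values=s,
        scores_X=scores_X, scores_Y=scores_Y,
        structure_loadings_X=np.empty(0), structure_loadings_Y=np.empty(0),
        x_names=x_names, y_names=y_names, subject_ids=subject_ids,
    )
    res.structure_loadings_X = structure_loadings(res, X, side="X")
    res.structure_loadings_Y = structure_loadings(res, Y, side="Y")
    return res


def structure_loadings(result: PLSResult, block: np.ndarray, side: str = "X") -> np.ndarray:
    """Pearson correlation of each original variable with its latent score.

    ``block`` must be the (z-scored) matrix the result was fit on for the
    requested side. Values are bounded in [-1, 1].
    """
    scores = result.scores_X if side == "X" else result.scores_Y
    B = np.asarray(block, dtype=float)
    Bc = B - B.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    denom = np.sqrt((Bc**2).sum(axis=0))[:, None] * np.sqrt((Sc**2).sum(axis=0))[None, :]
    return np.clip((Bc.T @ Sc) / denom, -1.0, 1.0)


def pls_permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    statistic: str = "per_component",
    permutations: Iterable[Sequence[int]] | None = None,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
    subject_ids: list[str] | None = None,
) -> PLSResult:
    """Fit PLS and attach subject-permutation p-values per component.

    The rows of Y are shuffled as whole subjects ``n_perm`` times. With the
    default ``statistic="per_component"`` the k-th observed singular value is
    compared with the distribution of k-th permuted singular values;
    ``statistic="max"`` compares every component against the permuted largest
    singular value (a conservative familywise variant). Counting uses >= with
    the +1 correction: p = (1 + #{s_perm >= s_obs}) / (1 + n_perm), so p-values
    lie on the grid {1/(n_perm+1), ..., 1} and are deterministic given seed.

    ``permutations`` overrides the random draws with an explicit iterable of
    row orders (n_perm is then ignored) - useful for exact/forced nulls.
    """
    if permutations is None and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("per_component", "max"):
        raise ValueError("statistic must be 'per_component' or 'max'")
    res = pls_fit(
        X, Y, x_names=x_names, y_names=y_names, subject_ids=subject_ids
    )
    Xz = zscore_columns(np.asarray(X, dtype=float))
    Yz = zscore_columns(np.asarray(Y, dtype=float))
    # observed statistic computed with the same SVD routine as the permuted
    # ones, so an identity permutation ties exactly
    s_obs = np.linalg.svd(_cross_cov(Xz, Yz), compute_uv=False)
    r = s_obs.size
    if permutations is None:
        rng = substream(seed, "pls-permutation")
        perm_iter: Iterable[Sequence[int]] = (
            rng.permutation(Xz.shape[0]) for _ in range(n_perm)
        )
    else:
        perm_iter = permutations
    count = np.zeros(r)
    m = 0
    for perm in perm_iter:
        s_perm = np.linalg.svd(_cross_cov(Xz, Yz[np.asarray(perm)]), compute_uv=False)
        if statistic == "max":
            count += s_perm[0] >= s_obs
        else:
            count += s_perm[:r] >= s_obs
        m += 1
    res.perm_p = (1.0 + count) / (1.0 + m)
    res.n_perm = m
    res.seed = seed
    return res


def threshold_loadings(loadings: np.ndarray, tau: float = 0.2) -> np.ndarray:
    """Boolean keep-mask: |loading| strictly greater than tau (default 0.2)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return np.abs(np.asarray(loadings)) > tau
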