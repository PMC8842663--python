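"""Second-level models: age moderation of the brain-behavior link, and
cross-analysis comparison of brain profiles.

Moderation: the behavioral latent score (from PLS) is regressed on the brain
latent score, age, their interaction, and optional covariates, all
standardized, by ordinary least squares. The interaction is built by z-scoring
the brain score and age, multiplying, and re-z-scoring the product (default;
the raw-product alternative is available by flag), so every reported beta is a
standardized coefficient with a two-sided t test on n - (k+1) residual degrees
of freedom.

Profile comparison: the brain-side structure loadings (and per-subject brain
scores) from two PLS analyses sharing the same brain block are Pearson
correlated, overall and within named groups of brain features (e.g. state
families), with the second analysis sign-aligned to the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .pls import PLSResult
from .preprocess import zscore_columns

__all__ = ["ModerationResult", "ProfileComparison", "moderation_fit", "compare_profiles"]


@dataclass
class ModerationResult:
    """Standardized OLS fit of behavior latent ~ brain latent * age (+ covariates)."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    n: int

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "df_resid": self.df_resid,
            "terms": {
                nm: {"beta": float(b), "se": float(s), "t": float(t), "p": float(p)}
                for nm, b, s, t, p in zip(self.names, self.beta, self.se, self.t, self.p)
            },
        }


@dataclass
class ProfileComparison:
    """Correlations between two PLS brain profiles."""

    r_loadings_overall: float
    p_loadings_overall: float
    r_loadings_per_group: dict[str, float]
    p_loadings_per_group: dict[str, float]
    r_scores: float
    p_scores: float
    n_loadings: int
    n_scores: int
    component_a: int
    component_b: int
    flipped_b: bool


def _z(v: np.ndarray) -> np.ndarray:
    return zscore_columns(np.asarray(v, dtype=float).reshape(-1, 1))[:, 0]


def moderation_fit(
    outcome: np.ndarray,
    brain: np.ndarray,
    age: np.ndarray,
    covariates: dict[str, np.ndarray] | None = None,
    *,
    interaction: str = "z_then_product",
) -> ModerationResult:
    """OLS of z(outcome) on z(brain), z(age), their interaction and covariates.

    ``interaction="z_then_product"`` (default): z(z(brain) * z(age));
    ``"product_then_z"``: z(brain * age). Covariates are z-scored too.
    Raises on rank-deficient designs, naming the collinear columns.
    """
    if interaction not in ("z_then_product", "product_then_z"):
        raise ValueError("interaction must be 'z_then_product' or 'product_then_z'")
    outcome = np.asarray(outcome, dtype=float)
    brain = np.asarray(brain, dtype=float)
    age = np.asarray(age, dtype=float)
    n = outcome.size
    if brain.size != n or age.size != n:
        raise ValueError("outcome, brain and age must have equal length")
    if np.isnan(outcome).any() or np.isnan(brain).any() or np.isnan(age).any():
        raise ValueError("missing values are not supported")
    zb, za = _z(brain), _z(age)
    if interaction == "z_then_product":
        inter = _z(zb * za)
    else:
        inter = _z(brain * age)
    names = ["brain", "age", "brain_x_age"]
    cols = [zb, za, inter]
    for nm, v in (covariates or {}).items():
        v = np.asarray(v, dtype=float)
        if v.size != n:
            raise ValueError(f"covariate {nm} has wrong length")
        names.append(nm)
        cols.append(_z(v))
    design = np.column_stack(cols)
    if n < design.shape[1] + 2:
        raise ValueError("too few observations for the number of predictors")
    full = np.column_stack([np.ones(n), design])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        # name the offending columns via pivoted QR on the standardized design
        _, _, piv = scipy.linalg.qr(design, pivoting=True)
        rank = np.linalg.matrix_rank(design)
        bad = [names[i] for i in sorted(piv[rank:])]
        raise ValueError(f"rank-deficient design; collinear column(s): {', '.join(bad)}")
    fit = sm.OLS(_z(outcome), sm.add_constant(design)).fit()
    return ModerationResult(
        names=names,
        beta=np.asarray(fit.params[1:]),
        se=np.asarray(fit.bse[1:]),
        t=np.asarray(fit.tvalues[1:]),
        p=np.asarray(fit.pvalues[1:]),
        df_resid=int(fit.df_resid),
        n=n,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    r, p = scipy.stats.pearsonr(a, b)
    return float(r), float(p)


def compare_profiles(
    resA: PLSResult,
    resB: PLSResult,
    groups: dict[str, list[str]] | None = None,
    *,
    component: str | tuple[int, int] = "first_significant",
    alpha: float = 0.05,
) -> ProfileComparison:
    """Correlate the brain-side loading vectors (and subject scores) of two
    PLS analyses fit on the same brain feature block.

    Component choice: ``"first_significant"`` (default; falls back to the
    first component when no permutation test was run) or an explicit
    ``(index_a, index_b)`` pair. The component of B is sign-aligned to A:
    if the overall loading correlation is negative B's loadings and scores
    are flipped, and the flip is recorded.
    """
    if resA.x_names is None or resA.x_names != resB.x_names:
        if resA.structure_loadings_X.shape[0] != resB.structure_loadings_X.shape[0]:
            raise ValueError("the two analyses do not share brain feature columns")
    if isinstance(component, tuple):
        ca, cb = component
    else:
        ca = resA.first_significant(alpha)
        cb = resB.first_significant(alpha)
    la = resA.structure_loadings_X[:, ca].copy()
    lb = resB.structure_loadings_X[:, cb].copy()
    r0, _ = _pearson(la, lb)
    flipped = r0 < 0
    sb = resB.scores_X[:, cb].copy()
    if flipped:
        lb, sb = -lb, -sb
    r_all, p_all = _pearson(la, lb)
    r_groups: dict[str, float] = {}
    p_groups: dict[str, float] = {}
    if groups:
        if resA.x_names is None:
            raise ValueError("named groups require x_names on the PLS results")
        name_to_idx = {nm: i for i, nm in enumerate(resA.x_names)}
        for gname, cols in groups.items():
            idx = [name_to_idx[c] for c in cols]
            r_groups[gname], p_groups[gname] = _pearson(la[idx], lb[idx])
    sa = resA.scores_X[:, ca]
    if resA.subject_ids is not None and resB.subject_ids is not None:
        if resA.subject_ids != resB.subject_ids:
            shared = [s for s in resA.subject_ids if s in set(resB.subject_ids)]
            if not shared:
                raise ValueError("disjoint subject sets: cannot correlate scores")
            ia = [resA.subject_ids.index(s) for s in shared]
            ib = [resB.subject_ids.index(s) for s in shared]
            sa, sb = sa[ia], sb[ib]
    elif sa.size != sb.size:
        raise ValueError("subject score vectors have different lengths")
    r_sc, p_sc = _pearson(sa, sb)
    return ProfileComparison(
        r_loadings_overall=r_all, p_loadings_overall=p_all,
        r_loadings_per_group=r_groups, p_loadings_per_group=p_groups,
        r_scores=r_sc, p_scores=p_sc,
        n_loadings=int(la.size), n_scores=int(sa.size),
        component_a=ca, component_b=cb, flipped_b=flipped,
    )
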