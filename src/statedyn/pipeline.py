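"""End-to-end orchestration: simulate -> preprocess -> HMM -> metrics ->
two PLS analyses (brain-sleep, brain-cognition) -> moderation -> profile
comparison, as one reproducible run.

Both PLS analyses consume the SAME fitted group HMM and the same brain metric
matrix, so their loadings and subject scores are directly comparable - which
is what the final profile-comparison stage relies on. All randomness flows
from one root seed through named substreams (simulation, HMM restarts,
permutations), so a run directory plus its config re-creates every artifact
bitwise.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream
from .config import ScenarioConfig
from .hmm import decode_cohort, fit_hmm
from .io import (
    save_envelopes, save_metrics_csv, save_model, save_paths, save_pls_result,
    write_json,
)
from .metrics import METRIC_NAMES, metrics_matrix, temporal_metrics
from .pls import pls_permutation_test, threshold_loadings
from .preprocess import standardize_for_hmm
from .second_level import compare_profiles, moderation_fit
from .simulate import simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "state_groups"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Flags mirror the method choices that have documented alternatives:
    per-subject standardization, diagonal covariances, the interaction
    construction order and the permutation statistic.
    """

    scenario: ScenarioConfig
    outdir: str | Path = "run"
    n_states: int | None = None        # fit K; default: the scenario's true K
    n_restarts: int = 2
    max_iter: int = 100
    n_perm: int = 1000
    threshold: float = 0.2
    alpha: float = 0.05
    seed: int = 0
    per_subject_standardize: bool = False
    covariance_type: str = "full"
    interaction: str = "z_then_product"
    perm_statistic: str = "per_component"
    write_envelopes: bool = True


def state_groups(K: int) -> dict[str, list[str]]:
    """Named brain-feature column groups, one per state (the synthetic
    analogue of the paper-style FTP/HOV/EV/SM state families)."""
    return {
        f"state{k}": [f"{m}_state{k}" for m in METRIC_NAMES] for k in range(1, K + 1)
    }


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the summary dictionary.

    Artifacts written to ``config.outdir``: config.yaml, versions.json,
    envelopes.h5 (optional), model.h5, paths.h5, metrics.csv, the two PLS
    result bundles, and summary.json. On failure the partial artifacts remain
    and the raised error names the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario
    K_fit = config.n_states or scenario.n_states

    with open(outdir / "config.yaml", "w") as f:
        yaml.safe_dump(_config_dict(config), f, sort_keys=True)
    write_json(outdir / "versions.json", {"statedyn": __version__, "numpy": np.__version__})

    # -- simulate ----------------------------------------------------------
    dataset, behavior, truth = _stage("simulate")(simulate_cohort)(scenario)
    if config.write_envelopes:
        save_envelopes(outdir / "envelopes.h5", dataset)

    # -- preprocess --------------------------------------------------------
    X, boundaries = _stage("preprocess")(standardize_for_hmm)(
        dataset, per_subject=config.per_subject_standardize
    )

    # -- fit HMM -----------------------------------------------------------
    model = _stage("fit-hmm")(fit_hmm)(
        X, boundaries, K_fit,
        n_restarts=config.n_restarts, max_iter=config.max_iter,
        seed=int(substream(config.seed, "hmm").integers(2**31 - 1)),
        covariance_type=config.covariance_type,
    )
    save_model(outdir / "model.h5", model)

    # -- decode + metrics --------------------------------------------------
    paths = _stage("decode")(decode_cohort)(model, X, boundaries, dataset.subjects)
    save_paths(outdir / "paths.h5", paths)
    per_subject = [temporal_metrics(p, dataset.dt) for p in paths]
    metrics, dropped = _stage("metrics")(metrics_matrix)(per_subject)
    save_metrics_csv(outdir / "metrics.csv", metrics)

    behavior = behavior.set_index("subject_id").loc[metrics.index]
    sleep_cols = [c for c in behavior.columns if c.startswith("sleep_")]
    cog_cols = [c for c in behavior.columns if c.startswith("cog_")]
    brain = metrics.to_numpy()
    x_names = list(metrics.columns)
    subject_ids = list(metrics.index)

    # -- PLS: brain <-> sleep and brain <-> cognition ----------------------
    run_pls = _stage("pls")(pls_permutation_test)
    pls_sleep = run_pls(
        brain, behavior[sleep_cols].to_numpy(float),
        n_perm=config.n_perm,
        seed=int(substream(config.seed, "perm-sleep").integers(2**31 - 1)),
        statistic=config.perm_statistic,
        x_names=x_names, y_names=sleep_cols, subject_ids=subject_ids,
    )
    pls_cog = run_pls(
        brain, behavior[cog_cols].to_numpy(float),
        n_perm=config.n_perm,
        seed=int(substream(config.seed, "perm-cog").integers(2**31 - 1)),
        statistic=config.perm_statistic,
        x_names=x_names, y_names=cog_cols, subject_ids=subject_ids,
    )
    save_pls_result(outdir / "pls_sleep", pls_sleep)
    save_pls_result(outdir / "pls_cognition", pls_cog)

    # -- moderation on the sleep pair --------------------------------------
    comp = 0
    try:
        comp = pls_sleep.first_significant(config.alpha)
    except ValueError:
        logger.warning("no significant sleep component; moderation uses component 1")
    moderation = _stage("moderation")(moderation_fit)(
        pls_sleep.scores_Y[:, comp],
        pls_sleep.scores_X[:, comp],
        behavior["age"].to_numpy(float),
        interaction=config.interaction,
    )

    # -- profile comparison -------------------------------------------------
    try:
        comparison = _stage("compare")(compare_profiles)(
            pls_sleep, pls_cog, groups=state_groups(K_fit),
            component="first_significant", alpha=config.alpha,
        )
        comparison_dict = dataclasses.asdict(comparison)
    except (ValueError, RuntimeError) as e:
        logger.warning("profile comparison unavailable: %s", e)
        comparison_dict = None

    summary = {
        "n_subjects": len(subject_ids),
        "n_dropped_incomplete": len(dropped),
        "dropped_subjects": dropped,
        "brain_feature_columns": x_names,
        "n_brain_features": len(x_names),
        "n_sleep_variables": len(sleep_cols),
        "n_cognition_variables": len(cog_cols),
        "hmm": {
            "K": model.K,
            "converged": bool(model.converged),
            "final_loglik": float(model.fit_log[-1]),
            "n_iter": int(model.fit_log.size),
        },
        "pls_sleep": _pls_summary(pls_sleep, config.threshold),
        "pls_cognition": _pls_summary(pls_cog, config.threshold),
        "moderation": moderation.as_dict(),
        "profile_comparison": comparison_dict,
        "flags": {
            "per_subject_standardize": config.per_subject_standardize,
            "covariance_type": config.covariance_type,
            "interaction": config.interaction,
            "perm_statistic": config.perm_statistic,
            "inference": "maximum-likelihood EM (not variational Bayes)",
            "loading_definition": "structure correlations thresholded at |tau|",
        },
        "seed": config.seed,
    }
    write_json(outdir / "summary.json", summary)
    return summary


def _pls_summary(res, tau: float) -> dict:
    kept = threshold_loadings(res.structure_loadings_X[:, 0], tau)
    return {
        "singular_values": res.singular_values,
        "perm_p": res.perm_p,
        "n_perm": res.n_perm,
        "n_significant_05": int((res.perm_p < 0.05).sum()),
        "comp1_loadings_X": res.structure_loadings_X[:, 0],
        "comp1_loadings_Y": res.structure_loadings_Y[:, 0],
        "comp1_kept_above_threshold": [
            nm for nm, k in zip(res.x_names, kept) if k
        ] if res.x_names else int(kept.sum()),
    }


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["outdir"] = str(d["outdir"])
    sc = d["scenario"]
    for k, v in sc.items():
        if isinstance(v, np.ndarray):
            sc[k] = v.tolist()
    return d
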