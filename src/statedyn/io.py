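"""Serialization: HDF5 containers for arrays, CSV for tables, JSON for results.

Formats
-------
- Envelopes: one HDF5 file, one group per subject holding a ``envelope``
  dataset (time x parcel) with ``dt`` and ``subject_id`` attributes.
- HMM model: one HDF5 file with a ``schema_version`` attribute.
- State paths: one HDF5 file, one dataset per subject.
- Temporal metrics / behavior tables: CSV with a header row; missing metric
  values are empty cells.
- PLS and second-level results: JSON (scalars, p-values) plus CSV for the
  salience/loading/score matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .hmm import HMMModel
from .metrics import MIL_CONVENTION
from .paths import StatePath
from .pls import PLSResult
from .preprocess import EnvelopeDataset

MODEL_SCHEMA_VERSION = 1

__all__ = [
    "save_envelopes", "load_envelopes",
    "save_model", "load_model",
    "save_paths", "load_paths",
    "save_metrics_csv", "load_metrics_csv",
    "save_pls_result", "write_json",
]


def save_envelopes(path: str | Path, data: EnvelopeDataset) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["dt"] = data.dt
        for sid, x in zip(data.subjects, data.series):
            g = f.create_group(sid)
            d = g.create_dataset("envelope", data=np.asarray(x, dtype=np.float64))
            d.attrs["dt"] = data.dt
            d.attrs["subject_id"] = sid


def load_envelopes(path: str | Path) -> EnvelopeDataset:
    with h5py.File(path, "r") as f:
        dt = float(f.attrs["dt"])
        subjects = sorted(f.keys())
        series = [np.asarray(f[sid]["envelope"]) for sid in subjects]
    return EnvelopeDataset(subjects=subjects, series=series, dt=dt)


def save_model(path: str | Path, model: HMMModel) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = MODEL_SCHEMA_VERSION
        f.attrs["K"] = model.K
        f.attrs["converged"] = bool(model.converged)
        f.attrs["n_restarts"] = model.n_restarts
        f.attrs["covariance_type"] = model.covariance_type
        if model.seed is not None:
            f.attrs["seed"] = model.seed
        for name in ("means", "covariances", "transitions", "initial", "fit_log"):
            f.create_dataset(name, data=np.asarray(getattr(model, name)))


def load_model(path: str | Path) -> HMMModel:
    with h5py.File(path, "r") as f:
        if int(f.attrs["schema_version"]) != MODEL_SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        return HMMModel(
            K=int(f.attrs["K"]),
            means=np.asarray(f["means"]),
            covariances=np.asarray(f["covariances"]),
            transitions=np.asarray(f["transitions"]),
            initial=np.asarray(f["initial"]),
            fit_log=np.asarray(f["fit_log"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            n_restarts=int(f.attrs["n_restarts"]),
            converged=bool(f.attrs["converged"]),
            covariance_type=str(f.attrs["covariance_type"]),
        )


def save_paths(path: str | Path, paths: list[StatePath]) -> None:
    with h5py.File(path, "w") as f:
        for i, p in enumerate(paths):
            sid = p.subject_id or f"sub{i + 1}"
            d = f.create_dataset(sid, data=p.states)
            d.attrs["K"] = p.K


def load_paths(path: str | Path) -> list[StatePath]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            out.append(
                StatePath(states=np.asarray(f[sid]), K=int(f[sid].attrs["K"]), subject_id=sid)
            )
    return out


def save_metrics_csv(path: str | Path, metrics: pd.DataFrame) -> None:
    """Subject x 4K metric matrix as CSV; missing values are empty cells; the
    interval-length convention travels in a comment-free sidecar column-less
    header via DataFrame attrs is not possible in CSV, so it is written to a
    companion ``.meta.json`` file."""
    metrics.to_csv(path)
    meta = {"mil_convention": metrics.attrs.get("mil_convention", MIL_CONVENTION)}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def load_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_json(path: str | Path, obj: dict) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n"
    )


def save_pls_result(stem: str | Path, result: PLSResult) -> None:
    """Write <stem>.json (scalars, p-values) and <stem>_{saliences,loadings,scores}.csv."""
    stem = Path(stem)
    write_json(
        stem.with_suffix(".json"),
        {
            "singular_values": result.singular_values,
            "perm_p": result.perm_p,
            "n_perm": result.n_perm,
            "seed": result.seed,
            "n_components": result.n_components,
        },
    )
    comp = [f"comp{j + 1}" for j in range(result.n_components)]
    x_idx = result.x_names or [f"x{i + 1}" for i in range(result.saliences_X.shape[0])]
    y_idx = result.y_names or [f"y{i + 1}" for i in range(result.saliences_Y.shape[0])]
    sub = result.subject_ids or [f"sub{i + 1}" for i in range(result.scores_X.shape[0])]
    pd.DataFrame(result.saliences_X, index=x_idx, columns=comp).to_csv(
        stem.parent / f"{stem.name}_saliences_X.csv"
    )
    pd.DataFrame(result.saliences_Y, index=y_idx, columns=comp).to_csv(
        stem.parent / f"{stem.name}_saliences_Y.csv"
    )
    pd.DataFrame(result.structure_loadings_X, index=x_idx, columns=comp).to_csv(
        stem.parent / f"{stem.name}_loadings_X.csv"
    )
    pd.DataFrame(result.structure_loadings_Y, index=y_idx, columns=comp).to_csv(
        stem.parent / f"{stem.name}_loadings_Y.csv"
    )
    pd.DataFrame(result.scores_X, index=sub, columns=comp).to_csv(
        stem.parent / f"{stem.name}_scores_X.csv"
    )
    pd.DataFrame(result.scores_Y, index=sub, columns=comp).to_csv(
        stem.parent / f"{stem.name}_scores_Y.csv"
    )
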