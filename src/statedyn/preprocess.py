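"""Envelope preprocessing: Hilbert amplitude envelopes, standardization, concatenation.

The analysis consumes parcel-level amplitude envelopes. Envelopes are obtained as
the modulus of the analytic signal (Hilbert transform) of each parcel time course.
Before HMM fitting the per-subject series are temporally concatenated and each
parcel column is z-scored over the concatenated (group) data, so a single set of
states is inferred for the whole cohort; per-subject standardization is available
as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

__all__ = [
    "EnvelopeDataset",
    "hilbert_envelope",
    "zscore_columns",
    "concatenate_subjects",
    "split_subjects",
    "moving_average_decimate",
    "standardize_for_hmm",
]


@dataclass
class EnvelopeDataset:
    """Per-subject time x parcel amplitude-envelope matrices.

    All subjects share the parcel count; ``dt`` is the sampling interval in
    seconds and is carried as explicit metadata (no sampling rate is assumed).
    """

    subjects: list[str]
    series: list[np.ndarray]  # each (T_i, P), nonnegative
    dt: float

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.series):
            raise ValueError("subjects and series length mismatch")
        if not self.series:
            raise ValueError("empty dataset")
        P = self.series[0].shape[1]
        for sid, x in zip(self.subjects, self.series):
            x = np.asarray(x)
            if x.ndim != 2 or x.shape[1] != P:
                raise ValueError(f"subject {sid}: expected 2-D series with {P} parcels")
            if x.shape[0] < 2:
                raise ValueError(f"subject {sid}: series needs at least 2 samples")
            if np.any(x < 0):
                raise ValueError(f"subject {sid}: envelope values must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_parcels(self) -> int:
        return int(self.series[0].shape[1])

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope of each column: modulus of the analytic signal.

    Parameters
    ----------
    x : (T, P) real array, finite, T >= 8.

    Returns
    -------
    (T, P) nonnegative envelope. Edge samples carry the usual analytic-signal
    edge distortion; they are returned untouched.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 8:
        raise ValueError("need at least 8 samples for a meaningful analytic signal")
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(x))
        t, p = bad[0]
        raise ValueError(
            f"non-finite input: {bad.shape[0]} bad samples, first at row {t}, column {p}"
        )
    return np.abs(scipy.signal.hilbert(x, axis=0))


def zscore_columns(X: np.ndarray, *, names: list[str] | None = None) -> np.ndarray:
    """Z-score each column to mean 0, sd 1 (n-1 denominator).

    Raises on constant columns, naming them — a constant variable carries no
    cross-covariance and silently propagating NaNs would corrupt the PLS.
    Idempotent to floating precision.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    sd = X.std(axis=0, ddof=1)
    const = np.where(sd == 0)[0]
    if const.size:
        labels = [names[i] if names else str(i) for i in const]
        raise ValueError(f"constant column(s), cannot z-score: {', '.join(labels)}")
    return (X - X.mean(axis=0)) / sd


def concatenate_subjects(data: EnvelopeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Temporally concatenate subjects; return (matrix, boundary index).

    The boundary index has length n_subjects + 1; subject i owns rows
    boundaries[i]:boundaries[i+1]. Downstream HMM code must not count
    transitions across these boundaries.
    """
    lengths = [x.shape[0] for x in data.series]
    boundaries = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
    return np.vstack(data.series), boundaries


def split_subjects(X: np.ndarray, boundaries: np.ndarray) -> list[np.ndarray]:
    """Inverse of :func:`concatenate_subjects` (bitwise round trip)."""
    return [X[boundaries[i]: boundaries[i + 1]] for i in range(len(boundaries) - 1)]


def moving_average_decimate(x: np.ndarray, window: int) -> np.ndarray:
    """Optional temporal smoothing: boxcar average over ``window`` samples then
    decimation by the same factor. Changes the effective dt by ``window``; the
    caller is responsible for updating dt metadata. Default pipeline: off.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return np.asarray(x, dtype=float)
    x = np.asarray(x, dtype=float)
    T = (x.shape[0] // window) * window
    return x[:T].reshape(T // window, window, x.shape[1]).mean(axis=1)


def standardize_for_hmm(
    data: EnvelopeDataset, *, per_subject: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate and z-score parcel columns for group-level HMM fitting.

    Default is group standardization (one mean/sd per parcel over the
    concatenated data), matching a single group-level state inference; set
    ``per_subject=True`` to standardize each subject's series separately.
    """
    if per_subject:
        series = [zscore_columns(x) for x in data.series]
        lengths = [x.shape[0] for x in series]
        boundaries = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
        return np.vstack(series), boundaries
    X, boundaries = concatenate_subjects(data)
    return zscore_columns(X), boundaries
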