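"""Temporal characteristics of brain states computed from hard state paths.

Four per-state summaries are computed from each subject's Viterbi path:

- FO  (fractional occupancy): proportion of scan time the state is active.
- MLT (mean lifetime, seconds): average visit duration before transitioning away.
- NO  (number of occurrences): count of distinct visits within the scan.
- MIL (mean interval length, seconds): average gap between consecutive visits,
  measured from the offset of one visit to the onset of the next. Only the
  NO - 1 gaps strictly between visits count; time before the first and after
  the last visit is excluded. This convention is recorded in output metadata
  because alternatives (including edge intervals) exist.

Missingness: a never-visited state has FO = 0, NO = 0 and undefined MLT/MIL;
a state visited exactly once has undefined MIL. These are flags, not errors.

Exactness: FO, MLT and MIL are float ratios of the integer counts also stored
on :class:`TemporalMetrics` (``samples`` and ``occurrences``); the accounting
identities FO_k * T = NO_k * MLT_k / dt and sum_k FO_k = 1 hold exactly in the
integer representation and to floating rounding in the float one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paths import StatePath

__all__ = ["TemporalMetrics", "visits", "temporal_metrics", "metrics_matrix", "METRIC_NAMES"]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("FO", "MLT", "NO", "MIL")

MIL_CONVENTION = "offset-to-onset gaps strictly between consecutive visits (NO-1 gaps)"


@dataclass
class TemporalMetrics:
    """Per-state temporal characteristics for one subject.

    ``fo``, ``mlt``, ``no``, ``mil`` are length-K float arrays (NaN = missing);
    ``samples`` and ``occurrences`` are the underlying integer counts; ``T`` is
    the path length in samples and ``dt`` the sampling interval in seconds.
    """

    fo: np.ndarray
    mlt: np.ndarray
    no: np.ndarray
    mil: np.ndarray
    samples: np.ndarray      # int, samples spent in each state; sums to T
    occurrences: np.ndarray  # int, visits to each state
    T: int
    dt: float
    subject_id: str | None = None

    @property
    def missing(self) -> np.ndarray:
        """Boolean per state: any of the four measures undefined."""
        return np.isnan(self.mlt) | np.isnan(self.mil)


def visits(path: StatePath, k: int) -> list[tuple[int, int]]:
    """Maximal runs of state ``k`` as (onset, run length), 0-based half-open.

    Plain run-length encoding; returns an empty list when the state never
    occurs.
    """
    if not (1 <= k <= path.K):
        raise ValueError(f"state {k} outside 1..{path.K}")
    active = np.asarray(path.states) == k
    if not active.any():
        return []
    d = np.diff(active.astype(np.int8))
    onsets = np.where(d == 1)[0] + 1
    offsets = np.where(d == -1)[0] + 1
    if active[0]:
        onsets = np.concatenate([[0], onsets])
    if active[-1]:
        offsets = np.concatenate([offsets, [active.size]])
    return [(int(a), int(b - a)) for a, b in zip(onsets, offsets)]


def temporal_metrics(path: StatePath, dt: float) -> TemporalMetrics:
    """Compute FO/MLT/NO/MIL for every state of one path."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    K, T = path.K, len(path)
    samples = np.zeros(K, dtype=np.int64)
    occurrences = np.zeros(K, dtype=np.int64)
    mlt = np.full(K, np.nan)
    mil = np.full(K, np.nan)
    for k in range(1, K + 1):
        runs = visits(path, k)
        occurrences[k - 1] = len(runs)
        if not runs:
            continue
        lengths = np.array([r[1] for r in runs], dtype=np.int64)
        samples[k - 1] = lengths.sum()
        mlt[k - 1] = dt * samples[k - 1] / len(runs)
        if len(runs) >= 2:
            onsets = np.array([r[0] for r in runs], dtype=np.int64)
            gaps = onsets[1:] - (onsets[:-1] + lengths[:-1])
            mil[k - 1] = dt * gaps.mean()
    fo = samples / T
    return TemporalMetrics(
        fo=fo, mlt=mlt, no=occurrences.astype(float), mil=mil,
        samples=samples, occurrences=occurrences, T=T, dt=dt,
        subject_id=path.subject_id,
    )


def metrics_matrix(
    all_metrics: list[TemporalMetrics], *, drop_incomplete: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble the subjects x (4K) first-level brain feature matrix.

    Column order is metric-major and fixed: FO_state1..FO_stateK, then MLT,
    NO, MIL blocks. Subjects with any missing metric (a state never visited,
    or visited only once so MIL is undefined) are dropped when
    ``drop_incomplete`` (default) and their IDs logged and returned.

    Returns (DataFrame indexed by subject_id, list of dropped subject IDs).
    """
    if not all_metrics:
        raise ValueError("no metrics supplied")
    K = all_metrics[0].fo.size
    cols = [f"{m}_state{k}" for m in METRIC_NAMES for k in range(1, K + 1)]
    rows, index = [], []
    for i, tm in enumerate(all_metrics):
        if tm.fo.size != K:
            raise ValueError("inconsistent state count across subjects")
        rows.append(np.concatenate([tm.fo, tm.mlt, tm.no, tm.mil]))
        index.append(tm.subject_id if tm.subject_id is not None else f"sub{i + 1}")
    df = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"), columns=cols)
    df.attrs["mil_convention"] = MIL_CONVENTION
    dropped: list[str] = []
    if drop_incomplete:
        bad = df.isna().any(axis=1)
        dropped = list(df.index[bad])
        if dropped:
            logger.info("dropping %d subject(s) with incomplete metrics: %s",
                        len(dropped), ", ".join(map(str, dropped)))
        df = df.loc[~bad]
        if df.empty:
            raise ValueError("all subjects dropped: every subject has missing metrics")
    return df, dropped
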