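"""State path container shared by the simulator, the HMM decoder and the metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StatePath"]


@dataclass
class StatePath:
    """A decoded (or simulated) sequence of discrete brain states.

    States are 1-based integers in ``1..K``; exactly one state is active per
    sample. ``indicators()`` gives the equivalent K x T binary representation.
    """

    states: np.ndarray  # shape (T,), int, values in 1..K
    K: int
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1 or self.states.size < 1:
            raise ValueError("state path must be a non-empty 1-D sequence")
        if self.states.min() < 1 or self.states.max() > self.K:
            raise ValueError(f"states must lie in 1..{self.K}")

    def __len__(self) -> int:
        return int(self.states.size)

    def indicators(self) -> np.ndarray:
        """K x T binary matrix; column sums are exactly 1."""
        out = np.zeros((self.K, self.states.size), dtype=np.int8)
        out[self.states - 1, np.arange(self.states.size)] = 1
        return out
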