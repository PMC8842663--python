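"""Named random substreams derived from a single root seed.

Every source of randomness in the package draws from a substream keyed by a
stable label, so stages are individually reproducible and re-running one stage
cannot perturb another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *labels: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``labels``.

    The stream is a deterministic function of (seed, labels): labels are mapped
    to 32-bit words (CRC-32 for strings) and fed to a SeedSequence together with
    the root seed.
    """
    words: list[int] = [int(seed) & 0xFFFFFFFF]
    for lab in labels:
        if isinstance(lab, str):
            words.append(zlib.crc32(lab.encode("utf-8")))
        else:
            words.append(int(lab) & 0xFFFFFFFF)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(words)))
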