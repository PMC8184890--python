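"""Seed fan-out.

One global integer seed is expanded into named, statistically independent
substreams so that each pipeline stage draws from its own generator: changing
the number of draws in one stage never perturbs another stage's stream.
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named child generator of the global ``seed``.

    Parameters
    ----------
    seed
        Global integer seed (non-negative).
    name
        Stage label, e.g. ``"haplotypes"`` or ``"trial"``. The same
        (seed, name) pair always yields an identical stream.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(name.encode()))
    return np.random.default_rng(ss)
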