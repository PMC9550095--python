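"""Seed handling: one root seed, named independent substreams.

Every source of randomness in the package derives from a single root seed
through :func:`substream`, so components can be re-run in isolation with
bit-identical draws (the init stream of a run does not depend on how many
numbers the search stream consumed, and vice versa).
"""

from __future__ import annotations

import numpy as np

# Fixed name -> spawn-key mapping; append only, never reorder.
_STREAMS = {
    "init": 0,
    "search": 1,
    "cls": 2,
    "folds": 3,
    "synth": 4,
    "binary": 5,
    "runs": 6,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named independent generator derived from ``seed``."""
    if name not in _STREAMS:
        raise KeyError(f"unknown stream name {name!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)


def as_generator(rng) -> np.random.Generator:
    """Coerce ``rng`` (Generator | int | None) to a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
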