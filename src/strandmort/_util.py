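"""Seeding helpers: one user seed, named deterministic substreams."""
from __future__ import annotations

import numpy as np

# Fixed registry so every pipeline stage draws from its own substream and
# adding a stage never perturbs the draws of another.
_STREAMS = (
    "natural",
    "bycatch",
    "thinning",
    "priors",
    "optimizer",
    "clouds",
    "imis",
    "resample",
)


def substream(seed: int | None, name: str) -> np.random.Generator:
    """Return the named child generator of ``seed``.

    The same (seed, name) pair always yields an identical stream, independent
    of which other streams were consumed.
    """
    if name not in _STREAMS:
        raise KeyError(f"unknown RNG substream {name!r}")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(name)])
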