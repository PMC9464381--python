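"""Named random substreams.

All randomness in the package flows from a single integer seed.  Every
consumer (trajectory draw, risk-matrix draw, each inner random-allocation
run, cohort event sampling) gets its own named substream so that the four
screening strategies are always compared on identical populations and so
that adding one consumer never perturbs another.
"""

from __future__ import annotations

import numpy as np

# stable stream ids; never renumber, only append
_STREAMS = {
    "trajectory": 0,
    "matrix": 1,
    "ra": 2,
    "events": 3,
    "cohort": 4,
}


def substream(seed: int, name: str, *path: int) -> np.random.Generator:
    """Return a Generator for stream `name` at integer coordinates `path`.

    `path` typically encodes (tdr index, scenario id, repetition, inner run).
    """
    if name not in _STREAMS:
        raise KeyError(f"unknown stream name {name!r}")
    entropy = [int(seed) & 0x7FFFFFFF, _STREAMS[name], *[int(p) for p in path]]
    return np.random.default_rng(np.random.SeedSequence(entropy))
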