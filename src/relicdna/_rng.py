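"""Deterministic seed-tree helpers.

One master seed per scenario; every stochastic operation draws from a child
stream derived from (master seed, fixed string labels).  Toggling one step
(e.g. in-vitro repair) therefore never perturbs the random stream of another
(e.g. fragment generation).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _label_words(labels: tuple) -> list[int]:
    return [zlib.crc32(repr(lab).encode("utf-8")) for lab in labels]


def child_seed(master: int, *labels) -> np.random.SeedSequence:
    """SeedSequence for the stream identified by ``labels`` under ``master``."""
    if master < 0:
        raise ValueError("master seed must be non-negative")
    return np.random.SeedSequence([int(master)] + _label_words(labels))


def child_rng(master: int, *labels) -> np.random.Generator:
    """Generator for the stream identified by ``labels`` under ``master``."""
    return np.random.default_rng(child_seed(master, *labels))
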