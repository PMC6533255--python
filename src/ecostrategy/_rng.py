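"""Named random substreams.

A single master seed drives the whole pipeline, but each stochastic stage
(imputation chains, hypervolume Monte-Carlo, null-model replicates,
extinction replicates) draws from its own named substream.  Changing the
replicate count of one stage therefore never perturbs the draws of another,
and partial reruns reproduce exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(seed: int, name: str) -> np.random.SeedSequence:
    """Seed sequence for the substream `name` under master `seed`."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the substream `name` under master `seed`.

    Deterministic in (seed, name); independent streams for distinct names.
    """
    return np.random.default_rng(subseed(seed, name))
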