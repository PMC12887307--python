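"""Small shared numerics."""

from __future__ import annotations

import numpy as np


def shannon_nats(weights) -> float:
    """Shannon entropy in nats of the normalized positive weight vector."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("shannon_nats needs at least one positive weight")
    p = w / w.sum()
    return float(-(p * np.log(p)).sum())


def rng_from_seed(seed) -> np.random.Generator:
    """One rule for turning a user seed into a Generator everywhere."""
    return np.random.default_rng(seed)
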