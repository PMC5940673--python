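"""Named random substreams derived from one master seed.

Every source of randomness in the package draws from a generator obtained via
:func:`substream`, keyed by the master seed plus a tuple of names (stage,
subject, ROI, ...).  The key is hashed with SHA-256 so adding a new named
stream never perturbs the draws of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "subseed"]


def _token(name: object) -> int:
    digest = hashlib.sha256(str(name).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def substream(master_seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_token(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def subseed(master_seed: int, *names: object) -> int:
    """A scalar seed (< 2**31) for APIs that want an integer."""
    return int(substream(master_seed, *names).integers(0, 2**31))
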