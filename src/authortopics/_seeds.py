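"""Deterministic seed derivation.

A single master seed fans out to per-stage (and per-substep) child seeds so
that any stage can be re-run in isolation and reproduce its random stream.
Child seeds are 31-bit so they are valid for every consumer (numpy
Generators and scikit-learn ``random_state`` alike).
"""

from __future__ import annotations

import numpy as np

_MOD = 2**31


def child_seed(master: int, *tags: int | str) -> int:
    """Derive a 31-bit child seed from ``master`` and a tag path.

    String tags are folded to integers via a stable hash (sum of byte
    values mixed with position) so the derivation does not depend on
    Python's randomized ``hash``.
    """
    keys = [int(master)]
    for tag in tags:
        if isinstance(tag, str):
            acc = 0
            for i, b in enumerate(tag.encode("utf-8")):
                acc = (acc * 257 + b + i) % _MOD
            keys.append(acc)
        else:
            keys.append(int(tag) % _MOD)
    ss = np.random.SeedSequence(keys)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % _MOD)


def rng_for(master: int, *tags: int | str) -> np.random.Generator:
    """A numpy Generator seeded from the derived child seed."""
    return np.random.default_rng(child_seed(master, *tags))
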