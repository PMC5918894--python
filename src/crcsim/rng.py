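"""Counter-based random substreams.

Every individual gets an independent stream per *concern* (population
attributes, natural history, screening participation, FIT noise, colonoscopy
noise).  Streams are derived from a master seed and integer keys with a
splitmix64 mixer, so toggling any screening parameter leaves the natural
history of every person byte-identical — the common-random-numbers contract
the paired screened/unscreened comparison relies on.
"""
from __future__ import annotations

import random

_MASK64 = (1 << 64) - 1

# concern labels
POPULATION = 1
NATURAL_HISTORY = 2
PARTICIPATION = 3
FIT = 4
COLONOSCOPY = 5


def splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def substream_seed(master_seed: int, *keys: int) -> int:
    """Deterministically mix a master seed with integer keys into a 64-bit seed."""
    x = splitmix64(master_seed & _MASK64)
    for k in keys:
        x = splitmix64(x ^ ((k & _MASK64) * 0xD1B54A32D192ED03 & _MASK64))
    return x


def substream(master_seed: int, *keys: int) -> random.Random:
    """A stdlib `random.Random` seeded from (master_seed, keys)."""
    return random.Random(substream_seed(master_seed, *keys))
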