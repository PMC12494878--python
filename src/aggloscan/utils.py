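"""Small shared helpers: seed derivation and worked-example arithmetic."""

from __future__ import annotations

import zlib

import numpy as np

# Every stochastic operation derives its generator from (seed, crc32(op_name)).
# A single global seed therefore fans out to stable per-operation child seeds:
# rerunning one stage in isolation reproduces exactly the stream it had in a
# full run.


def child_rng(seed: int, op_name: str) -> np.random.Generator:
    """Return the deterministic child generator for ``op_name`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(op_name.encode())]))


def child_seed(seed: int, op_name: str) -> int:
    """A plain integer child seed (< 2**31) for APIs that want one."""
    return int(np.random.SeedSequence([int(seed), zlib.crc32(op_name.encode())]).generate_state(1)[0] % (2**31))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` out of ``total`` rounded to ``ndigits`` decimals.

    Used for manual-count worked examples, e.g. dividing cells in which a
    filament extends from the mother into the daughter cell.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must lie in [0, total]")
    return round(100.0 * count / total, ndigits)
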