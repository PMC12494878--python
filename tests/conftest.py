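"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from aggloscan import synthetic


def brute_force_puncta(image, labels, background, fold=2.5, margin=100.0, connectivity=8):
    """Independent puncta oracle: exhaustive pixel scan + BFS flood fill.

    Pure-python re-derivation of the per-cell rule: candidate pixels satisfy
    both thresholds; components found by flood fill; the largest kept with
    ties broken by (min row, min col). Returns {cell_id: frozenset((r, c))}.
    """
    image = np.asarray(image, float)
    labels = np.asarray(labels)
    h, w = image.shape
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    out = {}
    for lab in sorted(set(labels.ravel().tolist()) - {0}):
        pix = [(r, c) for r in range(h) for c in range(w) if labels[r, c] == lab]
        vals = sorted(image[r, c] for r, c in pix)
        n = len(vals)
        med = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
        thr = max(fold * med, background + margin)
        cand = {(r, c) for r, c in pix if image[r, c] >= thr}
        if not cand:
            continue
        comps = []
        left = set(cand)
        while left:
            seed = left.pop()
            comp = {seed}
            queue = [seed]
            while queue:
                r, c = queue.pop()
                for dr, dc in steps:
                    nb = (r + dr, c + dc)
                    if nb in left:
                        left.remove(nb)
                        comp.add(nb)
                        queue.append(nb)
            comps.append(comp)
        comps.sort(key=lambda comp: (-len(comp), min(r for r, _ in comp), min(c for _, c in comp)))
        out[lab] = frozenset(comps[0])
    return out


def random_puncta_image(rng, size=48, n_cells=3):
    """A small random labeled field with arbitrary intensities for oracle tests."""
    labels = np.zeros((size, size), dtype=np.int32)
    for i in range(1, n_cells + 1):
        r0, c0 = rng.integers(0, size - 12, 2)
        hgt, wid = rng.integers(6, 13, 2)
        labels[r0 : r0 + hgt, c0 : c0 + wid] = i  # later cells may overwrite earlier
    image = rng.integers(0, 400, size=(size, size)).astype(float)
    # sprinkle bright patches so some cells yield calls
    for _ in range(rng.integers(1, 5)):
        r0, c0 = rng.integers(0, size - 4, 2)
        image[r0 : r0 + rng.integers(1, 5), c0 : c0 + rng.integers(1, 5)] += rng.integers(300, 1500)
    background = float(rng.integers(0, 120))
    return image, labels, background


@pytest.fixture
def small_field():
    params = synthetic.SimulationParams(
        field_shape=(256, 256), n_cells=20, noise_sd=0.0, seed=11, focus_probability=0.5
    )
    return synthetic.simulate_field(params), params
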