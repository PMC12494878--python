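"""Integrated absolute circular-dichroism difference (ΔCD).

ΔCD summarizes how much a mutant's CD spectrum departs from the wild type's:
both spectra are linearly interpolated onto the union of their wavelength
grids restricted to the overlapping range, and the trapezoidal integral of
the absolute ellipticity difference is taken over that range. Small values
indicate the mutant retains native secondary structure; large values signal
structural change. Units follow the inputs (conventionally
10³ deg·cm²·dmol⁻¹ per nm range); no mean-residue-ellipticity conversion is
applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _validate(spec: pd.DataFrame, name: str):
    wl = spec["wavelength_nm"].to_numpy(float)
    if len(wl) < 2:
        raise ValueError(f"{name}: need at least 2 points")
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{name}: wavelengths must be strictly increasing with no duplicates")
    return wl, spec["ellipticity"].to_numpy(float)


def delta_cd(
    spec_wt: pd.DataFrame,
    spec_mut: pd.DataFrame,
    wavelength_range: tuple[float, float] | None = None,
):
    """Integrated |wt − mut| over the overlapping wavelength range.

    Spectra are DataFrames with columns ``wavelength_nm, ellipticity``;
    mismatched grids are handled by linear interpolation onto the union grid
    inside the overlap. An explicit ``wavelength_range`` restricts the
    integration window (to match a published range). Returns
    ``(delta, (lo, hi))`` — the statistic and the integrated bounds.
    """
    wl_a, el_a = _validate(spec_wt, "wild-type spectrum")
    wl_b, el_b = _validate(spec_mut, "mutant spectrum")
    lo = max(wl_a[0], wl_b[0])
    hi = min(wl_a[-1], wl_b[-1])
    if wavelength_range is not None:
        lo, hi = max(lo, wavelength_range[0]), min(hi, wavelength_range[1])
    if hi <= lo:
        raise ValueError(f"spectra have no overlapping wavelength range of positive width (got [{lo}, {hi}])")
    grid = np.union1d(wl_a, wl_b)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid[0] > lo:
        grid = np.insert(grid, 0, lo)
    if grid[-1] < hi:
        grid = np.append(grid, hi)
    a = np.interp(grid, wl_a, el_a)
    b = np.interp(grid, wl_b, el_b)
    delta = float(np.trapezoid(np.abs(a - b), grid))
    return delta, (float(lo), float(hi))
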