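"""Seeded synthetic-data generators with ground truth for every pipeline stage.

The generators stand in for the instruments of the original workflow —
fluorescence microscope, plate reader, serial-transfer and chemostat
competitions, CD spectrometer and mass spectrometer — so that every estimator
in the package can be tested against known truth without any external data.

Conventions
-----------
* Images are float64 arrays in arbitrary intensity units (AU); the CLI writer
  converts to 16-bit TIFF. Coordinates are 0-based ``(row, col)``.
* Cells are non-overlapping ellipses. Base intensity per cell is log-normal
  (an assumption: the intensity distribution of real cells is not known; the
  log-normal is the conventional choice for fluorescence levels).
* Foci are rendered as isotropic 2-D Gaussians (``spot``) or anisotropic
  ridges with aspect ratio >= 4 (``filament``), scaled so the peak is
  ``focus_peak_fold`` times the cell's base intensity.
* All randomness flows through :func:`aggloscan.utils.child_rng`, so one
  global integer seed reproduces every stage bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from aggloscan.utils import child_rng

DISSOLUTION_MODES = ("agglomerate", "aggregate", "intermediate")

# Intermediate-regime foci probability bounds: foci are rarer than in the
# aggregate regime but still ratio-dependent.
_INTERMEDIATE_FLOOR = 0.12
_INTERMEDIATE_CEIL = 0.40
_AGGREGATE_P = 0.40

# max/median green-ratio draws used for record-level populations: focus cells
# always exceed the 2.5 classifier threshold, non-focus cells never do, and
# "dimmer" intermediate foci sit just above it.
_FOLD_FOCUS = (3.2, 8.0)
_FOLD_FOCUS_DIM = (2.7, 3.6)
_FOLD_NO_FOCUS = (1.05, 2.2)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic microscopy field and cell population."""

    field_shape: tuple[int, int] = (512, 512)
    n_cells: int = 100
    background_level: float = 200.0
    noise_sd: float = 10.0
    ratio_distribution: tuple[float, float] = (0.1, 10.0)  # log-uniform red/green bounds
    dissolution_mode: str = "agglomerate"
    dissolution_steepness: float = 3.0
    seed: int = 0
    # rendering knobs (defaults emulate ~60x yeast fields)
    cell_axes_px: tuple[float, float] = (6.0, 11.0)
    base_intensity_median: float = 500.0
    base_intensity_sigma: float = 0.35  # log-normal shape
    focus_probability: float = 0.5
    focus_kind: str = "spot"
    focus_peak_fold: tuple[float, float] = (4.0, 8.0)
    focus_sigma_px: float = 2.0
    filament_aspect: float = 5.0
    placement_retry_budget: int = 2000

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.dissolution_mode not in DISSOLUTION_MODES:
            raise ValueError(f"unknown dissolution_mode {self.dissolution_mode!r}; expected one of {DISSOLUTION_MODES}")
        if self.focus_kind not in ("spot", "filament", "none"):
            raise ValueError("focus_kind must be 'spot', 'filament' or 'none'")
        lo, hi = self.ratio_distribution
        if not (0 < lo < hi):
            raise ValueError("ratio_distribution bounds must satisfy 0 < lo < hi")


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails within the retry budget."""


# ---------------------------------------------------------------------------
# field rendering
# ---------------------------------------------------------------------------

def _place_cells(params: SimulationParams, rng: np.random.Generator) -> list[dict]:
    """Rejection-sample non-overlapping ellipse centers/axes."""
    h, w = params.field_shape
    placed: list[dict] = []
    tries = 0
    amin, amax = params.cell_axes_px
    while len(placed) < params.n_cells:
        tries += 1
        if tries > params.placement_retry_budget * max(params.n_cells, 1):
            density = len(placed) / (h * w / (np.pi * amax**2))
            raise PlacementError(
                f"placed only {len(placed)}/{params.n_cells} cells in a {h}x{w} field "
                f"(effective density {density:.2f} of capacity); reduce n_cells or enlarge the field"
            )
        ax_r = rng.uniform(amin, amax)
        ax_c = rng.uniform(amin, amax)
        margin = max(ax_r, ax_c) + 2.0
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        ok = True
        for other in placed:
            d = np.hypot(r - other["center_rc"][0], c - other["center_rc"][1])
            if d < margin + max(other["axes_px"]) + 2.0:
                ok = False
                break
        if ok:
            placed.append({"center_rc": (r, c), "axes_px": (ax_r, ax_c)})
    return placed


def _ellipse_mask(shape, center, axes):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _focus_profile(shape, center, kind, sigma, aspect, theta):
    """Unit-peak Gaussian spot or rotated anisotropic ridge."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    if kind == "spot":
        return np.exp(-(dr**2 + dc**2) / (2 * sigma**2))
    u = dr * np.cos(theta) + dc * np.sin(theta)   # long axis
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return np.exp(-(u**2 / (2 * (sigma * aspect) ** 2) + v**2 / (2 * sigma**2)))


def _focus_probability(params: SimulationParams, log_ratio: np.ndarray) -> np.ndarray:
    """Exact P(has_focus | ratio) for each dissolution regime.

    In the agglomerate regime the probability is a decreasing logistic in
    log(red/green) with slope -dissolution_steepness about the midpoint of the
    log-ratio range (wild-type excess dissolves the mutant assemblies); in the
    aggregate regime it is flat; the intermediate regime keeps the ratio
    dependence but with a compressed range.
    """
    lo, hi = np.log(params.ratio_distribution[0]), np.log(params.ratio_distribution[1])
    mid = 0.5 * (lo + hi)
    z = params.dissolution_steepness * (np.asarray(log_ratio, float) - mid)
    with np.errstate(over="ignore"):
        logistic = 1.0 / (1.0 + np.exp(z))
    if params.dissolution_mode == "agglomerate":
        return logistic
    if params.dissolution_mode == "aggregate":
        return np.full_like(logistic, _AGGREGATE_P)
    return _INTERMEDIATE_FLOOR + (_INTERMEDIATE_CEIL - _INTERMEDIATE_FLOOR) * logistic


def simulate_field(params: SimulationParams):
    """Render a two-channel field of non-overlapping elliptical cells.

    Returns ``(green, red, labels, truth)`` where ``labels`` is 0 for
    background and ``cell_id`` elsewhere, and ``truth`` is a DataFrame with
    one row per cell (position, axes, base intensities, focus ground truth).
    With ``noise_sd == 0`` and no focus, every cell pixel equals
    ``background_level + base`` exactly.
    """
    if params.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = child_rng(params.seed, "simulate_field")
    h, w = params.field_shape
    cells = _place_cells(params, rng)

    green = np.full((h, w), float(params.background_level))
    red = np.full((h, w), float(params.background_level))
    labels = np.zeros((h, w), dtype=np.uint16)

    log_lo, log_hi = np.log(params.ratio_distribution[0]), np.log(params.ratio_distribution[1])
    rows = []
    for i, cell in enumerate(cells, start=1):
        base_green = params.base_intensity_median * np.exp(rng.normal(0.0, params.base_intensity_sigma))
        ratio = float(np.exp(rng.uniform(log_lo, log_hi)))
        base_red = base_green * ratio
        mask = _ellipse_mask((h, w), cell["center_rc"], cell["axes_px"])
        labels[mask] = i
        green[mask] += base_green
        red[mask] += base_red

        has_focus = params.focus_kind != "none" and rng.random() < params.focus_probability
        focus_kind = params.focus_kind if has_focus else "none"
        peak_fold = float(rng.uniform(*params.focus_peak_fold)) if has_focus else np.nan
        focus_rc = (np.nan, np.nan)
        if has_focus:
            # keep the focus center inside the inner half of the ellipse so
            # its bright pixels stay within the cell mask
            fr = cell["center_rc"][0] + rng.uniform(-0.4, 0.4) * cell["axes_px"][0]
            fc = cell["center_rc"][1] + rng.uniform(-0.4, 0.4) * cell["axes_px"][1]
            focus_rc = (fr, fc)
            theta = rng.uniform(0, np.pi)
            prof = _focus_profile((h, w), focus_rc, params.focus_kind, params.focus_sigma_px, params.filament_aspect, theta)
            green[mask] += (peak_fold - 1.0) * base_green * prof[mask]
            red[mask] += (peak_fold - 1.0) * base_red * prof[mask]

        rows.append(
            dict(
                cell_id=i,
                center_r=cell["center_rc"][0],
                center_c=cell["center_rc"][1],
                axis_r=cell["axes_px"][0],
                axis_c=cell["axes_px"][1],
                base_green=base_green,
                base_red=base_red,
                ratio_red_green=ratio,
                has_focus=bool(has_focus),
                focus_kind=focus_kind,
                focus_peak_fold=peak_fold,
                focus_shared=bool(has_focus),
                focus_r=focus_rc[0],
                focus_c=focus_rc[1],
            )
        )

    if params.noise_sd > 0:
        green = green + rng.normal(0.0, params.noise_sd, size=green.shape)
        red = red + rng.normal(0.0, params.noise_sd, size=red.shape)
        np.clip(green, 0, None, out=green)
        np.clip(red, 0, None, out=red)

    return green, red, labels, pd.DataFrame(rows)


def simulate_coloc_pair(params: SimulationParams, shared_fraction: float = 1.0, min_separation_px: float = 8.0):
    """Two-channel field in which a stated fraction of foci co-localize.

    Shared foci occupy identical pixel coordinates in both channels; unshared
    foci are placed independently at least ``min_separation_px`` apart.
    Returns ``(green, red, labels, truth)``.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = child_rng(params.seed, "simulate_coloc_pair")
    h, w = params.field_shape
    cells = _place_cells(params, rng)

    green = np.full((h, w), float(params.background_level))
    red = np.full((h, w), float(params.background_level))
    labels = np.zeros((h, w), dtype=np.uint16)
    log_lo, log_hi = np.log(params.ratio_distribution[0]), np.log(params.ratio_distribution[1])

    rows = []
    for i, cell in enumerate(cells, start=1):
        base_green = params.base_intensity_median * np.exp(rng.normal(0.0, params.base_intensity_sigma))
        ratio = float(np.exp(rng.uniform(log_lo, log_hi)))
        base_red = base_green * ratio
        mask = _ellipse_mask((h, w), cell["center_rc"], cell["axes_px"])
        labels[mask] = i
        green[mask] += base_green
        red[mask] += base_red

        peak_fold = float(rng.uniform(*params.focus_peak_fold))
        shared = bool(rng.random() < shared_fraction)
        cr, cc_ = cell["center_rc"]
        ar, ac = cell["axes_px"]

        def _spot_at(frac_r, frac_c):
            return (cr + frac_r * ar, cc_ + frac_c * ac)

        if shared:
            g_rc = r_rc = _spot_at(rng.uniform(-0.4, 0.4), rng.uniform(-0.4, 0.4))
        else:
            # opposite-side placement guarantees the stated minimum separation
            side = rng.choice([-1.0, 1.0])
            g_rc = _spot_at(side * 0.45, side * 0.45)
            r_rc = _spot_at(-side * 0.45, -side * 0.45)
            if np.hypot(g_rc[0] - r_rc[0], g_rc[1] - r_rc[1]) < min_separation_px:
                g_rc = (cr - 0.6 * ar, cc_)
                r_rc = (cr + 0.6 * ar, cc_)
        g_prof = _focus_profile((h, w), g_rc, "spot", params.focus_sigma_px, 1.0, 0.0)
        r_prof = g_prof if shared else _focus_profile((h, w), r_rc, "spot", params.focus_sigma_px, 1.0, 0.0)
        green[mask] += (peak_fold - 1.0) * base_green * g_prof[mask]
        red[mask] += (peak_fold - 1.0) * base_red * r_prof[mask]

        rows.append(
            dict(
                cell_id=i,
                center_r=cr,
                center_c=cc_,
                base_green=base_green,
                base_red=base_red,
                ratio_red_green=ratio,
                has_focus=True,
                focus_kind="spot",
                focus_peak_fold=peak_fold,
                focus_shared=shared,
                focus_green_r=g_rc[0],
                focus_green_c=g_rc[1],
                focus_red_r=r_rc[0],
                focus_red_c=r_rc[1],
            )
        )

    if params.noise_sd > 0:
        green = green + rng.normal(0.0, params.noise_sd, size=green.shape)
        red = red + rng.normal(0.0, params.noise_sd, size=red.shape)
        np.clip(green, 0, None, out=green)
        np.clip(red, 0, None, out=red)

    return green, red, labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dissolution populations (record level)
# ---------------------------------------------------------------------------

def simulate_dissolution_population(params: SimulationParams) -> pd.DataFrame:
    """Per-cell records for the wild-type dissolution assay.

    Each record carries the red/green median-intensity ratio, the exact
    P(has_focus | ratio) the generator used, the realized focus flag, and a
    max/median green ratio consistent with that flag (focus cells exceed the
    2.5 classifier threshold; intermediate-regime foci are drawn dimmer).
    Columns: ``cell_id, ratio_red_green, p_focus, has_focus,
    focus_peak_fold, ratio_max_median_green``.
    """
    if params.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = child_rng(params.seed, "simulate_dissolution_population")
    log_lo, log_hi = np.log(params.ratio_distribution[0]), np.log(params.ratio_distribution[1])
    log_ratio = rng.uniform(log_lo, log_hi, size=params.n_cells)
    p = _focus_probability(params, log_ratio)
    has_focus = rng.random(params.n_cells) < p

    fold_lo, fold_hi = _FOLD_FOCUS_DIM if params.dissolution_mode == "intermediate" else _FOLD_FOCUS
    fold = np.where(has_focus, rng.uniform(fold_lo, fold_hi, params.n_cells), np.nan)
    ratio_max_median = np.where(
        has_focus,
        np.nan_to_num(fold, nan=0.0),
        rng.uniform(*_FOLD_NO_FOCUS, params.n_cells),
    )
    return pd.DataFrame(
        dict(
            cell_id=np.arange(1, params.n_cells + 1),
            ratio_red_green=np.exp(log_ratio),
            p_focus=p,
            has_focus=has_focus,
            focus_peak_fold=fold,
            ratio_max_median_green=ratio_max_median,
        )
    )


# ---------------------------------------------------------------------------
# growth and competition
# ---------------------------------------------------------------------------

def simulate_growth(
    r_per_hour: float,
    carrying_capacity: float,
    od0: float,
    times_min: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic OD600 trajectory with multiplicative log-normal noise.

    ``r_per_hour`` is the low-density growth rate in doublings per hour, so
    with infinite capacity ``log2(od)`` is exactly linear in time with slope
    ``r_per_hour / 60`` per minute. Returns columns ``time_min, od``.
    """
    times_min = np.asarray(times_min, dtype=float)
    if times_min.ndim != 1 or len(times_min) < 2 or np.any(np.diff(times_min) <= 0):
        raise ValueError("times must be a strictly increasing 1-D array")
    if od0 <= 0:
        raise ValueError("od0 must be > 0")
    if carrying_capacity <= 0:
        raise ValueError("carrying_capacity must be > 0")
    mu = r_per_hour * np.log(2.0) / 60.0  # per minute
    if np.isinf(carrying_capacity):
        od = od0 * np.exp(mu * times_min)
    else:
        e = np.exp(mu * times_min)
        od = carrying_capacity * od0 * e / (carrying_capacity + od0 * (e - 1.0))
    if noise_sd > 0:
        rng = child_rng(seed, "simulate_growth")
        od = od * np.exp(rng.normal(0.0, noise_sd, size=od.shape))
    return pd.DataFrame(dict(time_min=times_min, od=od))


def simulate_competition(
    s_per_generation: float,
    g_per_cycle: float = 10.0,
    n_cycles: int = 4,
    cells_counted_per_sample: int | None = 1000,
    seed: int = 0,
    f0: float = 0.5,
) -> pd.DataFrame:
    """Two-strain serial competition: deterministic growth, binomial counting.

    The mutant frequency evolves per cycle as
    ``f' = f (1+s)^g / (f (1+s)^g + (1 - f))`` and the imaging step counts
    ``cells_counted_per_sample`` cells binomially at every checkpoint
    (``None`` disables counting noise and reports exact frequencies).
    Returns columns ``cycle, generations, f_true, count_x, count_y`` plus a
    ``truth_s`` attribute in ``DataFrame.attrs``.
    """
    if abs(s_per_generation) >= 1:
        raise ValueError("|s| must be < 1 per generation")
    if cells_counted_per_sample is not None and cells_counted_per_sample < 1:
        raise ValueError("cells_counted_per_sample must be >= 1")
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    rng = child_rng(seed, "simulate_competition")
    f = float(f0)
    w = (1.0 + s_per_generation) ** g_per_cycle
    freqs = [f]
    for _ in range(n_cycles):
        f = f * w / (f * w + (1.0 - f))
        freqs.append(f)
    freqs = np.array(freqs)
    cycles = np.arange(n_cycles + 1)
    if cells_counted_per_sample is None:
        count_x = np.full_like(freqs, np.nan)
        count_y = np.full_like(freqs, np.nan)
    else:
        count_x = rng.binomial(cells_counted_per_sample, freqs).astype(float)
        count_y = cells_counted_per_sample - count_x
    out = pd.DataFrame(
        dict(cycle=cycles, generations=cycles * float(g_per_cycle), f_true=freqs, count_x=count_x, count_y=count_y)
    )
    out.attrs["truth_s"] = s_per_generation
    out.attrs["g_per_cycle"] = g_per_cycle
    return out


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

def simulate_abundance(
    n_proteins: int = 500,
    n_samples_per_group: int = 6,
    de_proteins: list[str] | int = 20,
    fold: float = 2.0,
    missing_rate: float = 0.1,
    categories: dict[str, int] | int = 10,
    seed: int = 0,
    noise_sd_log2: float = 0.25,
    frac_single_peptide: float = 0.1,
):
    """Log-normal protein-abundance matrix with spiked group effects.

    Proteins named ``P0001..``; groups ``A`` (reference) and ``B`` carry
    ``n_samples_per_group`` samples each. DE proteins are shifted by
    ``log2(fold)`` in group B. Entries go missing at random at
    ``missing_rate``; a ``frac_single_peptide`` fraction of proteins get a
    single unique peptide (and so fail the >= 2-peptide filter). Categories
    are assigned at random with the stated sizes.

    Returns ``(abundance, peptide_counts, annotations, truth)`` where
    ``abundance`` is a proteins x samples DataFrame (NaN = not detected),
    ``annotations`` has columns ``protein, category`` and ``truth`` records
    the DE set, the group map and the category membership.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = child_rng(seed, "simulate_abundance")
    proteins = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    if isinstance(de_proteins, int):
        if de_proteins > n_proteins:
            raise ValueError("de_proteins count exceeds protein set")
        de_set = list(rng.choice(proteins, size=de_proteins, replace=False))
    else:
        de_set = list(de_proteins)
        if not set(de_set) <= set(proteins):
            raise ValueError("de_proteins must be a subset of the protein set")

    samples = [f"A{i+1}" for i in range(n_samples_per_group)] + [f"B{i+1}" for i in range(n_samples_per_group)]
    groups = {s: s[0] for s in samples}
    base = rng.normal(20.0, 2.0, size=n_proteins)
    log2int = base[:, None] + rng.normal(0.0, noise_sd_log2, size=(n_proteins, 2 * n_samples_per_group))
    de_idx = [proteins.index(p) for p in de_set]
    log2int[de_idx, n_samples_per_group:] += np.log2(fold)
    abundance = pd.DataFrame(2.0**log2int, index=proteins, columns=samples)
    if missing_rate > 0:
        mask = rng.random(abundance.shape) < missing_rate
        abundance = abundance.mask(mask)

    n_single = int(round(frac_single_peptide * n_proteins))
    single = rng.choice(n_proteins, size=n_single, replace=False)
    pep = 2 + rng.poisson(4.0, size=n_proteins)
    pep[single] = 1
    peptide_counts = pd.Series(pep, index=proteins, name="unique_peptides")

    if isinstance(categories, int):
        sizes = {f"GO{j:03d}": int(rng.integers(5, max(6, n_proteins // 10))) for j in range(1, categories + 1)}
    else:
        sizes = dict(categories)
    ann_rows = []
    membership = {}
    for cat, size in sizes.items():
        members = rng.choice(proteins, size=min(size, n_proteins), replace=False)
        membership[cat] = set(members)
        ann_rows.extend({"protein": p, "category": cat} for p in members)
    annotations = pd.DataFrame(ann_rows, columns=["protein", "category"])

    truth = dict(de_proteins=set(de_set), groups=groups, categories=membership, fold=fold)
    return abundance, peptide_counts, annotations, truth


# ---------------------------------------------------------------------------
# circular dichroism spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _GaussianMix:
    """Sum of Gaussians over wavelength; analytic so oracles can refine freely."""

    amplitudes: tuple[float, ...]
    centers_nm: tuple[float, ...]
    widths_nm: tuple[float, ...]

    def __call__(self, wl: np.ndarray) -> np.ndarray:
        wl = np.asarray(wl, float)
        out = np.zeros_like(wl)
        for a, c, w in zip(self.amplitudes, self.centers_nm, self.widths_nm):
            out += a * np.exp(-((wl - c) ** 2) / (2 * w**2))
        return out


def simulate_spectra(
    grid_nm: np.ndarray,
    perturbation: float | tuple | str = "random",
    seed: int = 0,
    oracle_refinement: int = 100,
):
    """Smooth synthetic CD spectra for a wild-type/mutant pair plus true ΔCD.

    ``perturbation`` is either a scalar amplitude scale for a random
    Gaussian-mixture perturbation (0 leaves the spectra identical),
    ``("offset", c, a, b)`` for a constant offset ``c`` over ``[a, b]`` nm, or
    ``"random"``. The true integrated absolute difference is computed by
    trapezoidal quadrature on a grid ``oracle_refinement`` times finer than
    ``grid_nm``. Returns ``(wt, mut, true_delta)`` with spectra as DataFrames
    ``(wavelength_nm, ellipticity)``.
    """
    grid_nm = np.asarray(grid_nm, float)
    if grid_nm.ndim != 1 or len(grid_nm) < 2 or np.any(np.diff(grid_nm) <= 0):
        raise ValueError("grid_nm must be strictly increasing with >= 2 points")
    rng = child_rng(seed, "simulate_spectra")
    lo, hi = grid_nm[0], grid_nm[-1]
    wt_mix = _GaussianMix(
        amplitudes=tuple(rng.uniform(-30, 10, 3)),
        centers_nm=tuple(rng.uniform(lo, hi, 3)),
        widths_nm=tuple(rng.uniform(5, 15, 3)),
    )

    if isinstance(perturbation, tuple) and perturbation and perturbation[0] == "offset":
        _, c, a, b = perturbation

        def pert(wl):
            wl = np.asarray(wl, float)
            return np.where((wl >= a) & (wl <= b), float(c), 0.0)

    else:
        scale = 1.0 if perturbation == "random" else float(perturbation)
        if scale == 0.0:
            def pert(wl):
                return np.zeros_like(np.asarray(wl, float))
        else:
            pmix = _GaussianMix(
                amplitudes=tuple(scale * rng.uniform(-8, 8, 2)),
                centers_nm=tuple(rng.uniform(lo, hi, 2)),
                widths_nm=tuple(rng.uniform(4, 10, 2)),
            )
            pert = pmix

    wt_vals = wt_mix(grid_nm)
    mut_vals = wt_vals + pert(grid_nm)
    fine = np.linspace(lo, hi, oracle_refinement * (len(grid_nm) - 1) + 1)
    true_delta = float(np.trapezoid(np.abs(pert(fine)), fine))
    wt = pd.DataFrame(dict(wavelength_nm=grid_nm, ellipticity=wt_vals))
    mut = pd.DataFrame(dict(wavelength_nm=grid_nm, ellipticity=mut_vals))
    return wt, mut, true_delta
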