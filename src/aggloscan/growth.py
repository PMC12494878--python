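"""Growth-curve fitting and competition-based fitness estimation.

Doubling time comes from the slope of a linear model of log2(OD) against
time within the best exponential-phase window: all windows of at least
``min_window`` points are scanned, those with R² at or above ``r2_min`` are
kept, and the steepest (earliest on ties) wins. The area under the growth
curve (AUC, OD·h) is a model-free companion statistic.

Competition fitness: with frequencies ``f_t`` of strain x at cumulative
generation ``g_t``, the log-odds satisfy
``logit(f_t) = logit(f_0) + t·g·ln(1+s)``, so an unweighted least-squares
regression of ``ln(f/(1-f))`` on generations recovers ``s`` (per-generation
rate difference) as ``exp(slope) - 1``. Selective advantage is then
``S = (r_x - r_y) / r_ref``; the reference defaults to the wild-type
competitor's rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GrowthFit:
    doubling_time_min: float
    rate_doublings_per_hour: float
    window: tuple[int, int]        # [start, end) indices into the curve
    r_squared: float
    auc_od_h: float


@dataclass(frozen=True)
class SelectiveAdvantage:
    S: float
    se: float
    r_x: float
    r_y: float
    r_ref: float
    n_replicates: int


def fit_growth(curve: pd.DataFrame, min_window: int = 5, r2_min: float = 0.99) -> GrowthFit:
    """Max-slope log-linear window fit of an OD600 growth curve.

    ``curve`` has columns ``time_min, od``. Zero/negative OD points are
    excluded with a warning. Doubling time is ``1/slope`` with the slope in
    doublings per minute; exact on noise-free exponentials. Raises if no
    window reaches ``r2_min``, reporting the best achievable R².
    """
    t = curve["time_min"].to_numpy(float)
    od = curve["od"].to_numpy(float)
    ok = od > 0
    if not ok.all():
        warnings.warn(f"excluding {np.sum(~ok)} non-positive OD points from the fit", stacklevel=2)
    t_fit, y = t[ok], np.log2(od[ok])
    n = len(t_fit)
    if n < max(min_window, 4):
        raise ValueError("need at least max(min_window, 4) positive-OD points")

    best = None       # (slope, -start) maximizing slope, earliest on ties
    best_r2_any = -np.inf
    for w in range(min_window, n + 1):
        for start in range(0, n - w + 1):
            tt = t_fit[start : start + w]
            yy = y[start : start + w]
            res = stats.linregress(tt, yy)
            r2 = res.rvalue**2
            best_r2_any = max(best_r2_any, r2)
            if r2 >= r2_min:
                key = (res.slope, -start, -w)
                if best is None or key > best[0]:
                    best = (key, res, (start, start + w), r2)
    if best is None:
        raise ValueError(f"no window of >= {min_window} points reached R^2 >= {r2_min} (best was {best_r2_any:.4f})")
    _, res, window, r2 = best
    slope = res.slope  # doublings per minute
    if slope <= 0:
        raise ValueError("best exponential window has non-positive slope; curve is not growing")
    return GrowthFit(
        doubling_time_min=1.0 / slope,
        rate_doublings_per_hour=slope * 60.0,
        window=window,
        r_squared=float(r2),
        auc_od_h=auc(curve),
    )


def auc(curve: pd.DataFrame) -> float:
    """Trapezoidal area under the OD curve, in OD·hours."""
    t = curve["time_min"].to_numpy(float)
    od = curve["od"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("need at least 2 points for an AUC")
    return float(np.trapezoid(od, t / 60.0))


def generations_per_cycle(dilution_factor: float) -> float:
    """Generations needed to regrow a 1:factor dilution back to saturation.

    ``log2(dilution_factor)``; 1:1000 gives 9.97, conventionally reported as
    about 10 generations per daily cycle.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    return float(np.log2(dilution_factor))


def competition_rates(series: pd.DataFrame, g_per_cycle: float | None = None, haldane: bool = False):
    """Per-generation rate difference of strain x over strain y.

    ``series`` has columns ``cycle`` (or ``generations``) and either
    ``count_x, count_y`` or ``f_true``; counts are converted to frequencies
    ``f = count_x / (count_x + count_y)``. Checkpoints at f in {0, 1} are
    excluded with a warning unless ``haldane`` applies a +0.5 correction to
    both counts. The log-odds are regressed on cumulative generations;
    returns ``(s, frequencies_df)`` with ``s = exp(slope) - 1``.
    """
    df = series.copy()
    if "generations" in df.columns:
        gens = df["generations"].to_numpy(float)
    else:
        if g_per_cycle is None:
            g_per_cycle = df.attrs.get("g_per_cycle")
            if g_per_cycle is None:
                raise ValueError("g_per_cycle required when the series has no generations column")
        gens = df["cycle"].to_numpy(float) * float(g_per_cycle)

    if "count_x" in df.columns and df["count_x"].notna().any():
        cx = df["count_x"].to_numpy(float)
        cy = df["count_y"].to_numpy(float)
        tot = cx + cy
        if np.any(tot < 1):
            raise ValueError("each checkpoint needs count_x + count_y >= 1")
        if haldane:
            f = (cx + 0.5) / (tot + 1.0)
        else:
            f = cx / tot
    elif "f_true" in df.columns:
        f = df["f_true"].to_numpy(float)
    else:
        raise ValueError("series needs count_x/count_y or f_true")

    usable = (f > 0) & (f < 1)
    if not usable.all():
        warnings.warn(f"dropping {np.sum(~usable)} checkpoints with frequency 0 or 1", stacklevel=2)
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable checkpoints (frequencies strictly inside (0,1))")
    logit = np.log(f[usable] / (1.0 - f[usable]))
    res = stats.linregress(gens[usable], logit)
    s = float(np.expm1(res.slope))
    freqs = pd.DataFrame(dict(generations=gens, frequency=f, used=usable))
    return s, freqs


def selective_advantage(r_x: float, r_y: float, r_ref: float | None = None, replicate_S: np.ndarray | None = None) -> SelectiveAdvantage:
    """S = (r_x - r_y) / r_ref with replicate-based standard error.

    ``r_ref`` defaults to ``r_y`` (the wild-type competitor normalizes the
    rate difference). ``replicate_S`` — per-replicate S estimates — gives the
    SE as sample SD / sqrt(n); otherwise the SE is NaN.
    """
    if r_ref is None:
        r_ref = r_y
    if r_ref == 0:
        raise ValueError("r_ref must be nonzero")
    S = (r_x - r_y) / r_ref
    if replicate_S is not None and len(replicate_S) > 1:
        reps = np.asarray(replicate_S, float)
        se = float(reps.std(ddof=1) / np.sqrt(len(reps)))
        n = len(reps)
    else:
        se, n = float("nan"), 0 if replicate_S is None else len(replicate_S)
    return SelectiveAdvantage(S=float(S), se=se, r_x=r_x, r_y=r_y, r_ref=r_ref, n_replicates=n)
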