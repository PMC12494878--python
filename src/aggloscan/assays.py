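"""Dissolution assay, co-localization scoring, and strain-level summaries.

The dissolution assay asks whether a mutant's self-assembly is competitively
dissolved by its co-expressed wild-type subunit. Cells are grouped into ten
quantile bins of the red/green (wild-type/mutant) intensity ratio and the
fraction of foci-positive cells per bin is reported with 95% Wilson CIs. A
foci fraction that falls with increasing wild-type excess indicates an
agglomerate (folded, interface-driven assembly); a flat profile indicates an
aggregate (misfolding-driven, immune to subunit dilution).

The package formalizes the qualitative agglomerate/aggregate call as a
dissolution index: 1 minus the ratio of the top-tercile to bottom-tercile
pooled foci fraction, clipped to [-1, 1]. Default labels: agglomerate at
index >= 0.8, aggregate at <= 0.2, intermediate between.

Co-localization between channels is the intersection-over-union of each
channel's top-decile brightest pixels within the cell mask — a rank-based
score, invariant to any strictly monotone intensity transform of either
channel. Reference interpretation from the assay's calibration: shared foci
typically score above 0.45; unrelated signal below 0.3 (annotations, not
filters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from statsmodels.stats.proportion import proportion_confint

from aggloscan.image_quant import QuantParams

COLOC_SHARED_REFERENCE = 0.45   # typical score for shared foci
COLOC_UNRELATED_REFERENCE = 0.30


@dataclass(frozen=True)
class DissolutionThresholds:
    agglomerate_min_index: float = 0.8
    aggregate_max_index: float = 0.2
    min_cells_per_tercile: int = 10


@dataclass(frozen=True)
class DissolutionCall:
    label: str                     # agglomerate | aggregate | intermediate
    dissolution_index: float       # in [-1, 1]
    baseline_fraction: float       # bottom-tercile pooled foci fraction
    top_fraction: float            # top-tercile pooled foci fraction
    flagged: bool = False          # baseline fraction was 0 (index undefined)


def ratio_bins(
    cells: pd.DataFrame,
    n_bins: int = 10,
    params: QuantParams | None = None,
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Quantile-bin cells by red/green ratio; foci fraction + 95% CI per bin.

    ``cells`` needs columns ``ratio_red_green`` and either ``has_foci`` or
    ``ratio_max_median_green`` (classified against the 2.5 threshold). Bin
    edges are empirical quantiles of the finite ratios, computed per input
    table (per construct). CI is the Wilson score interval by default
    (``ci_method="normal"`` for the Wald approximation).

    Returns columns ``bin_index (1..n_bins), ratio_lo, ratio_hi, n_cells,
    foci_fraction, ci_lo, ci_hi``.
    """
    params = params or QuantParams()
    ratios = pd.to_numeric(cells["ratio_red_green"], errors="coerce")
    finite = np.isfinite(ratios)
    df = cells.loc[finite].copy()
    if len(df) < n_bins:
        raise ValueError(
            f"only {len(df)} cells with finite ratios for {n_bins} bins; use a smaller n_bins"
        )
    if "has_foci" in df.columns:
        foci = df["has_foci"].astype(bool).to_numpy()
    else:
        foci = (df["ratio_max_median_green"].to_numpy() > params.foci_ratio_threshold)
    r = df["ratio_red_green"].to_numpy(float)
    edges = np.quantile(r, np.linspace(0, 1, n_bins + 1))
    # right-closed bins; the lowest edge is inclusive
    idx = np.clip(np.searchsorted(edges, r, side="left") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        k = int(foci[sel].sum())
        frac = k / n if n else np.nan
        if n:
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson" if ci_method == "wilson" else "normal")
        else:
            lo = hi = np.nan
        rows.append(
            dict(bin_index=b + 1, ratio_lo=float(edges[b]), ratio_hi=float(edges[b + 1]),
                 n_cells=n, foci_fraction=frac, ci_lo=float(lo), ci_hi=float(hi))
        )
    return pd.DataFrame(rows)


def dissolution_call(bins: pd.DataFrame, thresholds: DissolutionThresholds | None = None) -> DissolutionCall:
    """Classify a binned dissolution profile on the agglomerate↔aggregate axis.

    Pools cells in the bottom and top terciles of the bin range; the index is
    ``1 - top_fraction / baseline_fraction`` clipped to [-1, 1]. A zero
    baseline makes the index undefined: the call is ``intermediate`` with a
    flag.
    """
    thresholds = thresholds or DissolutionThresholds()
    nb = len(bins)
    if nb < 3:
        raise ValueError("need at least 3 bins")
    t = max(1, nb // 3)
    bottom = bins.iloc[:t]
    top = bins.iloc[-t:]
    for part, name in ((bottom, "bottom"), (top, "top")):
        if part["n_cells"].sum() < thresholds.min_cells_per_tercile:
            raise ValueError(f"fewer than {thresholds.min_cells_per_tercile} cells in the {name} tercile")

    def pooled(part: pd.DataFrame) -> float:
        n = part["n_cells"].sum()
        k = (part["foci_fraction"] * part["n_cells"]).sum()
        return float(k / n)

    base = pooled(bottom)
    topf = pooled(top)
    if base == 0.0:
        return DissolutionCall("intermediate", float("nan"), base, topf, flagged=True)
    index = float(np.clip(1.0 - topf / base, -1.0, 1.0))
    if index >= thresholds.agglomerate_min_index:
        label = "agglomerate"
    elif index <= thresholds.aggregate_max_index:
        label = "aggregate"
    else:
        label = "intermediate"
    return DissolutionCall(label, index, base, topf)


def coloc_score(
    green: np.ndarray,
    red: np.ndarray,
    cell_mask: np.ndarray,
    top_fraction: float = 0.10,
) -> float | None:
    """Top-decile intersection-over-union between two channels in one cell.

    Each channel's ``ceil(top_fraction * area)`` brightest pixels inside the
    mask form a set; ties at the cutoff break by row-major pixel order after
    sorting by intensity descending (fully deterministic). Returns
    ``|A∩B| / |A∪B|``, or ``None`` (no signal) when a channel is constant
    inside the mask.
    """
    green = np.asarray(green, float)
    red = np.asarray(red, float)
    cell_mask = np.asarray(cell_mask, bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    flat = np.flatnonzero(cell_mask.ravel())  # row-major order
    g = green.ravel()[flat]
    r = red.ravel()[flat]
    if np.ptp(g) == 0 or np.ptp(r) == 0:
        return None
    m = int(np.ceil(top_fraction * flat.size))

    def top_set(vals: np.ndarray) -> set[int]:
        order = np.lexsort((np.arange(vals.size), -vals))  # stable: intensity desc, then row-major
        return set(flat[order[:m]].tolist())

    a, b = top_set(g), top_set(r)
    return len(a & b) / len(a | b)


def strain_pair_summary(
    scores: pd.DataFrame,
    params: QuantParams | None = None,
) -> dict:
    """Summarize one query-construct x library-marker pair.

    ``scores`` needs columns ``cell_id, score, has_foci`` (score may be NaN
    for no-signal cells). Only foci-positive cells with a defined score
    count; fewer than ``min_cells_per_strain`` usable cells yields status
    ``NA_too_few_cells`` and all-undefined scores yields ``NA_no_signal``.
    """
    params = params or QuantParams()
    foci = scores[scores["has_foci"].astype(bool)]
    usable = foci[foci["score"].notna()]
    if len(foci) and not len(usable):
        return dict(mean_score=np.nan, n_cells_used=0, status="NA_no_signal")
    if len(usable) < params.min_cells_per_strain:
        return dict(mean_score=np.nan, n_cells_used=int(len(usable)), status="NA_too_few_cells")
    return dict(mean_score=float(usable["score"].mean()), n_cells_used=int(len(usable)), status="ok")


def _pairwise_complete_euclidean(mat: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances using pairwise-complete entries.

    Distances are rescaled to the full column count so rows with few shared
    entries are comparable; pairs sharing no non-NA column get the maximal
    finite distance observed (plus epsilon), keeping the linkage well-defined.
    """
    n, p = mat.shape
    d = np.zeros(n * (n - 1) // 2)
    idx = 0
    missing_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
            if both.any():
                diff = mat[i, both] - mat[j, both]
                d[idx] = np.sqrt((diff**2).sum() * p / both.sum())
            else:
                missing_pairs.append(idx)
            idx += 1
    if missing_pairs:
        fill = (d[d > 0].max() if (d > 0).any() else 1.0) * 1.01
        d[missing_pairs] = fill
    return d


def cluster_matrix(matrix: pd.DataFrame):
    """Average-linkage hierarchical clustering of a score matrix with NAs.

    Returns ``(row_order, col_order, row_linkage, col_linkage)`` where orders
    are index/column labels in deterministic dendrogram leaf order.
    """
    mat = matrix.to_numpy(float)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix to cluster")
    if np.isnan(mat).all():
        raise ValueError("matrix is entirely NA")

    def _order(m: np.ndarray):
        link = hierarchy.linkage(_pairwise_complete_euclidean(m), method="average")
        return hierarchy.leaves_list(link), link

    ri, rl = _order(mat)
    ci, cl = _order(mat.T)
    return (
        [matrix.index[i] for i in ri],
        [matrix.columns[i] for i in ci],
        rl,
        cl,
    )
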