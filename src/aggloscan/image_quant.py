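"""Per-cell intensity statistics, puncta detection, and the foci classifier.

The central operator reproduces the per-cell puncta rule used for yeast
fluorescence screens: within each segmented cell, candidate pixels are those
at least ``foci_fold_threshold`` (default 2.5) times the cell's median
intensity AND at least ``background_margin_AU`` (default 100 AU) above the
field background; the largest connected component of candidates is the
punctum/filament call, annotated with its circularity (4πA/P²). A cell is
classified as foci-positive when its max/median intensity ratio strictly
exceeds ``foci_ratio_threshold`` (default 2.5).

Conventions (documented, configurable where noted):

* "2.5-folds above the median" is read multiplicatively: candidacy requires
  ``intensity >= 2.5 * median``; "above 100 AU above the background" requires
  ``intensity >= background + 100``. Both conditions are conjunctive. Pixel
  candidacy uses ``>=``; the per-cell classifier uses strict ``>``.
* Background is the median of non-cell pixels (the original description
  leaves "the background" undefined); an explicit value may be supplied.
* Circularity uses the Crofton (line-intercept) perimeter estimator
  (``skimage.measure.perimeter_crofton``, 4 directions); discrete geometry
  can push it slightly above 1. Regions of one or two pixels are assigned
  circularity 1.0.
* Largest-component ties break deterministically by (min row, then min col).
* Coordinates are 0-based (row, col); connectivity defaults to 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu, threshold_triangle

DECILES = tuple(range(10, 100, 10))


@dataclass(frozen=True)
class QuantParams:
    foci_fold_threshold: float = 2.5       # x cell median, pixel candidacy
    background_margin_AU: float = 100.0    # AU above background, pixel candidacy
    circularity_min: float = 0.4
    foci_ratio_threshold: float = 2.5      # max/median, per-cell classifier
    coloc_top_fraction: float = 0.10
    min_cells_per_strain: int = 20
    connectivity: int = 8                  # 4 or 8
    min_cell_area_px: int = 30             # segmentation size filter

    def __post_init__(self):
        for name in ("foci_fold_threshold", "background_margin_AU", "circularity_min", "foci_ratio_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.coloc_top_fraction < 1:
            raise ValueError("coloc_top_fraction must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def segment_cells(
    image: np.ndarray,
    params: QuantParams | None = None,
    external_mask: np.ndarray | None = None,
    method: str = "triangle",
) -> np.ndarray:
    """Label-mask segmentation: global threshold, hole filling, size filter.

    The default threshold is the triangle method, which stays robust when
    background dominates the histogram (sparse fields make Otsu land inside
    the cell-brightness range); ``method="otsu"`` selects Otsu instead. If
    ``external_mask`` is given it is validated (2-D, non-negative integer
    labels) and returned unchanged — the bypass for users with their own
    segmentation. A constant image yields an empty (all-zero) mask.
    """
    params = params or QuantParams()
    if external_mask is not None:
        external_mask = np.asarray(external_mask)
        if external_mask.ndim != 2:
            raise ValueError("external mask must be 2-D")
        if not np.issubdtype(external_mask.dtype, np.integer) or external_mask.min() < 0:
            raise ValueError("external mask must contain non-negative integer labels")
        return external_mask
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=np.int32)
    threshold = threshold_otsu(image) if method == "otsu" else threshold_triangle(image)
    fg = image > threshold
    fg = ndi.binary_fill_holes(fg)
    labels = measure.label(fg, connectivity=2 if params.connectivity == 8 else 1)
    # drop specks below the minimum area, then relabel 1..K
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= params.min_cell_area_px)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def estimate_background(image: np.ndarray, labels: np.ndarray) -> float:
    """Median intensity of background (label 0) pixels.

    Even-count median is the mean of the central pair (numpy convention).
    """
    image = np.asarray(image, float)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError("image and mask shapes differ")
    bg = image[labels == 0]
    if bg.size == 0:
        raise ValueError("mask has no background pixels; cannot estimate background")
    return float(np.median(bg))


def cell_stats(green: np.ndarray, red: np.ndarray, labels: np.ndarray, params: QuantParams | None = None) -> pd.DataFrame:
    """Per-cell intensity summaries for both channels.

    One row per nonzero label: area, median/mean/min/max and deciles
    p10..p90 (linear-interpolation percentiles) per channel, the red/green
    median ratio, the green max/median ratio, and the foci classification.
    A zero median yields an infinite ratio and a ``ratio_flagged`` mark.
    """
    params = params or QuantParams()
    green = np.asarray(green, float)
    red = np.asarray(red, float)
    labels = np.asarray(labels)
    if not (green.shape == red.shape == labels.shape):
        raise ValueError("images and mask must share a shape")
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        row: dict = {"cell_id": int(lab), "area_px": int(sel.sum())}
        for name, img in (("green", green), ("red", red)):
            px = img[sel]
            row[f"median_{name}"] = float(np.median(px))
            row[f"mean_{name}"] = float(px.mean())
            row[f"min_{name}"] = float(px.min())
            row[f"max_{name}"] = float(px.max())
            decs = np.percentile(px, DECILES)
            for d, v in zip(DECILES, decs):
                row[f"p{d}_{name}"] = float(v)
        mg, mr = row["median_green"], row["median_red"]
        row["ratio_red_green"] = mr / mg if mg > 0 else np.inf
        row["ratio_max_median_green"] = row["max_green"] / mg if mg > 0 else np.inf
        row["ratio_flagged"] = mg <= 0
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df["has_foci"] = [classify_foci_cell(r, params) for _, r in df.iterrows()]
    else:
        df["has_foci"] = pd.Series(dtype=bool)
    return df


def classify_foci_cell(record: pd.Series | dict, params: QuantParams | None = None) -> bool:
    """Foci-positive iff max/median green ratio strictly exceeds the threshold.

    A ratio of exactly 2.5 is negative ("above 2.5" read strictly). Zero
    medians carry an infinite ratio and classify positive (flagged upstream).
    The decision is invariant to rescaling the cell's intensities.
    """
    params = params or QuantParams()
    ratio = record["ratio_max_median_green"]
    return bool(ratio > params.foci_ratio_threshold)


def _perimeter(region_mask: np.ndarray) -> float:
    return float(measure.perimeter_crofton(region_mask, directions=4))


def circularity(region_mask: np.ndarray) -> float:
    """4π·area / perimeter²; regions of ≤ 2 pixels are 1.0 by convention."""
    area = int(region_mask.sum())
    if area <= 2:
        return 1.0
    p = _perimeter(region_mask)
    if p == 0:
        return 1.0
    return 4.0 * np.pi * area / p**2


def detect_puncta(
    image: np.ndarray,
    labels: np.ndarray,
    background: float,
    params: QuantParams | None = None,
) -> pd.DataFrame:
    """Detect at most one punctum/filament per cell.

    Per cell: candidate pixels satisfy both
    ``intensity >= foci_fold_threshold * cell_median`` and
    ``intensity >= background + background_margin_AU``; connected components
    of candidates are formed within the cell and only the largest is kept
    (ties by min row then min col). The call records area, centroid, mean and
    peak intensity, circularity, and whether it passes the circularity gate.
    Cells without candidates yield no call.

    Returns a DataFrame with columns ``cell_id, area_px, centroid_r,
    centroid_c, min_r, min_c, mean_AU, peak_AU, circularity,
    passed_circularity, pixels`` (``pixels`` holds the (row, col) list).
    """
    params = params or QuantParams()
    image = np.asarray(image, float)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError("image and mask shapes differ")
    if not np.isfinite(background):
        raise ValueError("background must be finite")
    structure = np.ones((3, 3), bool) if params.connectivity == 8 else ndi.generate_binary_structure(2, 1)
    calls = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        px = image[sel]
        med = float(np.median(px))
        thr = max(params.foci_fold_threshold * med, background + params.background_margin_AU)
        cand = sel & (image >= thr)
        if not cand.any():
            continue
        comp, n = ndi.label(cand, structure=structure)
        # pick the largest component; deterministic tie-break by bounding box
        best = None
        for cid in range(1, n + 1):
            rr, cc = np.nonzero(comp == cid)
            key = (-rr.size, rr.min(), cc.min())
            if best is None or key < best[0]:
                best = (key, rr, cc)
        _, rr, cc = best
        region = np.zeros_like(sel)
        region[rr, cc] = True
        circ = circularity(region)
        vals = image[rr, cc]
        calls.append(
            dict(
                cell_id=int(lab),
                area_px=int(rr.size),
                centroid_r=float(rr.mean()),
                centroid_c=float(cc.mean()),
                min_r=int(rr.min()),
                min_c=int(cc.min()),
                mean_AU=float(vals.mean()),
                peak_AU=float(vals.max()),
                circularity=float(circ),
                passed_circularity=bool(circ > params.circularity_min),
                pixels=list(zip(rr.tolist(), cc.tolist())),
            )
        )
    cols = [
        "cell_id", "area_px", "centroid_r", "centroid_c", "min_r", "min_c",
        "mean_AU", "peak_AU", "circularity", "passed_circularity", "pixels",
    ]
    return pd.DataFrame(calls, columns=cols)
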