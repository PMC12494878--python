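"""Protein-abundance filtering, normalization, differential testing, and a
joint resampling category-enrichment test.

The workflow mirrors a label-free pull-down comparison between strains:

1. keep proteins with at least 2 unique peptides that are detected in at
   least 80% of samples;
2. quantile-normalize sample columns on their detected values;
3. impute remaining missing entries (half-row-minimum or correlation-kNN;
   deliberately simple, method-labelled substitutes for model-based
   imputation — results are method-variant, not reproductions);
4. per-protein two-sided Welch t-test on log2 intensities with BH
   adjustment; a protein is a hit when its fold change exceeds 1.68-fold
   (strictly, in either direction) and the adjusted P is below 0.05;
5. optional exclusivity rule: hits seen in one contrast and not the other;
6. category over-representation by joint resampling: draw |hits| proteins
   from the universe without replacement, many times, and count iterations
   where a category's overlap reaches the observed count ("equal or above").
   All categories share each iteration's draw; the marginal null per
   category is exactly hypergeometric. Zero exceedances are reported as
   p < 1/m rather than 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from aggloscan.utils import child_rng

FOLD_THRESHOLD = 1.68
ALPHA = 0.05


# ---------------------------------------------------------------------------
# filtering / normalization / imputation
# ---------------------------------------------------------------------------

def filter_table(
    abundance: pd.DataFrame,
    peptide_counts: pd.Series,
    min_unique_peptides: int = 2,
    min_detection: float = 0.8,
):
    """Keep proteins with >= ``min_unique_peptides`` unique peptides detected
    in >= ``min_detection`` of the samples.

    Detection means a non-NaN intensity. Returns ``(filtered, report)`` where
    ``report`` counts removals per criterion (a protein failing both is
    counted in both). An empty result is a warning, not an error.
    """
    detected_frac = abundance.notna().mean(axis=1)
    pep = peptide_counts.reindex(abundance.index)
    fail_pep = pep < min_unique_peptides
    fail_det = detected_frac < min_detection
    keep = ~(fail_pep | fail_det)
    report = dict(
        n_input=len(abundance),
        removed_peptides=int(fail_pep.sum()),
        removed_detection=int(fail_det.sum()),
        n_kept=int(keep.sum()),
    )
    if report["n_kept"] == 0:
        warnings.warn("all proteins removed by filtering", stacklevel=2)
    return abundance.loc[keep], report


def quantile_normalize(abundance: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization of sample columns on detected values.

    With complete data this is the textbook algorithm: within each column,
    the k-th smallest value is replaced by the mean of the k-th smallest
    values across all columns. Missing entries are left missing; columns
    with unequal detected counts are mapped through interpolated quantiles
    of the reference (mean) distribution. A single column is returned
    unchanged.
    """
    if abundance.shape[1] <= 1:
        return abundance.copy()
    # reference distribution: mean of per-column quantile functions on the
    # grid k/(max_n - 1); with equal detected counts this reduces to the
    # textbook mean-of-k-th-smallest reference
    max_n = int(abundance.notna().sum(axis=0).max())
    if max_n == 0:
        raise ValueError("no detected values in any column")
    if max_n == 1:
        probs = np.array([0.5])
    else:
        probs = np.arange(max_n) / (max_n - 1)
    ref = np.zeros(max_n)
    for c in abundance.columns:
        vals = abundance[c].dropna().to_numpy(float)
        ref += np.quantile(vals, probs)
    ref /= abundance.shape[1]
    out = abundance.copy()
    for c in abundance.columns:
        col = abundance[c]
        det = col.notna()
        vals = col[det].to_numpy(float)
        n = vals.size
        ranks = stats.rankdata(vals, method="average")  # 1..n, ties averaged
        p = (ranks - 1.0) / (n - 1.0) if n > 1 else np.array([0.5])
        out.loc[det, c] = np.interp(p, probs, ref)
    return out


def impute(abundance: pd.DataFrame, method: str = "half_min", k: int = 5) -> pd.DataFrame:
    """Fill missing intensities; ``half_min`` or correlation-``knn``.

    half_min: missing entries become half the row minimum of detected
    values (missingness treated as censoring at the detection limit).
    knn: each incomplete row borrows the mean of its ``k`` most correlated
    complete-enough rows, column-wise. The method is recorded in
    ``DataFrame.attrs["impute_method"]``.
    """
    if (abundance.isna().all(axis=1)).any():
        raise ValueError("fully missing rows cannot be imputed (filter first)")
    out = abundance.copy()
    if method == "half_min":
        row_min = out.min(axis=1, skipna=True)
        for c in out.columns:
            miss = out[c].isna()
            out.loc[miss, c] = row_min[miss] / 2.0
    elif method == "knn":
        # rows are centered by their detected mean before both the neighbor
        # search and the transfer, so donors at different absolute abundance
        # still inform the missing entry's within-row deviation
        log = np.log2(out.where(out > 0))
        mat = log.to_numpy(float)
        row_mean = np.nanmean(mat, axis=1)
        centered = mat - row_mean[:, None]
        filled = np.nan_to_num(centered, nan=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(filled)
        corr = np.nan_to_num(corr, nan=-1.0)
        np.fill_diagonal(corr, -np.inf)
        for i in np.flatnonzero(np.isnan(mat).any(axis=1)):
            neighbors = np.argsort(-corr[i])[:k]
            for j in np.flatnonzero(np.isnan(mat[i])):
                donor = centered[neighbors, j]
                donor = donor[~np.isnan(donor)]
                mat[i, j] = row_mean[i] + (donor.mean() if donor.size else 0.0)
        out = pd.DataFrame(2.0**mat, index=out.index, columns=out.columns)
    else:
        raise ValueError("method must be 'half_min' or 'knn'")
    out.attrs["impute_method"] = method
    return out


def collapse_technical_replicates(abundance: pd.DataFrame, tech_map: dict[str, str]) -> pd.DataFrame:
    """Average technical replicates into their biological replicate.

    ``tech_map`` maps sample column -> biological replicate id. Averaging is
    on the log2 scale (geometric mean of intensities), avoiding
    pseudo-replication in downstream tests.
    """
    log = np.log2(abundance.where(abundance > 0))
    grouped = log.T.groupby(pd.Series(tech_map)).mean().T
    return 2.0**grouped


# ---------------------------------------------------------------------------
# differential testing and hit calling
# ---------------------------------------------------------------------------

def differential(abundance: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.DataFrame:
    """Per-protein Welch t-test of log2 intensities, group A vs group B.

    Returns columns ``protein, log2_fc (A - B means), p, p_adj, hit`` with BH
    adjustment across all tested proteins. Zero within-group variance in
    both groups with equal means gives p = 1 by convention.
    """
    for g, name in ((group_a, "A"), (group_b, "B")):
        if len(g) < 2:
            raise ValueError(f"group {name} needs >= 2 samples")
    la = np.log2(abundance[group_a].to_numpy(float))
    lb = np.log2(abundance[group_b].to_numpy(float))
    fc = la.mean(axis=1) - lb.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    p = np.where(degenerate & (np.abs(fc) == 0), 1.0, p)
    # degenerate but separated groups: perfect separation, smallest honest p
    p = np.where(np.isnan(p), np.finfo(float).tiny, p)
    p_adj = bh_adjust(p)
    hits = (np.abs(fc) > np.log2(FOLD_THRESHOLD)) & (p_adj < ALPHA)
    return pd.DataFrame(
        dict(protein=abundance.index, log2_fc=fc, p=p, p_adj=p_adj, hit=hits)
    ).set_index("protein")


def call_hits(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame | None = None,
    fold: float = FOLD_THRESHOLD,
    alpha: float = ALPHA,
    exclusive: bool = False,
):
    """Apply the hit rule; optionally the exclusivity rule across contrasts.

    A hit changes strictly more than ``fold``-fold in either direction with
    adjusted P below ``alpha``. With ``exclusive=True`` (requires two result
    tables over a shared universe) returns ``(hits_only_a, hits_only_b)``;
    otherwise the hit set of ``results_a``.
    """

    def hit_set(res: pd.DataFrame) -> set[str]:
        sel = (np.abs(res["log2_fc"]) > np.log2(fold)) & (res["p_adj"] < alpha)
        return set(res.index[sel])

    a = hit_set(results_a)
    if not exclusive:
        return a
    if results_b is None:
        raise ValueError("exclusive hit calling needs both result tables")
    b = hit_set(results_b)
    return a - b, b - a


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    n_hits_in_category: int
    n_hits: int
    category_size: int
    universe_size: int
    p: float
    p_is_upper_bound: bool   # True when no iteration reached k (p < 1/m)
    p_adj: float
    iterations: int


def bootstrap_enrichment(
    hits: set[str],
    universe: list[str],
    annotations: pd.DataFrame,
    iterations: int = 1_000_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> list[EnrichmentResult]:
    """Joint resampling over-representation test for annotated categories.

    For each of ``iterations`` rounds, ``n = |hits|`` proteins are drawn from
    the universe without replacement and every category's overlap with the
    draw is recorded; the P value is the fraction of rounds where the
    overlap was equal to or above the observed count. Drawing jointly leaves
    each category's marginal null exactly hypergeometric. Only categories
    with at least one observed hit are tested; BH adjustment is applied
    across them. A zero exceedance count reports ``p = 1/m`` flagged as an
    upper bound.
    """
    universe = list(universe)
    n_univ = len(universe)
    n = len(hits)
    if not set(hits) <= set(universe):
        raise ValueError("hits must be a subset of the universe")
    if n > n_univ:
        raise ValueError("cannot draw more hits than the universe holds")
    if iterations < 1000:
        warnings.warn("fewer than 1000 iterations gives poor p-value resolution", stacklevel=2)
    idx = {p: i for i, p in enumerate(universe)}
    ann = annotations[annotations["protein"].isin(idx)]
    cats = []
    members = []
    observed = []
    for cat, grp in ann.groupby("category", sort=True):
        mem = np.zeros(n_univ, dtype=bool)
        mem[[idx[p] for p in grp["protein"]]] = True
        k = sum(1 for h in hits if mem[idx[h]])
        if k >= 1:
            cats.append(cat)
            members.append(mem)
            observed.append(k)
    if not cats:
        return []
    members = np.asarray(members, dtype=np.int16)   # categories x universe
    observed = np.asarray(observed)
    exceed = np.zeros(len(cats), dtype=np.int64)
    rng = child_rng(seed, "bootstrap_enrichment")
    # keep each chunk's random-key matrix around ~20M doubles
    chunk = max(1, min(chunk, int(2e7 // max(n_univ, 1))))
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        # vectorized sampling without replacement: the n smallest of a row of
        # random keys is a uniform draw of n distinct universe indices
        keys = rng.random((m, n_univ))
        draw_idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        counts = members[:, draw_idx].sum(axis=2)   # categories x m
        exceed += (counts >= observed[:, None]).sum(axis=1)
        done += m
    p_raw = exceed / iterations
    bound = p_raw == 0.0
    p_eff = np.where(bound, 1.0 / iterations, p_raw)
    p_adj = bh_adjust(p_eff)
    return [
        EnrichmentResult(
            category=c,
            n_hits_in_category=int(k),
            n_hits=n,
            category_size=int(mem.sum()),
            universe_size=n_univ,
            p=float(pe),
            p_is_upper_bound=bool(b),
            p_adj=float(pa),
            iterations=iterations,
        )
        for c, k, mem, pe, b, pa in zip(cats, observed, members, p_eff, bound, p_adj)
    ]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
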