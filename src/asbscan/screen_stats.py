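"""CRISPR-screen and pseudotime (perturb-seq style) statistics.

The screen layer consumes per-gene directional p-values from an upstream
rank-aggregation tool (e.g. MAGeCK RRA on sorted marker-high vs marker-low
populations).  Because enrichment in one sorting gate and depletion from
the other are different, non-independent hypotheses, their Fisher-method
combination is only a *pseudo* p-value (psi-P); its false-discovery rate is
therefore calibrated by simulation under an assumed number of true
positives, using unexpressed genes as known true negatives.

The cell layer tests knockout effects on differentiation pseudotime:
one-sided Mann-Whitney shift tests per dataset combined across platforms by
weighted Stouffer, Hedges-g effect sizes combined as weighted Z-scores,
kernel-density window enrichment along the pseudotime axis, and a
LOWESS-residual test for marker-expression effects that controls for
pseudotime.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger("asbscan")

P_FLOOR = 1e-300


# ------------------------------------------------------------ combination

def fisher_combine_pseudo_p(p1: float, p2: float) -> float:
    """Fisher's method for two (possibly dependent) p-values.

    chi2 = -2(ln p1 + ln p2); the survival probability at 4 df has the
    closed form ``exp(-x/2) * (1 + x/2)``.  With dependent inputs the
    result is a pseudo p-value, to be calibrated rather than interpreted
    at face value.
    """
    for p in (p1, p2):
        if not (0 <= p <= 1):
            raise ValueError("p-values must lie in [0, 1]")
    if p1 == 0 or p2 == 0:
        logger.warning("p=0 clipped to %g before log", P_FLOOR)
    p1 = max(p1, P_FLOOR)
    p2 = max(p2, P_FLOOR)
    x = -2.0 * (math.log(p1) + math.log(p2))
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)


def pseudo_p_table(genes: pd.DataFrame, cutoff: float = 0.001) -> pd.DataFrame:
    """Per-gene psi-P in each direction and the overall minimum.

    Expects columns gene, p_high_enrich, p_low_deplete, p_high_deplete,
    p_low_enrich (and optional expressed / positive_control flags).  The
    "up" direction combines enrichment in the marker-high gate with
    depletion from the marker-low gate; "down" is the reverse.
    """
    df = genes.copy()
    df["psi_p_up"] = [fisher_combine_pseudo_p(a, b)
                      for a, b in zip(df["p_high_enrich"], df["p_low_deplete"])]
    df["psi_p_down"] = [fisher_combine_pseudo_p(a, b)
                        for a, b in zip(df["p_high_deplete"], df["p_low_enrich"])]
    df["psi_p"] = np.minimum(df["psi_p_up"], df["psi_p_down"])
    df["hit"] = df["psi_p"] < cutoff
    return df


def stouffer_combine(ps: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted Stouffer combination of one-sided p-values.

    ``Z = sum(w_i z_i) / sqrt(sum(w_i^2))`` with ``z_i`` the upper-tail
    normal quantile of ``p_i``; returns the combined one-sided p.
    """
    ps = np.asarray(ps, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be non-negative with at least one positive")
    if np.any((ps <= 0) | (ps >= 1)):
        logger.warning("p-values clipped into (0, 1) before normal quantile")
        ps = np.clip(ps, P_FLOOR, 1 - 1e-16)
    z = stats.norm.isf(ps)
    Z = float(np.sum(weights * z) / math.sqrt(np.sum(weights**2)))
    return float(stats.norm.sf(Z))


def two_sided_from_directions(p_greater: float, p_less: float) -> float:
    """Doubled smaller one-sided p, capped at 1."""
    return min(1.0, 2.0 * min(p_greater, p_less))


# --------------------------------------------------------- FDR simulation

def screen_fdr_simulation(
    genes: pd.DataFrame,
    cutoff: float = 0.001,
    true_positive_range: tuple[int, int] = (100, 300),
    n_t_grid: int = 5,
    n_sims: int = 100,
    fpr_grid: Sequence[float] | None = None,
    seed: int = 0,
) -> dict:
    """Simulation-calibrated FDR of the psi-P hit set.

    Assumes (1) unexpressed genes are all true negatives and (2) some
    number T of expressed genes are true positives, all detected.  For each
    T on a grid spanning ``true_positive_range``, false positives are drawn
    Bernoulli(f) over the N-T non-true genes for each f on ``fpr_grid``;
    the f whose simulated unexpressed fraction among hits best matches the
    observed fraction (mean absolute difference over ``n_sims`` draws) gives
    FDR = simulated false positives / observed hits.  Reports the FDR range
    over the T grid.

    ``genes`` needs boolean columns expressed and hit (psi_p < cutoff).
    """
    df = genes
    n_genes = len(df)
    hits = df["hit"].astype(bool)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("no hits at the chosen cutoff")
    n_unexp = int((~df["expressed"].astype(bool)).sum())
    n_exp = n_genes - n_unexp
    obs_unexp_hits = int((hits & ~df["expressed"].astype(bool)).sum())
    obs_frac = obs_unexp_hits / n_hits
    if obs_unexp_hits == 0 and n_unexp > 0:
        logger.info("no unexpressed genes among hits; FDR lower bound is 0")
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 0.5, 201)
    fpr_grid = np.asarray(fpr_grid, dtype=float)
    rng = np.random.default_rng(seed)
    t_lo, t_hi = true_positive_range
    t_grid = np.unique(np.linspace(t_lo, t_hi, n_t_grid).astype(int))
    results = []
    for T in t_grid:
        T = int(min(T, n_exp))
        n_null_unexp = n_unexp            # unexpressed genes are never true
        n_null_exp = n_exp - T
        best = None
        for f in fpr_grid:
            fp_unexp = rng.binomial(n_null_unexp, f, size=n_sims)
            fp_exp = rng.binomial(n_null_exp, f, size=n_sims)
            sim_frac = fp_unexp / n_hits
            mismatch = float(np.mean(np.abs(sim_frac - obs_frac)))
            fdr = float(np.mean(fp_unexp + fp_exp)) / n_hits
            if best is None or mismatch < best[0]:
                best = (mismatch, float(f), fdr)
        results.append({"T": T, "fpr": best[1], "fdr": best[2]})
    fdrs = [r["fdr"] for r in results]
    return {"fdr_min": min(fdrs), "fdr_max": max(fdrs), "per_T": results,
            "observed_unexpressed_fraction": obs_frac, "n_hits": n_hits}


# ------------------------------------------------------------ effect sizes

def hedges_g(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> float:
    """Standardized mean difference with the small-sample correction
    ``J = 1 - 3/(4(n1+n2)-9)`` and equal-variance pooled SD."""
    if n1 < 2 or n2 < 2:
        raise ValueError("hedges_g requires n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    s_pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if s_pooled == 0:
        if mean1 == mean2:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: infinite effect")
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return J * (mean1 - mean2) / s_pooled


def z_normalize(values: Sequence[float]) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    sd = np.std(v, ddof=0)
    if sd == 0:
        return np.zeros_like(v)
    return (v - np.mean(v)) / sd


def combine_effects(values: Sequence[Sequence[float]],
                    weights: Sequence[float]) -> np.ndarray:
    """Weighted mean of per-platform effect sizes after Z-normalization.

    ``values`` is one effect vector per platform (aligned across genes);
    ``weights`` one weight per platform (e.g. average cells per guide).
    """
    mat = np.vstack([z_normalize(v) for v in values])
    weights = np.asarray(weights, dtype=float)
    return np.average(mat, axis=0, weights=weights)


# -------------------------------------------------------- pseudotime tests

def _dataset_weights(cells: pd.DataFrame) -> dict[str, float]:
    """Per-dataset weight = total cells / number of guides.

    Uses a ``guide`` column when present, otherwise the number of distinct
    targets as a proxy for the guide count.
    """
    weights = {}
    for ds, grp in cells.groupby("dataset"):
        n_guides = grp["guide"].nunique() if "guide" in grp.columns else grp["target"].nunique()
        weights[ds] = len(grp) / max(n_guides, 1)
    return weights


def pseudotime_shift_test(
    cells: pd.DataFrame, target: str, weights: Mapping[str, float] | None = None
) -> dict:
    """One-sided Mann-Whitney pseudotime shift for a knockout target.

    Per dataset, target cells are compared against all other single-guide
    cells in both directions; directions are combined across datasets by
    Stouffer with cells-per-guide weights, and the two-sided p doubles the
    smaller combined direction.
    """
    weights = dict(weights) if weights is not None else _dataset_weights(cells)
    p_greater, p_less, w, per_dataset = [], [], [], {}
    for ds, grp in cells.groupby("dataset"):
        pt_t = grp.loc[grp["target"] == target, "pseudotime"].to_numpy()
        pt_o = grp.loc[grp["target"] != target, "pseudotime"].to_numpy()
        if len(pt_t) == 0 or len(pt_o) == 0:
            continue
        pooled_pt = np.concatenate([pt_t, pt_o])
        if np.all(pooled_pt == pooled_pt[0]):
            pg = pl = 1.0          # every pseudotime tied: no shift testable
        else:
            pg = float(stats.mannwhitneyu(pt_t, pt_o, alternative="greater").pvalue)
            pl = float(stats.mannwhitneyu(pt_t, pt_o, alternative="less").pvalue)
        p_greater.append(pg)
        p_less.append(pl)
        w.append(weights[ds])
        per_dataset[ds] = {"p_greater": pg, "p_less": pl, "n_target": len(pt_t)}
    if not p_greater:
        raise ValueError(f"target {target} absent from all datasets")
    comb_g = stouffer_combine(p_greater, w)
    comb_l = stouffer_combine(p_less, w)
    return {"p_greater": comb_g, "p_less": comb_l,
            "p_two_sided": two_sided_from_directions(comb_g, comb_l),
            "per_dataset": per_dataset}


def pseudotime_window_enrichment(
    cells: pd.DataFrame,
    target: str,
    grid: int = 40,
    window: int = 10,
    clip: float = 4.0,
    min_cells: int = 20,
) -> dict:
    """Where along pseudotime are a target's knockout cells enriched?

    Per dataset, Gaussian KDEs (Scott's bandwidth) of all cells' and target
    cells' pseudotimes are evaluated at ``grid`` evenly spaced positions
    over the pooled range; a window of ``window`` consecutive positions is
    rolled along the axis and a one-sided Mann-Whitney test asks whether
    target densities exceed all-cell densities (enrichment only).
    Per-window p-values are combined across datasets by Stouffer weighted
    by target-cell count, reported as -log10 capped at ``clip``.
    """
    pooled = cells["pseudotime"].to_numpy()
    xs = np.linspace(pooled.min(), pooled.max(), grid)
    n_windows = grid - window + 1
    per_ds_p, ds_weights, used = [], [], []
    for ds, grp in cells.groupby("dataset"):
        pt_t = grp.loc[grp["target"] == target, "pseudotime"].to_numpy()
        if len(pt_t) < min_cells:
            logger.info("dataset %s skipped for %s: %d target cells < floor %d",
                        ds, target, len(pt_t), min_cells)
            continue
        kde_all = stats.gaussian_kde(grp["pseudotime"].to_numpy())
        kde_t = stats.gaussian_kde(pt_t)
        d_all = kde_all(xs)
        d_t = kde_t(xs)
        pvals = np.empty(n_windows)
        for i in range(n_windows):
            pvals[i] = stats.mannwhitneyu(
                d_t[i : i + window], d_all[i : i + window], alternative="greater"
            ).pvalue
        per_ds_p.append(pvals)
        ds_weights.append(float(len(pt_t)))
        used.append(ds)
    if not per_ds_p:
        raise ValueError(f"target {target} below the cell floor in every dataset")
    combined = np.array([
        stouffer_combine([p[i] for p in per_ds_p], ds_weights)
        for i in range(n_windows)
    ])
    neglog = np.minimum(-np.log10(np.maximum(combined, P_FLOOR)), clip)
    return {"positions": xs, "neglog10p": neglog, "datasets": used,
            "best_window": int(np.argmax(neglog))}


def residual_marker_test(
    cells: pd.DataFrame,
    marker: str,
    lowess_frac: float = 0.3,
    control_label: str = "control",
) -> pd.DataFrame:
    """Marker-expression effects per knockout, controlling for pseudotime.

    LOWESS of marker expression on pseudotime over all cells provides the
    expected expression at each cell's pseudotime; per target, a two-sample
    t-test compares residuals of target cells against all other cells, with
    BH correction across targets.  Constant expression yields p = 1.
    """
    pt = cells["pseudotime"].to_numpy()
    y = cells[marker].to_numpy(dtype=float)
    if np.std(y) == 0:
        fitted = y.copy()
    else:
        fitted = sm.nonparametric.lowess(
            y, pt, frac=lowess_frac, return_sorted=False)
    resid = y - fitted
    rows = []
    targets = [t for t in cells["target"].unique() if t != control_label]
    for t in sorted(targets):
        mask = (cells["target"] == t).to_numpy()
        r_t, r_o = resid[mask], resid[~mask]
        if len(r_t) < 2 or np.std(resid) == 0:
            p = 1.0
            delta = 0.0 if np.std(resid) == 0 else float(np.mean(r_t) - np.mean(r_o))
        else:
            res = stats.ttest_ind(r_t, r_o)
            p = 1.0 if math.isnan(res.pvalue) else float(res.pvalue)
            delta = float(np.mean(r_t) - np.mean(r_o))
        rows.append({"target": t, "n_cells": int(mask.sum()),
                     "mean_residual_delta": delta, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        from .asb_core import bh_adjust

        out["q"] = bh_adjust(out["p"])
    return out
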