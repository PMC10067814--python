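"""Shared statistical machinery: Benjamini-Hochberg correction and the
one-sample t-test cutoff grid used for both barcode and window RELs.

The grid test asks, for each item with a small vector of replicate REL
estimates and for each cutoff c in {0.1, 0.2, ..., 1.0}, whether the REL
differs from c (two-sided one-sample t-test), corrects across items per
cutoff at FDR 0.05, and calls the item "significantly higher than c"
when the corrected test rejects and the mean REL exceeds c.  An item's
bin is the interval (c, c+0.1] for the highest cutoff it significantly
exceeds; items exceeding no cutoff fall in the lowest bin and items
exceeding the top cutoff in an open top bin.

Degenerate zero-variance vectors (all replicate estimates identical —
typically all-zero counts) are resolved by exact comparison to the
cutoff rather than NaN propagation, and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))

#: Label of the bin for items exceeding no cutoff.
NONSIG_BIN = "0.0-0.1"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bin_label(cutoff: float, cutoffs=DEFAULT_CUTOFFS) -> str:
    top = max(cutoffs)
    if cutoff >= top:
        return f"{top:.1f}+"
    return f"{cutoff:.1f}-{cutoff + 0.1:.1f}"


def bin_order(cutoffs=DEFAULT_CUTOFFS):
    """All bin labels from lowest (no cutoff exceeded) to highest."""
    return [NONSIG_BIN] + [bin_label(c, cutoffs) for c in cutoffs]


def one_sample_t_matrix(values: np.ndarray, popmean: float):
    """Row-wise two-sided one-sample t-test p-values, NaN-aware.

    ``values`` is (n_items, n_estimates).  Rows with zero variance get
    an exact-comparison p (0 when the common value differs from
    ``popmean``, 1 when equal); rows with fewer than two finite
    estimates get NaN.
    """
    v = np.asarray(values, dtype=float)
    n = np.sum(np.isfinite(v), axis=1)
    mean = np.nanmean(np.where(np.isfinite(v), v, np.nan), axis=1)
    sd = np.nanstd(np.where(np.isfinite(v), v, np.nan), axis=1, ddof=1)
    p = np.full(v.shape[0], np.nan)
    degenerate = (sd == 0) & (n >= 2)
    if degenerate.any():
        logger.info(
            "%d zero-variance estimate vectors resolved by exact comparison",
            int(degenerate.sum()),
        )
        p[degenerate] = np.where(mean[degenerate] == popmean, 1.0, 0.0)
    ok = (sd > 0) & (n >= 2)
    if ok.any():
        t = (mean[ok] - popmean) / (sd[ok] / np.sqrt(n[ok]))
        p[ok] = 2.0 * sps.t.sf(np.abs(t), df=n[ok] - 1)
    return p, mean


def cutoff_grid_tests(
    rel_estimates,
    cutoffs=DEFAULT_CUTOFFS,
    fdr: float = 0.05,
    index=None,
) -> pd.DataFrame:
    """Run the REL cutoff grid on a matrix of replicate REL estimates.

    Parameters
    ----------
    rel_estimates
        (n_items, n_estimates) array or DataFrame; each row is one
        barcode's or window's replicate REL estimates (NaN allowed for
        excluded estimates).
    cutoffs
        Increasing REL cutoffs; BH correction is applied per cutoff
        across items (the test family is one cutoff).
    fdr
        Benjamini-Hochberg false discovery rate.

    Returns
    -------
    DataFrame indexed by item with columns ``mean_rel``, per-cutoff
    ``p_<c>``, ``q_<c>``, ``exceeds_<c>`` and the final ``bin`` label.
    """
    if isinstance(rel_estimates, pd.DataFrame):
        if index is None:
            index = rel_estimates.index
        rel_estimates = rel_estimates.to_numpy()
    v = np.asarray(rel_estimates, dtype=float)
    if v.ndim != 2:
        raise ValueError("rel_estimates must be 2-dimensional")
    cutoffs = [float(c) for c in cutoffs]
    if sorted(cutoffs) != cutoffs:
        raise ValueError("cutoffs must be increasing")
    out = {}
    exceed_cols = []
    mean = None
    for c in cutoffs:
        p, mean = one_sample_t_matrix(v, c)
        q = np.full_like(p, np.nan)
        finite = np.isfinite(p)
        if finite.any():
            q[finite] = bh_adjust(p[finite])
        exceeds = finite & (q <= fdr) & (mean > c)
        out[f"p_{c:.1f}"] = p
        out[f"q_{c:.1f}"] = q
        out[f"exceeds_{c:.1f}"] = exceeds
        exceed_cols.append(exceeds)
    exceed = np.column_stack(exceed_cols)
    # bin = (c, c+0.1] for the highest exceeded cutoff
    bins = np.full(v.shape[0], NONSIG_BIN, dtype=object)
    any_exceed = exceed.any(axis=1)
    highest = np.where(any_exceed, exceed.shape[1] - 1 - np.argmax(exceed[:, ::-1], axis=1), -1)
    for i in np.nonzero(any_exceed)[0]:
        bins[i] = bin_label(cutoffs[highest[i]], cutoffs)
    df = pd.DataFrame(out, index=index)
    df.insert(0, "mean_rel", mean)
    df["bin"] = bins
    return df


def exceedance_curve(grid: pd.DataFrame, cutoffs=DEFAULT_CUTOFFS) -> pd.Series:
    """Fraction of items significantly exceeding each cutoff."""
    fracs = {
        float(c): float(grid[f"exceeds_{float(c):.1f}"].mean()) for c in cutoffs
    }
    return pd.Series(fracs, name="fraction_exceeding").rename_axis("cutoff")


def bin_fractions(grid: pd.DataFrame, cutoffs=DEFAULT_CUTOFFS) -> pd.Series:
    """Fraction of items per REL bin, in bin order (sums to 1)."""
    order = bin_order(cutoffs)
    counts = grid["bin"].value_counts()
    return pd.Series(
        [counts.get(b, 0) / len(grid) for b in order], index=order, name="fraction"
    ).rename_axis("bin")
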