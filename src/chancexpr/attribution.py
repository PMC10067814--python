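"""Attribution of intergenic expression to chance promoter activity.

Three decision layers:

* **Per-bin attribution** compares the REL-bin occupancy of intergenic
  windows (W_b) with that of random-promoter barcodes (B_b): within a
  bin, the attributable fraction is min(W_b, B_b)/W_b and the
  unattributable mass is max(0, W_b - B_b); summed over exceedance
  bins this gives the fraction of windows whose expression chance
  promoter activity cannot account for.

* **The iterative neighbor filter** removes windows whose expression
  likely leaks from highly expressed neighboring genes: windows above
  the REL threshold are ranked by neighbor expression and split into 50
  equal groups; the top group is removed repeatedly until the median
  neighbor expression of the remainder (ME1) is no longer unusually
  high relative to medians of equally sized random window samples (ME2,
  1000 resamples) — i.e. until fraction(ME2 >= ME1) exceeds 0.05.

* **The region-level Monte-Carlo test** asks whether a region's summary
  expression E_obs (max or 95th percentile of its window RELs) exceeds
  what N = ceil(L/120) random promoters could produce: each of the
  (default 100,000) replicates draws N promoters from the measured
  activity library and takes their maximum; the nominal P is the
  fraction of draws strictly exceeding E_obs, BH-corrected across
  regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as cstats

logger = logging.getLogger(__name__)


def attribution_by_bin(window_bins: pd.Series, barcode_bins: pd.Series):
    """Per-bin attributable fractions and the total unattributable mass.

    Both inputs are per-bin fractions (as from
    :func:`chancexpr.stats.bin_fractions`) computed on the same cutoff
    grid; mismatched grids are rejected.  The lowest bin (no cutoff
    significantly exceeded) is attributable by definition — expression
    indistinguishable from the lowest cutoff needs no promoter at all —
    so the unattributable total runs over the exceedance bins.

    Returns ``(bins DataFrame, total_unattributable)``.
    """
    if list(window_bins.index) != list(barcode_bins.index):
        raise ValueError("window and barcode bins use different cutoff grids")
    rows = []
    total = 0.0
    for b in window_bins.index:
        w, k = float(window_bins[b]), float(barcode_bins[b])
        if b == cstats.NONSIG_BIN:
            attr, unattr = 1.0, 0.0
        else:
            attr = 1.0 if w == 0 else min(w, k) / w
            unattr = max(0.0, w - k)
            total += unattr
        rows.append((b, w, k, attr, unattr))
    df = pd.DataFrame(
        rows, columns=["bin", "window_fraction", "barcode_fraction",
                       "attributable_fraction", "unattributable_mass"]
    )
    return df, total


@dataclass
class NeighborFilterState:
    """Trace of the iterative neighbor filter."""

    trace: pd.DataFrame  # iteration, n_remaining, me1, frac_me2_ge_me1
    removed_groups: int = 0
    retained_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def neighbor_filter(
    neighbor_expr_selected,
    neighbor_expr_all,
    n_groups: int = 50,
    n_resamples: int = 1000,
    stop_cutoff: float = 0.05,
    seed=None,
) -> NeighborFilterState:
    """Iteratively strip the windows most exposed to neighboring genes.

    ``neighbor_expr_selected`` holds the neighbor expression of the
    windows above the REL threshold; ``neighbor_expr_all`` the neighbor
    expression of *all* intergenic windows (the resampling pool).
    Groups are removed from the top of the neighbor-expression ordering
    until fraction(ME2 >= ME1) > ``stop_cutoff``.

    ``retained_index`` indexes into the *selected* input.
    """
    sel = np.asarray(neighbor_expr_selected, dtype=float)
    pool = np.asarray(neighbor_expr_all, dtype=float)
    if sel.size == 0:
        raise ValueError("no windows above threshold to filter")
    if pool.size < sel.size:
        raise ValueError("resampling pool smaller than the selected set")
    if n_groups > sel.size:
        logger.warning("neighbor_filter: fewer windows than groups; using size-1 groups")
        n_groups = sel.size
    rng = np.random.default_rng(seed)
    order = np.argsort(-sel, kind="mergesort")  # decreasing neighbor expression
    groups = np.array_split(order, n_groups)
    rows = []
    for removed in range(n_groups):
        remaining = np.concatenate(groups[removed:])
        me1 = float(np.median(sel[remaining]))
        k = remaining.size
        me2 = np.empty(n_resamples)
        for t in range(n_resamples):
            me2[t] = np.median(rng.choice(pool, size=k, replace=False))
        frac = float(np.mean(me2 >= me1))
        rows.append((removed, k, me1, frac))
        if frac > stop_cutoff:
            return NeighborFilterState(
                trace=pd.DataFrame(rows, columns=["iteration", "n_remaining", "me1", "frac_me2_ge_me1"]),
                removed_groups=removed,
                retained_index=np.sort(remaining),
            )
    logger.warning("neighbor_filter: stop criterion never met; all groups removed")
    return NeighborFilterState(
        trace=pd.DataFrame(rows, columns=["iteration", "n_remaining", "me1", "frac_me2_ge_me1"]),
        removed_groups=n_groups,
        retained_index=np.array([], dtype=int),
    )


def region_chance_test(
    window_rels: pd.DataFrame,
    n_segments,
    library,
    summary: str = "max",
    n_reps: int = 100_000,
    fdr: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """Monte-Carlo test of each region against chance promoter sampling.

    Parameters
    ----------
    window_rels
        Long-form window REL point estimates with columns ``region_id``,
        ``rel`` and optionally ``direction`` (each (region, direction)
        is then tested separately).
    n_segments
        Mapping region_id -> N = ceil(L/120).
    library
        Measured promoter activity sample (REL scale) to draw from,
        with replacement.
    summary
        ``"max"`` or ``"p95"`` — the window summary used as E_obs.

    Returns one row per tested unit with the nominal Monte-Carlo P
    (strict exceedance), BH q and the unexplainable flag (q < fdr).
    """
    lib = np.asarray(library, dtype=float)
    if lib.size == 0:
        raise ValueError("empty promoter activity library")
    if summary not in ("max", "p95"):
        raise ValueError("summary must be 'max' or 'p95'")
    rng = np.random.default_rng(seed)
    keys = ["region_id"] + (["direction"] if "direction" in window_rels.columns else [])
    rows = []
    for key, sub in window_rels.groupby(keys, observed=True, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        region_id = key[0]
        rels = sub["rel"].to_numpy(dtype=float)
        if rels.size == 0:
            logger.info("region %s skipped: no windows", region_id)
            continue
        e_obs = float(np.max(rels)) if summary == "max" else float(np.percentile(rels, 95))
        N = int(n_segments[region_id])
        draws = lib[rng.integers(0, lib.size, size=(n_reps, N))]
        e_sampled = draws.max(axis=1)
        p = float(np.mean(e_sampled > e_obs))
        rows.append((*key, e_obs, N, p))
    out = pd.DataFrame(rows, columns=[*keys, "e_obs", "n_segments", "p"])
    out["q"] = cstats.bh_adjust(out["p"]) if len(out) else []
    out["unexplainable"] = out["q"] < fdr
    return out


def shared_fraction(grid_a: pd.DataFrame, grid_b: pd.DataFrame, cutoffs=cstats.DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Environment-sharing of significance calls across the cutoff grid.

    For items significantly exceeding a cutoff in one environment, the
    shared fraction is the proportion also exceeding it in the other.
    Both grids must cover the same item universe.  An empty denominator
    set yields NaN (undefined), reported as such.
    """
    if not grid_a.index.sort_values().equals(grid_b.index.sort_values()):
        raise ValueError("the two environments cover different item universes")
    b = grid_b.reindex(grid_a.index)
    rows = []
    for c in cutoffs:
        col = f"exceeds_{float(c):.1f}"
        ea = grid_a[col].to_numpy(dtype=bool)
        eb = b[col].to_numpy(dtype=bool)
        both = ea & eb
        rows.append(
            (
                float(c), int(ea.sum()), int(eb.sum()),
                both.sum() / ea.sum() if ea.sum() else np.nan,
                both.sum() / eb.sum() if eb.sum() else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["cutoff", "n_exceed_a", "n_exceed_b", "shared_a_to_b", "shared_b_to_a"]
    )


def group_difference_check(neighbor_unexplainable, neighbor_rest) -> dict:
    """One-sided Wilcoxon rank-sum: are neighbor expressions of
    unexplainable regions greater than those of the rest?"""
    x = np.asarray(list(neighbor_unexplainable), dtype=float)
    y = np.asarray(list(neighbor_rest), dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        return {"p": None, "n_unexplainable": int(x.size), "n_rest": int(y.size),
                "reason": "empty group"}
    res = sps.mannwhitneyu(x, y, alternative="greater", method="auto")
    return {"p": float(res.pvalue), "n_unexplainable": int(x.size), "n_rest": int(y.size)}
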