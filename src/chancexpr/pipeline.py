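"""Convenience wiring of the pipeline stages.

These helpers connect the per-module operations into the two arms of
the analysis — the barcode (reporter) arm and the intergenic-landscape
arm — exactly as the numbered analysis drivers run them.  They contain
no logic of their own beyond plumbing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assembly, attribution, landscape, quant
from . import stats as cstats


def quantify_environment(
    reads: pd.DataFrame,
    positive_barcodes,
    negative_barcodes,
    s: float,
    min_dna_reads: int = 100,
    fdr: float = 0.05,
    cutoffs=cstats.DEFAULT_CUTOFFS,
) -> dict:
    """Barcode quantification for one environment's reads.

    UMI collapse -> depth filter -> E estimates -> activity calls
    against the negative control -> REL profile and cutoff grid.
    """
    table = quant.CountTable.from_reads(reads)
    kept = assembly.filter_by_dna_depth(table.counts, min_reads=min_dna_reads)
    E = quant.estimate_expression(table)["E"]
    E = E.loc[E.index.isin(kept)].dropna()
    pos = [b for b in positive_barcodes if b in E.index]
    neg_E = E.loc[[b for b in negative_barcodes if b in E.index]].to_numpy()
    active = quant.call_active(E, neg_E, fdr=fdr)
    rels = quant.compute_rel(E, pos, s)
    controls = set(positive_barcodes) | set(negative_barcodes)
    rels = rels.loc[[b for b in rels.index if b not in controls]]
    grid, curve, bins = quant.rel_significance_profile(rels, cutoffs=cutoffs, fdr=fdr)
    rel_point = rels.mean(axis=1)
    return {
        "count_table": table,
        "E": E,
        "active": active,
        "rels": rels,
        "rel_point": rel_point,
        "grid": grid,
        "curve": curve,
        "bins": bins,
    }


def barcode_arm(reads: pd.DataFrame, truth, s: float, **kw) -> dict:
    """Run :func:`quantify_environment` for every environment in a
    generated read table, keyed by environment."""
    out = {}
    for env, sub in reads.groupby("environment", observed=True):
        out[env] = quantify_environment(
            sub[["barcode", "replicate", "molecule", "umi"]],
            truth.positive_barcodes, truth.negative_barcodes, s, **kw
        )
    return out


def landscape_arm(sim, cutoffs=cstats.DEFAULT_CUTOFFS, fdr: float = 0.05) -> dict:
    """Quantify a generated landscape: regions, window RPM/REL grids,
    per-window REL point estimates and neighbor expressions."""
    regions = landscape.build_intergenic_regions(
        sim.annotation, utr_ext=sim.design.utr_ext, rna_ext=sim.design.rna_ext
    )
    wexp = landscape.window_expression(sim.window_counts, sim.totals)
    gene_expr, reference = landscape.gene_expression_and_reference(
        sim.gene_window_counts, sim.totals
    )
    grids = landscape.window_rel_tests(wexp, reference, cutoffs=cutoffs, fdr=fdr)
    rel = wexp.merge(reference, on=["environment", "replicate"])
    rel["rel"] = rel["rpm"] / rel["reference"]
    point = (
        rel.groupby(["environment", "region_id", "window_index", "strand"], observed=True)["rel"]
        .mean()
        .rename("rel")
        .reset_index()
    )
    gene_mean = (
        gene_expr.groupby(["gene_id", "environment"], observed=True)["expr"].mean()
    )
    gene_strand = {g.gene_id: g.strand for g in sim.annotation.genes}
    neighbors = {
        env: landscape.neighbor_expression_table(
            regions, gene_mean.xs(env, level="environment").to_dict(), gene_strand
        )
        for env in sim.totals["environment"].unique()
    }
    return {
        "regions": regions,
        "n_segments": {r.region_id: r.n_segments for r in regions},
        "window_expression": wexp,
        "gene_expression": gene_expr,
        "reference": reference,
        "grids": grids,
        "rel_point": point,
        "neighbors": neighbors,
    }


def region_tests(
    arm: dict, library, environment: str, summary: str = "max",
    n_reps: int = 100_000, fdr: float = 0.05, seed=None,
) -> pd.DataFrame:
    """Region-level chance test for one environment, per transcriptional
    direction (the window strand)."""
    point = arm["rel_point"]
    sub = point[point["environment"] == environment].rename(columns={"strand": "direction"})
    return attribution.region_chance_test(
        sub[["region_id", "direction", "rel"]], arm["n_segments"], library,
        summary=summary, n_reps=n_reps, fdr=fdr, seed=seed,
    )


def align_universe(grid_a: pd.DataFrame, grid_b: pd.DataFrame):
    """Restrict two significance grids to their common item universe
    (items passing filters in both environments)."""
    common = grid_a.index.intersection(grid_b.index)
    return grid_a.loc[common], grid_b.loc[common]


def slope_sign_test(shared: pd.DataFrame, min_n: int = 10) -> dict:
    """One-sided sign test for a decreasing shared-fraction trend.

    Slopes from both sharing directions of a
    :func:`chancexpr.attribution.shared_fraction` table are pooled;
    cutoffs whose denominator set holds fewer than ``min_n`` items are
    masked first (a fraction over a handful of items is granularity,
    not signal), and zero slopes are dropped.  The binomial test asks
    whether negative slopes dominate.
    """
    from scipy.stats import binomtest

    pieces = []
    for frac_col, n_col in (
        ("shared_a_to_b", "n_exceed_a"),
        ("shared_b_to_a", "n_exceed_b"),
    ):
        vals = shared[frac_col].where(shared[n_col] >= min_n).to_numpy(dtype=float)
        pieces.append(np.diff(vals))
    slopes = np.concatenate(pieces)
    slopes = slopes[np.isfinite(slopes) & (slopes != 0)]
    n_neg = int((slopes < 0).sum())
    n = len(slopes)
    p = binomtest(n_neg, n, 0.5, alternative="greater").pvalue if n else np.nan
    return {"n_slopes": n, "n_negative": n_neg, "p": float(p) if n else np.nan}
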