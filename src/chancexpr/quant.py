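"""Expression quantification from UMI-tagged barcode reads.

The estimator follows the normalized-read-count (NRC) scheme: reads
sharing a UMI collapse to one molecule; each barcode's molecule count is
divided by the sample total to give its NRC; per-replicate NRCs are
summed into the total NRC (TNRC); and a barcode's expression level is

    E_i = TNRC_i^cDNA / TNRC_i^DNA.

Relative expression levels (REL) place barcodes on the native-gene
scale: eight positive-control barcodes j give eight estimates
REL_ij = (E_i / E_j) * s, where s is the positive-control gene's
expression relative to the median of all native genes (an external
RNA-seq-derived scalar supplied by the caller).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as cstats

logger = logging.getLogger(__name__)

SAMPLE_KEYS = ("replicate", "molecule")


def collapse_umis(reads: pd.DataFrame) -> pd.DataFrame:
    """Count distinct UMIs per (barcode, replicate, molecule).

    Reads sharing a UMI within a sample/barcode are PCR duplicates of
    one molecule and count once.  Returns a long-form count table.
    """
    keys = ["barcode", *SAMPLE_KEYS]
    counts = (
        reads.groupby(keys, observed=True)["umi"].nunique().rename("count").reset_index()
    )
    return counts


@dataclass
class CountTable:
    """UMI-collapsed counts plus per-sample totals.

    ``counts`` is long-form (barcode, replicate, molecule, count);
    ``totals`` maps each (replicate, molecule) sample to its total
    molecule count over all observed barcodes.
    """

    counts: pd.DataFrame
    totals: pd.Series

    @classmethod
    def from_reads(cls, reads: pd.DataFrame) -> "CountTable":
        return cls.from_counts(collapse_umis(reads))

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CountTable":
        if (counts["count"] < 0).any():
            raise ValueError("negative counts")
        totals = counts.groupby(list(SAMPLE_KEYS), observed=True)["count"].sum()
        return cls(counts=counts.copy(), totals=totals)

    def nrc(self) -> pd.DataFrame:
        """Counts with a ``nrc`` column: count / sample total."""
        out = self.counts.merge(
            self.totals.rename("total").reset_index(), on=list(SAMPLE_KEYS)
        )
        out["nrc"] = out["count"] / out["total"]
        return out

    def tnrc(self) -> pd.DataFrame:
        """Total NRC per (barcode, molecule): per-replicate NRCs summed."""
        nrc = self.nrc()
        return (
            nrc.groupby(["barcode", "molecule"], observed=True)["nrc"]
            .sum()
            .rename("tnrc")
            .reset_index()
        )


def estimate_expression(table: CountTable) -> pd.DataFrame:
    """Per-barcode expression E = TNRC^cDNA / TNRC^DNA plus per-replicate
    NRC-ratio variants.

    Barcodes with zero DNA TNRC cannot be quantified and are flagged
    ``usable=False`` (E is NaN) rather than silently zero.
    """
    tnrc = table.tnrc().pivot(index="barcode", columns="molecule", values="tnrc")
    for mol in ("DNA", "cDNA"):
        if mol not in tnrc.columns:
            tnrc[mol] = 0.0
    tnrc = tnrc.fillna(0.0)
    usable = tnrc["DNA"] > 0
    if (~usable).any():
        logger.warning(
            "estimate_expression: %d barcodes with zero DNA TNRC flagged unusable",
            int((~usable).sum()),
        )
    E = np.where(usable, tnrc["cDNA"] / tnrc["DNA"].where(usable), np.nan)
    out = pd.DataFrame({"E": E, "usable": usable}, index=tnrc.index)

    nrc = table.nrc().pivot_table(
        index="barcode", columns=["molecule", "replicate"], values="nrc",
        fill_value=0.0, observed=True,
    )
    if "DNA" in nrc.columns.get_level_values(0):
        for rep in nrc["DNA"].columns:
            dna = nrc[("DNA", rep)]
            cdna = (
                nrc[("cDNA", rep)]
                if ("cDNA", rep) in nrc.columns
                else pd.Series(0.0, index=nrc.index)
            )
            out[f"E_rep{rep}"] = np.where(dna > 0, cdna / dna.where(dna > 0), np.nan)
    return out.rename_axis("barcode")


def compute_rel(
    E: pd.Series, positive_control_barcodes, s: float
) -> pd.DataFrame:
    """REL estimates: one column per positive-control barcode j with
    REL_ij = (E_i / E_j) * s.

    Control barcodes with E_j = 0 (or missing) cannot normalise and are
    excluded with a warning; if none remain the call fails.
    """
    controls = list(positive_control_barcodes)
    if len(controls) < 2:
        raise ValueError("need at least two positive-control barcodes")
    cols = {}
    for j, bc in enumerate(controls, start=1):
        ej = E.get(bc, np.nan)
        if not np.isfinite(ej) or ej == 0:
            logger.warning("compute_rel: control barcode %s has E=0/NaN; excluded", bc)
            continue
        cols[f"rel_{j}"] = (E / ej) * s
    if not cols:
        raise ValueError("all positive-control barcodes have zero expression")
    return pd.DataFrame(cols, index=E.index).rename_axis("barcode")


def call_active(
    E: pd.Series, negative_control_estimates, fdr: float = 0.05
) -> pd.DataFrame:
    """Test each barcode's E against the negative-control distribution.

    One-sample t-test of the negative-control E values against E_i as
    the reference value, BH-corrected across barcodes; a barcode is
    active when the corrected test rejects *and* E_i exceeds the
    negative-control mean.
    """
    neg = np.asarray(list(negative_control_estimates), dtype=float)
    neg = neg[np.isfinite(neg)]
    if neg.size < 2:
        raise ValueError("need at least two negative-control estimates")
    e = E.to_numpy(dtype=float)
    # t-test of (neg - E_i) against zero, row per barcode
    diffs = neg[None, :] - e[:, None]
    p, _ = cstats.one_sample_t_matrix(diffs, 0.0)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q[ok] = cstats.bh_adjust(p[ok])
    active = ok & (q <= fdr) & (e > neg.mean())
    return pd.DataFrame(
        {"E": e, "p": p, "q": q, "active": active}, index=E.index
    ).rename_axis("barcode")


def rel_significance_profile(
    rel_estimates: pd.DataFrame,
    cutoffs=cstats.DEFAULT_CUTOFFS,
    fdr: float = 0.05,
):
    """Cutoff-grid significance of barcode RELs.

    ``rel_estimates`` holds one row per barcode and one column per
    positive-control-derived REL estimate.  Returns ``(grid, curve,
    bins)``: the per-barcode grid results with bin labels, the
    fraction-exceeding curve over cutoffs, and per-bin fractions.
    """
    grid = cstats.cutoff_grid_tests(rel_estimates, cutoffs=cutoffs, fdr=fdr)
    curve = cstats.exceedance_curve(grid, cutoffs)
    bins = cstats.bin_fractions(grid, cutoffs)
    return grid, curve, bins
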