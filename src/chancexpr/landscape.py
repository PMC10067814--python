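"""Intergenic regions, 20-nt windows and strand-specific expression.

Intergenic regions are the genome minus every gene's UTR-extended
footprint and minus excluded features (centromeres, telomeres, LTRs,
LTR retrotransposons).  Protein-coding genes with annotated UTRs are
extended 200 nt outward from each UTR end; genes without annotated UTRs
get 200 nt allocated outward from each end of the coding sequence; RNA
genes get 50 nt per end.  Each region is tiled into non-overlapping
20-nt windows starting from its lower coordinate, dropping a short
terminal remainder, and window expression is reads-per-million,
strand-specifically.

Coordinates are 1-based inclusive throughout (GFF3 convention); BED
output converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as cstats

logger = logging.getLogger(__name__)

RNA_TYPES = {"rRNA", "tRNA", "snRNA", "snoRNA", "ncRNA"}
EXCLUDED_TYPES = {"centromere", "telomere", "long_terminal_repeat", "LTR_retrotransposon"}

UTR_EXTENSION = 200
RNA_EXTENSION = 50
WINDOW_SIZE = 20
SEGMENT_SIZE = 120  # promoter-equivalent segment length for the chance null


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # CDS / gene body span, 1-based inclusive
    end: int
    gtype: str = "protein_coding"
    utr5: Optional[tuple] = None
    utr3: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"degenerate gene span for {self.gene_id}")


@dataclass
class ExcludedFeature:
    chrom: str
    start: int
    end: int
    ftype: str


@dataclass
class GenomeAnnotation:
    genes: list = field(default_factory=list)
    excluded: list = field(default_factory=list)
    chrom_lengths: dict = field(default_factory=dict)

    def validate(self) -> None:
        for g in self.genes:
            L = self.chrom_lengths.get(g.chrom)
            if L is None or g.start < 1 or g.end > L:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")


@dataclass
class IntergenicRegion:
    """A maximal interval free of extended genic and excluded features."""

    region_id: str
    chrom: str
    start: int
    end: int
    left_gene: Optional[str] = None
    right_gene: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_segments(self) -> int:
        """N = ceil(L / 120): non-overlapping promoter-sized segments."""
        return -(-self.length // SEGMENT_SIZE)


def extended_footprint(
    gene: Gene, utr_ext: int = UTR_EXTENSION, rna_ext: int = RNA_EXTENSION
):
    """The genomic interval a gene masks out of the intergenic space."""
    if gene.gtype != "protein_coding":
        return gene.start - rna_ext, gene.end + rna_ext
    lo, hi = gene.start, gene.end
    for utr in (gene.utr5, gene.utr3):
        if utr is not None:
            lo = min(lo, utr[0])
            hi = max(hi, utr[1])
    return lo - utr_ext, hi + utr_ext


def merge_intervals(intervals):
    """Merge overlapping or adjacent 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(iv) for iv in merged]


def build_intergenic_regions(
    annotation: GenomeAnnotation,
    utr_ext: int = UTR_EXTENSION,
    rna_ext: int = RNA_EXTENSION,
):
    """Complement of extended genic plus excluded features, per chromosome,
    with nearest-gene neighbor assignment on each side."""
    annotation.validate()
    regions = []
    genes_by_chrom: dict[str, list] = {}
    for g in annotation.genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    excl_by_chrom: dict[str, list] = {}
    for f in annotation.excluded:
        excl_by_chrom.setdefault(f.chrom, []).append(f)
    for chrom, clen in annotation.chrom_lengths.items():
        masks = []
        foots = []
        for g in genes_by_chrom.get(chrom, []):
            lo, hi = extended_footprint(g, utr_ext, rna_ext)
            lo, hi = max(1, lo), min(clen, hi)
            foots.append((g.gene_id, lo, hi))
            masks.append((lo, hi))
        for f in excl_by_chrom.get(chrom, []):
            masks.append((max(1, f.start), min(clen, f.end)))
        merged = merge_intervals(masks)
        # complement within [1, clen]
        free = []
        cursor = 1
        for lo, hi in merged:
            if lo > cursor:
                free.append((cursor, lo - 1))
            cursor = max(cursor, hi + 1)
        if cursor <= clen:
            free.append((cursor, clen))
        if not free:
            logger.info("chromosome %s fully masked; no intergenic regions", chrom)
        ends = sorted(foots, key=lambda t: t[2])
        starts = sorted(foots, key=lambda t: t[1])
        for lo, hi in free:
            left = None
            for gid, _, fhi in reversed(ends):
                if fhi < lo:
                    left = gid
                    break
            right = None
            for gid, flo, _ in starts:
                if flo > hi:
                    right = gid
                    break
            regions.append(
                IntergenicRegion(
                    region_id=f"{chrom}:{lo}-{hi}",
                    chrom=chrom, start=lo, end=hi,
                    left_gene=left, right_gene=right,
                )
            )
    return regions


def tile_windows(region: IntergenicRegion) -> pd.DataFrame:
    """Non-overlapping 20-nt windows from the region's lower coordinate;
    a terminal remainder shorter than 20 nt is discarded."""
    n = region.length // WINDOW_SIZE
    starts = region.start + WINDOW_SIZE * np.arange(n)
    return pd.DataFrame(
        {
            "region_id": region.region_id,
            "window_index": np.arange(n),
            "start": starts,
            "end": starts + WINDOW_SIZE - 1,
        }
    )


def tile_all_windows(regions) -> pd.DataFrame:
    frames = [tile_windows(r) for r in regions]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["region_id", "window_index", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def rpm(counts, totals):
    """Reads-per-million: count / (sample total / 1e6)."""
    return np.asarray(counts, dtype=float) / (np.asarray(totals, dtype=float) / 1e6)


def window_expression(counts: pd.DataFrame, totals: pd.DataFrame) -> pd.DataFrame:
    """Attach strand-specific RPM to a long window count table.

    ``counts``: region_id, window_index, strand, environment, replicate,
    count.  ``totals``: environment, replicate, total.
    """
    if (counts["count"] < 0).any():
        raise ValueError("negative window counts")
    if (totals["total"] <= 0).any():
        raise ValueError("sample totals must be positive")
    out = counts.merge(totals, on=["environment", "replicate"], how="left")
    if out["total"].isna().any():
        raise ValueError("missing total for some (environment, replicate)")
    out["rpm"] = rpm(out["count"], out["total"])
    return out


def gene_expression_and_reference(gene_window_counts: pd.DataFrame, totals: pd.DataFrame):
    """Per-gene expression and the native-gene reference level.

    A gene's expression in a sample is the mean RPM of its sense-strand
    windows; the reference for each (environment, replicate) is the
    median over all genes.  Returns ``(gene_expr, reference)`` where
    ``gene_expr`` has columns gene_id, environment, replicate, expr and
    ``reference`` has environment, replicate, reference.
    """
    ge = window_expression(
        gene_window_counts.rename(columns={"gene_id": "region_id"}), totals
    ).rename(columns={"region_id": "gene_id"})
    gene_expr = (
        ge.groupby(["gene_id", "environment", "replicate"], observed=True)["rpm"]
        .mean()
        .rename("expr")
        .reset_index()
    )
    reference = (
        gene_expr.groupby(["environment", "replicate"], observed=True)["expr"]
        .median()
        .rename("reference")
        .reset_index()
    )
    return gene_expr, reference


def window_rel_tests(
    window_rpm: pd.DataFrame,
    reference: pd.DataFrame,
    cutoffs=cstats.DEFAULT_CUTOFFS,
    fdr: float = 0.05,
) -> dict:
    """Cutoff-grid REL tests for every (window, strand), per environment.

    Per-replicate REL = window RPM / reference RPM of the same
    (environment, replicate); the grid engine then tests each cutoff
    with BH across windows.  Returns a dict environment -> grid
    DataFrame indexed by (region_id, window_index, strand).
    """
    df = window_rpm.merge(reference, on=["environment", "replicate"], how="left")
    if df["reference"].isna().any() or (df["reference"] <= 0).any():
        raise ValueError("invalid reference level")
    df["rel"] = df["rpm"] / df["reference"]
    out = {}
    for env, sub in df.groupby("environment", observed=True):
        mat = sub.pivot_table(
            index=["region_id", "window_index", "strand"],
            columns="replicate", values="rel", observed=True,
        )
        out[env] = cstats.cutoff_grid_tests(mat, cutoffs=cutoffs, fdr=fdr)
    return out


def neighbor_expression(
    region: IntergenicRegion,
    gene_expr: dict,
    gene_strand: dict,
    direction: str,
) -> dict:
    """Three neighbor-expression summaries for one transcriptional direction.

    1. mean of the two flanking genes' expressions;
    2. expression of the upstream neighbor for this direction
       (the left gene for '+', the right gene for '-');
    3. readthrough level: the upstream neighbor's expression if it is
       transcribed in the same direction, else 0.

    A missing neighbor makes the affected variant NaN (undefined), not 0.
    """
    left = gene_expr.get(region.left_gene) if region.left_gene else None
    right = gene_expr.get(region.right_gene) if region.right_gene else None
    mean_both = np.nan if left is None or right is None else (left + right) / 2.0
    up_gene = region.left_gene if direction == "+" else region.right_gene
    up = gene_expr.get(up_gene) if up_gene else None
    if up is None:
        upstream = np.nan
        readthrough = np.nan
    else:
        upstream = up
        readthrough = up if gene_strand.get(up_gene) == direction else 0.0
    return {"mean_both": mean_both, "upstream": upstream, "readthrough": readthrough}


def neighbor_expression_table(regions, gene_expr: dict, gene_strand: dict) -> pd.DataFrame:
    rows = []
    for r in regions:
        for direction in ("+", "-"):
            v = neighbor_expression(r, gene_expr, gene_strand, direction)
            rows.append((r.region_id, direction, v["mean_both"], v["upstream"], v["readthrough"]))
    return pd.DataFrame(
        rows, columns=["region_id", "direction", "mean_both", "upstream", "readthrough"]
    )


def regions_to_bed(regions) -> pd.DataFrame:
    """Regions as a BED-style frame (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.end for r in regions],
            "name": [r.region_id for r in regions],
        }
    )
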