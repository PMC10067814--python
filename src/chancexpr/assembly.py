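"""Library reconstruction from promoter-barcode linkage reads.

Barcodes and promoters are clustered separately by greedy Hamming-
distance clustering (tolerance two mismatches for 20-nt barcodes, six
for 120-nt promoters — distinct random sequences differ at far more
sites, so the tolerance absorbs sequencing errors without merging
genuine library members).  Barcode clusters linked to more than one
promoter cluster are chimeric artifacts and are discarded; a promoter
cluster may legitimately own several barcodes.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import encode

logger = logging.getLogger(__name__)

BARCODE_LENGTH = 20
PROMOTER_LENGTH = 120
BARCODE_MISMATCH = 2
PROMOTER_MISMATCH = 6


@dataclass
class SequenceCluster:
    """A greedy cluster: centroid plus members with read abundances."""

    centroid: str
    members: dict = field(default_factory=dict)  # sequence -> abundance

    @property
    def total(self) -> int:
        return sum(self.members.values())


@dataclass
class LinkageMap:
    """Retained barcode-cluster -> promoter-cluster mapping.

    ``discarded`` maps discarded barcode centroids to a reason string.
    """

    barcode_to_promoter: dict = field(default_factory=dict)
    discarded: dict = field(default_factory=dict)


def filter_read_lengths(
    pairs: pd.DataFrame,
    barcode_length: int = BARCODE_LENGTH,
    promoter_length: int = PROMOTER_LENGTH,
) -> pd.DataFrame:
    """Keep read pairs whose barcode and promoter have the exact designed
    lengths; log the number discarded."""
    keep = pairs["barcode"].str.len().eq(barcode_length) & pairs[
        "promoter"
    ].str.len().eq(promoter_length)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_read_lengths: discarded %d malformed pairs", n_drop)
    if keep.sum() == 0:
        logger.warning("filter_read_lengths: no read pairs passed the length filter")
    return pairs.loc[keep].reset_index(drop=True)


def cluster_sequences(abundances, max_mismatch: int):
    """Deterministic greedy centroid clustering by Hamming distance.

    Sequences are processed in decreasing abundance (ties broken
    lexicographically); each is assigned to the first existing centroid
    within ``max_mismatch`` mismatches, else founds a new cluster.  The
    centroid of a cluster is therefore its most abundant member.

    Parameters
    ----------
    abundances
        Mapping sequence -> read count, or an iterable of sequences
        (counted with multiplicity).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if not isinstance(abundances, dict):
        abundances = dict(Counter(abundances))
    if not abundances:
        return []
    order = sorted(abundances, key=lambda s: (-abundances[s], s))
    enc = encode(order)  # also rejects mixed lengths
    clusters: list[SequenceCluster] = []
    centroid_rows: list[np.ndarray] = []
    centroid_mat = None
    for i, seq in enumerate(order):
        if centroid_rows:
            if centroid_mat is None or centroid_mat.shape[0] != len(centroid_rows):
                centroid_mat = np.vstack(centroid_rows)
            dists = (centroid_mat != enc[i]).sum(axis=1)
            hit = np.nonzero(dists <= max_mismatch)[0]
        else:
            hit = []
        if len(hit):
            clusters[int(hit[0])].members[seq] = abundances[seq]
        else:
            clusters.append(SequenceCluster(centroid=seq, members={seq: abundances[seq]}))
            centroid_rows.append(enc[i])
            centroid_mat = None
    return clusters


def _member_index(clusters) -> dict:
    idx = {}
    for cl in clusters:
        for seq in cl.members:
            idx[seq] = cl.centroid
    return idx


def link_promoter_barcodes(
    barcode_clusters, promoter_clusters, pairs: pd.DataFrame
) -> LinkageMap:
    """Link barcode clusters to promoter clusters through read pairs.

    A barcode cluster whose pairs reach two or more promoter clusters is
    discarded with reason ``"conflict"``; each retained barcode cluster
    maps to its unique promoter cluster.
    """
    b_idx = _member_index(barcode_clusters)
    p_idx = _member_index(promoter_clusters)
    seen = defaultdict(set)
    for bc, pr in zip(pairs["barcode"], pairs["promoter"]):
        if bc in b_idx and pr in p_idx:
            seen[b_idx[bc]].add(p_idx[pr])
    lm = LinkageMap()
    for bc_centroid, proms in seen.items():
        if len(proms) > 1:
            lm.discarded[bc_centroid] = "conflict"
        else:
            lm.barcode_to_promoter[bc_centroid] = next(iter(proms))
    if lm.discarded:
        logger.info(
            "link_promoter_barcodes: discarded %d conflicting barcode clusters",
            len(lm.discarded),
        )
    return lm


def filter_by_dna_depth(counts: pd.DataFrame, min_reads: int = 100):
    """Barcodes with at least ``min_reads`` DNA counts in *every* replicate.

    ``counts`` is long-form with columns ``barcode``, ``replicate``,
    ``molecule`` and ``count``.  Returns the sorted list of retained
    barcodes.
    """
    for col in ("barcode", "replicate", "molecule", "count"):
        if col not in counts.columns:
            raise ValueError(f"count table lacks required column {col!r}")
    dna = counts[counts["molecule"] == "DNA"]
    replicates = counts["replicate"].unique()
    wide = (
        dna.pivot_table(
            index="barcode", columns="replicate", values="count",
            aggfunc="sum", fill_value=0, observed=True,
        )
        .reindex(columns=replicates, fill_value=0)
    )
    keep = wide.ge(min_reads).all(axis=1)
    return sorted(wide.index[keep])
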