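"""Promoter sequence features: PWM scanning, TFBS effect tests and the
promoter-strength / GC-content profile.

PWMs are additive log-odds matrices with a per-TF score cutoff (the
matrix-file dialect mirrors ScerTF-style 4-row matrices; matrices are
assumed pre-processed, so no pseudocounts are applied at scan time).
The forward strand is the strand transcribed into the barcode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as cstats
from .sequences import BASES, encode, revcomp

logger = logging.getLogger(__name__)


@dataclass
class PWMModel:
    """Position weight matrix for one TF with its score cutoff.

    ``matrix`` is 4 x w in alphabet order A, C, G, T.
    """

    tf_id: str
    matrix: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x w")
        if self.matrix.shape[1] < 1:
            raise ValueError("PWM width must be >= 1")
        if not np.all(np.isfinite(self.matrix)) or not np.isfinite(self.cutoff):
            raise ValueError("PWM matrix and cutoff must be finite")

    @property
    def width(self) -> int:
        return int(self.matrix.shape[1])


def read_pwm_file(path) -> list[PWMModel]:
    """Read PWMs from a ScerTF-like text file.

    Each record: a header line ``>tf_id cutoff=<float>`` followed by
    four rows ``A <w values>``, ``C ...``, ``G ...``, ``T ...``.
    """
    models = []
    tf_id = None
    cutoff = None
    rows: dict[str, list[float]] = {}

    def flush():
        if tf_id is None:
            return
        missing = set(BASES) - set(rows)
        if missing:
            raise ValueError(f"PWM {tf_id}: missing rows {sorted(missing)}")
        mat = np.array([rows[b] for b in BASES])
        models.append(PWMModel(tf_id=tf_id, matrix=mat, cutoff=cutoff))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].split()
                tf_id = head[0]
                cutoff = None
                rows = {}
                for tok in head[1:]:
                    if tok.startswith("cutoff="):
                        cutoff = float(tok.split("=", 1)[1])
                if cutoff is None:
                    raise ValueError(f"PWM {tf_id}: header lacks cutoff=")
            else:
                parts = line.replace("|", " ").split()
                rows[parts[0]] = [float(x) for x in parts[1:]]
    flush()
    return models


def write_pwm_file(path, models) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.tf_id} cutoff={m.cutoff:g}\n")
            for b, row in zip(BASES, m.matrix):
                fh.write(b + " " + " ".join(f"{x:g}" for x in row) + "\n")


def scan_pwm(seq: str, pwm: PWMModel, strand: str = "+"):
    """All PWM hits (additive score >= cutoff) on one strand.

    Returns a list of ``(position, score)`` with 1-based positions on
    the forward axis; a reverse-strand hit reports the forward-axis
    coordinate of its lowest base.
    """
    w = pwm.width
    L = len(seq)
    if w > L:
        logger.warning("scan_pwm(%s): motif wider than sequence", pwm.tf_id)
        return []
    target = seq if strand == "+" else revcomp(seq)
    enc = encode([target])[0]
    # score of window starting at i: sum_k matrix[enc[i+k], k]
    idx = np.arange(L - w + 1)[:, None] + np.arange(w)[None, :]
    scores = pwm.matrix[enc[idx], np.arange(w)[None, :]].sum(axis=1)
    hits = []
    for i in np.nonzero(scores >= pwm.cutoff)[0]:
        pos = int(i) + 1 if strand == "+" else L - (int(i) + w) + 1
        hits.append((pos, float(scores[i])))
    return sorted(hits)


def pwm_hit_table(promoters: dict, pwms, strands=("+", "-")) -> pd.DataFrame:
    """Long-form TFBS hit table over a promoter library.

    ``promoters`` maps promoter id -> sequence.  Columns: promoter,
    tf_id, strand, position (1-based forward axis), score.
    """
    rows = []
    for pid, seq in promoters.items():
        for pwm in pwms:
            for strand in strands:
                for pos, score in scan_pwm(seq, pwm, strand):
                    rows.append((pid, pwm.tf_id, strand, pos, score))
    return pd.DataFrame(
        rows, columns=["promoter", "tf_id", "strand", "position", "score"]
    )


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value: exact for small untied samples, normal
    approximation with tie correction otherwise (scipy's policy)."""
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.pvalue)


def tf_effect_tests(
    activities: pd.Series,
    hits: pd.DataFrame,
    strand: str,
    shuffle: bool = False,
    seed=None,
    fdr: float = 0.05,
    min_group: int = 2,
) -> pd.DataFrame:
    """Per-TF Wilcoxon rank-sum tests of activity with vs without a TFBS.

    For each TF, promoters split by presence of at least one binding
    site on ``strand``; the two-tailed rank-sum p is BH-corrected across
    TFs, and the effect is median activity(with) / median(without).
    With ``shuffle=True`` the activities are first permuted among
    promoters (seeded), giving the chance-association null.
    """
    acts = activities.dropna()
    if shuffle:
        rng = np.random.default_rng(seed)
        acts = pd.Series(rng.permutation(acts.to_numpy()), index=acts.index)
    sub = hits[hits["strand"] == strand]
    with_sets = sub.groupby("tf_id", observed=True)["promoter"].agg(set)
    rows = []
    for tf_id, with_set in with_sets.items():
        has = acts.index.isin(with_set)
        a_with = acts[has].to_numpy()
        a_without = acts[~has].to_numpy()
        if len(a_with) < min_group or len(a_without) < min_group:
            logger.info("tf_effect_tests: %s skipped (group too small)", tf_id)
            continue
        p = wilcoxon_rank_sum(a_with, a_without)
        med_wo = np.median(a_without)
        effect = np.median(a_with) / med_wo if med_wo > 0 else np.inf
        rows.append((tf_id, strand, len(a_with), len(a_without), p, effect))
    out = pd.DataFrame(
        rows, columns=["tf_id", "strand", "n_with", "n_without", "p", "effect"]
    )
    if len(out):
        out["q"] = cstats.bh_adjust(out["p"])
        out["significant"] = out["q"] <= fdr
    else:
        out["q"] = []
        out["significant"] = []
    return out


def strength_gc_profile(
    activities: pd.Series, gc: pd.Series, n_bins: int = 50
):
    """Mean GC per promoter-strength bin plus the unbinned association.

    Promoters are ranked by activity and split into ``n_bins``
    equal-size bins (any remainder spread over the leading bins); each
    bin reports mean GC with a normal-approximation 95% CI.  The
    unbinned Spearman correlation is returned alongside.

    Returns ``(profile DataFrame, rho, p)``.
    """
    df = pd.DataFrame({"activity": activities, "gc": gc}).dropna()
    if len(df) < n_bins:
        raise ValueError(f"need at least {n_bins} promoters, got {len(df)}")
    df = df.sort_values(["activity", "gc"], kind="mergesort")
    parts = np.array_split(np.arange(len(df)), n_bins)
    rows = []
    for b, idx in enumerate(parts):
        sub = df.iloc[idx]
        m = sub["gc"].mean()
        se = sub["gc"].std(ddof=1) / np.sqrt(len(sub)) if len(sub) > 1 else 0.0
        rows.append(
            (b, len(sub), sub["activity"].mean(), m, m - 1.96 * se, m + 1.96 * se)
        )
    profile = pd.DataFrame(
        rows, columns=["bin", "n", "mean_activity", "mean_gc", "gc_lo", "gc_hi"]
    )
    rho, p = sps.spearmanr(df["activity"], df["gc"])
    return profile, float(rho), float(p)


def extract_promoters(
    genome: dict, genes, upstream: int = 500
) -> dict:
    """Native-gene promoter sequences: ``upstream`` nt ending just before
    each gene's start anchor (translation or transcription start),
    strand-aware.  Genes too close to a chromosome end are skipped.

    ``genome`` maps chromosome -> sequence; ``genes`` yields objects
    with ``gene_id``, ``chrom``, ``strand``, ``start``, ``end``
    (1-based inclusive anchors).
    """
    out = {}
    for g in genes:
        seq = genome.get(g.chrom)
        if seq is None:
            continue
        if g.strand == "+":
            lo, hi = g.start - upstream, g.start - 1
            if lo < 1:
                continue
            out[g.gene_id] = seq[lo - 1 : hi]
        else:
            lo, hi = g.end + 1, g.end + upstream
            if hi > len(seq):
                continue
            out[g.gene_id] = revcomp(seq[lo - 1 : hi])
    return out
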