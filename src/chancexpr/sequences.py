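"""Low-level sequence utilities: nucleotide profiles, Hamming statistics,
GC content and TATA-box detection.

Sequences are plain Python strings over the alphabet ``ACGT``.  Encoded
``numpy`` views (one ``uint8`` code per base, A=0, C=1, G=2, T=3) are used
internally wherever pairwise comparisons need to be vectorised.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# TATA-box consensus TATAWAWR (W = A/T, R = A/G), the standard yeast
# core-promoter element definition.
TATA_CONSENSUS = re.compile(r"(?=(TATA[AT]A[AT][AG]))")


@dataclass(frozen=True)
class NucleotideProfile:
    """Mononucleotide frequencies (fA, fT, fG, fC), summing to one.

    The library-design profile determines both the composition of
    generated random sequences and closed-form sequence statistics such
    as the expected pairwise Hamming distance.
    """

    fA: float
    fT: float
    fG: float
    fC: float

    def __post_init__(self) -> None:
        freqs = (self.fA, self.fT, self.fG, self.fC)
        if any(f < 0 for f in freqs):
            raise ValueError(f"nucleotide frequencies must be non-negative: {freqs}")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError(
                f"nucleotide frequencies must sum to 1 (got {sum(freqs)!r})"
            )

    @classmethod
    def uniform(cls) -> "NucleotideProfile":
        return cls(0.25, 0.25, 0.25, 0.25)

    @classmethod
    def from_sequences(cls, seqs) -> "NucleotideProfile":
        """Empirical profile of a collection of sequences."""
        counts = dict.fromkeys(BASES, 0)
        for s in seqs:
            for b in BASES:
                counts[b] += s.count(b)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no bases to profile")
        return cls(
            counts["A"] / total, counts["T"] / total,
            counts["G"] / total, counts["C"] / total,
        )

    @property
    def acgt(self) -> np.ndarray:
        """Frequencies in alphabet order A, C, G, T."""
        return np.array([self.fA, self.fC, self.fG, self.fT], dtype=float)

    @property
    def gc(self) -> float:
        return self.fG + self.fC


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seqs) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(seqs), lengths.pop())
    out = np.empty_like(arr)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    bad = ~np.isin(arr, [ord(b) for b in BASES])
    if bad.any():
        raise ValueError("sequences contain characters outside ACGT")
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def gc_content(seq: str) -> float:
    """Fraction of G or C bases.  Ambiguous bases are rejected."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set(BASES):
        raise ValueError(f"ambiguous bases in sequence: {set(seq) - set(BASES)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def expected_hamming_distance(length: int, profile: NucleotideProfile) -> float:
    """Expected Hamming distance between two i.i.d. random sequences.

    For each site, two independent draws from the profile differ with
    probability ``sum_X (1 - f_X) f_X``; the expectation is that
    probability times the length.  At equal frequencies and length 120
    this is 90.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    f = profile.acgt
    return float(length * np.sum((1.0 - f) * f))


def observed_mean_hamming(seqs, max_pairs: int = 200_000, seed=None):
    """Mean pairwise Hamming distance of a library, with its standard error.

    All pairs are used when there are at most ``max_pairs`` of them;
    otherwise a seeded random sample of ``max_pairs`` pairs is scored.

    Returns ``(mean, se, n_pairs)``.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    enc = encode(seqs)
    n = len(seqs)
    n_all = n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    if n_all <= max_pairs:
        ii, jj = np.triu_indices(n, k=1)
    else:
        ii = rng.integers(0, n, size=max_pairs)
        jj = rng.integers(0, n - 1, size=max_pairs)
        jj = np.where(jj >= ii, jj + 1, jj)  # j != i, uniform over ordered pairs
    dists = (enc[ii] != enc[jj]).sum(axis=1)
    mean = float(dists.mean())
    se = float(dists.std(ddof=1) / np.sqrt(len(dists))) if len(dists) > 1 else 0.0
    return mean, se, len(dists)


def find_tata(seq: str):
    """TATA-box consensus hits (TATAWAWR) on both strands.

    Returns a list of ``(position, strand)`` with 1-based positions of
    the match start on the forward axis; reverse-strand hits report the
    forward-axis coordinate of the site's lowest base.
    """
    hits = []
    for m in TATA_CONSENSUS.finditer(seq):
        hits.append((m.start() + 1, "+"))
    rc = revcomp(seq)
    w = 8
    for m in TATA_CONSENSUS.finditer(rc):
        pos_fwd = len(seq) - (m.start() + w) + 1
        hits.append((pos_fwd, "-"))
    return sorted(hits)
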