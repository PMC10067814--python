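"""Synthetic data with the statistical structure the pipeline assumes.

Two generators cover the two arms of the analysis:

* :func:`gen_barcode_reads` emulates the reporter library — random
  120-nt promoters each linked to a random 20-nt barcode, mixed with
  eight-barcode negative and positive controls at 100:5:1, sequenced as
  UMI-tagged DNA and cDNA reads with negative-binomial depth and a
  configurable PCR-duplicate fraction, plus promoter-barcode linkage
  read pairs with a configurable chimera rate.

* :func:`gen_intergenic_landscape` emulates a small annotated genome
  whose intergenic windows express at chance-promoter levels: each
  120-nt segment of each region draws a relative expression level (REL)
  from a supplied chance-activity sample, per strand, shared between
  environments; a planted minority of "functional" regions get one
  segment elevated in a single environment; and an optional
  readthrough term decays exponentially into regions from neighboring
  genes transcribed toward them.

Every generated byte is a deterministic function of the seed.  Ground
truth is returned alongside the observables and is never read by the
pipeline stages themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import (
    RNA_EXTENSION,
    SEGMENT_SIZE,
    UTR_EXTENSION,
    WINDOW_SIZE,
    ExcludedFeature,
    Gene,
    GenomeAnnotation,
    IntergenicRegion,
    extended_footprint,
)
from .sequences import NucleotideProfile

#: Mononucleotide frequencies measured in the assay's synthesised
#: library (A, T, G, C) — the default composition for simulations.
LIBRARY_PROFILE = NucleotideProfile(fA=0.243, fT=0.324, fG=0.257, fC=0.176)

_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(mat: np.ndarray) -> list:
    s = _CHARS[mat].tobytes().decode("ascii")
    L = mat.shape[1]
    return [s[i * L : (i + 1) * L] for i in range(mat.shape[0])]


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_random_sequences(n: int, length: int, profile: NucleotideProfile, seed=None):
    """``n`` i.i.d. random sequences of ``length`` nt under ``profile``."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    if not isinstance(profile, NucleotideProfile):
        profile = NucleotideProfile(*profile)
    rng = _rng(seed)
    codes = rng.choice(4, size=(n, length), p=profile.acgt)
    return _decode(codes.astype(np.uint8))


def negative_binomial(rng, mean, dispersion: float):
    """NB draws with the given mean and size (dispersion) parameter;
    variance = mean + mean^2 / dispersion.  Zero mean gives zero."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


@dataclass
class ActivityModel:
    """Chance promoter activity on the REL scale: a point mass of
    inactive promoters plus a lognormal tail.

    Defaults are calibrated so that ~63% of promoters are active and
    ~0.02% exceed the native-gene median (REL > 1), the scale observed
    for fully random yeast promoters.
    """

    zero_fraction: float = 0.368
    lognorm_mu: float = -3.37
    lognorm_sigma: float = 1.0

    def sample(self, n: int, seed=None) -> np.ndarray:
        rng = _rng(seed)
        act = rng.lognormal(self.lognorm_mu, self.lognorm_sigma, size=n)
        act[rng.random(n) < self.zero_fraction] = 0.0
        return act


@dataclass
class LibraryDesign:
    """Study-condition parameters of the synthetic reporter library."""

    n_promoters: int = 2000
    promoter_length: int = 120
    barcode_length: int = 20
    mix_ratio: tuple = (100, 5, 1)  # library : negative : positive
    n_control_barcodes: int = 8
    replicates: int = 3
    environments: tuple = ("YPD", "SCD")
    mean_dna_reads: float = 300.0  # DNA molecules per library barcode per replicate
    cdna_depth_factor: float = 10.0  # cDNA mean = DNA mean * activity * factor
    dispersion: float = 20.0
    umi_length: int = 6
    duplication_fraction: float = 0.1  # fraction of reads that are UMI duplicates
    linkage_reads_per_barcode: float = 30.0
    chimera_rate: float = 0.002
    read_error_rate: float = 0.0
    cdna_leak: float = 0.0  # baseline activity added to every barcode
    positive_control_rel: float = 0.37  # s: positive-control gene REL
    profile: NucleotideProfile = field(default_factory=lambda: LIBRARY_PROFILE)

    def __post_init__(self) -> None:
        if min(self.promoter_length, self.barcode_length, self.umi_length) < 1:
            raise ValueError("lengths must be positive")
        if any(r <= 0 for r in self.mix_ratio):
            raise ValueError("mix ratio components must be strictly positive")
        if self.n_control_barcodes < 2:
            raise ValueError("need at least two control barcodes for t-tests")
        if self.mean_dna_reads <= 0:
            raise ValueError("zero sequencing depth")


@dataclass
class LibraryTruth:
    """Ground truth of a generated library (not read by the pipeline)."""

    promoters: list
    library_barcodes: list
    negative_barcodes: list
    positive_barcodes: list
    activity: np.ndarray  # true REL per library barcode
    barcode_to_promoter: dict
    weights: pd.Series  # mix-ratio-weighted relative DNA abundance per barcode

    @property
    def all_barcodes(self) -> list:
        return list(self.library_barcodes) + self.negative_barcodes + self.positive_barcodes

    def barcode_activity(self) -> pd.Series:
        """True REL per barcode including controls (negative = 0,
        positive = the positive-control gene's REL)."""
        s = pd.Series(self.activity, index=self.library_barcodes, dtype=float)
        neg = pd.Series(0.0, index=self.negative_barcodes)
        pos = pd.Series(self._positive_rel, index=self.positive_barcodes)
        return pd.concat([s, neg, pos]).rename_axis("barcode")

    _positive_rel: float = 0.37


def build_library(
    design: LibraryDesign, activity_model: ActivityModel | None = None, seed=None
) -> LibraryTruth:
    """Draw the library: promoter and barcode sequences, true activities
    and mix-ratio abundance weights."""
    rng = _rng(seed)
    model = activity_model or ActivityModel()
    promoters = gen_random_sequences(design.n_promoters, design.promoter_length, design.profile, rng)
    lib_bc = gen_random_sequences(design.n_promoters, design.barcode_length, design.profile, rng)
    neg_bc = gen_random_sequences(design.n_control_barcodes, design.barcode_length, design.profile, rng)
    pos_bc = gen_random_sequences(design.n_control_barcodes, design.barcode_length, design.profile, rng)
    activity = model.sample(design.n_promoters, rng)
    w_lib, w_neg, w_pos = (r / sum(design.mix_ratio) for r in design.mix_ratio)
    weights = pd.concat(
        [
            pd.Series(w_lib / design.n_promoters, index=lib_bc),
            pd.Series(w_neg / design.n_control_barcodes, index=neg_bc),
            pd.Series(w_pos / design.n_control_barcodes, index=pos_bc),
        ]
    ).rename_axis("barcode")
    truth = LibraryTruth(
        promoters=promoters,
        library_barcodes=lib_bc,
        negative_barcodes=neg_bc,
        positive_barcodes=pos_bc,
        activity=activity,
        barcode_to_promoter=dict(zip(lib_bc, promoters)),
        weights=weights,
    )
    truth._positive_rel = design.positive_control_rel
    return truth


def _mutate(rng, seqs, rate: float):
    if rate <= 0:
        return seqs
    out = list(seqs)
    n_mut = rng.binomial(len(out[0]) if out else 0, rate, size=len(out))
    for i in np.nonzero(n_mut)[0]:
        s = list(out[i])
        for pos in rng.choice(len(s), size=n_mut[i], replace=False):
            s[pos] = "ACGT"[rng.integers(4)]
        out[i] = "".join(s)
    return out


def gen_barcode_reads(design: LibraryDesign, truth: LibraryTruth, seed=None):
    """UMI-tagged DNA/cDNA barcode reads plus promoter-barcode linkage pairs.

    DNA molecule counts per barcode are negative-binomial around the
    mix-weighted depth; cDNA molecule counts are proportional to the
    barcode's true activity (so the expected cDNA/DNA ratio is linear in
    activity, and exactly 0 for negative controls when ``cdna_leak`` is
    0).  Each molecule carries a random UMI; a configurable fraction of
    reads are UMI duplicates.

    Returns ``(reads, pairs)``: reads with columns environment,
    replicate, molecule, barcode, umi; pairs with columns barcode,
    promoter.
    """
    rng = _rng(seed)
    barcodes = truth.all_barcodes
    act = truth.barcode_activity().loc[barcodes].to_numpy() + design.cdna_leak
    weights = truth.weights.loc[barcodes].to_numpy()
    w_lib_each = (design.mix_ratio[0] / sum(design.mix_ratio)) / design.n_promoters
    depth_scale = design.mean_dna_reads / w_lib_each
    mu_dna = weights * depth_scale
    mu_cdna = mu_dna * act * design.cdna_depth_factor
    dup_lam = design.duplication_fraction / (1.0 - design.duplication_fraction)
    bc_cat = pd.CategoricalDtype(categories=barcodes)

    frames = []
    for env in design.environments:
        for rep in range(1, design.replicates + 1):
            for mol, mu in (("DNA", mu_dna), ("cDNA", mu_cdna)):
                mols = negative_binomial(rng, mu, design.dispersion)
                total = int(mols.sum())
                bc_idx = np.repeat(np.arange(len(barcodes)), mols)
                umis = rng.integers(0, 4 ** design.umi_length, size=total)
                extra = rng.poisson(dup_lam, size=total) if dup_lam > 0 else np.zeros(total, dtype=int)
                reps_per_mol = 1 + extra
                frames.append(
                    pd.DataFrame(
                        {
                            "environment": env,
                            "replicate": rep,
                            "molecule": mol,
                            "barcode": pd.Categorical.from_codes(
                                np.repeat(bc_idx, reps_per_mol), dtype=bc_cat
                            ),
                            "umi": np.repeat(umis, reps_per_mol),
                        }
                    )
                )
    reads = pd.concat(frames, ignore_index=True)

    n_pairs = rng.poisson(design.linkage_reads_per_barcode, size=design.n_promoters)
    bc_idx = np.repeat(np.arange(design.n_promoters), n_pairs)
    prom_idx = bc_idx.copy()
    chim = rng.random(len(bc_idx)) < design.chimera_rate
    prom_idx[chim] = rng.integers(0, design.n_promoters, size=int(chim.sum()))
    bc_seqs = _mutate(rng, [truth.library_barcodes[i] for i in bc_idx], design.read_error_rate)
    pr_seqs = _mutate(rng, [truth.promoters[i] for i in prom_idx], design.read_error_rate)
    pairs = pd.DataFrame({"barcode": bc_seqs, "promoter": pr_seqs})
    return reads, pairs


def umi_to_string(umi_codes, umi_length: int = 6):
    """Integer UMI codes as base-4 ACGT strings (for TSV export)."""
    codes = np.asarray(umi_codes, dtype=np.int64)
    mat = np.empty((len(codes), umi_length), dtype=np.uint8)
    for k in range(umi_length - 1, -1, -1):
        mat[:, k] = codes % 4
        codes = codes // 4
    return _decode(mat)


# ---------------------------------------------------------------------------
# Intergenic landscape
# ---------------------------------------------------------------------------


@dataclass
class LandscapeDesign:
    """Study-condition parameters of the synthetic genome landscape."""

    n_regions: int = 500
    region_length_range: tuple = (60, 600)  # nt
    cds_length_range: tuple = (300, 1500)
    utr_length_range: tuple = (30, 150)
    rna_length_range: tuple = (80, 300)
    utr_annotated_fraction: float = 0.5
    rna_gene_fraction: float = 0.1
    n_chromosomes: int = 4
    telomere_length: int = 500
    functional_fraction: float = 0.05
    functional_effect: float = 4.0  # multiple of the chance sample's 99th pct
    environments: tuple = ("YPD", "SCD")
    #: RNA-seq samples per environment: an int (same everywhere) or a
    #: mapping environment -> count.  The default mirrors the data the
    #: analysis assumes: ten wild-type samples in rich medium, three in
    #: minimal medium.
    replicates: object = field(default_factory=lambda: {"YPD": 10, "SCD": 3})
    total_reads: float = 2e7  # per (environment, replicate)
    median_gene_rpm: float = 15.0
    gene_rpm_sigma: float = 1.0
    dispersion: float = 20.0
    background_rpm: float = 0.0
    readthrough_scale: float = 0.2  # readthrough RPM at the gene edge / gene RPM
    readthrough_decay: float = 150.0  # nt
    utr_ext: int = UTR_EXTENSION
    rna_ext: int = RNA_EXTENSION

    def __post_init__(self) -> None:
        if not (0.0 <= self.functional_fraction <= 1.0):
            raise ValueError("functional_fraction must be in [0, 1]")
        if self.n_regions < 1:
            raise ValueError("need at least one region")

    def replicates_for(self, env: str) -> list:
        if isinstance(self.replicates, int):
            n = self.replicates
        else:
            n = self.replicates[env]
        return list(range(1, n + 1))


@dataclass
class LandscapeSim:
    """A generated landscape: observables plus ground truth."""

    annotation: GenomeAnnotation
    regions: list  # planned IntergenicRegion list (matches the annotation)
    window_counts: pd.DataFrame
    gene_window_counts: pd.DataFrame
    totals: pd.DataFrame
    truth: dict  # window_truth / region_truth / gene_truth DataFrames + scalars
    design: LandscapeDesign


def _plan_gene(rng, design: LandscapeDesign, gid: str, chrom: str, fp_start: int) -> Gene:
    """A gene whose extended footprint starts exactly at ``fp_start``."""
    strand = str(rng.choice(["+", "-"]))
    if rng.random() < design.rna_gene_fraction:
        gtype = str(rng.choice(sorted({"rRNA", "tRNA", "snRNA", "snoRNA", "ncRNA"})))
        body = int(rng.integers(*design.rna_length_range))
        start = fp_start + design.rna_ext
        return Gene(gid, chrom, strand, start, start + body - 1, gtype=gtype)
    cds = int(rng.integers(*design.cds_length_range))
    if rng.random() < design.utr_annotated_fraction:
        ul = int(rng.integers(*design.utr_length_range))
        ur = int(rng.integers(*design.utr_length_range))
        cds_start = fp_start + design.utr_ext + ul
        cds_end = cds_start + cds - 1
        left_utr = (fp_start + design.utr_ext, cds_start - 1)
        right_utr = (cds_end + 1, cds_end + ur)
        utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
        return Gene(gid, chrom, strand, cds_start, cds_end, utr5=utr5, utr3=utr3)
    start = fp_start + design.utr_ext
    return Gene(gid, chrom, strand, start, start + cds - 1)


def gen_intergenic_landscape(
    design: LandscapeDesign, chance_activity_sample, seed=None
) -> LandscapeSim:
    """Generate the annotated toy genome and its window counts.

    ``chance_activity_sample`` is the REL distribution chance promoters
    follow (e.g. the measured barcode RELs, or an
    :class:`ActivityModel` sample).  Each region's 120-nt segments draw
    one chance REL per strand, shared across environments; functional
    regions get one (segment, strand) raised to ``functional_effect``
    times the sample's 99th percentile in one environment only.
    """
    rng = _rng(seed)
    chance = np.asarray(chance_activity_sample, dtype=float)
    if chance.size == 0:
        raise ValueError("chance_activity_sample must be non-empty")
    lengths = rng.integers(
        design.region_length_range[0], design.region_length_range[1] + 1,
        size=design.n_regions,
    )
    if (lengths < WINDOW_SIZE).all():
        raise ValueError("all region lengths below one window; no windows possible")
    q99 = float(np.quantile(chance, 0.99))
    functional_rel = design.functional_effect * q99

    genes: list[Gene] = []
    excluded: list[ExcludedFeature] = []
    regions: list[IntergenicRegion] = []
    chrom_lengths: dict[str, int] = {}
    region_rows = []  # (region index, IntergenicRegion)
    per_chrom = np.array_split(np.arange(design.n_regions), design.n_chromosomes)
    gid = 0
    for ci, ridx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = 1
        excluded.append(ExcludedFeature(chrom, 1, design.telomere_length, "telomere"))
        cursor = design.telomere_length + 1
        for k, ri in enumerate(ridx):
            g = _plan_gene(rng, design, f"g{gid:04d}", chrom, cursor)
            gid += 1
            genes.append(g)
            lo, hi = extended_footprint(g, design.utr_ext, design.rna_ext)
            assert lo == cursor
            cursor = hi + 1
            if k == len(ridx) // 2:  # centromere flush between footprints
                excluded.append(ExcludedFeature(chrom, cursor, cursor + 119, "centromere"))
                cursor += 120
                g2 = _plan_gene(rng, design, f"g{gid:04d}", chrom, cursor)
                gid += 1
                genes.append(g2)
                cursor = extended_footprint(g2, design.utr_ext, design.rna_ext)[1] + 1
                g = g2
            L = int(lengths[ri])
            reg = IntergenicRegion(
                region_id=f"{chrom}:{cursor}-{cursor + L - 1}",
                chrom=chrom, start=cursor, end=cursor + L - 1,
                left_gene=g.gene_id,
            )
            cursor += L
            regions.append(reg)
            region_rows.append((ri, reg))
        g = _plan_gene(rng, design, f"g{gid:04d}", chrom, cursor)
        gid += 1
        genes.append(g)
        cursor = extended_footprint(g, design.utr_ext, design.rna_ext)[1] + 1
        excluded.append(ExcludedFeature(chrom, cursor, cursor + design.telomere_length - 1, "telomere"))
        chrom_lengths[chrom] = cursor + design.telomere_length - 1
    # assign right neighbors: the next gene on the same chromosome
    genes_sorted = sorted(genes, key=lambda g: (g.chrom, g.start))
    for reg in regions:
        after = [g for g in genes_sorted if g.chrom == reg.chrom and g.start > reg.end]
        reg.right_gene = after[0].gene_id if after else None
    annotation = GenomeAnnotation(genes=genes, excluded=excluded, chrom_lengths=chrom_lengths)

    gene_by_id = {g.gene_id: g for g in genes}
    # gene expression: lognormal, pinned so the median equals the design value
    raw = rng.lognormal(np.log(design.median_gene_rpm), design.gene_rpm_sigma, size=len(genes))
    gene_rpm = raw * (design.median_gene_rpm / np.median(raw))
    gene_rpm = pd.Series(gene_rpm, index=[g.gene_id for g in genes])

    envs = list(design.environments)
    reps_by_env = {env: design.replicates_for(env) for env in envs}
    strands = ["+", "-"]
    R = design.median_gene_rpm
    read_scale = design.total_reads / 1e6

    func_flags = rng.random(design.n_regions) < design.functional_fraction
    win_frames = []
    truth_frames = []
    region_truth_rows = []
    for ri, reg in region_rows:
        n_win = reg.length // WINDOW_SIZE
        if n_win == 0:
            region_truth_rows.append((reg.region_id, False, None, None, None))
            continue
        N = reg.n_segments
        seg_rel = rng.choice(chance, size=(N, 2))  # per (segment, strand)
        rel = np.repeat(seg_rel[None, :, :], len(envs), axis=0)  # (env, seg, strand)
        functional = bool(func_flags[ri])
        f_env = f_seg = f_strand = None
        if functional:
            f_env = int(rng.integers(len(envs)))
            f_seg = int(rng.integers(N))
            f_strand = int(rng.integers(2))
            rel = rel.copy()
            rel[f_env, f_seg, f_strand] = functional_rel
        region_truth_rows.append(
            (reg.region_id, functional,
             envs[f_env] if functional else None,
             f_seg, strands[f_strand] if functional else None)
        )
        widx = np.arange(n_win)
        seg_of_win = (widx * WINDOW_SIZE) // SEGMENT_SIZE
        win_rel = rel[:, seg_of_win, :]  # (env, win, strand)
        # readthrough decaying into the region from genes transcribed toward it
        rt = np.zeros((n_win, 2))
        if design.readthrough_scale > 0:
            w_start = reg.start + WINDOW_SIZE * widx
            lg = gene_by_id.get(reg.left_gene)
            if lg is not None and lg.strand == "+":
                dist = w_start - reg.start
                rt[:, 0] += gene_rpm[lg.gene_id] * design.readthrough_scale * np.exp(
                    -dist / design.readthrough_decay
                )
            rg = gene_by_id.get(reg.right_gene)
            if rg is not None and rg.strand == "-":
                dist = reg.end - (w_start + WINDOW_SIZE - 1)
                rt[:, 1] += gene_rpm[rg.gene_id] * design.readthrough_scale * np.exp(
                    -dist / design.readthrough_decay
                )
        mean_rpm = win_rel * R + rt[None, :, :] + design.background_rpm
        for ei, env in enumerate(envs):
            reps = reps_by_env[env]
            mean_counts = mean_rpm[ei][..., None] * read_scale  # (win, strand, rep)
            counts = negative_binomial(
                rng, np.broadcast_to(mean_counts, (n_win, 2, len(reps))),
                design.dispersion,
            )
            w_i, s_i, r_i = np.meshgrid(
                widx, np.arange(2), np.arange(len(reps)), indexing="ij"
            )
            win_frames.append(
                pd.DataFrame(
                    {
                        "region_id": reg.region_id,
                        "window_index": w_i.ravel(),
                        "strand": np.array(strands)[s_i.ravel()],
                        "environment": env,
                        "replicate": np.array(reps)[r_i.ravel()],
                        "count": counts.ravel(),
                    }
                )
            )
        e_i, w_i, s_i = np.meshgrid(
            np.arange(len(envs)), widx, np.arange(2), indexing="ij"
        )
        is_func = np.zeros((len(envs), n_win, 2), dtype=bool)
        if functional:
            is_func[f_env, seg_of_win == f_seg, f_strand] = True
        truth_frames.append(
            pd.DataFrame(
                {
                    "region_id": reg.region_id,
                    "window_index": w_i.ravel(),
                    "strand": np.array(strands)[s_i.ravel()],
                    "environment": np.array(envs)[e_i.ravel()],
                    "true_rel": win_rel.ravel(),
                    "rt_rpm": np.broadcast_to(rt[None, :, :], (len(envs), n_win, 2)).ravel(),
                    "functional": is_func.ravel(),
                }
            )
        )

    gene_frames = []
    for g in genes:
        body = g.end - g.start + 1
        n_win = body // WINDOW_SIZE
        if n_win == 0:
            continue
        mean = gene_rpm[g.gene_id] * read_scale
        for env in envs:
            reps = reps_by_env[env]
            counts = negative_binomial(
                rng, np.full((n_win, len(reps)), mean), design.dispersion
            )
            w_i, r_i = np.meshgrid(
                np.arange(n_win), np.arange(len(reps)), indexing="ij"
            )
            gene_frames.append(
                pd.DataFrame(
                    {
                        "gene_id": g.gene_id,
                        "window_index": w_i.ravel(),
                        "strand": g.strand,
                        "environment": env,
                        "replicate": np.array(reps)[r_i.ravel()],
                        "count": counts.ravel(),
                    }
                )
            )

    totals = pd.DataFrame(
        [(e, r, design.total_reads) for e in envs for r in reps_by_env[e]],
        columns=["environment", "replicate", "total"],
    )
    truth = {
        "window_truth": pd.concat(truth_frames, ignore_index=True),
        "region_truth": pd.DataFrame(
            region_truth_rows,
            columns=["region_id", "functional", "functional_env",
                     "functional_segment", "functional_strand"],
        ),
        "gene_truth": pd.DataFrame(
            {"gene_id": gene_rpm.index, "rpm": gene_rpm.to_numpy(),
             "strand": [gene_by_id[g].strand for g in gene_rpm.index]}
        ),
        "functional_rel": functional_rel,
        "chance_q99": q99,
    }
    return LandscapeSim(
        annotation=annotation,
        regions=regions,
        window_counts=pd.concat(win_frames, ignore_index=True),
        gene_window_counts=pd.concat(gene_frames, ignore_index=True),
        totals=totals,
        truth=truth,
        design=design,
    )
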