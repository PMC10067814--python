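#!/usr/bin/env python
"""Generate the study's synthetic inputs: the barcoded random-promoter
library (both environments, UMI-tagged DNA/cDNA reads, linkage pairs)
and the annotated toy genome with intergenic window counts.

Raw read-scale tables are large and land under scratch/; small summary
tables and the annotation land under the results directory.
"""

import argparse
from pathlib import Path

import pandas as pd

from chancexpr import io, simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch/sim"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    args.scratch.mkdir(parents=True, exist_ok=True)

    design = simulate.LibraryDesign(n_promoters=1500)
    truth = simulate.build_library(design, seed=args.seed)
    reads, pairs = simulate.gen_barcode_reads(design, truth, seed=args.seed + 1)

    io.write_fasta(
        args.scratch / "promoters.fa",
        {f"p{i}": s for i, s in enumerate(truth.promoters)},
    )
    io.write_fasta(
        args.scratch / "barcodes.fa",
        {f"b{i}": s for i, s in enumerate(truth.all_barcodes)},
    )
    out_reads = reads.copy()
    out_reads["umi"] = simulate.umi_to_string(out_reads["umi"], design.umi_length)
    out_reads.to_csv(args.scratch / "barcode_reads.tsv", sep="\t", index=False)
    pairs.to_csv(args.scratch / "linkage_pairs.tsv", sep="\t", index=False)

    chance = simulate.ActivityModel().sample(2000, seed=args.seed + 2)
    ldesign = simulate.LandscapeDesign(n_regions=500)
    sim = simulate.gen_intergenic_landscape(ldesign, chance, seed=args.seed + 3)
    io.write_gff3(sim.annotation, args.outdir / "toy_genome.gff3")
    sim.window_counts.to_csv(args.scratch / "window_counts.tsv", sep="\t", index=False)
    sim.gene_window_counts.to_csv(args.scratch / "gene_window_counts.tsv", sep="\t", index=False)
    sim.totals.to_csv(args.outdir / "sample_totals.tsv", sep="\t", index=False)
    io.write_json(
        {
            "n_promoters": design.n_promoters,
            "n_reads": int(len(reads)),
            "n_linkage_pairs": int(len(pairs)),
            "n_regions": ldesign.n_regions,
            "n_intergenic_windows": int(
                sim.window_counts[["region_id", "window_index", "strand"]]
                .drop_duplicates()
                .shape[0]
            ),
            "n_functional_regions": int(sim.truth["region_truth"]["functional"].sum()),
        },
        args.outdir / "simulation_summary.json",
    )

    rt = sim.truth["region_truth"]
    print(f"library: {design.n_promoters} promoters, {len(reads):,} reads, "
          f"{len(pairs):,} linkage pairs")
    print(f"landscape: {ldesign.n_regions} regions, "
          f"{int(rt['functional'].sum())} functional "
          f"({ldesign.functional_fraction:.0%} planted)")
    print(f"wrote raw tables to {args.scratch}/ and summaries to {args.outdir}/")


if __name__ == "__main__":
    main()
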