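#!/usr/bin/env python
"""Simulate the synthetic chromatin dataset used by the downstream analyses.

Writes a 5 Mb genome, the dyad tiling (NRL 191 bp, jitter sd 5), the
sparse positioned dyad subset, cellular events carrying translational
(A=0.3, linker-peaked) and rotational (A=0.2 at 10.2 bp) modulation,
and the matched naked control, all in the BED/FASTA dialects the
analysis modules read.
"""

import argparse
from pathlib import Path

from perilesion.synthetic_chromatin import (
    SimConfig,
    generate_genome,
    place_dyads,
    sample_events,
    select_positioned_dyads,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=101)
    ap.add_argument("--outdir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--genome-length", type=int, default=5_000_000)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(genome_length=args.genome_length, seed=args.seed, base_rate=0.4)
    genome = generate_genome(cfg)
    with open(args.outdir / "genome.fa", "w") as fh:
        fh.write(f">{cfg.contig}\n")
        seq = genome.contigs[cfg.contig]
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")

    tiling = place_dyads(cfg, genome)
    tiling.write_bed(args.outdir / "dyads_tiling.bed")
    positioned = select_positioned_dyads(tiling)
    positioned.write_bed(args.outdir / "dyads_positioned.bed")

    for naked, name in ((False, "events_cellular.bed"), (True, "events_naked.bed")):
        events = sample_events(cfg, genome, tiling, naked=naked)
        with open(args.outdir / name, "w") as fh:
            for row in events.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t.\t0\t{row.strand}\n")
        print(f"{name}: {len(events)} events")

    print(
        f"genome {args.genome_length} bp, {tiling.n_dyads} tiled dyads, "
        f"{positioned.n_dyads} positioned dyads -> {args.outdir}"
    )


if __name__ == "__main__":
    main()
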