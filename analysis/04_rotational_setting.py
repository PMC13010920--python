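#!/usr/bin/env python
"""Rotational setting: minor-out-enriched damage inside the core.

Restricts the naked-normalized enrichment profile to the +/-60 bp
nucleosome core, estimates the helical period on the 5-25 bp grid, and
summarizes mean enrichment per rotational label (minor_out, out_to_in,
minor_in, in_to_out).  The planted helical repeat is 10.2 bp with the
minor-out maximum at the dyad.
"""

import argparse
from pathlib import Path

from perilesion.periodicity import (
    RotationalConfig,
    count_relative_to_dyads,
    lomb_scargle_periodogram,
    ratio_profile,
    rotational_summary,
)
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
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(genome_length=5_000_000, seed=args.seed, base_rate=0.4)
    genome = generate_genome(cfg)
    tiling = place_dyads(cfg, genome)
    analyzed = select_positioned_dyads(tiling)
    enrich = ratio_profile(
        count_relative_to_dyads(sample_events(cfg, genome, tiling), analyzed, 1000),
        count_relative_to_dyads(
            sample_events(cfg, genome, tiling, naked=True), analyzed, 1000
        ),
    )
    core = enrich.restrict(cfg.core_half_width)
    pg = lomb_scargle_periodogram(core, (5, 25))
    rot = rotational_summary(
        enrich, RotationalConfig(cfg.rotational_period, cfg.rotational_phase, 60)
    )
    rot.to_csv(args.outdir / "rotational_summary.tsv", sep="\t", index=False)
    core.to_frame().to_csv(args.outdir / "rotational_profile.tsv", sep="\t", index=False)
    means = dict(zip(rot["label"], rot["mean_value"]))
    print(f"core rotational period {pg.peak_period:.3f} bp (planted 10.2), SNR {pg.snr:.1f}")
    print(
        "mean enrichment: "
        + ", ".join(f"{k}={v:.3f}" for k, v in sorted(means.items()))
    )
    print(
        "minor_out > minor_in:",
        means["minor_out"] > means["minor_in"],
    )


if __name__ == "__main__":
    main()
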