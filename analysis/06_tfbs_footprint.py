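#!/usr/bin/env python
"""TFBS footprint: central depletion recovered from the window profile.

Plants 500 binding sites whose footprints retain events at a factor of
0.3 (flanks enriched 1.5x) in a uniform event background, counts events
relative to standardized site midpoints, and recovers the depletion
factor as footprint density over far background density.
"""

import argparse
from pathlib import Path

from perilesion.experiments import tfbs_recovery_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=101)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    res = tfbs_recovery_experiment(args.seed, n_sites=500, target_events=100_000)
    print(
        f"{res.n_events} events over {res.n_sites} sites: planted depletion "
        f"{res.planted_depletion}, recovered {res.depletion_estimate:.3f}"
    )
    (args.outdir / "tfbs_footprint.txt").write_text(
        f"planted_depletion\t{res.planted_depletion}\n"
        f"recovered_depletion\t{res.depletion_estimate}\n"
        f"n_events\t{res.n_events}\nn_sites\t{res.n_sites}\n"
    )


if __name__ == "__main__":
    main()
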