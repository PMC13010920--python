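# perilesion

Nucleosome- and transcription-factor-relative analysis of bulky-adduct DNA
damage formation, excision repair, and somatic mutagenesis.

## The problem

Bulky carcinogen adducts (the motivating case is benzo[a]pyrene diol
epoxide, BPDE, which reacts with the exocyclic N2 amino group of guanine)
do not form uniformly across chromatin.  Nucleosomes modulate damage in two
registers: *translational* positioning (where a nucleosome sits; its
signature is the nucleosome repeat length, ~191 bp, separating accessible
linker DNA from the wrapped core) and *rotational* setting (which face of
the helix contacts the histone octamer; minor-groove-out positions recur
with the ~10.2 bp helical repeat and are more solvent-exposed than
minor-groove-in positions).  DNA-bound transcription factors such as CTCF
and SP1 shield their binding sites while leaving flanking nucleosome-free
DNA exposed.  Whether these damage asymmetries — rather than asymmetries in
nucleotide excision repair — explain the distinctive enrichment of lung
cancer mutations in linker DNA and at minor-out positions is the question
this pipeline is built to ask.

`perilesion` provides every stage of that analysis as a tested library:

- **genome_io** — FASTA/BED/GTF readers with fixed 0-based half-open
  coordinates, trinucleotide context extraction, blacklist filtering
  (positions within 1000 bp of a blacklisted region are dropped).
- **event_prep** — somatic SNV parsing (minimal VCF / MAF-like TSV),
  pyrimidine-strand normalization, PASS filtering, priority-based sample
  de-duplication, pooling and sorting.
- **lesion_caller** — damage-seq lesion calling (the damaged base is
  immediately 5′ of the read; guanine-filtered) and tXR-seq repair-read
  calling via per-read-length guanine-frequency offset inference
  (read lengths 22–29 nt).
- **periodicity_core** — dyad-relative counting (combined or
  strand-aligned), trinucleotide-context expected profiles, naked-control
  ratio normalization, floating-mean Lomb–Scargle periodograms with SNR,
  and quarter-cycle rotational-setting classification.
- **feature_windows** — TFBS midpoint standardization, feature-relative
  profiles, flanking-nucleosome peak calling, TSS extraction and
  expression-quartile stratification, Pearson window correlations.
- **signatures** — 96-context mutational signatures stratified by the
  73-bp nucleosomal/linker rule, compared by cosine similarity.
- **sasa_rotation** — Shrake–Rupley solvent-accessible surface area of
  guanine N2 atoms in nucleosome structures, grouped by rotational
  setting and compared with an exact/corrected Mann–Whitney test.
- **synthetic_chromatin** — a seeded generator of genomes, dyad maps,
  modulated events, TFBS footprints, and reads with damage-seq/tXR-seq
  geometry, so the full pipeline runs and is validated without any
  external download.

## The statistics at the core

Observed counts `O_i` at dyad-relative position `i ∈ [−1000, 1000]` are
normalized either by a context expectation
`E_i = Σ_t f_t(i)·m_t` (with `m_t` the genome-wide event rate per
trinucleotide `t` and `f_t(i)` the per-position context census over all
dyads), giving enrichment `e_i = O_i/E_i`, or by a matched naked-DNA
control, `r_i = (N_i/ΣN)/(D_i/ΣD)`.  Periodicity is estimated with a
floating-mean (generalized) Lomb–Scargle periodogram over a uniform
frequency grid; the normalized power at each period equals the fractional
χ² reduction of the sinusoid-plus-offset least-squares fit, so the peak
period provably agrees with a brute-force fit.
`SNR = peak power / median off-peak power` (periods within ±5 % of the
peak excluded).  Rotational settings are quarter-cycle bins of
`c = ((i − φ) mod P)/P`: minor_out around `c = 0`, minor_in around
`c = ½`, transitions between.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (each accepts `--seed` and `--outdir`):

```sh
python analysis/01_simulate_chromatin.py      # 5 Mb genome, dyads, events
python analysis/03_translational_periodicity.py
python analysis/04_rotational_setting.py
```

prints, for the default seed:

```
peak period 191.09 bp (planted 191), SNR 651.5, shuffled-null 95th pct 10.8

core rotational period 10.113 bp (planted 10.2), SNR 106.9
mean enrichment: in_to_out=0.853, minor_in=0.721, minor_out=1.039, out_to_in=0.847
minor_out > minor_in: True
```

Reading this: the naked-normalized damage enrichment around positioned
dyads oscillates at the planted nucleosome repeat length (191 bp,
recovered to 0.1 bp) with a periodogram SNR two orders of magnitude above
the 95th percentile of 200 position-shuffled nulls; inside the ±60 bp
core the helical repeat is recovered and mean enrichment at minor-out
positions exceeds minor-in, the damage asymmetry the rotational analysis
is designed to detect.  `analysis/05_null_calibration.py` shows the other
side of the coin — with no planted signal the context-normalized profile
is flat (`max|e−1| ≈ 0.02`) and the SNR falls inside the shuffled null.

A config-driven CLI wraps the same machinery for file-based runs:
`perilesion simulate --config sim.yaml --outdir data/`, then
`perilesion translational --config run.yaml` (see `perilesion --help`).

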