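# Methods

## Model and procedure

The pipeline treats three classes of single-base events — damage lesions,
excision-repair events, and somatic SNVs — as points with strand on a
reference genome, and asks how their rate varies relative to single-base
anchor features: nucleosome dyad centers, TFBS midpoints, or TSSs.

**Counting.**  For each anchor, events within a `±half_window` (default
1000 bp) are histogrammed at dyad-relative positions.  In *combined*
orientation an event at genomic `p` near anchor `d` contributes at
`i = p − d` regardless of event strand; in *strand-aligned* orientation
minus-strand events contribute at `−(p − d)`, aligning both strands
5′→3′.  Events within range of several anchors count toward each; anchor
maps used here are sparse enough that this does not occur (see below).

**Normalization.**  Two normalizations are supported and are deliberately
not mixed:

- *Context expectation* (mutations, repair): genome-wide per-trinucleotide
  rates `m_t = events with centered context t / occurrences of t`
  (strand-resolved, both strands, blacklist-maskable), combined with the
  per-position context census over all anchors to give
  `E_i = Σ_t f_t(i) m_t` and enrichment `e_i = O_i / E_i`.  Contexts
  containing N or touching a contig edge are uncountable and excluded
  from both numerator and denominator.
- *Naked-control ratio* (damage): `r_i = (N_i/ΣN)/(D_i/ΣD)`, each raw
  track scaled to its window total first.  Zero-denominator positions are
  masked rather than imputed.  The naked ratio is applied to raw counts
  only; no additional context correction is layered on top, since the
  control carries the identical sequence bias by construction.

**Periodogram.**  Periodicity is estimated with a floating-mean
(generalized) Lomb–Scargle periodogram, computed in closed form
(Zechmeister–Kürster sums) on a uniform frequency grid spanning the
period range; default grids are 100–250 bp (translational) and 5–25 bp
(rotational), 2001 points each, bracketing every period regime of
interest.  The normalized power is the fractional χ² reduction of the
sinusoid-plus-offset least-squares fit, which makes the peak period
exactly the argmin-RSS of a brute-force fit over the same grid — a
property the test suite asserts.  `SNR = peak power / median power`,
excluding grid periods within ±5 % of the peak from the background; the
median is used because the background power distribution is heavy-tailed
under noise.  Significance is judged against the 95th percentile of SNRs
from 200 position-shuffled copies of the same profile (values permuted
across unmasked positions, trigonometric sums reused).  Profiles enter
the periodogram unsmoothed; the 11-bp centered moving average (window
truncated at edges, masked positions excluded from each local mean) is
display-only, since smoothing suppresses the 10-bp rotational component.

**Rotational classification.**  Position `i` maps to cycle coordinate
`c = ((i − φ) mod P)/P` with helical period `P` (default 10.2 bp) and
phase `φ` (offset of the minor-out center nearest the dyad; default 0,
always set explicitly in tests).  Quarter-cycle bins label `c` near 0 as
`minor_out`, near ½ as `minor_in`, and the two transitions
`out_to_in`/`in_to_out` between.  Group summaries average unmasked
enrichment per label over the ±60 bp core.

**Lesion calling.**  Damage-seq: after per-replicate deduplication
(identical chrom/start/end/strand collapse; replicates then concatenated)
a plus-strand read `[s, e)` nominates `s − 1` and a minus-strand read
nominates `e` (the 5′ flank on its strand); the nomination is kept iff
the strand-resolved base is G.  Concordant mate pairs are first merged
to one spanning interval; discordant pairs keep mate 1 (the lesion-
adjacent mate).  tXR-seq: reads of length 22–29 are scanned per length
for the read-internal offset with maximal strand-resolved guanine
frequency (ties to the smallest offset, a deterministic choice); the
lesion is then placed at that offset (`start + o` on plus,
`end − 1 − o` on minus) with no further base filter, since the offset
already encodes the base preference.

**SASA.**  Shrake–Rupley with golden-spiral test points (default 960,
probe 1.4 Å, van der Waals radii C 1.70 / N 1.55 / O 1.52 / P 1.80 /
S 1.80 / H 1.20 Å, configurable).  Occlusion is evaluated in a canonical
structure-intrinsic frame (principal axes of the coordinate covariance,
signs fixed by third moments with a largest-projection fallback), which
makes the quadrature exactly invariant under rigid motion of the input —
a property asserted to 10⁻⁶.  Guanine N2 atoms are grouped by the
rotational label of their dyad-relative nucleotide index (the DNA
residue number in dyad-centered structures); transition labels are
excluded and the minor-out/minor-in groups are compared by medians and a
Mann–Whitney test: exact two-sided p by dynamic-programming enumeration
of the null U distribution when `n_a·n_b ≤ 400` and there are no ties,
otherwise the normal approximation with midrank tie correction and
continuity correction.

## Synthetic data: what it emulates and what it does not

The generator produces a genome from a first-order Markov chain whose
stationary trinucleotide frequencies approximate a 64-entry weight table
(uniform weights reduce to i.i.d. sampling); dyads tiled at the
nucleosome repeat length (default 191 bp) with independent Gaussian
jitter (sd 5 bp) around the arithmetic grid; and per-site independent
Bernoulli events on eligible sites (strand-resolved G for lesions,
pyrimidines for mutations) with intensity

```
λ(site) = base_rate · w_t · (1 + A_t cos(2π d/NRL + φ_t))
                     · (1 + A_r cos(2π d/P_r + φ_r))   if |d| ≤ 60
```

where `d` is the signed distance to the nearest tiled dyad.  Defaults
place the translational peak in linkers (`φ_t = π`, `A_t = 0.3`) and the
rotational peak at minor-out (`φ_r = 0`, `A_r = 0.2`, `P_r = 10.2`),
the qualitative structure the analyses are designed to detect.  The
naked control uses the same formula with both amplitudes zero, so
sequence-context bias is the only cellular/naked difference.  TFBS
placement thins footprint events by a retention factor and duplicates
flank events with probability `enrichment − 1` (hence the factor is
capped at 2).  Read emission inverts the two calling geometries exactly.

**Analyzed dyad subset.**  Real "strongly positioned" nucleosome maps
are sparse — their mean dyad spacing exceeds the 2000-bp analysis
window — so analysis windows around distinct map entries do not overlap.
The generator's dense tiling, by contrast, would count every event in
~10 overlapping windows, making the counting noise itself periodic at
the repeat length (the same fluctuation reappears at lags of ±NRL), which
inflates the null periodogram in a way position-shuffling cannot
reproduce.  Analyses therefore use `select_positioned_dyads` (greedy
subset with spacing ≥ 2101 bp ≥ window width) as the analyzed map, while
the full tiling still defines the chromatin that modulates intensity.
This both matches the real maps' geometry and makes the shuffled-null
SNR test well calibrated.

Not emulated: sequencing error, PCR duplicates, mappability structure,
diploidy, inter-sample heterogeneity, repair kinetics, and any coupling
between sequence and nucleosome positioning.  Passing tests therefore
demonstrate estimator correctness and calibration under the generative
model, not robustness to library artifacts in real data.

## Study-condition sizes

- *Planted-signal experiment*: 5 Mb genome, uniform weights,
  `base_rate = 0.4` (≈1 × 10⁶ cellular events, matched naked control),
  ~2.3 × 10³ positioned dyads.  Sized so the per-position ratio SE
  (≈9 %) leaves the planted 30 % translational and 20 % rotational
  amplitudes overwhelmingly detectable, with the 191 bp peak localized
  to ≪1 bp and the 10.2 bp peak to ≲0.1 bp.
- *Null-calibration experiment*: 60 Mb genome with a G/C-skewed weight
  table, `base_rate = 0.45` (≈2 × 10⁷ events).  The size was set by a
  power analysis done before running: the maximum of ~2000 per-position
  deviations sits near 4 standard errors, so holding `max|e−1|` below
  5 % needs a per-position SE below ~1 %, i.e. ≳8 × 10³ counted events
  per position.
- *TFBS recovery*: 500 sites at 4 kb spacing, 10⁵ background events,
  depletion 0.3, flank enrichment 1.5.  The footprint estimator's SE is
  ≈0.025 at these sizes, so ±0.05 recovery is a ~2σ statement.
- *Shuffled nulls*: 200 permutations throughout.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere in memory; GTF converts
  on read; half-integer motif centers round up on '+' and down on '−'.
- Blacklist distance is the gap to the nearest region edge (0 inside);
  filtering is idempotent and order-preserving; regions are merged
  before search so nested inputs are handled.
- Dyad tiling places centers at `floor(NRL/2 + k·NRL + jitter)`.
- Constant profiles yield ~zero periodogram power and are flagged
  (`degenerate=True`) rather than raised; fewer than 8 unmasked
  positions is an error.
- Expression quartiles are rank quartiles with boundary ties expanded
  inclusively; genes absent from the expression table are unassigned.
- "Within 73 bp" of a dyad is inclusive; every mutation receives exactly
  one nucleosomal/linker label (nearest-dyad distance).
- Signatures are stored L1-normalized; cosine similarity refuses zero
  vectors.
- Flanking-nucleosome peak calling: 11-bp smooth, minimum peak
  separation 120 bp (nucleosome geometry bound), prominence ≥ 0.5 × the
  profile median (avoids shoulder peaks), ±73 bp labeled nucleosome,
  ±100 bp around the feature always excluded.  All configurable.
- Sample de-duplication in pooling follows an explicit ordered priority
  list of sources, not hard-coded names; chromosome order is the
  genome's contig order.  Multi-allelic VCF records keep the first
  alternate; non-SNVs are counted and skipped.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single configuration seed; outputs are byte-identical across reruns.

## Known limitations

- The SNR definition (peak over median off-peak power) is one of several
  in use; absolute SNR values are comparable within this package but not
  across tools with other definitions.
- The rotational phase that maps nucleotide indices to minor-in/minor-out
  in real crystal structures must be supplied (`RotationalConfig.phase`);
  the default 0 is a convention, not a fit to any published structure.
- The tXR-seq offset scan reads sequences from the reference genome, so
  it cannot see mismatches present in the original reads.
- `pearson_window` requires ≥3 jointly unmasked positions and refuses
  constant tracks instead of returning NaN.
- The synthetic nucleosome used in the structural analysis is a
  geometric stand-in (see its docstring); conclusions about real
  structures require a real PDB input via `analysis/08_sasa_structure.py
  --pdb`.
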