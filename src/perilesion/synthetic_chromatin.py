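"""Seeded synthetic chromatin: genomes, dyads, modulated events, reads.

The generator emulates the statistical structure the analysis modules
are built to detect: a genome with controllable trinucleotide
composition, dyads at a nucleosome repeat length (NRL) with jitter,
per-site lesion/mutation intensities modulated sinusoidally at the NRL
(translational, linker enrichment) and -- within the +/-core bp
nucleosome core -- at the DNA helical period (rotational, minor-out
enrichment), a naked-DNA control carrying only sequence-context bias,
TFBS footprints that deplete events centrally and enrich flanks, and
reads emitted under the damage-seq / tXR-seq geometries so the lesion
callers can be round-tripped.

Everything is deterministic per (seed, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .genome_io import GenomeSequence, TRINUC_REVCOMP, trinuc_str_to_code
from .lesion_caller import OffsetTable
from .periodicity import DyadMap

try:  # sequential Markov sampling is the only hot loop
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class TfbsSpec:
    n_sites: int = 0
    motif_length: int = 19
    footprint_depletion: float = 0.3  # event retention prob inside footprint
    flank_enrichment: float = 1.5  # multiplier in flanks (<= 2)
    flank_width: int = 30
    spacing: int = 4000

    def __post_init__(self) -> None:
        if not 0 <= self.footprint_depletion <= 1:
            raise ValueError("footprint_depletion must lie in [0, 1]")
        if not 1 <= self.flank_enrichment <= 2:
            raise ValueError("flank_enrichment must lie in [1, 2]")


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 1_000_000
    contig: str = "chrS"
    trinuc_weights: dict[str, float] | None = None  # None -> uniform
    nrl: float = 191.0
    dyad_jitter_sd: float = 5.0
    translational_amplitude: float = 0.3
    translational_phase: float = math.pi  # peak in linkers, trough at dyad
    rotational_amplitude: float = 0.2
    rotational_period: float = 10.2
    rotational_phase: float = 0.0  # minor-out maximum at the dyad
    core_half_width: int = 60
    base_rate: float = 0.05  # events per eligible strand-site
    event_kind: str = "lesion"  # or "mutation"
    tfbs: TfbsSpec = field(default_factory=TfbsSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("translational_amplitude", "rotational_amplitude"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tfbs = TfbsSpec(**raw.pop("tfbs", {}))
        return cls(tfbs=tfbs, **raw)


_BASES = np.array(list("ACGT"))


def _marginal_transition(weights: np.ndarray) -> np.ndarray:
    """4x4 first-order transition matrix implied by a 64-trinucleotide
    weight table: P(c | b) from summed weights of *b c trinucleotides."""
    w = weights.reshape(4, 4, 4)
    pair = w.sum(axis=0)  # weight of (center, right) pairs
    row = pair.sum(axis=1, keepdims=True)
    uniform = np.full((4, 4), 0.25)
    with np.errstate(invalid="ignore"):
        t = np.where(row > 0, pair / np.maximum(row, 1e-300), uniform)
    return t


if _HAVE_NUMBA:

    @njit(cache=True)
    def _markov_walk(cdf: np.ndarray, u: np.ndarray, first: int) -> np.ndarray:
        n = u.size
        out = np.empty(n + 1, dtype=np.int8)
        out[0] = first
        state = first
        for i in range(n):
            x = u[i]
            row = cdf[state]
            nxt = 0
            while row[nxt] < x and nxt < 3:
                nxt += 1
            out[i + 1] = nxt
            state = nxt
        return out

else:  # pragma: no cover

    def _markov_walk(cdf: np.ndarray, u: np.ndarray, first: int) -> np.ndarray:
        n = u.size
        out = np.empty(n + 1, dtype=np.int8)
        out[0] = first
        state = first
        for i in range(n):
            out[i + 1] = int(np.searchsorted(cdf[state], u[i]))
            state = out[i + 1]
        return out


def weight_array(trinuc_weights: dict[str, float] | None) -> np.ndarray:
    if trinuc_weights is None:
        return np.ones(64)
    w = np.zeros(64)
    for tri, weight in trinuc_weights.items():
        if weight < 0:
            raise ValueError("trinucleotide weights must be nonnegative")
        w[trinuc_str_to_code(tri)] = weight
    if w.sum() == 0:
        raise ValueError("trinucleotide weights must not all be zero")
    return w


def generate_genome(config: SimConfig) -> GenomeSequence:
    """Sample a genome from the first-order Markov chain implied by the
    trinucleotide weight table (uniform weights -> i.i.d. uniform)."""
    rng = np.random.default_rng(config.seed)
    w = weight_array(config.trinuc_weights)
    t = _marginal_transition(w)
    marginal = w.reshape(4, 4, 4).sum(axis=(0, 2))
    marginal = marginal / marginal.sum()
    n = config.genome_length
    if np.allclose(t, 0.25):  # i.i.d. fast path
        codes = rng.choice(4, size=n, p=marginal).astype(np.int8)
    else:
        first = int(rng.choice(4, p=marginal))
        u = rng.random(n - 1)
        codes = _markov_walk(np.cumsum(t, axis=1), u, first)
    ascii_map = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytes(ascii_map[codes.astype(np.int64)]).decode("ascii")
    return GenomeSequence({config.contig: seq})


def place_dyads(config: SimConfig, genome: GenomeSequence) -> DyadMap:
    """Dyads at NRL spacing from nrl/2, plus independent Gaussian jitter,
    clipped to valid positions (duplicates collapse)."""
    rng = np.random.default_rng(config.seed + 1)
    length = genome.length(config.contig)
    if config.nrl >= length:
        raise ValueError("nrl must be smaller than the genome")
    centers = np.arange(config.nrl / 2, length, config.nrl)
    if config.dyad_jitter_sd > 0:
        centers = centers + rng.normal(0, config.dyad_jitter_sd, centers.size)
    pos = np.unique(np.clip(np.floor(centers).astype(np.int64), 0, length - 1))
    return DyadMap({config.contig: pos}, label="synthetic")


def select_positioned_dyads(dyads: DyadMap, min_spacing: int = 2101) -> DyadMap:
    """Sparse 'strongly positioned' subset of a dyad tiling.

    Keeps a greedy subset with pairwise spacing >= min_spacing, so
    analysis windows around the kept dyads do not overlap and no event
    is counted toward more than one dyad.  This mirrors real
    strongly-positioned nucleosome maps, whose mean dyad spacing
    exceeds the 2000-bp analysis window; the full tiling still defines
    the chromatin context that modulates event intensity.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, pos in dyads.by_chrom.items():
        keep = []
        last = -(1 << 62)
        for x in pos:
            if x - last >= min_spacing:
                keep.append(x)
                last = x
        out[chrom] = np.asarray(keep, dtype=np.int64)
    return DyadMap(out, label=f"{dyads.label}_positioned")


def _site_intensity(
    config: SimConfig, d: np.ndarray, trinuc_weight: np.ndarray
) -> np.ndarray:
    """Per-site event intensity given signed distance d to the nearest
    dyad.  The naked control uses the same formula with amplitudes 0."""
    lam = config.base_rate * trinuc_weight
    lam = lam * (
        1
        + config.translational_amplitude
        * np.cos(2 * np.pi * d / config.nrl + config.translational_phase)
    )
    in_core = np.abs(d) <= config.core_half_width
    rot = 1 + config.rotational_amplitude * np.cos(
        2 * np.pi * d / config.rotational_period + config.rotational_phase
    )
    lam = lam * np.where(in_core, rot, 1.0)
    return lam


def _eligible_sites(
    config: SimConfig, genome: GenomeSequence
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pos, strand_is_minus, normalized trinuc weight) of eligible sites.

    Lesions target G on either strand (a minus-strand G reads as C on
    the plus strand); mutations target pyrimidines on either strand.
    The returned weight is the site's trinucleotide weight scaled to
    mean 1 over eligible sites, so base_rate stays interpretable.
    """
    codes = genome.base_codes(config.contig)
    tri = genome.trinuc_codes(config.contig)
    w = weight_array(config.trinuc_weights)
    w = w / w[w > 0].mean() if (w > 0).any() else w
    if config.event_kind == "lesion":
        plus_sel = codes == 2  # G
        minus_sel = codes == 1  # C on plus strand = G on minus strand
    elif config.event_kind == "mutation":
        plus_sel = (codes == 1) | (codes == 3)  # C or T
        minus_sel = (codes == 0) | (codes == 2)  # A or G (pyrimidine on minus)
    else:
        raise ValueError(f"unknown event_kind {config.event_kind!r}")
    out_pos, out_minus, out_w = [], [], []
    for minus, sel in ((False, plus_sel), (True, minus_sel)):
        pos = np.flatnonzero(sel & (tri >= 0))
        t = tri[pos]
        if minus:
            t = TRINUC_REVCOMP[t]
        out_pos.append(pos)
        out_minus.append(np.full(pos.size, minus))
        out_w.append(w[t])
    return (
        np.concatenate(out_pos),
        np.concatenate(out_minus),
        np.concatenate(out_w),
    )


def _signed_distance_to_nearest_dyad(
    pos: np.ndarray, dyads: np.ndarray
) -> np.ndarray:
    j = np.searchsorted(dyads, pos)
    left = np.where(j > 0, pos - dyads[np.clip(j - 1, 0, None)], np.iinfo(np.int64).max)
    right = np.where(
        j < dyads.size, pos - dyads[np.clip(j, None, dyads.size - 1)], -np.iinfo(np.int64).max
    )
    return np.where(np.abs(left) <= np.abs(right), left, right)


def sample_events(
    config: SimConfig,
    genome: GenomeSequence,
    dyads: DyadMap,
    naked: bool = False,
) -> pd.DataFrame:
    """Independent Bernoulli draw per eligible strand-site with the
    modulated intensity; ``naked=True`` zeroes both amplitudes (control
    carrying only sequence-context bias)."""
    cfg = replace(
        config, translational_amplitude=0.0, rotational_amplitude=0.0
    ) if naked else config
    rng = np.random.default_rng(config.seed + (3 if naked else 2))
    pos, minus, w = _eligible_sites(config, genome)
    d = _signed_distance_to_nearest_dyad(pos, dyads.by_chrom[config.contig])
    lam = _site_intensity(cfg, d.astype(float), w)
    if (lam > 1).any():
        raise ValueError(
            f"site intensity exceeds 1 (max {lam.max():.3f}); lower base_rate"
        )
    hit = rng.random(lam.size) < lam
    frame = pd.DataFrame(
        {
            "chrom": config.contig,
            "pos": pos[hit],
            "strand": np.where(minus[hit], "-", "+"),
            "source": "damage_naked" if naked else "damage_cellular",
        }
    )
    if config.event_kind == "mutation":
        frame = _attach_mutation_alleles(frame, genome, rng)
    return frame.sort_values("pos", kind="stable").reset_index(drop=True)


_PYR_ALTS = {"C": np.array(list("AGT")), "T": np.array(list("ACG"))}


def _attach_mutation_alleles(
    frame: pd.DataFrame, genome: GenomeSequence, rng: np.random.Generator
) -> pd.DataFrame:
    refs, alts = [], []
    for row in frame.itertuples(index=False):
        ref = genome.base_at(row.chrom, row.pos, row.strand)
        refs.append(ref)
        alts.append(rng.choice(_PYR_ALTS[ref]))
    out = frame.copy()
    out["ref"] = refs
    out["alt"] = alts
    out["sample"] = "sim"
    return out


def emit_damage_reads(
    lesions: pd.DataFrame,
    genome: GenomeSequence,
    read_length: int = 50,
    replicate: str = "rep1",
) -> tuple[pd.DataFrame, int]:
    """Inverse of the damage-seq calling geometry.

    '+' lesion at p -> read [p+1, p+1+L) on '+'; '-' lesion at p ->
    read [p-L, p) on '-'.  Lesions whose read would leave the contig
    are skipped and counted.
    """
    frames = []
    skipped = 0
    for chrom, group in lesions.groupby("chrom", sort=False):
        n = genome.length(chrom)
        pos = group["pos"].to_numpy(np.int64)
        plus = group["strand"].to_numpy() == "+"
        start = np.where(plus, pos + 1, pos - read_length)
        end = start + read_length
        ok = (start >= 0) & (end <= n)
        skipped += int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": start[ok],
                    "end": end[ok],
                    "strand": np.where(plus[ok], "+", "-"),
                    "replicate": replicate,
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end", "strand", "replicate"])
    )
    return out, skipped


def emit_txr_reads(
    lesions: pd.DataFrame,
    genome: GenomeSequence,
    offsets: OffsetTable,
    length_probs: dict[int, float] | None = None,
    seed: int = 0,
    replicate: str = "rep1",
) -> tuple[pd.DataFrame, int]:
    """Inverse of the tXR-seq calling geometry.

    For each lesion a read length L is drawn from length_probs (uniform
    over the offset table's lengths by default) and the read is placed
    so the lesion sits at offsets[L] in read coordinates on the lesion
    strand.  Contig-edge reads are skipped and counted.
    """
    rng = np.random.default_rng(seed)
    if length_probs is None:
        lengths = np.array(sorted(offsets.offsets))
        probs = np.full(lengths.size, 1 / lengths.size)
    else:
        lengths = np.array(sorted(length_probs))
        missing = [int(L) for L in lengths if L not in offsets]
        if missing:
            raise ValueError(f"offset table lacks read length(s) {missing}")
        probs = np.array([length_probs[L] for L in lengths], dtype=float)
        probs = probs / probs.sum()
    frames = []
    skipped = 0
    for chrom, group in lesions.groupby("chrom", sort=False):
        n = genome.length(chrom)
        pos = group["pos"].to_numpy(np.int64)
        plus = group["strand"].to_numpy() == "+"
        L = lengths[rng.choice(lengths.size, size=pos.size, p=probs)]
        off = np.array([offsets[length] for length in L])
        start = np.where(plus, pos - off, pos + off - (L - 1))
        end = start + L
        ok = (start >= 0) & (end <= n)
        skipped += int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": start[ok],
                    "end": end[ok],
                    "strand": np.where(plus[ok], "+", "-"),
                    "replicate": replicate,
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end", "strand", "replicate"])
    )
    return out, skipped


def place_tfbs(
    config: SimConfig, genome: GenomeSequence, events: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant TFBS footprints: thin events within each footprint by the
    depletion factor, up-sample flank events by the enrichment factor.

    Sites are placed at regular spacing (alternating strand); overlap
    of footprint+flank zones between neighboring sites is an error.
    Returns (standardized midpoint feature table, modified events).
    """
    spec = config.tfbs
    if spec.n_sites == 0:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "feature_class"]), events
    zone = spec.motif_length + 2 * spec.flank_width
    if spec.spacing <= zone:
        raise ValueError("TFBS spacing smaller than footprint+flank zone")
    length = genome.length(config.contig)
    rng = np.random.default_rng(config.seed + 4)
    first = spec.spacing // 2
    mids = np.arange(first, length - spec.spacing // 2, spec.spacing)[: spec.n_sites]
    if mids.size < spec.n_sites:
        raise ValueError("genome too short for requested TFBS count")
    strands = np.where(np.arange(mids.size) % 2 == 0, "+", "-")
    sites = pd.DataFrame(
        {
            "chrom": config.contig,
            "pos": mids,
            "strand": strands,
            "feature_class": "other",
        }
    )
    pos = events["pos"].to_numpy(np.int64)
    j = np.searchsorted(mids, pos)
    nearest = np.where(
        (j > 0)
        & (
            (j >= mids.size)
            | (np.abs(pos - mids[np.clip(j - 1, 0, None)]) <= np.abs(mids[np.clip(j, None, mids.size - 1)] - pos))
        ),
        mids[np.clip(j - 1, 0, None)],
        mids[np.clip(j, None, mids.size - 1)],
    )
    d = np.abs(pos - nearest)
    half_fp = spec.motif_length // 2
    in_fp = d <= half_fp
    in_flank = (d > half_fp) & (d <= half_fp + spec.flank_width)
    u = rng.random(pos.size)
    keep = ~in_fp | (u < spec.footprint_depletion)
    dup = in_flank & (rng.random(pos.size) < (spec.flank_enrichment - 1))
    out = pd.concat([events[keep], events[dup]], ignore_index=True)
    out = out.sort_values("pos", kind="stable").reset_index(drop=True)
    return sites, out
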