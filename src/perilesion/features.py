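"""Feature-relative analysis: TFBS midpoints, TSSs, window profiles,
flanking-nucleosome segmentation, and track correlation.

Transcription-factor binding sites and TSSs are reduced to standardized
single-nucleotide positions so the same dyad-style window counting
applies.  Profiles around features are oriented 5'->3' along the strand
carrying the feature and combined over both strands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .genome_io import (
    BlacklistPolicy,
    GeneRecord,
    GenomicInterval,
    apply_blacklist,
)
from .periodicity import PositionProfile, smooth_profile

#: feature-table columns
FEATURE_COLUMNS = ["chrom", "pos", "strand", "feature_class"]


@dataclass(frozen=True)
class FeatureSite:
    chrom: str
    pos: int  # standardized single-nucleotide midpoint
    strand: str
    feature_class: str = "other"  # {CTCF, SP1, TSS, other}


def features_to_frame(sites: Sequence[FeatureSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.pos, s.strand, s.feature_class) for s in sites],
        columns=FEATURE_COLUMNS,
    )


def standardize_tfbs_midpoint(
    motif: GenomicInterval, feature_class: str = "other"
) -> FeatureSite:
    """Reduce a strand-aware motif interval to a single midpoint.

    Half-base centers (even-length motifs) round up on '+' and down on
    '-', so plus- and minus-strand midpoints of the same even-length
    interval differ by exactly one base.
    """
    if motif.strand not in ("+", "-"):
        raise ValueError("motif must carry a strand")
    center2 = motif.start + motif.end - 1  # 2 * center
    if center2 % 2 == 0:
        mid = center2 // 2
    else:
        mid = (center2 + 1) // 2 if motif.strand == "+" else center2 // 2
    return FeatureSite(motif.chrom, mid, motif.strand, feature_class)


def count_relative_to_features(
    events: pd.DataFrame, features: pd.DataFrame, half_window: int = 1000
) -> PositionProfile:
    """Histogram events over feature-relative positions.

    i = p - midpoint for '+' features and midpoint - p for '-' features
    (5'->3' along the feature strand); event strand is ignored.
    """
    if features.empty:
        raise ValueError("empty feature set")
    hist = np.zeros(2 * half_window + 1, dtype=np.int64)
    for chrom, feats in features.groupby("chrom", sort=False):
        ev = events[events["chrom"] == chrom]
        if ev.empty:
            continue
        pos = np.sort(ev["pos"].to_numpy(np.int64))
        mids = feats["pos"].to_numpy(np.int64)
        minus = feats["strand"].to_numpy() == "-"
        lo = np.searchsorted(pos, mids - half_window, side="left")
        hi = np.searchsorted(pos, mids + half_window, side="right")
        for m, neg, a, b in zip(mids, minus, lo, hi):
            i = pos[a:b] - m
            if neg:
                i = -i
            np.add.at(hist, i + half_window, 1)
    return PositionProfile(half_window, hist, "raw_count", "combined")


@dataclass
class SegmentMap:
    """Per feature-relative position: nucleosome / linker / excluded."""

    half_window: int
    labels: np.ndarray  # array of strings
    peak_positions: np.ndarray  # dyad-peak centers (feature-relative bp)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.half_window, self.half_window + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "label": self.labels})


def call_flanking_nucleosomes(
    dyad_profile: PositionProfile,
    exclusion_bp: int = 100,
    min_separation: int = 120,
    prominence_fraction: float = 0.5,
    core_half_width: int = 73,
    smooth_width: int = 11,
) -> SegmentMap:
    """Segment the window around a feature into nucleosome and linker.

    Smooths the dyad-count profile, finds local maxima separated by at
    least min_separation bp with prominence above prominence_fraction
    of the profile median, labels +/-core_half_width around each peak
    as nucleosome and the rest linker, then overrides positions within
    exclusion_bp of the feature as excluded.
    """
    hw = dyad_profile.half_window
    sm = smooth_profile(dyad_profile, smooth_width)
    median = float(np.median(sm.values))
    peaks, _ = signal.find_peaks(
        sm.values,
        distance=min_separation,
        prominence=max(prominence_fraction * median, 1e-12),
    )
    labels = np.full(2 * hw + 1, "linker", dtype=object)
    if peaks.size == 0:
        warnings.warn("no dyad peaks found; all-linker segment map")
    for p in peaks:
        lo = max(0, p - core_half_width)
        hi = min(2 * hw, p + core_half_width)
        labels[lo : hi + 1] = "nucleosome"
    center = hw
    labels[
        max(0, center - exclusion_bp) : min(2 * hw, center + exclusion_bp) + 1
    ] = "excluded"
    return SegmentMap(hw, labels, peaks - hw)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_window(
    track_a: PositionProfile, track_b: PositionProfile, window_half: int
) -> CorrelationResult:
    """Two-sided Pearson correlation over jointly unmasked positions with
    |i| <= window_half."""
    if (
        track_a.half_window != track_b.half_window
        or track_a.orientation != track_b.orientation
    ):
        raise ValueError("track shape or orientation mismatch")
    a = track_a.restrict(window_half)
    b = track_b.restrict(window_half)
    keep = ~(a.mask | b.mask)
    x, y = a.values[keep], b.values[keep]
    if x.size < 3:
        raise ValueError("fewer than 3 jointly unmasked positions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant track over the window: correlation undefined")
    r, p = stats.pearsonr(x, y, alternative="two-sided")
    return CorrelationResult(float(r), float(p), int(x.size))


def tss_from_annotation(
    genes: Sequence[GeneRecord],
    blacklist: Sequence[GenomicInterval] = (),
    mito_names: Sequence[str] = ("chrM", "MT", "M"),
) -> tuple[pd.DataFrame, int]:
    """TSSs of protein-coding, non-mitochondrial genes.

    '+' gene [s, e) -> TSS at s; '-' gene -> TSS at e-1.  Genes
    overlapping the blacklist are removed (overlap mode).  Records
    without a biotype are skipped and counted.
    Returns (feature table with gene_id column, n_skipped_no_biotype).
    """
    skipped = 0
    rows = []
    for g in genes:
        if g.biotype is None:
            skipped += 1
            continue
        if g.biotype != "protein_coding" or g.chrom in mito_names:
            continue
        rows.append((g.chrom, g.start, g.end, g.strand, g.gene_id))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    if blacklist:
        frame = apply_blacklist(
            frame, blacklist, BlacklistPolicy(mode="overlap_exclusion")
        )
    tss = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "pos": np.where(frame["strand"] == "+", frame["start"], frame["end"] - 1),
            "strand": frame["strand"],
            "feature_class": "TSS",
            "gene_id": frame["gene_id"],
        }
    )
    return tss.reset_index(drop=True), skipped


def stratify_by_expression(
    tss: pd.DataFrame, expression: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Split TSSs into top/bottom expression quartiles by rank.

    ``expression``: columns gene_id, value.  Quartile membership is by
    rank over genes present in the table, with boundary ties expanded
    inclusively; TSSs of genes absent from the table are unassigned.
    """
    if expression.empty:
        raise ValueError("empty expression table")
    if len(expression) < 4:
        raise ValueError("need >= 4 genes for quartiles")
    expr = expression.dropna(subset=["value"]).copy()
    values = expr["value"].to_numpy(float)
    n = len(expr)
    order = np.sort(values)
    lower_cut = order[math.ceil(n / 4) - 1]  # value of the n/4-th smallest
    upper_cut = order[n - math.ceil(n / 4)]
    bottom_genes = set(expr.loc[expr["value"] <= lower_cut, "gene_id"])
    top_genes = set(expr.loc[expr["value"] >= upper_cut, "gene_id"])
    return {
        "top_quartile": tss[tss["gene_id"].isin(top_genes)].reset_index(drop=True),
        "bottom_quartile": tss[tss["gene_id"].isin(bottom_genes)].reset_index(
            drop=True
        ),
    }


#: correlation window presets (half-widths, bp) used in the analyses
CORRELATION_PRESETS = {
    "ctcf_wide": 1000,
    "ctcf_mid": 100,
    "ctcf_narrow": 25,
    "sp1_narrow": 50,
    "sp1_mid": 100,
    "tss_wide": 1000,
}
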