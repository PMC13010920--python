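"""Single-base lesion calling from damage-seq and tXR-seq aligned reads.

Damage-seq chemistry blocks the sequencing polymerase at the adduct, so
the damaged base lies immediately 5' of the aligned read: position
start-1 for a plus-strand read, position ``end`` for a minus-strand read
(the 5' flank on the minus strand).  Candidates are kept only when the
strand-resolved base is guanine, the dominant adduct site.

tXR-seq reads are the ~22-29 nt excision products of nucleotide
excision repair; the lesion sits at a read-length-dependent internal
offset, inferred per length as the offset of maximal guanine frequency.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeSequence

#: read-table columns
READ_COLUMNS = ["chrom", "start", "end", "strand", "replicate"]
#: lesion-table columns
LESION_COLUMNS = ["chrom", "pos", "strand", "source"]


@dataclass(frozen=True)
class AlignedRead:
    chrom: str
    start: int
    end: int
    strand: str
    replicate: str = "rep1"
    mate_rank: str = "merged"  # {1, 2, merged}

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read start {self.start} >= end {self.end}")


@dataclass(frozen=True)
class Lesion:
    chrom: str
    pos: int
    strand: str
    source: str  # {damage_cellular, damage_naked, repair}


def reads_to_frame(reads: Iterable[AlignedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.strand, r.replicate) for r in reads],
        columns=READ_COLUMNS,
    )


def lesions_to_frame(lesions: Iterable[Lesion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.chrom, l.pos, l.strand, l.source) for l in lesions],
        columns=LESION_COLUMNS,
    )


def combine_mates(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse paired-end alignments to single read intervals.

    Expects columns chrom/start/end/strand/replicate/mate (1 or 2) and a
    'concordant' boolean.  A concordant pair becomes one interval
    spanning both mates (on mate 1's strand); discordant pairs keep mate
    1 only, which is the mate adjacent to the lesion.
    """
    conc = pairs[pairs["concordant"]]
    merged = (
        conc.groupby(["chrom", "replicate", "pair_id"], sort=False)
        .agg(
            start=("start", "min"),
            end=("end", "max"),
            strand=("strand", "first"),
        )
        .reset_index()
    )
    disc = pairs[~pairs["concordant"] & (pairs["mate"] == 1)]
    out = pd.concat(
        [merged[READ_COLUMNS], disc[READ_COLUMNS]], ignore_index=True
    )
    return out


def deduplicate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Remove duplicate (chrom,start,end,strand) within each replicate,
    then concatenate replicates (cross-replicate duplicates retained)."""
    return (
        reads.drop_duplicates(subset=["replicate", "chrom", "start", "end", "strand"])
        .reset_index(drop=True)
    )


def call_damage_lesions(
    reads: pd.DataFrame, genome: GenomeSequence, source: str = "damage_cellular"
) -> tuple[pd.DataFrame, int]:
    """Call lesions at the base immediately 5' of each read.

    Returns (lesion table, n_edge_skipped).  Candidates off the contig
    edge are skipped and counted; candidates whose strand-resolved base
    is not G are dropped (not counted as edge skips).
    """
    frames = []
    edge_skipped = 0
    for chrom, group in reads.groupby("chrom", sort=False):
        codes = genome.base_codes(chrom)
        n = codes.size
        plus = group["strand"].to_numpy() == "+"
        pos = np.where(plus, group["start"].to_numpy() - 1, group["end"].to_numpy())
        in_range = (pos >= 0) & (pos < n)
        edge_skipped += int((~in_range).sum())
        pos, plus = pos[in_range], plus[in_range]
        base = codes[pos]
        # G code is 2; a minus-strand G appears as C (code 1) on the plus strand
        is_g = np.where(plus, base == 2, base == 1)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[is_g],
                    "strand": np.where(plus[is_g], "+", "-"),
                    "source": source,
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=LESION_COLUMNS)
    )
    return out, edge_skipped


@dataclass
class OffsetTable:
    """Read length -> 0-based lesion offset within the read (5'->3')."""

    offsets: dict[int, int]

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if not 0 <= off < length:
                raise ValueError(f"offset {off} outside read length {length}")

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    def __contains__(self, length: int) -> bool:
        return length in self.offsets

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.offsets.items()), columns=["read_length", "offset"]
        )

    @classmethod
    def read_tsv(cls, path) -> "OffsetTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(dict(zip(frame["read_length"], frame["offset"])))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def guanine_frequency_by_offset(
    reads: pd.DataFrame, genome: GenomeSequence, length: int
) -> np.ndarray:
    """Fraction of reads of the given length with G at each internal
    offset of the strand-resolved read sequence."""
    sel = reads[(reads["end"] - reads["start"]) == length]
    counts = np.zeros(length)
    total = 0
    for chrom, group in sel.groupby("chrom", sort=False):
        codes = genome.base_codes(chrom)
        n = codes.size
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        ok = (starts >= 0) & (ends <= n)
        starts, ends = starts[ok], ends[ok]
        plus = group["strand"].to_numpy()[ok] == "+"
        total += starts.size
        if starts.size == 0:
            continue
        offs = np.arange(length)
        plus_pos = starts[plus, None] + offs[None, :]
        counts += (codes[plus_pos] == 2).sum(axis=0) if plus.any() else 0
        # minus strand: offset o (5'->3' on read) is genomic end-1-o, G appears as C
        minus_pos = ends[~plus, None] - 1 - offs[None, :]
        counts += (codes[minus_pos] == 1).sum(axis=0) if (~plus).any() else 0
    return counts / total if total else counts


def infer_txr_offset_table(
    reads: pd.DataFrame,
    genome: GenomeSequence,
    length_range: tuple[int, int] = (22, 29),
) -> OffsetTable:
    """Infer the per-length lesion offset as the argmax of guanine
    frequency over read-internal offsets (ties -> smallest offset).

    Lengths outside length_range are ignored; lengths with zero reads
    are absent from the table.
    """
    lo, hi = length_range
    offsets: dict[int, int] = {}
    lengths = reads["end"] - reads["start"]
    for length in range(lo, hi + 1):
        if not (lengths == length).any():
            continue
        freq = guanine_frequency_by_offset(reads, genome, length)
        offsets[length] = int(np.argmax(freq))  # argmax takes first on ties
    return OffsetTable(offsets)


def call_repair_lesions(
    reads: pd.DataFrame,
    offsets: OffsetTable,
    length_range: tuple[int, int] = (22, 29),
) -> tuple[pd.DataFrame, int]:
    """Call repair lesions at the per-length offset.

    Plus-strand read: pos = start + offset; minus-strand: end-1-offset.
    No guanine filter is applied (the offset already encodes the base
    preference).  Reads outside length_range or with a length missing
    from the table are skipped and counted.
    """
    lengths = (reads["end"] - reads["start"]).to_numpy()
    lo, hi = length_range
    known = np.array([length in offsets for length in lengths])
    ok = (lengths >= lo) & (lengths <= hi) & known
    skipped = int((~ok).sum())
    sel = reads[ok]
    sel_len = lengths[ok]
    off = np.array([offsets[length] for length in sel_len], dtype=int)
    plus = sel["strand"].to_numpy() == "+"
    pos = np.where(
        plus, sel["start"].to_numpy() + off, sel["end"].to_numpy() - 1 - off
    )
    out = pd.DataFrame(
        {
            "chrom": sel["chrom"].to_numpy(),
            "pos": pos,
            "strand": np.where(plus, "+", "-"),
            "source": "repair",
        }
    )
    return out.reset_index(drop=True), skipped
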