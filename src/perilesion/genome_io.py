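"""Genome sequence, interval, gene-annotation and blacklist I/O.

Coordinate convention: everything in memory is 0-based, half-open
(BED-style).  GTF input (1-based, closed) is converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = np.array(list("ACGT"))


class GenomeError(ValueError):
    """Malformed genome input or out-of-range lookup."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """In-memory genome: contig name -> upper-case A/C/G/T/N string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        bad = [n for n, s in self.contigs.items() if re.search(r"[^ACGTN]", s)]
        if bad:
            raise GenomeError(f"non-ACGTN characters in contig(s): {bad}")

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def length(self, chrom: str) -> int:
        return len(self.contigs[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.contigs

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.contigs[chrom]
        if not (0 <= start < end <= len(seq)):
            raise GenomeError(
                f"fetch {chrom}:{start}-{end} outside [0, {len(seq)})"
            )
        s = seq[start:end]
        return reverse_complement(s) if strand == "-" else s

    def base_at(self, chrom: str, pos: int, strand: str = "+") -> str:
        return self.fetch(chrom, pos, pos + 1, strand)

    # --- integer base/trinucleotide encodings used by the counting code ---

    def base_codes(self, chrom: str) -> np.ndarray:
        """Per-position base codes A,C,G,T -> 0..3; N -> -1 (int8)."""
        return encode_bases(self.contigs[chrom])

    def trinuc_codes(self, chrom: str) -> np.ndarray:
        """Plus-strand trinucleotide code centered at each position.

        code = 16*b[-1] + 4*b[0] + b[+1]; -1 at edges or where any base is N.
        """
        return trinuc_codes(self.base_codes(chrom))


def encode_bases(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def trinuc_codes(base_codes: np.ndarray) -> np.ndarray:
    n = base_codes.size
    out = np.full(n, -1, dtype=np.int16)
    if n < 3:
        return out
    b0, b1, b2 = base_codes[:-2], base_codes[1:-1], base_codes[2:]
    valid = (b0 >= 0) & (b1 >= 0) & (b2 >= 0)
    codes = 16 * b0.astype(np.int16) + 4 * b1 + b2
    out[1:-1][valid] = codes[valid]
    return out


def trinuc_code_to_str(code: int) -> str:
    return "".join(_CODE_BASE[[code // 16, (code // 4) % 4, code % 4]])


def trinuc_str_to_code(tri: str) -> int:
    return 16 * _BASE_CODE[tri[0]] + 4 * _BASE_CODE[tri[1]] + _BASE_CODE[tri[2]]


# reverse-complement lookup for the 64 trinucleotide codes
def _build_revcomp_table() -> np.ndarray:
    table = np.empty(64, dtype=np.int16)
    for code in range(64):
        tri = trinuc_code_to_str(code)
        table[code] = trinuc_str_to_code(reverse_complement(tri))
    return table


TRINUC_REVCOMP = _build_revcomp_table()


def read_genome(path) -> GenomeSequence:
    """Load a multi-contig FASTA, normalizing bases to upper case."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise GenomeError(f"duplicate contig name: {record.id}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise GenomeError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise GenomeError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def read_intervals(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (file order; missing strand -> '.')."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise GenomeError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            name = fields[3] if len(fields) >= 4 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def trinucleotide_at(
    genome: GenomeSequence, chrom: str, pos: int, strand: str
) -> str | None:
    """3-mer centered on pos, read 5'->3' on the given strand.

    Returns None (uncountable) when the window touches a contig edge or
    contains an N.
    """
    if pos - 1 < 0 or pos + 2 > genome.length(chrom):
        return None
    tri = genome.fetch(chrom, pos - 1, pos + 2, strand)
    return None if "N" in tri else tri


@dataclass(frozen=True)
class BlacklistPolicy:
    flank_bp: int = 1000
    mode: str = "flank_exclusion"  # or "overlap_exclusion"

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if self.mode not in ("flank_exclusion", "overlap_exclusion"):
            raise ValueError(f"unknown blacklist mode {self.mode!r}")


def _regions_by_chrom(
    blacklist: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in blacklist:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by.items():
        pairs.sort()
        merged: list[list[int]] = []
        for s, e in pairs:  # merge so starts and ends are both monotone
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([p[0] for p in merged])
        ends = np.array([p[1] for p in merged])
        out[chrom] = (starts, ends)
    return out


def apply_blacklist(
    sites: pd.DataFrame,
    blacklist: Sequence[GenomicInterval],
    policy: BlacklistPolicy = BlacklistPolicy(),
) -> pd.DataFrame:
    """Filter single-position features (flank mode) or intervals (overlap).

    Flank mode expects a ``pos`` column; a position is removed when the
    gap to the nearest blacklist region edge is <= flank_bp (0 inside a
    region).  Overlap mode expects ``start``/``end`` columns and removes
    any interval intersecting any region.  Order-preserving, idempotent.
    """
    if not blacklist or sites.empty:
        return sites.copy()
    regions = _regions_by_chrom(blacklist)
    keep = np.ones(len(sites), dtype=bool)
    for chrom, group in sites.groupby("chrom", sort=False):
        if chrom not in regions:
            continue
        starts, ends = regions[chrom]
        idx = group.index.to_numpy()
        if policy.mode == "flank_exclusion":
            pos = group["pos"].to_numpy()
            # distance to nearest region: 0 if inside, else gap to edge
            i = np.searchsorted(starts, pos, side="right") - 1
            dist_left = np.where(
                (i >= 0) & (pos < ends[np.clip(i, 0, None)]),
                0,
                np.where(i >= 0, pos - ends[np.clip(i, 0, None)], np.inf),
            )
            j = np.searchsorted(starts, pos, side="right")
            dist_right = np.where(
                j < len(starts), starts[np.clip(j, None, len(starts) - 1)] - pos, np.inf
            )
            dist = np.minimum(dist_left, dist_right)
            keep[sites.index.get_indexer(idx)] &= dist > policy.flank_bp
        else:
            s = group["start"].to_numpy()
            e = group["end"].to_numpy()
            j = np.searchsorted(ends, s, side="right")
            overlaps = (j < len(starts)) & (
                starts[np.clip(j, None, len(starts) - 1)] < e
            )
            keep[sites.index.get_indexer(idx)] &= ~overlaps
    return sites.loc[keep]


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int  # 0-based half-open after conversion from GTF
    end: int
    strand: str
    gene_id: str
    biotype: str | None


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_genes(path) -> list[GeneRecord]:
    """Extract 'gene' feature records from a GTF file.

    Only gene_id and gene_type/gene_biotype attributes are parsed.
    """
    out: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GenomeError(f"{path}:{lineno}: fewer than 9 GTF columns")
            if fields[2] != "gene":
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            biotype = attrs.get("gene_type", attrs.get("gene_biotype"))
            out.append(
                GeneRecord(
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    gene_id=attrs.get("gene_id", f"line{lineno}"),
                    biotype=biotype,
                )
            )
    return out
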