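"""96-context mutational signatures stratified by nucleosome occupancy.

Mutations (pyrimidine-normalized) are binned into the standard 96
categories (6 substitution classes x 16 flanking-base combinations) and
compared between nucleosomal and linker cohorts by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeSequence, trinucleotide_at
from .periodicity import DyadMap

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
FLANKS = tuple(a + b for a in "ACGT" for b in "ACGT")

#: canonical 96-context order: substitution-major, then 5' x 3' flank
CONTEXTS_96 = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in "ACGT" for f3 in "ACGT"
)
_CONTEXT_INDEX = {ctx: k for k, ctx in enumerate(CONTEXTS_96)}


@dataclass
class Signature96:
    """L1-normalized nonnegative weights over the 96 contexts."""

    weights: np.ndarray
    n_mutations: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != 96:
            raise ValueError("signature must have 96 weights")
        if (self.weights < 0).any():
            raise ValueError("negative signature weight")
        total = self.weights.sum()
        if total > 0:
            self.weights = self.weights / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"context": CONTEXTS_96, "weight": self.weights})

    @classmethod
    def from_counts(cls, counts: dict[str, int] | np.ndarray) -> "Signature96":
        if isinstance(counts, dict):
            arr = np.zeros(96)
            for ctx, c in counts.items():
                arr[_CONTEXT_INDEX[ctx]] = c
            n = int(sum(counts.values()))
        else:
            arr = np.asarray(counts, dtype=float)
            n = int(arr.sum())
        return cls(arr, n)


def classify_nucleosomal(
    mutations: pd.DataFrame, dyads: DyadMap, radius: int = 73
) -> np.ndarray:
    """Label each mutation 'nucleosomal' (within radius bp of the nearest
    dyad, inclusive) or 'linker'."""
    if dyads.n_dyads == 0:
        raise ValueError("empty dyad map")
    labels = np.full(len(mutations), "linker", dtype=object)
    for chrom, group in mutations.groupby("chrom", sort=False):
        dy = dyads.by_chrom.get(chrom)
        idx = mutations.index.get_indexer(group.index)
        if dy is None or dy.size == 0:
            continue
        pos = group["pos"].to_numpy(np.int64)
        j = np.searchsorted(dy, pos)
        left = np.where(j > 0, np.abs(pos - dy[np.clip(j - 1, 0, None)]), np.iinfo(np.int64).max)
        right = np.where(j < dy.size, np.abs(dy[np.clip(j, None, dy.size - 1)] - pos), np.iinfo(np.int64).max)
        nearest = np.minimum(left, right)
        labels[idx[nearest <= radius]] = "nucleosomal"
    return labels


def signature96(
    mutations: pd.DataFrame, genome: GenomeSequence
) -> tuple[Signature96, int]:
    """Build a 96-context signature from pyrimidine-normalized SNVs.

    Context is strand-resolved (read on the strand carrying the
    pyrimidine reference).  Mutations whose context touches a contig
    edge or contains N are skipped and counted.
    Returns (signature, n_skipped).
    """
    counts = np.zeros(96)
    skipped = 0
    for row in mutations.itertuples(index=False):
        tri = trinucleotide_at(genome, row.chrom, row.pos, row.strand)
        if tri is None:
            skipped += 1
            continue
        ctx = f"{tri[0]}[{row.ref}>{row.alt}]{tri[2]}"
        if tri[1] != row.ref or ctx not in _CONTEXT_INDEX:
            skipped += 1
            continue
        counts[_CONTEXT_INDEX[ctx]] += 1
    return Signature96(counts, int(counts.sum())), skipped


def cosine_similarity(a: Signature96, b: Signature96) -> float:
    """dot(a, b) / (|a| |b|); errors on zero signatures."""
    na = np.linalg.norm(a.weights)
    nb = np.linalg.norm(b.weights)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero signature")
    return float(a.weights @ b.weights / (na * nb))
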