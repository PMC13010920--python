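"""Somatic SNV parsing, pyrimidine-strand normalization, filtering, pooling.

Every SNV is re-expressed so its reference base is a pyrimidine (C or T):
purine-reference records have both bases complemented and the strand set
to '-', pyrimidine-reference records keep '+'.  This is the standard
convention for trinucleotide signature analysis and makes mutation,
damage and repair tracks directly comparable on the same strand axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")
BASES = frozenset("ACGT")

#: standard event-table columns used across the package
EVENT_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "strand"]


class MutationParseError(ValueError):
    pass


@dataclass(frozen=True)
class MutationRecord:
    chrom: str
    pos: int  # 0-based
    ref: str  # pyrimidine after normalization
    alt: str
    strand: str  # strand carrying the pyrimidine reference
    sample: str = "."

    def __post_init__(self) -> None:
        if self.ref not in PYRIMIDINES:
            raise MutationParseError(f"ref {self.ref!r} not pyrimidine-normalized")
        if self.ref == self.alt:
            raise MutationParseError("ref == alt")


def normalize_to_pyrimidine(
    chrom: str, pos: int, ref: str, alt: str, sample: str = "."
) -> MutationRecord:
    """Express an SNV on the strand carrying the pyrimidine reference."""
    if ref not in BASES or alt not in BASES:
        raise MutationParseError(f"not an SNV: {ref}>{alt}")
    if ref == alt:
        raise MutationParseError(f"ref == alt ({ref})")
    if ref in PYRIMIDINES:
        return MutationRecord(chrom, pos, ref, alt, "+", sample)
    return MutationRecord(chrom, pos, _COMP[ref], _COMP[alt], "-", sample)


def _records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.pos, r.ref, r.alt, r.sample, r.strand) for r in records
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def read_vcf(path, sample_id: str) -> tuple[pd.DataFrame, int]:
    """Read a minimal VCF (CHROM/POS/REF/ALT/FILTER) into an event table.

    Positions are converted to 0-based.  Non-SNV records are skipped and
    counted; only the first alternate allele of multi-allelic records is
    kept.  Returns (frame with a 'filter' column, n_skipped).
    """
    from cyvcf2 import VCF

    rows = []
    skipped = 0
    for v in VCF(str(path)):
        alts = v.ALT or []
        if len(v.REF) != 1 or not alts or len(alts[0]) != 1:
            skipped += 1
            continue
        ref, alt = v.REF.upper(), alts[0].upper()
        if ref not in BASES or alt not in BASES or ref == alt:
            skipped += 1
            continue
        filt = v.FILTER if v.FILTER is not None else "PASS"
        rows.append((v.CHROM, v.POS - 1, ref, alt, sample_id, filt))
    frame = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample", "filter"]
    )
    return frame, skipped


def read_maf(path) -> tuple[pd.DataFrame, int]:
    """Read a MAF-like TSV with at least
    Chromosome/Start_Position/Reference_Allele/Tumor_Seq_Allele2/
    Tumor_Sample_Barcode columns (1-based positions)."""
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {
        "Chromosome": "chrom",
        "Start_Position": "pos",
        "Reference_Allele": "ref",
        "Tumor_Seq_Allele2": "alt",
        "Tumor_Sample_Barcode": "sample",
    }
    missing = [c for c in cols if c not in raw.columns]
    if missing:
        raise MutationParseError(f"MAF file missing columns: {missing}")
    frame = raw[list(cols)].rename(columns=cols)
    frame["pos"] = frame["pos"].astype(int) - 1
    is_snv = frame["ref"].isin(BASES) & frame["alt"].isin(BASES)
    is_snv &= frame["ref"] != frame["alt"]
    skipped = int((~is_snv).sum())
    frame = frame[is_snv].copy()
    frame["filter"] = "PASS"
    return frame, skipped


def normalize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized pyrimidine-strand normalization of an event table."""
    ref = frame["ref"].to_numpy()
    alt = frame["alt"].to_numpy()
    purine = pd.Series(ref).isin(["A", "G"]).to_numpy()
    out = frame.copy()
    comp = lambda arr: pd.Series(arr).map(_COMP).to_numpy()  # noqa: E731
    out["ref"] = pd.Series(ref).where(~purine, comp(ref)).to_numpy()
    out["alt"] = pd.Series(alt).where(~purine, comp(alt)).to_numpy()
    out["strand"] = pd.Series(["+"] * len(frame)).where(~purine, "-").to_numpy()
    return out


def pool_events(
    sources: Sequence[tuple[str, pd.DataFrame]],
    filter_pass: bool = True,
    priority: Sequence[str] | None = None,
    contig_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pool pyrimidine-normalized SNV tables into one sorted table.

    sources: (source_name, frame) pairs; frames carry a 'filter' column.
    When the same sample appears in several sources and ``priority``
    lists the source names, only the highest-priority source's records
    for that sample are kept.  Sorting is by (contig order, position),
    stable; contig order defaults to first-appearance order.
    """
    frames = []
    seen_samples: dict[str, str] = {}
    order = list(priority) if priority else [name for name, _ in sources]
    for name, frame in sorted(
        sources, key=lambda kv: order.index(kv[0]) if kv[0] in order else len(order)
    ):
        frame = frame.copy()
        if filter_pass and "filter" in frame.columns:
            frame = frame[frame["filter"] == "PASS"]
        keep_samples = []
        for sample in frame["sample"].unique():
            if sample in seen_samples and seen_samples[sample] != name:
                continue  # already supplied by a higher-priority source
            seen_samples[sample] = name
            keep_samples.append(sample)
        frames.append(frame[frame["sample"].isin(keep_samples)])
    pooled = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=EVENT_COLUMNS
    )
    if "strand" not in pooled.columns:
        pooled = normalize_frame(pooled)
    if contig_order is None:
        contig_order = list(dict.fromkeys(pooled["chrom"]))
    rank = {c: i for i, c in enumerate(contig_order)}
    pooled["_rank"] = pooled["chrom"].map(rank)
    pooled = pooled.sort_values(["_rank", "pos"], kind="stable").drop(columns="_rank")
    return pooled.reset_index(drop=True)[
        [c for c in EVENT_COLUMNS if c in pooled.columns]
        + [c for c in pooled.columns if c not in EVENT_COLUMNS]
    ]


def write_events_bed(frame: pd.DataFrame, path) -> None:
    """Write the internal 6-column BED-like table (chrom, pos, pos+1,
    ref>alt, sample, strand)."""
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t"
                f"{row.ref}>{row.alt}\t{row.sample}\t{row.strand}\n"
            )
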