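import numpy as np
import pandas as pd
import pytest

from perilesion.genome_io import GenomeSequence, reverse_complement
from perilesion.lesion_caller import (
    OffsetTable,
    call_damage_lesions,
    call_repair_lesions,
    combine_mates,
    deduplicate_reads,
    guanine_frequency_by_offset,
    infer_txr_offset_table,
)
from perilesion.synthetic_chromatin import (
    SimConfig,
    emit_damage_reads,
    emit_txr_reads,
    generate_genome,
)
from perilesion.experiments import random_guanine_lesions


def reads(*rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "replicate"]
    )


class TestDeduplicate:
    def test_duplicates_within_replicate_collapse(self):
        out = deduplicate_reads(
            reads(("c1", 10, 60, "+", "A"), ("c1", 10, 60, "+", "A"))
        )
        assert len(out) == 1

    def test_cross_replicate_duplicates_retained(self):
        out = deduplicate_reads(
            reads(("c1", 10, 60, "+", "A"), ("c1", 10, 60, "+", "B"))
        )
        assert len(out) == 2

    def test_empty_replicate_contributes_nothing(self):
        out = deduplicate_reads(reads(("c1", 10, 60, "+", "A")))
        assert len(out) == 1


class TestCombineMates:
    def test_concordant_pair_spans_both_mates(self):
        pairs = pd.DataFrame(
            [
                ("c1", 100, 150, "+", "r1", "p1", 1, True),
                ("c1", 180, 230, "+", "r1", "p1", 2, True),
                ("c1", 500, 550, "-", "r1", "p2", 1, False),
                ("c1", 900, 950, "-", "r1", "p2", 2, False),
            ],
            columns=[
                "chrom", "start", "end", "strand", "replicate",
                "pair_id", "mate", "concordant",
            ],
        )
        out = combine_mates(pairs)
        spans = set(zip(out["start"], out["end"]))
        assert ("c1", 100, 230) not in spans  # chrom not in tuple
        assert (100, 230) in spans  # merged concordant pair
        assert (500, 550) in spans  # discordant mate 1 only
        assert (900, 950) not in spans


class TestDamageCalling:
    #                0123456789
    GENOME = GenomeSequence({"c1": "AGCGTACGTG" * 20})

    def test_plus_strand_lesion_is_base_5prime_of_read(self):
        g = GenomeSequence({"c1": "A" * 99 + "G" + "C" * 100})
        called, _ = call_damage_lesions(reads(("c1", 100, 150, "+", "r")), g)
        assert list(zip(called["pos"], called["strand"])) == [(99, "+")]

    def test_minus_strand_lesion_at_read_end(self):
        # plus-strand base at 150 is C, i.e. G on the minus strand
        g = GenomeSequence({"c1": "A" * 150 + "C" + "A" * 100})
        called, _ = call_damage_lesions(reads(("c1", 100, 150, "-", "r")), g)
        assert list(zip(called["pos"], called["strand"])) == [(150, "-")]

    def test_non_guanine_flank_yields_no_lesion(self):
        g = GenomeSequence({"c1": "A" * 300})
        called, _ = call_damage_lesions(reads(("c1", 100, 150, "+", "r")), g)
        assert called.empty

    def test_edge_candidates_skipped_and_counted(self):
        g = GenomeSequence({"c1": "G" * 200})
        called, skipped = call_damage_lesions(
            reads(("c1", 0, 50, "+", "r"), ("c1", 150, 200, "-", "r")), g
        )
        assert skipped == 2 and called.empty

    def test_every_called_lesion_sits_on_strand_guanine(self, rng):
        cfg = SimConfig(genome_length=50_000, seed=5)
        genome = generate_genome(cfg)
        pos = rng.integers(60, 49_940, 500)
        strand = np.where(rng.random(500) < 0.5, "+", "-")
        frame = reads(*[("chrS", int(p), int(p) + 40, s, "r") for p, s in zip(pos, strand)])
        called, _ = call_damage_lesions(frame, genome)
        for row in called.itertuples(index=False):
            assert genome.base_at(row.chrom, row.pos, row.strand) == "G"

    def test_strand_mirror_symmetry(self):
        """Complementing the genome and flipping read strands maps plus
        calls onto minus calls at mirrored coordinates."""
        cfg = SimConfig(genome_length=10_000, seed=3)
        genome = generate_genome(cfg)
        seq = genome.contigs["chrS"]
        flipped = GenomeSequence({"chrS": reverse_complement(seq)})
        n = len(seq)
        frame = reads(("chrS", 1000, 1050, "+", "r"), ("chrS", 2000, 2060, "+", "r"))
        mirrored = reads(
            *[
                ("chrS", n - row.end, n - row.start, "-", "r")
                for row in frame.itertuples(index=False)
            ]
        )
        a, _ = call_damage_lesions(frame, genome)
        b, _ = call_damage_lesions(mirrored, flipped)
        assert sorted(n - 1 - b["pos"]) == sorted(a["pos"])


class TestTxrOffsets:
    def test_constructed_maximum_recovered(self):
        # 50 reads of length 26 with G planted at offset 6 on an A background
        seq = ["A"] * 10_000
        starts = [100 + 30 * k for k in range(50)]
        for s in starts:
            seq[s + 6] = "G"
        genome = GenomeSequence({"c1": "".join(seq)})
        frame = reads(*[("c1", s, s + 26, "+", "r") for s in starts])
        table = infer_txr_offset_table(frame, genome, (22, 29))
        assert table.offsets == {26: 6}

    def test_tie_breaks_to_smallest_offset(self):
        seq = ["A"] * 1000
        seq[100 + 3] = "G"
        seq[100 + 7] = "G"
        genome = GenomeSequence({"c1": "".join(seq)})
        frame = reads(("c1", 100, 122, "+", "r"))
        freq = guanine_frequency_by_offset(frame, genome, 22)
        assert freq[3] == freq[7] == 1.0
        table = infer_txr_offset_table(frame, genome, (22, 29))
        assert table.offsets[22] == 3

    def test_out_of_range_lengths_ignored(self):
        genome = GenomeSequence({"c1": "G" * 1000})
        frame = reads(("c1", 100, 121, "+", "r"))  # length 21
        table = infer_txr_offset_table(frame, genome, (22, 29))
        assert table.offsets == {}

    def test_offset_outside_read_rejected(self):
        with pytest.raises(ValueError):
            OffsetTable({26: 26})


class TestRepairCalling:
    TABLE = OffsetTable({26: 6})

    def test_plus_strand_arithmetic(self):
        called, _ = call_repair_lesions(reads(("c1", 200, 226, "+", "r")), self.TABLE)
        assert list(zip(called["pos"], called["strand"])) == [(206, "+")]

    def test_minus_strand_mirror(self):
        called, _ = call_repair_lesions(reads(("c1", 200, 226, "-", "r")), self.TABLE)
        assert list(zip(called["pos"], called["strand"])) == [(219, "-")]

    def test_unknown_length_skipped_and_counted(self):
        called, skipped = call_repair_lesions(
            reads(("c1", 200, 230, "+", "r")), self.TABLE
        )
        assert called.empty and skipped == 1


class TestRoundTrips:
    def test_damage_emit_then_call_is_identity(self):
        cfg = SimConfig(genome_length=200_000, seed=8)
        genome = generate_genome(cfg)
        lesions = random_guanine_lesions(genome, 2000, seed=9)
        emitted, skipped = emit_damage_reads(lesions, genome, read_length=50)
        called, _ = call_damage_lesions(emitted, genome)
        assert skipped == 0
        got = sorted(zip(called["pos"], called["strand"]))
        want = sorted(zip(lesions["pos"], lesions["strand"]))
        assert got == want

    def test_txr_emit_then_infer_recovers_planted_offsets(self):
        cfg = SimConfig(genome_length=300_000, seed=21)
        genome = generate_genome(cfg)
        planted = OffsetTable({L: (L // 3) for L in range(22, 30)})
        lesions = random_guanine_lesions(genome, 1600, seed=22)
        emitted, _ = emit_txr_reads(lesions, genome, planted, seed=23)
        inferred = infer_txr_offset_table(emitted, genome, (22, 29))
        assert inferred.offsets == planted.offsets

    def test_txr_emit_rejects_length_missing_from_table(self):
        genome = generate_genome(SimConfig(genome_length=10_000, seed=1))
        lesions = random_guanine_lesions(genome, 10, seed=2)
        with pytest.raises(ValueError, match="30"):
            emit_txr_reads(
                lesions, genome, OffsetTable({26: 6}), length_probs={30: 1.0}
            )
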