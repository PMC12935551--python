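"""IRR detection, locus assignment, spanning calls and genotyping."""

import random

import numpy as np
import pytest

from strmosaic.catalog import (
    RepeatCatalogEntry,
    index_by_chrom,
    read_catalog,
    write_catalog,
)
from strmosaic.harvest import (
    AMBIGUOUS,
    IrrCall,
    assign_locus,
    call_spanning,
    detect_irrs,
    find_irr_pairs,
    genotype_sample,
    harvest,
)
from strmosaic.motif import reverse_complement
from strmosaic.simulate import simulate_mosaic, simulate_reads, to_read_records

from conftest import make_read


def _entry(locus="L1", chrom="chr1", start=1000, end=1054, motif="CAG"):
    return RepeatCatalogEntry(
        locus_id=locus,
        chrom=chrom,
        start=start,
        end=end,
        motif=motif,
        ref_units=(end - start) // len(motif),
        left_flank="TTGACCTGAATGCACTGGTCAAGGCTTCAC",
        right_flank="GGATCCTTAGCTACCTGGAACTGATCGGAT",
    )


class TestCatalogIO:
    def test_roundtrip(self, tmp_path):
        entries = [_entry(), _entry(locus="L2", start=5000, end=5030, motif="AAAG")]
        path = tmp_path / "catalog.tsv"
        write_catalog(entries, path)
        back = read_catalog(path)
        assert back == sorted(entries, key=lambda e: e.start)

    def test_motif_canonicalized_on_load(self, tmp_path):
        path = tmp_path / "catalog.tsv"
        write_catalog([_entry(motif="CTG")], path)
        assert read_catalog(path)[0].motif == "AGC"

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            _entry(start=100, end=100)


class TestDetectIrrs:
    def test_pure_tiling_emits_single_best_call(self):
        read = make_read(("AAAG" * 38)[:151])
        calls = detect_irrs([read], {"CAG", "AAAG"})
        assert len(calls) == 1
        assert calls[0].motif == "AAAG"
        assert calls[0].purity_value == pytest.approx(1.0)

    def test_random_read_not_called(self, rng):
        read = make_read("".join(rng.choice(list("ACGT"), size=151)))
        assert detect_irrs([read], {"CAG", "AAAG"}) == []

    def test_specificity_on_random_reads(self, rng):
        """Monte-Carlo: random 151-mers essentially never reach tau=0.95."""
        reads = [
            make_read("".join(seq), read_id=f"r{i}/1", fragment=f"r{i}")
            for i, seq in enumerate(rng.choice(list("ACGT"), size=(20_000, 151)))
        ]
        calls = detect_irrs(reads, {"CAG"}, tau=0.95)
        assert len(calls) / len(reads) <= 0.001

    def test_sensitivity_inside_repeat(self):
        reads = [
            make_read(("CAG" * 51)[rot : rot + 151], read_id=f"r{rot}/1")
            for rot in range(3)
        ]
        assert len(detect_irrs(reads, {"CAG"})) == 3


class TestAssignLocus:
    def setup_method(self):
        self.index = index_by_chrom([_entry()])

    def _irr(self):
        return IrrCall(
            read_id="r1/1", fragment_id="r1", mate_index=1,
            sample_id="S1", motif="AGC", purity_value=1.0,
        )

    def test_mate_within_window_assigned(self):
        mate = make_read("A" * 151, chrom="chr1", pos=649, mate=2)  # gap 200
        irr = assign_locus(self._irr(), mate, self.index, window_bp=500)
        assert irr.assigned_locus == "L1"
        assert irr.assignment_distance == 200

    def test_mate_too_far_unassigned(self):
        mate = make_read("A" * 151, chrom="chr1", pos=3054 + 1849, mate=2)
        irr = assign_locus(self._irr(), mate, self.index, window_bp=500)
        assert irr.assigned_locus is None
        assert irr.unassigned_reason == "no-locus-in-window"

    def test_two_candidate_loci_ambiguous(self):
        index = index_by_chrom([_entry(), _entry(locus="L2", start=1500, end=1530)])
        mate = make_read("A" * 151, chrom="chr1", pos=1200, mate=2)
        irr = assign_locus(self._irr(), mate, index, window_bp=500)
        assert irr.assigned_locus is None
        assert irr.unassigned_reason == "ambiguous-locus"

    def test_unmapped_mate(self):
        mate = make_read("A" * 151, mate=2)
        mate.mapped = False
        irr = assign_locus(self._irr(), mate, self.index, window_bp=500)
        assert irr.unassigned_reason == "mate-unmapped"

    def test_never_assigns_across_motif_classes(self):
        index = index_by_chrom([_entry(motif="AAAG")])
        mate = make_read("A" * 151, chrom="chr1", pos=1000, mate=2)
        irr = assign_locus(self._irr(), mate, index, window_bp=500)  # AGC class
        assert irr.assigned_locus is None


class TestIrrPairs:
    def _call(self, frag, mate, motif="AGC", locus=None, sample="S1"):
        return IrrCall(
            read_id=f"{frag}/{mate}", fragment_id=frag, mate_index=mate,
            sample_id=sample, motif=motif, purity_value=1.0,
            assigned_locus=locus,
        )

    def test_pair_inherits_unique_anchored_locus(self):
        calls = [
            self._call("f1", 1), self._call("f1", 2),
            self._call("f2", 1, locus="L1"),
        ]
        pairs = find_irr_pairs(calls)
        assert len(pairs) == 1
        assert pairs[0].assigned_locus == "L1"

    def test_two_anchored_loci_give_ambiguous_pair(self):
        calls = [
            self._call("f1", 1), self._call("f1", 2),
            self._call("f2", 1, locus="L1"), self._call("f3", 1, locus="L2"),
        ]
        assert find_irr_pairs(calls)[0].assigned_locus == AMBIGUOUS

    def test_single_irr_mate_is_not_a_pair(self):
        assert find_irr_pairs([self._call("f1", 1)]) == []


class TestCallSpanning:
    def test_exact_allele(self):
        e = _entry()
        read = make_read(e.left_flank[-20:] + "CAG" * 10 + e.right_flank[:20])
        call = call_spanning(read, e)
        assert call.unit_count == 10
        assert call.bp_length == 30
        assert call.interruptions == []
        assert call.left_anchor_len == 20
        assert call.right_anchor_len == 20

    def test_interrupted_unit_recorded(self):
        # 18 units with the ninth reading CAT: the interrupted-allele class
        e = _entry()
        tract = "CAG" * 8 + "CAT" + "CAG" * 9
        read = make_read(e.left_flank[-20:] + tract + e.right_flank[:20])
        call = call_spanning(read, e)
        assert call.unit_count == 18
        assert call.interruptions == [(9, "CAT")]

    def test_reverse_orientation_recovered(self):
        e = _entry()
        read = make_read(
            reverse_complement(e.left_flank[-20:] + "CAG" * 12 + e.right_flank[:20])
        )
        call = call_spanning(read, e)
        assert call.unit_count == 12
        assert call.orientation == "-"

    def test_missing_right_anchor_returns_none(self):
        e = _entry()
        read = make_read(e.left_flank[-20:] + "CAG" * 40)
        assert call_spanning(read, e) is None

    def test_too_many_interruptions_rejected(self):
        e = _entry()
        tract = "CAT" * 4 + "CAG" * 10
        read = make_read(e.left_flank[-20:] + tract + e.right_flank[:20])
        assert call_spanning(read, e, max_interruptions=3) is None

    def test_short_flank_configuration_error(self):
        e = RepeatCatalogEntry(
            locus_id="L", chrom="c", start=0, end=3, motif="CAG",
            ref_units=1, left_flank="ACGTA", right_flank="ACGTA",
        )
        with pytest.raises(ValueError):
            call_spanning(make_read("ACGT" * 40), e, min_anchor_bp=10)


class TestGenotype:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({10: 14, 17: 12, 11: 1}, (10, 17)),
            ({10: 20}, (10, 10)),
            ({10: 20, 11: 2}, (10, 10)),  # 2 < max(2, 0.2*20)
        ],
    )
    def test_allele_rules(self, counts, expected, entry):
        calls = []
        for units, n in counts.items():
            for i in range(n):
                c = _spanning_stub(units, f"r{units}_{i}")
                calls.append(c)
        gt = genotype_sample(calls, min_support=2, minor_frac=0.2)
        assert gt.alleles == expected

    def test_insufficient_support(self):
        assert genotype_sample([_spanning_stub(10, "r0")], min_support=2) is None

    def test_read_order_invariance(self):
        calls = [_spanning_stub(u, f"r{i}") for i, u in enumerate([10] * 5 + [17] * 4)]
        shuffled = calls.copy()
        random.Random(0).shuffle(shuffled)
        assert genotype_sample(calls).alleles == genotype_sample(shuffled).alleles


def _spanning_stub(units, read_id):
    from strmosaic.harvest import SpanningCall

    return SpanningCall(
        locus_id="L1", sample_id="S1", read_id=read_id,
        unit_count=units, bp_length=units * 3, interruptions=[],
        left_anchor_len=10, right_anchor_len=10,
        repeat_end_offset=10 + units * 3, tract_start_offset=10,
        motif_variant="CAG", orientation="+",
    )


class TestHarvestDriver:
    def test_zero_error_spanning_recovers_truth(self, clean_config, rng):
        """Simulator truth oracle: every spanning call matches its molecule."""
        reads = []
        for i, units in enumerate((8, 14, 23)):
            mix = [[(units, 1.0)]]
            reads += simulate_reads(f"S{i}", mix, clean_config, rng)
        records = to_read_records(reads, clean_config)
        result = harvest(records, [clean_config.catalog_entry()])
        truth = {r.read_id: r.source_units for r in reads}
        assert result.spanning_calls, "expected some spanning reads"
        for call in result.spanning_calls:
            assert call.unit_count == truth[call.read_id]

    def test_read_order_invariance(self, clean_config, rng):
        mix = simulate_mosaic((12, 25), 50, clean_config)
        reads = simulate_reads("S0", mix, clean_config, rng)
        records = to_read_records(reads, clean_config)
        shuffled = records.copy()
        random.Random(1).shuffle(shuffled)
        r1 = harvest(records, [clean_config.catalog_entry()])
        r2 = harvest(shuffled, [clean_config.catalog_entry()])
        assert [c.read_id for c in r1.spanning_calls] == [
            c.read_id for c in r2.spanning_calls
        ]
        assert r1.genotypes == r2.genotypes

    def test_assignment_distance_bounded(self, clean_config, rng):
        cfg = clean_config
        reads = simulate_reads("S0", [[(120, 1.0)]], cfg, rng)
        result = harvest(to_read_records(reads, cfg), [cfg.catalog_entry()])
        for call in result.irr_calls:
            if call.assigned_locus:
                assert call.assignment_distance <= 500
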