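"""RepeatMasker parsing, repeat filtering, satellite search and merging."""

import numpy as np
import pytest

from karyoscan.assembly_io import SequenceRecord
from karyoscan.centromere_scan import (
    RepeatRecord,
    SuperRegion,
    call_centromeres,
    filter_repeats,
    merge_and_collapse,
    predict_centromeres,
    read_repeatmasker_out,
    search_satellite_monomers,
    select_centromeric,
)
from karyoscan.telomere_scan import revcomp

RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching repeat\n"
    "score  div. del. ins.  sequence  begin end (left)     repeat class/family begin end (left) ID\n"
    "\n"
)

PLUS_LINE = "  463   1.3  0.6  1.7  chr1  1001  1300  (698700)  +  SAT1  Satellite/centr  1  300  (50)  1\n"
C_LINE = "  400  10.0  0.0  0.0  chr1  5001  5200  (694800)  C  SAT2  Satellite/centr  (20)  320  101  2\n"


class TestReadRepeatmaskerOut:
    def test_plus_strand_consensus_arithmetic(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER + PLUS_LINE)
        (rec,) = read_repeatmasker_out(p)
        assert (rec.seq_id, rec.start, rec.end) == ("chr1", 1000, 1300)
        assert rec.strand == "+"
        assert rec.consensus_aligned == 300
        assert rec.consensus_length == 350
        assert rec.pct_div == 1.3

    def test_c_strand_swapped_columns(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER + C_LINE)
        (rec,) = read_repeatmasker_out(p)
        assert rec.strand == "-"
        assert rec.consensus_aligned == 320 - 101 + 1
        assert rec.consensus_length == 320 + 20
        assert rec.repeat_name == "SAT2"

    def test_headers_only_is_empty(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER)
        assert read_repeatmasker_out(p) == []

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER + "  463  1.3  0.6\n")
        with pytest.raises(ValueError, match="line 4"):
            read_repeatmasker_out(p)


def _repeat(pct_div=10.0, aligned=300, length=300):
    return RepeatRecord("c", 0, aligned, "+", "R", "Satellite/centr",
                        pct_div, aligned, length, 100.0)


class TestFilterRepeats:
    @pytest.mark.parametrize(
        "pct_div,aligned,length,kept",
        [
            (40.0, 300, 300, True),   # divergence boundary kept
            (41.0, 300, 300, False),  # above boundary removed
            (10.0, 200, 300, False),  # 66.7% of consensus removed
            (10.0, 210, 300, True),   # 70.0% exactly kept
        ],
    )
    def test_boundaries(self, pct_div, aligned, length, kept):
        recs = [_repeat(pct_div, aligned, length)]
        assert bool(filter_repeats(recs)) is kept

    def test_empty_and_subset_property(self, rng):
        assert filter_repeats([]) == []
        recs = [_repeat(float(rng.uniform(0, 80)), int(rng.integers(50, 300)), 300)
                for _ in range(200)]
        kept = filter_repeats(recs)
        assert set(id(r) for r in kept) <= set(id(r) for r in recs)
        # order independence
        back = filter_repeats(recs[::-1])
        assert {id(r) for r in back} == {id(r) for r in kept}

    def test_select_centromeric_by_class_or_name(self):
        sat = _repeat()
        line = RepeatRecord("c", 0, 100, "+", "SSC-CEN-1", "Unknown", 5.0, 100, 100, 50.0)
        assert select_centromeric([sat, line]) == [sat]
        both = select_centromeric([sat, line], name_pattern="CEN")
        assert both == [sat, line]


class TestSearchSatelliteMonomers:
    def test_exact_tandem_copies(self, rng):
        monomer = "".join(rng.choice(list("ACGT"), size=340))
        flank = "".join(rng.choice(list("ACGT"), size=2000))
        seq = SequenceRecord("c", flank + monomer * 20 + flank)
        hits = search_satellite_monomers(seq, [SequenceRecord("m", monomer)])
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].start, plus[0].end) == (2000, 2000 + 20 * 340)
        assert plus[0].identity == 1.0

    def test_no_seed_no_hits(self, rng):
        monomer = "".join(rng.choice(list("ACGT"), size=100))
        seq = SequenceRecord("c", "AC" * 3000)
        assert search_satellite_monomers(seq, [SequenceRecord("m", monomer)]) == []

    def test_reverse_strand_detected(self, rng):
        monomer = "".join(rng.choice(list("ACGT"), size=200))
        seq = SequenceRecord("c", "".join(rng.choice(list("ACGT"), size=500))
                             + revcomp(monomer * 10)
                             + "".join(rng.choice(list("ACGT"), size=500)))
        hits = search_satellite_monomers(seq, [SequenceRecord("m", monomer)])
        minus = [h for h in hits if h.strand == "-"]
        assert minus and minus[0].end - minus[0].start == 2000

    def test_mutated_copies_recovered(self, rng):
        monomer = "".join(rng.choice(list("ACGT"), size=340))
        recovered = 0
        for rep in range(10):
            array = list(monomer * 15)
            hit_mask = rng.random(len(array)) < 0.10
            bases = np.array(list("ACGT"))
            for i in np.flatnonzero(hit_mask):
                array[i] = str(bases[(np.searchsorted(bases, array[i]) + 1) % 4])
            seq = SequenceRecord(
                "c",
                "".join(rng.choice(list("ACGT"), size=1000)) + "".join(array)
                + "".join(rng.choice(list("ACGT"), size=1000)),
            )
            hits = search_satellite_monomers(seq, [SequenceRecord("m", monomer)])
            covered = sum(h.end - h.start for h in hits if h.strand == "+")
            if covered >= 0.9 * 15 * 340:
                assert all(0.8 < h.identity <= 1.0 for h in hits if h.strand == "+")
                recovered += 1
        assert recovered >= 9

    def test_short_monomer_rejected(self):
        with pytest.raises(ValueError):
            search_satellite_monomers(SequenceRecord("c", "ACGT" * 100),
                                      [SequenceRecord("m", "ACGTACGT")])


def merge_bruteforce(intervals, dist):
    """O(n^2) transitive-closure oracle."""
    groups = [[iv] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = (min(s for s, _ in groups[i]), max(e for _, e in groups[i]))
                b = (min(s for s, _ in groups[j]), max(e for _, e in groups[j]))
                if a[0] <= b[1] + dist and b[0] <= a[1] + dist:
                    groups[i] += groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g)) for g in groups
    )


class TestMergeAndCollapse:
    def test_empty(self):
        assert merge_and_collapse([]) == []

    def test_worked_example(self):
        out = merge_and_collapse([(0, 3000), (3400, 6000), (7000, 7200)], 500)
        assert [(r.start, r.end) for r in out] == [(0, 6000), (7000, 7200)]
        assert out[0].n_merged == 2

    def test_idempotent(self):
        once = merge_and_collapse([(0, 3000), (3400, 6000), (7000, 7200)], 500)
        twice = merge_and_collapse(once, 500)
        assert [(r.start, r.end) for r in twice] == [(r.start, r.end) for r in once]

    def test_matches_bruteforce_on_random_sets(self, rng):
        for _ in range(1000):
            n = int(rng.integers(0, 30))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 20_000))
                ivs.append((s, s + int(rng.integers(1, 3000))))
            dist = int(rng.integers(0, 1000))
            got = [(r.start, r.end) for r in merge_and_collapse(ivs, dist)]
            assert got == merge_bruteforce(ivs, dist)
            # output separation invariant
            assert all(b[0] - a[1] > dist for a, b in zip(got, got[1:]))

    def test_sources_unioned(self):
        regions = [
            SuperRegion("c", 0, 100, frozenset({"a"})),
            SuperRegion("c", 150, 300, frozenset({"b"})),
        ]
        (merged,) = merge_and_collapse(regions, 500)
        assert merged.sources == {"a", "b"}


class TestCallCentromeres:
    def test_strict_5kb_boundary(self):
        regions = [SuperRegion("c", 0, 5000), SuperRegion("c", 10_000, 16_000)]
        calls = call_centromeres(regions)
        assert [(c.start, c.end) for c in calls] == [(10_000, 16_000)]

    def test_worked_merge_then_call(self):
        merged = merge_and_collapse([(0, 3000), (3400, 6000), (7000, 7200)], 500)
        calls = call_centromeres(merged)
        assert len(calls) == 1 and calls[0].length == 6000

    def test_predict_from_planted_array(self, default_genome):
        _, records, _, truth = default_genome
        hits = search_satellite_monomers(
            records, [SequenceRecord("mono", truth.monomer)]
        )
        calls, summary = predict_centromeres({"monomer_search": hits})
        by_seq = {c.seq_id: c for c in calls}
        for chrom, start, end in truth.centromeres:
            call = by_seq[chrom]
            assert call.start <= start and end <= call.end
        assert summary["n_merged_regions"] >= len(truth.centromeres)
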