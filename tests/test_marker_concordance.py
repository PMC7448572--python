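"""Rank assignment, Spearman concordance, spacing and probe placement."""

import numpy as np
import pandas as pd
import pytest

from karyoscan.assembly_io import SequenceRecord
from karyoscan.marker_concordance import (
    assign_ranks,
    dotplot_export,
    karyotype_order,
    marker_spacing,
    normalize_chrom,
    place_probes_exact,
    spearman_rho,
)
from karyoscan.telomere_scan import revcomp


def avg_ranks(values):
    """Independent average-rank transform (no scipy)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5


def spearman_oracle(x, y):
    return pearson(avg_ranks(x), avg_ranks(y))


def _pairs(manifest_ranks, assembly_ranks):
    return pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(len(manifest_ranks))],
         "manifest_rank": manifest_ranks, "assembly_rank": assembly_ranks}
    )


class TestKaryotypeOrder:
    def test_numeric_then_sex(self):
        assert karyotype_order(["2", "10", "1", "X"]) == ["1", "2", "10", "X"]

    def test_sex_mt_scaffold_convention(self):
        assert karyotype_order(["X", "Y", "MT", "AEMK02000361.1"]) == [
            "X", "Y", "MT", "AEMK02000361.1"
        ]

    def test_scaffolds_sort_after_chromosomes(self):
        out = karyotype_order(["scaffold_10", "scaffold_2", "3", "X"])
        assert out == ["3", "X", "scaffold_2", "scaffold_10"]

    def test_permutation_invariant(self, rng):
        names = [str(i) for i in range(1, 19)] + ["X", "Y", "MT"] + [
            f"ctg{i}" for i in range(80)
        ]
        base = karyotype_order(names)
        for _ in range(10):
            shuffled = list(rng.permutation(names))
            assert karyotype_order(shuffled) == base

    def test_normalize_chrom_dialects(self):
        assert normalize_chrom("SSC1") == "1"
        assert normalize_chrom("chrX") == "X"
        assert normalize_chrom("7") == "7"
        assert normalize_chrom("SSC12", aliases={"SSC12": "12"}) == "12"


def _manifest(rows):
    return pd.DataFrame(rows, columns=["marker_id", "chip", "manifest_chrom", "manifest_pos"])


def _placements(rows):
    return pd.DataFrame(rows, columns=["marker_id", "assembly_chrom", "assembly_pos"])


class TestAssignRanks:
    def test_identity_order(self):
        man = _manifest([(f"m{i}", "c", "1", i * 100) for i in range(5)])
        plc = _placements([(f"m{i}", "1", i * 100) for i in range(5)])
        out = assign_ranks(man, plc)
        assert list(out["assembly_rank"]) == [1, 2, 3, 4, 5]

    def test_unmapped_penalty(self):
        man = _manifest([(f"m{i}", "c", "1", i * 100) for i in range(5)])
        plc = _placements([(f"m{i}", "1", i * 100) for i in range(5) if i != 2])
        out = assign_ranks(man, plc)
        assert list(out["assembly_rank"]) == [1, 2, -1, 3, 4]

    def test_inverted_chromosome_block_reversed(self):
        man = _manifest(
            [(f"a{i}", "c", "1", i * 100) for i in range(3)]
            + [(f"b{i}", "c", "2", i * 100) for i in range(4)]
        )
        plc = _placements(
            [(f"a{i}", "1", i * 100) for i in range(3)]
            + [(f"b{i}", "2", (3 - i) * 100) for i in range(4)]  # inverted chr2
        )
        out = assign_ranks(man, plc)
        assert list(out["assembly_rank"]) == [1, 2, 3, 7, 6, 5, 4]

    def test_unknown_placement_warns_and_ignored(self):
        man = _manifest([(f"m{i}", "c", "1", i) for i in range(3)])
        plc = _placements([("m0", "1", 0), ("ghost", "1", 5), ("m1", "1", 10), ("m2", "1", 20)])
        with pytest.warns(UserWarning):
            out = assign_ranks(man, plc)
        assert list(out["assembly_rank"]) == [1, 2, 3]


class TestSpearmanRho:
    def test_identity_is_one(self):
        rep = spearman_rho(_pairs([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]))
        assert rep.rho == pytest.approx(1.0)
        assert rep.n_unmapped == 0

    def test_penalty_worked_example(self):
        # y ranks become (2,3,1,4,5): cov 7, variances 10 and 10 -> 0.7
        rep = spearman_rho(_pairs([1, 2, 3, 4, 5], [1, 2, -1, 3, 4]))
        assert rep.rho == pytest.approx(0.7, abs=1e-12)
        assert rep.n_unmapped == 1

    def test_full_reversal_is_minus_one(self):
        rep = spearman_rho(_pairs([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]))
        assert rep.rho == pytest.approx(-1.0)

    def test_matches_oracle_with_penalty_ties(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 50))
            x = list(rng.permutation(np.arange(1, n + 1)).astype(float))
            mapped = rng.random(n) > 0.25
            if mapped.sum() < 2:
                continue
            y = np.full(n, -1.0)
            y[mapped] = rng.permutation(np.arange(1, int(mapped.sum()) + 1))
            if len(set(y)) < 2:
                continue
            rep = spearman_rho(_pairs(x, list(y)))
            assert rep.rho == pytest.approx(spearman_oracle(x, list(y)), abs=1e-12)

    def test_matches_textbook_formula_no_ties(self, rng):
        # for n <= 8 permutations without ties: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        for _ in range(200):
            n = int(rng.integers(3, 9))
            x = np.arange(1, n + 1, dtype=float)
            y = rng.permutation(x)
            d2 = ((x - y) ** 2).sum()
            expected = 1 - 6 * d2 / (n * (n**2 - 1))
            assert spearman_rho(_pairs(list(x), list(y))).rho == pytest.approx(
                expected, abs=1e-12
            )

    def test_zero_variance_reported_undefined(self):
        rep = spearman_rho(_pairs([1, 2, 3], [-1, -1, -1]))
        assert np.isnan(rep.rho)


class TestMarkerSpacing:
    def test_single_spacing(self):
        plc = _placements([("a", "1", 0), ("b", "1", 1000)])
        rep = marker_spacing(plc)
        assert rep.mean_spacing == 1000
        assert rep.sd_spacing == 0

    def test_two_spacings(self):
        plc = _placements([("a", "1", 0), ("b", "1", 1000), ("c", "1", 3000)])
        rep = marker_spacing(plc)
        assert rep.mean_spacing == pytest.approx(1500)
        assert rep.sd_spacing == pytest.approx(np.std([1000, 2000], ddof=1))
        assert (rep.max_desert_start, rep.max_desert_end) == (1000, 3000)

    def test_never_across_chromosomes(self):
        plc = _placements(
            [("a", "1", 0), ("b", "1", 500), ("c", "2", 10_000_000), ("d", "2", 10_000_500)]
        )
        rep = marker_spacing(plc)
        assert rep.mean_spacing == 500
        assert rep.n_spacings == 2

    def test_translation_and_scale_invariance(self, rng):
        pos = np.sort(rng.integers(0, 1_000_000, size=30))
        plc = _placements([(f"m{i}", "1", int(p)) for i, p in enumerate(pos)])
        base = marker_spacing(plc)
        shifted = _placements([(f"m{i}", "1", int(p) + 7777) for i, p in enumerate(pos)])
        scaled = _placements([(f"m{i}", "1", int(p) * 3) for i, p in enumerate(pos)])
        assert marker_spacing(shifted).mean_spacing == base.mean_spacing
        assert marker_spacing(shifted).sd_spacing == base.sd_spacing
        assert marker_spacing(scaled).mean_spacing == pytest.approx(3 * base.mean_spacing)
        assert marker_spacing(scaled).sd_spacing == pytest.approx(3 * base.sd_spacing)

    def test_too_few_markers(self):
        with pytest.raises(ValueError):
            marker_spacing(_placements([("a", "1", 0)]))


class TestPlaceProbesExact:
    def _genome(self, rng):
        return [SequenceRecord("1", "".join(rng.choice(list("ACGT"), size=5000)))]

    def test_unique_probe_mapped_at_start(self, rng):
        recs = self._genome(rng)
        probe = recs[0].sequence[1000:1070]
        man = pd.DataFrame(
            {"marker_id": ["p1"], "chip": ["c"], "manifest_chrom": ["1"],
             "manifest_pos": [1000], "probe_seq": [probe]}
        )
        out = place_probes_exact(recs, man)
        assert out.loc[0, "unique"]
        assert out.loc[0, "assembly_pos"] == 1000

    def test_duplicate_occurrence_unmapped(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        dup = seq[100:170]
        recs = [SequenceRecord("1", seq + dup + seq[2000:])]
        man = pd.DataFrame(
            {"marker_id": ["p1"], "chip": ["c"], "manifest_chrom": ["1"],
             "manifest_pos": [100], "probe_seq": [dup]}
        )
        out = place_probes_exact(recs, man)
        assert not out.loc[0, "unique"]
        assert pd.isna(out.loc[0, "assembly_chrom"])

    def test_reverse_complement_only_maps_minus(self, rng):
        recs = self._genome(rng)
        probe = revcomp(recs[0].sequence[2000:2070])
        man = pd.DataFrame(
            {"marker_id": ["p1"], "chip": ["c"], "manifest_chrom": ["1"],
             "manifest_pos": [2000], "probe_seq": [probe]}
        )
        out = place_probes_exact(recs, man)
        assert out.loc[0, "unique"] and out.loc[0, "strand"] == "-"
        assert out.loc[0, "assembly_pos"] == 2000
        anchored = place_probes_exact(recs, man, anchor="three_prime")
        assert anchored.loc[0, "assembly_pos"] == 2000


class TestDotplotExport:
    def test_rows_and_penalty(self, tmp_path):
        man = _manifest([(f"m{i}", "c", "1", i * 10) for i in range(5)])
        plc = _placements([(f"m{i}", "1", i * 10) for i in range(5) if i != 3])
        pairs = assign_ranks(man, plc)
        out = dotplot_export(pairs, tmp_path / "dot.tsv")
        assert len(out) == 5
        assert (out["assembly_rank"] == -1).sum() == 1
        assert "facet_chrom" in out.columns
        assert (tmp_path / "dot.tsv").exists()

    def test_inversion_visible_as_decreasing_block(self):
        man = _manifest(
            [(f"a{i}", "c", "1", i * 10) for i in range(10)]
            + [(f"b{i}", "c", "2", i * 10) for i in range(10)]
        )
        plc = _placements(
            [(f"a{i}", "1", i * 10) for i in range(10)]
            + [(f"b{i}", "2", (9 - i) * 10) for i in range(10)]
        )
        out = dotplot_export(assign_ranks(man, plc))
        block = out[out["facet_chrom"] == "2"]["assembly_rank"].to_numpy()
        assert (np.diff(block) < 0).all()
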