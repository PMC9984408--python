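"""Allele tables, outcome classes, window summaries, editor comparison."""

import numpy as np
import pandas as pd
import pytest

from beamplicon.alleles import (AlleleTable, WindowSpec, build_allele_table,
                                classify_alleles, compare_editors,
                                editable_efficiencies, editable_positions,
                                max_position_efficiency,
                                simultaneous_fraction, window_summary)
from beamplicon.io import Read
from beamplicon.quant import iter_usable_alignments, quantify
from conftest import perfect_read, read_with_bases

# protospacer GTACATCGATCAGTACCTAG: As at 3,5,9,12,15,19; Cs at 4,7,11,16,17


def _table(site, reads):
    alns = list(iter_usable_alignments(reads, site))
    return build_allele_table(alns, site)


class TestBuildAlleleTable:
    def test_all_reference_single_entry(self, plus_site):
        t = _table(plus_site, [perfect_read(plus_site, f"r{i}")
                               for i in range(6)])
        assert t.entries == [(plus_site.protospacer, False, 6)]
        assert t.n_total == 6

    def test_mixture_sorted_by_count(self, plus_site):
        reads = ([perfect_read(plus_site, f"r{i}") for i in range(6)]
                 + [read_with_bases(plus_site, {5: "G"}, f"a{i}")
                    for i in range(3)]
                 + [read_with_bases(plus_site, {5: "G", 7: "T"}, "b0")])
        t = _table(plus_site, reads)
        assert [e[2] for e in t.entries] == [6, 3, 1]
        assert t.entries[0][0] == plus_site.protospacer
        assert t.entries[1][0][4] == "G"
        assert t.entries[2][0][4] == "G" and t.entries[2][0][6] == "T"

    def test_deletion_flags_has_indel(self, plus_site):
        off = plus_site.positions[10]
        seq = plus_site.amplicon[:off] + plus_site.amplicon[off + 1:]
        t = _table(plus_site, [Read(id="d", sequence=seq,
                                    qualities=[40] * len(seq))])
        assert t.entries[0][1] is True
        assert "-" in t.entries[0][0]

    def test_mutant_type_count_with_frequency_floor(self, plus_site):
        reads = ([perfect_read(plus_site, f"r{i}") for i in range(6)]
                 + [read_with_bases(plus_site, {5: "G"}, f"a{i}")
                    for i in range(3)]
                 + [read_with_bases(plus_site, {3: "G"}, "c0")])
        t = _table(plus_site, reads)
        assert t.n_mutant_types(min_frequency=0.0) == 2
        assert t.n_mutant_types(min_frequency=0.25) == 1  # floor drops c0


class TestClassifyAlleles:
    def _fixture_table(self, plus_site):
        proto = plus_site.protospacer
        entries = [
            (proto, False, 4),                                   # unedited
            (_sub(proto, {5: "G"}), False, 2),                   # only A->G
            (_sub(proto, {7: "T"}), False, 1),                   # only C->T
            (_sub(proto, {5: "G", 7: "T"}), False, 1),           # simultaneous
            (_sub(proto, {2: "C"}), False, 1),                   # other subst
            (_sub(proto, {5: "G"}), True, 1),                    # indel
        ]
        return AlleleTable(site=plus_site, entries=entries, n_total=10)

    def test_classes_match_brute_force(self, plus_site):
        t = self._fixture_table(plus_site)
        c = classify_alleles(t)
        # independent per-entry classification
        expected = {"unedited": 0, "only_a2g": 0, "only_c2t": 0,
                    "simultaneous": 0, "other_subst": 0, "indel": 0}
        a_pos = editable_positions(plus_site, "A")
        c_pos = editable_positions(plus_site, "C")
        for seq, has_indel, n in t.entries:
            if has_indel:
                expected["indel"] += n
                continue
            a = any(seq[p - 1] == "G" for p in a_pos)
            cc = any(seq[p - 1] == "T" for p in c_pos)
            if a and cc:
                expected["simultaneous"] += n
            elif a:
                expected["only_a2g"] += n
            elif cc:
                expected["only_c2t"] += n
            elif seq != plus_site.protospacer:
                expected["other_subst"] += n
            else:
                expected["unedited"] += n
        assert c.as_dict() == {**expected, "n_total": 10}

    def test_partition_sums_to_total(self, plus_site):
        c = classify_alleles(self._fixture_table(plus_site))
        assert c.n_total == 10

    def test_position_set_outside_protospacer_raises(self, plus_site):
        with pytest.raises(ValueError, match="outside protospacer"):
            classify_alleles(self._fixture_table(plus_site),
                             a_positions={5, 21})

    def test_restricted_windows_change_qualification(self, plus_site):
        t = self._fixture_table(plus_site)
        # restrict A window away from position 5: its A5G becomes other_subst
        c = classify_alleles(t, a_positions={3}, c_positions={7})
        assert c.only_a2g == 0
        assert c.other_subst == 1 + 2  # previous other + the two A5G alleles

    def test_simultaneous_fraction(self, plus_site):
        c = classify_alleles(self._fixture_table(plus_site))
        assert simultaneous_fraction(c) == pytest.approx(10.0)


def _sub(proto, changes):
    seq = list(proto)
    for pos, base in changes.items():
        seq[pos - 1] = base
    return "".join(seq)


class TestMatrixSummaries:
    def test_max_position_matches_exhaustive_scan(self, plus_site, rng):
        for _ in range(10):
            reads = [perfect_read(plus_site, f"r{i}") for i in range(5)]
            for pos, k in zip((3, 5, 9, 15), rng.integers(0, 6, size=4)):
                reads += [read_with_bases(plus_site, {pos: "G"}, f"e{pos}_{i}")
                          for i in range(int(k))]
            m = quantify(reads, plus_site)
            pos, val = max_position_efficiency(m, ("A", "G"))
            effs = editable_efficiencies(m, ("A", "G"))
            best = max(effs.values())
            assert val == pytest.approx(best)
            assert pos == min(p for p, v in effs.items() if v == best)

    def test_window_summary_means_and_skips(self):
        effs = {"site1": {3: 40.0, 5: 60.0}, "site2": {12: 10.0},
                "site3": {14: 30.0}}
        w = WindowSpec.from_range(2, 9, "A2-A9")
        s = window_summary(effs, w)
        assert s.per_site == {"site1": 50.0}
        assert sorted(s.skipped_sites) == ["site2", "site3"]
        w2 = WindowSpec.from_range(10, 15, "A10-A15")
        s2 = window_summary(effs, w2)
        assert s2.median == pytest.approx(20.0)
        assert s2.range == (10.0, 30.0)


class TestCompareEditors:
    def _frames(self):
        idx = [f"site{i}" for i in range(6)]
        x = pd.DataFrame(np.arange(1.0, 19.0).reshape(6, 3),
                         index=idx, columns=[4, 5, 6])
        return x

    def test_identity_gives_fold_one_and_p_one(self):
        x = self._frames()
        cmp = compare_editors(x, x.copy(),
                              windows=[WindowSpec.from_range(4, 6)])
        assert np.allclose(cmp.fold, 1.0)
        assert cmp.window_pvalues["4-6"] == 1.0

    def test_all_greater_exact_signed_rank(self):
        x = self._frames()
        y = x + 5.0  # strictly greater at every site, n=6 pairs
        cmp = compare_editors(x, y, windows=[WindowSpec.from_range(4, 6)])
        assert cmp.window_pvalues["4-6"] == pytest.approx(2 / 2 ** 6)
        assert (cmp.fold > 1).all()

    def test_fold_nan_where_mean_x_zero(self):
        x = self._frames()
        x[4] = 0.0
        cmp = compare_editors(x, x + 1.0)
        assert np.isnan(cmp.fold[0])

    def test_mismatched_positions_raise(self):
        x = self._frames()
        y = x.copy()
        y.columns = [4, 5, 7]
        with pytest.raises(ValueError, match="different positions"):
            compare_editors(x, y)
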