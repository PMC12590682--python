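"""Identity filtering and the unique/total/shared counting modes."""

import numpy as np
import pysam
import pytest
from hypothesis import given, strategies as st

from microcat import (
    AlignmentGroup,
    AlignmentRecord,
    alignment_identity,
    count_sam,
    count_shared,
    count_total,
    count_unique,
    filter_alignments,
    load_groups,
)
from microcat.counting import FAST_MIN_IDENTITY, CountingError, FilterStats


def rec(read, gene, alen=80, nm=0):
    return AlignmentRecord(read_id=read, gene_id=gene, aligned_length=alen, edit_distance=nm)


def groups_of(*gene_lists):
    return [
        AlignmentGroup(f"r{i}", [rec(f"r{i}", g) for g in genes])
        for i, genes in enumerate(gene_lists)
    ]


class TestIdentityFilter:
    @pytest.mark.parametrize(
        "alen,nm,expected",
        [(80, 0, 1.0), (80, 4, 0.95), (80, 5, 0.9375), (100, 2, 0.98)],
    )
    def test_identity_value(self, alen, nm, expected):
        assert alignment_identity(rec("r", "g", alen, nm)) == pytest.approx(expected)

    def test_threshold_keeps_best_drops_rest(self):
        records = [rec("r1", "g1", 100, 1), rec("r1", "g2", 100, 7)]  # 0.99, 0.93
        (group,) = filter_alignments(records, min_identity=0.95)
        assert group.gene_ids == ["g1"]

    def test_read_below_threshold_dropped_and_counted(self):
        stats = FilterStats()
        records = [rec("r1", "g1", 80, 5)]  # 0.9375
        assert list(filter_alignments(records, 0.95, stats)) == []
        assert stats.n_retained == 0 and stats.n_dropped_identity == 1

    def test_boundary_alignment_at_threshold_is_kept(self):
        (group,) = filter_alignments([rec("r1", "g1", 80, 4)], 0.95)  # exactly 0.95
        assert group.gene_ids == ["g1"]

    def test_fast_mode_is_stricter(self):
        records = [rec("r1", "g1", 100, 4)]  # identity 0.96: passes complete, not fast
        assert len(list(filter_alignments(records, 0.95))) == 1
        assert list(filter_alignments(records, FAST_MIN_IDENTITY)) == []

    def test_best_alignment_per_gene_deduplicated(self):
        records = [rec("r1", "g1", 80, 2), rec("r1", "g1", 80, 0)]
        (group,) = filter_alignments(records, 0.95)
        assert len(group.records) == 1
        assert group.records[0].edit_distance == 0


class TestCountingModes:
    def test_unique_excludes_multimapped(self):
        gs = groups_of(["g1"], ["g1"], ["g1"], ["g1", "g2"])
        assert count_unique(gs).counts == {"g1": 3}

    def test_unique_empty_and_all_multimapped(self):
        assert count_unique([]).counts == {}
        gs = groups_of(*[["g1", "g2"]] * 10)
        assert count_unique(gs).counts == {}

    def test_total_credits_every_gene(self):
        gs = groups_of(["g1"], ["g1"], ["g1"], ["g1", "g2"])
        assert count_total(gs).counts == {"g1": 4, "g2": 1}

    def test_shared_proportional_apportionment(self):
        gs = groups_of(["g1"], ["g1"], ["g1"], ["g2"], ["g1", "g2"])
        shared = count_shared(gs).counts
        assert shared["g1"] == pytest.approx(3 + 0.75)
        assert shared["g2"] == pytest.approx(1 + 0.25)

    def test_shared_even_split_without_unique_anchor(self):
        gs = groups_of(["g1", "g2", "g3"])
        shared = count_shared(gs).counts
        assert shared == pytest.approx({"g1": 1 / 3, "g2": 1 / 3, "g3": 1 / 3})

    @given(
        st.lists(
            st.sets(st.sampled_from(["g1", "g2", "g3", "g4", "g5"]), min_size=1, max_size=4),
            max_size=40,
        )
    )
    def test_shared_invariants(self, gene_sets):
        gs = groups_of(*[sorted(s) for s in gene_sets])
        unique = count_unique(gs).counts
        total = count_total(gs).counts
        shared = count_shared(gs).counts
        # conservation of read mass
        assert sum(shared.values()) == pytest.approx(len(gs), abs=1e-9 * max(len(gs), 1))
        # unique <= shared <= total per gene
        for g in total:
            assert unique.get(g, 0) - 1e-9 <= shared.get(g, 0) <= total[g] + 1e-9

    def test_shared_equals_total_when_all_unique(self):
        gs = groups_of(["g1"], ["g2"], ["g1"])
        assert count_shared(gs).counts == pytest.approx(count_total(gs).counts)

    def test_shared_oracle_on_random_fixture(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(8)]
        gs = groups_of(
            *[
                sorted(rng.choice(genes, size=rng.integers(1, 4), replace=False))
                for _ in range(50)
            ]
        )
        shared = count_shared(gs).counts
        # independent naive apportionment, read by read
        unique = {}
        for g in gs:
            if len(g.records) == 1:
                unique[g.records[0].gene_id] = unique.get(g.records[0].gene_id, 0) + 1
        oracle = {}
        for g in gs:
            gene_ids = [r.gene_id for r in g.records]
            if len(gene_ids) == 1:
                oracle[gene_ids[0]] = oracle.get(gene_ids[0], 0.0) + 1.0
            else:
                denom = sum(unique.get(x, 0) for x in gene_ids)
                for x in gene_ids:
                    w = unique.get(x, 0) / denom if denom else 1 / len(gene_ids)
                    oracle[x] = oracle.get(x, 0.0) + w
        assert shared == pytest.approx(oracle)


class TestSamInput:
    def _write_sam(self, path, rows, paired=False):
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": f"g{i}", "LN": 500} for i in range(5)]}
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for name, gene, nm, flag in rows:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = name
                a.flag = flag
                a.reference_id = fh.get_tid(gene)
                a.reference_start = 0
                a.mapping_quality = 40
                a.cigarstring = "80M"
                a.query_sequence = "A" * 80
                a.query_qualities = [30] * 80
                if nm is not None:
                    a.set_tag("NM", nm)
                fh.write(a)

    def test_counts_from_sam(self, tmp_path):
        sam = tmp_path / "x.sam"
        self._write_sam(
            sam,
            [("r1", "g0", 0, 0), ("r2", "g0", 0, 0), ("r3", "g0", 0, 0), ("r3", "g1", 2, 256)],
        )
        counts, stats = count_sam(sam, mode="total")
        assert counts.counts == {"g0": 3, "g1": 1}
        assert stats.n_retained == 3

    def test_ungrouped_sam_demands_name_sort(self, tmp_path):
        sam = tmp_path / "x.sam"
        self._write_sam(sam, [("r1", "g0", 0, 0), ("r2", "g1", 0, 0), ("r1", "g2", 0, 0)])
        with pytest.raises(CountingError, match="name-sort"):
            count_sam(sam)

    def test_missing_nm_rejected_with_counter(self, tmp_path):
        sam = tmp_path / "x.sam"
        self._write_sam(sam, [("r1", "g0", None, 0), ("r2", "g1", 0, 0)])
        groups, stats = load_groups(sam)
        assert stats.n_missing_nm == 1
        assert [g.read_id for g in groups] == ["r2"]

    def test_duplicates_excluded_secondary_included(self, tmp_path):
        sam = tmp_path / "x.sam"
        self._write_sam(sam, [("r1", "g0", 0, 1024), ("r2", "g1", 0, 0), ("r2", "g2", 0, 256)])
        counts, _ = count_sam(sam, mode="total")
        assert counts.counts == {"g1": 1, "g2": 1}

    def test_mates_counted_independently(self, tmp_path):
        sam = tmp_path / "x.sam"
        # flags: 0x1 paired + 0x40 read1 = 65 ; 0x1 + 0x80 read2 = 129
        self._write_sam(sam, [("r1", "g0", 0, 65), ("r1", "g0", 0, 129)])
        counts, stats = count_sam(sam, mode="unique")
        assert counts.counts == {"g0": 2}
        assert stats.n_retained == 2
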