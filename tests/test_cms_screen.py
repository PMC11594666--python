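import itertools

import numpy as np
import pytest

from mitocms.cms_screen import (
    OrfClassification,
    build_report,
    classify_chimeric,
    find_specific_orfs,
    rank_candidates,
    venn_counts,
)
from mitocms.mito_io import CircularGenome, GeneModel, Interval
from mitocms.orf_caller import OrfRecord, find_orfs


def make_orf(orf_id, start, end, protein="M" + "A" * 110, strand="+", wraps=False):
    nt = (end - start) if not wraps else None
    return OrfRecord(
        id=orf_id,
        interval=Interval(start, end, wraps),
        strand=strand,
        frame=start % 3,
        start_codon="ATG",
        nt_length=3 * (len(protein) + 1),
        aa_length=len(protein),
        protein=protein,
    )


def make_gene(name, start, end, strand="+"):
    return GeneModel(name, "protein_coding", strand, [Interval(start, end)])


class TestSpecificOrfs:
    def test_identical_genomes_give_empty_set(self, default_pair):
        orfs = find_orfs(default_pair["maintainer"])
        assert find_specific_orfs(orfs, orfs) == set()

    def test_planted_novel_orf_detected(self, default_pair):
        cms_orfs = find_orfs(default_pair["cms"])
        mnt_orfs = find_orfs(default_pair["maintainer"])
        specific = find_specific_orfs(cms_orfs, mnt_orfs)
        by_id = {o.id: o for o in cms_orfs}
        assert {by_id[i].protein for i in specific} == default_pair["truth"].proteins()

    def test_exact_mode_symmetry(self, default_pair):
        cms_orfs = find_orfs(default_pair["cms"])
        mnt_orfs = find_orfs(default_pair["maintainer"])
        cms_specific = find_specific_orfs(cms_orfs, mnt_orfs)
        mnt_specific = find_specific_orfs(mnt_orfs, cms_orfs)
        cms_prot = {o.protein for o in cms_orfs if o.id in cms_specific}
        mnt_prot = {o.protein for o in mnt_orfs if o.id in mnt_specific}
        assert not cms_prot & mnt_prot

    def test_identity_mode_tolerates_point_mutation(self):
        a = make_orf("a", 0, 336, protein="M" + "A" * 110)
        mutated = "M" + "A" * 50 + "V" + "A" * 59
        b = make_orf("b", 0, 336, protein=mutated)
        assert find_specific_orfs([a], [b], mode="exact") == {"a"}
        assert find_specific_orfs([a], [b], mode="identity") == set()

    def test_unknown_mode_error(self):
        with pytest.raises(ValueError):
            find_specific_orfs([], [], mode="fuzzy")


class TestClassifyChimeric:
    def test_window_boundary_500_in_501_out(self):
        gene = make_gene("rpl5", 2000, 2600)
        for gap, expected in ((500, True), (501, False)):
            orf = make_orf("o", 2000 - gap - 336, 2000 - gap)
            cls = classify_chimeric(orf, [gene], 10_000)
            assert cls.ch_flag is expected
            assert cls.gap_bp == gap

    def test_fig3d_distances(self, fig3d):
        L = fig3d.cms_genome.length
        conserved = [g for g in fig3d.cms_annotations if g.category == "protein_coding"]
        orf = make_orf(
            "orf116", fig3d.orf116_interval.start, fig3d.orf116_interval.end
        )
        cls = classify_chimeric(orf, conserved, L)
        assert cls.ch_flag and cls.nearest_gene == "rpl2"
        hits = {h.gene: h for h in cls.neighbors}
        assert hits["rpl2"].overlap_bp == 41
        assert hits["rpl5"].gap_bp == 187

    def test_origin_straddling_orf(self):
        gene = make_gene("cox1", 5, 800)
        orf = make_orf("o", 9900, 140, wraps=True)
        cls = classify_chimeric(orf, [gene], 10_000)
        assert cls.ch_flag and cls.overlap_bp == 135 and cls.neighbor_side == "overlapping"

    def test_monotone_in_window(self, rng):
        gene = make_gene("g", 4000, 4600)
        for _ in range(40):
            start = int(rng.integers(0, 9000))
            orf = make_orf("o", start, start + 339)
            flags = [
                classify_chimeric(orf, [gene], 10_000, window=w).ch_flag
                for w in (100, 300, 500, 900)
            ]
            assert flags == sorted(flags)  # once chimeric, stays chimeric

    def test_negative_window_error(self):
        with pytest.raises(ValueError):
            classify_chimeric(make_orf("o", 0, 336), [make_gene("g", 500, 900)], 5000, window=-1)

    def test_non_coding_gene_rejected(self):
        trna = GeneModel("trnA", "tRNA", "+", [Interval(10, 80)])
        with pytest.raises(ValueError, match="protein_coding"):
            classify_chimeric(make_orf("o", 200, 560), [trna], 5000)


class TestVennAndRanking:
    def _cls(self, orf_id, as_f, tm_f, ch_f, overlap=0, gap=0):
        return OrfClassification(
            orf_id, as_f, tm_f, ch_f, "g" if ch_f else None, gap, overlap,
            "overlapping" if overlap else "upstream",
        )

    def test_empty_and_single(self):
        counts = venn_counts([])
        assert all(counts[k] == 0 for k in counts)
        counts = venn_counts([self._cls("a", True, True, True)])
        assert counts["as_tm_ch"] == 1
        assert counts["n_as"] == counts["n_tm"] == counts["n_ch"] == 1

    def test_duplicate_id_error(self):
        c = self._cls("a", True, False, False)
        with pytest.raises(ValueError, match="duplicate"):
            venn_counts([c, c])

    def test_matches_set_algebra_oracle(self, rng):
        flags = [tuple(bool(b) for b in rng.integers(0, 2, 3)) for _ in range(30)]
        cls = [self._cls(f"o{i}", *f) for i, f in enumerate(flags)]
        counts = venn_counts(cls)
        AS = {i for i, f in enumerate(flags) if f[0]}
        TM = {i for i, f in enumerate(flags) if f[1]}
        CH = {i for i, f in enumerate(flags) if f[2]}
        assert counts["as_tm_ch"] == len(AS & TM & CH)
        assert counts["as_only"] == len(AS - TM - CH)
        assert counts["as_tm"] == len((AS & TM) - CH)
        assert counts["tm_ch"] == len((TM & CH) - AS)
        assert counts["n_as"] == len(AS)
        assert counts["n_tm"] == len(TM)
        assert counts["n_ch"] == len(CH)

    def test_marginals_reconstruct_from_regions(self, rng):
        flags = [tuple(bool(b) for b in rng.integers(0, 2, 3)) for _ in range(25)]
        counts = venn_counts([self._cls(f"o{i}", *f) for i, f in enumerate(flags)])
        assert counts["n_as"] == (
            counts["as_only"] + counts["as_tm"] + counts["as_ch"] + counts["as_tm_ch"]
        )

    def test_rank_order_all_flag_combinations(self):
        cls = [
            self._cls("triple", True, True, True, overlap=41),
            self._cls("as_ch", True, False, True, gap=187),
            self._cls("as_tm", True, True, False),
            self._cls("as_plain", True, False, False),
            self._cls("not_as", False, True, True),
        ]
        ranked = rank_candidates(cls)
        assert [c.orf_id for c in ranked] == ["triple", "as_ch", "as_tm", "as_plain"]

    def test_rank_matches_sort_key_oracle(self, rng):
        cls = []
        for i in range(20):
            as_f, tm_f, ch_f = (bool(b) for b in rng.integers(0, 2, 3))
            cls.append(
                self._cls(
                    f"o{i:02d}", as_f, tm_f, ch_f,
                    overlap=int(rng.integers(0, 50)), gap=int(rng.integers(0, 500)),
                )
            )
        tier = {(True, True): 0, (False, True): 1, (True, False): 2, (False, False): 3}
        expected = sorted(
            (c for c in cls if c.as_flag),
            key=lambda c: (
                tier[(c.tm_flag, c.ch_flag)], -c.overlap_bp, c.gap_bp, c.orf_id
            ),
        )
        assert [c.orf_id for c in rank_candidates(cls)] == [c.orf_id for c in expected]

    def test_empty_ranking(self):
        assert rank_candidates([]) == []

    def test_report_roundtrip_counts(self, rng):
        flags = [tuple(bool(b) for b in rng.integers(0, 2, 3)) for _ in range(12)]
        report = build_report([self._cls(f"o{i}", *f) for i, f in enumerate(flags)])
        assert report.n_orfs == 12
        assert sum(report.venn.values()) <= 12
        assert "venn" in report.to_json()
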