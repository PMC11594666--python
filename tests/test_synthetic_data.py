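import numpy as np
import pytest

from mitocms.fig3d import build_fig3d_fixture, make_fig3d_fixture, packaged_fixture_paths
from mitocms.mito_io import circular_distance, load_annotations, load_genome
from mitocms.orf_caller import find_orfs, translate
from mitocms.synthetic_data import (
    STOP_WALL,
    GeneratorConfig,
    derive_cms,
    generate_maintainer,
    generate_pair,
    write_pair,
)

SMALL = dict(genome_length=112_000)


class TestGeneratorConfig:
    def test_subset_constraint(self):
        with pytest.raises(ValueError, match="cannot exceed"):
            GeneratorConfig(n_as_orfs=5, n_tm_orfs=6)

    def test_gc_bounds(self):
        with pytest.raises(ValueError):
            GeneratorConfig(gc_target=1.2)

    def test_genome_too_small_error(self):
        with pytest.raises(ValueError, match="genome_length"):
            generate_maintainer(GeneratorConfig(seed=0, genome_length=90_000))


class TestMaintainer:
    def test_determinism_byte_identical(self, tmp_path):
        p1 = write_pair(GeneratorConfig(seed=7, **SMALL), tmp_path / "a")
        p2 = write_pair(GeneratorConfig(seed=7, **SMALL), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self):
        g1, _ = generate_maintainer(GeneratorConfig(seed=1, **SMALL))
        g2, _ = generate_maintainer(GeneratorConfig(seed=2, **SMALL))
        assert g1.seq != g2.seq

    def test_gene_table_structure(self, default_pair):
        ann = default_pair["maintainer_ann"]
        assert len(ann) == 36
        introns = {g.name: g.n_introns() for g in ann}
        for name in ("nad1", "nad2", "nad5", "nad7"):
            assert introns[name] == 4
        for name in ("cox2", "ccmFC", "rps3", "rps10"):
            assert introns[name] == 1
        assert sum(1 for n in introns.values() if n > 0) == 8
        starts = {g.name: g.start_codon for g in ann}
        assert starts["nad1"] == starts["nad4L"] == starts["rps10"] == "ACG"
        assert starts["mttB"] == "ATT"

    def test_conserved_cds_recovered_as_orfs_at_coordinates(self, default_pair):
        genome = default_pair["maintainer"]
        ann = default_pair["maintainer_ann"]
        called = {
            (o.interval.start, o.interval.end, o.strand): o.protein
            for o in find_orfs(genome)
        }
        from mitocms.mito_io import revcomp

        for gene in ann:
            if gene.n_introns() or gene.coding_length(genome.length) // 3 - 1 < 101:
                continue
            span = gene.span(genome.length)
            cds = genome.fetch(span)
            if gene.strand == "-":
                cds = revcomp(cds)
            key = (span.start, span.end, gene.strand)
            assert called.get(key) == translate(cds), gene.name

    def test_gc_close_to_target(self):
        for target in (0.40, 0.45):
            g, _ = generate_maintainer(
                GeneratorConfig(seed=5, genome_length=120_000, gc_target=target)
            )
            gc = (g.seq.count("G") + g.seq.count("C")) / g.length
            assert abs(gc - target) < 0.01


class TestDeriveCms:
    def test_conserved_cds_sequences_preserved(self, default_pair):
        from mitocms.mito_io import revcomp

        def cds_by_name(genome, ann):
            out = {}
            for g in ann:
                if g.category != "protein_coding":
                    continue
                seq = "".join(genome.fetch(e) for e in g.exons)
                out[g.name] = revcomp(seq) if g.strand == "-" else seq
            return out

        a = cds_by_name(default_pair["maintainer"], default_pair["maintainer_ann"])
        b = cds_by_name(default_pair["cms"], default_pair["cms_ann"])
        assert a == b

    def test_truth_rows_match_annotation_features(self, default_pair):
        truth = default_pair["truth"]
        ann = {g.name: g for g in default_pair["cms_ann"] if g.category == "ORF"}
        assert set(ann) == {r.orf_id for r in truth.rows}
        for row in truth.rows:
            exon = ann[row.orf_id].exons[0]
            assert (exon.start, exon.end) == (row.start, row.end)

    def test_zero_planting_keeps_screens_empty(self):
        config = GeneratorConfig(seed=9, n_as_orfs=0, n_tm_orfs=0, n_ch_orfs=0, **SMALL)
        mnt, ann, cms, cms_ann, truth = generate_pair(config)
        assert truth.rows == []
        assert cms.seq != mnt.seq  # neutral spacer translocation applied
        mnt_prot = {o.protein for o in find_orfs(mnt)}
        cms_prot = {o.protein for o in find_orfs(cms)}
        assert cms_prot == mnt_prot

    def test_planted_distances_exact(self, default_pair):
        cms = default_pair["cms"]
        genes = {
            g.name: g for g in default_pair["cms_ann"] if g.category == "protein_coding"
        }
        from mitocms.mito_io import Interval

        for row in default_pair["truth"].rows:
            if not row.ch_flag:
                continue
            orf_iv = Interval(row.start, row.end)
            span = genes[row.neighbor_gene].span(cms.length)
            gap, overlap = circular_distance(orf_iv, span, cms.length)
            assert (gap, overlap) == (row.gap_bp, row.overlap_bp), row.orf_id

    def test_requested_overlap_geometry_respected(self):
        config = GeneratorConfig(
            seed=21, n_as_orfs=2, n_tm_orfs=1, n_ch_orfs=2,
            ch_overlap_fraction=1.0, ch_overlap_bp=(40, 45), **SMALL
        )
        _, _, _, _, truth = generate_pair(config)
        overlaps = [r.overlap_bp for r in truth.rows if r.event == "gene_overlap_fusion"]
        assert len(overlaps) == 2
        assert all(40 <= k <= 45 and k % 3 != 0 for k in overlaps)

    def test_derive_requires_generated_maintainer(self):
        from mitocms.mito_io import CircularGenome

        foreign = CircularGenome(id="x", seq="ACGT" * 30_000)
        with pytest.raises(ValueError, match="generate_maintainer"):
            derive_cms(foreign, [], GeneratorConfig(seed=0))


class TestTruthRecovery:
    @pytest.mark.parametrize("seed", range(25))
    def test_planted_truth_recovered_exactly(self, seed):
        """Exact-mode screen recall and precision vs the truth table are 1.0."""
        config = GeneratorConfig(
            seed=seed,
            genome_length=112_000,
            n_as_orfs=4 + seed % 5,
            n_tm_orfs=(4 + seed % 5) // 2,
            n_ch_orfs=seed % 4,
            ch_overlap_fraction=(seed % 3) / 2.0,
        )
        mnt, ann, cms, cms_ann, truth = generate_pair(config)
        as_proteins = {o.protein for o in find_orfs(cms)} - {
            o.protein for o in find_orfs(mnt)
        }
        assert as_proteins == truth.proteins(), seed


class TestFig3dFixture:
    def test_packaged_files_match_regeneration(self, tmp_path):
        fresh = make_fig3d_fixture(tmp_path)
        packaged = packaged_fixture_paths()
        for key, path in packaged.items():
            assert fresh[key].read_bytes() == path.read_bytes(), key

    def test_fixture_lengths_and_truth(self, fig3d):
        assert len(fig3d.orf116_protein) == 116
        assert len(fig3d.orf103_protein) == 103
        L = fig3d.cms_genome.length
        rpl5 = next(g for g in fig3d.cms_annotations if g.name == "rpl5").span(L)
        rpl2 = next(g for g in fig3d.cms_annotations if g.name == "rpl2").span(L)
        assert circular_distance(fig3d.orf116_interval, rpl5, L) == (187, 0)
        assert circular_distance(fig3d.orf116_interval, rpl2, L) == (0, 41)

    def test_fixture_files_load_cleanly(self):
        paths = packaged_fixture_paths()
        genome = load_genome(paths["cms_fasta"])
        ann = load_annotations(paths["cms_gff3"], genome)
        assert {g.name for g in ann} >= {"rpl2", "rpl5"}
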