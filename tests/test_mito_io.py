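import numpy as np
import pytest

from mitocms.mito_io import (
    CircularGenome,
    GeneModel,
    Interval,
    circular_distance,
    load_annotations,
    load_genome,
    rotate_origin,
    write_annotations,
    write_genome,
)
from oracles import circular_distance_oracle, interval_bases


def random_interval(rng, L):
    start = int(rng.integers(0, L))
    length = int(rng.integers(1, L))
    end = start + length
    if end <= L:
        return Interval(start, end, False)
    return Interval(start, end - L, True)


class TestGenomeIO:
    def test_fasta_identity_roundtrip(self, tmp_path):
        genome = CircularGenome(id="mini", seq="ACGT" * 15)
        path = tmp_path / "mini.fasta"
        write_genome(genome, path)
        back = load_genome(path)
        assert back.id == "mini" and back.seq == genome.seq and back.length == 60

    def test_ambiguous_base_error_names_position(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">bad\nACGTACGTACNACGT\n")
        with pytest.raises(ValueError, match="position 10"):
            load_genome(path)

    def test_multi_record_error_lists_ids(self, tmp_path):
        path = tmp_path / "multi.fasta"
        path.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="a, b"):
            load_genome(path)

    def test_lowercase_sequence_uppercased(self, tmp_path):
        path = tmp_path / "low.fasta"
        path.write_text(">x\nacgtacgt\n")
        assert load_genome(path).seq == "ACGTACGT"


class TestGff3Roundtrip:
    def _random_genes(self, rng, L, n=8):
        genes = []
        pos = 5
        for i in range(n):
            n_exons = int(rng.integers(1, 4))
            exons = []
            for _ in range(n_exons):
                length = int(rng.integers(30, 90))
                exons.append(Interval(pos, pos + length))
                pos += length + int(rng.integers(10, 30))
            genes.append(
                GeneModel(
                    name=f"g{i}",
                    category=["protein_coding", "tRNA", "rRNA", "ORF"][i % 4],
                    strand="+-"[i % 2],
                    exons=exons,
                    start_codon=["ATG", "ACG", "ATT"][i % 3],
                    copies=1 + i % 2,
                )
            )
        return genes, pos + 50

    def test_write_read_roundtrip_exact(self, tmp_path, rng):
        genes, L = self._random_genes(rng, 4000)
        genome = CircularGenome(id="g", seq="".join(rng.choice(list("ACGT"), size=L)))
        path = tmp_path / "ann.gff3"
        write_annotations(genes, genome, path)
        back = load_annotations(path, genome)
        key = lambda g: g.name
        for a, b in zip(sorted(genes, key=key), sorted(back, key=key)):
            assert (a.name, a.category, a.strand, a.start_codon, a.copies) == (
                b.name, b.category, b.strand, b.start_codon, b.copies
            )
            assert a.exons == b.exons

    def test_origin_crossing_feature_split_and_merged(self, tmp_path):
        genome = CircularGenome(id="g", seq="ACGT" * 50)
        gene = GeneModel("wrap", "protein_coding", "+", [Interval(190, 11, True)])
        path = tmp_path / "wrap.gff3"
        write_annotations([gene], genome, path)
        lines = [l for l in path.read_text().splitlines() if "\tCDS\t" in l]
        assert len(lines) == 2  # split into two standard lines
        back = load_annotations(path, genome)
        assert back[0].exons == [Interval(190, 11, True)]

    def test_coordinate_convention(self, tmp_path):
        # GFF3 start=1,end=303 becomes the 0-based half-open [0, 303)
        genome = CircularGenome(id="g", seq="A" * 400)
        path = tmp_path / "conv.gff3"
        path.write_text(
            "##gff-version 3\n##sequence-region g 1 400\n"
            "g\tx\tgene\t1\t303\t.\t+\t.\tID=g1;Name=n1;gene_category=protein_coding\n"
            "g\tx\tCDS\t1\t303\t.\t+\t0\tID=g1.0;Parent=g1\n"
        )
        back = load_annotations(path, genome)
        assert back[0].exons == [Interval(0, 303)]

    def test_unknown_strand_is_error(self, tmp_path):
        genome = CircularGenome(id="g", seq="A" * 100)
        path = tmp_path / "bad.gff3"
        path.write_text(
            "##gff-version 3\ng\tx\tgene\t1\t30\t.\t?\t.\tID=g1\n"
        )
        with pytest.raises(ValueError, match="strand"):
            load_annotations(path, genome)

    def test_feature_beyond_linear_genome_is_error(self, tmp_path):
        genome = CircularGenome(id="g", seq="A" * 100, circular=False)
        path = tmp_path / "bad.gff3"
        path.write_text(
            "##gff-version 3\ng\tx\tgene\t90\t120\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ValueError, match="beyond"):
            load_annotations(path, genome)


class TestCircularDistance:
    def test_identical_intervals(self):
        iv = Interval(10, 60)
        assert circular_distance(iv, iv, 100) == (0, 50)

    def test_gap_187_layout(self):
        # 187 intervening non-coding bases
        assert circular_distance(Interval(0, 100), Interval(287, 400), 1000) == (187, 0)

    def test_origin_straddling_overlap(self):
        assert circular_distance(Interval(950, 30, True), Interval(20, 60), 1000) == (0, 10)

    def test_abutting_intervals(self):
        assert circular_distance(Interval(0, 50), Interval(50, 80), 1000) == (0, 0)

    def test_invalid_genome_length(self):
        with pytest.raises(ValueError):
            circular_distance(Interval(0, 5), Interval(6, 9), 0)

    def test_matches_membership_oracle_and_symmetry(self, rng):
        for _ in range(300):
            L = int(rng.integers(20, 2000))
            a = random_interval(rng, L)
            b = random_interval(rng, L)
            got = circular_distance(a, b, L)
            assert got == circular_distance(b, a, L)
            expected = circular_distance_oracle(
                interval_bases(a.start, a.end, a.wraps, L),
                interval_bases(b.start, b.end, b.wraps, L),
                L,
            )
            assert got == expected, (a, b, L)


class TestRotation:
    def test_zero_offset_identity(self, default_pair):
        g, a = rotate_origin(default_pair["maintainer"], default_pair["maintainer_ann"], 0)
        assert g.seq == default_pair["maintainer"].seq
        assert a[0].exons == default_pair["maintainer_ann"][0].exons

    def test_rotation_roundtrip(self, default_pair, rng):
        genome = default_pair["maintainer"]
        ann = default_pair["maintainer_ann"]
        offset = int(rng.integers(1, genome.length))
        g2, a2 = rotate_origin(genome, ann, offset)
        g3, a3 = rotate_origin(g2, a2, genome.length - offset)
        assert g3.seq == genome.seq
        for x, y in zip(ann, a3):
            assert x.exons == y.exons

    def test_rotating_linear_genome_is_error(self):
        genome = CircularGenome(id="g", seq="ACGT" * 10, circular=False)
        with pytest.raises(ValueError, match="linear"):
            rotate_origin(genome, [], 4)

    def test_sequence_content_preserved(self, rng):
        genome = CircularGenome(id="g", seq="".join(rng.choice(list("ACGT"), size=500)))
        g2, _ = rotate_origin(genome, [], 123)
        assert sorted(g2.seq) == sorted(genome.seq)
        assert g2.seq == genome.seq[123:] + genome.seq[:123]
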