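"""Deterministic miniature fixture of the orf116b locus architecture.

The fixture is a pair of small circular genomes sharing two conserved
ribosomal-protein genes (labelled rpl2 and rpl5).  The CMS-like genome
additionally carries:

* a 116-aa candidate ORF with two transmembrane segments whose 3' end
  overlaps the 5' end of rpl2 by 41 bp and which lies 187 bp from rpl5
  (on rpl5's 5'/upstream side — rpl5 is on the minus strand to the
  genomic left of the ORF);
* a distant 103-aa ORF with a single transmembrane segment, far (>500 bp)
  from every conserved gene.

All filler sequence comes from a fixed-seed RNG, so the emitted files are
byte-identical across runs and platforms.  The construction is
self-checking: it asserts that the CMS-specific protein set, the 41/187 bp
distances and the 2/1 TM-segment counts hold before returning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mito_io import (
    CircularGenome,
    GeneModel,
    Interval,
    circular_distance,
    revcomp,
    write_annotations,
    write_genome,
)
from .orf_caller import find_orfs, translate
from .tm_predict import predict_tm_segments
from .cotranscription import PrimerPair, TranscriptModel, write_primers
from .synthetic_data import STOP_WALL, _random_bases, _random_sense_codon

RPL2_LEN = 1050
RPL5_LEN = 558
ORF116_OVERLAP = 41  # bp shared between the ORF 3' end and rpl2 5' end
ORF116_GAP_RPL5 = 187  # non-coding bp between rpl5 and the ORF
_FIXTURE_SEED = 20241114

# Hydrophilic background tile (Leu-Ser-Asn-Tyr).  Its repeats contain no
# start codon in any frame on either strand — so no ORF can begin inside
# designed background — and a stop in every minus-strand frame, so
# opposite-strand reads cannot run through it.
BG_TILE = ("TTA", "TCT", "AAC", "TAC")


def _bg_codons(n: int, phase: int = 0) -> str:
    return "".join(BG_TILE[(phase + i) % 4] for i in range(n))


def _rpl2_cds(rng: np.random.Generator) -> str:
    """rpl2-analog CDS whose first 41 bases complete the candidate ORF.

    Bases 38-40 spell TGA in the ORF's reading frame (offset 2), closing
    the 116-codon ORF exactly 41 bp into the gene; bases 3-37 are AGC
    repeats, stop-free in the ORF frame.  A background-tile stretch after
    the head puts minus-strand stops close to the gene's 5' end so no
    opposite-strand read can cross the fusion junction.
    """
    head = "ATG" + "AGC" * 11 + "CCT" + "GAA"  # bases 0..41, base38='T',39-40='GA'
    assert head[38:41] == "TGA"
    insulator = _bg_codons(12, phase=1) + "CAA"  # starts TCT: safe head junction
    n_body = (RPL2_LEN - len(head) - len(insulator) - 3) // 3
    body = "".join(_random_sense_codon(rng, 0.45) for _ in range(n_body))
    cds = head + insulator + body + "TAA"
    assert len(cds) == RPL2_LEN
    return cds


def _orf116_prefix() -> str:
    """First 310 nt of the candidate ORF (the part absent from the
    maintainer): Met + serine background with two 21-leucine runs, ending
    with a TAA stop guard in the *rpl2* frame so the conserved gene's own
    ORF is untouched by the fusion."""
    prefix = (
        "ATG"
        + _bg_codons(18)   # res 2-19
        + "CTG" * 21       # res 20-40, first TM run
        + _bg_codons(29)   # res 41-69
        + "CTG" * 21       # res 70-90, second TM run
        + _bg_codons(12)   # res 91-102
        + "CTA"            # res 103; its last 2 bases start the rpl2-frame TAA guard
        + "A"              # completes the guard; first base of the straddling codon
    )
    assert len(prefix) == 310
    assert prefix[-3:] == "TAA"
    return prefix


def _orf103_cds() -> str:
    cds = "ATG" + _bg_codons(38) + "CTG" * 21 + _bg_codons(43) + "TAA"
    assert len(cds) == 312
    return cds


@dataclass
class Fig3dFixture:
    cms_genome: CircularGenome
    cms_annotations: list[GeneModel]
    maintainer_genome: CircularGenome
    maintainer_annotations: list[GeneModel]
    primers: list[PrimerPair]
    orf116_interval: Interval
    orf116_protein: str
    orf103_interval: Interval
    orf103_protein: str


def build_fig3d_fixture() -> Fig3dFixture:
    """Construct (and verify) the fixture pair in memory."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    rpl2 = _rpl2_cds(rng)
    rpl5 = "ATG" + "".join(
        _random_sense_codon(rng, 0.45) for _ in range((RPL5_LEN - 6) // 3)
    ) + "TAA"
    spacer_a = _random_bases(rng, 400, 0.45)
    spacer_b = _random_bases(rng, 160, 0.45)
    spacer_c = _random_bases(rng, 700, 0.45)
    spacer_d = _random_bases(rng, 800, 0.45)
    prefix = _orf116_prefix()
    orf103 = _orf103_cds()

    # CMS-like genome ------------------------------------------------------
    parts = []
    pos = 0

    def add(piece: str) -> int:
        nonlocal pos
        parts.append(piece)
        start = pos
        pos += len(piece)
        return start

    add(STOP_WALL); add(spacer_a); add(STOP_WALL)
    rpl5_start = add(revcomp("TAA" + rpl5))  # '-' strand block: revcomp(cds)+TTA
    rpl5_span = Interval(rpl5_start, rpl5_start + RPL5_LEN)
    add(STOP_WALL); add(spacer_b); add(STOP_WALL)
    orf116_start = add(prefix)
    rpl2_start = add(rpl2)
    orf116_iv = Interval(orf116_start, rpl2_start + ORF116_OVERLAP)
    rpl2_span = Interval(rpl2_start, rpl2_start + RPL2_LEN)
    add(STOP_WALL); add(spacer_c); add(STOP_WALL)
    orf103_start = add(orf103)
    orf103_iv = Interval(orf103_start, orf103_start + len(orf103))
    add(STOP_WALL); add(spacer_d); add(STOP_WALL)
    cms_seq = "".join(parts)
    orf116_protein = translate(cms_seq[orf116_iv.start : orf116_iv.end])
    orf103_protein = translate(orf103)
    cms_genome = CircularGenome(id="fig3d_cms", seq=cms_seq)
    cms_annotations = [
        GeneModel("rpl5", "protein_coding", "-", [rpl5_span]),
        GeneModel(f"orf{len(orf116_protein)}b", "ORF", "+", [orf116_iv]),
        GeneModel("rpl2", "protein_coding", "+", [rpl2_span]),
        GeneModel(f"orf{len(orf103_protein)}a", "ORF", "+", [orf103_iv]),
    ]

    # maintainer-like genome ----------------------------------------------
    parts = []
    pos = 0
    add(STOP_WALL); add(spacer_a); add(STOP_WALL)
    m_rpl5_start = add(revcomp("TAA" + rpl5))
    m_rpl5_span = Interval(m_rpl5_start, m_rpl5_start + RPL5_LEN)
    add(STOP_WALL); add(spacer_b); add(STOP_WALL)
    add("TAA")
    m_rpl2_start = add(rpl2)
    m_rpl2_span = Interval(m_rpl2_start, m_rpl2_start + RPL2_LEN)
    add(STOP_WALL); add(spacer_c); add(STOP_WALL)
    add(STOP_WALL); add(spacer_d); add(STOP_WALL)
    maintainer_genome = CircularGenome(id="fig3d_maintainer", seq="".join(parts))
    maintainer_annotations = [
        GeneModel("rpl5", "protein_coding", "-", [m_rpl5_span]),
        GeneModel("rpl2", "protein_coding", "+", [m_rpl2_span]),
    ]

    # junction-spanning primer pairs (2O: ORF->rpl2, 5O: rpl5->ORF).  The
    # ORF-side primers straddle background/leucine-run boundaries, which
    # occur nowhere in the maintainer genome.
    fwd_2o = cms_seq[orf116_start + 46 : orf116_start + 68]
    rev_2o = revcomp(cms_seq[rpl2_start + 300 : rpl2_start + 322])
    fwd_5o = cms_seq[rpl5_span.start + 100 : rpl5_span.start + 122]
    rev_5o = revcomp(cms_seq[orf116_start + 100 : orf116_start + 122])
    primers = [
        PrimerPair("2O", fwd_2o, rev_2o),
        PrimerPair("5O", fwd_5o, rev_5o),
    ]

    fixture = Fig3dFixture(
        cms_genome=cms_genome,
        cms_annotations=cms_annotations,
        maintainer_genome=maintainer_genome,
        maintainer_annotations=maintainer_annotations,
        primers=primers,
        orf116_interval=orf116_iv,
        orf116_protein=orf116_protein,
        orf103_interval=orf103_iv,
        orf103_protein=orf103_protein,
    )
    _verify(fixture)
    return fixture


def _verify(fx: Fig3dFixture) -> None:
    """Internal consistency checks; failure means a construction bug."""
    L = fx.cms_genome.length
    gap5, ov5 = circular_distance(
        fx.orf116_interval,
        next(g for g in fx.cms_annotations if g.name == "rpl5").span(L),
        L,
    )
    gap2, ov2 = circular_distance(
        fx.orf116_interval,
        next(g for g in fx.cms_annotations if g.name == "rpl2").span(L),
        L,
    )
    assert (gap5, ov5) == (ORF116_GAP_RPL5, 0), (gap5, ov5)
    assert (gap2, ov2) == (0, ORF116_OVERLAP), (gap2, ov2)
    for gene in fx.cms_annotations:
        if gene.category != "protein_coding":
            continue
        gap, ov = circular_distance(fx.orf103_interval, gene.span(L), L)
        assert ov == 0 and gap > 500, (gene.name, gap, ov)
    assert len(fx.orf116_protein) == 116 and len(fx.orf103_protein) == 103
    assert len(predict_tm_segments(fx.orf116_protein)) == 2
    assert len(predict_tm_segments(fx.orf103_protein)) == 1
    cms_prot = {o.protein for o in find_orfs(fx.cms_genome)}
    mnt_prot = {o.protein for o in find_orfs(fx.maintainer_genome)}
    assert cms_prot - mnt_prot == {fx.orf116_protein, fx.orf103_protein}
    called = {
        (o.interval.start, o.interval.end, o.strand): o.protein
        for o in find_orfs(fx.cms_genome)
    }
    key = (fx.orf116_interval.start, fx.orf116_interval.end, "+")
    assert called.get(key) == fx.orf116_protein


def cotranscript_models(fx: Fig3dFixture) -> list[TranscriptModel]:
    """Anther-cDNA-like templates: the CMS co-transcript covers the
    rpl5-ORF-rpl2 stretch; the maintainer template covers the homologous
    region without the ORF."""
    L = fx.cms_genome.length
    rpl5 = next(g for g in fx.cms_annotations if g.name == "rpl5").span(L)
    rpl2 = next(g for g in fx.cms_annotations if g.name == "rpl2").span(L)
    cms_model = TranscriptModel.from_genome(
        fx.cms_genome, [Interval(rpl5.start, rpl2.end)], "+", id="J4A_like_cotranscript"
    )
    Lm = fx.maintainer_genome.length
    m_rpl5 = next(g for g in fx.maintainer_annotations if g.name == "rpl5").span(Lm)
    m_rpl2 = next(g for g in fx.maintainer_annotations if g.name == "rpl2").span(Lm)
    maintainer_model = TranscriptModel.from_genome(
        fx.maintainer_genome,
        [Interval(m_rpl5.start, m_rpl2.end)],
        "+",
        id="J4B_like_transcript",
    )
    return [cms_model, maintainer_model]


def packaged_fixture_paths() -> dict[str, Path]:
    """Paths of the fixture files shipped with the package."""
    from importlib.resources import files

    root = Path(str(files("mitocms").joinpath("data/fig3d")))
    return {
        "cms_fasta": root / "fig3d_cms.fasta",
        "cms_gff3": root / "fig3d_cms.gff3",
        "maintainer_fasta": root / "fig3d_maintainer.fasta",
        "maintainer_gff3": root / "fig3d_maintainer.gff3",
        "primers_tsv": root / "fig3d_primers.tsv",
    }


def make_fig3d_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the fixture files (FASTA/GFF3 pair + primer TSV) to ``outdir``."""
    fx = build_fig3d_fixture()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cms_fasta": outdir / "fig3d_cms.fasta",
        "cms_gff3": outdir / "fig3d_cms.gff3",
        "maintainer_fasta": outdir / "fig3d_maintainer.fasta",
        "maintainer_gff3": outdir / "fig3d_maintainer.gff3",
        "primers_tsv": outdir / "fig3d_primers.tsv",
    }
    write_genome(fx.cms_genome, paths["cms_fasta"])
    write_annotations(fx.cms_annotations, fx.cms_genome, paths["cms_gff3"])
    write_genome(fx.maintainer_genome, paths["maintainer_fasta"])
    write_annotations(
        fx.maintainer_annotations, fx.maintainer_genome, paths["maintainer_gff3"]
    )
    write_primers(fx.primers, paths["primers_tsv"])
    return paths
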