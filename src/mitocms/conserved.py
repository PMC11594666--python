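"""Reference table of the 36 conserved mitochondrial protein-coding genes.

Gene inventory, intron counts and start codons follow the upland-cotton
mitogenome: eight genes carry introns (nad1, nad2, nad5, nad7 with four
each; cox2, ccmFC, rps3, rps10 with one each), nad1/nad4L/rps10 start at
ACG and mttB at ATT, and annotated gene lengths range from 303 bp (nad4L)
to 2013 bp (nad5).  CDS lengths other than the two extremes are plausible
in-range placeholders (synthetic, not transcribed from any assembly) used
by the genome generator; ``cds_len`` includes the stop codon, so the
encoded protein has ``cds_len/3 - 1`` residues.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ConservedGene:
    name: str
    cds_len: int  # bp, includes stop codon
    introns: int
    start_codon: str = "ATG"

    @property
    def aa_length(self) -> int:
        return self.cds_len // 3 - 1


CONSERVED_GENES: tuple[ConservedGene, ...] = (
    ConservedGene("atp1", 1530, 0),
    ConservedGene("atp4", 597, 0),
    ConservedGene("atp6", 873, 0),
    ConservedGene("atp8", 483, 0),
    ConservedGene("atp9", 312, 0),
    ConservedGene("ccmB", 591, 0),
    ConservedGene("ccmC", 753, 0),
    ConservedGene("ccmFC", 1341, 1),
    ConservedGene("ccmFN", 1740, 0),
    ConservedGene("cob", 1182, 0),
    ConservedGene("cox1", 1584, 0),
    ConservedGene("cox2", 783, 1),
    ConservedGene("cox3", 798, 0),
    ConservedGene("matR", 1968, 0),
    ConservedGene("mttB", 753, 0, "ATT"),
    ConservedGene("nad1", 978, 4, "ACG"),
    ConservedGene("nad2", 1467, 4),
    ConservedGene("nad3", 357, 0),
    ConservedGene("nad4", 1488, 0),
    ConservedGene("nad4L", 303, 0, "ACG"),
    ConservedGene("nad5", 2013, 4),
    ConservedGene("nad6", 594, 0),
    ConservedGene("nad7", 1185, 4),
    ConservedGene("nad9", 573, 0),
    ConservedGene("rpl2", 1050, 0),
    ConservedGene("rpl5", 558, 0),
    ConservedGene("rpl10", 489, 0),
    ConservedGene("rpl16", 543, 0),
    ConservedGene("rps3", 1680, 1),
    ConservedGene("rps4", 1068, 0),
    ConservedGene("rps7", 447, 0),
    ConservedGene("rps10", 378, 1, "ACG"),
    ConservedGene("rps12", 378, 0),
    ConservedGene("rps14", 309, 0),
    ConservedGene("rps19", 321, 0),
    ConservedGene("sdh4", 423, 0),
)

assert len(CONSERVED_GENES) == 36
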