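# Methods

## The screen

The package compares two circular mitochondrial genomes — a CMS
(sterile) line and its isonuclear maintainer — and classifies every ORF
of the CMS genome on three axes.  An ORF here is a maximal start-to-stop
span in any of the six reading frames, scanning across the sequence
origin, whose encoded protein exceeds 100 residues (`min_aa = 101`,
i.e. "more than 100 amino acids").  Within one stop-bounded reading
segment only the most upstream permitted start codon defines the ORF, so
nested in-frame starts are not reported separately.  Plant mitochondria
translate with the standard genetic code but initiate not only at ATG:
C-to-U RNA editing turns genomic ACG (and occasionally ATT) into
functional starts, so the caller accepts `{ATG, ACG, ATT}` by default
(configurable down to `{ATG}`), reading the first residue as Met.

The three axes:

* **AS (line-specific).**  An ORF is AS when its protein has no
  counterpart among the maintainer's ORFs.  The default criterion is an
  exact protein-string match, which makes the test symmetric and
  reproducible.  An alignment mode (`identity`) declares a counterpart
  when a global alignment (match 1, mismatch −1, gap −2) reaches
  identity ≥ 0.95 over coverage ≥ 0.9 of the longer protein; it exists
  for SNP-carrying homologs and is off by default.
* **TM (transmembrane).**  The protein contains at least one predicted
  membrane-spanning segment under the hydropathy scan described below.
* **CH (chimeric).**  The ORF's nucleotide span overlaps, or lies within
  a 500 bp window of, a conserved mitochondrial protein-coding gene.
  Distances are measured on the circle between whole gene spans
  (introns included) and are strand-agnostic; tRNA/rRNA genes do not
  anchor chimerism.  The boundary is inclusive: a 500 bp gap is
  chimeric, 501 bp is not.

Candidates are the AS ORFs, ranked AS∧TM∧CH → AS∧CH → AS∧TM → AS, with
ties broken by larger overlap, then smaller gap, then identifier.  A
seven-region Venn summary over the three flags is reported alongside.

ORFs whose protein equals a translated annotated conserved gene are
excluded from classification — they are the known genes, not candidates.

## Transmembrane prediction

TM status uses the classic Kyte–Doolittle criterion rather than an HMM:
the per-residue hydropathy index is averaged over a 19-residue sliding
window, maximal runs of window centres with mean ≥ 1.6 are expanded to
full windows, runs separated by fewer than 5 residues are merged, and
segments shorter than 18 residues are dropped.  All four parameters are
configurable.  The 19/1.6 combination is the published
membrane-spanning setting for this scale; 4.5 (Ile) is the scale's
maximum, so thresholds above 4.5 can never fire.  This predictor is
deterministic and dependency-free but is *not* TMHMM: on real proteins
the two will disagree near the margin.  Segment counts on the package's
archetype proteins (two segments for the 116-aa candidate, one for the
103-aa control) are the behavioural contract.  Segment *count* is
monotone in the threshold only in the non-merging regime; at very low
thresholds adjacent segments merge and the count can drop.

## Circular coordinates

Intervals are 0-based half-open; an origin-crossing feature is a single
interval with `wraps=True` (`end <= start`), split into two lines only on
GFF3 export and re-merged on import.  `circular_distance` returns the
base-set overlap and, when disjoint, the number of bases strictly
separating the intervals along the shorter arc (abutting features give
gap 0, overlap 0).  Rotating the origin is a group action; ORF calling,
distances and genome summaries are rotation-invariant, which the tests
exercise directly.

## In-silico RT-PCR

Co-transcription of a candidate with its neighbour is modelled as
presence/absence of a PCR product on a transcript template: the forward
primer must match the template sense strand and the reverse-complemented
reverse primer must match downstream, exactly by default
(`max_mismatch = 0`; when mismatches are allowed the 3'-terminal base
must still match).  The primary product pairs the leftmost forward site
with its nearest downstream reverse site; additional products are
returned flagged `multiproduct`.  No hybridization thermodynamics are
modelled — the experimental readout being reproduced is a band on a gel.
Maintainer templates carry the conserved gene alone; CMS co-transcript
templates span ORF + intergenic + neighbour, so a junction-spanning pair
amplifies on the CMS template only.

## Composition statistics and expression

`summarize_genome` reports length, GC (as a fraction, and as a percent
rounded to two decimals in reports), per-category gene counts (distinct
and per-copy totals), intron-bearing genes, start-codon usage,
multi-copy genes, the protein-coding length extremes, and a histogram of
encoded protein lengths in left-closed 100-aa bins `[100,200) …
[600,700)` with explicit underflow/overflow buckets (a 200-aa protein
falls in `[200,300)`).  Relative expression follows 2^−ΔΔCt with a
reference gene (default `18S`) and calibrator sample; replicate Ct rows
are averaged, the calibrator's fold is 1 by construction, and the
statistic is invariant to any per-sample additive shift applied to both
target and reference.

## The synthetic genome-pair generator

The generator emulates the comparative study design at desk scale.  The
maintainer genome (default 200 kb, GC 0.45; tests and the acceptance
script use 112 kb to keep runs fast) carries the 36 conserved
protein-coding genes in seeded random order and strand, with the
canonical structure: eight intron-bearing genes (nad1/nad2/nad5/nad7
with four introns, cox2/ccmFC/rps3/rps10 with one), ACG starts for
nad1/nad4L/rps10, ATT for mttB, and annotated lengths spanning 303 bp
(nad4L) to 2013 bp (nad5).  Only the two extremes are authoritative;
other CDS lengths in the packaged table are plausible in-range
placeholders.  CDS content is random sense codons at the GC target;
intergenic spacers are i.i.d. bases at the GC target, at least 1800 bp
each (which bounds the minimum genome length at roughly 107 kb).

The CMS genome is derived by seeded rearrangement: a neutral
translocation (permutation) of spacer interiors plus insertion of
novel-ORF cassettes — mid-spacer for plain line-specific ORFs, adjacent
to a conserved gene at an exact planted distance for gap-type chimerics,
and fused with the first *k* bases of a gene for overlap-type chimerics.
Conserved CDS sequences are moved, never mutated.

Planted truth is *structural*, not statistical:

* every spacer and cassette is flanked by a 12 bp wall (`TTAGTTAGTTAG`)
  containing a stop codon in all six frames and no start codon in any
  frame on either strand, so no reading frame crosses a junction and no
  ORF can begin inside a wall;
* novel-ORF backgrounds are built from a Leu-Ser-Asn-Tyr codon tile with
  the same start-free property plus minus-strand stops in every frame
  (mean hydropathy −0.45, far below the TM threshold); TM-positive ORFs
  get a 21-codon hydrophobic run;
* insertion points must have a stop codon, in every frame on both
  strands, within 280 bp on each side (sides abutting walls or guards
  are safe by construction).  This bounds any junction-truncated reading
  segment below the 101-aa calling threshold, so cutting a spacer cannot
  create a novel ORF;
* each gene start is preceded by an in-frame stop guard, so intron-less
  conserved genes are recovered by the caller exactly at their planted
  coordinates; overlap cassettes end with the same guard in the *gene's*
  frame, so the fused gene's own ORF is unchanged;
* cassette interiors are rejection-sampled until they contain exactly
  the intended ORF.

Overlap geometry is constrained: the planted overlap `k` must satisfy
`k mod 3 ≠ 0` (otherwise the ORF's stop would be an internal stop of the
gene) and the gene must present a stop codon in the ORF's frame exactly
at bases `[k−3, k)` with none earlier; feasible `(gene, k)` pairs are
searched within the configured range and an error is raised if none
exists.  The published 41 bp overlap (41 mod 3 = 2) is representable.

Consequently the CMS-specific protein set equals the planted set by
construction, and the screen's recall and precision against the truth
table are 1.0 in exact mode — verified across 25+ seeded configurations
in the test suite.  What passing these tests does *not* show: behaviour
on real mitogenomes with recombination repeats, substoichiometric
molecules, RNA editing, or proteins whose TM status is marginal under
TMHMM; the generator models none of these.

`n_tm_orfs` and `n_ch_orfs` are subsets of the `n_as_orfs` planted novel
ORFs (defaults 8 and 8 of 15), with `ch_overlap_fraction` (default 0.5)
splitting chimerics between overlap- and gap-type.  Non-line-specific
TM/CH ORFs arise naturally from conserved genes and shared background
and are not planted.

## The packaged fixture

A hand-built ~4.4 kb circular genome pair encodes the candidate-locus
architecture exactly: a 116-aa ORF with leucine runs at residues 20–40
and 70–90 (two predicted segments) whose final 41 nt are the first 41 nt
of an rpl2-labelled gene — the ORF's stop codon sits at gene bases
38–40 in the ORF's frame — and which lies 187 bp from an rpl5-labelled
gene on its 5' side (rpl5 is on the minus strand to the genomic left, so
the ORF sits upstream of rpl5 in rpl5's own orientation); plus a 103-aa
single-segment ORF more than 500 bp from every gene.  The construction
is self-verifying (distances, TM counts, and the exact CMS-specific
protein set are asserted at build time) and byte-stable; the shipped
copies under `mitocms/data/fig3d/` are regenerated and compared in the
tests.

## Numerical and convention choices

* ORF identifiers are `orf<aa_length>` plus a/b/c… suffixes assigned in
  order of genomic start position among equal-length ORFs.
* `nt_length` includes the stop codon (`nt = 3·(aa+1)`); annotated gene
  lengths likewise include the stop.
* Degenerate inputs: genomes shorter than 3 bp yield no ORFs (not an
  error); proteins shorter than the window yield no TM segments;
  `min_aa < 1`, negative proximity windows, empty sequences and
  non-positive genome lengths raise `ValueError`.
* Nearest-gene ties break by larger overlap, then smaller gap, then gene
  name; candidate-ranking ties break by overlap, gap, then ORF id —
  every reported ordering is deterministic.
* GFF3 I/O is 1-based inclusive per the standard and round-trips the
  internal models exactly; exports are sorted by start then name.
* All randomness flows from one `numpy` Generator seeded once per
  operation; derived streams use `default_rng([seed, 1])` so maintainer
  generation and CMS derivation are independently reproducible.

## Known limitations

* The KD window scan is a proxy for TMHMM; only segment counts on the
  archetypes are contractual.
* Exact-protein AS matching treats any amino-acid difference as
  line-specific; use identity mode for divergent homolog tolerance.
* The generator does not model recombination-repeat structure,
  heteroplasmy, multi-copy gene amplification, or read-level noise;
  rearrangement breakpoints are restricted to wall-safe spacer
  positions rather than uniform over the genome.
* Overlap-type chimerics are planted only on plus-strand intron-less
  genes (the mirrored construction would be symmetric but is not
  implemented).
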