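"""Seedable maintainer/CMS mitogenome pair generator with planted truth.

The generator emulates the comparative design of a CMS study: a fertile
maintainer mitogenome carrying the 36 conserved protein-coding genes
(intron structure and start codons per the packaged table) separated by
random intergenic spacers, and a derived sterile-line (CMS) genome in
which rearrangement events create novel ORFs — line-specific (AS),
optionally membrane-spanning (TM), and optionally chimeric (CH, placed
within a configured distance of, or overlapping, a conserved gene).  A
machine-readable truth table records every planted property so the whole
screen can be validated without sequencing data.

Structural guarantees (what makes planted truth exact rather than
statistical):

* every intergenic spacer and every inserted cassette is flanked by a
  12 bp "stop wall" (``TTAATTAATTAA``) containing a stop codon in all six
  frames, so no reading frame crosses a rearrangement junction;
* every gene start is preceded by an in-frame stop guard, so each
  intron-less conserved gene is recovered by the ORF caller exactly at its
  planted coordinates;
* cassette interiors are rejection-sampled until they contain exactly the
  intended ORF.

Consequently the CMS-specific protein set equals the planted set by
construction, and the screen's recall and precision against the truth
table are 1.0 in exact mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conserved import CONSERVED_GENES, ConservedGene
from .mito_io import (
    CircularGenome,
    GeneModel,
    Interval,
    revcomp,
    write_annotations,
    write_genome,
)
from .orf_caller import find_orfs, translate
from .tm_predict import predict_tm_segments

# Junction insulator: a stop codon in all six frames and no start codon in
# any frame on either strand, so no reading frame can cross it and no ORF
# can begin inside it.
STOP_WALL = "TTAGTTAGTTAG"

STOP_CODONS = ("TAA", "TAG", "TGA")

# Novel-ORF design alphabet.  The hydrophilic background is a
# Leu-Ser-Asn-Tyr codon tile whose repeats contain no start codon in any
# frame on either strand (so no ORF can begin inside designed background)
# and a stop codon in every minus-strand frame (so opposite-strand reads
# cannot run through it); its mean hydropathy (-0.45) keeps every window
# far below the TM calling threshold.  Membrane-spanning runs are sampled
# from strongly hydrophobic codons.
BG_TILE = ("TTA", "TCT", "AAC", "TAC")
HYDROPHOBIC_CODONS = ("CTG", "CTC", "GTG", "GTC", "ATC")
TM_RUN_LEN = 21


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic genome pair."""

    seed: int = 0
    genome_length: int = 200_000
    gc_target: float = 0.45
    n_as_orfs: int = 15
    n_tm_orfs: int = 8
    n_ch_orfs: int = 8
    ch_overlap_bp: tuple[int, int] = (20, 60)
    ch_gap_bp: tuple[int, int] = (60, 450)
    ch_overlap_fraction: float = 0.5
    orf_aa_range: tuple[int, int] = (101, 180)
    min_spacer: int = 1800
    intron_len_range: tuple[int, int] = (80, 300)
    conserved_table: tuple[ConservedGene, ...] = CONSERVED_GENES

    def __post_init__(self) -> None:
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        if self.n_tm_orfs > self.n_as_orfs or self.n_ch_orfs > self.n_as_orfs:
            raise ValueError(
                "n_tm_orfs and n_ch_orfs are subsets of the planted novel ORFs "
                "and cannot exceed n_as_orfs"
            )


@dataclass
class TruthRow:
    """One planted novel ORF and its expected classification."""

    orf_id: str
    as_flag: bool
    tm_flag: bool
    ch_flag: bool
    start: int
    end: int
    strand: str
    aa_length: int
    protein: str
    neighbor_gene: str | None
    gap_bp: int
    overlap_bp: int
    event: str


@dataclass
class SyntheticTruth:
    rows: list[TruthRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def proteins(self) -> set[str]:
        return {r.protein for r in self.rows}


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _random_sense_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = _random_bases(rng, 3, gc)
        if codon not in STOP_CODONS:
            return codon


def _build_cds(
    rng: np.random.Generator, length: int, start_codon: str, gc: float
) -> str:
    """A translatable CDS of ``length`` bp (start + sense codons + stop)."""
    if length % 3 or length < 9:
        raise ValueError(f"CDS length {length} invalid")
    n_codons = length // 3 - 2
    body = "".join(_random_sense_codon(rng, gc) for _ in range(n_codons))
    stop = STOP_CODONS[rng.integers(0, 3)]
    return start_codon + body + stop


def generate_maintainer(
    config: GeneratorConfig,
) -> tuple[CircularGenome, list[GeneModel]]:
    """Deterministically generate the fertile maintainer mitogenome.

    Layout per gene: ``WALL  spacer  WALL  [stop-guard] gene``; the
    conserved genes are placed in seeded random order and strand with
    intron structure and start codons from the packaged table.
    """
    rng = np.random.default_rng(config.seed)
    table = config.conserved_table
    n = len(table)
    order = rng.permutation(n)
    strands = rng.choice(list("+-"), size=n)
    gene_specs = []  # (ConservedGene, strand, sense_block, exon_offsets)
    for idx, strand in zip(order, strands):
        gene = table[idx]
        cds = _build_cds(rng, gene.cds_len, gene.start_codon, config.gc_target)
        if gene.introns:
            cuts = sorted(
                rng.choice(np.arange(1, gene.cds_len), size=gene.introns, replace=False)
            )
        else:
            cuts = []
        exon_bounds = list(zip([0] + cuts, cuts + [gene.cds_len]))
        pieces = []
        exon_local: list[tuple[int, int]] = []  # within the sense gene seq
        pos = 0
        for i, (lo, hi) in enumerate(exon_bounds):
            pieces.append(cds[lo:hi])
            exon_local.append((pos, pos + hi - lo))
            pos += hi - lo
            if i < len(exon_bounds) - 1:
                ilen = int(rng.integers(*config.intron_len_range))
                pieces.append(_random_bases(rng, ilen, config.gc_target))
                pos += ilen
        sense_gene = "".join(pieces)
        gene_specs.append((gene, strand, sense_gene, exon_local))
    fixed = sum(len(s[2]) + 3 for s in gene_specs) + 24 * n  # guards + walls
    spacer_total = config.genome_length - fixed
    if spacer_total < config.min_spacer * n:
        raise ValueError(
            f"genome_length {config.genome_length} too small for planted features; "
            f"need at least {fixed + config.min_spacer * n}"
        )
    extra = rng.multinomial(spacer_total - config.min_spacer * n, [1.0 / n] * n)
    spacer_lens = [config.min_spacer + int(e) for e in extra]
    parts: list[str] = []
    annotations: list[GeneModel] = []
    offset = 0
    for (gene, strand, sense_gene, exon_local), sp_len in zip(gene_specs, spacer_lens):
        spacer = _random_bases(rng, sp_len, config.gc_target)
        for piece in (STOP_WALL, spacer, STOP_WALL):
            parts.append(piece)
            offset += len(piece)
        if strand == "+":
            block = "TAA" + sense_gene
            span_start = offset + 3
            exons = [
                Interval(span_start + lo, span_start + hi) for lo, hi in exon_local
            ]
        else:
            block = revcomp("TAA" + sense_gene)
            span_start = offset
            B = len(sense_gene)
            exons = sorted(
                (
                    Interval(span_start + B - hi, span_start + B - lo)
                    for lo, hi in exon_local
                ),
                key=lambda iv: iv.start,
            )
        parts.append(block)
        offset += len(block)
        annotations.append(
            GeneModel(
                name=gene.name,
                category="protein_coding",
                strand=strand,
                exons=exons,
                start_codon=gene.start_codon,
            )
        )
    seq = "".join(parts)
    assert len(seq) == config.genome_length
    genome = CircularGenome(id=f"synthetic_maintainer_s{config.seed}", seq=seq)
    annotations.sort(key=lambda g: g.span(genome.length).start)
    return genome, annotations


# ---------------------------------------------------------------------------
# CMS derivation


def _intergap_bounds(
    seq: str, genes: list[GeneModel], L: int
) -> list[tuple[int, int]]:
    """(body_start, body_end) of the spacer body preceding each gene."""
    bounds = []
    for i, gene in enumerate(genes):
        span = gene.span(L)
        if i == 0:
            lo_raw = 0
        else:
            prev = genes[i - 1]
            lo_raw = prev.span(L).end + (3 if prev.strand == "-" else 0)
        hi_raw = span.start - (3 if gene.strand == "+" else 0)
        if seq[lo_raw : lo_raw + 12] != STOP_WALL or seq[hi_raw - 12 : hi_raw] != STOP_WALL:
            raise ValueError(
                "maintainer genome lacks the generator's spacer walls; "
                "derive_cms requires a genome produced by generate_maintainer"
            )
        bounds.append((lo_raw + 12, hi_raw - 12))
    return bounds


REV_STOPS = ("TTA", "CTA", "TCA")  # minus-strand stop codons read on '+'
SAFE_REACH = 280  # bp; bounds any junction-truncated ORF below the 101-aa cut


def _wall_filler(n: int) -> str:
    """Start-free, stop-dense padding of length n (the wall motif cycled)."""
    return ("TTAG" * (n // 4 + 1))[:n]


def _stops_all_classes(seq: str, lo: int, hi: int, stops, skip_class=None) -> bool:
    """A stop triplet from ``stops`` in every position class mod 3 of
    [lo, hi)."""
    lo = max(lo, 0)
    need = {0, 1, 2} - ({skip_class} if skip_class is not None else set())
    for p in range(lo, min(hi, len(seq)) - 2):
        if p % 3 in need and seq[p : p + 3] in stops:
            need.discard(p % 3)
            if not need:
                return True
    return not need


def _safe_insertion_point(
    seq: str,
    x: int,
    check_left: bool = True,
    check_right: bool = True,
    skip_fwd_class_right: int | None = None,
) -> bool:
    """True when cutting the sequence at ``x`` cannot create a novel ORF.

    Inserting a wall-flanked cassette truncates every reading segment that
    crossed ``x``; the truncated piece can only be called as a new ORF if
    it still spans >= 101 codons.  Requiring a stop codon (both strands,
    every frame class) within ``SAFE_REACH`` bp on each side of the cut
    bounds all truncated pieces below that size.  A side that abuts a stop
    wall or guard is safe by construction and can be skipped.
    """
    for stops, skip in ((STOP_CODONS, skip_fwd_class_right), (REV_STOPS, None)):
        if check_left and not _stops_all_classes(seq, x - SAFE_REACH, x, stops):
            return False
        if check_right and not _stops_all_classes(
            seq, x, x + SAFE_REACH, stops, skip_class=skip
        ):
            return False
    return True


def _novel_protein_codons(
    rng: np.random.Generator, n_codons: int, tm: bool
) -> list[str]:
    phase = int(rng.integers(0, 4))
    codons = [BG_TILE[(phase + i) % 4] for i in range(n_codons)]
    if tm:
        run_start = int(rng.integers(3, max(4, n_codons - TM_RUN_LEN - 10)))
        for i in range(run_start, run_start + TM_RUN_LEN):
            codons[i] = HYDROPHOBIC_CODONS[rng.integers(0, len(HYDROPHOBIC_CODONS))]
    return codons


def _cassette_is_clean(
    cassette: str,
    orf_rel_start: int,
    orf_len: int,
    shared_from: int | None = None,
    min_aa: int = 101,
) -> bool:
    """True iff every ORF in the cassette (scanned as a linear sequence) is
    either the planted one or starts at/after ``shared_from`` — the point
    from which the sequence is conserved-gene material identical in the
    maintainer, so any ORF there exists in both genomes."""
    probe = CircularGenome(id="cassette", seq=cassette, circular=False)
    if shared_from is None:
        shared_from = len(cassette)
    for orf in find_orfs(probe, min_aa=min_aa):
        s, e = orf.interval.start, orf.interval.end
        if s == orf_rel_start and e == orf_rel_start + orf_len and orf.strand == "+":
            continue
        if s >= shared_from:
            continue
        return False
    return True


def _build_plain_cassette(
    rng: np.random.Generator, aa: int, tm: bool
) -> tuple[str, str]:
    """WALL + cds + WALL cassette; returns (cassette, protein)."""
    for _ in range(80):
        codons = _novel_protein_codons(rng, aa - 1, tm)
        cds = "ATG" + "".join(codons) + STOP_CODONS[rng.integers(0, 3)]
        protein = translate(cds)
        segs = predict_tm_segments(protein)
        if tm != bool(segs):
            continue
        cassette = STOP_WALL + cds + STOP_WALL
        if _cassette_is_clean(cassette, 12, len(cds)):
            return cassette, protein
    raise RuntimeError("failed to build a clean ORF cassette")


def _feasible_overlaps(
    gene_seq: str, k_range: tuple[int, int]
) -> list[int]:
    """Overlap lengths k whose geometry is representable on this gene:
    k % 3 != 0, a stop codon in the ORF frame at gene bases [k-3, k) and
    no earlier ORF-frame stop inside the overlap."""
    out = []
    for k in range(k_range[0], k_range[1] + 1):
        if k % 3 == 0 or k + 3 > len(gene_seq):
            continue
        if gene_seq[k - 3 : k] not in STOP_CODONS:
            continue
        ok = True
        for b in range(k % 3, k - 3, 3):
            if gene_seq[b : b + 3] in STOP_CODONS:
                ok = False
                break
        if ok:
            out.append(k)
    return out


def _build_overlap_cassette(
    rng: np.random.Generator, aa: int, k: int, gene_seq: str, tm: bool
) -> tuple[str, str]:
    """WALL + prefix cassette for an ORF whose last ``k`` bases are the
    first ``k`` bases of a conserved gene.  The prefix ends with a stop
    guard in the *gene* frame so the conserved gene's own ORF is unchanged.
    Returns (cassette, full ORF protein)."""
    orf_len = 3 * (aa + 1)
    prefix_len = orf_len - k
    n_codons = (prefix_len - 3) // 3  # codons after ATG fully inside prefix
    rem = (prefix_len - 3) % 3
    for _ in range(200):
        codons = _novel_protein_codons(rng, n_codons, tm)
        tail = "".join(
            "ACGT"[rng.integers(0, 4)] for _ in range(rem)
        )
        prefix = "ATG" + "".join(codons) + tail
        assert len(prefix) == prefix_len
        prefix = prefix[:-3] + "TAA"  # gene-frame stop guard
        cds = prefix + gene_seq[:k]
        try:
            protein = translate(cds)
        except ValueError:
            continue
        segs = predict_tm_segments(protein)
        if tm != bool(segs):
            continue
        cassette = STOP_WALL + prefix
        region = cassette + gene_seq + STOP_WALL
        if _cassette_is_clean(region, 12, orf_len, shared_from=len(cassette)):
            return cassette, protein
    raise RuntimeError("failed to build a clean overlap cassette")


def derive_cms(
    maintainer: CircularGenome,
    annotations: Sequence[GeneModel],
    config: GeneratorConfig,
) -> tuple[CircularGenome, list[GeneModel], SyntheticTruth]:
    """Derive the sterile-line genome by seeded rearrangement.

    Spacer bodies are translocated (a neutral permutation between the
    stop walls) and novel-ORF cassettes are inserted: plain line-specific
    ORFs mid-spacer, chimeric ones adjacent to or overlapping a conserved
    gene.  Conserved gene sequences are moved, never mutated.
    """
    rng = np.random.default_rng([config.seed, 1])
    L = maintainer.length
    genes = sorted(annotations, key=lambda g: g.span(L).start)
    if not genes:
        raise ValueError(
            "no annotated genes; derive_cms requires a genome produced by "
            "generate_maintainer"
        )
    bounds = _intergap_bounds(maintainer.seq, genes, L)
    # --- neutral spacer translocation -------------------------------------
    bodies = [maintainer.seq[lo:hi] for lo, hi in bounds]
    perm = rng.permutation(len(bodies))
    parts: list[str] = []
    new_genes: list[GeneModel] = []
    offset = 0
    for i, gene in enumerate(genes):
        span = gene.span(L)
        lo, hi = bounds[i]
        body = bodies[perm[i]]
        lead = maintainer.seq[lo - 12 : lo]  # wall
        trail_region = maintainer.seq[hi : span.end + (3 if gene.strand == "-" else 0)]
        parts.extend([lead, body])
        offset += 12 + len(body)
        # wall + optional '+' guard + gene sequence (+ optional '-' guard)
        block = trail_region
        new_span_start = offset + (span.start - hi)
        shift = new_span_start - span.start
        parts.append(block)
        offset += len(block)
        new_genes.append(
            replace(gene, exons=[
                Interval(e.start + shift, e.end + shift) for e in gene.exons
            ])
        )
    seq = "".join(parts)
    assert len(seq) == L
    # --- plan insertions ---------------------------------------------------
    n_as, n_tm, n_ch = config.n_as_orfs, config.n_tm_orfs, config.n_ch_orfs
    tm_flags = np.zeros(n_as, dtype=bool)
    if n_tm:
        tm_flags[rng.choice(n_as, size=n_tm, replace=False)] = True
    n_overlap = int(round(config.ch_overlap_fraction * n_ch))
    gene_by_name = {g.name: g for g in new_genes}
    bounds2 = _intergap_bounds(seq, new_genes, L)
    table_by_name = {g.name: g for g in config.conserved_table}
    overlap_candidates = [
        i for i, g in enumerate(new_genes)
        if g.strand == "+" and g.n_introns() == 0
    ]
    rng.shuffle(overlap_candidates)
    gap_candidates = list(rng.permutation(len(new_genes)))
    used_genes: set[int] = set()
    used_gaps: set[int] = set()
    insertions = []  # (pos, cassette, orf_rel_start, orf_len, TruthRow-proto)
    truth_rows_proto = []
    orf_counter = 0

    def next_id(aa: int) -> str:
        nonlocal orf_counter
        orf_counter += 1
        return f"orf{aa}.{orf_counter}"

    # chimeric overlap-mode
    planted_overlap = 0
    for gi in overlap_candidates:
        if planted_overlap >= n_overlap:
            break
        if gi in used_genes:
            continue
        gene = new_genes[gi]
        span = gene.span(L)
        gene_seq = seq[span.start : span.end]
        ks = _feasible_overlaps(gene_seq, config.ch_overlap_bp)
        if not ks:
            continue
        # the left flank is the gene's stop guard + wall (safe); on the
        # right, the gene's own frame is protected by the prefix guard
        if not _safe_insertion_point(
            seq, span.start, check_left=False,
            skip_fwd_class_right=span.start % 3,
        ):
            continue
        k = int(ks[rng.integers(0, len(ks))])
        aa = int(rng.integers(config.orf_aa_range[0], config.orf_aa_range[1] + 1))
        tm = bool(tm_flags[len(truth_rows_proto)])
        try:
            cassette, protein = _build_overlap_cassette(rng, aa, k, gene_seq, tm)
        except RuntimeError:
            continue
        used_genes.add(gi)
        used_gaps.add(gi)  # its upstream intergap now hosts a cassette
        planted_overlap += 1
        orf_len = 3 * (aa + 1)
        insertions.append(
            dict(pos=span.start, cassette=cassette, orf_rel=12, orf_len=orf_len,
                 id=next_id(aa), tm=tm, ch=True, aa=aa, protein=protein,
                 neighbor=gene.name, gap=0, overlap=k, event="gene_overlap_fusion")
        )
        truth_rows_proto.append(None)
    if planted_overlap < n_overlap:
        raise ValueError(
            "could not plant the requested number of overlapping chimeric ORFs; "
            "widen ch_overlap_bp or reduce n_ch_orfs"
        )
    # chimeric gap-mode
    n_gap_mode = n_ch - n_overlap
    planted_gap = 0
    for gi in gap_candidates:
        if planted_gap >= n_gap_mode:
            break
        gi = int(gi)
        if gi in used_genes or gi in used_gaps:
            continue
        gene = new_genes[gi]
        span = gene.span(L)
        lo, hi = bounds2[gi]
        d = int(rng.integers(config.ch_gap_bp[0], config.ch_gap_bp[1] + 1))
        guard = 3 if gene.strand == "+" else 0
        if d < 24 + guard or hi - lo < 600:
            continue
        # insert just before the gene's leading wall (right flank safe) and
        # pad the cassette so the planted gap is exactly d; slide left if
        # the spacer approach lacks nearby stops
        pos = None
        for slide in range(0, max(3, d - 24 - guard), 3):
            x = hi - slide
            if x < lo + 50:
                break
            if _safe_insertion_point(seq, x, check_right=(slide > 0)):
                pos = x
                break
        if pos is None:
            continue
        filler = d - 12 - (span.start - pos)
        if filler < 0:
            continue
        aa = int(rng.integers(config.orf_aa_range[0], config.orf_aa_range[1] + 1))
        tm = bool(tm_flags[len(truth_rows_proto)])
        cassette, protein = _build_plain_cassette(rng, aa, tm)
        cassette = cassette[:-12] + _wall_filler(filler + 12)
        used_genes.add(gi)
        used_gaps.add(gi)
        planted_gap += 1
        orf_len = 3 * (aa + 1)
        insertions.append(
            dict(pos=pos, cassette=cassette, orf_rel=12, orf_len=orf_len,
                 id=next_id(aa), tm=tm, ch=True, aa=aa, protein=protein,
                 neighbor=gene.name, gap=d, overlap=0, event="insertion_near_gene")
        )
        truth_rows_proto.append(None)
    if planted_gap < n_gap_mode:
        raise ValueError("could not plant the requested gap-mode chimeric ORFs")
    # plain line-specific ORFs mid-spacer
    n_plain = n_as - n_ch
    free_gaps = [i for i in range(len(new_genes)) if i not in used_gaps]
    rng.shuffle(free_gaps)
    if n_plain > len(free_gaps):
        raise ValueError("not enough intergenic spacers for the requested ORFs")
    planted_plain = 0
    for gi in free_gaps:
        if planted_plain >= n_plain:
            break
        lo, hi = bounds2[gi]
        pos = None
        # keep > 500 bp of spacer between the planted ORF and both
        # flanking genes so the ORF is not chimeric
        for slide in range(0, 240, 7):
            x = (lo + hi) // 2 + slide
            if x > hi - 520:
                break
            if _safe_insertion_point(seq, x):
                pos = x
                break
        if pos is None or pos < lo + 500:
            continue
        aa = int(rng.integers(config.orf_aa_range[0], config.orf_aa_range[1] + 1))
        tm = bool(tm_flags[len(truth_rows_proto)])
        cassette, protein = _build_plain_cassette(rng, aa, tm)
        planted_plain += 1
        orf_len = 3 * (aa + 1)
        insertions.append(
            dict(pos=pos, cassette=cassette, orf_rel=12, orf_len=orf_len,
                 id=next_id(aa), tm=tm, ch=False, aa=aa, protein=protein,
                 neighbor=None, gap=0, overlap=0, event="spacer_insertion")
        )
        truth_rows_proto.append(None)
    if planted_plain < n_plain:
        raise ValueError("could not place the requested spacer-insertion ORFs")
    # --- apply insertions --------------------------------------------------
    insertions.sort(key=lambda d: d["pos"])
    pieces = []
    cursor = 0
    for ins in insertions:
        pieces.append(seq[cursor : ins["pos"]])
        pieces.append(ins["cassette"])
        cursor = ins["pos"]
    pieces.append(seq[cursor:])
    cms_seq = "".join(pieces)

    def remap(x: int) -> int:
        return x + sum(len(i["cassette"]) for i in insertions if i["pos"] <= x)

    cms_genes = [
        replace(g, exons=[Interval(remap(e.start), remap(e.end - 1) + 1) for e in g.exons])
        for g in new_genes
    ]
    truth = SyntheticTruth()
    offset_before = 0
    for ins in insertions:
        abs_start = ins["pos"] + offset_before + ins["orf_rel"]
        offset_before += len(ins["cassette"])
        start, end = abs_start, abs_start + ins["orf_len"]
        cms_genes.append(
            GeneModel(
                name=ins["id"], category="ORF", strand="+",
                exons=[Interval(start, end)],
            )
        )
        truth.rows.append(
            TruthRow(
                orf_id=ins["id"], as_flag=True, tm_flag=ins["tm"], ch_flag=ins["ch"],
                start=start, end=end, strand="+", aa_length=ins["aa"],
                protein=ins["protein"], neighbor_gene=ins["neighbor"],
                gap_bp=ins["gap"], overlap_bp=ins["overlap"], event=ins["event"],
            )
        )
    cms_genome = CircularGenome(
        id=f"synthetic_cms_s{config.seed}", seq=cms_seq
    )
    cms_genes.sort(key=lambda g: g.span(cms_genome.length).start)
    return cms_genome, cms_genes, truth


def generate_pair(
    config: GeneratorConfig,
) -> tuple[CircularGenome, list[GeneModel], CircularGenome, list[GeneModel], SyntheticTruth]:
    """Maintainer and derived CMS genome with the planted truth table."""
    maintainer, ann = generate_maintainer(config)
    cms, cms_ann, truth = derive_cms(maintainer, ann, config)
    return maintainer, ann, cms, cms_ann, truth


def write_pair(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a pair and write FASTA/GFF3/truth files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    maintainer, ann, cms, cms_ann, truth = generate_pair(config)
    paths = {
        "maintainer_fasta": outdir / "maintainer.fasta",
        "maintainer_gff3": outdir / "maintainer.gff3",
        "cms_fasta": outdir / "cms.fasta",
        "cms_gff3": outdir / "cms.gff3",
        "truth_tsv": outdir / "truth.tsv",
    }
    write_genome(maintainer, paths["maintainer_fasta"])
    write_annotations(ann, maintainer, paths["maintainer_gff3"])
    write_genome(cms, paths["cms_fasta"])
    write_annotations(cms_ann, cms, paths["cms_gff3"])
    truth.write_tsv(paths["truth_tsv"])
    return paths
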