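"""Genome/annotation I/O and circular-coordinate arithmetic.

Plant mitochondrial genomes are circular molecules, so features may cross
the sequence origin.  Internally every feature location is a 0-based,
half-open :class:`Interval`; an origin-crossing feature is stored as a
single interval with ``wraps=True`` (``end <= start``) and is split into
two lines only on GFF3 export.  GFF3 files use the standard 1-based,
inclusive convention.

Distances and overlaps between features are measured on the circle and are
strand-agnostic: the chimeric-ORF criterion used downstream is purely
positional.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
GENE_CATEGORIES = ("protein_coding", "tRNA", "rRNA", "ORF")


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a (possibly circular) sequence.

    ``start`` is 0-based inclusive, ``end`` exclusive.  When ``wraps`` is
    true the interval crosses the origin and ``end <= start``; its bases are
    ``[start, L) + [0, end)``.
    """

    start: int
    end: int
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in {self}")
        if not self.wraps and self.start >= self.end:
            raise ValueError(f"empty or inverted non-wrapping interval {self}")
        if self.wraps and self.end > self.start:
            raise ValueError(f"wraps=True requires end <= start, got {self}")

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + self.end
        return self.end - self.start

    def segments(self, genome_length: int) -> list[tuple[int, int]]:
        """Linear (start, end) pieces covering the interval."""
        if self.wraps:
            pieces = [(self.start, genome_length)]
            if self.end > 0:
                pieces.append((0, self.end))
            return pieces
        return [(self.start, self.end)]

    def shift(self, offset: int, genome_length: int) -> "Interval":
        """Interval after moving the origin by ``offset`` bases."""
        length = self.length(genome_length)
        start = (self.start - offset) % genome_length
        end_raw = start + length
        if end_raw <= genome_length:
            return Interval(start, end_raw, False)
        return Interval(start, end_raw - genome_length, True)


@dataclass
class CircularGenome:
    """A DNA sequence with explicit topology."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"genome {self.id!r}: invalid symbol {self.seq[pos]!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, interval: Interval) -> str:
        """Sequence of ``interval`` on the forward strand."""
        return "".join(self.seq[s:e] for s, e in interval.segments(self.length))


@dataclass
class GeneModel:
    """An annotated gene: exon intervals on the circle plus metadata."""

    name: str
    category: str
    strand: str
    exons: list[Interval]
    start_codon: str = "ATG"
    copies: int = 1

    def __post_init__(self) -> None:
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown gene category {self.category!r}")
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.name}: no exons")

    def coding_length(self, genome_length: int) -> int:
        return sum(e.length(genome_length) for e in self.exons)

    def n_introns(self) -> int:
        return len(self.exons) - 1

    def span(self, genome_length: int) -> Interval:
        """Whole-gene interval from first exon start to last exon end."""
        first, last = self.exons[0], self.exons[-1]
        if last.wraps or (first.start >= last.end and len(self.exons) > 1):
            return Interval(first.start, last.end, True)
        if first.wraps:
            return first
        return Interval(first.start, last.end, False)


def load_genome(path: str | Path, circular: bool = True) -> CircularGenome:
    """Read a single-record FASTA file into a :class:`CircularGenome`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        ids = ", ".join(r.id for r in records)
        raise ValueError(f"{path}: expected a single record, found {len(records)}: {ids}")
    return CircularGenome(id=records[0].id, seq=str(records[0].seq), circular=circular)


def write_genome(genome: CircularGenome, path: str | Path, wrap: int = 70) -> None:
    record = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file([record])


def _format_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key] = value
    return out


def write_annotations(
    genes: Sequence[GeneModel], genome: CircularGenome, path: str | Path
) -> None:
    """Write GeneModels as GFF3 (1-based inclusive, deterministic order).

    Origin-crossing exons are split into two CDS/exon lines sharing a
    Parent, the standard-compatible serialization of a circular feature.
    """
    length = genome.length
    lines = [
        "##gff-version 3",
        f"##sequence-region {genome.id} 1 {length}",
    ]
    topo = "true" if genome.circular else "false"
    lines.append(
        "\t".join(
            [genome.id, "mitocms", "region", "1", str(length), ".", "+", ".",
             _format_attributes({"ID": f"{genome.id}:region", "Is_circular": topo})]
        )
    )
    child_type = {"protein_coding": "CDS", "ORF": "CDS", "tRNA": "exon", "rRNA": "exon"}
    ordered = sorted(genes, key=lambda g: (g.span(length).start, g.name))
    for idx, gene in enumerate(ordered):
        gene_id = f"gene{idx}:{gene.name}"
        span = gene.span(length)
        pieces = span.segments(length)
        attrs = {
            "ID": gene_id,
            "Name": gene.name,
            "gene_category": gene.category,
            "start_codon": gene.start_codon,
            "copies": str(gene.copies),
        }
        for s, e in pieces:
            lines.append(
                "\t".join(
                    [genome.id, "mitocms", "gene", str(s + 1), str(e), ".",
                     gene.strand, ".", _format_attributes(attrs)]
                )
            )
        ctype = child_type[gene.category]
        for ei, exon in enumerate(gene.exons):
            for s, e in exon.segments(length):
                lines.append(
                    "\t".join(
                        [genome.id, "mitocms", ctype, str(s + 1), str(e), ".",
                         gene.strand, "0" if ctype == "CDS" else ".",
                         _format_attributes({"ID": f"{gene_id}.{ei}", "Parent": gene_id})]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def declared_region_length(path: str | Path) -> int | None:
    """Length declared by the ``##sequence-region`` pragma, if present."""
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            return int(line.split()[-1])
        if line and not line.startswith("#"):
            break
    return None


def load_annotations(path: str | Path, genome: CircularGenome) -> list[GeneModel]:
    """Read a GFF3 file written by :func:`write_annotations` back into models.

    Multi-exon genes are assembled from CDS/exon lines sharing a Parent;
    a feature whose pieces abut the origin on a circular genome is merged
    back into a single ``wraps=True`` interval.
    """
    length = genome.length
    gene_meta: dict[str, dict] = {}
    children: dict[str, list[tuple[int, int, str]]] = {}
    gene_pieces: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        _, _, ftype, start_s, end_s, _, strand, _, attr_s = cols
        if ftype == "region":
            continue
        if strand not in "+-":
            raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        start, end = int(start_s) - 1, int(end_s)
        if end > length and not genome.circular:
            raise ValueError(
                f"{path}:{lineno}: feature end {end} beyond linear genome length {length}"
            )
        attrs = _parse_attributes(attr_s)
        if ftype == "gene":
            gid = attrs["ID"]
            if gid not in gene_meta:
                gene_meta[gid] = {
                    "name": attrs.get("Name", gid),
                    "category": attrs.get("gene_category", "protein_coding"),
                    "strand": strand,
                    "start_codon": attrs.get("start_codon", "ATG"),
                    "copies": int(attrs.get("copies", "1")),
                }
                order.append(gid)
            gene_pieces.setdefault(gid, []).append((start, end))
        else:
            parent = attrs.get("Parent")
            if parent is None:
                raise ValueError(f"{path}:{lineno}: child feature without Parent")
            children.setdefault(parent, []).append((start, end, attrs.get("ID", "")))
    genes: list[GeneModel] = []
    for gid in order:
        meta = gene_meta[gid]
        kids = sorted(children.get(gid, []), key=lambda t: (t[2], t[0]))
        exons = _merge_pieces([(s, e, i) for s, e, i in kids], length, genome.circular)
        if not exons:  # gene line(s) only
            exons = _merge_pieces(
                [(s, e, "") for s, e in gene_pieces[gid]], length, genome.circular
            )
        genes.append(
            GeneModel(
                name=meta["name"], category=meta["category"], strand=meta["strand"],
                exons=exons, start_codon=meta["start_codon"], copies=meta["copies"],
            )
        )
    return genes


def _merge_pieces(
    pieces: list[tuple[int, int, str]], length: int, circular: bool
) -> list[Interval]:
    """Rebuild exon Intervals, re-joining origin-split pieces by shared ID."""
    by_id: dict[str, list[tuple[int, int]]] = {}
    for s, e, pid in pieces:
        by_id.setdefault(pid, []).append((s, e))
    exons: list[Interval] = []
    for pid, segs in by_id.items():
        segs.sort()
        if (
            circular
            and len(segs) == 2
            and segs[0][0] == 0
            and segs[1][1] == length
        ):
            exons.append(Interval(segs[1][0], segs[0][1], True))
        else:
            for s, e in segs:
                exons.append(Interval(s, e, False))
    exons.sort(key=lambda iv: iv.start)
    return exons


def circular_distance(
    a: Interval, b: Interval, genome_length: int
) -> tuple[int, int]:
    """``(gap_bp, overlap_bp)`` between two intervals on one circle.

    ``overlap_bp`` is the size of the base-set intersection.  When it is
    zero, ``gap_bp`` is the number of bases strictly separating the
    intervals along the shorter arc; abutting intervals give (0, 0).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    overlap = 0
    for s1, e1 in a.segments(genome_length):
        for s2, e2 in b.segments(genome_length):
            overlap += max(0, min(e1, e2) - max(s1, s2))
    if overlap > 0:
        return 0, int(overlap)
    d1 = (b.start - a.end) % genome_length
    d2 = (a.start - b.end) % genome_length
    return int(min(d1, d2)), 0


def rotate_origin(
    genome: CircularGenome,
    annotations: Sequence[GeneModel],
    offset: int,
) -> tuple[CircularGenome, list[GeneModel]]:
    """Move the sequence origin by ``offset`` bases (circular genomes only)."""
    if not genome.circular:
        raise ValueError("cannot rotate a linear genome")
    if not 0 <= offset < genome.length:
        raise ValueError(f"offset {offset} outside [0, {genome.length})")
    seq = genome.seq[offset:] + genome.seq[:offset]
    rotated = CircularGenome(id=genome.id, seq=seq, circular=True)
    new_genes = [
        replace(g, exons=[e.shift(offset, genome.length) for e in g.exons])
        for g in annotations
    ]
    return rotated, new_genes


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
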