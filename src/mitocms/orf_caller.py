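"""Six-frame ORF extraction on circular plant mitochondrial genomes.

Plant mitochondria initiate translation not only at ATG but, after C-to-U
RNA editing, also at genomic ACG and ATT codons, so all three are accepted
as start codons by default.  The screen keeps ORFs whose protein exceeds
100 residues (``min_aa=101``), the conventional cut-off for annotating
anonymous mitochondrial ORFs.

Within one stop-bounded reading segment only the most upstream permitted
start codon defines the ORF (the "maximal ORF" convention); on a circular
genome the codon walk continues across the origin, so ORFs may wrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .mito_io import CircularGenome, Interval, revcomp

DEFAULT_START_CODONS = ("ATG", "ACG", "ATT")
DEFAULT_STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_MIN_AA = 101


@dataclass
class OrfRecord:
    """A called open reading frame.

    ``nt_length`` includes the stop codon, so ``nt_length == 3*(aa_length+1)``.
    ``interval`` is the genomic span on the forward-strand coordinate system
    regardless of strand; ``frame`` is the strand-local start offset mod 3.
    """

    id: str
    interval: Interval
    strand: str
    frame: int
    start_codon: str
    nt_length: int
    aa_length: int
    protein: str


def translate(cds: str, start_codon_as_met: bool = True) -> str:
    """Translate a CDS with the standard genetic code.

    Plant mitochondria use the standard table; nonstandard ACG/ATT start
    codons are read as methionine when ``start_codon_as_met``.  A trailing
    stop codon is removed; an internal stop is an error.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon at codon index {protein.index('*')}")
    if start_codon_as_met and cds[:3] in ("ACG", "ATT") and protein:
        protein = "M" + protein[1:]
    return protein


def _scan_strand(
    seq: str,
    circular: bool,
    min_aa: int,
    start_codons: frozenset[str],
    stop_codons: frozenset[str],
) -> list[tuple[int, int]]:
    """All maximal ORFs on one strand as (start, nt_length) in local coords.

    Circular case: for every stop codon, walk the codon chain forward
    (mod L) to the next stop, taking the first permitted start codon.
    Each stop-bounded segment is visited exactly once, from its upstream
    stop, which enforces the maximal-ORF rule including across the origin.
    """
    L = len(seq)
    if L < 3:
        return []
    out: list[tuple[int, int]] = []
    if not circular:
        for frame in range(3):
            start = None
            for p in range(frame, L - 2, 3):
                codon = seq[p : p + 3]
                if codon in stop_codons:
                    if start is not None:
                        nt_len = p + 3 - start
                        if nt_len // 3 - 1 >= min_aa:
                            out.append((start, nt_len))
                    start = None
                elif start is None and codon in start_codons:
                    start = p
        return out
    doubled = seq + seq[:2]
    stops = [p for p in range(L) if doubled[p : p + 3] in stop_codons]
    for q in stops:
        p = (q + 3) % L
        start = None
        walked = 3
        while walked <= L:
            codon = doubled[p : p + 3]
            if codon in stop_codons:
                if start is not None:
                    nt_len = (p - start) % L + 3
                    if nt_len // 3 - 1 >= min_aa:
                        out.append((start, nt_len))
                break
            if start is None and codon in start_codons:
                start = p
            p = (p + 3) % L
            walked += 3
    return out


def _suffix(i: int) -> str:
    """a, b, ..., z, aa, ab, ... (spreadsheet-style)."""
    letters = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("a") + rem) + letters
    return letters


def find_orfs(
    genome: CircularGenome,
    min_aa: int = DEFAULT_MIN_AA,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    stop_codons: Sequence[str] = DEFAULT_STOP_CODONS,
) -> list[OrfRecord]:
    """Call ORFs in all six frames, scanning across the origin if circular."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    starts = frozenset(c.upper() for c in start_codons)
    stops = frozenset(c.upper() for c in stop_codons)
    L = genome.length
    if L < 3:
        return []
    raw: list[tuple[Interval, str, int, int]] = []  # interval, strand, local_start, nt_len
    for strand in "+-":
        seq = genome.seq if strand == "+" else revcomp(genome.seq)
        for local_start, nt_len in _scan_strand(seq, genome.circular, min_aa, starts, stops):
            if strand == "+":
                gstart = local_start
            else:
                gstart = (L - local_start - nt_len) % L
            gend = gstart + nt_len
            interval = (
                Interval(gstart, gend, False)
                if gend <= L
                else Interval(gstart, gend - L, True)
            )
            raw.append((interval, strand, local_start, nt_len))
    records: list[OrfRecord] = []
    for interval, strand, local_start, nt_len in raw:
        seq = genome.seq if strand == "+" else revcomp(genome.seq)
        if local_start + nt_len <= len(seq):
            cds = seq[local_start : local_start + nt_len]
        else:  # wraps in local coordinates
            cds = seq[local_start:] + seq[: local_start + nt_len - len(seq)]
        protein = translate(cds)
        records.append(
            OrfRecord(
                id="",
                interval=interval,
                strand=strand,
                frame=local_start % 3,
                start_codon=cds[:3],
                nt_length=nt_len,
                aa_length=nt_len // 3 - 1,
                protein=protein,
            )
        )
    records.sort(key=lambda r: (r.interval.start, r.strand))
    counters: dict[int, int] = {}
    for rec in records:
        n = counters.get(rec.aa_length, 0)
        counters[rec.aa_length] = n + 1
        rec.id = f"orf{rec.aa_length}{_suffix(n)}"
    return records


def orfs_to_protein_fasta(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    lines = []
    for orf in orfs:
        lines.append(f">{orf.id}")
        seq = orf.protein
        lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
    Path(path).write_text("\n".join(lines) + "\n")


def orfs_to_gff3(
    orfs: Iterable[OrfRecord], genome: CircularGenome, path: str | Path
) -> None:
    L = genome.length
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {L}"]
    for orf in orfs:
        attrs = f"ID={orf.id};aa_length={orf.aa_length};start_codon={orf.start_codon}"
        for s, e in orf.interval.segments(L):
            lines.append(
                "\t".join(
                    [genome.id, "mitocms", "open_reading_frame", str(s + 1), str(e),
                     ".", orf.strand, "0", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
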