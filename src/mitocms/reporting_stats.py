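"""Genome composition summaries and qPCR relative expression.

The composition summary mirrors how comparative mitogenome studies report
an assembly: length, GC%, gene counts per category, intron-bearing genes,
start-codon usage, the gene-length extremes, and a histogram of encoded
protein lengths in 100-aa classes.  Relative expression follows the
2^-ddCt method with a reference gene (18S rRNA by default) and a
calibrator sample.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio.SeqUtils import gc_fraction

from .mito_io import CircularGenome, GeneModel

HIST_BINS = tuple(range(100, 800, 100))  # left-closed [100,200) ... [600,700)
DEFAULT_REFERENCE_GENE = "18S"


@dataclass
class GenomeSummary:
    length: int
    gc_fraction: float
    counts: dict[str, int]
    n_genes_distinct: int
    n_genes_total: int  # counting multi-copy genes per copy
    n_intron_genes: int
    start_codon_usage: dict[str, int]
    multi_copy_genes: list[str]
    min_gene: tuple[str, int] | None  # (name, bp) among protein-coding
    max_gene: tuple[str, int] | None
    protein_length_hist: dict[str, int]

    @property
    def gc_percent(self) -> float:
        """GC as percent, rounded to 2 decimals (report style)."""
        return round(100 * self.gc_fraction, 2)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["gc_percent"] = self.gc_percent
        return json.dumps(payload, indent=2, sort_keys=True)


def gc_content(seq: str) -> float:
    """(#G + #C) / length of an ACGT string."""
    if not seq:
        raise ValueError("empty sequence")
    return gc_fraction(seq)


def _hist_key(lo: int) -> str:
    return f"{lo}-{lo + 100}"


def summarize_genome(
    genome: CircularGenome, annotations: Sequence[GeneModel]
) -> GenomeSummary:
    """Compute all composition statistics for one annotated genome."""
    L = genome.length
    counts = Counter(g.category for g in annotations)
    for cat in ("protein_coding", "tRNA", "rRNA", "ORF"):
        counts.setdefault(cat, 0)
    coding = [g for g in annotations if g.category == "protein_coding"]
    intron_genes = [g for g in coding if g.n_introns() > 0]
    start_usage = Counter(g.start_codon for g in coding)
    multi = sorted({g.name for g in coding if g.copies > 1})
    name_counts = Counter(g.name for g in coding)
    multi = sorted(set(multi) | {n for n, c in name_counts.items() if c > 1})
    hist = {_hist_key(lo): 0 for lo in HIST_BINS[:-1]}
    hist["underflow"] = 0
    hist["overflow"] = 0
    lengths: list[tuple[int, str]] = []
    for g in coding:
        bp = int(g.coding_length(L))
        lengths.append((bp, g.name))
        aa = bp // 3 - 1
        if aa < HIST_BINS[0]:
            hist["underflow"] += 1
        elif aa >= HIST_BINS[-1]:
            hist["overflow"] += 1
        else:
            lo = (aa // 100) * 100
            hist[_hist_key(lo)] += 1
    min_gene = max_gene = None
    if lengths:
        bp, name = min(lengths)
        min_gene = (name, bp)
        bp, name = max(lengths)
        max_gene = (name, bp)
    return GenomeSummary(
        length=L,
        gc_fraction=gc_content(genome.seq),
        counts=dict(counts),
        n_genes_distinct=len({(g.name, g.category) for g in annotations}),
        n_genes_total=sum(g.copies for g in annotations),
        n_intron_genes=len(intron_genes),
        start_codon_usage=dict(start_usage),
        multi_copy_genes=multi,
        min_gene=min_gene,
        max_gene=max_gene,
        protein_length_hist=hist,
    )


def load_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV with columns sample, gene, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "gene", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing Ct columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def rel_expression(
    ct: pd.DataFrame,
    target: str,
    calibrator: str,
    reference: str = DEFAULT_REFERENCE_GENE,
) -> pd.Series:
    """Fold change of ``target`` per sample by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the
    calibrator sample's dCt; fold = 2^-ddCt (calibrator == 1 by
    construction).  Replicate Ct rows are averaged first.
    """
    pivot = ct.groupby(["sample", "gene"])["ct"].mean().unstack()
    for gene in (target, reference):
        if gene not in pivot.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    missing_ref = pivot.index[pivot[reference].isna()].tolist()
    if missing_ref:
        raise ValueError(f"missing reference Ct for sample(s): {missing_ref}")
    if calibrator not in pivot.index:
        raise ValueError(f"calibrator sample {calibrator!r} absent from Ct table")
    dct = pivot[target] - pivot[reference]
    if pd.isna(dct[calibrator]):
        raise ValueError(f"missing target Ct for calibrator {calibrator!r}")
    ddct = dct - dct[calibrator]
    fold = 2.0 ** (-ddct)
    fold.name = f"fold_{target}"
    return fold
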