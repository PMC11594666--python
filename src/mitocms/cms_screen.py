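"""Three-way ORF classification and candidate ranking for CMS screening.

Each ORF called on the sterile-line (CMS) mitogenome is scored on three
independent axes:

* **AS** - line-specific: its protein has no counterpart among the
  maintainer-line ORFs (exact protein match by default; an alignment-based
  identity mode covers SNP-carrying homologs);
* **TM** - its protein carries >= 1 predicted transmembrane segment;
* **CH** - chimeric: it overlaps a conserved protein-coding gene or lies
  within a proximity window (500 bp by default) of one.

The resulting flag triples feed a seven-region Venn summary and a
deterministic candidate ranking in which line-specific chimeric membrane
ORFs (the orf116b-like profile) come first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

from .mito_io import GeneModel, Interval, circular_distance
from .orf_caller import OrfRecord
from . import tm_predict

DEFAULT_PROXIMITY_WINDOW = 500

VENN_REGIONS = ("as_only", "tm_only", "ch_only", "as_tm", "as_ch", "tm_ch", "as_tm_ch")


@dataclass(frozen=True)
class NeighborHit:
    """Distance evidence from one ORF to one conserved gene."""

    gene: str
    gap_bp: int
    overlap_bp: int
    side: str  # upstream / downstream / overlapping (gene relative to ORF)


@dataclass
class OrfClassification:
    orf_id: str
    as_flag: bool
    tm_flag: bool
    ch_flag: bool
    nearest_gene: str | None
    gap_bp: int
    overlap_bp: int
    neighbor_side: str  # upstream / downstream / overlapping / none
    neighbors: list[NeighborHit] = field(default_factory=list)


@dataclass
class ScreenReport:
    """Class counts, Venn regions and the ranked candidate list."""

    n_orfs: int
    n_as: int
    n_tm: int
    n_ch: int
    venn: dict[str, int]
    candidates: list[OrfClassification]

    def to_json(self) -> str:
        payload = {
            "n_orfs": self.n_orfs,
            "n_as": self.n_as,
            "n_tm": self.n_tm,
            "n_ch": self.n_ch,
            "venn": self.venn,
            "candidates": [
                {k: v for k, v in asdict(c).items() if k != "neighbors"}
                for c in self.candidates
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _alignment_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, coverage) of the best global alignment of two proteins.

    Identity is matches over aligned (both-non-gap) columns; coverage is
    aligned columns over the longer sequence.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(a, b)[0]
    matches = aligned_cols = 0
    for (s1, e1), (s2, e2) in zip(*alignment.aligned):
        aligned_cols += e1 - s1
        matches += sum(1 for i in range(e1 - s1) if a[s1 + i] == b[s2 + i])
    longer = max(len(a), len(b))
    if aligned_cols == 0:
        return 0.0, 0.0
    return matches / aligned_cols, aligned_cols / longer


def find_specific_orfs(
    orfs_cms: Sequence[OrfRecord],
    orfs_maintainer: Sequence[OrfRecord],
    mode: str = "exact",
    id_min: float = 0.95,
    cov_min: float = 0.9,
) -> set[str]:
    """IDs of CMS ORFs with no protein counterpart in the maintainer set."""
    if mode not in ("exact", "identity"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact":
        maintainer_proteins = {o.protein for o in orfs_maintainer}
        return {o.id for o in orfs_cms if o.protein not in maintainer_proteins}
    specific: set[str] = set()
    for orf in orfs_cms:
        has_counterpart = False
        for other in orfs_maintainer:
            ident, cov = _alignment_identity(orf.protein, other.protein)
            if ident >= id_min and cov >= cov_min:
                has_counterpart = True
                break
        if not has_counterpart:
            specific.add(orf.id)
    return specific


def classify_chimeric(
    orf: OrfRecord,
    conserved: Sequence[GeneModel],
    genome_length: int,
    window: int = DEFAULT_PROXIMITY_WINDOW,
) -> OrfClassification:
    """Chimeric-axis classification of one ORF against conserved genes.

    Proximity is measured between nucleotide spans (whole gene span
    including introns), strand-agnostic.  ``neighbors`` lists every
    conserved gene overlapping the ORF or within the window; the nearest
    gene minimizes (overlap descending, then gap ascending).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    hits: list[tuple[int, int, str, str]] = []  # (overlap, gap, side, name)
    for gene in conserved:
        if gene.category != "protein_coding":
            raise ValueError(
                f"conserved list must contain protein_coding genes only, got "
                f"{gene.name} ({gene.category})"
            )
        span = gene.span(genome_length)
        gap, overlap = circular_distance(orf.interval, span, genome_length)
        if overlap > 0:
            side = "overlapping"
        else:
            d_down = (span.start - orf.interval.end) % genome_length
            d_up = (orf.interval.start - span.end) % genome_length
            side = "downstream" if d_down <= d_up else "upstream"
        hits.append((overlap, gap, side, gene.name))
    if not hits:
        return OrfClassification(orf.id, False, False, False, None, 0, 0, "none", [])
    hits.sort(key=lambda h: (-h[0], h[1], h[3]))
    best_overlap, best_gap, best_side, best_name = hits[0]
    neighbors = [
        NeighborHit(name, gap, overlap, side)
        for overlap, gap, side, name in hits
        if overlap > 0 or gap <= window
    ]
    ch = bool(neighbors)
    return OrfClassification(
        orf_id=orf.id,
        as_flag=False,
        tm_flag=False,
        ch_flag=ch,
        nearest_gene=best_name,
        gap_bp=best_gap,
        overlap_bp=best_overlap,
        neighbor_side=best_side,
        neighbors=neighbors,
    )


def classify_orfs(
    orfs: Sequence[OrfRecord],
    conserved: Sequence[GeneModel],
    genome_length: int,
    as_ids: set[str],
    window: int = DEFAULT_PROXIMITY_WINDOW,
    tm_params: dict | None = None,
) -> list[OrfClassification]:
    """Full AS/TM/CH classification of a list of ORFs."""
    tm_params = tm_params or {}
    out = []
    for orf in orfs:
        cls = classify_chimeric(orf, conserved, genome_length, window)
        cls.as_flag = orf.id in as_ids
        cls.tm_flag = tm_predict.is_tm_orf(orf, **tm_params)
        out.append(cls)
    return out


def venn_counts(classifications: Sequence[OrfClassification]) -> dict[str, int]:
    """Seven disjoint AS/TM/CH region counts plus the three marginals."""
    seen: set[str] = set()
    counts = {region: 0 for region in VENN_REGIONS}
    counts["none"] = 0
    for cls in classifications:
        if cls.orf_id in seen:
            raise ValueError(f"duplicate orf_id {cls.orf_id!r}")
        seen.add(cls.orf_id)
        key = {
            (True, False, False): "as_only",
            (False, True, False): "tm_only",
            (False, False, True): "ch_only",
            (True, True, False): "as_tm",
            (True, False, True): "as_ch",
            (False, True, True): "tm_ch",
            (True, True, True): "as_tm_ch",
            (False, False, False): "none",
        }[(cls.as_flag, cls.tm_flag, cls.ch_flag)]
        counts[key] += 1
    counts["n_as"] = counts["as_only"] + counts["as_tm"] + counts["as_ch"] + counts["as_tm_ch"]
    counts["n_tm"] = counts["tm_only"] + counts["as_tm"] + counts["tm_ch"] + counts["as_tm_ch"]
    counts["n_ch"] = counts["ch_only"] + counts["as_ch"] + counts["tm_ch"] + counts["as_tm_ch"]
    return counts


def rank_candidates(
    classifications: Sequence[OrfClassification],
) -> list[OrfClassification]:
    """Line-specific ORFs in deterministic priority order.

    AS&TM&CH first (the orf116b-like profile), then AS&CH, AS&TM, plain AS;
    ties broken by larger overlap, smaller gap, then id.
    """
    def tier(c: OrfClassification) -> int:
        if c.tm_flag and c.ch_flag:
            return 0
        if c.ch_flag:
            return 1
        if c.tm_flag:
            return 2
        return 3

    candidates = [c for c in classifications if c.as_flag]
    candidates.sort(key=lambda c: (tier(c), -c.overlap_bp, c.gap_bp, c.orf_id))
    return candidates


def build_report(classifications: Sequence[OrfClassification]) -> ScreenReport:
    counts = venn_counts(classifications)
    return ScreenReport(
        n_orfs=len(classifications),
        n_as=counts["n_as"],
        n_tm=counts["n_tm"],
        n_ch=counts["n_ch"],
        venn={k: counts[k] for k in VENN_REGIONS},
        candidates=rank_candidates(classifications),
    )


def classification_table(classifications: Sequence[OrfClassification]):
    """Flat pandas table of the classification evidence (for TSV export)."""
    import pandas as pd

    ranked = {c.orf_id: i + 1 for i, c in enumerate(rank_candidates(classifications))}
    rows = [
        {
            "orf_id": c.orf_id,
            "as": c.as_flag,
            "tm": c.tm_flag,
            "ch": c.ch_flag,
            "nearest_gene": c.nearest_gene or "",
            "gap_bp": c.gap_bp,
            "overlap_bp": c.overlap_bp,
            "neighbor_side": c.neighbor_side,
            "rank": ranked.get(c.orf_id, 0),
        }
        for c in classifications
    ]
    return pd.DataFrame(
        rows,
        columns=["orf_id", "as", "tm", "ch", "nearest_gene", "gap_bp",
                 "overlap_bp", "neighbor_side", "rank"],
    )
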