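"""End-to-end CMS candidate screen: ORF calling -> AS/TM/CH -> report.

``run_screen`` wires the stages together deterministically: call ORFs on
both genomes, drop the ORFs that are the annotated conserved genes
themselves, flag line-specific (AS), transmembrane (TM) and chimeric (CH)
ORFs, and emit the Venn summary plus a ranked candidate list.  All
tunables live in :class:`RunConfig` with the screen's standard defaults
(>100 aa ORFs, 500 bp chimeric window, 19/1.6 Kyte-Doolittle predictor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import cms_screen, orf_caller, tm_predict
from .cms_screen import ScreenReport, build_report, classification_table, classify_orfs
from .mito_io import CircularGenome, GeneModel, load_annotations, load_genome
from .orf_caller import OrfRecord, find_orfs, translate

logger = logging.getLogger("mitocms")


@dataclass
class RunConfig:
    """All screen tunables in one place (YAML round-trippable)."""

    cms_fasta: str = ""
    maintainer_fasta: str = ""
    cms_gff3: str = ""
    maintainer_gff3: str = ""
    outdir: str = "mitocms_out"
    min_aa: int = orf_caller.DEFAULT_MIN_AA
    start_codons: tuple[str, ...] = orf_caller.DEFAULT_START_CODONS
    tm_window: int = tm_predict.DEFAULT_WINDOW
    tm_threshold: float = tm_predict.DEFAULT_THRESHOLD
    tm_min_len: int = tm_predict.DEFAULT_MIN_LEN
    tm_min_gap: int = tm_predict.DEFAULT_MIN_GAP
    proximity_window: int = cms_screen.DEFAULT_PROXIMITY_WINDOW
    as_mode: str = "exact"
    max_mismatch: int = 0
    seed: int = 0
    log_level: str = "INFO"

    def tm_params(self) -> dict:
        return {
            "window": self.tm_window,
            "threshold": self.tm_threshold,
            "min_len": self.tm_min_len,
            "min_gap": self.tm_min_gap,
        }

    def to_yaml(self) -> str:
        payload = asdict(self)
        payload["start_codons"] = list(self.start_codons)
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "start_codons" in data:
            data["start_codons"] = tuple(data["start_codons"])
        return cls(**data)


def conserved_proteins(
    genome: CircularGenome, annotations: Sequence[GeneModel]
) -> set[str]:
    """Translated proteins of the annotated conserved protein-coding genes."""
    out = set()
    for gene in annotations:
        if gene.category != "protein_coding":
            continue
        cds = "".join(genome.fetch(e) for e in gene.exons)
        if gene.strand == "-":
            from .mito_io import revcomp

            cds = revcomp(cds)
        try:
            out.add(translate(cds))
        except ValueError:
            logger.warning("gene %s: CDS does not translate cleanly", gene.name)
    return out


def candidate_orfs(
    orfs: Sequence[OrfRecord],
    genome: CircularGenome,
    annotations: Sequence[GeneModel],
) -> list[OrfRecord]:
    """ORFs that are not themselves annotated conserved genes."""
    known = conserved_proteins(genome, annotations)
    return [o for o in orfs if o.protein not in known]


def run_screen(config: RunConfig) -> ScreenReport:
    """Execute the full screen and write all report artifacts."""
    logging.basicConfig(level=config.log_level)
    cms_genome = load_genome(config.cms_fasta)
    maintainer_genome = load_genome(config.maintainer_fasta)
    cms_ann = load_annotations(config.cms_gff3, cms_genome)
    mnt_ann = (
        load_annotations(config.maintainer_gff3, maintainer_genome)
        if config.maintainer_gff3
        else []
    )
    return screen_in_memory(
        cms_genome, cms_ann, maintainer_genome, mnt_ann, config
    )


def screen_in_memory(
    cms_genome: CircularGenome,
    cms_ann: Sequence[GeneModel],
    maintainer_genome: CircularGenome,
    mnt_ann: Sequence[GeneModel],
    config: RunConfig | None = None,
) -> ScreenReport:
    """The screen on already-loaded objects; writes artifacts if an
    output directory is configured."""
    config = config or RunConfig()
    orfs_cms = find_orfs(
        cms_genome, min_aa=config.min_aa, start_codons=config.start_codons
    )
    orfs_mnt = find_orfs(
        maintainer_genome, min_aa=config.min_aa, start_codons=config.start_codons
    )
    logger.info("ORFs called: %d (CMS) / %d (maintainer)", len(orfs_cms), len(orfs_mnt))
    candidates = candidate_orfs(orfs_cms, cms_genome, cms_ann)
    as_ids = cms_screen.find_specific_orfs(candidates, orfs_mnt, mode=config.as_mode)
    conserved = [g for g in cms_ann if g.category == "protein_coding"]
    classifications = classify_orfs(
        candidates,
        conserved,
        cms_genome.length,
        as_ids,
        window=config.proximity_window,
        tm_params=config.tm_params(),
    )
    report = build_report(classifications)
    logger.info(
        "screen: %d ORFs, %d AS / %d TM / %d CH",
        report.n_orfs, report.n_as, report.n_tm, report.n_ch,
    )
    if config.outdir:
        _write_artifacts(report, classifications, config)
    return report


def _write_artifacts(report, classifications, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    classification_table(classifications).to_csv(
        outdir / "classification.tsv", sep="\t", index=False
    )
    (outdir / "report.json").write_text(report.to_json() + "\n")
    (outdir / "config.yaml").write_text(config.to_yaml())
    lines = [
        "CMS candidate screen summary",
        f"ORFs classified: {report.n_orfs}",
        f"AS-ORFs: {report.n_as}  TM-ORFs: {report.n_tm}  CH-ORFs: {report.n_ch}",
        "Venn regions: "
        + ", ".join(f"{k}={v}" for k, v in report.venn.items()),
    ]
    if report.candidates:
        top = report.candidates[0]
        evidence = [
            flag
            for flag, on in (("AS", top.as_flag), ("TM", top.tm_flag), ("CH", top.ch_flag))
            if on
        ]
        lines.append(
            f"Top candidate: {top.orf_id} [{'+'.join(evidence)}] "
            f"nearest gene {top.nearest_gene} "
            f"(overlap {top.overlap_bp} bp, gap {top.gap_bp} bp, {top.neighbor_side})"
        )
    else:
        lines.append("Top candidate: none (no line-specific ORFs)")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
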