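"""In-silico RT-PCR for co-transcription tests.

A rearrangement-born CMS ORF is co-transcribed with its neighbouring
conserved gene when a single transcript covers both.  A primer pair with
the forward primer inside the ORF and the reverse primer inside the
neighbour therefore yields an amplicon on the CMS co-transcript but not on
the maintainer transcript, which lacks the ORF.  This module predicts that
band pattern by exact (optionally mismatch-tolerant) primer-site matching;
no hybridization thermodynamics are modelled because the readout is
presence/absence of a product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .mito_io import CircularGenome, Interval, revcomp


@dataclass
class TranscriptModel:
    """A (spliced) transcript carried as RNA-as-DNA sequence."""

    id: str
    genome_id: str
    strand: str
    intervals: list[Interval]
    sequence: str

    @classmethod
    def from_genome(
        cls,
        genome: CircularGenome,
        intervals: Sequence[Interval],
        strand: str = "+",
        id: str | None = None,
    ) -> "TranscriptModel":
        seq = "".join(genome.fetch(iv) for iv in intervals)
        if strand == "-":
            seq = revcomp(seq)
        return cls(
            id=id or f"{genome.id}:transcript",
            genome_id=genome.id,
            strand=strand,
            intervals=list(intervals),
            sequence=seq,
        )


@dataclass(frozen=True)
class PrimerPair:
    name: str
    fwd: str
    rev: str

    def __post_init__(self) -> None:
        for label, seq in (("fwd", self.fwd), ("rev", self.rev)):
            if not 15 <= len(seq) <= 35:
                raise ValueError(
                    f"primer {self.name}/{label}: length {len(seq)} outside 15-35 nt"
                )


@dataclass(frozen=True)
class Product:
    fwd_pos: int  # 0-based template position of the forward primer 5' base
    rev_pos: int  # 0-based template position of the product's last base, so
    # that length == rev_pos - fwd_pos + 1
    length: int


@dataclass
class AmpliconPrediction:
    present: bool
    length: int | None
    fwd_pos: int | None
    rev_pos: int | None
    multiproduct: bool = False
    products: list[Product] = field(default_factory=list)


def _match_sites(
    template: str, probe: str, max_mismatch: int, three_prime_index: int
) -> list[int]:
    """Start positions where ``probe`` matches with <= max_mismatch
    mismatches and an exact base at ``three_prime_index`` (probe-local)."""
    sites = []
    n, m = len(template), len(probe)
    for p in range(n - m + 1):
        if template[p + three_prime_index] != probe[three_prime_index]:
            continue
        mismatches = 0
        for i in range(m):
            if template[p + i] != probe[i]:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        if mismatches <= max_mismatch:
            sites.append(p)
    return sites


def predict_amplicon(
    template: TranscriptModel | str,
    pair: PrimerPair,
    max_mismatch: int = 0,
) -> AmpliconPrediction:
    """Predict the PCR product(s) of one primer pair on one template.

    The forward primer must match the template sense strand and the
    reverse-complemented reverse primer must match downstream of it; the
    3'-terminal base of each primer must match exactly.  The primary
    product pairs the leftmost forward site with its nearest downstream
    reverse site; additional discontiguous products are returned too,
    flagged ``multiproduct``.
    """
    seq = template.sequence if isinstance(template, TranscriptModel) else template
    if not seq:
        raise ValueError("empty template")
    fwd = pair.fwd.upper()
    rc_rev = revcomp(pair.rev.upper())
    # rev primer 3' end pairs with the first base of the revcomp site
    fwd_sites = _match_sites(seq, fwd, max_mismatch, len(fwd) - 1)
    rev_sites = _match_sites(seq, rc_rev, max_mismatch, 0)
    products: list[Product] = []
    used_rev: set[int] = set()
    for f in fwd_sites:
        downstream = [r for r in rev_sites if r >= f + len(fwd)]
        if not downstream:
            continue
        r = min(downstream)
        if r in used_rev:
            continue  # nested product sharing the same reverse site
        used_rev.add(r)
        products.append(Product(f, r + len(rc_rev) - 1, r + len(rc_rev) - f))
    if not products:
        return AmpliconPrediction(False, None, None, None)
    first = products[0]
    return AmpliconPrediction(
        present=True,
        length=first.length,
        fwd_pos=first.fwd_pos,
        rev_pos=first.rev_pos,
        multiproduct=len(products) > 1,
        products=products,
    )


def evaluate_cotranscription(
    models: Sequence[TranscriptModel],
    pairs: Sequence[PrimerPair],
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """Template x primer-pair presence matrix with product lengths."""
    if not models or not pairs:
        return pd.DataFrame(
            columns=["template", "pair", "present", "length"]
        )
    names = [p.name for p in pairs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate primer pair names: {sorted(names)}")
    rows = []
    for model in models:
        for pair in pairs:
            pred = predict_amplicon(model, pair, max_mismatch)
            rows.append(
                {
                    "template": model.id,
                    "pair": pair.name,
                    "present": pred.present,
                    "length": pred.length if pred.present else 0,
                }
            )
    return pd.DataFrame(rows, columns=["template", "pair", "present", "length"])


def load_primers(path: str | Path) -> list[PrimerPair]:
    """Read a primer TSV with columns name, fwd, rev."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"name", "fwd", "rev"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing primer columns {sorted(missing)}")
    return [PrimerPair(r["name"], r["fwd"].upper(), r["rev"].upper()) for _, r in df.iterrows()]


def write_primers(pairs: Sequence[PrimerPair], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": p.name, "fwd": p.fwd, "rev": p.rev} for p in pairs]
    ).to_csv(path, sep="\t", index=False)
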