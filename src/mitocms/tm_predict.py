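"""Hydropathy-based transmembrane segment prediction.

CMS candidate proteins are typically membrane proteins, so the screen
flags ORFs whose protein carries at least one predicted membrane-spanning
segment.  The predictor is a classic Kyte-Doolittle sliding-window scan:
a 19-residue window whose mean hydropathy reaches 1.6 is the canonical
criterion for a membrane-spanning helix.  It is deterministic and
dependency-free; it is not an HMM and will not reproduce TMHMM calls on
arbitrary real proteins (segment *counts* on the archetypes used here are
the behavioural contract).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Kyte & Doolittle hydropathy index, one value per standard residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_LEN = 18
DEFAULT_MIN_GAP = 5


@dataclass(frozen=True)
class TmSegment:
    """A predicted membrane-spanning segment (1-based inclusive residues)."""

    start_res: int
    end_res: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end_res - self.start_res + 1


def _residue_values(protein: str) -> np.ndarray:
    values = np.empty(len(protein))
    for i, res in enumerate(protein.upper()):
        try:
            values[i] = KYTE_DOOLITTLE[res]
        except KeyError:
            raise ValueError(f"unknown residue {res!r} at position {i + 1}") from None
    return values


def hydropathy_profile(protein: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Windowed mean hydropathy; entry i is the window centred at residue
    i + window//2 (0-based), i.e. a plain sliding mean of length
    ``len(protein) - window + 1``."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    values = _residue_values(protein)
    if len(values) < window:
        raise ValueError(f"protein length {len(values)} shorter than window {window}")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")


def predict_tm_segments(
    protein: str,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    min_gap: int = DEFAULT_MIN_GAP,
) -> list[TmSegment]:
    """Maximal above-threshold runs of window centres, expanded to full
    windows, merged across gaps < ``min_gap`` residues, filtered to
    ``min_len``.  Proteins shorter than the window yield no segments."""
    if len(protein) < window:
        return []
    profile = hydropathy_profile(protein, window)
    above = profile >= threshold
    runs: list[tuple[int, int]] = []  # 1-based residue spans
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((i + 1, j + window))  # expand centres to full windows
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] - 1 < min_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    values = _residue_values(protein)
    segments = [
        TmSegment(s, e, float(values[s - 1 : e].mean()))
        for s, e in merged
        if e - s + 1 >= min_len
    ]
    return segments


def is_tm_orf(
    orf,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    min_gap: int = DEFAULT_MIN_GAP,
) -> bool:
    """True iff the ORF's protein has >= 1 predicted TM segment."""
    protein = orf.protein if hasattr(orf, "protein") else orf
    return bool(predict_tm_segments(protein, window, threshold, min_len, min_gap))


def tm_report(orfs, **params) -> "pandas.DataFrame":
    """Per-ORF TM summary table (orf_id, n_segments, coordinates, hydropathy)."""
    import pandas as pd

    rows = []
    for orf in orfs:
        segs = predict_tm_segments(orf.protein, **params)
        rows.append(
            {
                "orf_id": orf.id,
                "n_segments": len(segs),
                "segments": ";".join(f"{s.start_res}-{s.end_res}" for s in segs),
                "mean_hydropathy": (
                    round(float(np.mean([s.mean_hydropathy for s in segs])), 4)
                    if segs
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows, columns=["orf_id", "n_segments", "segments", "mean_hydropathy"])
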