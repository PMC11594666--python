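"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available
(base-membership sets, rotation + linear scan, explicit sliding means)
and is deliberately kept independent of the package implementations it
checks.
"""

from __future__ import annotations

STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "ACG", "ATT"}

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def interval_bases(start: int, end: int, wraps: bool, L: int) -> set[int]:
    if wraps:
        return set(range(start, L)) | set(range(0, end))
    return set(range(start, end))


def circular_distance_oracle(bases_a: set[int], bases_b: set[int], L: int):
    """(gap, overlap) by enumerating base memberships."""
    overlap = len(bases_a & bases_b)
    if overlap:
        return 0, overlap
    best = min(
        min((a - b) % L, (b - a) % L) for a in bases_a for b in bases_b
    )
    return best - 1, 0


def _linear_orfs_with_upstream_stop(seq: str, min_aa: int):
    """ORFs in a linear window whose stop-bounded segment is fully
    visible (an in-frame stop precedes the start)."""
    out = []
    for frame in range(3):
        start = None
        stop_seen = False
        for p in range(frame, len(seq) - 2, 3):
            codon = seq[p : p + 3]
            if codon in STOPS:
                if start is not None and stop_seen:
                    nt = p + 3 - start
                    if nt // 3 - 1 >= min_aa:
                        out.append((start, nt))
                start = None
                stop_seen = True
            elif stop_seen and start is None and codon in STARTS:
                start = p
    return out


def circular_orfs_oracle(seq: str, min_aa: int):
    """All maximal ORFs on a circle, as {(genome_start, strand, nt_len)},
    by rotating to every origin and scanning linearly."""
    L = len(seq)
    found = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for r in range(L):
            # 3 extra bases so a segment spanning the whole circle can show
            # one stop codon as both its upstream and terminal boundary
            rotated = s[r:] + s[:r] + s[r : r + 3]
            for local, nt in _linear_orfs_with_upstream_stop(rotated, min_aa):
                if nt > L:
                    continue
                local_abs = (r + local) % L  # position on strand s
                if strand == "+":
                    gstart = local_abs
                else:
                    gstart = (L - local_abs - nt) % L
                found.add((gstart, strand, nt))
    return found


def sliding_mean_oracle(values, window):
    out = []
    for i in range(len(values) - window + 1):
        out.append(sum(values[i : i + window]) / window)
    return out


def amplicon_oracle(template: str, fwd: str, rev: str):
    """(present, length) by naive substring scanning, exact matching."""
    rc = revcomp(rev)
    fwd_sites = [
        i for i in range(len(template) - len(fwd) + 1)
        if template[i : i + len(fwd)] == fwd
    ]
    rev_sites = [
        i for i in range(len(template) - len(rc) + 1)
        if template[i : i + len(rc)] == rc
    ]
    for f in fwd_sites:
        down = [r for r in rev_sites if r >= f + len(fwd)]
        if down:
            r = min(down)
            return True, r + len(rc) - f
    return False, None
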