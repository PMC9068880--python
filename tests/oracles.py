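"""Independent oracles, written separately from the package code paths.

The melting-temperature oracle is a literal pen-and-paper summation over the
published unified nearest-neighbor table (dict lookups, complement fallback,
math.log) rather than the package's vectorized encoding.  The hit-count
oracle is a brute-force both-strand full scan of the reference with an
explicit per-base mismatch count.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

R = 1.987  # cal / (K mol)

# dH (kcal/mol), dS (cal/K/mol) for the ten unique Watson-Crick stacks.
STACKS = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def tm_oracle(
    seq: str,
    ct: float = 5e-9,
    na: float = 1.0,
    formamide_pct: float = 0.0,
    formamide_coeff: float = 0.65,
) -> float:
    """Two-state nearest-neighbor Tm by literal table summation, in degC."""
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in STACKS:
            pair = revcomp(pair)
        h, s = STACKS[pair]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        if terminal in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    if seq == revcomp(seq):
        ds += -1.4
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(na)
    tm_k = dh * 1000.0 / (ds_salt + R * math.log(ct))
    return tm_k - 273.15 - formamide_coeff * formamide_pct


def mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def brute_force_loci(
    target: str, contigs: Dict[str, str], max_mismatches: int
) -> List[Tuple[str, int, str]]:
    """Every maximal locus matching the target on either strand.

    Scans every reference position explicitly; overlapping match starts on
    the same contig/strand collapse into one locus (the leftmost start).
    """
    length = len(target)
    binding = revcomp(target)
    raw = []
    for name, seq in contigs.items():
        for pos in range(len(seq) - length + 1):
            window = seq[pos : pos + length]
            if mismatches(window, target) <= max_mismatches:
                raw.append((name, pos, "+"))
            if mismatches(window, binding) <= max_mismatches:
                raw.append((name, pos, "-"))
    merged = []
    last = {}
    for name, pos, strand in sorted(raw, key=lambda t: (t[0], t[2], t[1])):
        key = (name, strand)
        if key in last and pos < last[key]:
            last[key] = max(last[key], pos + length)
            continue
        merged.append((name, pos, strand))
        last[key] = pos + length
    return sorted(merged)
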