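"""Candidate window enumeration and hybridization-thermodynamics screening.

Melting temperatures use the unified nearest-neighbor DNA parameter set
(10 Watson-Crick stack enthalpies/entropies plus terminal initiation terms)
with the two-state transition formula

    Tm = dH / (dS + R * ln(C_T / x)) - 273.15

at a probe concentration of 5 nM with probe in excess (x = 1), both
configurable through :class:`~hcrprobe.sequences.DesignParameters`.  The
working-buffer correction lowers Tm for sub-molar monovalent salt (entropy
adjustment, or the Owczarzy reciprocal form) and subtracts a linear formamide
penalty of 0.65 degC per percent (v/v).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .sequences import (
    DesignParameters,
    HybridizationConditions,
    TranscriptRecord,
    ValidationError,
    reverse_complement,
)

#: Gas constant in cal / (K mol), matching the nearest-neighbor literature.
GAS_CONSTANT = 1.987

# Unified nearest-neighbor stack parameters: dH in kcal/mol, dS in cal/(K mol),
# keyed by the 5'->3' dinucleotide of one strand.  The ten unique stacks are
# listed; the remaining six are filled in below from reverse-complement
# symmetry (e.g. TT == AA read on the other strand).
_NN_UNIQUE: dict[str, Tuple[float, float]] = {
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

# Duplex initiation terms per terminal base pair.
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)

NN_TABLE: dict[str, Tuple[float, float]] = dict(_NN_UNIQUE)
for _dinuc, _vals in _NN_UNIQUE.items():
    _rc = reverse_complement(_dinuc)
    NN_TABLE.setdefault(_rc, _vals)

# Vectorized lookup arrays indexed by 4*code(first) + code(second).
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_NN_DH = np.zeros(16)
_NN_DS = np.zeros(16)
for _dinuc, (_dh, _ds) in NN_TABLE.items():
    _idx = 4 * _BASE_CODE[_dinuc[0]] + _BASE_CODE[_dinuc[1]]
    _NN_DH[_idx] = _dh
    _NN_DS[_idx] = _ds


@dataclass
class ProbeCandidate:
    """One probe-length window on a transcript with screening annotations.

    ``target_seq`` is the transcript (sense) subsequence; ``binding_seq`` is
    its reverse complement, i.e. the sequence the probe's binding region will
    carry.  Verdict fields stay ``None`` until the corresponding stage runs.
    """

    transcript_id: str
    window: Tuple[int, int]
    target_seq: str
    binding_seq: str
    gc: Optional[float] = None
    tm_raw_c: Optional[float] = None
    tm_corrected_c: Optional[float] = None
    passed_thermo: Optional[bool] = None
    unique: Optional[bool] = None
    n_loci: Optional[int] = None

    @property
    def id(self) -> str:
        return f"{self.transcript_id}:{self.window[0]}-{self.window[1]}"

    @property
    def start(self) -> int:
        return self.window[0]

    @property
    def end(self) -> int:
        return self.window[1]


def gc_content(seq: str) -> float:
    """Fraction of G+C bases; raises on an empty sequence."""
    if not seq:
        raise ValidationError("gc_content of empty sequence is undefined")
    return (seq.count("G") + seq.count("C")) / len(seq)


def longest_homopolymer(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if seq else 0


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def enumerate_windows(
    transcript: TranscriptRecord, probe_len: int = 25
) -> List[ProbeCandidate]:
    """All probe_len windows of the transcript, excluding any containing N.

    Returns candidates in transcript order with thermodynamic fields unset.
    A transcript shorter than ``probe_len`` yields an empty list (callers
    record the warning in the design report).
    """
    seq = transcript.sequence
    n = len(seq)
    if n < probe_len:
        return []
    # Prefix sums of N positions let each window test for N in O(1).
    has_n = np.concatenate(([0], np.cumsum(_encode(seq) == ord("N"))))
    out: List[ProbeCandidate] = []
    for start in range(n - probe_len + 1):
        end = start + probe_len
        if has_n[end] - has_n[start]:
            continue
        target = seq[start:end]
        out.append(
            ProbeCandidate(
                transcript_id=transcript.id,
                window=(start, end),
                target_seq=target,
                binding_seq=reverse_complement(target),
            )
        )
    return out


def _duplex_dh_ds(seq: str) -> Tuple[float, float]:
    codes = np.array([_BASE_CODE[b] for b in seq])
    idx = 4 * codes[:-1] + codes[1:]
    dh = float(_NN_DH[idx].sum())
    ds = float(_NN_DS[idx].sum())
    for terminal in (seq[0], seq[-1]):
        inc = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += inc[0]
        ds += inc[1]
    if seq == reverse_complement(seq):
        ds += -1.4  # self-complementary symmetry correction
    return dh, ds


def melting_temperature(
    seq: str,
    conditions: HybridizationConditions,
    params: Optional[DesignParameters] = None,
) -> Tuple[float, float]:
    """Nearest-neighbor Tm of ``seq`` against its perfect complement.

    Returns ``(tm_raw_c, tm_corrected_c)``: the 1 M Na+ reference Tm and the
    Tm corrected to the given salt molarity and formamide fraction.
    """
    params = params or DesignParameters()
    if len(seq) < 8:
        raise ValidationError("melting_temperature requires length >= 8")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValidationError(f"non-ACGT character(s) {sorted(bad)} in Tm input")

    dh, ds = _duplex_dh_ds(seq)
    r_ln_ct = GAS_CONSTANT * math.log(params.probe_conc_molar)
    tm_raw_k = dh * 1000.0 / (ds + r_ln_ct)

    na = conditions.na_molar
    if params.salt_correction == "santalucia":
        ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(na)
        tm_salt_k = dh * 1000.0 / (ds_salt + r_ln_ct)
    else:  # owczarzy reciprocal correction
        fgc = gc_content(seq)
        inv = (
            1.0 / tm_raw_k
            + (4.29 * fgc - 3.95) * 1e-5 * math.log(na)
            + 9.40e-6 * math.log(na) ** 2
        )
        tm_salt_k = 1.0 / inv

    tm_raw_c = tm_raw_k - 273.15
    tm_corrected_c = (
        tm_salt_k - 273.15 - params.formamide_coeff_c_per_pct * conditions.formamide_pct
    )
    return tm_raw_c, tm_corrected_c


def screen_candidates(
    candidates: Sequence[ProbeCandidate],
    conditions: HybridizationConditions,
    params: DesignParameters,
) -> List[ProbeCandidate]:
    """Annotate every candidate with GC, Tm, and a pass/fail thermo verdict.

    The verdict is a pure function of the candidate's own sequence and the
    parameters: GC within [gc_min, gc_max], corrected Tm at least
    ``tm_margin_c`` above the hybridization temperature, and no homopolymer
    run longer than ``max_homopolymer``.  All candidates are retained with
    verdicts set; nothing is dropped silently.
    """
    tm_floor = conditions.temperature_c + params.tm_margin_c
    for cand in candidates:
        cand.gc = gc_content(cand.target_seq)
        cand.tm_raw_c, cand.tm_corrected_c = melting_temperature(
            cand.target_seq, conditions, params
        )
        cand.passed_thermo = (
            params.gc_min <= cand.gc <= params.gc_max
            and cand.tm_corrected_c >= tm_floor
            and longest_homopolymer(cand.target_seq) <= params.max_homopolymer
        )
    return list(candidates)
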