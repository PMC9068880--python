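"""Off-target screening: drop probes whose binding sequence maps to more
than one reference locus.

The built-in matcher reports every maximal reference interval, on either
strand, where a candidate's target window matches with at most
``max_mismatches`` substitutions (indels are not modeled; a gapped external
aligner can be used instead via :func:`import_sam_hits`).  Candidate loci are
found from an exact k-mer seed index when the pigeonhole guarantee
``(max_mismatches + 1) * k <= probe_len`` holds; otherwise an exact
vectorized full scan of the reference is used, so hit counts always agree
with a brute-force scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam

from .sequences import (
    DesignParameters,
    ParseError,
    ValidationError,
    reverse_complement,
)
from .thermo import ProbeCandidate

Locus = Tuple[str, int, str]  # contig, 0-based start, strand


@dataclass
class HitSummary:
    candidate_id: str
    n_loci: int
    loci: List[Locus]


@dataclass
class ReferenceIndex:
    """Exact k-mer index over both strands of a reference, plus raw arrays.

    ``index`` maps each k-mer to the forward-coordinate positions where it
    occurs: strand '+' entries are the contig's own k-mers, strand '-'
    entries the reverse complement of the window starting at that position.
    K-mers containing N are not indexed (contigs with Ns are indexed around
    the Ns), but N positions remain in the arrays and mismatch everything.
    """

    source: str
    k: int
    index: Dict[str, List[Locus]]
    contigs: Dict[str, str]
    _arrays: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def array(self, contig: str) -> np.ndarray:
        if contig not in self._arrays:
            self._arrays[contig] = np.frombuffer(
                self.contigs[contig].encode("ascii"), dtype=np.uint8
            )
        return self._arrays[contig]


def _read_reference(reference: str | Path | Mapping[str, str]) -> Dict[str, str]:
    if isinstance(reference, Mapping):
        return {name: seq.upper() for name, seq in reference.items()}
    from Bio import SeqIO

    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference), "fasta")
    }
    return contigs


def build_index(
    reference_fasta: str | Path | Mapping[str, str], k: int = 11
) -> ReferenceIndex:
    """Build the two-strand exact k-mer index of a reference FASTA.

    ``reference_fasta`` may also be a mapping of contig name to sequence.
    """
    contigs = _read_reference(reference_fasta)
    if not contigs or all(len(s) == 0 for s in contigs.values()):
        raise ValidationError("empty reference: nothing to index")
    if k < 1:
        raise ValidationError("seed length k must be positive")
    index: Dict[str, List[Locus]] = {}
    for name, seq in contigs.items():
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((name, pos, "+"))
            index.setdefault(reverse_complement(kmer), []).append((name, pos, "-"))
    return ReferenceIndex(
        source=str(reference_fasta) if not isinstance(reference_fasta, Mapping) else "<dict>",
        k=k,
        index=index,
        contigs=contigs,
    )


def _merge_loci(raw: Sequence[Locus], length: int) -> List[Locus]:
    """Collapse overlapping match intervals on the same contig/strand."""
    merged: List[Locus] = []
    cur_end = None
    for contig, start, strand in sorted(set(raw)):
        if (
            merged
            and merged[-1][0] == contig
            and merged[-1][2] == strand
            and start < cur_end
        ):
            cur_end = max(cur_end, start + length)
            continue
        merged.append((contig, start, strand))
        cur_end = start + length
    return merged


def _hamming_le(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def _seed_hits(target: str, index: ReferenceIndex, mm: int) -> List[Locus]:
    length = len(target)
    binding = reverse_complement(target)
    raw: List[Locus] = []
    seen: set = set()
    for i in range(mm + 1):
        off = i * index.k
        kmer = target[off : off + index.k]
        for contig, pos, strand in index.index.get(kmer, ()):
            if strand == "+":
                start = pos - off
            else:
                start = pos - (length - off - index.k)
            key = (contig, start, strand)
            if key in seen:
                continue
            seen.add(key)
            seq = index.contigs[contig]
            if start < 0 or start + length > len(seq):
                continue
            window = seq[start : start + length]
            query = target if strand == "+" else binding
            if _hamming_le(window, query, mm):
                raw.append(key)
    return _merge_loci(raw, length)


def _scan_hits(
    targets: Sequence[str], index: ReferenceIndex, mm: int, chunk: int = 64
) -> List[List[Locus]]:
    """Exact full scan: match positions for every target on both strands."""
    if not targets:
        return []
    length = len(targets[0])
    plus = np.stack([np.frombuffer(t.encode(), dtype=np.uint8) for t in targets])
    minus = np.stack(
        [
            np.frombuffer(reverse_complement(t).encode(), dtype=np.uint8)
            for t in targets
        ]
    )
    raw: List[List[Locus]] = [[] for _ in targets]
    for contig, seq in index.contigs.items():
        if len(seq) < length:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(index.array(contig), length)
        for strand, probes in (("+", plus), ("-", minus)):
            for lo in range(0, len(targets), chunk):
                block = probes[lo : lo + chunk]
                mism = (windows[None, :, :] != block[:, None, :]).sum(axis=2)
                rows, cols = np.nonzero(mism <= mm)
                for r, c in zip(rows.tolist(), cols.tolist()):
                    raw[lo + r].append((contig, c, strand))
    return [_merge_loci(r, length) for r in raw]


def count_hits(
    candidate: ProbeCandidate, index: ReferenceIndex, max_mismatches: int = 2
) -> HitSummary:
    """Reference loci matching the candidate with <= max_mismatches substitutions."""
    target = candidate.target_seq
    if (max_mismatches + 1) * index.k <= len(target):
        loci = _seed_hits(target, index, max_mismatches)
    else:
        loci = _scan_hits([target], index, max_mismatches)[0]
    return HitSummary(candidate_id=candidate.id, n_loci=len(loci), loci=loci)


def apply_uniqueness(
    candidates: Sequence[ProbeCandidate],
    index: ReferenceIndex,
    params: DesignParameters,
) -> List[ProbeCandidate]:
    """Set the ``unique`` verdict on every candidate that passed thermo.

    A candidate is unique when it matches at most ``params.max_hits`` loci
    and at least one (a probe absent from the design reference cannot be
    vetted and is dropped unless ``keep_unmapped`` is set).
    """
    todo = [c for c in candidates if c.passed_thermo]
    if not todo:
        return list(candidates)
    if (params.max_mismatches + 1) * index.k <= params.probe_len:
        loci_lists = [
            _seed_hits(c.target_seq, index, params.max_mismatches) for c in todo
        ]
    else:
        loci_lists = _scan_hits(
            [c.target_seq for c in todo], index, params.max_mismatches
        )
    for cand, loci in zip(todo, loci_lists):
        cand.n_loci = len(loci)
        if cand.n_loci == 0:
            cand.unique = bool(params.keep_unmapped)
        else:
            cand.unique = cand.n_loci <= params.max_hits
    return list(candidates)


def apply_sam_hits(
    candidates: Sequence[ProbeCandidate],
    hits: Mapping[str, HitSummary],
    params: DesignParameters,
) -> List[ProbeCandidate]:
    """Set uniqueness verdicts from an external aligner's hit summaries.

    Candidates absent from ``hits`` are treated as unmapped (0 loci).
    """
    for cand in candidates:
        if not cand.passed_thermo:
            continue
        summary = hits.get(cand.id)
        cand.n_loci = summary.n_loci if summary else 0
        if cand.n_loci == 0:
            cand.unique = bool(params.keep_unmapped)
        else:
            cand.unique = cand.n_loci <= params.max_hits
    return list(candidates)


def _validate_sam_text(sam_path: str | Path) -> None:
    # Only runs after pysam has rejected the file, to name the offending line.
    with open(sam_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ParseError(
                    f"{sam_path}: line {lineno}: SAM record has "
                    f"{len(fields)} fields, expected >= 11"
                )
            try:
                int(fields[1]), int(fields[3])
            except ValueError:
                raise ParseError(
                    f"{sam_path}: line {lineno}: FLAG/POS not integer"
                ) from None


def import_sam_hits(
    sam_path: str | Path, min_score: Optional[int] = None
) -> Dict[str, HitSummary]:
    """Summarize an external aligner's SAM output per candidate.

    Counts distinct loci over primary and secondary alignments (supplementary
    records are partial alignments of the same locus and are skipped; the
    unmapped flag yields 0 loci).  ``min_score`` is an optional floor on the
    AS alignment-score tag.
    """
    loci_by_name: Dict[str, List[Locus]] = {}
    try:
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
            for rec in sam:
                name = rec.query_name
                loci_by_name.setdefault(name, [])
                if rec.is_unmapped or rec.is_supplementary:
                    continue
                if min_score is not None and rec.has_tag("AS"):
                    if rec.get_tag("AS") < min_score:
                        continue
                strand = "-" if rec.is_reverse else "+"
                loci_by_name[name].append(
                    (rec.reference_name, rec.reference_start, strand)
                )
    except (ValueError, OSError) as exc:
        _validate_sam_text(sam_path)
        raise ParseError(f"{sam_path}: malformed SAM: {exc}") from exc
    return {
        name: HitSummary(
            candidate_id=name, n_loci=len(set(loci)), loci=sorted(set(loci))
        )
        for name, loci in loci_by_name.items()
    }
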