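"""Domain types, coordinate conventions, and file I/O for probe design.

Coordinates are 0-based, half-open everywhere inside the library and in BED
output.  The CLI accepts 1-based inclusive CDS coordinates (the convention of
GenBank-style annotations) and converts them on ingestion via
:func:`parse_cds_arg` / :func:`read_cds_table`.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ProbeDesignError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ProbeDesignError):
    """An input violates a documented invariant."""


class ParseError(ProbeDesignError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(ProbeDesignError):
    """A configuration value is missing or inconsistent."""


VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Minimum transcript length for one probe pair at default geometry
#: (25 + 2 + 25 nt).
MIN_DESIGN_LENGTH = 52


class Region(Enum):
    """Transcript region of a probe-pair footprint.

    UNANNOTATED is used only when the transcript carries no CDS interval.
    """

    UTR5 = "UTR5"
    ORF = "ORF"
    UTR3 = "UTR3"
    UNANNOTATED = "UNANNOTATED"


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValidationError(
            f"non-IUPAC character(s) {sorted(bad)} in sequence for reverse complement"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptRecord:
    """A sense-strand mRNA sequence with an optional CDS interval.

    The CDS is a half-open ``(start, end)`` interval in 0-based transcript
    coordinates; ``None`` means the transcript is unannotated and all probe
    pairs will be designated :attr:`Region.UNANNOTATED`.
    """

    id: str
    sequence: str
    cds: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValidationError(
                f"transcript {self.id!r}: invalid character(s) {sorted(bad)}"
            )
        if self.cds is not None:
            start, end = self.cds
            if not (0 <= start < end <= len(self.sequence)):
                raise ValidationError(
                    f"transcript {self.id!r}: CDS [{start}, {end}) outside "
                    f"sequence of length {len(self.sequence)}"
                )
            self.cds = (int(start), int(end))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HybridizationConditions:
    """Hybridization buffer conditions the probes must tolerate.

    Defaults are 37 degC, 1 M monovalent Na+, 30% (v/v) formamide -- the
    standard HCR hybridization buffer.
    """

    temperature_c: float = 37.0
    na_molar: float = 1.0
    formamide_pct: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 < self.temperature_c < 100.0):
            raise ValidationError("temperature_c must lie in (0, 100)")
        if self.na_molar <= 0:
            raise ValidationError("na_molar must be positive")
        if not (0.0 <= self.formamide_pct <= 50.0):
            raise ValidationError("formamide_pct must lie in [0, 50]")


DEFAULT_REGION_PRIORITY: Tuple[Region, ...] = (Region.ORF, Region.UTR3, Region.UTR5)


@dataclass
class DesignParameters:
    """Tunable parameters of the design pipeline.

    The geometry defaults (25-nt probes, 2-nt spacer, at most 36 pairs) are
    the HCR v3 split-initiator conventions; the screening defaults (GC bounds,
    Tm margin, homopolymer cap) are conventional probe-mining values.
    """

    probe_len: int = 25
    spacer_len: int = 2
    max_pairs: int = 36
    region_priority: Tuple[Region, ...] = DEFAULT_REGION_PRIORITY
    gc_min: float = 0.25
    gc_max: float = 0.75
    tm_margin_c: float = 5.0
    max_homopolymer: int = 4
    max_hits: int = 1
    max_mismatches: int = 2
    seed_k: int = 11
    probe_conc_molar: float = 5e-9
    formamide_coeff_c_per_pct: float = 0.65
    salt_correction: str = "santalucia"
    keep_unmapped: bool = False

    def __post_init__(self) -> None:
        if self.probe_len < 10:
            raise ValidationError("probe_len must be >= 10")
        if self.spacer_len < 0:
            raise ValidationError("spacer_len must be >= 0")
        if self.max_pairs < 1:
            raise ValidationError("max_pairs must be >= 1")
        self.region_priority = tuple(self.region_priority)
        if sorted(r.value for r in self.region_priority) != sorted(
            r.value for r in DEFAULT_REGION_PRIORITY
        ):
            raise ValidationError(
                "region_priority must be a permutation of {ORF, UTR5, UTR3}"
            )
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValidationError("require 0 <= gc_min <= gc_max <= 1")
        if self.salt_correction not in ("santalucia", "owczarzy"):
            raise ValidationError(
                "salt_correction must be 'santalucia' or 'owczarzy'"
            )
        if self.probe_conc_molar <= 0:
            raise ValidationError("probe_conc_molar must be positive")

    @property
    def pair_footprint(self) -> int:
        """Total transcript footprint of one pair (2*probe_len + spacer_len)."""
        return 2 * self.probe_len + self.spacer_len


def parse_cds_arg(text: str) -> Tuple[int, int]:
    """Parse a ``START-END`` CDS argument (1-based inclusive) to 0-based half-open."""
    try:
        start_s, end_s = text.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValidationError(f"CDS must be START-END, got {text!r}") from exc
    if start < 1 or end < start:
        raise ValidationError(f"CDS {text!r}: need 1 <= START <= END")
    return start - 1, end


def read_cds_table(path: str | Path) -> dict[str, Tuple[int, int]]:
    """Read a two-column annotation TSV (id, START-END 1-based inclusive)."""
    table: dict[str, Tuple[int, int]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            table[fields[0]] = parse_cds_arg(fields[1])
    return table


def read_transcripts(
    fasta_path: str | Path,
    annotation: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> list[TranscriptRecord]:
    """Read transcripts from FASTA, attaching CDS intervals by record id.

    Sequences are uppercased and U is converted to T.  ``annotation`` maps
    record id to a 0-based half-open CDS interval (use :func:`read_cds_table`
    or :func:`parse_cds_arg` to convert 1-based inclusive input).
    """
    path = Path(fasta_path)
    if not path.exists():
        raise ValidationError(f"FASTA file not found: {path}")
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: FASTA must start with a '>' header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cds = annotation.get(rec.id) if annotation else None
        records.append(TranscriptRecord(id=rec.id, sequence=str(rec.seq), cds=cds))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def _plate_wells() -> Iterable[str]:
    """Generic 96-well positions in column order (A1, B1, ... H1, A2, ...)."""
    plate = 1
    while True:
        for col in range(1, 13):
            for row in string.ascii_uppercase[:8]:
                yield f"{row}{col}" if plate == 1 else f"P{plate}:{row}{col}"
        plate += 1


def write_outputs(probe_set, out_prefix: str | Path) -> dict[str, Path]:
    """Write the order sheet (TSV), footprints (BED), oligos (FASTA), report (JSON).

    Returns a mapping from format name to written path.  Raises
    :class:`ValidationError` for an empty probe set before touching the disk.
    """
    if not probe_set.pairs:
        raise ValidationError(
            f"transcript {probe_set.transcript_id!r}: empty probe set, nothing to write"
        )
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tid = probe_set.transcript_id

    rows = []
    bed_lines = []
    fasta_records = []
    wells = _plate_wells()
    for pair in probe_set.pairs:
        for tag, cand, oligo in (
            ("P1", pair.p1, pair.oligo1),
            ("P2", pair.p2, pair.oligo2),
        ):
            name = f"{tid}_pair{pair.index:03d}_{tag}"
            rows.append((name, next(wells), oligo))
            bed_lines.append(
                f"{tid}\t{cand.window[0]}\t{cand.window[1]}\tpair{pair.index:03d}_{tag}"
            )
            fasta_records.append(SeqRecord(Seq(oligo), id=name, description=""))

    paths = {
        "tsv": prefix.with_suffix(".order.tsv"),
        "bed": prefix.with_suffix(".probes.bed"),
        "fasta": prefix.with_suffix(".oligos.fasta"),
        "json": prefix.with_suffix(".report.json"),
    }
    with open(paths["tsv"], "w") as handle:
        handle.write("oligo_name\twell\tsequence\n")
        for name, well, oligo in rows:
            handle.write(f"{name}\t{well}\t{oligo}\n")
    with open(paths["bed"], "w") as handle:
        handle.write("\n".join(bed_lines) + "\n")
    with open(paths["fasta"], "w") as handle:
        SeqIO.write(fasta_records, handle, "fasta")
    with open(paths["json"], "w") as handle:
        json.dump(probe_set.report.to_dict() if probe_set.report else {}, handle, indent=2)
        handle.write("\n")
    return paths
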