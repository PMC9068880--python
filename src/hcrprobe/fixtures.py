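"""Synthetic transcript and genome fixtures for desk-scale pipeline runs.

The generator emulates a design target plus its reference: a random
transcript of chosen length and GC with a defined CDS, embedded once in a
synthetic genome between random flanks, optionally with segments of the
transcript planted a second time elsewhere to trigger the multi-mapping
filter.  The manifest records the ground truth: which duplicated intervals
were planted, and which candidate window starts must therefore be dropped.

GC composition is hit exactly (up to rounding): the generator fixes the
number of G+C positions to round(gc * length) and shuffles, rather than
sampling each base independently, so the realized GC of every fixture is
within 1/length of the target.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .sequences import TranscriptRecord, ValidationError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureManifest:
    """Ground truth for one generated fixture."""

    seed: int
    transcript: TranscriptRecord
    genome: dict  # contig name -> sequence
    genome_path: Optional[str] = None
    transcript_path: Optional[str] = None
    planted_duplications: List[Tuple[int, int]] = field(default_factory=list)
    expected_dropped_windows: List[int] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence with exactly round(gc * length) G+C bases."""
    n_gc = int(round(gc * length))
    is_gc = np.zeros(length, dtype=bool)
    is_gc[:n_gc] = True
    rng.shuffle(is_gc)
    # Within each class, G vs C and A vs T are chosen uniformly.
    pick = rng.integers(0, 2, size=length)
    codes = np.where(is_gc, np.where(pick, 1, 2), np.where(pick, 0, 3))
    return bytes(_BASES[codes]).decode("ascii")


def generate_fixture(
    seed: int,
    length: int = 2000,
    gc: float = 0.5,
    cds: Optional[Tuple[int, int]] = None,
    n_duplications: int = 0,
    dup_len: int = 300,
    flank: int = 1000,
    probe_len: int = 25,
    out_dir: Optional[str | Path] = None,
    transcript_id: str = "fixture_tx",
) -> FixtureManifest:
    """Generate a reproducible transcript + genome fixture.

    ``cds`` is a 0-based half-open interval on the transcript.  Duplicated
    segments of ``dup_len`` nt are copied from evenly spaced positions in the
    transcript into extra genome sequence after the right flank; every
    candidate window lying fully inside a planted segment then matches two
    genomic loci and must be dropped by the uniqueness filter.
    """
    if length < 200:
        raise ValidationError("fixture length must be >= 200")
    if cds is not None and not (0 <= cds[0] < cds[1] <= length):
        raise ValidationError(f"fixture CDS {cds} outside transcript [0, {length})")
    if n_duplications > 0 and n_duplications * dup_len > length:
        raise ValidationError("duplications do not fit in the transcript")

    rng = np.random.default_rng(seed)
    tx_seq = _random_seq(rng, length, gc)
    transcript = TranscriptRecord(id=transcript_id, sequence=tx_seq, cds=cds)

    left = _random_seq(rng, flank, gc)
    right = _random_seq(rng, flank, gc)
    pieces = [left, tx_seq, right]

    duplications: List[Tuple[int, int]] = []
    if n_duplications:
        stride = length // n_duplications
        for i in range(n_duplications):
            start = i * stride + (stride - dup_len) // 2
            duplications.append((start, start + dup_len))
        for start, end in duplications:
            pieces.append(_random_seq(rng, 50, gc))  # spacer between copies
            pieces.append(tx_seq[start:end])
    genome_seq = "".join(pieces)
    genome = {"fixture_genome": genome_seq}

    dropped = sorted(
        {
            s
            for start, end in duplications
            for s in range(start, end - probe_len + 1)
        }
    )

    manifest = FixtureManifest(
        seed=seed,
        transcript=transcript,
        genome=genome,
        planted_duplications=duplications,
        expected_dropped_windows=dropped,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tx_path = out / "transcript.fasta"
        genome_path = out / "genome.fasta"
        _write_fasta(tx_path, transcript_id, tx_seq)
        _write_fasta(genome_path, "fixture_genome", genome_seq)
        manifest.transcript_path = str(tx_path)
        manifest.genome_path = str(genome_path)
        with open(out / "manifest.json", "w") as handle:
            json.dump(
                {
                    "seed": seed,
                    "transcript_id": transcript_id,
                    "length": length,
                    "gc": gc,
                    "cds": list(cds) if cds else None,
                    "planted_duplications": [list(d) for d in duplications],
                    "expected_dropped_windows": dropped,
                },
                handle,
                indent=2,
            )
            handle.write("\n")
    return manifest


def _write_fasta(path: Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as handle:
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")
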