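"""Region designation and prioritized selection of probe pairs.

Each pair is designated by the transcript region (5'UTR / ORF / 3'UTR)
containing the majority of its footprint bases; selection then walks the
regions in priority order (ORF, then 3'UTR, then 5'UTR by default), sweeping
pairs 5'->3' within each region and keeping every pair whose footprint is
disjoint from all pairs already kept, until the cap (36 by default) is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .sequences import DesignParameters, Region, TranscriptRecord
from .pairing import ProbePair


@dataclass
class ProbeSet:
    """Final selection for one transcript, sorted by footprint start."""

    transcript_id: str
    pairs: List[ProbePair]
    per_region_counts: Dict[str, int]
    report: Optional["DesignReport"] = None  # noqa: F821 - set by the pipeline


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def designate_region(
    pair: ProbePair,
    transcript: TranscriptRecord,
    params: Optional[DesignParameters] = None,
) -> Region:
    """Region containing the majority of the pair's footprint bases.

    An exact tie is resolved toward the earlier region in the priority order
    (ORF by default).  Transcripts without a CDS yield UNANNOTATED.
    """
    if transcript.cds is None:
        return Region.UNANNOTATED
    params = params or DesignParameters()
    cds_start, cds_end = transcript.cds
    fp = pair.footprint
    counts = {
        Region.UTR5: _overlap(fp, (0, cds_start)),
        Region.ORF: _overlap(fp, (cds_start, cds_end)),
        Region.UTR3: _overlap(fp, (cds_end, len(transcript))),
    }
    best = max(counts.values())
    for region in params.region_priority:
        if counts[region] == best:
            return region
    return Region.ORF  # unreachable: priority covers all regions


def select_pairs(
    pairs: Sequence[ProbePair], params: DesignParameters
) -> ProbeSet:
    """Greedy prioritized selection of up to ``max_pairs`` disjoint pairs.

    Deterministic: within each region pairs are swept left-to-right by
    footprint start; a pair is kept iff its footprint shares no transcript
    base with any already-kept pair (across regions).  An empty input yields
    an empty ProbeSet (a warning condition, not an error).
    """
    transcript_id = pairs[0].p1.transcript_id if pairs else ""
    order = list(params.region_priority) + [Region.UNANNOTATED]
    kept: List[ProbePair] = []
    for region in order:
        if len(kept) >= params.max_pairs:
            break
        for pair in sorted(
            (p for p in pairs if p.region == region), key=lambda p: p.footprint
        ):
            if len(kept) >= params.max_pairs:
                break
            if all(_overlap(pair.footprint, k.footprint) == 0 for k in kept):
                kept.append(pair)
    kept.sort(key=lambda p: p.footprint)
    for i, pair in enumerate(kept, start=1):
        pair.index = i
    counts: Dict[str, int] = {}
    for pair in kept:
        counts[pair.region.value] = counts.get(pair.region.value, 0) + 1
    return ProbeSet(
        transcript_id=transcript_id, pairs=kept, per_region_counts=counts
    )
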