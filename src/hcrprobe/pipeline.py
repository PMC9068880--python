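"""End-to-end orchestration: enumerate -> screen -> uniqueness -> pair ->
designate -> select -> assemble, with a per-stage design report."""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from typing import Any, Dict, List, Mapping, Optional

from . import __version__
from .pairing import Amplifier, attach_initiators, pair_candidates
from .selection import ProbeSet, designate_region, select_pairs
from .sequences import (
    DesignParameters,
    HybridizationConditions,
    TranscriptRecord,
)
from .specificity import (
    HitSummary,
    ReferenceIndex,
    apply_sam_hits,
    apply_uniqueness,
)
from .thermo import enumerate_windows, screen_candidates

logger = logging.getLogger("hcrprobe")


@dataclass
class DesignReport:
    """Per-stage counts of the design funnel for one transcript.

    Invariant on every run: n_windows >= n_pass_thermo >= n_unique and
    n_pairs_selected <= min(n_pairs_candidate, max_pairs).
    """

    transcript_id: str
    n_windows: int = 0
    n_pass_thermo: int = 0
    n_unique: int = 0
    n_pairs_candidate: int = 0
    n_pairs_selected: int = 0
    per_region_counts: Dict[str, int] = field(default_factory=dict)
    parameters_echo: Dict[str, Any] = field(default_factory=dict)
    tool_version: str = __version__
    timestamp: str = ""
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def _echo_parameters(
    params: DesignParameters, conditions: HybridizationConditions
) -> Dict[str, Any]:
    echo = dataclasses.asdict(params)
    echo["region_priority"] = [r.value for r in params.region_priority]
    echo["conditions"] = dataclasses.asdict(conditions)
    return echo


def design_probes(
    transcript: TranscriptRecord,
    amplifier: Amplifier,
    conditions: Optional[HybridizationConditions] = None,
    params: Optional[DesignParameters] = None,
    reference_index: Optional[ReferenceIndex] = None,
    sam_hits: Optional[Mapping[str, HitSummary]] = None,
) -> ProbeSet:
    """Design a probe set for one transcript.

    Specificity screening runs when a reference index or external SAM hit
    summaries are supplied; with neither, every thermodynamically passing
    candidate is retained (the uniqueness stage is a no-op and the report's
    n_unique equals n_pass_thermo).
    """
    conditions = conditions or HybridizationConditions()
    params = params or DesignParameters()
    report = DesignReport(
        transcript_id=transcript.id,
        parameters_echo=_echo_parameters(params, conditions),
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )

    candidates = enumerate_windows(transcript, params.probe_len)
    report.n_windows = len(candidates)
    if not candidates:
        report.warnings.append(
            f"transcript {transcript.id!r} shorter than probe length "
            f"{params.probe_len}: no candidate windows"
        )
    screen_candidates(candidates, conditions, params)
    report.n_pass_thermo = sum(1 for c in candidates if c.passed_thermo)

    if sam_hits is not None:
        apply_sam_hits(candidates, sam_hits, params)
        report.n_unique = sum(1 for c in candidates if c.passed_thermo and c.unique)
    elif reference_index is not None:
        apply_uniqueness(candidates, reference_index, params)
        report.n_unique = sum(1 for c in candidates if c.passed_thermo and c.unique)
    else:
        report.n_unique = report.n_pass_thermo

    pairs = pair_candidates(candidates, params)
    report.n_pairs_candidate = len(pairs)
    for pair in pairs:
        pair.region = designate_region(pair, transcript, params)

    probe_set = select_pairs(pairs, params)
    probe_set.transcript_id = transcript.id
    report.n_pairs_selected = len(probe_set.pairs)
    report.per_region_counts = dict(probe_set.per_region_counts)
    if not probe_set.pairs:
        report.warnings.append(
            f"transcript {transcript.id!r}: zero probe pairs survived"
        )
    for pair in probe_set.pairs:
        attach_initiators(pair, amplifier)
    probe_set.report = report
    logger.info(
        "%s: %d windows -> %d pass thermo -> %d unique -> %d candidate pairs "
        "-> %d selected",
        transcript.id,
        report.n_windows,
        report.n_pass_thermo,
        report.n_unique,
        report.n_pairs_candidate,
        report.n_pairs_selected,
    )
    return probe_set
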