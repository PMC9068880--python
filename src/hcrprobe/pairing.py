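"""Assembly of adjacent candidates into HCR v3 split-initiator probe pairs.

A pair is two probe windows on the transcript separated by exactly the spacer
length (2 nt by default).  The 5'-ward window ("P1") receives the amplifier's
upstream initiator arm, the 3'-ward window ("P2") the downstream arm; split
arms only nucleate hairpin amplification when both probes bind side by side,
so the arm placement convention is fixed and the config can swap arms if a
user's amplifier definitions differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .sequences import ConfigError, DesignParameters, Region, ValidationError
from .thermo import ProbeCandidate


@dataclass(frozen=True)
class Amplifier:
    """One HCR amplifier's split-initiator arms and arm/binding linkers."""

    name: str
    initiator_up: str
    initiator_down: str
    arm_spacer_up: str = "AA"
    arm_spacer_down: str = "AA"

    def __post_init__(self) -> None:
        for label, arm in (("initiator_up", self.initiator_up),
                           ("initiator_down", self.initiator_down)):
            if not arm or set(arm) - set("ACGT"):
                raise ConfigError(
                    f"amplifier {self.name!r}: {label} must be nonempty over ACGT"
                )
        for label, linker in (("arm_spacer_up", self.arm_spacer_up),
                              ("arm_spacer_down", self.arm_spacer_down)):
            if set(linker) - set("ACGT"):
                raise ConfigError(
                    f"amplifier {self.name!r}: {label} must be over ACGT"
                )


@dataclass
class ProbePair:
    """Two adjacent probe candidates and their assembled order-ready oligos."""

    p1: ProbeCandidate
    p2: ProbeCandidate
    spacer_interval: Tuple[int, int]
    index: Optional[int] = None
    region: Optional[Region] = None
    oligo1: Optional[str] = None
    oligo2: Optional[str] = None

    @property
    def footprint(self) -> Tuple[int, int]:
        """Half-open transcript interval covered by both windows and the spacer."""
        return (self.p1.window[0], self.p2.window[1])


def _passes(cand: ProbeCandidate) -> bool:
    # unique is None when no specificity screen ran; that is not a failure.
    return bool(cand.passed_thermo) and cand.unique is not False


def pair_candidates(
    candidates: Sequence[ProbeCandidate], params: DesignParameters
) -> List[ProbePair]:
    """Emit a pair for every window pair at offset probe_len + spacer_len.

    Both windows must pass every upstream filter.  Pairs are ordered by the
    P1 window start; overlapping pairs are allowed here (disjointness is
    enforced at selection).
    """
    offset = params.probe_len + params.spacer_len
    by_start: Dict[int, ProbeCandidate] = {
        c.window[0]: c for c in candidates if _passes(c)
    }
    pairs: List[ProbePair] = []
    for start in sorted(by_start):
        mate = by_start.get(start + offset)
        if mate is None:
            continue
        p1 = by_start[start]
        pairs.append(
            ProbePair(
                p1=p1,
                p2=mate,
                spacer_interval=(p1.window[1], mate.window[0]),
            )
        )
    return pairs


def attach_initiators(pair: ProbePair, amplifier: Amplifier) -> ProbePair:
    """Set the order-ready oligo sequences by exact concatenation (5'->3').

    oligo1 = initiator_up + arm_spacer_up + P1 binding region;
    oligo2 = P2 binding region + arm_spacer_down + initiator_down.
    No other edits are made, so each binding sequence appears verbatim.
    """
    pair.oligo1 = amplifier.initiator_up + amplifier.arm_spacer_up + pair.p1.binding_seq
    pair.oligo2 = pair.p2.binding_seq + amplifier.arm_spacer_down + amplifier.initiator_down
    return pair
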