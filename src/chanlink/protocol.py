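"""Pulse protocols for two-electrode voltage-clamp recordings.

A recording is a series of timed ligand applications: ten-second pulses of
PTX, GABA or DZ separated by washout in buffer, with the ligand series
bookended by PTX pulses that report the spontaneous (PTX-blockable) current
and anchor the rundown correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

from .exceptions import ProtocolError, UnknownLigandError

__all__ = ["LIGANDS", "PulseEvent", "validate_protocol", "has_ptx_bookends",
           "bookended_protocol"]

LIGANDS = ("PTX", "GABA", "DZ", "buffer")


@dataclass(frozen=True)
class PulseEvent:
    """A single timed ligand application.

    concentration is molar; t_start and duration in seconds.
    """

    ligand: str
    concentration: float
    t_start: float
    duration: float

    def __post_init__(self) -> None:
        if self.ligand not in LIGANDS:
            raise UnknownLigandError(
                f"unknown ligand {self.ligand!r}; expected one of {LIGANDS}"
            )
        if not self.duration > 0:
            raise ProtocolError("pulse duration must be > 0")
        if self.concentration < 0:
            raise ProtocolError("concentration must be >= 0")
        if self.t_start < 0:
            raise ProtocolError("t_start must be >= 0")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def to_dict(self) -> dict:
        return dict(ligand=self.ligand, concentration_M=self.concentration,
                    t_start_s=self.t_start, duration_s=self.duration)

    @classmethod
    def from_dict(cls, d: dict) -> "PulseEvent":
        return cls(d["ligand"], d["concentration_M"], d["t_start_s"], d["duration_s"])


def validate_protocol(events: Sequence[PulseEvent]) -> None:
    """Require time-ordered, non-overlapping events."""
    if not events:
        raise ProtocolError("protocol is empty")
    for prev, nxt in zip(events, events[1:]):
        if nxt.t_start < prev.t_start:
            raise ProtocolError("pulse events are not time-ordered")
        if nxt.t_start < prev.t_end:
            raise ProtocolError(
                f"pulses overlap: {prev.ligand} ends at {prev.t_end} s but "
                f"{nxt.ligand} starts at {nxt.t_start} s"
            )


def has_ptx_bookends(events: Sequence[PulseEvent]) -> bool:
    """True when the first and last non-buffer applications are PTX."""
    ligand_pulses = [e for e in events if e.ligand != "buffer"]
    return (len(ligand_pulses) >= 2
            and ligand_pulses[0].ligand == "PTX"
            and ligand_pulses[-1].ligand == "PTX")


def bookended_protocol(
    ligand: str,
    concentrations: Sequence[float],
    ptx_conc: float = 1e-3,
    duration: float = 10.0,
    gap: float = 60.0,
    t0: float = 30.0,
) -> List[PulseEvent]:
    """Standard recording protocol: a PTX pulse, the ligand series in
    ascending concentration, and a closing PTX pulse, each ``duration``
    seconds long with ``gap`` seconds of washout in between."""
    if ligand not in ("GABA", "DZ"):
        raise UnknownLigandError(f"series ligand must be GABA or DZ, got {ligand!r}")
    events = [PulseEvent("PTX", ptx_conc, t0, duration)]
    t = t0 + duration + gap
    for conc in sorted(concentrations):
        events.append(PulseEvent(ligand, conc, t, duration))
        t += duration + gap
    events.append(PulseEvent("PTX", ptx_conc, t, duration))
    validate_protocol(events)
    return events
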