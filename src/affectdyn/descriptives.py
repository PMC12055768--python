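"""Per-session descriptive aggregation of SPAFF code streams.

Produces, per actor and session: exact seconds and percentages per
code, the positive/negative valence totals, and the four meta-state
totals (positive affect, facilitate, negative affect, control) plus
Neutral.  Percentages are always computed from exact seconds and the
session's total coded seconds, never from re-rounded intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .codes import (
    CODES,
    META_STATES,
    NEGATIVE_CODES,
    POSITIVE_CODES,
    CodeStream,
)


@dataclass(frozen=True)
class SessionSummary:
    session_id: str
    actor: str
    per_code_seconds: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "per_code_seconds",
            {c: int(self.per_code_seconds.get(c, 0)) for c in CODES},
        )
        if self.total_seconds <= 0:
            raise ValueError("session has no coded seconds")

    @property
    def total_seconds(self) -> int:
        return sum(self.per_code_seconds.values())

    @property
    def per_code_percent(self) -> dict[str, float]:
        total = self.total_seconds
        return {c: s / total * 100.0 for c, s in self.per_code_seconds.items()}

    @property
    def total_positive_s(self) -> int:
        return sum(self.per_code_seconds[c] for c in POSITIVE_CODES)

    @property
    def total_negative_s(self) -> int:
        return sum(self.per_code_seconds[c] for c in NEGATIVE_CODES)

    @property
    def meta_seconds(self) -> dict[str, int]:
        return meta_states(self)

    @property
    def meta_percent(self) -> dict[str, float]:
        total = self.total_seconds
        return {m: s / total * 100.0 for m, s in self.meta_seconds.items()}


def summarize(stream: CodeStream, session_id: str) -> SessionSummary:
    """Count exact seconds per code for one actor's session stream."""
    stream.validate_codes()
    counts: dict[str, int] = {c: 0 for c in CODES}
    for code in stream.codes:
        counts[code] += 1
    return SessionSummary(
        session_id=session_id, actor=stream.actor, per_code_seconds=counts
    )


def meta_states(summary: SessionSummary) -> dict[str, int]:
    """Meta-state seconds: the fixed code groupings summed per session."""
    return {
        meta: sum(summary.per_code_seconds[c] for c in group)
        for meta, group in META_STATES.items()
    }


def session_total_from_table(per_code_seconds: Mapping[str, float]) -> int:
    """Total coded seconds as the sum of a per-code row.

    Session lengths are not recorded separately; the total used for
    percentages is the sum of the actor's per-code seconds.
    """
    return int(round(sum(per_code_seconds.values())))
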