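"""SPAFF code registry, weighting, and windowed score series.

The Specific Affect Coding System (SPAFF) assigns one of 20 mutually
exclusive affect codes to each second of a recorded interaction, per
actor.  Downstream modeling works on *weighted window scores*: each code
carries a signed weight (positive affect up, negative affect down) and
consecutive 6-second windows of per-second weights are summed into a
single score, turning a categorical stream into a numeric time series
(e.g. 900 s of material becomes 150 scores).

This module holds the canonical code set with its valence and meta-state
groupings, the configurable weight table, and the stream -> series
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

ACTORS = ("therapist", "client")

# Meta-state groupings: positive codes split into expressed positive
# affect vs. relationship-facilitating behavior; negative codes split
# into expressed negative affect vs. relationship-controlling behavior.
META_STATES: dict[str, tuple[str, ...]] = {
    "positive_affect": ("Affection", "Humor", "Surprise/Joy"),
    "facilitate": ("Low Validation", "High Validation", "Interest"),
    "negative_affect": (
        "Anger",
        "Sadness",
        "Whining",
        "Disgust",
        "Contempt",
        "Tension",
        "Tense Humor",
    ),
    "control": (
        "Belligerence",
        "Low Domineering",
        "High Domineering",
        "Criticism",
        "Defensiveness",
        "Stonewalling",
    ),
    "neutral": ("Neutral",),
}

#: All 20 canonical code names, in a stable order.
CODES: tuple[str, ...] = tuple(
    code for group in META_STATES.values() for code in group
)

#: code -> meta-state name
META_OF: dict[str, str] = {
    code: meta for meta, group in META_STATES.items() for code in group
}

# Valence used for the Total positive / Total negative session rows.
# Tense Humor counts toward the negative total (it expresses tension)
# even though some code lists describe it as a positive code; the
# negative_affect meta-state grouping and the session total arithmetic
# both place it on the negative side.
VALENCE_OF: dict[str, str] = {
    code: (
        "neutral"
        if meta == "neutral"
        else "positive"
        if meta in ("positive_affect", "facilitate")
        else "negative"
    )
    for code, meta in META_OF.items()
}

POSITIVE_CODES: tuple[str, ...] = tuple(
    c for c in CODES if VALENCE_OF[c] == "positive"
)
NEGATIVE_CODES: tuple[str, ...] = tuple(
    c for c in CODES if VALENCE_OF[c] == "negative"
)

# Default weights, in dimensionless affect units per second.  The
# historical weighting conventions of the marital-interaction literature
# are followed: strong positive codes +4, mild positive +2, Neutral a
# small positive nudge, mild negative -1, hostile codes -2 to -4.  These
# are an implementer default and are fully configurable.
DEFAULT_WEIGHTS: dict[str, float] = {
    "Affection": 4.0,
    "High Validation": 4.0,
    "Humor": 4.0,
    "Surprise/Joy": 4.0,
    "Low Validation": 2.0,
    "Interest": 2.0,
    "Tense Humor": -1.0,
    "Neutral": 0.1,
    "Tension": -1.0,
    "Whining": -1.0,
    "Sadness": -1.0,
    "Anger": -1.0,
    "Low Domineering": -1.0,
    "High Domineering": -1.0,
    "Belligerence": -2.0,
    "Defensiveness": -2.0,
    "Criticism": -2.0,
    "Stonewalling": -2.0,
    "Disgust": -3.0,
    "Contempt": -4.0,
}

DEFAULT_WINDOW_S = 6


class UnknownCodeError(ValueError):
    """A stream or table refers to a code outside the canonical set."""


@dataclass(frozen=True)
class WeightTable:
    """Signed per-second weight for every SPAFF code."""

    mapping: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))

    def __getitem__(self, code: str) -> float:
        try:
            return self.mapping[code]
        except KeyError:
            raise UnknownCodeError(f"no weight for code {code!r}") from None

    def validate(self) -> list[str]:
        return validate_weight_table(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"weights": dict(self.mapping)}, fh, sort_keys=True
            )

    @classmethod
    def from_yaml(cls, path) -> "WeightTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        mapping = data.get("weights", data) if isinstance(data, dict) else None
        if not isinstance(mapping, dict):
            raise ValueError(f"weight config {path} is not a mapping")
        return cls(mapping={str(k): float(v) for k, v in mapping.items()})


def validate_weight_table(weights: WeightTable) -> list[str]:
    """Report (not raise) violations of coverage and sign conventions.

    An empty list means the table covers all 20 codes, every
    negative-valence code has weight <= 0, every positive-valence code
    has weight >= 0.  Neutral may carry a small positive constant.
    """
    violations: list[str] = []
    for code in CODES:
        if code not in weights.mapping:
            violations.append(f"missing code: {code}")
    for code, w in weights.mapping.items():
        if code not in META_OF:
            violations.append(f"unknown code: {code}")
            continue
        valence = VALENCE_OF[code]
        if valence == "negative" and w > 0:
            violations.append(
                f"sign constraint: negative code {code} has weight {w} > 0"
            )
        elif valence == "positive" and w < 0:
            violations.append(
                f"sign constraint: positive code {code} has weight {w} < 0"
            )
    return violations


@dataclass(frozen=True)
class CodeStream:
    """One actor's per-second SPAFF code sequence (0-based seconds)."""

    actor: str
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.actor not in ACTORS:
            raise ValueError(f"actor must be one of {ACTORS}, got {self.actor!r}")
        object.__setattr__(self, "codes", tuple(self.codes))
        if not self.codes:
            raise ValueError("empty code stream")

    @property
    def length_s(self) -> int:
        return len(self.codes)

    def validate_codes(self) -> None:
        for t, code in enumerate(self.codes):
            if code not in META_OF:
                raise UnknownCodeError(
                    f"unknown code {code!r} at second {t} "
                    f"({self.actor} stream)"
                )


@dataclass(frozen=True)
class WeightedSeries:
    """Per-actor windowed weighted score series (one score per window)."""

    actor: str
    scores: np.ndarray
    window_s: int = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        if self.actor not in ACTORS:
            raise ValueError(f"actor must be one of {ACTORS}, got {self.actor!r}")
        object.__setattr__(
            self, "scores", np.asarray(self.scores, dtype=float)
        )
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if self.window_s < 1:
            raise ValueError("window_s must be >= 1")

    def __len__(self) -> int:
        return len(self.scores)


def weight_and_window(
    stream: CodeStream,
    weights: WeightTable | None = None,
    window_s: int = DEFAULT_WINDOW_S,
) -> WeightedSeries:
    """Convert a per-second code stream into summed window scores.

    Each second's code is replaced by its weight and consecutive
    half-open windows ``[k*window_s, (k+1)*window_s)`` are summed; a
    trailing partial window is discarded.

    Raises on an empty stream, ``window_s < 1``, or a code with no
    weight (reported with its time index).
    """
    if weights is None:
        weights = WeightTable()
    if window_s < 1:
        raise ValueError("window_s must be >= 1")
    per_second = np.empty(stream.length_s, dtype=float)
    for t, code in enumerate(stream.codes):
        if code not in weights.mapping:
            raise UnknownCodeError(
                f"unknown code {code!r} at second {t} ({stream.actor} stream)"
            )
        per_second[t] = weights.mapping[code]
    n_windows = stream.length_s // window_s
    if n_windows == 0:
        scores = np.empty(0, dtype=float)
    else:
        scores = per_second[: n_windows * window_s].reshape(
            n_windows, window_s
        ).sum(axis=1)
    return WeightedSeries(actor=stream.actor, scores=scores, window_s=window_s)
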