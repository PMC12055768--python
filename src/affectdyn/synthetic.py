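"""Synthetic dyad data with known ground truth.

Raw per-second affect streams from the study sessions are not publicly
deposited, so every pipeline stage is exercised against generated data
instead: (1) per-second code streams from a sticky first-order Markov
chain with prescribed stationary code propensities and persistence,
emulating the long Neutral runs of real coded sessions; (2) windowed
score series simulated forward from a known dyad model with additive
Gaussian window noise, for parameter-recovery studies; (3) an exact
inverse that emits a code stream whose weighted 6-second sums reproduce
a given score series, for round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .codes import CODES, CodeStream, WeightTable, WeightedSeries
from .model import DyadModel, step


@dataclass(frozen=True)
class StreamSpec:
    """Sticky-Markov generator spec for one actor's code stream."""

    actor: str
    length_s: int
    code_propensity: Mapping[str, float]
    persistence: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length_s < 1:
            raise ValueError("length_s must be positive")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        probs = dict(self.code_propensity)
        for code in probs:
            if code not in CODES:
                raise ValueError(f"unknown code in propensities: {code!r}")
        total = sum(probs.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"propensities sum to {total}, not 1")
        if any(p < 0 for p in probs.values()):
            raise ValueError("propensities must be non-negative")
        object.__setattr__(self, "code_propensity", probs)


@dataclass(frozen=True)
class DyadSpec:
    """Forward-simulation spec for a dyad's windowed score series."""

    true_model: DyadModel
    n_windows: int
    noise_sd: float = 0.5
    seed: int | None = None
    start_perturbation_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_windows < 2:
            raise ValueError("need at least 2 windows")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_stream(spec: StreamSpec) -> CodeStream:
    """Draw a per-second stream: repeat the previous code with
    probability ``persistence``, else draw fresh from the propensities."""
    rng = np.random.default_rng(spec.seed)
    names = list(spec.code_propensity)
    probs = np.array([spec.code_propensity[c] for c in names])
    probs = probs / probs.sum()
    draws = rng.choice(len(names), size=spec.length_s, p=probs)
    if spec.persistence > 0:
        repeat = rng.random(spec.length_s) < spec.persistence
        repeat[0] = False
        for t in range(1, spec.length_s):
            if repeat[t]:
                draws[t] = draws[t - 1]
    return CodeStream(actor=spec.actor, codes=tuple(names[i] for i in draws))


def generate_dyad_series(
    spec: DyadSpec, overflow: float = 1e9
) -> tuple[WeightedSeries, WeightedSeries]:
    """Simulate (therapist, client) window scores from the true model.

    The state starts at the uninfluenced steady states plus a Gaussian
    perturbation and evolves by the dyad map with independent Gaussian
    window noise added to each actor's score.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.true_model
    state = (
        model.therapist.unss + spec.start_perturbation_sd * rng.standard_normal(),
        model.client.unss + spec.start_perturbation_sd * rng.standard_normal(),
    )
    T = np.empty(spec.n_windows)
    C = np.empty(spec.n_windows)
    T[0], C[0] = state
    for t in range(1, spec.n_windows):
        nxt = step(model, (T[t - 1], C[t - 1]))
        noise = spec.noise_sd * rng.standard_normal(2)
        T[t] = nxt[0] + noise[0]
        C[t] = nxt[1] + noise[1]
        if max(abs(T[t]), abs(C[t])) > overflow:
            raise RuntimeError(f"dyad simulation diverged at window {t}")
    return (
        WeightedSeries(actor="therapist", scores=T),
        WeightedSeries(actor="client", scores=C),
    )


def _weight_scale(weights: WeightTable) -> int:
    """Smallest power-of-ten multiplier making every weight integral."""
    vals = np.array(list(weights.mapping.values()), dtype=float)
    for scale in (1, 10, 100):
        if np.allclose(vals * scale, np.round(vals * scale), atol=1e-9):
            return scale
    raise ValueError("weights are not representable on a 0.01 grid")


def stream_for_series(
    series: WeightedSeries,
    weights: WeightTable | None = None,
    seed: int | None = None,
) -> CodeStream:
    """Emit per-second codes whose windowed weighted sums equal ``series``.

    Each window is an integer composition problem: choose ``window_s``
    codes whose weights sum to the window score.  Solved exactly by
    dynamic programming on the (integerised) weight grid; the seeded rng
    shuffles among equally valid codes so round trips are reproducible
    but not degenerate.  Raises when a window score is not achievable.
    """
    if weights is None:
        weights = WeightTable()
    rng = np.random.default_rng(seed)
    scale = _weight_scale(weights)
    w = series.window_s
    codes = sorted(weights.mapping)
    int_w = {c: int(round(weights.mapping[c] * scale)) for c in codes}
    values = sorted(set(int_w.values()))
    by_value: dict[int, list[str]] = {v: [] for v in values}
    for c in codes:
        by_value[int_w[c]].append(c)

    # reachable[j] = set of sums achievable with j seconds
    reachable = [set() for _ in range(w + 1)]
    reachable[0].add(0)
    for j in range(1, w + 1):
        for s in reachable[j - 1]:
            for v in values:
                reachable[j].add(s + v)

    out: list[str] = []
    for idx, score in enumerate(series.scores):
        target = int(round(score * scale))
        if abs(score * scale - target) > 1e-6 or target not in reachable[w]:
            raise ValueError(
                f"window {idx}: score {score} not achievable with the given weights"
            )
        remaining = target
        for j in range(w, 0, -1):
            opts = [v for v in values if remaining - v in reachable[j - 1]]
            # prefer balanced compositions (the value closest to the
            # per-second average still owed), so e.g. a zero window under
            # a zero Neutral weight comes out all-Neutral
            gap = min(abs(v - remaining / j) for v in opts)
            close = [v for v in opts if abs(v - remaining / j) <= gap + 1e-12]
            v = close[rng.integers(len(close))]
            names = by_value[v]
            out.append(names[rng.integers(len(names))])
            remaining -= v
    return CodeStream(actor=series.actor, codes=tuple(out))
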