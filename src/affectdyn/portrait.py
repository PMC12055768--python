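"""Phase portraits of the fitted dyad map.

The dyad state lives in the (client score, therapist score) plane.  A
portrait collects: short trajectories started from every point of a
rectangular lattice ("all potential starting coordinates", 10 updates
by default), the map's critical points with a stability and quadrant
label, and the projected session trajectory started from the average of
the first 10% of each actor's windowed scores.

Because the influence and repair terms are piecewise linear in the
partner's score, the plane decomposes into rectangles on which the map
is affine; critical points are found exactly by solving the 2x2 linear
fixed-point system in each rectangle and keeping solutions that lie in
their own rectangle.  Stability comes from the eigenvalues of the
region's Jacobian: all moduli < 1 is an attractor, exactly one > 1 a
saddle, otherwise a repeller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .codes import WeightedSeries
from .model import DyadModel, InfluenceFunction, RepairTerm, iterate, step

_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice of starting coordinates (client x, therapist y)."""

    client_range: tuple[float, float] = (-12.0, 12.0)
    therapist_range: tuple[float, float] = (-12.0, 12.0)
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if (
            self.client_range[0] >= self.client_range[1]
            or self.therapist_range[0] >= self.therapist_range[1]
        ):
            raise ValueError("degenerate grid range")

    def points(self) -> list[tuple[float, float]]:
        cs = np.arange(self.client_range[0], self.client_range[1] + self.step / 2, self.step)
        ts = np.arange(self.therapist_range[0], self.therapist_range[1] + self.step / 2, self.step)
        return [(float(t), float(c)) for c in cs for t in ts]


@dataclass(frozen=True)
class CriticalPoint:
    therapist: float
    client: float
    stability: str  # attractor | repeller | saddle
    quadrant: str

    @property
    def state(self) -> tuple[float, float]:
        return (self.therapist, self.client)


@dataclass(frozen=True)
class PhasePortrait:
    model: DyadModel
    grid: GridSpec
    steps: int
    trajectories: list[np.ndarray]
    critical_points: list[CriticalPoint]
    session_start: tuple[float, float] | None = None  # (C0, T0)
    session_trajectory: np.ndarray | None = None

    @property
    def session_end(self) -> tuple[float, float] | None:
        if self.session_trajectory is None:
            return None
        T, C = self.session_trajectory[-1]
        return (float(T), float(C))

    @property
    def attractors(self) -> list[CriticalPoint]:
        return [p for p in self.critical_points if p.stability == "attractor"]


def classify_quadrant(point: tuple[float, float]) -> str:
    """Quadrant label of a (therapist, client) state; axes are 'boundary'."""
    T, C = point
    if not (math.isfinite(T) and math.isfinite(C)):
        raise ValueError("non-finite point")
    if T == 0 or C == 0:
        return "boundary"
    t_side = "positive" if T > 0 else "negative"
    c_side = "positive" if C > 0 else "negative"
    return f"therapist {t_side}–client {c_side}"


def session_start(
    therapist: WeightedSeries,
    client: WeightedSeries,
    fraction: float = 0.10,
) -> tuple[float, float]:
    """Session starting coordinates (C0, T0): the mean of the first
    ceil(fraction * n) window scores per actor."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(therapist) == 0 or len(client) == 0:
        raise ValueError("empty series")
    k_t = math.ceil(fraction * len(therapist))
    k_c = math.ceil(fraction * len(client))
    return (
        float(np.mean(client.scores[:k_c])),
        float(np.mean(therapist.scores[:k_t])),
    )


def _breakpoints(influence: InfluenceFunction, repair: RepairTerm) -> list[float]:
    pts = []
    if influence.neg_threshold is not None:
        pts.append(influence.neg_threshold)
    if influence.pos_threshold is not None:
        pts.append(influence.pos_threshold)
    if repair.active and repair.threshold is not None:
        pts.append(repair.threshold)
    return sorted(set(pts))


def _affine_on_interval(
    influence: InfluenceFunction, repair: RepairTerm, lo: float, hi: float
) -> tuple[float, float]:
    """Slope and intercept of I(z) + R(z) on the open interval (lo, hi)."""
    if math.isinf(lo) and math.isinf(hi):
        mid = 0.0
    elif math.isinf(lo):
        mid = hi - 1.0
    elif math.isinf(hi):
        mid = lo + 1.0
    else:
        mid = (lo + hi) / 2.0
    # probe at two interior points to recover the affine pieces
    d = 1e-4 if not (math.isinf(lo) or math.isinf(hi)) else 1.0
    span = (hi - lo) if not (math.isinf(lo) or math.isinf(hi)) else None
    if span is not None:
        d = span / 4.0
    z1, z2 = mid - d / 2, mid + d / 2
    f1 = float(influence(z1)) + float(repair(z1))
    f2 = float(influence(z2)) + float(repair(z2))
    slope = (f2 - f1) / (z2 - z1)
    intercept = f1 - slope * z1
    return slope, intercept


def _intervals(breaks: list[float]) -> list[tuple[float, float]]:
    edges = [-math.inf, *breaks, math.inf]
    return list(zip(edges[:-1], edges[1:]))


def find_critical_points(model: DyadModel, tol: float = 1e-8) -> list[CriticalPoint]:
    """Exact fixed points of the piecewise-affine dyad map, per region."""
    p_t, p_c = model.therapist, model.client
    c_intervals = _intervals(_breakpoints(p_t.influence_from_partner, p_t.repair))
    t_intervals = _intervals(_breakpoints(p_c.influence_from_partner, p_c.repair))
    found: list[CriticalPoint] = []
    for c_lo, c_hi in c_intervals:
        sT, cT = _affine_on_interval(p_t.influence_from_partner, p_t.repair, c_lo, c_hi)
        for t_lo, t_hi in t_intervals:
            sC, cC = _affine_on_interval(p_c.influence_from_partner, p_c.repair, t_lo, t_hi)
            # Fixed point of T' = r_T T + a_T + sT C + cT, C' = r_C C + a_C + sC T + cC
            A = np.array([[p_t.inertia - 1.0, sT], [sC, p_c.inertia - 1.0]])
            b = -np.array([p_t.initial_state + cT, p_c.initial_state + cC])
            if abs(np.linalg.det(A)) < 1e-14:
                continue
            T_star, C_star = np.linalg.solve(A, b)
            if not (
                c_lo - _EDGE_TOL <= C_star <= c_hi + _EDGE_TOL
                and t_lo - _EDGE_TOL <= T_star <= t_hi + _EDGE_TOL
            ):
                continue
            # verify against the true (possibly boundary-discontinuous) map
            T_next, C_next = step(model, (float(T_star), float(C_star)))
            if abs(T_next - T_star) > tol or abs(C_next - C_star) > tol:
                continue
            jac = np.array([[p_t.inertia, sT], [sC, p_c.inertia]])
            moduli = np.abs(np.linalg.eigvals(jac))
            if np.all(moduli < 1):
                stability = "attractor"
            elif np.sum(moduli > 1) == 1:
                stability = "saddle"
            else:
                stability = "repeller"
            point = CriticalPoint(
                therapist=float(T_star),
                client=float(C_star),
                stability=stability,
                quadrant=classify_quadrant((float(T_star), float(C_star))),
            )
            if not any(
                abs(point.therapist - q.therapist) < 1e-6
                and abs(point.client - q.client) < 1e-6
                for q in found
            ):
                found.append(point)
    return found


def build_portrait(
    model: DyadModel,
    grid: GridSpec | None = None,
    steps: int = 10,
    therapist_series: WeightedSeries | None = None,
    client_series: WeightedSeries | None = None,
    start_fraction: float = 0.10,
    overflow: float = 1e9,
) -> PhasePortrait:
    """Vector field, critical points and (optionally) the session path.

    Trajectories are ``steps`` iterations of the fitted map from every
    grid point.  When the session's score series are supplied, the
    projected session trajectory is iterated from the first-fraction
    average starting coordinates.
    """
    if grid is None:
        grid = GridSpec()
    if steps < 1:
        raise ValueError("steps must be >= 1")
    trajectories = [
        iterate(model, state, steps, overflow=overflow) for state in grid.points()
    ]
    critical = find_critical_points(model)
    start = traj = None
    if therapist_series is not None and client_series is not None:
        C0, T0 = session_start(therapist_series, client_series, start_fraction)
        start = (C0, T0)
        traj = iterate(model, (T0, C0), steps, overflow=overflow)
    return PhasePortrait(
        model=model,
        grid=grid,
        steps=steps,
        trajectories=trajectories,
        critical_points=critical,
        session_start=start,
        session_trajectory=traj,
    )


def render(portrait: PhasePortrait, path) -> None:
    """Write the portrait as an image (deterministic for fixed inputs).

    Grid trajectories are thin grey lines, attractors filled red dots,
    other critical points open markers; the session path is a black
    line from a green square (start) to a black circle (end).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for traj in portrait.trajectories:
        ax.plot(traj[:, 1], traj[:, 0], color="0.7", lw=0.5, zorder=1)
    for pt in portrait.critical_points:
        if pt.stability == "attractor":
            ax.plot(pt.client, pt.therapist, "o", color="red", ms=8, zorder=3)
        elif pt.stability == "saddle":
            ax.plot(pt.client, pt.therapist, "s", mfc="none", mec="red", ms=8, zorder=3)
        else:
            ax.plot(pt.client, pt.therapist, "^", mfc="none", mec="red", ms=8, zorder=3)
    if portrait.session_trajectory is not None:
        traj = portrait.session_trajectory
        ax.plot(traj[:, 1], traj[:, 0], color="black", lw=1.8, zorder=4)
        ax.plot(traj[0, 1], traj[0, 0], "s", color="green", ms=9, zorder=5)
        ax.plot(traj[-1, 1], traj[-1, 0], "o", color="black", ms=9, zorder=5)
    ax.axhline(0, color="0.4", lw=0.8)
    ax.axvline(0, color="0.4", lw=0.8)
    ax.set_xlabel("client score")
    ax.set_ylabel("therapist score")
    ax.set_xlim(*portrait.grid.client_range)
    ax.set_ylim(*portrait.grid.therapist_range)
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
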