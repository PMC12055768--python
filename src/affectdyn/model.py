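"""Coupled dyadic dynamical-systems model of windowed affect scores.

Each actor's next window score is modeled as a discrete-time update

    T[t+1] = r_T * T[t] + a_T + I_C(C[t]) + R_C(C[t])
    C[t+1] = r_C * C[t] + a_C + I_T(T[t]) + R_T(T[t])

where ``r`` is the actor's emotional *inertia* (tendency to remain in
the current state), ``a`` the *initial state* (uninfluenced
disposition), ``I`` the partner's piecewise-linear *influence function*
with a dead zone between a negative threshold ``nth`` and a positive
threshold ``pth``, and ``R`` an optional *repair* term: a constant
positive boost triggered when the partner's score drops below a
threshold ``kr``.  With no influence the actor relaxes geometrically to
the uninfluenced steady state ``unss = a / (1 - r)``.

Estimation follows the classical two-stage scheme for this model
family: (1) ``(a, r)`` by ordinary least squares on the transitions
where the partner is neutral (window score zero, optionally within a
small tolerance band); (2) influence thresholds by scanning the
observed partner scores and fitting regime slopes to the stage-1
residuals; (3) repair by scanning negative partner scores for a
constant residual lift, refitting the regime slopes jointly with it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from .codes import WeightedSeries

#: relative SSE tolerance treating two threshold candidates as tied
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class InfluenceFunction:
    """Piecewise-linear influence of the partner's score.

    ``I(z) = neg_slope*(z - nth)`` for ``z <= nth``; 0 in the dead zone
    ``nth < z < pth``; ``pos_slope*(z - pth)`` for ``z >= pth``.
    Continuous by construction.  With one threshold absent the function
    is bilinear; with both absent it is identically zero.
    """

    neg_threshold: float | None = None
    pos_threshold: float | None = None
    neg_slope: float = 0.0
    pos_slope: float = 0.0

    def __post_init__(self) -> None:
        if (
            self.neg_threshold is not None
            and self.pos_threshold is not None
            and self.neg_threshold > self.pos_threshold
        ):
            raise ValueError("negative threshold must not exceed positive threshold")

    @property
    def form(self) -> str:
        has_n = self.neg_threshold is not None
        has_p = self.pos_threshold is not None
        if has_n and has_p:
            return "trilinear"
        if has_n or has_p:
            return "bilinear"
        return "null"

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        if self.neg_threshold is not None:
            mask = z <= self.neg_threshold
            out = np.where(mask, self.neg_slope * (z - self.neg_threshold), out)
        if self.pos_threshold is not None:
            mask = z >= self.pos_threshold
            out = np.where(mask, self.pos_slope * (z - self.pos_threshold), out)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class RepairTerm:
    """Constant positive boost when the partner's score falls below kr."""

    threshold: float | None = None
    strength: float = 0.0
    active: bool = False

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        if not self.active or self.threshold is None:
            out = np.zeros_like(z)
        else:
            out = np.where(z <= self.threshold, self.strength, 0.0)
        return out if out.ndim else float(out)


NULL_INFLUENCE = InfluenceFunction()
NO_REPAIR = RepairTerm()


@dataclass(frozen=True)
class ModelParameters:
    """One actor's fitted parameters.

    ``influence_from_partner`` and ``repair`` both take the *partner's*
    current score as input and feed this actor's next score.
    """

    actor: str
    initial_state: float
    inertia: float
    influence_from_partner: InfluenceFunction = NULL_INFLUENCE
    repair: RepairTerm = NO_REPAIR

    @property
    def unss(self) -> float:
        return steady_state(self.initial_state, self.inertia)


@dataclass(frozen=True)
class DyadModel:
    therapist: ModelParameters
    client: ModelParameters


def steady_state(a: float, r: float) -> float:
    """Uninfluenced steady state a / (1 - r) of one actor's update."""
    if r == 1:
        raise ValueError("inertia r = 1: no uninfluenced fixed point")
    return a / (1.0 - r)


def _uninfluenced_mask(partner: np.ndarray, neutral_tol: float | None) -> np.ndarray:
    if neutral_tol is None:
        return np.ones_like(partner, dtype=bool)
    return np.abs(partner) <= neutral_tol


def estimate_uninfluenced(
    self_series: WeightedSeries,
    partner_series: WeightedSeries,
    neutral_tol: float | None = 0.0,
) -> tuple[float, float]:
    """OLS fit of x[t+1] = r*x[t] + a on partner-neutral transitions.

    A transition t -> t+1 is used when the partner's window-t score is
    neutral: exactly zero by default, within ``|score| <= neutral_tol``
    if a band is given, or every transition with ``neutral_tol=None``
    (appropriate when the partner is known to exert no influence).
    Returns ``(a, r)``.
    """
    x = np.asarray(self_series.scores, dtype=float)
    z = np.asarray(partner_series.scores, dtype=float)
    if len(x) != len(z):
        raise ValueError("series lengths differ")
    mask = _uninfluenced_mask(z[:-1], neutral_tol)
    x_now = x[:-1][mask]
    x_next = x[1:][mask]
    if len(x_now) == 0:
        raise ValueError("no uninfluenced points")
    if len(x_now) < 3:
        raise ValueError(
            f"only {len(x_now)} uninfluenced transitions (need >= 3)"
        )
    if np.ptp(x_now) == 0:
        raise ValueError("singular design: self scores constant on uninfluenced points")
    design = np.column_stack([x_now, np.ones_like(x_now)])
    (r, a), *_ = np.linalg.lstsq(design, x_next, rcond=None)
    return float(a), float(r)


def _residuals(
    x: np.ndarray, z: np.ndarray, a: float, r: float, neutral_tol: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-1 residuals e[t] = x[t+1] - (r x[t] + a) on influenced points."""
    tol = 0.0 if neutral_tol is None else neutral_tol
    mask = np.abs(z[:-1]) > tol
    e = x[1:] - (r * x[:-1] + a)
    return e[mask], z[:-1][mask]


def _regime_design(
    z: np.ndarray, nth: float | None, pth: float | None, kr: float | None
) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    if nth is not None:
        cols.append(np.where(z <= nth, z - nth, 0.0))
        names.append("neg_slope")
    if pth is not None:
        cols.append(np.where(z >= pth, z - pth, 0.0))
        names.append("pos_slope")
    if kr is not None:
        cols.append((z <= kr).astype(float))
        names.append("strength")
    return (
        np.column_stack(cols) if cols else np.empty((len(z), 0)),
        names,
    )


def _fit_regimes(e, z, nth, pth, kr):
    """Least-squares slopes/strength for fixed thresholds; returns (coef, sse)."""
    X, names = _regime_design(z, nth, pth, kr)
    if X.shape[1] == 0:
        return {}, float(np.sum(e**2))
    coef, *_ = np.linalg.lstsq(X, e, rcond=None)
    resid = e - X @ coef
    return dict(zip(names, coef)), float(np.sum(resid**2))


def estimate_influence(
    self_series: WeightedSeries,
    partner_series: WeightedSeries,
    uninfluenced: tuple[float, float],
    neutral_tol: float | None = 0.0,
    min_support: int = 3,
) -> InfluenceFunction:
    """Threshold-scan fit of the partner's influence function.

    Candidate thresholds are the distinct observed partner scores; for
    every admissible (nth, pth) pair — including one or both absent —
    regime slopes are fitted by least squares to the stage-1 residuals
    and the candidate with minimal SSE wins.  A regime is admissible
    only with at least ``min_support`` supporting points, mirroring the
    reported fits in which unsupported regimes are absent; ties in SSE
    are broken toward the smallest total threshold magnitude.
    """
    a, r = uninfluenced
    x = np.asarray(self_series.scores, dtype=float)
    z_all = np.asarray(partner_series.scores, dtype=float)
    if len(x) != len(z_all):
        raise ValueError("series lengths differ")
    e, z = _residuals(x, z_all, a, r, neutral_tol)
    if len(z) == 0:
        return NULL_INFLUENCE

    order = np.argsort(z, kind="stable")
    zs, es = z[order], e[order]
    sse_tot = float(np.sum(es**2))
    uniq, last_idx = np.unique(zs, return_index=True)
    # prefix sums up to and including each unique value
    counts = np.searchsorted(zs, uniq, side="right")
    cz = np.cumsum(zs)
    cz2 = np.cumsum(zs**2)
    ce = np.cumsum(es)
    cez = np.cumsum(es * zs)

    def _pick(arr):  # value of a cumulative array at each unique threshold
        return arr[counts - 1]

    # Negative regime at threshold c: u_i = z_i - c on z <= c; the LS
    # slope is A/B with A = sum e*u, B = sum u^2, and the SSE reduction
    # is A^2/B.  Positive regime symmetric via suffix sums.
    m_neg = counts.astype(float)
    A_neg = _pick(cez) - uniq * _pick(ce)
    B_neg = _pick(cz2) - 2 * uniq * _pick(cz) + uniq**2 * m_neg
    ok_neg = (m_neg >= min_support) & (B_neg > 0)
    red_neg = np.where(ok_neg, np.divide(A_neg**2, B_neg, out=np.zeros_like(B_neg), where=B_neg > 0), -np.inf)
    slope_neg = np.divide(A_neg, B_neg, out=np.zeros_like(B_neg), where=B_neg > 0)

    n_pts = len(zs)
    first = np.searchsorted(zs, uniq, side="left")
    m_pos = (n_pts - first).astype(float)
    sz, sz2 = cz[-1], cz2[-1]
    se, sez = ce[-1], cez[-1]
    before = lambda arr: np.where(first > 0, arr[np.maximum(first - 1, 0)], 0.0)
    A_pos = (sez - before(cez)) - uniq * (se - before(ce))
    B_pos = (sz2 - before(cz2)) - 2 * uniq * (sz - before(cz)) + uniq**2 * m_pos
    ok_pos = (m_pos >= min_support) & (B_pos > 0)
    red_pos = np.where(ok_pos, np.divide(A_pos**2, B_pos, out=np.zeros_like(B_pos), where=B_pos > 0), -np.inf)
    slope_pos = np.divide(A_pos, B_pos, out=np.zeros_like(B_pos), where=B_pos > 0)

    # Enumerate candidate forms; regimes have disjoint support, so the
    # trilinear SSE is separable into the two single-regime reductions.
    cand_sse: list[float] = [sse_tot]
    cand_mag: list[float] = [0.0]
    cand_idx: list[tuple[int | None, int | None]] = [(None, None)]
    for i in np.flatnonzero(ok_neg):
        cand_sse.append(sse_tot - red_neg[i])
        cand_mag.append(abs(uniq[i]))
        cand_idx.append((int(i), None))
    for j in np.flatnonzero(ok_pos):
        cand_sse.append(sse_tot - red_pos[j])
        cand_mag.append(abs(uniq[j]))
        cand_idx.append((None, int(j)))
    for i in np.flatnonzero(ok_neg):
        for j in np.flatnonzero(ok_pos):
            if uniq[i] < uniq[j]:
                cand_sse.append(sse_tot - red_neg[i] - red_pos[j])
                cand_mag.append(abs(uniq[i]) + abs(uniq[j]))
                cand_idx.append((int(i), int(j)))

    sse_arr = np.asarray(cand_sse)
    mag_arr = np.asarray(cand_mag)
    best_sse = sse_arr.min()
    tied = sse_arr <= best_sse + _TIE_RTOL * max(abs(best_sse), sse_tot, 1.0)
    winner = int(np.flatnonzero(tied)[np.argmin(mag_arr[tied])])
    i, j = cand_idx[winner]
    return InfluenceFunction(
        neg_threshold=None if i is None else float(uniq[i]),
        pos_threshold=None if j is None else float(uniq[j]),
        neg_slope=0.0 if i is None else float(slope_neg[i]),
        pos_slope=0.0 if j is None else float(slope_pos[j]),
    )


def estimate_repair(
    self_series: WeightedSeries,
    partner_series: WeightedSeries,
    params: ModelParameters,
    neutral_tol: float | None = 0.0,
    min_support: int = 3,
    alpha: float = 0.05,
) -> RepairTerm:
    """Scan negative partner scores for a repair threshold.

    For each candidate threshold the influence slopes and the repair
    strength are refitted jointly (the regressors overlap, so the
    strength is *not* simply the mean residual below the threshold
    unless the influence is null).  Repair is kept only when the best
    candidate has >= ``min_support`` supporting points, a positive
    fitted strength, and the extra parameter survives a partial F-test
    at level ``alpha`` against the no-repair fit; otherwise the term is
    inactive, mirroring the reported sessions with no repair estimate.
    """
    a, r = params.initial_state, params.inertia
    infl = params.influence_from_partner
    x = np.asarray(self_series.scores, dtype=float)
    z_all = np.asarray(partner_series.scores, dtype=float)
    e, z = _residuals(x, z_all, a, r, neutral_tol)
    if len(z) == 0:
        return NO_REPAIR

    nth, pth = infl.neg_threshold, infl.pos_threshold
    _, sse0 = _fit_regimes(e, z, nth, pth, None)
    cands = [
        c
        for c in np.unique(z)
        if c < 0 and np.sum(z <= c) >= min_support
    ]
    best: tuple[float, float, float] | None = None  # (sse, |kr|, strength)
    best_kr: float | None = None
    for kr in cands:
        coef, sse = _fit_regimes(e, z, nth, pth, kr)
        strength = float(coef.get("strength", 0.0))
        if strength <= 0:
            continue
        mag = abs(kr)
        if (
            best is None
            or sse < best[0] * (1 - _TIE_RTOL)
            or (sse <= best[0] * (1 + _TIE_RTOL) and mag < best[1])
        ):
            best = (sse, mag, strength)
            best_kr = float(kr)
    if best is None:
        return NO_REPAIR
    sse1 = best[0]
    n_par = 1 + (nth is not None) + (pth is not None)
    dof = len(z) - n_par
    if dof <= 0:
        return NO_REPAIR
    if sse1 <= 0:  # exact fit: keep
        return RepairTerm(threshold=best_kr, strength=best[2], active=True)
    f_stat = (sse0 - sse1) / (sse1 / dof)
    from scipy.stats import f as f_dist

    if f_dist.sf(f_stat, 1, dof) > alpha:
        return NO_REPAIR
    return RepairTerm(threshold=best_kr, strength=best[2], active=True)


def _refit_actor(
    self_series: WeightedSeries,
    partner_series: WeightedSeries,
    actor: str,
    neutral_tol: float | None,
    min_support: int,
) -> ModelParameters:
    a, r = estimate_uninfluenced(self_series, partner_series, neutral_tol)
    infl = estimate_influence(
        self_series, partner_series, (a, r), neutral_tol, min_support
    )
    params = ModelParameters(
        actor=actor, initial_state=a, inertia=r, influence_from_partner=infl
    )
    repair = estimate_repair(
        self_series, partner_series, params, neutral_tol, min_support
    )
    # Final joint least-squares pass: with the thresholds profiled, all
    # linear parameters (a, r, slopes, strength) are refitted on EVERY
    # transition, not only the partner-neutral subset — the dead zone
    # contributes zero regime columns, so the full regression is exact
    # under the model and markedly more efficient for (a, r).
    x = np.asarray(self_series.scores, dtype=float)
    z_all = np.asarray(partner_series.scores, dtype=float)
    z_prev, x_prev, x_next = z_all[:-1], x[:-1], x[1:]
    regime, names = _regime_design(
        z_prev,
        infl.neg_threshold,
        infl.pos_threshold,
        repair.threshold if repair.active else None,
    )
    design = np.column_stack([x_prev, np.ones_like(x_prev), regime])
    if np.linalg.matrix_rank(design) == design.shape[1]:
        coef, *_ = np.linalg.lstsq(design, x_next, rcond=None)
        r, a = float(coef[0]), float(coef[1])
        fitted = dict(zip(names, coef[2:]))
        infl = replace(
            infl,
            neg_slope=float(fitted.get("neg_slope", infl.neg_slope)),
            pos_slope=float(fitted.get("pos_slope", infl.pos_slope)),
        )
        if repair.active:
            repair = replace(
                repair, strength=float(fitted.get("strength", repair.strength))
            )
    return ModelParameters(
        actor=actor,
        initial_state=a,
        inertia=r,
        influence_from_partner=infl,
        repair=repair,
    )


def fit_dyad(
    therapist_series: WeightedSeries,
    client_series: WeightedSeries,
    neutral_tol: float | None = 0.25,
    min_support: int = 3,
) -> DyadModel:
    """Fit both actors' parameters from one session's score series.

    The default neutral band (|partner score| <= 0.25) treats windows
    whose weighted sum is essentially zero as exerting no influence.
    """
    therapist = _refit_actor(
        therapist_series, client_series, "therapist", neutral_tol, min_support
    )
    client = _refit_actor(
        client_series, therapist_series, "client", neutral_tol, min_support
    )
    return DyadModel(therapist=therapist, client=client)


def step(model: DyadModel, state: tuple[float, float]) -> tuple[float, float]:
    """One simultaneous update of the dyad state (T, C)."""
    T, C = state
    p_t, p_c = model.therapist, model.client
    T_next = (
        p_t.inertia * T
        + p_t.initial_state
        + p_t.influence_from_partner(C)
        + p_t.repair(C)
    )
    C_next = (
        p_c.inertia * C
        + p_c.initial_state
        + p_c.influence_from_partner(T)
        + p_c.repair(T)
    )
    return (float(T_next), float(C_next))


def iterate(
    model: DyadModel,
    state: tuple[float, float],
    steps: int,
    overflow: float = 1e9,
) -> np.ndarray:
    """Trajectory of ``steps`` updates, including the start: shape (steps+1, 2).

    Diverging trajectories (|state| beyond ``overflow``) are truncated.
    """
    out = [state]
    for _ in range(steps):
        state = step(model, state)
        if not np.all(np.isfinite(state)) or np.max(np.abs(state)) > overflow:
            break
        out.append(state)
    return np.asarray(out, dtype=float)
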