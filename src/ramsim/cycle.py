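"""Cell-cycle clock and the division procedure.

Each cell carries a two-species Lotka-Volterra oscillator standing for the
out-of-phase oscillations of D-type (activator, u) and B-type (inhibitor,
v) cyclins over one division cycle:

    du/dt = u (1 - v)
    dv/dt = alpha v (u - 1)

The single parameter ``alpha`` sets the clock speed; around the fixed point
(u, v) = (1, 1) the small-amplitude period is

    T_c = 2 pi / sqrt(alpha)

so the period scales as ``alpha**-1/2``.  Auxin couples in through a linear
map ``alpha = a C + b``: outside a concentration window the cycle is
arrested (no division), mirroring the experimental observation that both
auxin depletion and auxin excess stall the root cell cycle.  Division is
triggered by an iteration-count threshold: a cell divides once its clock
has accumulated ``m_theta * T_c(alpha)`` iterations since the last reset.
Quiescent-centre cells run the same clock but divide at a tenfold longer
interval, and their generating points never move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import Domain, Tessellation, extend_domain, min_separation
from .state import Cells

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CycleParams:
    """Clock and division constants.

    alpha_map : (a, b) of the linear auxin coupling  alpha = a C + b.
    alpha_range : oscillatory range; alpha is clipped into it.
    arrest_below / arrest_above : auxin window outside which the cycle stops.
    m_theta : division threshold in units of the local period T_c.
    qc_factor : how many times slower the quiescent centre divides.
    offset_frac : daughter offset as a fraction of the effective cell
        radius sqrt(A/pi) (a quarter-radius by default).
    min_area_frac : a cell may divide only once it has regrown to this
        fraction of the equilibrium area Abar (daughters must approach
        adult size before cycling again; also keeps crowded regions from
        subdividing without space).
    dt_c : Euler sub-step for the cyclin oscillator, per iteration.
    u0, v0 : post-division reset point of the oscillator.
    """

    alpha_map: tuple[float, float]
    alpha_range: tuple[float, float] = (1e-6, 10.0)
    arrest_below: float = 0.2
    arrest_above: float = 0.99
    m_theta: float = 1.0
    qc_factor: float = 10.0
    offset_frac: float = 0.25
    min_area_frac: float = 0.15
    dt_c: float = 0.25
    u0: float = 1.3
    v0: float = 1.0


@dataclass
class DivisionEvent:
    iteration: int
    parent_id: int
    child_id: int
    x: float
    y: float


def lv_step(
    u: np.ndarray, v: np.ndarray, alpha: np.ndarray | float, dt_c: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """One explicit Euler step of the adimensional Lotka-Volterra clock."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    un = u + dt_c * u * (1.0 - v)
    vn = v + dt_c * alpha * v * (u - 1.0)
    if (un <= 0).any() or (vn <= 0).any():
        raise FloatingPointError(
            "cyclin concentration left the positive quadrant; dt_c too large"
        )
    return un, vn


def lv_invariant(u, v, alpha):
    """First integral of the clock: alpha(u - ln u) + (v - ln v)."""
    return alpha * (u - np.log(u)) + (v - np.log(v))


def period(alpha: np.ndarray | float) -> np.ndarray | float:
    """Small-amplitude cycle period T_c = 2 pi / sqrt(alpha), in iterations.

    Non-positive or non-finite alpha signals an arrested clock and maps to
    an infinite period.
    """
    a = np.asarray(alpha, dtype=float)
    out = np.full(a.shape, np.inf)
    ok = np.isfinite(a) & (a > 0)
    out[ok] = 2.0 * np.pi / np.sqrt(a[ok])
    return float(out) if np.isscalar(alpha) else out


def alpha_from_auxin(
    C: np.ndarray | float, params: CycleParams
) -> tuple[np.ndarray, np.ndarray]:
    """Map auxin concentration to the clock rate parameter.

    Returns ``(alpha, arrested)``.  alpha is the linear map clipped to the
    oscillatory range; cells whose auxin lies outside the arrest window get
    ``arrested=True`` (their alpha is still reported, but no division may
    be triggered from it).
    """
    C = np.atleast_1d(np.asarray(C, dtype=float))
    a, b = params.alpha_map
    lo, hi = params.alpha_range
    alpha = np.clip(a * C + b, lo, hi)
    arrested = (C < params.arrest_below) | (C > params.arrest_above)
    return alpha, arrested


def advance_clocks(cells: Cells, params: CycleParams, *, substeps: int = 4) -> None:
    """Advance every cell's cyclin oscillator and phase counter by one
    iteration (in place).  Arrested cells hold their phase."""
    alpha, arrested = alpha_from_auxin(cells.C, params)
    arrested = arrested & ~cells.is_qc  # the niche clock never arrests
    u, v = cells.u, cells.v
    for _ in range(substeps):
        u, v = lv_step(u, v, alpha, params.dt_c)
    cells.u, cells.v = u, v
    cells.phase_iters = cells.phase_iters + np.where(arrested, 0.0, 1.0)


def division_threshold(cells: Cells, params: CycleParams) -> np.ndarray:
    """Per-cell division threshold m_theta * T_c, in iterations (inf = never)."""
    alpha, arrested = alpha_from_auxin(cells.C, params)
    thr = params.m_theta * period(alpha)
    thr = np.where(arrested & ~cells.is_qc, np.inf, thr)
    # the quiescent cells reproduce at a rate `qc_factor` times lower than
    # "the others": their threshold is ten times the typical threshold of
    # the currently cycling ordinary cells (their own auxin is pinned at
    # the maximum, so their own alpha is not a meaningful rate reference)
    cycling = ~arrested & ~cells.is_qc & np.isfinite(thr)
    ref = np.median(thr[cycling]) if cycling.any() else params.m_theta * period(
        params.alpha_map[0] * 0.5 + params.alpha_map[1]
    )
    thr = np.where(cells.is_qc, params.qc_factor * ref, thr)
    return thr


def check_and_divide(
    cells: Cells,
    tess: Tessellation,
    domain: Domain,
    params: CycleParams,
    rng: np.random.Generator,
    iteration: int = 0,
) -> tuple[Domain, list[DivisionEvent]]:
    """Execute every due division (threshold-passing clocks), in id order.

    For each dividing cell the generating point is replaced by two points
    placed symmetrically along a uniform-random axis, each a quarter of the
    effective cell radius away; the mother's kinetic energy is split
    equally between the two (velocities along +/- the division axis); the
    daughters inherit the mother's auxin; clocks reset to zero.  A dividing
    quiescent cell keeps its pinned mother point and sheds one ordinary
    daughter, so the QC count never changes.  Afterwards the domain's upper
    edge is shifted to add exactly one equilibrium cell area per division.

    Mutates ``cells`` in place; returns the extended domain and the events.
    """
    thr = division_threshold(cells, params)
    # cells must regrow toward adult size before dividing again; the pinned
    # quiescent cells are exempt (they shed a daughter without moving)
    grown = (tess.areas >= params.min_area_frac * tess.mean_area) | cells.is_qc
    due = np.flatnonzero((cells.phase_iters >= thr) & grown)
    if len(due) == 0:
        return domain, []

    events: list[DivisionEvent] = []
    eps = 1.5 * min_separation(tess.mean_area)
    occupied = [cells.positions[i] for i in range(cells.n)]

    def placeable(p: np.ndarray, skip: int) -> bool:
        if not domain.contains(p[None, :])[0]:
            return False
        for k, q in enumerate(occupied):
            if k != skip and np.hypot(*(p - q)) < eps:
                return False
        return True

    def find_placement(mother, i, symmetric):
        """Random division axis with offset shrinkage; several axis retries.

        Returns (axis, offset) or None if the neighborhood is too crowded —
        in which case the division is postponed to a later iteration.
        """
        r_eff = np.sqrt(tess.areas[i] / np.pi)
        for _ in range(8):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            axis = np.array([np.cos(theta), np.sin(theta)])
            offset = params.offset_frac * r_eff
            while offset >= eps:
                if symmetric:
                    ok = placeable(mother - offset * axis, i) and placeable(
                        mother + offset * axis, i
                    )
                else:
                    ok = placeable(mother + offset * axis, -1)
                if ok:
                    return axis, offset
                offset *= 0.5
        return None

    for i in due:  # ascending index == ascending creation order
        mother = cells.positions[i].copy()
        ek = 0.5 * (cells.velocities[i] ** 2).sum()
        speed = np.sqrt(ek)  # |v| such that each daughter carries ek/2

        place = find_placement(mother, i, symmetric=not cells.is_qc[i])
        if place is None:
            log.warning(
                "division of cell %d postponed: no room at iteration %d",
                int(cells.ids[i]), iteration,
            )
            continue
        axis, offset = place

        if cells.is_qc[i]:
            # pinned mother stays put; one ordinary daughter buds off
            child_pos = mother + offset * axis
            cid = cells.append(
                position=child_pos, velocity=speed * axis, C=cells.C[i],
                u=params.u0, v=params.v0, is_qc=False,
            )
            occupied.append(child_pos)
        else:
            p1 = mother - offset * axis
            p2 = mother + offset * axis
            cells.positions[i] = p1
            cells.velocities[i] = -speed * axis
            cid = cells.append(
                position=p2, velocity=speed * axis, C=cells.C[i],
                u=params.u0, v=params.v0, is_qc=False,
            )
            occupied[i] = p1
            occupied.append(p2)
        cells.u[i], cells.v[i] = params.u0, params.v0
        cells.phase_iters[i] = 0.0
        events.append(
            DivisionEvent(iteration, int(cells.ids[i]), cid, mother[0], mother[1])
        )

    domain = extend_domain(domain, len(events) * tess.mean_area)
    return domain, events
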