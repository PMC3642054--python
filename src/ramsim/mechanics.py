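"""Elastic field on the tessellated tissue and damped Newtonian dynamics.

Each interior cell i contributes a harmonic potential

    V_i = K_v (A_i - Abar)^2 + K_c |r_i - c_i|^2

where ``A_i`` is the cell area, ``Abar`` the equilibrium per-cell share of
the domain, ``r_i`` the generating point and ``c_i`` the polygon centroid.
The first term penalizes cells that are too large or too small; the second
penalizes asymmetric (badly shaped) cells, since in a relaxed packing the
generating point and the center of mass coincide.  The total force on a
mobile generator is the exact negative gradient of ``sum_i V_i``.

Gradient of the Voronoi geometry.  The wall between cells i and j is the
perpendicular bisector of their generators.  When generator ``r_i`` moves
with velocity ``u``, a wall point ``z`` moves with outward-normal speed
``(z - r_i) . u / d_ij``, which gives exact first-order edge integrals

    dA_i/dr_i  (per edge)  =  L_ij (m_ij - r_i) / d_ij
    dM_i/dr_i  (per edge)  =  S_ij / d_ij,   S_ij = ∮ z (z - r_i)^T ds

with ``m_ij`` the wall midpoint and ``M_i = ∮ z dA`` the first area moment
(so ``c_i = M_i / A_i``).  The same edge removes the mirrored amount from
the neighbor.  ``S_ij`` is quadratic along the straight wall, so a 3-point
Simpson rule evaluates it exactly.  Walls against the fixed outline do not
move and contribute nothing.  Correctness of this assembly is guarded by a
central-difference oracle in the test suite.

Velocities obey  dv/dt = F - lambda v  with unit cell mass, integrated with
a simple (semi-implicit) Euler step; fixed boundary generators never move.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .geometry import Domain, Tessellation, tessellate


@dataclass(frozen=True)
class MechParams:
    """Elastic and dynamical constants of the tissue.

    K_v : size-restoring constant (energy / area^2)
    K_c : shape-restoring constant (energy / length^2)
    lambda_f : friction coefficient (1/time, cell mass == 1)
    dt : Euler step (iteration units)
    tol : relative-change stopping tolerance for relaxation
    """

    K_v: float
    K_c: float
    lambda_f: float
    dt: float = 0.05
    tol: float = 1e-4

    def __post_init__(self):
        if min(self.K_v, self.K_c, self.lambda_f, self.dt) <= 0:
            raise ValueError("K_v, K_c, lambda_f and dt must be positive")
        if not 0 < self.tol < 1:
            raise ValueError("tol must lie in (0, 1)")
        bound = 0.1 * min(1.0 / self.lambda_f, 1.0 / np.sqrt(self.K_c))
        if self.dt > bound:
            warnings.warn(
                f"dt={self.dt:g} exceeds the stability bound {bound:g} "
                "(0.1 * min(1/lambda, 1/sqrt(K_c)))",
                stacklevel=2,
            )


@dataclass
class MechState:
    """Positions, velocities and energy bookkeeping of the mobile generators."""

    positions: np.ndarray      # (n, 2)
    velocities: np.ndarray     # (n, 2)
    mobile: np.ndarray         # (n,) bool; False for quiescent-centre cells

    @property
    def kinetic_energy(self) -> np.ndarray:
        """Per-cell kinetic energy, |v|^2 / 2 with unit mass."""
        return 0.5 * (self.velocities**2).sum(axis=1)

    @classmethod
    def at_rest(cls, positions: np.ndarray, mobile: np.ndarray | None = None):
        positions = np.asarray(positions, dtype=float)
        if mobile is None:
            mobile = np.ones(len(positions), dtype=bool)
        return cls(positions.copy(), np.zeros_like(positions), np.asarray(mobile))


def potential(tess: Tessellation, params: MechParams) -> tuple[np.ndarray, float]:
    """Per-cell elastic potential V_i and its total."""
    da = tess.areas - tess.mean_area
    off = tess.generators - tess.centroids
    v = params.K_v * da**2 + params.K_c * (off**2).sum(axis=1)
    return v, float(v.sum())


def _edge_moments(v1, v2, gen):
    """Simpson-exact  S = ∮ z (z - r)^T ds  over straight wall segments.

    v1, v2 : (E, 2) wall endpoints; gen : (E, 2) generator r of the side
    being differentiated.  Returns (E, 2, 2).
    """
    lengths = np.hypot(*(v2 - v1).T)
    mid = 0.5 * (v1 + v2)

    def f(z):
        return np.einsum("ea,eb->eab", z, z - gen)

    return (lengths / 6.0)[:, None, None] * (f(v1) + 4.0 * f(mid) + f(v2))


def forces(
    tess: Tessellation, params: MechParams, mobile: np.ndarray | None = None
) -> np.ndarray:
    """Exact negative gradient of the total potential w.r.t. the generators.

    Fixed generators (the outline and any non-mobile interior cell) are
    reported with zero force.
    """
    n = tess.n_cells
    if mobile is None:
        mobile = np.ones(n, dtype=bool)
    grad = np.zeros((n, 2))

    ia, ib = tess.edge_cells[:, 0], tess.edge_cells[:, 1]
    ra, rb = tess.edge_gen[:, 0], tess.edge_gen[:, 1]
    d = np.hypot(*(rb - ra).T)
    mid = 0.5 * (tess.edge_v1 + tess.edge_v2)
    L = tess.edge_lengths

    # interior-cell fields gathered per edge side; boundary sides are inert
    def side(idx):
        ok = idx >= 0
        i = np.clip(idx, 0, None)
        da = np.where(ok, tess.areas[i] - tess.mean_area, 0.0)
        w = np.where(
            ok[:, None],
            (tess.generators[i] - tess.centroids[i]) / tess.areas[i, None],
            0.0,
        )
        wc = np.einsum("ea,ea->e", w, np.where(ok[:, None], tess.centroids[i], 0.0))
        return ok, da, w, wc

    ok_a, da_a, w_a, wc_a = side(ia)
    ok_b, da_b, w_b, wc_b = side(ib)
    Kv2, Kc2 = 2.0 * params.K_v, 2.0 * params.K_c

    for idx, ok, r_self, da_s, da_o, w_s, w_o, wc_s, wc_o in (
        (ia, ok_a, ra, da_a, da_b, w_a, w_b, wc_a, wc_b),
        (ib, ok_b, rb, da_b, da_a, w_b, w_a, wc_b, wc_a),
    ):
        g = L[:, None] * (mid - r_self) / d[:, None]
        S = _edge_moments(tess.edge_v1, tess.edge_v2, r_self)
        contrib = (
            Kv2 * (da_s - da_o)[:, None] * g
            - Kc2 * np.einsum("ea,eab->eb", w_s - w_o, S) / d[:, None]
            + Kc2 * (wc_s - wc_o)[:, None] * g
        )
        np.add.at(grad, np.clip(idx[ok], 0, None), contrib[ok])

    grad += Kc2 * (tess.generators - tess.centroids)
    F = -grad
    F[~mobile] = 0.0
    return F


def step(
    state: MechState,
    tess: Tessellation,
    params: MechParams,
    domain: Domain | None = None,
) -> MechState:
    """One damped Euler step: v += dt (F - lambda v); r += dt v.

    If ``domain`` is given, a generator that would cross the rigid
    epidermal outline stays put and loses its velocity (inelastic stop).
    """
    F = forces(tess, params, state.mobile)
    if not np.isfinite(F).all():
        bad = np.flatnonzero(~np.isfinite(F).all(axis=1))
        raise FloatingPointError(f"non-finite force on cells {bad.tolist()}")
    v = state.velocities + params.dt * (F - params.lambda_f * state.velocities)
    v[~state.mobile] = 0.0
    r = state.positions + params.dt * v
    r[~state.mobile] = state.positions[~state.mobile]
    if domain is not None:
        inside = domain.contains(r)
        if not inside.all():
            out = ~inside
            r[out] = state.positions[out]
            v[out] = 0.0
    return MechState(r, v, state.mobile)


def relax(
    domain: Domain,
    state: MechState,
    params: MechParams,
    max_iter: int,
    *,
    record: bool = False,
):
    """Iterate damped dynamics with re-tessellation until quasi-equilibrium.

    Stops when the largest position/velocity change of an iteration, relative
    to the cell-size scale sqrt(Abar), drops below ``params.tol``.  Returns
    ``(state, tess, iterations_used, converged[, trace])``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    tess = tessellate(domain, state.positions)
    scale = np.sqrt(tess.mean_area)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = step(state, tess, params, domain)
        dr = np.abs(new.positions - state.positions).max()
        dv = np.abs(new.velocities - state.velocities).max() * params.dt
        state = new
        tess = tessellate(domain, state.positions)
        if record:
            _, vt = potential(tess, params)
            trace.append((it, vt, max(dr, dv) / scale, tess.n_cells))
        if max(dr, dv) / scale < params.tol:
            converged = True
            break
    if record:
        return state, tess, it, converged, trace
    return state, tess, it, converged


def calibrate(
    elastic_modulus: float,
    mature_cell_diameter: float,
    period_iterations: float,
    *,
    wall_thickness: float = 1.0,
    reduction_factor: float = 10.0,
    dt: float | None = None,
    tol: float = 1e-4,
) -> MechParams:
    """Derive elastic and friction constants from biophysical inputs.

    K_c comes from matching the restoring force of an elastic cell wall to
    the model's shape force just after a division of a regular hexagonal
    cell of diameter d (centroid spacing):  the wall of Young's modulus E,
    cross-section (side length x thickness), strained by the post-division
    contraction ``1 - 1/sqrt(2)`` (area halves, lengths shrink by sqrt(2)),
    must equal ``K_c |r - c|`` with the daughter offset ``|r - c| = d/8``
    (a quarter of the cell radius).  With hexagon side ``s = d/sqrt(3)``:

        K_c = 8 E h s (1 - 1/sqrt(2)) / d**2 * d = 8 E h (1 - 1/sqrt(2)) / sqrt(3)

    K_v is set so that, at the same post-division deviation, the size term
    stores comparable energy to the shape term:  ``K_v = K_c / (12 d^2)``.

    lambda is the smallest friction that damps the oscillatory motion by
    ``reduction_factor`` within one period T of the relevant dynamics
    (amplitude envelope exp(-lambda t / 2) with unit mass):

        lambda = 2 ln(reduction_factor) / T
    """
    if min(elastic_modulus, mature_cell_diameter, period_iterations) <= 0:
        raise ValueError("all calibration inputs must be positive")
    E, d = elastic_modulus, mature_cell_diameter
    K_c = 8.0 * E * wall_thickness * (1.0 - 1.0 / np.sqrt(2.0)) / np.sqrt(3.0)
    K_v = K_c / (12.0 * d**2)
    lam = 2.0 * np.log(reduction_factor) / period_iterations
    if dt is None:
        dt = 0.1 * min(1.0 / lam, 1.0 / np.sqrt(K_c))
    return MechParams(K_v=K_v, K_c=K_c, lambda_f=lam, dt=dt, tol=tol)
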