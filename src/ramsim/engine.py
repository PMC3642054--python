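"""Simulation orchestration: the coupled growth loop of the root tip.

One iteration of the loop performs, in order: re-tessellation of the
current generating points, one damped-Euler mechanics step under the
elastic potential, one gated auxin transport step driven by the local
potential, one advance of every cell's cyclin clock, and finally the
execution of any due divisions together with the matching upward
extension of the domain.  Iterations are mapped to physical time by
requiring that a fixed number of them represent a fixed number of days of
root growth (seven days over 3400 iterations by default, about 3 minutes
per iteration).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import auxin as auxin_mod
from . import cycle as cycle_mod
from . import mechanics
from .cycle import CycleParams, DivisionEvent
from .geometry import Domain, Tessellation, build_domain, tessellate
from .mechanics import MechParams, MechState
from .state import Cells

log = logging.getLogger(__name__)


def calibrate_time(days: float, target_iterations: int) -> float:
    """Minutes of real development represented by one loop iteration."""
    if days <= 0 or target_iterations <= 0:
        raise ValueError("days and target_iterations must be positive")
    return days * 1440.0 / target_iterations


@dataclass(frozen=True)
class SimConfig:
    """Complete, serializable description of one run."""

    # geometry (µm)
    n_interior: int = 8
    qc_offsets: tuple[tuple[float, float], ...] = ((-5.0, 12.0), (5.0, 12.0))
    width: float = 80.0
    tip_depth: float = 30.0
    rect_height: float = 10.0
    boundary_spacing: float = 12.0
    # mechanics
    mech: MechParams = field(
        default_factory=lambda: MechParams(
            K_v=1.2e-3, K_c=4.0, lambda_f=0.25, dt=0.05, tol=1e-4
        )
    )
    # auxin
    D: float = 1.0e-4
    pin: bool = True
    qc_clamp: bool = True
    fickian_D: float = 2.5e-3
    normalize_V_for_transport: bool = False
    # cell cycle
    cycle: CycleParams = field(
        default_factory=lambda: CycleParams(
            alpha_map=(-7.139e-4, 9.834e-4),
            arrest_below=0.15,
            arrest_above=0.85,
            m_theta=0.5,
            min_area_frac=0.15,
        )
    )
    # loop
    total_iterations: int = 3400
    seed: int = 0
    snapshot_every: int = 400
    auxin_before_mechanics: bool = False
    days: float = 7.0
    calibration_iterations: int = 3400

    @property
    def minutes_per_iteration(self) -> float:
        return calibrate_time(self.days, self.calibration_iterations)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["mech"] = dataclasses.asdict(self.mech)
        d["cycle"] = dataclasses.asdict(self.cycle)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "mech" in d:
            d["mech"] = MechParams(**d["mech"])
        if "cycle" in d:
            c = dict(d["cycle"])
            c["alpha_map"] = tuple(c["alpha_map"])
            c["alpha_range"] = tuple(c.get("alpha_range", (1e-6, 10.0)))
            d["cycle"] = CycleParams(**c)
        if "qc_offsets" in d:
            d["qc_offsets"] = tuple(tuple(p) for p in d["qc_offsets"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class Snapshot:
    iteration: int
    domain: Domain
    cells: Cells
    tess: Tessellation
    potential: np.ndarray


@dataclass
class Trace:
    """Per-iteration summaries, division events and periodic snapshots."""

    config: SimConfig
    records: list[tuple] = field(default_factory=list)
    events: list[DivisionEvent] = field(default_factory=list)
    snapshots: dict[int, Snapshot] = field(default_factory=dict)
    initial_area: float = 0.0
    final_domain: Domain | None = None
    final_cells: Cells | None = None

    @property
    def minutes_per_iteration(self) -> float:
        return self.config.minutes_per_iteration

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["iteration", "n_cells", "total_V", "max_C_y", "divisions"],
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.iteration, e.parent_id, e.child_id, e.x, e.y)
                for e in self.events
            ],
            columns=["iteration", "parent_id", "child_id", "x", "y"],
        )

    @property
    def n_cells_final(self) -> int:
        return self.final_cells.n if self.final_cells is not None else 0


def initial_state(config: SimConfig, rng: np.random.Generator):
    """Domain, cells and auxin field of the paper-style initial condition:
    random interior points in the tip, two pinned quiescent cells near the
    centre with the auxin maximum."""
    domain, pts = build_domain(
        config.n_interior,
        config.width,
        config.rect_height,
        config.tip_depth,
        config.boundary_spacing,
        rng,
    )
    qc = np.array(
        [
            (dx, domain.apex_y + dy)
            for dx, dy in config.qc_offsets
        ]
    )
    positions = np.vstack([qc, pts])
    is_qc = np.zeros(len(positions), dtype=bool)
    is_qc[: len(qc)] = True
    C = rng.uniform(0.0, 0.5, size=len(positions))
    C[is_qc] = 1.0
    cells = Cells.create(positions, is_qc, C, config.cycle.u0, config.cycle.v0)
    return domain, cells


def run(config: SimConfig, *, initial_C: np.ndarray | None = None) -> Trace:
    """Execute the full coupled loop for ``config.total_iterations``."""
    seq = np.random.SeedSequence(config.seed)
    rng_init, rng_axes = (np.random.default_rng(s) for s in seq.spawn(2))
    domain, cells = initial_state(config, rng_init)
    if initial_C is not None:
        cells.C = np.asarray(initial_C, dtype=float).copy()
        cells.C[cells.is_qc] = 1.0
    trace = Trace(config=config, initial_area=domain.area)

    astate = auxin_mod.AuxinState(
        C=cells.C, D=config.D, pin=config.pin,
        qc_clamp=config.qc_clamp, fickian_D=config.fickian_D,
    )
    tess = tessellate(domain, cells.positions)
    V, _ = mechanics.potential(tess, config.mech)
    trace.snapshots[0] = Snapshot(0, domain, _copy_cells(cells), tess, V)

    for it in range(1, config.total_iterations + 1):
        tess = tessellate(domain, cells.positions)
        V, Vtot = mechanics.potential(tess, config.mech)
        if config.normalize_V_for_transport and V.max() > 0:
            Vn = V / V.max()
        else:
            Vn = V

        def mech_step():
            st = MechState(cells.positions, cells.velocities, cells.mobile)
            st = mechanics.step(st, tess, config.mech, domain)
            cells.positions, cells.velocities = st.positions, st.velocities
            _enforce_separation(cells, domain, tess.mean_area)

        def auxin_step():
            nonlocal astate
            astate = auxin_mod.AuxinState(
                C=cells.C, D=config.D, pin=config.pin,
                qc_clamp=config.qc_clamp, fickian_D=config.fickian_D,
            )
            astate = auxin_mod.transport_step(
                astate, tess, Vn, qc_mask=cells.is_qc
            )
            cells.C = astate.C

        if config.auxin_before_mechanics:
            auxin_step()
            mech_step()
        else:
            mech_step()
            auxin_step()

        cycle_mod.advance_clocks(cells, config.cycle)
        domain, events = cycle_mod.check_and_divide(
            cells, tess, domain, config.cycle, rng_axes, iteration=it
        )
        for e in events:
            log.debug("division it=%d parent=%d child=%d", it, e.parent_id, e.child_id)
        if events:
            _enforce_separation(cells, domain, tess.mean_area)
        trace.events.extend(events)

        trace.records.append(
            (it, cells.n, Vtot, float(cells.positions[np.argmax(cells.C), 1]),
             len(trace.events))
        )
        if config.snapshot_every and (
            it % config.snapshot_every == 0 or it == config.total_iterations
        ):
            snap_tess = tessellate(domain, cells.positions)
            snap_V, _ = mechanics.potential(snap_tess, config.mech)
            trace.snapshots[it] = Snapshot(
                it, domain, _copy_cells(cells), snap_tess, snap_V
            )
            log.info("iteration %d: %d cells, %d divisions",
                     it, cells.n, len(trace.events))

    trace.final_domain = domain
    trace.final_cells = cells
    return trace


def _enforce_separation(cells: Cells, domain: Domain, mean_area: float) -> None:
    """Nudge apart generators squeezed below the Delaunay-safety separation
    (rare; keeps the tessellation non-degenerate).  Fixed points (boundary,
    QC) never move; their mobile partner is pushed away instead."""
    from scipy.spatial import cKDTree

    from .geometry import min_separation

    eps = min_separation(mean_area)
    bpts = domain.boundary_points()
    nb = len(bpts)
    mobile = np.concatenate([np.zeros(nb, dtype=bool), cells.mobile])
    for _ in range(50):
        allp = np.vstack([bpts, cells.positions])
        pairs = cKDTree(allp).query_pairs(eps, output_type="ndarray")
        moved = False
        for a, b in pairs:
            if not (mobile[a] or mobile[b]):
                continue
            d = allp[b] - allp[a]
            norm = np.hypot(*d)
            axis = d / norm if norm > 0 else np.array([1.0, 0.0])
            push = (1.5 * eps - norm) / (int(mobile[a]) + int(mobile[b]))
            for idx, sign in ((a, -1.0), (b, 1.0)):
                if mobile[idx]:
                    cand = allp[idx] + sign * push * axis
                    if domain.contains(cand[None, :])[0]:
                        cells.positions[idx - nb] = cand
                        moved = True
            log.debug("separated generators %d and %d", a, b)
        if not moved:
            break


def _copy_cells(cells: Cells) -> Cells:
    return Cells(
        ids=cells.ids.copy(),
        positions=cells.positions.copy(),
        velocities=cells.velocities.copy(),
        C=cells.C.copy(),
        u=cells.u.copy(),
        v=cells.v.copy(),
        phase_iters=cells.phase_iters.copy(),
        is_qc=cells.is_qc.copy(),
        next_id=cells.next_id,
    )
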