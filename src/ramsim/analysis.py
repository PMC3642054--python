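"""Validation statistics computed from a simulation trace.

All quantities are pure functions of the :class:`~ramsim.engine.Trace`:
spatial profiles along the apical-basal axis (auxin, potential, clock
advance, cell length, velocity), the division histogram and the stationary
meristem length derived from it, and the power-law dependence of meristem
length on the auxin transport constant D.

Distances are measured from the tip (the parabola apex) internally; the
profiles that the experimental literature reports against distance from
the quiescent centre are shifted by the QC's own distance from the tip at
reporting time only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Snapshot, Trace


@dataclass
class Profile:
    """A binned statistic along the root axis."""

    bin_edges: np.ndarray     # (k+1,) µm
    values: np.ndarray        # (k,) statistic; NaN where undefined
    n_per_bin: np.ndarray     # (k,) int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": self.bin_centers, "value": self.values,
             "n": self.n_per_bin}
        )


def _default_bin_width(trace: Trace) -> float:
    snap = trace.snapshots[min(trace.snapshots)]
    return float(np.sqrt(snap.tess.mean_area))


def _tip_distance(trace: Trace, y: np.ndarray) -> np.ndarray:
    apex = trace.snapshots[min(trace.snapshots)].domain.apex_y
    return np.asarray(y) - apex


def qc_shift(trace: Trace) -> float:
    """Distance from the tip to the quiescent centre (for re-origined plots)."""
    snap = trace.snapshots[min(trace.snapshots)]
    qc_y = snap.cells.positions[snap.cells.is_qc, 1]
    if len(qc_y) == 0:
        return 0.0
    return float(qc_y.mean() - snap.domain.apex_y)


# --------------------------------------------------------------------------
# divisions
# --------------------------------------------------------------------------

def division_histogram(trace: Trace, bin_width: float | None = None) -> Profile:
    """Counts of division events per distance-from-tip bin."""
    bw = bin_width or _default_bin_width(trace)
    ev = trace.events_frame()
    if len(ev) == 0:
        edges = np.array([0.0, bw])
        return Profile(edges, np.zeros(1), np.zeros(1, dtype=int))
    d = _tip_distance(trace, ev.y.to_numpy())
    edges = np.arange(0.0, d.max() + bw, bw)
    if len(edges) < 2:
        edges = np.array([0.0, bw])
    counts, _ = np.histogram(d, bins=edges)
    return Profile(edges, counts.astype(float), counts)


def ram_length(trace: Trace, method: str = "robust") -> float:
    """Stationary meristem length: how far from the tip divisions still occur.

    ``method='max'`` is the literal largest division distance; the default
    ``'robust'`` is the smallest distance containing 90% of the division
    events of the last quarter of the run, which ignores the occasional
    stray division pocket left behind in the elongation zone.
    """
    ev = trace.events_frame()
    if len(ev) == 0:
        return 0.0
    if method == "max":
        return float(_tip_distance(trace, ev.y.to_numpy()).max())
    if method != "robust":
        raise ValueError(f"unknown method {method!r}")
    t_last = trace.config.total_iterations * 0.75
    tail = ev[ev.iteration >= t_last]
    if len(tail) == 0:
        tail = ev
    return float(np.percentile(_tip_distance(trace, tail.y.to_numpy()), 90))


def proliferation_rate_profile(
    trace: Trace,
    bin_width: float | None = None,
    window: tuple[int, int] | None = None,
    *,
    from_qc: bool = True,
) -> Profile:
    """Division rate in events per cell per hour, binned along the axis.

    Cell occupancy per bin is averaged over the snapshots inside ``window``
    (default: the second half of the run); event counts come from the event
    log over the same iterations.  The origin is shifted to the quiescent
    centre unless ``from_qc`` is false.
    """
    bw = bin_width or _default_bin_width(trace)
    if window is None:
        window = (trace.config.total_iterations // 2, trace.config.total_iterations)
    lo, hi = window
    snaps = [s for it, s in sorted(trace.snapshots.items()) if lo <= it <= hi]
    if not snaps:
        raise ValueError("no snapshots inside the requested window")
    ev = trace.events_frame()
    ev = ev[(ev.iteration >= lo) & (ev.iteration <= hi)]

    top = max(_tip_distance(trace, s.cells.positions[:, 1]).max() for s in snaps)
    edges = np.arange(0.0, top + bw, bw)
    occupancy = np.zeros(len(edges) - 1)
    for s in snaps:
        d = _tip_distance(trace, s.cells.positions[:, 1])
        occupancy += np.histogram(d, bins=edges)[0]
    occupancy /= len(snaps)

    counts = np.histogram(
        _tip_distance(trace, ev.y.to_numpy()), bins=edges
    )[0].astype(float)
    hours = (hi - lo) * trace.minutes_per_iteration / 60.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, counts / (occupancy * hours), np.nan)
    if from_qc:
        edges = edges - qc_shift(trace)
    return Profile(edges, rate, occupancy.round().astype(int))


# --------------------------------------------------------------------------
# cell size and kinematics
# --------------------------------------------------------------------------

def cell_lengths(snap: Snapshot, transverse_width: float | None = None) -> np.ndarray:
    """Per-cell length from area: L_i = A_i / w.

    The 2D model assigns each cell an area; dividing by a fixed transverse
    width w (default sqrt(Abar) of the snapshot) reads off a length the way
    longitudinal sections are measured.
    """
    w = transverse_width or float(np.sqrt(snap.tess.mean_area))
    return snap.tess.areas / w


def length_distribution(
    snap: Snapshot, bins: int | np.ndarray = 20,
    transverse_width: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, edges) of the cell-length distribution."""
    L = cell_lengths(snap, transverse_width)
    counts, edges = np.histogram(L, bins=bins)
    return counts, edges


def count_modes(counts: np.ndarray, smooth: int = 3) -> int:
    """Number of interior local maxima of a (smoothed) histogram."""
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        counts = np.convolve(counts, kernel, mode="same")
    counts = np.concatenate([[0.0], counts, [0.0]])  # edge bins can be modes
    peaks = 0
    for k in range(1, len(counts) - 1):
        if counts[k] > counts[k - 1] and counts[k] >= counts[k + 1]:
            peaks += 1
    return max(peaks, 1)


def length_profile(
    trace: Trace, snap: Snapshot, bin_width: float | None = None,
    *, from_qc: bool = True,
) -> Profile:
    """Binned mean cell length along the axis."""
    bw = bin_width or _default_bin_width(trace)
    d = _tip_distance(trace, snap.cells.positions[:, 1])
    L = cell_lengths(snap)
    edges = np.arange(0.0, d.max() + bw, bw)
    n, _ = np.histogram(d, bins=edges)
    s, _ = np.histogram(d, bins=edges, weights=L)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    if from_qc:
        edges = edges - qc_shift(trace)
    return Profile(edges, mean, n)


def velocity_profile(
    trace: Trace, bin_width: float | None = None, *, from_qc: bool = True,
) -> Profile:
    """Binned mean apex-relative displacement rate (µm/h) along the axis.

    Cells are matched by id between consecutive snapshots; their change in
    distance from the (fixed) apex per elapsed hour is averaged per bin of
    the earlier snapshot's position.
    """
    bw = bin_width or _default_bin_width(trace)
    items = sorted(trace.snapshots.items())
    if len(items) < 2:
        raise ValueError("velocity profile needs at least two snapshots")
    ds, vs = [], []
    for (it0, s0), (it1, s1) in zip(items[:-1], items[1:]):
        hours = (it1 - it0) * trace.minutes_per_iteration / 60.0
        if hours <= 0:
            continue
        common, i0, i1 = np.intersect1d(
            s0.cells.ids, s1.cells.ids, return_indices=True
        )
        d0 = _tip_distance(trace, s0.cells.positions[i0, 1])
        d1 = _tip_distance(trace, s1.cells.positions[i1, 1])
        ds.append(d0)
        vs.append((d1 - d0) / hours)
    d = np.concatenate(ds)
    v = np.concatenate(vs)
    edges = np.arange(0.0, d.max() + bw, bw)
    n, _ = np.histogram(d, bins=edges)
    s, _ = np.histogram(d, bins=edges, weights=v)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    if from_qc:
        edges = edges - qc_shift(trace)
    return Profile(edges, mean, n)


def coupled_profile(
    trace: Trace, snap: Snapshot, bin_width: float | None = None
) -> pd.DataFrame:
    """The auxin / potential / clock triplet along the axis.

    Binned means of the auxin concentration, the local elastic potential
    normalized by its maximum, and the cell-cycle clock advance (iterations
    since last division), against distance from the tip.
    """
    bw = bin_width or _default_bin_width(trace)
    d = _tip_distance(trace, snap.cells.positions[:, 1])
    edges = np.arange(0.0, d.max() + bw, bw)
    n, _ = np.histogram(d, bins=edges)
    vmax = snap.potential.max() or 1.0

    def binned(w):
        s, _ = np.histogram(d, bins=edges, weights=w)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, s / np.maximum(n, 1), np.nan)

    return pd.DataFrame(
        {
            "distance_from_tip_bin": 0.5 * (edges[:-1] + edges[1:]),
            "mean_C": binned(snap.cells.C),
            "mean_V_normalized": binned(snap.potential / vmax),
            "mean_clock_phase": binned(snap.cells.phase_iters),
            "n": n,
        }
    )


def auxin_profile(trace: Trace, snap: Snapshot, bin_width: float | None = None) -> Profile:
    """Binned mean auxin concentration vs distance from the tip."""
    bw = bin_width or _default_bin_width(trace)
    d = _tip_distance(trace, snap.cells.positions[:, 1])
    edges = np.arange(0.0, d.max() + bw, bw)
    n, _ = np.histogram(d, bins=edges)
    s, _ = np.histogram(d, bins=edges, weights=snap.cells.C)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return Profile(edges, mean, n)


# --------------------------------------------------------------------------
# RAM-length scaling in D
# --------------------------------------------------------------------------

def fit_power_law(D_values: np.ndarray, ram: np.ndarray):
    """Least-squares fit of log(RAM) = slope*log(D) + intercept.

    Returns ``(slope, intercept, r_squared)``; raises on degenerate input.
    """
    D_values = np.asarray(D_values, dtype=float)
    ram = np.asarray(ram, dtype=float)
    if (ram <= 0).any() or (D_values <= 0).any():
        raise ValueError("power-law fit needs positive RAM lengths and D")
    if np.allclose(ram, ram[0]):
        raise ValueError("degenerate scan: all RAM lengths equal")
    x, y = np.log(D_values), np.log(ram)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return float(slope), float(intercept), float(r2)


def ram_length_scan(
    config_base, D_values, seeds, *, method: str = "robust"
) -> tuple[pd.DataFrame, tuple[float, float, float]]:
    """Run the full model across a grid of transport constants D.

    Returns the per-(D, seed) RAM-length table and the power-law fit of the
    per-D median RAM length.  Needs >= 4 D values and >= 1 seed each.
    """
    from .engine import run

    D_values = np.asarray(list(D_values), dtype=float)
    if len(D_values) < 4:
        raise ValueError("scan needs at least 4 D values")
    rows = []
    for D in D_values:
        for seed in seeds:
            cfg = dataclasses.replace(config_base, D=float(D), seed=int(seed))
            trace = run(cfg)
            rows.append((float(D), int(seed), ram_length(trace, method=method)))
    table = pd.DataFrame(rows, columns=["D", "seed", "ram_length"])
    med = table.groupby("D")["ram_length"].median()
    fit = fit_power_law(med.index.to_numpy(), med.to_numpy())
    return table, fit
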