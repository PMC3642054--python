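"""Writers for snapshots, traces and figures (CSV / JSON / SVG)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Snapshot, Trace


def snapshot_frame(snap: Snapshot) -> pd.DataFrame:
    c = snap.cells
    return pd.DataFrame(
        {
            "cell_id": c.ids,
            "x": c.positions[:, 0],
            "y": c.positions[:, 1],
            "area": snap.tess.areas,
            "centroid_x": snap.tess.centroids[:, 0],
            "centroid_y": snap.tess.centroids[:, 1],
            "is_qc": c.is_qc,
            "auxin": c.C,
            "clock_phase": c.phase_iters,
        }
    )


def write_snapshot_csv(snap: Snapshot, path) -> None:
    snapshot_frame(snap).to_csv(path, index=False)


def write_adjacency_json(snap: Snapshot, path) -> None:
    adj: dict[int, list[int]] = {int(i): [] for i in snap.cells.ids}
    for a, b in snap.tess.adjacency():
        adj[int(snap.cells.ids[a])].append(int(snap.cells.ids[b]))
        adj[int(snap.cells.ids[b])].append(int(snap.cells.ids[a]))
    Path(path).write_text(json.dumps({str(k): sorted(v) for k, v in adj.items()}))


def render_svg(snap: Snapshot, path, field: str = "auxin") -> None:
    """Draw the cell polygons colored by a per-cell field.

    The auxin colormap runs blue (minimum) to red (maximum), matching the
    usual presentation of root auxin gradients.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    values = {
        "auxin": snap.cells.C,
        "potential": snap.potential,
        "area": snap.tess.areas,
        "clock_phase": snap.cells.phase_iters,
    }[field]
    vmax = values.max() if values.max() > 0 else 1.0
    fig, ax = plt.subplots(figsize=(4, 8))
    coll = PolyCollection(
        snap.tess.polygons,
        array=np.asarray(values, dtype=float),
        cmap="coolwarm", edgecolor="k", linewidth=0.3, clim=(0.0, vmax),
    )
    ax.add_collection(coll)
    bx = snap.domain.polygon().exterior.xy
    ax.plot(*bx, color="0.4", lw=0.8)
    qc = snap.cells.positions[snap.cells.is_qc]
    if len(qc):
        ax.plot(qc[:, 0], qc[:, 1], "w^", ms=6, mec="k")
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm), apex at bottom")
    fig.colorbar(coll, ax=ax, label=field, shrink=0.5)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def write_trace(trace: Trace, outdir) -> None:
    """Dump a run: summary CSV, division-event log, per-snapshot files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    trace.summary().to_csv(out / "summary.csv", index=False)
    ev = trace.events_frame()
    if len(ev):
        apex = trace.snapshots[min(trace.snapshots)].domain.apex_y
        ev["distance_from_tip"] = ev["y"] - apex
    ev.to_csv(out / "divisions.csv", index=False)
    for it, snap in sorted(trace.snapshots.items()):
        write_snapshot_csv(snap, out / f"snapshot_{it:06d}.csv")
    trace.config.to_yaml(out / "config.yaml")
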