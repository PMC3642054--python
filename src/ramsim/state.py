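"""Per-cell state container shared by the cycle and engine modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Cells:
    """Structure-of-arrays record of every living cell.

    Index order matches the generator order handed to the tessellation.
    ``ids`` are stable, unique and never reused, so division events can be
    traced across the whole run.
    """

    ids: np.ndarray           # (n,) int
    positions: np.ndarray     # (n, 2) generating points (µm)
    velocities: np.ndarray    # (n, 2) µm / iteration
    C: np.ndarray             # (n,) auxin concentration, in [0, 1]
    u: np.ndarray             # (n,) activator cyclin (CYCD role)
    v: np.ndarray             # (n,) inhibitor cyclin (CYCB role)
    phase_iters: np.ndarray   # (n,) iterations since last division
    is_qc: np.ndarray         # (n,) bool quiescent-centre flag
    next_id: int = 0

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def mobile(self) -> np.ndarray:
        """QC generators are spatially pinned; everything else moves."""
        return ~self.is_qc

    @classmethod
    def create(
        cls,
        positions: np.ndarray,
        is_qc: np.ndarray,
        C: np.ndarray,
        u0: float,
        v0: float,
    ) -> "Cells":
        n = len(positions)
        return cls(
            ids=np.arange(n),
            positions=np.asarray(positions, dtype=float).copy(),
            velocities=np.zeros((n, 2)),
            C=np.asarray(C, dtype=float).copy(),
            u=np.full(n, u0),
            v=np.full(n, v0),
            phase_iters=np.zeros(n),
            is_qc=np.asarray(is_qc, dtype=bool).copy(),
            next_id=n,
        )

    def append(self, **fields) -> int:
        """Append one cell; returns its new id."""
        new_id = self.next_id
        self.ids = np.append(self.ids, new_id)
        self.positions = np.vstack([self.positions, fields["position"]])
        self.velocities = np.vstack([self.velocities, fields["velocity"]])
        self.C = np.append(self.C, fields["C"])
        self.u = np.append(self.u, fields["u"])
        self.v = np.append(self.v, fields["v"])
        self.phase_iters = np.append(self.phase_iters, 0.0)
        self.is_qc = np.append(self.is_qc, fields.get("is_qc", False))
        self.next_id = new_id + 1
        return new_id
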