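"""Polar auxin transport on the tessellation, gated by PIN carriers.

Auxin moves between adjacent cells through their shared wall.  Transport
is active (PIN-mediated): the binary membrane "gates" standing in for
polarly localized PIN efflux carriers set the *direction* of the flux —
possibly against the potential and concentration gradients — while the
magnitude of the local elastic-potential difference across the wall sets
its *rate*:

    flux(i -> j) = D * L_ij * |V_i - V_j|      gate i->j open only,
    flux(i -> j) = D * L_ij * (V_i - V_j)      both directions open,

so that with every gate open the law reduces to a plain down-gradient
Darcy/Fourier permeation.  The default rule set reproduces the
reverse-fountain circulation of the root tip — auxin streams toward the
apex through the inner tissue, spreads laterally below the quiescent
centre, and is pumped back baseward through the outermost
(epidermis-contacting) cell file.

The concentration field is dimensionless: after every step it is rescaled
by its maximum, and the quiescent-centre cells are (by default) re-clamped
to 1, making the niche an implicit auxin source.  Exchange itself is
exactly antisymmetric, so with rescaling and clamping disabled the total
auxin is conserved to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Tessellation


@dataclass(frozen=True)
class ReverseFountainRules:
    """Default PIN gate logic.

    For an ordered adjacent pair (i, j), all gates are closed except:

    * i and j are both inner cells (not touching the epidermis) and j lies
      apexward of i (smaller y): auxin may flow i -> j toward the tip;
    * i and j both lie below the quiescent centre: both directions open
      (lateral redistribution around the apex);
    * i and j are both surface cells and j lies baseward of i (larger y):
      auxin may flow i -> j back toward the base.

    Ties in y (within ``tie_frac * sqrt(Abar)``) leave the gate closed.
    """

    tie_frac: float = 1e-6

    def __call__(
        self,
        tess: Tessellation,
        pairs: np.ndarray,
        qc_mask: np.ndarray,
    ) -> np.ndarray:
        """Open/closed gates for both directions of each unordered pair.

        Returns an (E, 2) boolean array: column 0 is the gate a->b,
        column 1 the gate b->a, for ``pairs[:, 0] == a``.
        """
        y = tess.generators[:, 1]
        tie = self.tie_frac * np.sqrt(tess.mean_area)
        a, b = pairs[:, 0], pairs[:, 1]
        surf = tess.surface
        inner = ~surf[a] & ~surf[b]
        both_surf = surf[a] & surf[b]
        open_ab = (inner & (y[b] < y[a] - tie)) | (both_surf & (y[b] > y[a] + tie))
        open_ba = (inner & (y[a] < y[b] - tie)) | (both_surf & (y[a] > y[b] + tie))
        if qc_mask.any():
            y_qc = y[qc_mask].min()
            below = (y[a] < y_qc) & (y[b] < y_qc)
            open_ab = open_ab | below
            open_ba = open_ba | below
        return np.column_stack([open_ab, open_ba])


@dataclass
class AuxinState:
    """Per-cell auxin concentrations and transport constants."""

    C: np.ndarray                 # (n,) concentrations, max-normalized to 1
    D: float                      # transport rate constant (1/iteration)
    pin: bool = True              # False = knockout: every gate open
    qc_clamp: bool = True         # re-pin QC concentration at 1 each step
    fickian_D: float = 0.0        # ungated symplastic diffusion constant
    rules: ReverseFountainRules = field(default_factory=ReverseFountainRules)

    @classmethod
    def random_with_qc_max(
        cls, n: int, qc_mask: np.ndarray, rng: np.random.Generator, D: float, **kw
    ) -> "AuxinState":
        """Random initial field with the maximum at the quiescent centre."""
        C = rng.uniform(0.0, 0.5, size=n)
        C[qc_mask] = 1.0
        return cls(C=C, D=D, **kw)


def gates(
    tess: Tessellation,
    qc_mask: np.ndarray,
    *,
    pin: bool = True,
    rules: ReverseFountainRules | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gate matrix for every interior-interior adjacent pair.

    Returns ``(pairs, P)`` where pairs is (E, 2) cell indices and P is the
    (E, 2) boolean gate array (directions a->b, b->a).  Gates are derived
    from the current tessellation only and are never persisted across
    re-tessellations.
    """
    mask = tess.interior_edges()
    pairs = tess.edge_cells[mask]
    if pin:
        P = (rules or ReverseFountainRules())(tess, pairs, qc_mask)
    else:
        P = np.ones((len(pairs), 2), dtype=bool)
    return pairs, P


def permeability(P: np.ndarray, D: float) -> np.ndarray:
    """Wall permeability phi = D * P: the gate modulates the Darcy constant."""
    return D * P.astype(float)


def transport_step(
    state: AuxinState,
    tess: Tessellation,
    V_local: np.ndarray,
    dt_a: float = 1.0,
    *,
    qc_mask: np.ndarray | None = None,
    normalize: bool = True,
) -> AuxinState:
    """One explicit Euler step of gated wall-to-wall auxin exchange.

    ``V_local`` is the per-cell elastic potential.  Across each wall the
    open gate's direction carries a flux of magnitude ``D * L * |dV|``
    (signed down-potential where both directions are open), plus the
    optional ungated diffusive term.  After the exchange the field is
    clipped at zero, rescaled by its maximum, and the QC cells are
    re-clamped to 1 (both steps optional).
    """
    n = tess.n_cells
    if qc_mask is None:
        qc_mask = np.zeros(n, dtype=bool)
    C = state.C.astype(float).copy()
    pairs, P = gates(tess, qc_mask, pin=state.pin, rules=state.rules)
    L = tess.edge_lengths[tess.interior_edges()]
    a, b = pairs[:, 0], pairs[:, 1]
    dV = V_local[a] - V_local[b]
    # PIN transport is active: a one-way gate pumps at a rate set by the
    # magnitude of the potential difference, in the gate's direction (even
    # against the potential); where both directions are open the wall
    # reduces to the signed down-potential Darcy law.
    both = P[:, 0] & P[:, 1]
    one_ab = P[:, 0] & ~P[:, 1]
    one_ba = P[:, 1] & ~P[:, 0]
    flux = L * state.D * (
        np.where(both, dV, 0.0)
        + np.where(one_ab, np.abs(dV), 0.0)
        - np.where(one_ba, np.abs(dV), 0.0)
    )
    if state.fickian_D > 0.0:
        flux = flux + state.fickian_D * L * (C[a] - C[b])
    # positivity limiter: a wall may not export more than its donor holds,
    # so each cell's total efflux is capped at C_i / dt (still antisymmetric)
    donor = np.where(flux >= 0.0, a, b)
    out = np.zeros(n)
    np.add.at(out, donor, dt_a * np.abs(flux))
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(out > C, np.where(out > 0, C / out, 1.0), 1.0)
    flux = flux * scale[donor]
    dC = np.zeros(n)
    np.add.at(dC, a, -dt_a * flux)
    np.add.at(dC, b, dt_a * flux)
    C += dC
    if C.min() < -1e-12:
        raise FloatingPointError(
            f"auxin concentration underflow ({C.min():.3e}); "
            "transport step too large for D"
        )
    if normalize:
        np.clip(C, 0.0, None, out=C)
        m = C.max()
        if m > 0:
            C /= m
        if state.qc_clamp and qc_mask.any():
            C[qc_mask] = 1.0
    return AuxinState(
        C=C, D=state.D, pin=state.pin, qc_clamp=state.qc_clamp,
        fickian_D=state.fickian_D, rules=state.rules,
    )
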