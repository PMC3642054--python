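"""Shared fixtures: reference domains, lattices and parameter sets."""

from __future__ import annotations

import numpy as np
import pytest

from ramsim.geometry import Domain, build_domain, tessellate
from ramsim.mechanics import MechParams


def box_domain(width=120.0, height=120.0, spacing=10.0) -> Domain:
    """A mostly rectangular domain (vestigial tip) for geometry-free tests."""
    return Domain(
        width=width, tip_depth=2.0, rect_height=height, boundary_spacing=spacing
    )


def hex_lattice(domain: Domain, a: float) -> tuple[np.ndarray, np.ndarray]:
    """Hexagonal lattice of generators inside ``domain``.

    Returns (points, deep_mask) where deep cells sit at least 2.5 lattice
    constants away from the outline and are therefore perfect hexagons.
    """
    w = domain.width
    y0, y1 = domain.apex_y + domain.tip_depth, domain.top_y
    dy = np.sqrt(3.0) / 2.0 * a
    pts = []
    row = 0
    y = y0 + a
    while y < y1 - 0.5 * a:
        xoff = 0.5 * a if row % 2 else 0.0
        x = -w / 2 + 0.6 * a + xoff
        while x < w / 2 - 0.5 * a:
            pts.append((x, y))
            x += a
        y += dy
        row += 1
    pts = np.array(pts)
    margin = 2.5 * a
    deep = (
        (pts[:, 0] > -domain.width / 2 + margin)
        & (pts[:, 0] < domain.width / 2 - margin)
        & (pts[:, 1] > y0 + margin)
        & (pts[:, 1] < y1 - margin)
    )
    return pts, deep


@pytest.fixture
def small_root():
    """A modest random root-tip configuration (20 cells)."""
    domain, pts = build_domain(
        20, width=80.0, rect_height=60.0, tip_depth=30.0,
        boundary_spacing=12.0, rng_seed=3,
    )
    return domain, pts, tessellate(domain, pts)


@pytest.fixture
def mech_params():
    return MechParams(K_v=3.0e-4, K_c=1.0, lambda_f=1.0, dt=0.05, tol=1e-4)
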