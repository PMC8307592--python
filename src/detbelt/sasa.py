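"""Solvent-accessible surface area by the Shrake-Rupley method.

Each heavy atom is a van der Waals sphere inflated by the probe radius
(water, 1.4 Å by default).  A deterministic Fibonacci lattice of test points
is placed on every inflated sphere; a point is accessible when it lies
outside every neighbouring inflated sphere, and the atom's SASA is the
accessible fraction of its inflated-sphere area.  The lattice makes results
exactly reproducible for a given point count.

Downstream, the belt pipeline only thresholds these areas at a few Å², so
moderate point counts (default 960) are ample; convergence and a Monte-Carlo
cross-check live in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pdb_io import AtomRecord

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii (Å) for the elements common in proteins and
#: amphiphiles.  Unlisted elements fall back to ``DEFAULT_VDW_RADIUS``.
BONDI_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "D": 1.20,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

DEFAULT_VDW_RADIUS = 1.70
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class SphereSet:
    """Atom centres and van der Waals radii, indexed back to the atom list."""

    centers: np.ndarray  # (n, 3) Å
    radii: np.ndarray  # (n,) Å
    atom_index: np.ndarray  # (n,) positions in the originating atom list

    def __len__(self) -> int:
        return len(self.radii)


@dataclass
class SasaResult:
    """Per-atom solvent-accessible areas (Å²), aligned with a SphereSet."""

    per_atom_area: np.ndarray
    probe_radius: float
    n_points: int


def assign_vdw_radii(
    atoms: list[AtomRecord],
    table: dict[str, float] | None = None,
    default_radius: float = DEFAULT_VDW_RADIUS,
) -> SphereSet:
    """Map each atom to its van der Waals radius (Bondi table by default)."""
    if not atoms:
        raise ValueError("assign_vdw_radii: empty atom list")
    table = BONDI_RADII if table is None else table
    lookup = {k.upper(): v for k, v in table.items()}
    centers = np.array([(a.x, a.y, a.z) for a in atoms], dtype=float)
    radii = np.empty(len(atoms))
    unknown: set[str] = set()
    for i, a in enumerate(atoms):
        r = lookup.get(a.element.upper())
        if r is None:
            unknown.add(a.element)
            r = default_radius
        radii[i] = r
    if unknown:
        logger.warning(
            "no van der Waals radius for element(s) %s; using default %.2f Å",
            sorted(unknown),
            default_radius,
        )
    return SphereSet(centers=centers, radii=radii, atom_index=np.arange(len(atoms)))


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle spiral)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(
    spheres: SphereSet,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Per-atom SASA for a set of van der Waals spheres.

    Neighbour candidates come from a k-d tree queried at the largest possible
    contact distance; the result is identical to the all-pairs computation.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    centers = spheres.centers
    expanded = spheres.radii + probe_radius
    n = len(expanded)
    unit = fibonacci_sphere(n_points)
    areas = np.empty(n)
    tree = cKDTree(centers)
    cutoff = 2.0 * float(expanded.max())
    neighbor_lists = tree.query_ball_point(centers, r=cutoff)
    for i in range(n):
        pts = centers[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d = np.linalg.norm(centers[j] - centers[i])
            if d >= expanded[i] + expanded[j]:
                continue
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 >= expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.sum() / n_points * 4.0 * np.pi * expanded[i] ** 2
    return SasaResult(per_atom_area=areas, probe_radius=probe_radius, n_points=n_points)


def sasa_for_atoms(
    atoms: list[AtomRecord],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Convenience wrapper: radii assignment plus Shrake-Rupley in one call."""
    return shrake_rupley_sasa(assign_vdw_radii(atoms), probe_radius, n_points)
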