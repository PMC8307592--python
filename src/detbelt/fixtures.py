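"""Synthetic membrane-oriented structures with analytically known geometry.

A fixture is a cylindrical shell of carbon pseudo-atoms: ``n_rings`` circles
of radius ``ring_radius`` stacked evenly over a z-span inside the membrane
slab, optionally with Gaussian radial jitter and a second, smaller decoy
shell (mimicking a grooved oligomer whose inner surfaces also face solvent).
Because the radial coordinate of every atom is known by construction, the
whole belt pipeline — SASA filtering, density peak, inner radius — can be
checked against closed forms without any external structure files.

Jitter is purely radial, so the target radial density stays one-dimensional.
Atoms are spaced at least ~2.5 Å apart by construction, keeping shell atoms
well above the solvent-exposure cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FixtureError
from .pdb_io import AtomRecord, OrientedStructure, serialize_pdb

_MIN_SPACING = 2.5  # Å, keeps every pseudo-atom partly solvent-exposed


@dataclass
class FixtureParams:
    """Geometry of a synthetic cylindrical-shell structure (lengths in Å)."""

    ring_radius: float = 20.0
    n_rings: int = 5
    atoms_per_ring: int = 36
    z_span: float = 24.0
    radial_jitter_sd: float = 0.0
    half_thickness: float = 15.0
    seed: int = 0
    decoy_inner_radius: float | None = None

    def __post_init__(self) -> None:
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be > 0")
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if self.atoms_per_ring < 3:
            raise ValueError("atoms_per_ring must be >= 3")
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be > 0")
        if self.radial_jitter_sd < 0:
            raise ValueError("radial_jitter_sd must be >= 0")


def _ring_spacing(radius: float, n: int) -> float:
    return 2.0 * radius * math.sin(math.pi / n)


def _check_spacing(params: FixtureParams, radius: float, n_per_ring: int) -> None:
    if _ring_spacing(radius, n_per_ring) < _MIN_SPACING:
        raise FixtureError(
            f"atoms_per_ring={n_per_ring} packs atoms closer than "
            f"{_MIN_SPACING} Å on a radius-{radius:g} ring; use fewer atoms per ring"
        )
    if params.n_rings > 1:
        dz = params.z_span / (params.n_rings - 1)
        if dz < _MIN_SPACING:
            raise FixtureError(
                f"{params.n_rings} rings over z_span={params.z_span:g} Å are closer "
                f"than {_MIN_SPACING} Å; use fewer rings or a wider z_span"
            )


def _shell_atoms(
    radius: float,
    n_per_ring: int,
    params: FixtureParams,
    rng: np.random.Generator,
    serial0: int,
    resnum0: int,
) -> list[AtomRecord]:
    atoms = []
    if params.n_rings > 1:
        z_values = np.linspace(-params.z_span / 2.0, params.z_span / 2.0, params.n_rings)
    else:
        z_values = np.array([0.0])
    serial = serial0
    resnum = resnum0
    for z in z_values:
        for k in range(n_per_ring):
            theta = 2.0 * math.pi * k / n_per_ring
            rho = radius
            if params.radial_jitter_sd > 0:
                rho = radius + rng.normal(0.0, params.radial_jitter_sd)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name="CA",
                    element="C",
                    residue_name="ALA",
                    chain_id="A",
                    residue_number=resnum,
                    x=rho * math.cos(theta),
                    y=rho * math.sin(theta),
                    z=float(z),
                )
            )
            serial += 1
            resnum += 1
    return atoms


def make_ring_fixture(params: FixtureParams) -> tuple[OrientedStructure, str]:
    """Build a cylindrical-shell structure and its serialized PDB text.

    Returns the in-memory structure (exact coordinates) and the PDB stream
    (3-decimal coordinates, half-thickness REMARK included) so tests can
    exercise both the direct and the parsed path.
    """
    rng = np.random.default_rng(params.seed)
    _check_spacing(params, params.ring_radius, params.atoms_per_ring)
    atoms = _shell_atoms(
        params.ring_radius, params.atoms_per_ring, params, rng, serial0=1, resnum0=1
    )
    if params.decoy_inner_radius is not None:
        if params.decoy_inner_radius >= params.ring_radius:
            raise FixtureError("decoy_inner_radius must be smaller than ring_radius")
        n_decoy = max(
            3,
            int(params.atoms_per_ring * params.decoy_inner_radius / params.ring_radius),
        )
        _check_spacing(params, params.decoy_inner_radius, n_decoy)
        atoms += _shell_atoms(
            params.decoy_inner_radius,
            n_decoy,
            params,
            rng,
            serial0=len(atoms) + 1,
            resnum0=len(atoms) + 1,
        )
    structure = OrientedStructure(
        atoms=atoms,
        half_thickness=params.half_thickness,
        source_label=f"ring fixture rho={params.ring_radius:g}",
    )
    return structure, serialize_pdb(structure)
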