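"""Hollow-cylinder belt geometry.

The belt around a solubilized membrane protein is idealized as a hollow
cylinder coaxial with the membrane normal (z):

* height ``h`` — twice the membrane half-thickness carried by the oriented
  structure;
* inner radius ``r`` — the radial position of the outermost shell of
  solvent-exposed transmembrane atoms (the rightmost peak of the radial
  density of exposed atoms within the membrane slab), plus an offset for the
  average heavy-atom van der Waals radius (1.66 Å);
* outer radius ``R`` — fixed by conservation of the total detergent volume
  ``V``:  V = π·h·(R² − r²), hence R = sqrt(V/(π·h) + r²).

Detergent mixtures are rendered as stacked hollow-cylinder slabs sharing r
and R, each slab's height proportional to that detergent's share of V.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

from .detergent_db import BeltSpec, DetergentEntry, total_volume
from .errors import (
    BeltComputationError,
    NoExposedAtomsError,
    ThicknessUnavailableError,
)
from .pdb_io import AtomRecord, OrientedStructure, protein_heavy_atoms
from .sasa import SasaResult, sasa_for_atoms

logger = logging.getLogger(__name__)

#: Radius added to the detected peak: average van der Waals radius of protein
#: heavy atoms, so the inner cylinder wall touches atom surfaces, not centres.
DEFAULT_VDW_OFFSET = 1.66

#: Exposure threshold (Å², strict) separating buried from belt-facing atoms.
DEFAULT_ASA_CUTOFF = 3.0

_DEGENERATE_SPREAD = 1e-9
_KDE_GRID_SIZE = 512


@dataclass
class BeltOptions:
    """Tunable parameters of the belt computation (lengths in Å, areas Å²)."""

    asa_cutoff: float = DEFAULT_ASA_CUTOFF
    vdw_offset: float = DEFAULT_VDW_OFFSET
    probe_radius: float = 1.4
    sasa_n_points: int = 960
    inner_radius_override: float | None = None
    half_thickness_override: float | None = None
    kde_bandwidth: float | str = "silverman"
    peak_min_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.asa_cutoff < 0:
            raise ValueError("asa_cutoff must be >= 0")
        if self.vdw_offset < 0:
            raise ValueError("vdw_offset must be >= 0")
        for name in ("inner_radius_override", "half_thickness_override"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when set")


@dataclass
class RadialProfile:
    """Kernel density estimate over radial distances of exposed TM atoms."""

    grid: np.ndarray  # ascending radial positions (Å)
    density: np.ndarray  # aligned, nonnegative
    bandwidth: float  # kernel standard deviation (Å)
    n_samples: int
    point_mass: float | None = None  # set when all samples coincide


@dataclass
class Stack:
    """One detergent slab of the (possibly mixed) belt."""

    detergent_id: str
    n_monomers: int
    volume: float  # Å³
    z_lo: float  # Å
    z_hi: float  # Å


@dataclass
class BeltGeometry:
    """The belt answer: h, r, R, V plus per-detergent stack slabs."""

    h: float
    r: float
    R: float
    V_total: float
    stacks: list[Stack] = field(default_factory=list)
    r_source: str = "computed"  # "computed" | "override"
    peak_radius: float | None = None


def belt_height(half_thickness: float | None) -> float:
    """Belt height = twice the membrane half-thickness."""
    if half_thickness is None:
        raise ThicknessUnavailableError(
            "thickness unavailable: no REMARK, no dummy layer, no override"
        )
    if half_thickness <= 0:
        raise ValueError("half_thickness must be > 0")
    return 2.0 * half_thickness


def select_exposed_tm_atoms(
    structure: OrientedStructure,
    sasa: SasaResult,
    options: BeltOptions | None = None,
) -> list[AtomRecord]:
    """Heavy atoms inside the membrane slab with SASA strictly above cutoff.

    Slab membership is by atom centre: |z| <= half-thickness (inclusive).
    ``sasa`` must be aligned with :func:`protein_heavy_atoms` of *structure*.
    """
    options = options or BeltOptions()
    half = options.half_thickness_override
    if half is None:
        half = structure.half_thickness
    if half is None:
        raise ThicknessUnavailableError(
            "thickness unavailable for transmembrane slab selection"
        )
    heavy = protein_heavy_atoms(structure)
    if len(heavy) != len(sasa.per_atom_area):
        raise ValueError("SASA result not aligned with heavy-atom list")
    kept = [
        a
        for a, area in zip(heavy, sasa.per_atom_area)
        if abs(a.z) <= half and area > options.asa_cutoff
    ]
    if not kept:
        raise NoExposedAtomsError(
            "no exposed transmembrane atoms: the protein may not span the "
            f"slab |z| <= {half:g} Å, or the ASA cutoff {options.asa_cutoff:g} "
            "Å² is too high"
        )
    return kept


def radial_distances(atoms: list[AtomRecord]) -> np.ndarray:
    """Distance of each atom to the membrane normal (z axis), order kept."""
    if not atoms:
        raise ValueError("radial_distances: empty atom list")
    xy = np.array([(a.x, a.y) for a in atoms], dtype=float)
    return np.hypot(xy[:, 0], xy[:, 1])


def density_estimate(
    distances: np.ndarray | list[float], options: BeltOptions | None = None
) -> RadialProfile:
    """Gaussian KDE of radial distances on a 512-point grid.

    Bandwidth follows Silverman's rule unless an explicit bandwidth (Å) is
    given.  When every sample coincides the density is a point mass; the
    profile is flagged so peak extraction short-circuits to that value.
    """
    options = options or BeltOptions()
    d = np.asarray(distances, dtype=float)
    if d.size < 1:
        raise ValueError("density_estimate: no distances")
    if np.ptp(d) < _DEGENERATE_SPREAD:
        v = float(d[0])
        return RadialProfile(
            grid=np.array([v]),
            density=np.array([np.inf]),
            bandwidth=0.0,
            n_samples=int(d.size),
            point_mass=v,
        )
    if d.size < 2:
        raise ValueError("density_estimate: need at least 2 values")
    if isinstance(options.kde_bandwidth, str):
        kde = gaussian_kde(d, bw_method=options.kde_bandwidth)
    else:
        sd = float(np.std(d, ddof=1))
        kde = gaussian_kde(d, bw_method=options.kde_bandwidth / sd)
    bw = float(kde.factor * np.std(d, ddof=1))
    lo = max(0.0, float(d.min()) - 3.0 * bw)
    hi = float(d.max()) + 3.0 * bw
    grid = np.linspace(lo, hi, _KDE_GRID_SIZE)
    density = kde(grid)
    return RadialProfile(
        grid=grid, density=density, bandwidth=bw, n_samples=int(d.size)
    )


def rightmost_peak(
    profile: RadialProfile, options: BeltOptions | None = None
) -> float:
    """Largest-radius local density maximum above the guard fraction.

    Minor modes below ``peak_min_fraction`` of the global maximum are ignored
    so a handful of stray outermost atoms cannot define the belt wall.
    """
    options = options or BeltOptions()
    if profile.point_mass is not None:
        return profile.point_mass
    dens = profile.density
    peaks = argrelmax(dens)[0]
    threshold = options.peak_min_fraction * float(dens.max())
    qualifying = [i for i in peaks if dens[i] >= threshold]
    if not qualifying:
        logger.warning("no qualifying local maximum; using global maximum")
        return float(profile.grid[int(np.argmax(dens))])
    return float(profile.grid[qualifying[-1]])


def inner_radius(peak: float, options: BeltOptions | None = None) -> float:
    """Inner belt radius: peak position plus the van der Waals offset.

    An explicit ``inner_radius_override`` wins over the computed value.
    """
    options = options or BeltOptions()
    if options.inner_radius_override is not None:
        return options.inner_radius_override
    if peak < 0:
        raise ValueError("peak radius must be >= 0")
    return peak + options.vdw_offset


def outer_radius(V: float, h: float, r: float) -> float:
    """Outer radius from volume conservation: π·h·(R² − r²) = V."""
    if V < 0:
        raise ValueError("V must be >= 0")
    if h <= 0:
        raise ValueError("h must be > 0")
    if r < 0:
        raise ValueError("r must be >= 0")
    return math.sqrt(V / (math.pi * h) + r * r)


def stack_mixture(
    h: float,
    r: float,
    R: float,
    volumes: list[tuple[str, float]],
    counts: dict[str, int] | None = None,
) -> list[Stack]:
    """Tile [−h/2, +h/2] with one slab per detergent, bottom-up in input order.

    Slab i gets height h·Vᵢ/ΣV so its hollow-cylinder volume equals Vᵢ
    exactly; all slabs share r and R.
    """
    if any(v < 0 for _, v in volumes):
        raise ValueError("stack volumes must be >= 0")
    v_total = sum(v for _, v in volumes)
    if v_total <= 0:
        raise ValueError("at least one stack volume must be > 0")
    counts = counts or {}
    stacks: list[Stack] = []
    z = -h / 2.0
    acc = 0.0
    for det_id, v in volumes:
        acc += v
        z_hi = -h / 2.0 + h * acc / v_total
        stacks.append(
            Stack(
                detergent_id=det_id,
                n_monomers=counts.get(det_id, 0),
                volume=v,
                z_lo=z,
                z_hi=z_hi,
            )
        )
        z = z_hi
    # close the tiling exactly against accumulated rounding
    stacks[-1].z_hi = h / 2.0
    return stacks


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        if isinstance(exc, BeltComputationError):
            raise
        raise BeltComputationError(f"stage '{name}': {exc}") from exc


def build_belt(
    structure: OrientedStructure,
    spec: BeltSpec,
    db: list[DetergentEntry],
    options: BeltOptions | None = None,
    volume_overrides: dict[str, float] | None = None,
) -> BeltGeometry:
    """End-to-end belt computation.

    Pipeline: half-thickness → h; heavy atoms → SASA → exposed TM atoms →
    radial distances → density → rightmost peak → r (unless overridden);
    spec + database → V; volume conservation → R; mixture → stacks.
    """
    options = options or BeltOptions()
    half = options.half_thickness_override
    if half is None:
        half = structure.half_thickness
    h = _stage("belt height", belt_height, half)

    per_det, V_total = _stage("total volume", total_volume, spec, db, volume_overrides)

    if options.inner_radius_override is not None:
        r = options.inner_radius_override
        r_source = "override"
        peak = None
    else:
        heavy = _stage("heavy atoms", protein_heavy_atoms, structure)
        sres = _stage(
            "SASA", sasa_for_atoms, heavy, options.probe_radius, options.sasa_n_points
        )
        exposed = _stage(
            "exposed TM atoms", select_exposed_tm_atoms, structure, sres, options
        )
        dists = _stage("radial distances", radial_distances, exposed)
        profile = _stage("radial density", density_estimate, dists, options)
        peak = _stage("rightmost peak", rightmost_peak, profile, options)
        r = _stage("inner radius", inner_radius, peak, options)
        r_source = "computed"

    R = _stage("outer radius", outer_radius, V_total, h, r)
    counts = {d: n for d, n in spec.entries}
    stacks = _stage("mixture stacks", stack_mixture, h, r, R, per_det, counts)
    return BeltGeometry(
        h=h,
        r=r,
        R=R,
        V_total=V_total,
        stacks=stacks,
        r_source=r_source,
        peak_radius=peak,
    )
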