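"""Belt output: metrics, a PyMOL script, and a pseudo-atom PDB shell.

The hollow cylinder has no native primitive in the PyMOL compiled-graphics
dialect, so each stack is drawn as two coaxial solid cylinders: the outer one
semi-transparent in the detergent's colour, the inner one opaque in a neutral
tone.  For viewer-independent inspection, the belt can also be written as a
cloud of pseudo-atoms uniformly sampled inside the annulus of each stack.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .beltcore import BeltGeometry, BeltOptions, Stack
from .detergent_db import BeltSpec, DetergentEntry

_CGO_CYLINDER = 9.0  # PyMOL CGO opcode
_INNER_COLOR = (0.75, 0.75, 0.75)


@dataclass
class BeltReport:
    """A belt geometry plus the provenance needed to reproduce it."""

    geometry: BeltGeometry
    structure_label: str = ""
    spec: BeltSpec | None = None
    options: BeltOptions | None = None
    warnings: list[str] = field(default_factory=list)


def _metrics_dict(report: BeltReport) -> dict:
    g = report.geometry
    out = {
        "h_A": g.h,
        "inner_radius_A": g.r,
        "outer_radius_A": g.R,
        "total_volume_A3": g.V_total,
        "r_source": g.r_source,
        "peak_radius_A": g.peak_radius,
        "stacks": [
            {
                "detergent_id": s.detergent_id,
                "n_monomers": s.n_monomers,
                "volume_A3": s.volume,
                "z_lo_A": s.z_lo,
                "z_hi_A": s.z_hi,
            }
            for s in g.stacks
        ],
        "structure_label": report.structure_label,
        "warnings": list(report.warnings),
    }
    if report.spec is not None:
        out["spec"] = [[d, n] for d, n in report.spec.entries]
    if report.options is not None:
        opts = asdict(report.options)
        out["options"] = opts
    return out


def write_metrics(report: BeltReport, format: str = "json") -> str:
    """Serialize the belt metrics (h, r, R, V, stacks).

    ``json`` keeps full precision and is machine-readable; ``text`` is an
    aligned table with two decimals.
    """
    if format == "json":
        return json.dumps(_metrics_dict(report), indent=2, sort_keys=True) + "\n"
    if format != "text":
        raise ValueError(f"unknown metrics format {format!r}")
    g = report.geometry
    lines = [
        f"structure        : {report.structure_label or '-'}",
        f"belt height h    : {g.h:10.2f} A",
        f"inner radius r   : {g.r:10.2f} A  ({g.r_source})",
        f"outer radius R   : {g.R:10.2f} A",
        f"total volume V   : {g.V_total:10.2f} A^3",
    ]
    if g.peak_radius is not None:
        lines.append(f"density peak     : {g.peak_radius:10.2f} A")
    lines.append("stacks (bottom to top):")
    for s in g.stacks:
        lines.append(
            f"  {s.detergent_id:<10s} n={s.n_monomers:<6d}"
            f" V={s.volume:12.2f} A^3  z=[{s.z_lo:8.2f},{s.z_hi:8.2f}] A"
        )
    for w in report.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"


def read_metrics(text: str) -> dict:
    """Parse metrics JSON back into a dictionary (round-trip counterpart)."""
    return json.loads(text)


def _stack_color(
    stack: Stack, db: list[DetergentEntry] | None
) -> tuple[float, float, float]:
    if db:
        for e in db:
            if e.id.lower() == stack.detergent_id.lower():
                return e.display_color
    return (0.2, 0.7, 0.3)


def write_viewer_script(
    report: BeltReport,
    structure_path: str,
    db: list[DetergentEntry] | None = None,
    transparency: float = 0.5,
) -> str:
    """PyMOL script drawing the belt as coaxial compiled-graphics cylinders.

    Per stack: one outer cylinder (radius R, stack colour, semi-transparent)
    and one inner cylinder (radius r, neutral opaque), both spanning the
    stack's z-range.  All literals carry the geometry values to 3 decimals.
    """
    g = report.geometry
    lines = [
        "# detbelt viewer script (PyMOL)",
        "# hollow cylinder drawn as two coaxial solid CGO cylinders per stack:",
        "# outer = belt boundary (semi-transparent), inner = protein shell.",
        f"load {structure_path}, protein",
        "hide everything, protein",
        "show cartoon, protein",
        "python",
        "from pymol import cmd",
    ]
    for k, s in enumerate(g.stacks, start=1):
        color = _stack_color(s, db)
        rgb = f"{color[0]:.3f}, {color[1]:.3f}, {color[2]:.3f}"
        grey = ", ".join(f"{c:.3f}" for c in _INNER_COLOR)
        lines.append(
            f"belt_outer_{k} = [{_CGO_CYLINDER}, 0.0, 0.0, {s.z_lo:.3f},"
            f" 0.0, 0.0, {s.z_hi:.3f}, {g.R:.3f}, {rgb}, {rgb}]"
        )
        lines.append(
            f"belt_inner_{k} = [{_CGO_CYLINDER}, 0.0, 0.0, {s.z_lo:.3f},"
            f" 0.0, 0.0, {s.z_hi:.3f}, {g.r:.3f}, {grey}, {grey}]"
        )
        lines.append(f"cmd.load_cgo(belt_outer_{k}, 'belt_outer_{k}')")
        lines.append(f"cmd.load_cgo(belt_inner_{k}, 'belt_inner_{k}')")
        lines.append(
            f"cmd.set('cgo_transparency', {transparency:.3f}, 'belt_outer_{k}')"
        )
    lines.append("python end")
    lines.append("zoom")
    return "\n".join(lines) + "\n"


def _apportion(n_points: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n_points by weight."""
    quota = n_points * weights / weights.sum()
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = n_points - base.sum()
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    return base


def write_belt_pseudoatoms(
    report: BeltReport, n_points: int = 1000, seed: int = 0
) -> str:
    """PDB stream of pseudo-atoms uniformly filling each stack's annulus.

    Radius² uniform in [r², R²], angle uniform, z uniform within the stack;
    per-stack counts proportional to stack volume (largest remainder).
    Neon pseudo-atoms in residue "BLT" render as unbonded small spheres.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    g = report.geometry
    rng = np.random.default_rng(seed)
    volumes = np.array([s.volume for s in g.stacks], dtype=float)
    counts = _apportion(n_points, volumes)
    lines = [
        "REMARK     detbelt pseudo-atom belt shell",
        f"REMARK     r={g.r:.3f} R={g.R:.3f} h={g.h:.3f}",
    ]
    serial = 1
    for s, count in zip(g.stacks, counts):
        for _ in range(int(count)):
            radius = np.sqrt(rng.uniform(g.r**2, g.R**2))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            z = rng.uniform(s.z_lo, s.z_hi)
            x = radius * np.cos(theta)
            y = radius * np.sin(theta)
            lines.append(
                f"HETATM{serial % 100000:>5d} NE   BLT X{serial % 10000:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          NE"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
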