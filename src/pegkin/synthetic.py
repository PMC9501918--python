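"""Generated test inputs: toy PDB structures and noisy progress curves.

The toy structures place lysine ε-amine nitrogens at exactly controlled
geometry (line, ring, or helix arrangements) with an idealized backbone,
so distance-dependent behaviour — minimum spacings, shielding radii,
contact maps — can be asserted against constructed values.  The
generated PDB text is syntactically standard and round-trips through
:func:`pegkin.structure.parse_pdb`.  Backbone geometry is idealized,
not stereochemically valid: only distances and annotation records
matter to the models under test.

Synthetic progress curves are simulator output sampled at requested
times with seeded Gaussian noise proportional to the initial protein
concentration, clipped at zero — the data-generating process assumed by
the parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import ProgressCurve
from .simulation import KineticParameters, simulate

__all__ = ["ToySpec", "make_toy_structure", "make_synthetic_curves"]


@dataclass(frozen=True)
class ToySpec:
    """Geometry specification for a generated toy structure.

    ``spacing`` is the nearest-neighbour NZ–NZ distance in Å (for the
    ring placement this is the chord length, so a 6-lysine ring of
    spacing 20 Å has radius 20 Å).  ``helix_fraction`` of the residues
    (from the start of the chain) are covered by a HELIX record.
    """

    n_lysines: int
    placement: str = "line"  # "line" | "ring" | "helix"
    spacing: float = 10.0
    helix_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_lysines < 0:
            raise ValueError("n_lysines must be >= 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.placement not in ("line", "ring", "helix"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if not 0 <= self.helix_fraction <= 1:
            raise ValueError("helix_fraction must lie in [0, 1]")


def _nz_positions(spec: ToySpec) -> np.ndarray:
    n = spec.n_lysines
    if n == 0:
        return np.zeros((0, 3))
    if spec.placement == "line":
        return np.column_stack([spec.spacing * np.arange(n),
                                np.zeros(n), np.zeros(n)])
    if spec.placement == "ring":
        if n == 1:
            return np.zeros((1, 3))
        radius = spec.spacing / (2.0 * np.sin(np.pi / n))
        # half-step offset keeps the vertex set mirror-symmetric, so the
        # 0.001 Å PDB coordinate rounding preserves equal chord lengths
        theta = 2.0 * np.pi * (np.arange(n) + 0.5) / n
        return np.column_stack([radius * np.cos(theta),
                                radius * np.sin(theta), np.zeros(n)])
    # helix: rise chosen so consecutive NZ atoms sit `spacing` apart
    radius = max(spec.spacing, 5.0)
    turn = np.pi / 4
    chord = 2.0 * radius * np.sin(turn / 2.0)
    rise = np.sqrt(max(spec.spacing ** 2 - chord ** 2, 1.0))
    theta = turn * np.arange(n)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                            rise * np.arange(n)])


def _pdb_atom(serial: int, name: str, resname: str, chain: str, resnum: int,
              xyz: np.ndarray, element: str) -> str:
    pad = "" if len(name) == 4 else " "
    return (f"ATOM  {serial:5d} {pad}{name:<3s} {resname:>3s} {chain}{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}\n")


def make_toy_structure(spec: ToySpec, n_extra_residues: int = 2,
                       chain_id: str = "A") -> str:
    """Emit PDB text with lysine NZ atoms at the specified geometry.

    Each lysine gets backbone N/CA/C/O atoms offset from its NZ;
    ``n_extra_residues`` alanines are appended beyond the lysines so
    contact maps have non-lysine columns.  A HELIX record covers the
    leading ``helix_fraction`` of all residues.
    """
    nz = _nz_positions(spec)
    lines = ["HEADER    SYNTHETIC TOY STRUCTURE\n"]
    n_total = spec.n_lysines + n_extra_residues
    n_helix = int(round(spec.helix_fraction * n_total))
    if n_helix >= 1:
        lines.append(
            f"HELIX    1   1 LYS {chain_id}    1  LYS {chain_id} {n_helix:4d}  1"
            f"{'':30s}{n_helix:5d}\n")
    serial = 1
    body: list[str] = []
    # backbone offsets relative to the residue anchor point
    offsets = {"N": np.array([-1.2, 0.8, 0.3]), "CA": np.array([0.0, 0.0, 0.0]),
               "C": np.array([1.3, 0.6, -0.2]), "O": np.array([1.5, 1.8, -0.3])}
    for i in range(spec.n_lysines):
        anchor = nz[i] + np.array([0.0, 3.9, 0.0])  # CA sits off the amine
        for name in ("N", "CA", "C", "O"):
            body.append(_pdb_atom(serial, name, "LYS", chain_id, i + 1,
                                  anchor + offsets[name], name[0]))
            serial += 1
        body.append(_pdb_atom(serial, "NZ", "LYS", chain_id, i + 1, nz[i], "N"))
        serial += 1
    far = (nz.max(axis=0) if len(nz) else np.zeros(3)) + np.array([30.0, 30.0, 0.0])
    for k in range(n_extra_residues):
        anchor = far + np.array([6.0 * k, 0.0, 0.0])
        resnum = spec.n_lysines + k + 1
        for name in ("N", "CA", "C", "O"):
            body.append(_pdb_atom(serial, name, "ALA", chain_id, resnum,
                                  anchor + offsets[name], name[0]))
            serial += 1
    lines.extend(body)
    lines.append("TER\nEND\n")
    return "".join(lines)


def make_synthetic_curves(params: KineticParameters, k_avg: list[float],
                          t_points: np.ndarray, noise_sd: float = 0.0,
                          seed: int | None = None,
                          include_reagent: bool = True,
                          basis: str = "relative") -> list[ProgressCurve]:
    """Simulate and sample noisy progress curves.

    Gaussian noise with standard deviation ``noise_sd·protein0`` is
    added to every sampled molar concentration, then clipped at zero,
    before any conversion to the relative basis.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t_points = np.asarray(t_points, dtype=float)
    t_grid = np.unique(np.concatenate([[0.0], t_points]))
    result = simulate(params, k_avg, t_grid)
    dense = result._dense
    rng = np.random.default_rng(seed)
    n = len(k_avg)
    curves: list[ProgressCurve] = []
    species = [("native", 0)] + [(f"PEG-{j}", j) for j in range(1, n + 1)]
    for label, j in species:
        vals = np.array([float(dense(t)[j]) for t in t_points])
        vals = vals + rng.normal(0.0, noise_sd * params.protein0, size=len(vals))
        vals = np.clip(vals, 0.0, None)
        if basis == "relative":
            vals = vals / params.protein0
        curves.append(ProgressCurve(times=t_points.copy(), species=label,
                                    concentrations=vals, basis=basis))
    if include_reagent:
        vals = np.array([float(dense(t)[n + 1]) for t in t_points])
        vals = vals + rng.normal(0.0, noise_sd * params.protein0, size=len(vals))
        vals = np.clip(vals, 0.0, None)
        if basis == "relative":
            vals = vals / params.peg0
        curves.append(ProgressCurve(times=t_points.copy(), species="reagent",
                                    concentrations=vals, basis=basis))
    return curves
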