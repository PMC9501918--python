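"""Per-site molecular descriptors for amine-reactivity prediction.

Exposed surface area (ESA) is computed with a Shrake–Rupley rolling-ball
algorithm whose probe mimics the effective size of the PEG reagent:
4.2 Å for a small-molecule (ATRP-initiator-like) probe, 12/17/24 Å for
5/10/20 kDa PEG (freely-jointed-chain radii of gyration), capped at
8.8 Å for proteins of 60 kDa and above.  Hydrophobicity
(Kyte–Doolittle) and helicity (Levitt) come from ProtScale-style
sliding-window averages; secondary structure from HELIX/SHEET records;
amine pKa and Coulombic charge are ingested from delimited tables
produced by external tools (H++, PROPKA, Chimera) — computing them is
out of scope here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import AmineSite, ProteinStructure

__all__ = [
    "ProbeSpec",
    "ResidueScale",
    "KYTE_DOOLITTLE",
    "LEVITT_HELICITY",
    "VDW_RADII",
    "probe_radius_for",
    "shrake_rupley_esa",
    "sliding_window_score",
    "assign_secondary_structure",
    "load_site_descriptors",
    "annotate_sites",
]


@dataclass(frozen=True)
class ProbeSpec:
    """A rolling-ball probe: label plus radius in Å."""

    label: str
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("probe radius must be positive")


# PEG-mimicking probe radii (Å): initiator molecule and freely-jointed-chain
# radii of gyration for 5/10/20 kDa PEG; hard cap for large proteins.
_INITIATOR_RADIUS = 4.2
_PEG_PROBE_RADII = {5: 12.0, 10: 17.0, 20: 24.0}
_LARGE_PROTEIN_CAP = 8.8
_LARGE_PROTEIN_MW_KDA = 60.0


def probe_radius_for(peg_mw_kda: float | None = None,
                     protein_mw_kda: float = 0.0,
                     initiator: bool = False,
                     custom_radius: float | None = None) -> ProbeSpec:
    """Select the ESA probe for a reagent/protein pairing.

    Proteins of ≥60 kDa use a capped 8.8 Å probe regardless of PEG size.
    """
    if custom_radius is not None:
        spec = ProbeSpec("custom", custom_radius)
    elif initiator:
        spec = ProbeSpec("atrp_initiator", _INITIATOR_RADIUS)
    elif peg_mw_kda in _PEG_PROBE_RADII:
        spec = ProbeSpec(f"peg{int(peg_mw_kda)}k", _PEG_PROBE_RADII[peg_mw_kda])
    else:
        raise ValueError(
            f"no probe radius for PEG {peg_mw_kda} kDa; supported sizes are "
            f"{sorted(_PEG_PROBE_RADII)} kDa (pass custom_radius otherwise)")
    if protein_mw_kda >= _LARGE_PROTEIN_MW_KDA and spec.radius > _LARGE_PROTEIN_CAP:
        return ProbeSpec(spec.label, _LARGE_PROTEIN_CAP)
    return spec


# van der Waals radii (Å), heavy atoms; a standard published set.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_esa(structure: ProteinStructure, probe: ProbeSpec,
                      n_sphere_points: int = 960) -> dict[str, float]:
    """Per-residue solvent-exposed surface area (Å²), Shrake–Rupley.

    Each heavy atom is inflated to r_vdw + probe radius and sampled with
    a fixed Fibonacci lattice; the accessible fraction of sphere points
    (those inside no neighbouring inflated sphere) times the sphere area
    is the atom's contribution, summed per residue.  Deterministic for a
    fixed point count.  Hydrogens are ignored; an atom whose element has
    no tabulated radius raises.
    """
    if n_sphere_points < 92:
        raise ValueError("n_sphere_points must be >= 92")
    heavy = [a for a in structure.atoms if a.element.upper() != "H"]
    radii = np.empty(len(heavy))
    for i, a in enumerate(heavy):
        el = a.element.upper() or a.atom_name[0].upper()
        if el not in VDW_RADII:
            raise ValueError(
                f"atom {a.chain_id}:{a.residue_number}:{a.atom_name}: "
                f"unknown element {el!r} (no van der Waals radius)")
        radii[i] = VDW_RADII[el]
    xyz = np.array([a.coords for a in heavy])
    inflated = radii + probe.radius
    sphere = _fibonacci_sphere(n_sphere_points)
    tree = cKDTree(xyz)

    esa: dict[str, float] = {}
    for i, atom in enumerate(heavy):
        ri = inflated[i]
        pts = xyz[i] + ri * sphere
        # neighbours whose inflated sphere could occlude any test point
        nbrs = [j for j in tree.query_ball_point(xyz[i], ri + inflated.max())
                if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in nbrs:
            d2 = ((pts - xyz[j]) ** 2).sum(1)
            accessible &= d2 > inflated[j] ** 2
        area = 4.0 * np.pi * ri * ri * accessible.mean()
        label = f"{atom.chain_id}:{atom.residue_number}"
        esa[label] = esa.get(label, 0.0) + float(area)
    return esa


# Kyte & Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Levitt α-helix propensity (frequency-of-occurrence scale)
LEVITT_HELICITY = {
    "A": 1.29, "R": 0.96, "N": 0.90, "D": 1.04, "C": 1.11,
    "Q": 1.27, "E": 1.44, "G": 0.56, "H": 1.22, "I": 0.97,
    "L": 1.30, "K": 1.23, "M": 1.47, "F": 1.07, "P": 0.52,
    "S": 0.82, "T": 0.82, "W": 0.99, "Y": 0.72, "V": 0.91,
}


@dataclass(frozen=True)
class ResidueScale:
    """A per-residue score table over the 20 standard amino acids."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name}: missing residues {sorted(missing)}")


SCALES = {
    "kyte_doolittle": ResidueScale("kyte_doolittle", KYTE_DOOLITTLE),
    "levitt": ResidueScale("levitt", LEVITT_HELICITY),
}


def sliding_window_score(sequence: str, scale: ResidueScale,
                         window: int = 7, edge_weight: float = 0.1) -> np.ndarray:
    """ProtScale-style weighted sliding-window average of a residue scale.

    The centre residue carries weight 1.0, decreasing linearly to
    ``edge_weight`` at the outermost window position (window 7 with
    edge weight 0.1 gives 0.1, 0.4, 0.7, 1.0, 0.7, 0.4, 0.1).  At the
    termini the window is truncated and the weights renormalized over
    the residues actually present.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if not 0 < edge_weight <= 1:
        raise ValueError("edge_weight must lie in (0, 1]")
    half = window // 2
    vals = np.empty(len(sequence))
    for i, letter in enumerate(sequence):
        if letter not in scale.values:
            raise ValueError(f"position {i + 1}: unknown residue {letter!r}")
        vals[i] = scale.values[letter]
    offsets = np.arange(-half, half + 1)
    if half > 0:
        weights = 1.0 - (1.0 - edge_weight) * np.abs(offsets) / half
    else:
        weights = np.ones(1)
    scores = np.empty(len(sequence))
    for i in range(len(sequence)):
        idx = i + offsets
        ok = (idx >= 0) & (idx < len(sequence))
        w = weights[ok]
        scores[i] = float(np.dot(w, vals[idx[ok]]) / w.sum())
    return scores


def assign_secondary_structure(structure: ProteinStructure) -> dict[str, str]:
    """Map each residue label ``chain:resnum`` to helix / sheet / coil.

    HELIX annotations take precedence over SHEET on conflict; residues
    without any annotation are coil.
    """
    ss: dict[str, str] = {}
    for chain_id, resnum, _name in structure.residues():
        label = f"{chain_id}:{resnum}"
        cls = "coil"
        for lo, hi in structure.sheet_ranges.get(chain_id, []):
            if lo <= resnum <= hi:
                cls = "sheet"
        for lo, hi in structure.helix_ranges.get(chain_id, []):
            if lo <= resnum <= hi:
                cls = "helix"
        ss[label] = cls
    return ss


def load_site_descriptors(sites: list[AmineSite], table: str) -> list[str]:
    """Merge ingested pKa / Coulombic-charge values onto sites.

    ``table`` is delimited text (comma or tab) with a header row and
    columns ``site_id``, ``pka`` and optionally ``charge``.  Values are
    written in place onto matching sites; the list of table site_ids
    that matched no site is returned so callers can warn.  Duplicate
    site_ids in the table raise.
    """
    df = pd.read_csv(io.StringIO(table), sep=None, engine="python")
    if df.empty:
        return []
    df.columns = [c.strip().lower() for c in df.columns]
    if "site_id" not in df.columns or "pka" not in df.columns:
        raise ValueError("descriptor table needs columns site_id, pka[, charge]")
    if df["site_id"].duplicated().any():
        dupes = sorted(df.loc[df["site_id"].duplicated(), "site_id"].unique())
        raise ValueError(f"duplicate site_id rows in descriptor table: {dupes}")
    by_id = {s.site_id: s for s in sites}
    unmatched: list[str] = []
    for row in df.itertuples(index=False):
        site = by_id.get(str(row.site_id))
        if site is None:
            unmatched.append(str(row.site_id))
            continue
        if not pd.isna(row.pka):
            site.pka = float(row.pka)
        if "charge" in df.columns and not pd.isna(row.charge):
            site.charge = float(row.charge)
    return unmatched


def annotate_sites(sites: list[AmineSite], structure: ProteinStructure,
                   probe: ProbeSpec, n_sphere_points: int = 960,
                   window: int = 7, edge_weight: float = 0.1) -> list[AmineSite]:
    """Fill computable descriptors (ESA, ss_class, hydrophobicity, helicity).

    pKa and charge remain file inputs (:func:`load_site_descriptors`).
    """
    esa = shrake_rupley_esa(structure, probe, n_sphere_points)
    ss = assign_secondary_structure(structure)
    hydro: dict[str, np.ndarray] = {}
    helic: dict[str, np.ndarray] = {}
    chain_residues: dict[str, list[int]] = {}
    for chain_id, resnum, _name in structure.residues():
        chain_residues.setdefault(chain_id, []).append(resnum)
    for chain_id, seq in structure.sequences.items():
        clean = seq.replace("X", "A")  # nonstandard residues: neutral stand-in
        hydro[chain_id] = sliding_window_score(clean, SCALES["kyte_doolittle"],
                                               window, edge_weight)
        helic[chain_id] = sliding_window_score(clean, SCALES["levitt"],
                                               window, edge_weight)
    for s in sites:
        label = f"{s.chain_id}:{s.residue_number}"
        s.esa = esa.get(label, 0.0)
        s.ss_class = ss.get(label, "coil")
        resnums = chain_residues.get(s.chain_id, [])
        if s.residue_number in resnums:
            pos = resnums.index(s.residue_number)
            s.hydrophobicity = float(hydro[s.chain_id][pos])
            s.helicity = float(helic[s.chain_id][pos])
    return sites
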