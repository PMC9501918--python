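"""Protein structure input and amine-site geometry.

Reads PDB coordinate files into a light internal model, enumerates the
amine-reactive sites (lysine ε-amines, denoted NZ in PDB files, and the
α-amine at each chain's N-terminus), and computes the inter-residue
Euclidean distances and contact maps on which the PEG-shielding metric
is built.  Lysine–lysine distances are NZ–NZ; lysine-to-other-residue
distances are NZ-to-CA.

Parsing is delegated to :mod:`gemmi`; this module resolves alternate
locations (highest occupancy, then file order), drops HETATM records,
and keeps only the first model of multi-model (NMR) files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_mw

__all__ = [
    "Atom",
    "ProteinStructure",
    "AmineSite",
    "ContactMap",
    "PdbParseError",
    "SiteLookupError",
    "parse_pdb",
    "amine_sites",
    "site_distance",
    "min_lysine_spacing",
    "contact_map",
]


class PdbParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


class SiteLookupError(KeyError):
    """Raised when a site reference cannot be resolved to an atom."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom from an ATOM record (author numbering)."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray  # (3,) Å
    element: str = ""
    insertion_code: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.atom_name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")


# 3-letter -> 1-letter for the 20 standard residues
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class ProteinStructure:
    """Parsed coordinates plus secondary-structure annotations.

    ``helix_ranges`` / ``sheet_ranges`` map chain id to a list of
    inclusive ``(first, last)`` author residue-number intervals taken
    from HELIX / SHEET records.
    """

    atoms: list[Atom]
    chains: list[str]
    sequences: dict[str, str]
    helix_ranges: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    sheet_ranges: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def molecular_weight(self) -> float:
        """Total protein mass in Da, computed from the chain sequences."""
        mw = 0.0
        for seq in self.sequences.values():
            clean = "".join(c for c in seq if c != "X")
            if clean:
                mw += _bio_mw(clean, seq_type="protein")
        if mw <= 0:
            raise ValueError("no standard residues: molecular weight undefined")
        return mw

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_number, residue_name)."""
        seen: dict[tuple[str, int, str], str] = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.insertion_code)
            if key not in seen:
                seen[key] = a.residue_name
        return [(c, n, name) for (c, n, _i), name in seen.items()]

    def find_atom(self, chain_id: str, residue_number: int, atom_name: str) -> Atom:
        for a in self.atoms:
            if (a.chain_id == chain_id and a.residue_number == residue_number
                    and a.atom_name == atom_name):
                return a
        raise SiteLookupError(
            f"atom {atom_name} of residue {residue_number} in chain {chain_id} not found")


@dataclass
class AmineSite:
    """One amine-reactive site and its molecular descriptors.

    Descriptors are ``None`` until computed or ingested; an operation
    that requires a missing one raises, naming the descriptor.
    ``charge`` is the Coulombic charge at the ε-amino group in
    kcal·e⁻¹·mol⁻¹; ``esa`` the probe-exposed surface area in Å².
    """

    site_id: str
    kind: str  # "lysine" | "n_terminus"
    chain_id: str
    residue_number: int
    nitrogen_coords: np.ndarray
    esa: float | None = None
    pka: float | None = None
    charge: float | None = None
    hydrophobicity: float | None = None
    helicity: float | None = None
    ss_class: str | None = None  # "helix" | "sheet" | "coil"

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise ValueError(f"site {self.site_id}: descriptor '{name}' is missing")


def _validate_coordinate_fields(pdb_text: str) -> None:
    """Fail early, naming the offending line, on malformed coordinates."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PdbParseError(
                        f"line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                    ) from None


def parse_pdb(pdb_text: str) -> ProteinStructure:
    """Parse PDB text into a :class:`ProteinStructure`.

    Only ATOM records are kept (HETATM ignored); for multi-model files
    only MODEL 1 is used; alternate locations are resolved by highest
    occupancy, then file order.  HELIX and SHEET records become
    per-chain residue-number intervals.
    """
    if not any(line.startswith("ATOM") for line in pdb_text.splitlines()):
        raise PdbParseError("no ATOM records in input")
    _validate_coordinate_fields(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi message passthrough
        raise PdbParseError(str(exc)) from exc
    if len(st) == 0:
        raise PdbParseError("no models in input")
    model = st[0]  # NMR ensembles: single conformer convention

    atoms: list[Atom] = []
    chains: list[str] = []
    sequences: dict[str, str] = {}
    for chain in model:
        chain_atoms: list[Atom] = []
        seq_parts: list[str] = []
        for res in chain:
            if res.het_flag != "A":  # HETATM
                continue
            seq_parts.append(_THREE_TO_ONE.get(res.name, "X"))
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in res:  # preserve file order among the winners
                if best.get(at.name) is not at:
                    continue
                chain_atoms.append(Atom(
                    atom_name=at.name,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain_id=chain.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    element=at.element.name,
                    insertion_code=(res.seqid.icode or "").strip(),
                ))
        if chain_atoms:
            chains.append(chain.name)
            sequences[chain.name] = "".join(seq_parts)
            atoms.extend(chain_atoms)
    if not atoms:
        raise PdbParseError("no polymer ATOM records after filtering")

    helix_ranges: dict[str, list[tuple[int, int]]] = {}
    for h in st.helices:
        helix_ranges.setdefault(h.start.chain_name, []).append(
            (h.start.res_id.seqid.num, h.end.res_id.seqid.num))
    sheet_ranges: dict[str, list[tuple[int, int]]] = {}
    for sheet in st.sheets:
        for strand in sheet.strands:
            sheet_ranges.setdefault(strand.start.chain_name, []).append(
                (strand.start.res_id.seqid.num, strand.end.res_id.seqid.num))
    return ProteinStructure(atoms=atoms, chains=chains, sequences=sequences,
                            helix_ranges=helix_ranges, sheet_ranges=sheet_ranges)


def amine_sites(structure: ProteinStructure,
                include_n_terminus: bool = True) -> list[AmineSite]:
    """Enumerate amine-reactive sites.

    One site per lysine possessing an NZ atom (lysines whose side chain
    is unresolved in the crystal structure are skipped with a warning),
    plus, if requested, one α-amine site per chain at the backbone N of
    the first resolved residue.
    """
    sites: list[AmineSite] = []
    if include_n_terminus:
        for chain in structure.chains:
            backbone_n = [a for a in structure.atoms
                          if a.chain_id == chain and a.atom_name == "N"]
            first = min(backbone_n, key=lambda a: a.residue_number, default=None)
            if first is not None:
                sites.append(AmineSite(
                    site_id=f"{chain}:Nterm", kind="n_terminus", chain_id=chain,
                    residue_number=first.residue_number,
                    nitrogen_coords=first.coords.copy()))
    lys_seen: set[tuple[str, int, str]] = set()
    for a in structure.atoms:
        if a.residue_name != "LYS":
            continue
        key = (a.chain_id, a.residue_number, a.insertion_code)
        if key in lys_seen:
            continue
        lys_seen.add(key)
        try:
            nz = structure.find_atom(a.chain_id, a.residue_number, "NZ")
        except SiteLookupError:
            warnings.warn(
                f"lysine {a.chain_id}:{a.residue_number} has no NZ atom "
                "(unresolved side chain); skipped", stacklevel=2)
            continue
        sites.append(AmineSite(
            site_id=f"{a.chain_id}:K{a.residue_number}", kind="lysine",
            chain_id=a.chain_id, residue_number=a.residue_number,
            nitrogen_coords=nz.coords.copy()))
    return sites


def _resolve_site_atoms(structure: ProteinStructure, ref: str) -> list[np.ndarray]:
    """Resolve a site reference to candidate atom coordinates.

    Accepted forms: ``"A:K33"`` / ``"K33"`` (lysine NZ), ``"A:Nterm"``,
    ``"A:45"`` / ``"45"`` (any residue's CA).  A chain-less reference on
    a multimer matches every chain carrying that residue.
    """
    chain = None
    token = ref
    if ":" in ref:
        chain, token = ref.split(":", 1)
    coords: list[np.ndarray] = []
    if token.lower() in ("nterm", "n-term"):
        for s in amine_sites(structure, include_n_terminus=True):
            if s.kind == "n_terminus" and (chain is None or s.chain_id == chain):
                coords.append(s.nitrogen_coords)
        if not coords:
            raise SiteLookupError(f"site {ref!r}: no N-terminus found")
        return coords
    if token.upper().startswith("K") and token[1:].isdigit():
        resnum, atom_name, resname = int(token[1:]), "NZ", "LYS"
    elif token.isdigit() or (token[0] == "-" and token[1:].isdigit()):
        resnum, atom_name, resname = int(token), "CA", None
    else:
        raise SiteLookupError(f"unrecognized site reference {ref!r}")
    for a in structure.atoms:
        if a.residue_number != resnum or a.atom_name != atom_name:
            continue
        if resname is not None and a.residue_name != resname:
            continue
        if chain is not None and a.chain_id != chain:
            continue
        coords.append(a.coords)
    if not coords:
        raise SiteLookupError(f"site {ref!r}: atom {atom_name} of residue {resnum} not found")
    return coords


def site_distance(structure: ProteinStructure, site_a: str, site_b: str) -> float:
    """Euclidean distance (Å) between two site references.

    Lysine references resolve to the ε-amine NZ, other residues to CA.
    When a residue number occurs in several chains the minimum over all
    chain pairings is returned — the conservative choice for shielding.
    """
    ca = _resolve_site_atoms(structure, site_a)
    cb = _resolve_site_atoms(structure, site_b)
    return float(min(np.linalg.norm(a - b) for a in ca for b in cb))


def min_lysine_spacing(structure: ProteinStructure) -> float:
    """Smallest NZ–NZ Euclidean distance over all lysine pairs (Å)."""
    nz = np.array([s.nitrogen_coords for s in amine_sites(structure, include_n_terminus=False)])
    if len(nz) < 2:
        raise ValueError("min_lysine_spacing requires at least 2 lysine sites")
    diff = nz[:, None, :] - nz[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(len(nz), k=1)
    return float(d[iu].min())


@dataclass
class ContactMap:
    """Max-normalized lysine-to-all-residue distance matrix.

    Rows are lysine ε-amines (NZ), columns all residues (CA); entries
    are Euclidean distances divided by the matrix maximum so they lie
    in [0, 1], then classed into thirds (near / mid / far).
    """

    normalized: np.ndarray  # (n_lys, n_res) in [0, 1]
    row_labels: list[str]
    col_labels: list[str]

    def bins(self) -> np.ndarray:
        """3-bin classification: 0 for [0, 1/3), 1 for [1/3, 2/3), 2 above."""
        return np.minimum((self.normalized * 3).astype(int), 2)

    def to_text(self, sep: str = ",") -> str:
        lines = [sep.join(["site"] + self.col_labels)]
        for lab, row in zip(self.row_labels, self.normalized):
            lines.append(sep.join([lab] + [f"{v:.6f}" for v in row]))
        return "\n".join(lines) + "\n"


def contact_map(structure: ProteinStructure) -> ContactMap:
    """Contact map of every lysine NZ against every residue CA."""
    lys = amine_sites(structure, include_n_terminus=False)
    if not lys:
        raise ValueError("contact_map requires at least one lysine site")
    cols: list[tuple[str, np.ndarray]] = []
    for chain_id, resnum, _name in structure.residues():
        try:
            ca = structure.find_atom(chain_id, resnum, "CA")
        except SiteLookupError:
            continue
        cols.append((f"{chain_id}:{resnum}", ca.coords))
    nz = np.array([s.nitrogen_coords for s in lys])
    ca_xyz = np.array([c for _l, c in cols])
    d = np.sqrt(((nz[:, None, :] - ca_xyz[None, :, :]) ** 2).sum(-1))
    dmax = d.max()
    if dmax == 0:
        raise ValueError("degenerate structure: all distances zero")
    return ContactMap(normalized=d / dmax,
                      row_labels=[s.site_id for s in lys],
                      col_labels=[lab for lab, _c in cols])
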