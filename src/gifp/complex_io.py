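"""Reading GPCR-ligand complexes from PDB files.

Isolates one receptor chain and one small-molecule ligand per file, and
attaches Ballesteros-Weinstein generic-position annotations supplied as a
GPCRdb-style TSV table (numbering is input data here, never computed).

Conventions:

* coordinates in Angstrom, author numbering preserved verbatim;
* hydrogens are dropped on read (donor/acceptor roles downstream come from
  heavy-atom templates, so protonation-free files work);
* altlocs resolved by highest occupancy (biotite default), tie -> first;
* ligand bonds come from CONECT records when present, otherwise from a
  covalent-radius distance rule (cutoff = r_i + r_j + 0.45 A).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .bw import BWPosition, parse_bw

__all__ = [
    "Atom",
    "Residue",
    "Ligand",
    "LigandReceptorComplex",
    "read_complex",
    "load_bw_map",
    "annotate",
    "write_pdb",
    "complex_to_json",
    "complex_from_json",
    "ComplexError",
]

ACTIVATION_STATES = ("active", "inactive", "intermediate", "unknown")
FUNCTION_LABELS = ("agonist", "antagonist", "inverse_agonist", "inactive", "unlabeled")

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# single-element covalent radii (A) for bond inference on CONECT-less ligands
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "B": 0.84, "SE": 1.20,
    "ZN": 1.22, "FE": 1.32, "MG": 1.41, "NA": 1.66, "K": 2.03, "CA": 1.76,
    "MN": 1.39, "CU": 1.32, "NI": 1.24, "CO": 1.26,
}
_BOND_TOLERANCE = 0.45


class ComplexError(ValueError):
    """Raised on unreadable or ambiguous complex structures."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    formal_charge: int = 0

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class Residue:
    chain_id: str
    author_number: int
    insertion_code: str
    amino_acid: str
    atoms: list[Atom]
    bw_position: BWPosition | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.author_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class Ligand:
    ligand_id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)

    def graph(self) -> nx.Graph:
        """Bond graph over heavy atoms; nodes carry element/charge, edges order."""
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element, charge=a.formal_charge)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    @property
    def aromatic_rings(self) -> list[frozenset[int]]:
        """5/6-membered planar rings of C/N/O/S atoms in the bond graph."""
        rings: list[frozenset[int]] = []
        g = self.graph()
        for cycle in nx.cycle_basis(g):
            if len(cycle) not in (5, 6):
                continue
            if any(self.atoms[i].element not in ("C", "N", "O", "S") for i in cycle):
                continue
            coords = np.array([self.atoms[i].xyz for i in cycle])
            centered = coords - coords.mean(axis=0)
            # smallest singular value ~ max out-of-plane deviation
            if np.linalg.svd(centered, compute_uv=False)[-1] > 0.4:
                continue
            rings.append(frozenset(cycle))
        return rings

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class LigandReceptorComplex:
    complex_id: str
    receptor_id: str
    residues: list[Residue]
    ligand: Ligand
    is_modeled: int = 0
    activation_state: str = "unknown"
    function_label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.is_modeled not in (0, 1):
            raise ValueError("is_modeled must be 0 or 1")
        if self.activation_state not in ACTIVATION_STATES:
            raise ValueError(f"unknown activation state: {self.activation_state!r}")
        if self.function_label not in FUNCTION_LABELS:
            raise ValueError(f"unknown function label: {self.function_label!r}")
        if not self.ligand.atoms:
            raise ValueError("ligand must have at least one heavy atom")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue (chain, number, icode) keys")

    def annotated_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.bw_position is not None]

    def bw_positions(self) -> set[BWPosition]:
        return {r.bw_position for r in self.annotated_residues()}

    def residue_by_bw(self, pos: BWPosition) -> Residue | None:
        for r in self.residues:
            if r.bw_position == pos:
                return r
        return None


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _infer_bonds(atoms: list[Atom]) -> list[tuple[int, int, int]]:
    coords = np.array([a.xyz for a in atoms], dtype=float)
    radii = np.array(
        [_COVALENT_RADII.get(a.element.upper(), 0.77) for a in atoms]
    )
    bonds = []
    n = len(atoms)
    for i in range(n):
        for j in range(i + 1, n):
            cutoff = radii[i] + radii[j] + _BOND_TOLERANCE
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                bonds.append((i, j, 1))
    return bonds


def _parse_conect(pdb_path: Path) -> dict[int, list[int]]:
    table: dict[int, list[int]] = {}
    with open(pdb_path) as fh:
        for line in fh:
            if not line.startswith("CONECT"):
                continue
            fields = [line[6:11]] + [line[11 + 5 * k: 16 + 5 * k] for k in range(4)]
            serials = [int(f) for f in fields if f.strip()]
            if len(serials) >= 2:
                table.setdefault(serials[0], []).extend(serials[1:])
    return table


def read_complex(
    pdb_path: str | Path,
    ligand_selector: str = "auto",
    receptor_chain: str = "auto",
    complex_id: str | None = None,
    receptor_id: str = "",
    is_modeled: int = 0,
    activation_state: str = "unknown",
    function_label: str = "unlabeled",
) -> LigandReceptorComplex:
    """Read a PDB file and isolate one receptor chain plus one ligand.

    ``receptor_chain="auto"`` keeps the longest polymer chain.
    ``ligand_selector="auto"`` keeps the non-water, non-ion heteroatom group
    with the most heavy atoms lying within 10 A of the receptor; a residue
    name selects explicitly (ambiguity is an error listing candidates).
    Waters, ions and any other entities are discarded.
    """
    pdb_path = Path(pdb_path)
    try:
        pdb = PDBFile.read(str(pdb_path))
        arr = pdb.get_structure(
            model=1, altloc="occupancy", extra_fields=["charge", "atom_id"]
        )
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise ComplexError(f"cannot parse PDB file {pdb_path}: {exc}") from exc

    arr = arr[arr.element != "H"]
    if arr.array_length() == 0:
        raise ComplexError("no heavy atoms in file")

    is_aa = struc.filter_amino_acids(arr)
    polymer = arr[is_aa]
    if polymer.array_length() == 0:
        raise ComplexError("no polymer chain found")

    # receptor chain selection
    chain_sizes: dict[str, int] = {}
    for cid in np.unique(polymer.chain_id):
        sub = polymer[polymer.chain_id == cid]
        chain_sizes[str(cid)] = len(struc.get_residue_starts(sub))
    if receptor_chain == "auto":
        chain = max(sorted(chain_sizes), key=lambda c: chain_sizes[c])
    else:
        if receptor_chain not in chain_sizes:
            raise ComplexError(
                f"chain {receptor_chain!r} not found; have {sorted(chain_sizes)}"
            )
        chain = receptor_chain
    rec = polymer[polymer.chain_id == chain]

    residues: list[Residue] = []
    for start in struc.get_residue_starts(rec):
        mask = (
            (rec.res_id == rec.res_id[start])
            & (rec.chain_id == rec.chain_id[start])
            & (rec.ins_code == rec.ins_code[start])
        )
        sub = rec[mask]
        atoms = [
            Atom(
                name=str(sub.atom_name[k]),
                element=str(sub.element[k]),
                xyz=tuple(float(x) for x in sub.coord[k]),
                formal_charge=int(sub.charge[k]),
            )
            for k in range(sub.array_length())
        ]
        residues.append(
            Residue(
                chain_id=str(sub.chain_id[0]),
                author_number=int(sub.res_id[0]),
                insertion_code=str(sub.ins_code[0]).strip(),
                amino_acid=str(sub.res_name[0]),
                atoms=atoms,
            )
        )
    # duplicate residue ids within the chain (no icode distinction) collapse
    seen: dict[tuple, Residue] = {}
    for r in residues:
        seen.setdefault(r.key, r)
    residues = list(seen.values())

    # ligand candidates: heteroatom groups, non-water, >1 heavy atom (ions out)
    het = arr[~is_aa]
    groups: list[tuple[str, "np.ndarray"]] = []
    if het.array_length() > 0:
        for start in struc.get_residue_starts(het):
            mask = (
                (het.res_id == het.res_id[start])
                & (het.chain_id == het.chain_id[start])
                & (het.res_name == het.res_name[start])
            )
            sub = het[mask]
            name = str(sub.res_name[0]).strip()
            if name in _WATER_NAMES or sub.array_length() < 2:
                continue
            groups.append((name, sub))
    if not groups:
        raise ComplexError("no heteroatom group (ligand candidate) found")

    rec_coords = np.concatenate([r.coords() for r in residues])
    if ligand_selector == "auto":
        def near_count(sub) -> int:
            d = np.linalg.norm(
                sub.coord[:, None, :] - rec_coords[None, :, :], axis=-1
            )
            return int(np.sum(d.min(axis=1) <= 10.0))

        counted = [(near_count(sub), name, sub) for name, sub in groups]
        counted = [c for c in counted if c[0] > 0]
        if not counted:
            raise ComplexError("no heteroatom group within 10 A of the receptor")
        counted.sort(key=lambda c: -c[0])
        lig_name, lig_sub = counted[0][1], counted[0][2]
    else:
        matches = [(name, sub) for name, sub in groups if name == ligand_selector]
        if not matches:
            raise ComplexError(
                f"ligand {ligand_selector!r} not found; candidates: "
                f"{sorted({n for n, _ in groups})}"
            )
        if len(matches) > 1:
            raise ComplexError(
                f"ligand selector {ligand_selector!r} matches {len(matches)} groups"
            )
        lig_name, lig_sub = matches[0]

    lig_atoms = [
        Atom(
            name=str(lig_sub.atom_name[k]),
            element=str(lig_sub.element[k]),
            xyz=tuple(float(x) for x in lig_sub.coord[k]),
            formal_charge=int(lig_sub.charge[k]),
        )
        for k in range(lig_sub.array_length())
    ]
    serial_to_index = {
        int(lig_sub.atom_id[k]): k for k in range(lig_sub.array_length())
    }
    conect = _parse_conect(pdb_path)
    bond_counts: dict[tuple[int, int], int] = {}
    for serial, partners in conect.items():
        if serial not in serial_to_index:
            continue
        i = serial_to_index[serial]
        for p in partners:
            if p in serial_to_index:
                j = serial_to_index[p]
                if i < j:
                    bond_counts[(i, j)] = bond_counts.get((i, j), 0) + 1
    if bond_counts:
        bonds = [(i, j, order) for (i, j), order in sorted(bond_counts.items())]
    else:
        bonds = _infer_bonds(lig_atoms)

    ligand = Ligand(ligand_id=lig_name, atoms=lig_atoms, bonds=bonds)
    return LigandReceptorComplex(
        complex_id=complex_id or pdb_path.stem,
        receptor_id=receptor_id or pdb_path.stem,
        residues=residues,
        ligand=ligand,
        is_modeled=is_modeled,
        activation_state=activation_state,
        function_label=function_label,
    )


# ---------------------------------------------------------------------------
# BW annotation
# ---------------------------------------------------------------------------

def load_bw_map(annotation_path: str | Path) -> dict[tuple[str, int, str], BWPosition]:
    """Load a 4-column TSV (chain, author_number, insertion_code, bw_position).

    ``.`` denotes an empty insertion code and ``-`` an unmapped (loop or
    terminal) residue, which is simply left out of the mapping.
    """
    df = pd.read_csv(
        annotation_path,
        sep="\t",
        dtype=str,
        comment="#",
        names=["chain", "author_number", "insertion_code", "bw_position"],
        header=None,
        skip_blank_lines=True,
    )
    # tolerate a header row
    if df.iloc[0]["chain"].lower() == "chain":
        df = df.iloc[1:]
    mapping: dict[tuple[str, int, str], BWPosition] = {}
    seen_bw: dict[BWPosition, tuple] = {}
    for _, row in df.iterrows():
        raw = str(row["bw_position"]).strip()
        if raw == "-":
            continue
        icode = str(row["insertion_code"]).strip()
        icode = "" if icode == "." else icode
        key = (str(row["chain"]).strip(), int(row["author_number"]), icode)
        pos = parse_bw(raw)
        if pos in seen_bw:
            raise ValueError(
                f"duplicate BW position {pos} claimed by {seen_bw[pos]} and {key}"
            )
        seen_bw[pos] = key
        mapping[key] = pos
    return mapping


def annotate(
    cplx: LigandReceptorComplex,
    bw_map: Mapping[tuple[str, int, str], BWPosition],
) -> LigandReceptorComplex:
    """Return a copy with ``bw_position`` set on every mapped residue.

    Residues without a mapping stay in the complex but are non-indexed (they
    never emit contacts or profile entries). Map keys that reference absent
    residues produce a warning only. Idempotent.
    """
    by_key = {r.key: r for r in cplx.residues}
    for key in bw_map:
        if key not in by_key:
            warnings.warn(f"BW map references absent residue {key}", stacklevel=2)
    new_residues = [
        replace(r, bw_position=bw_map.get(r.key, None)) for r in cplx.residues
    ]
    assigned = [r.bw_position for r in new_residues if r.bw_position is not None]
    if len(set(assigned)) != len(assigned):
        raise ValueError("BW positions are not unique within the complex")
    return replace(cplx, residues=new_residues)


# ---------------------------------------------------------------------------
# PDB writing (round-trip support, synthetic fixtures)
# ---------------------------------------------------------------------------

def _pdb_line(
    record: str, serial: int, name: str, res_name: str, chain: str,
    res_id: int, icode: str, xyz, element: str, charge: int,
) -> str:
    atom_name = name if len(name) >= 4 else f" {name:<3s}"
    charge_str = ""
    if charge:
        charge_str = f"{abs(charge)}{'+' if charge > 0 else '-'}"
    return (
        f"{record:<6s}{serial:>5d} {atom_name:<4s} {res_name:>3s} {chain:1s}"
        f"{res_id:>4d}{icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}{charge_str:<2s}"
    )


def write_pdb(cplx: LigandReceptorComplex, path: str | Path | None = None) -> str:
    """Serialize the complex back to PDB text (ATOM/HETATM/TER/CONECT/END)."""
    lines: list[str] = []
    serial = 0
    for res in cplx.residues:
        for atom in res.atoms:
            serial += 1
            lines.append(
                _pdb_line(
                    "ATOM", serial, atom.name, res.amino_acid, res.chain_id,
                    res.author_number, res.insertion_code, atom.xyz,
                    atom.element, atom.formal_charge,
                )
            )
    lines.append(f"TER   {serial + 1:>5d}")
    lig_serials: list[int] = []
    for atom in cplx.ligand.atoms:
        serial += 1
        lig_serials.append(serial)
        lines.append(
            _pdb_line(
                "HETATM", serial, atom.name, cplx.ligand.ligand_id[:3] or "LIG",
                "L", 1, "", atom.xyz, atom.element, atom.formal_charge,
            )
        )
    partners: dict[int, list[int]] = {}
    for i, j, order in cplx.ligand.bonds:
        for _ in range(max(1, order)):
            partners.setdefault(lig_serials[i], []).append(lig_serials[j])
            partners.setdefault(lig_serials[j], []).append(lig_serials[i])
    for s in sorted(partners):
        plist = partners[s]
        for k in range(0, len(plist), 4):
            chunk = plist[k: k + 4]
            lines.append(
                "CONECT" + f"{s:>5d}" + "".join(f"{p:>5d}" for p in chunk)
            )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# JSON round-trip for CLI hand-off between subcommands
# ---------------------------------------------------------------------------

def complex_to_json(cplx: LigandReceptorComplex) -> str:
    payload = {
        "complex_id": cplx.complex_id,
        "receptor_id": cplx.receptor_id,
        "is_modeled": cplx.is_modeled,
        "activation_state": cplx.activation_state,
        "function_label": cplx.function_label,
        "residues": [
            {
                "chain_id": r.chain_id,
                "author_number": r.author_number,
                "insertion_code": r.insertion_code,
                "amino_acid": r.amino_acid,
                "bw_position": str(r.bw_position) if r.bw_position else None,
                "atoms": [
                    [a.name, a.element, list(a.xyz), a.formal_charge]
                    for a in r.atoms
                ],
            }
            for r in cplx.residues
        ],
        "ligand": {
            "ligand_id": cplx.ligand.ligand_id,
            "atoms": [
                [a.name, a.element, list(a.xyz), a.formal_charge]
                for a in cplx.ligand.atoms
            ],
            "bonds": [list(b) for b in cplx.ligand.bonds],
        },
    }
    return json.dumps(payload, indent=1)


def complex_from_json(text: str) -> LigandReceptorComplex:
    payload = json.loads(text)

    def to_atoms(rows: Iterable) -> list[Atom]:
        return [
            Atom(name=n, element=e, xyz=tuple(xyz), formal_charge=c)
            for n, e, xyz, c in rows
        ]

    residues = [
        Residue(
            chain_id=r["chain_id"],
            author_number=r["author_number"],
            insertion_code=r["insertion_code"],
            amino_acid=r["amino_acid"],
            atoms=to_atoms(r["atoms"]),
            bw_position=parse_bw(r["bw_position"]) if r["bw_position"] else None,
        )
        for r in payload["residues"]
    ]
    ligand = Ligand(
        ligand_id=payload["ligand"]["ligand_id"],
        atoms=to_atoms(payload["ligand"]["atoms"]),
        bonds=[tuple(b) for b in payload["ligand"]["bonds"]],
    )
    return LigandReceptorComplex(
        complex_id=payload["complex_id"],
        receptor_id=payload["receptor_id"],
        residues=residues,
        ligand=ligand,
        is_modeled=payload["is_modeled"],
        activation_state=payload["activation_state"],
        function_label=payload["function_label"],
    )
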