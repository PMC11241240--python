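"""Ligand-residue contact detection, typing, scoring, surrogate energies.

The distance-based interaction score is 1 at <= 3.23 A, 0 at >= 4.63 A and
linear in between, so a 0.5 cutoff is equivalent to a 3.93 A distance cap.

Typing is geometric and template-driven (standard PLIF-style criteria, no
explicit hydrogens), with priority
Covalent > Metal > Ionic > Hbond > Arene > Distance:

* Covalent: heavy-atom distance <= 1.9 A
* Metal:    ligand metal atom <= 2.8 A from residue O/N/S
* Ionic:    opposite formal charges <= 4.5 A
* Hbond:    donor-acceptor heavy-atom pair <= 3.5 A
* Arene:    ring-centroid pair <= 5.5 A or centroid-cation <= 5.0 A,
            reported once at the closest heavy-atom pair of the two groups
* Distance: any remaining heavy-atom pair <= 4.63 A (van der Waals)

Per-contact energies are a documented surrogate, ``-w(type) * score``; all
downstream logic uses only their ordering and sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bw import BWPosition
from .complex_io import LigandReceptorComplex, Residue

__all__ = [
    "Contact",
    "INTERACTION_TYPES",
    "DEFAULT_WELL_DEPTHS",
    "SCORE_ONE_DISTANCE",
    "SCORE_ZERO_DISTANCE",
    "interaction_score",
    "detect_contacts",
    "surrogate_energy",
    "filter_by_score",
    "type_priority",
]

SCORE_ONE_DISTANCE = 3.23
SCORE_ZERO_DISTANCE = 4.63

# priority order: earlier wins when one atom pair satisfies several rules
INTERACTION_TYPES = ("Covalent", "Metal", "Ionic", "Hbond", "Arene", "Distance")

DEFAULT_WELL_DEPTHS = {
    "Covalent": 10.0,
    "Ionic": 5.0,
    "Metal": 5.0,
    "Hbond": 3.0,
    "Arene": 2.0,
    "Distance": 0.5,
}

COVALENT_CUTOFF = 1.9
METAL_CUTOFF = 2.8
IONIC_CUTOFF = 4.5
HBOND_CUTOFF = 3.5
ARENE_RING_RING_CUTOFF = 5.5
ARENE_RING_CATION_CUTOFF = 5.0

_METAL_ELEMENTS = {
    "ZN", "FE", "MG", "MN", "CU", "NI", "CO", "CA", "NA", "K", "LI", "CD", "HG",
}

# heavy-atom hydrogen-bond roles of standard residues (sidechain + backbone)
_RES_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"},
}
_RES_ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "HIS": {"ND1", "NE2"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "MET": {"SD"},
}
_BACKBONE_DONORS = {"N"}
_BACKBONE_ACCEPTORS = {"O", "OXT"}

_RES_ANION_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
_RES_CATION_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}

_RES_RING_ATOMS = {
    "PHE": [{"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}],
    "TYR": [{"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}],
    "HIS": [{"CG", "ND1", "CD2", "CE1", "NE2"}],
    "TRP": [
        {"CG", "CD1", "CD2", "NE1", "CE2"},
        {"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    ],
}


@dataclass(frozen=True)
class Contact:
    """One typed ligand-residue heavy-atom interaction."""

    bw_position: BWPosition
    residue_atom: str
    ligand_atom: str
    interaction_type: str
    distance: float
    score: float
    energy: float

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")
        if not self.distance > 0:
            raise ValueError("contact distance must be positive")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("contact score must lie in [0, 1]")
        if self.energy > 0:
            raise ValueError("contact energy must be <= 0")


def type_priority(interaction_type: str) -> int:
    return INTERACTION_TYPES.index(interaction_type)


def interaction_score(distance: float) -> float:
    """Distance-based interaction score, linear between 3.23 and 4.63 A."""
    if not (isinstance(distance, (int, float)) and math.isfinite(distance)):
        raise ValueError(f"non-finite distance: {distance!r}")
    if distance <= 0:
        raise ValueError(f"non-positive distance: {distance!r}")
    if distance <= SCORE_ONE_DISTANCE:
        return 1.0
    if distance >= SCORE_ZERO_DISTANCE:
        return 0.0
    return (SCORE_ZERO_DISTANCE - distance) / (SCORE_ZERO_DISTANCE - SCORE_ONE_DISTANCE)


def surrogate_energy(
    contact_type: str,
    score: float,
    well_depths: dict[str, float] | None = None,
) -> float:
    """Surrogate contact energy ``-w(type) * score`` (kcal/mol scale, <= 0)."""
    depths = DEFAULT_WELL_DEPTHS if well_depths is None else well_depths
    if contact_type not in depths:
        raise ValueError(f"unknown interaction type {contact_type!r}")
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must lie in [0, 1]")
    return -depths[contact_type] * score


def filter_by_score(contacts: list[Contact], cutoff: float) -> list[Contact]:
    """Keep contacts with score >= cutoff (cutoff 0.5 <=> distance <= 3.93 A)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    return [c for c in contacts if c.score >= cutoff]


# ---------------------------------------------------------------------------
# ligand atom roles
# ---------------------------------------------------------------------------

def _ligand_roles(cplx: LigandReceptorComplex):
    lig = cplx.ligand
    g = lig.graph()
    donors, acceptors, cations, anions, metals = set(), set(), set(), set(), set()
    for i, a in enumerate(lig.atoms):
        heavy_deg = g.degree(i)
        if a.element.upper() in _METAL_ELEMENTS:
            metals.add(i)
            cations.add(i)
            continue
        if a.formal_charge > 0:
            cations.add(i)
        elif a.formal_charge < 0:
            anions.add(i)
        if a.element == "O":
            acceptors.add(i)
            if heavy_deg <= 1:  # hydroxyl-like in a protonation-free file
                donors.add(i)
        elif a.element == "N":
            if a.formal_charge <= 0:
                acceptors.add(i)
            if heavy_deg <= 2 or a.formal_charge > 0:
                donors.add(i)
        elif a.element == "S":
            acceptors.add(i)
    return donors, acceptors, cations, anions, metals


def _residue_roles(res: Residue):
    donors = set(_BACKBONE_DONORS) | _RES_DONORS.get(res.amino_acid, set())
    acceptors = set(_BACKBONE_ACCEPTORS) | _RES_ACCEPTORS.get(res.amino_acid, set())
    anions = _RES_ANION_ATOMS.get(res.amino_acid, set())
    cations = _RES_CATION_ATOMS.get(res.amino_acid, set())
    present = {a.name for a in res.atoms}
    return donors & present, acceptors & present, cations & present, anions & present


def _residue_rings(res: Residue) -> list[list[int]]:
    rings = []
    for names in _RES_RING_ATOMS.get(res.amino_acid, []):
        idx = [k for k, a in enumerate(res.atoms) if a.name in names]
        if len(idx) == len(names):
            rings.append(idx)
    return rings


def detect_contacts(
    cplx: LigandReceptorComplex,
    well_depths: dict[str, float] | None = None,
) -> list[Contact]:
    """Detect and type every ligand contact of the BW-annotated residues.

    Each residue-atom/ligand-atom heavy-atom pair within 4.63 A produces at
    most one :class:`Contact`, assigned the highest-priority type whose
    geometric rule it satisfies. A ring-ring or ring-cation (arene) group
    interaction is reported once, at the group pair's closest heavy-atom
    pair; the remaining atom pairs between those two groups are consumed.
    """
    annotated = cplx.annotated_residues()
    if not annotated:
        raise ValueError("complex has no BW-annotated residues; run annotate() first")

    lig = cplx.ligand
    lig_coords = lig.coords()
    ldon, lacc, lcat, lani, lmet = _ligand_roles(cplx)
    lig_rings = [sorted(r) for r in lig.aromatic_rings]

    contacts: list[Contact] = []
    for res in annotated:
        res_coords = res.coords()
        dmat = np.linalg.norm(
            res_coords[:, None, :] - lig_coords[None, :, :], axis=-1
        )
        pairs = np.argwhere(dmat <= SCORE_ZERO_DISTANCE)
        if pairs.size == 0:
            continue
        rdon, racc, rcat, rani = _residue_roles(res)
        res_rings = _residue_rings(res)

        # arene group pass: mark one winning pair per group pair, consume rest
        arene_winner: dict[tuple[int, int], None] = {}
        consumed: set[tuple[int, int]] = set()

        def group_pairs(res_idx: list[int], lig_idx: list[int]):
            sub = dmat[np.ix_(res_idx, lig_idx)]
            best = np.unravel_index(np.argmin(sub), sub.shape)
            best_pair = (res_idx[best[0]], lig_idx[best[1]])
            all_pairs = {(ri, li) for ri in res_idx for li in lig_idx}
            return best_pair, all_pairs

        arene_groups: list[tuple[list[int], list[int]]] = []
        for rring in res_rings:
            rcent = res_coords[rring].mean(axis=0)
            for lring in lig_rings:
                lcent = lig_coords[lring].mean(axis=0)
                if np.linalg.norm(rcent - lcent) <= ARENE_RING_RING_CUTOFF:
                    arene_groups.append((rring, lring))
            for li in lcat:
                if np.linalg.norm(rcent - lig_coords[li]) <= ARENE_RING_CATION_CUTOFF:
                    arene_groups.append((rring, [li]))
        cation_idx = [k for k, a in enumerate(res.atoms) if a.name in rcat]
        if cation_idx:
            for lring in lig_rings:
                lcent = lig_coords[lring].mean(axis=0)
                dist = np.linalg.norm(
                    res_coords[cation_idx] - lcent[None, :], axis=1
                )
                if dist.min() <= ARENE_RING_CATION_CUTOFF:
                    arene_groups.append((cation_idx, lring))

        for res_idx, lig_idx in arene_groups:
            best_pair, all_pairs = group_pairs(res_idx, lig_idx)
            if dmat[best_pair[0], best_pair[1]] <= SCORE_ZERO_DISTANCE:
                arene_winner.setdefault(best_pair, None)
            consumed |= all_pairs

        for ri, li in map(tuple, pairs):
            d = float(dmat[ri, li])
            ratom, latom = res.atoms[ri], lig.atoms[li]
            ctype = None
            if d <= COVALENT_CUTOFF:
                ctype = "Covalent"
            elif (
                li in lmet
                and ratom.element in ("O", "N", "S")
                and d <= METAL_CUTOFF
            ):
                ctype = "Metal"
            elif d <= IONIC_CUTOFF and (
                (ratom.name in rani and li in lcat and li not in lmet)
                or (ratom.name in rcat and li in lani)
            ):
                ctype = "Ionic"
            elif d <= HBOND_CUTOFF and (
                (ratom.name in rdon and li in lacc)
                or (ratom.name in racc and li in ldon)
            ):
                ctype = "Hbond"
            elif (ri, li) in arene_winner:
                ctype = "Arene"
            elif (ri, li) in consumed:
                continue  # non-winning pair of an arene group interaction
            else:
                ctype = "Distance"
            score = interaction_score(d)
            contacts.append(
                Contact(
                    bw_position=res.bw_position,
                    residue_atom=ratom.name,
                    ligand_atom=latom.name,
                    interaction_type=ctype,
                    distance=d,
                    score=score,
                    energy=surrogate_energy(ctype, score, well_depths),
                )
            )
    return contacts
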