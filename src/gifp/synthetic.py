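"""Synthetic fixtures: toy 3D complexes, labeled profile tables, pose sets.

Everything downstream consumes only coordinates and annotations, so toy
receptors are idealized single helices (3.6 residues/turn, 1.5 A rise) with
generic positions assigned arithmetically. Planted contacts are realized by
giving the chosen residue a sidechain "tip" atom pointing radially outward
and placing the matching ligand group exactly the requested distance beyond
it; the rest of the ligand (linker stalks and an outer rail that keeps the
heavy-atom bond graph connected) stays outside the 4.63 A contact ceiling
of every residue atom, so contact detection recovers exactly what was
planted. Builders self-check this closed loop and raise on unsatisfiable
plantings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bw import BWPosition
from .complex_io import (
    Atom,
    Ligand,
    LigandReceptorComplex,
    Residue,
    write_pdb,
)
from .features import FeatureTable, InteractionProfile, PositionFeatures
from .interactions import detect_contacts
from .pose_eval import PoseSet

__all__ = [
    "PlantingError",
    "SyntheticSpec",
    "make_toy_complex",
    "make_profile_dataset",
    "make_pose_fixture",
    "PLANTABLE_TYPES",
    "planted_distance_range",
]

RISE_PER_RESIDUE = 1.5
TURN_DEGREES = 100.0
TIP_RADIUS = 7.5
RAIL_RADIUS = 14.0
RING_RADIUS = 1.39
CONTACT_SPACING = 6  # residues between planted contacts (9 A rise)

# residue type, tip atom name, tip element, ligand element, ligand charge
_PLANT_RECIPES = {
    "Hbond": ("SER", "OG", "O", "O", 0),
    "Ionic": ("ASP", "OD1", "O", "N", 1),
    "Metal": ("SER", "OG", "O", "ZN", 2),
    "Covalent": ("CYS", "SG", "S", "C", 0),
    "Distance": ("ALA", "CB", "C", "C", 0),
    "Arene": ("PHE", None, None, None, 0),
}
PLANTABLE_TYPES = tuple(_PLANT_RECIPES)

# distance windows in which each planted type is geometrically recoverable
_DISTANCE_RANGES = {
    "Covalent": (1.0, 1.9),
    "Metal": (1.9, 2.8),
    "Hbond": (1.9, 3.5),
    "Ionic": (1.9, 4.5),
    "Arene": (1.9, 4.63),
    "Distance": (1.9, 4.63),
}

_PHE_RING = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


class PlantingError(ValueError):
    """A planted contact set cannot be realized geometrically."""


def planted_distance_range(contact_type: str) -> tuple[float, float]:
    """Open/closed (lo, hi] distance window recoverable for this type."""
    return _DISTANCE_RANGES[contact_type]


def _cyl(radius: float, theta: float, z: float) -> tuple[float, float, float]:
    return (radius * math.cos(theta), radius * math.sin(theta), z)


def _backbone(theta: float, z: float) -> list[Atom]:
    return [
        Atom("N", "N", _cyl(1.6, theta - 0.45, z - 0.9)),
        Atom("CA", "C", _cyl(2.3, theta, z)),
        Atom("C", "C", _cyl(2.0, theta + 0.40, z + 0.6)),
        Atom("O", "O", _cyl(2.9, theta + 0.40, z + 1.2)),
    ]


def _filler_positions(n: int, taken: set[BWPosition]) -> list[BWPosition]:
    pool = []
    for segment in range(1, 8):
        for offset in range(20, 80):
            pos = BWPosition(segment, offset)
            if pos not in taken:
                pool.append(pos)
    if len(pool) < n:
        raise PlantingError("not enough filler BW positions")
    return pool[:n]


def make_toy_complex(
    planted_contacts: list[tuple[BWPosition, str, float]],
    seed: int = 0,
    complex_id: str = "toy",
    receptor_id: str = "TOYR",
    validate: bool = True,
    **complex_kwargs,
) -> tuple[str, str, LigandReceptorComplex]:
    """Build an idealized helix + ligand realizing the planted contacts.

    Returns ``(pdb_text, bw_annotation_tsv, annotated_complex)``. When
    ``validate`` is on, contact detection is run on the built complex and a
    :class:`PlantingError` is raised unless it recovers exactly the planted
    (position, type, distance) set.
    """
    planted = list(planted_contacts)
    positions = [p for p, _, _ in planted]
    if len(set(positions)) != len(positions):
        raise PlantingError("each planted contact needs its own BW position")
    for pos, ctype, d in planted:
        if ctype not in _PLANT_RECIPES:
            raise PlantingError(f"cannot plant contacts of type {ctype!r}")
        if not 1.0 < d < 6.0:
            raise PlantingError(f"planted distance {d} outside (1.0, 6.0) A")
        lo, hi = _DISTANCE_RANGES[ctype]
        if not lo < d <= hi:
            raise PlantingError(
                f"{ctype} contact at {d} A not recoverable (needs ({lo}, {hi}])"
            )

    n_res = max(20, CONTACT_SPACING * len(planted) + CONTACT_SPACING)
    contact_res_idx = [3 + CONTACT_SPACING * k for k in range(len(planted))]

    lig_atoms: list[Atom] = []
    lig_bonds: list[tuple[int, int, int]] = []
    counters: dict[str, int] = {}

    def add_atom(element: str, xyz, charge: int = 0) -> int:
        counters[element] = counters.get(element, 0) + 1
        lig_atoms.append(
            Atom(
                name=f"{element}{counters[element]}",
                element=element,
                xyz=tuple(float(v) for v in xyz),
                formal_charge=charge,
            )
        )
        return len(lig_atoms) - 1

    residues: list[Residue] = []
    planted_by_res = dict(zip(contact_res_idx, planted))
    stalk_tops: list[tuple[int, float, float]] = []  # (atom idx, theta, z)

    for i in range(n_res):
        theta = math.radians(TURN_DEGREES * i)
        z = RISE_PER_RESIDUE * i
        atoms = _backbone(theta, z)
        res_name = "GLY"
        if i in planted_by_res:
            pos, ctype, d = planted_by_res[i]
            recipe = _PLANT_RECIPES[ctype]
            res_name = recipe[0]
            u = np.array([math.cos(theta), math.sin(theta), 0.0])
            v1 = np.array([0.0, 0.0, 1.0])
            v2 = np.cross(u, v1)
            tip_center = np.array(_cyl(TIP_RADIUS, theta, z))
            if ctype == "Arene":
                for k, name in enumerate(_PHE_RING):
                    ang = math.radians(60.0 * k)
                    xyz = tip_center + RING_RADIUS * (
                        math.cos(ang) * v1 + math.sin(ang) * v2
                    )
                    atoms.append(Atom(name, "C", tuple(xyz)))
                ring_center = tip_center + d * u
                ring_idx = []
                for k in range(6):
                    ang = math.radians(60.0 * k)
                    xyz = ring_center + RING_RADIUS * (
                        math.cos(ang) * v1 + math.sin(ang) * v2
                    )
                    ring_idx.append(add_atom("C", xyz))
                for k in range(6):
                    lig_bonds.append((ring_idx[k], ring_idx[(k + 1) % 6], 1))
                anchor = ring_center
                attach_idx = ring_idx[0]
            else:
                _, tip_name, tip_el, lig_el, lig_charge = recipe
                atoms.append(Atom(tip_name, tip_el, tuple(tip_center)))
                anchor = tip_center + d * u
                attach_idx = add_atom(lig_el, anchor, charge=lig_charge)
            # linker stalk: first step long enough to clear the 4.63 A ceiling
            first = max(1.5, 4.8 - d)
            radius = float(np.linalg.norm(anchor[:2])) + first
            prev = attach_idx
            while True:
                radius = min(radius, RAIL_RADIUS)
                idx = add_atom("C", _cyl(radius, theta, z))
                lig_bonds.append((prev, idx, 1))
                prev = idx
                if radius >= RAIL_RADIUS:
                    break
                radius += 1.5
            stalk_tops.append((prev, theta, z))
        residues.append(
            Residue(
                chain_id="A",
                author_number=i + 1,
                insertion_code="",
                amino_acid=res_name,
                atoms=atoms,
            )
        )

    # rail along the helix surface joining consecutive stalk tops
    for (ia, ta, za), (ib, tb, zb) in zip(stalk_tops, stalk_tops[1:]):
        # shortest way around the helix surface
        dtheta = math.remainder(tb - ta, 2 * math.pi)
        tb = ta + dtheta
        arc = math.hypot(RAIL_RADIUS * (tb - ta), zb - za)
        steps = max(1, math.ceil(arc / 1.4))
        prev = ia
        for s in range(1, steps + 1):
            f = s / steps
            theta = ta + f * (tb - ta)
            z = za + f * (zb - za)
            if s == steps:
                idx = ib
            else:
                idx = add_atom("C", _cyl(RAIL_RADIUS, theta, z))
            lig_bonds.append((prev, idx, 1))
            prev = idx

    if not lig_atoms:  # plant nothing -> a 2-atom spectator near the helix
        z_mid = RISE_PER_RESIDUE * n_res / 2
        i0 = add_atom("C", _cyl(10.0, 0.0, z_mid))
        i1 = add_atom("C", _cyl(11.4, 0.0, z_mid))
        lig_bonds.append((i0, i1, 1))

    ligand = Ligand(ligand_id="LIG", atoms=lig_atoms, bonds=lig_bonds)

    taken = set(positions)
    fillers = _filler_positions(n_res - len(planted), taken)
    bw_assign: dict[int, BWPosition] = {}
    fi = 0
    for i in range(n_res):
        if i in planted_by_res:
            bw_assign[i] = planted_by_res[i][0]
        else:
            bw_assign[i] = fillers[fi]
            fi += 1
    for i, res in enumerate(residues):
        res.bw_position = bw_assign[i]

    cplx = LigandReceptorComplex(
        complex_id=complex_id,
        receptor_id=receptor_id,
        residues=residues,
        ligand=ligand,
        **complex_kwargs,
    )

    if validate:
        detected = {
            (c.bw_position, c.interaction_type, round(c.distance, 3))
            for c in detect_contacts(cplx)
        }
        wanted = {(p, t, round(d, 3)) for p, t, d in planted}
        if detected != wanted:
            raise PlantingError(
                f"planting unsatisfiable: wanted {sorted(map(str, wanted))}, "
                f"detected {sorted(map(str, detected))}"
            )

    pdb_text = write_pdb(cplx)
    tsv_lines = ["chain\tauthor_number\tinsertion_code\tbw_position"]
    for res in residues:
        tsv_lines.append(
            f"{res.chain_id}\t{res.author_number}\t.\t{res.bw_position}"
        )
    return pdb_text, "\n".join(tsv_lines) + "\n", cplx


# ---------------------------------------------------------------------------
# labeled profile tables with planted class signal
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for a labeled interaction-profile dataset."""

    n_receptors: int
    complexes_per_receptor: int
    positions: list[BWPosition]
    class_signatures: dict[str, list[tuple[BWPosition, str, float]]]
    noise_sd: float = 0.5
    contact_prob_background: float = 0.1
    na_fraction: float = 0.1
    modeled_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for p in (self.contact_prob_background, self.na_fraction,
                  self.modeled_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.class_signatures) < 2:
            raise ValueError("need signatures for at least 2 classes")
        declared = set(self.positions)
        for label, sig in self.class_signatures.items():
            for pos, _, _ in sig:
                if pos not in declared:
                    raise ValueError(
                        f"signature for {label!r} references undeclared position {pos}"
                    )


def make_profile_dataset(spec: SyntheticSpec) -> FeatureTable:
    """Sample a labeled feature table with class-conditional planted signal.

    Signature positions get energies ~ Normal(mean, sd) truncated below 0
    with the signature type; other present positions get background Distance
    contacts with the configured probability; a per-receptor fraction of
    positions is absent (NA) to exercise the NA semantics. Deterministic
    given the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = sorted(spec.class_signatures)
    n_pos = len(spec.positions)

    # signature positions are never absent: the class-conditional signal must
    # not be silently erased by the NA mechanism
    signature_positions = {
        pos for sig in spec.class_signatures.values() for pos, _, _ in sig
    }
    receptor_absent: list[set[BWPosition]] = []
    for _ in range(spec.n_receptors):
        mask = rng.random(n_pos) < spec.na_fraction
        receptor_absent.append(
            {
                p
                for p, absent in zip(spec.positions, mask)
                if absent and p not in signature_positions
            }
        )

    rows: list[InteractionProfile] = []
    k = 0
    for r in range(spec.n_receptors):
        absent = receptor_absent[r]
        for _ in range(spec.complexes_per_receptor):
            label = labels[rng.integers(len(labels))]
            signature = {
                pos: (ctype, mean)
                for pos, ctype, mean in spec.class_signatures[label]
            }
            features: dict[BWPosition, PositionFeatures] = {}
            for pos in spec.positions:
                if pos in absent:
                    features[pos] = PositionFeatures.absent()
                    continue
                if pos in signature:
                    ctype, mean = signature[pos]
                    e = min(
                        float(rng.normal(mean, spec.noise_sd)), -1e-6
                    )
                    features[pos] = PositionFeatures(e, ctype, e, "None", 0.0)
                elif rng.random() < spec.contact_prob_background:
                    e = -float(rng.uniform(0.05, 0.5))
                    features[pos] = PositionFeatures(e, "Distance", e, "None", 0.0)
                else:
                    features[pos] = PositionFeatures.empty()
            rows.append(
                InteractionProfile(
                    complex_id=f"synth_{k:05d}",
                    features=features,
                    is_modeled=int(rng.random() < spec.modeled_fraction),
                    function_label=label,
                )
            )
            k += 1
    return FeatureTable(rows=rows, retained_positions=sorted(spec.positions))


# ---------------------------------------------------------------------------
# pose fixtures at known RMSD
# ---------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(degrees)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    return np.array(
        [
            [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
            [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
            [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
        ]
    )


def make_pose_fixture(
    reference: LigandReceptorComplex,
    perturbations: list[tuple[float, float]],
    seed: int = 0,
    n_top: int = 5,
) -> PoseSet:
    """Pose set from (rotation degrees, translation A) perturbations.

    Rotation is about the ligand centroid around a seeded random axis; the
    translation direction is also seeded. A pure translation by t gives a
    ligand RMSD of exactly t. Pose order follows the perturbation list and
    scores are the list index (best first).
    """
    if not perturbations:
        raise ValueError("perturbation list must be non-empty")
    rng = np.random.default_rng(seed)
    ref_coords = reference.ligand.coords()
    centroid = ref_coords.mean(axis=0)
    poses = []
    for k, (rot_deg, trans) in enumerate(perturbations):
        coords = ref_coords.copy()
        if rot_deg:
            rot = _rotation_matrix(rng.normal(size=3), rot_deg)
            coords = (coords - centroid) @ rot.T + centroid
        if trans:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords = coords + trans * direction
        poses.append((coords, float(k)))
    return PoseSet(reference=reference, poses=poses, n_top=n_top)
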