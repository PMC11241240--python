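"""Docked-pose quality evaluation.

Alpha-carbon least-squares (Kabsch) superposition of the docked complex
onto the reference, followed by symmetry-aware ligand heavy-atom RMSD: the
minimum over element- and bond-order-preserving automorphisms of the ligand
bond graph, so chemically equivalent atoms (e.g. the two ortho/meta carbon
pairs of a para-disubstituted phenyl) never inflate the deviation.

RMSD bands follow the successful (<2 A) / acceptable (2-3 A, boundaries
closed) / unsuccessful (>3 A) convention; sampling quality looks at the
best pose anywhere in the ensemble, scoring quality at the best pose among
the top-ranked few.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import islice

import networkx as nx
import numpy as np
import pandas as pd

from .complex_io import Ligand, LigandReceptorComplex

__all__ = [
    "PoseSet",
    "RMSDReport",
    "RigidTransform",
    "superpose_ca",
    "ligand_rmsd",
    "categorize",
    "evaluate_pose_set",
    "summarize",
    "AUTOMORPHISM_CAP",
    "CATEGORIES",
]

AUTOMORPHISM_CAP = 10_000
CATEGORIES = ("successful", "acceptable", "unsuccessful")


@dataclass
class PoseSet:
    """A reference complex plus score-sorted ligand poses (best first)."""

    reference: LigandReceptorComplex
    poses: list[tuple[np.ndarray, float]]
    n_top: int = 5

    def __post_init__(self) -> None:
        n_ref = len(self.reference.ligand.atoms)
        for coords, _ in self.poses:
            if np.asarray(coords).shape != (n_ref, 3):
                raise ValueError("every pose must carry the full ligand atom set")
        scores = [s for _, s in self.poses]
        if any(b < a for a, b in zip(scores, scores[1:])) and any(
            b > a for a, b in zip(scores, scores[1:])
        ):
            warnings.warn("pose scores are not monotone; order taken as given")


@dataclass
class RMSDReport:
    rmsds: list[float]
    n_top: int
    best_in_top_n: float = field(init=False)
    best_in_all: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.rmsds:
            raise ValueError("empty pose set")
        self.best_in_all = float(min(self.rmsds))
        self.best_in_top_n = float(min(self.rmsds[: self.n_top]))

    @property
    def sampling_category(self) -> str:
        return categorize(self.best_in_all)

    @property
    def scoring_category(self) -> str:
        return categorize(self.best_in_top_n)


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rot, translation=rc - rot @ mc)


def superpose_ca(
    mobile: LigandReceptorComplex, reference: LigandReceptorComplex
) -> tuple[RigidTransform, dict]:
    """Least-squares CA superposition of the mobile chain onto the reference.

    Residues are matched by BW position when both complexes are annotated,
    otherwise by (chain, author number, insertion code). Returns the rigid
    transform (to apply to the mobile ligand) and an alignment report with
    the matched-residue count and CA RMSD.
    """
    def ca_map(cplx: LigandReceptorComplex, by_bw: bool):
        out = {}
        for r in cplx.residues:
            ca = r.atom("CA")
            if ca is None:
                continue
            key = r.bw_position if by_bw else r.key
            if key is not None:
                out[key] = ca.coord
        return out

    by_bw = bool(mobile.annotated_residues()) and bool(reference.annotated_residues())
    m_map = ca_map(mobile, by_bw)
    r_map = ca_map(reference, by_bw)
    shared = sorted(set(m_map) & set(r_map), key=str)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared residues; need at least 3")
    m = np.array([m_map[k] for k in shared])
    r = np.array([r_map[k] for k in shared])
    tf = _kabsch(m, r)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(m) - r) ** 2, axis=1))))
    report = {"n_matched": len(shared), "ca_rmsd": rmsd, "matched_by_bw": by_bw}
    return tf, report


def _automorphisms(ligand: Ligand, cap: int = AUTOMORPHISM_CAP):
    g = ligand.graph()
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g,
        g,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a.get("order", 1) == b.get("order", 1),
    )
    mappings = list(islice(matcher.isomorphisms_iter(), cap + 1))
    if len(mappings) > cap:
        warnings.warn(
            f"more than {cap} bond-graph automorphisms; "
            "falling back to the identity mapping",
            stacklevel=2,
        )
        return [{i: i for i in range(len(ligand.atoms))}]
    return mappings


def ligand_rmsd(
    pose_coords: np.ndarray,
    reference_coords: np.ndarray,
    ligand: Ligand,
    cap: int = AUTOMORPHISM_CAP,
) -> float:
    """Symmetry-aware heavy-atom RMSD in the already-superposed frame.

    No re-fitting is performed on the ligand atoms; the value is the minimum
    plain RMSD over all bond-graph automorphisms of the ligand.
    """
    pose = np.asarray(pose_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    n = len(ligand.atoms)
    if pose.shape != (n, 3) or ref.shape != (n, 3):
        raise ValueError("coordinate arrays must match the ligand atom count")
    best = np.inf
    for mapping in _automorphisms(ligand, cap=cap):
        perm = np.array([mapping[i] for i in range(n)])
        rmsd = float(np.sqrt(np.mean(np.sum((pose[perm] - ref) ** 2, axis=1))))
        best = min(best, rmsd)
    return best


def categorize(rmsd: float) -> str:
    """successful (<2), acceptable ([2, 3], boundaries closed), unsuccessful (>3)."""
    if rmsd < 0:
        raise ValueError("RMSD cannot be negative")
    if rmsd < 2.0:
        return "successful"
    if rmsd <= 3.0:
        return "acceptable"
    return "unsuccessful"


def evaluate_pose_set(pose_set: PoseSet, cap: int = AUTOMORPHISM_CAP) -> RMSDReport:
    ref_coords = pose_set.reference.ligand.coords()
    rmsds = [
        ligand_rmsd(coords, ref_coords, pose_set.reference.ligand, cap=cap)
        for coords, _ in pose_set.poses
    ]
    return RMSDReport(rmsds=rmsds, n_top=pose_set.n_top)


def summarize(reports: list[RMSDReport]) -> pd.DataFrame:
    """Sampling/scoring success percentages per RMSD band.

    Rows ``sampling`` and ``scoring``; columns the three bands plus the
    combined ``successful+acceptable`` (<= 3 A) bucket.
    """
    if not reports:
        raise ValueError("at least one pose set required")
    n = len(reports)

    def pct(values: list[str], cat: str) -> float:
        return 100.0 * sum(v == cat for v in values) / n

    rows = {}
    for kind, cats in (
        ("sampling", [r.sampling_category for r in reports]),
        ("scoring", [r.scoring_category for r in reports]),
    ):
        rows[kind] = {
            "successful": pct(cats, "successful"),
            "acceptable": pct(cats, "acceptable"),
            "successful+acceptable": pct(cats, "successful") + pct(cats, "acceptable"),
            "unsuccessful": pct(cats, "unsuccessful"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
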