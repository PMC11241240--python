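import math
from dataclasses import replace

import numpy as np
import pytest

from gifp.bw import BWPosition
from gifp.complex_io import Atom, Ligand
from gifp.pose_eval import (
    PoseSet,
    categorize,
    evaluate_pose_set,
    ligand_rmsd,
    summarize,
    superpose_ca,
)
from gifp.synthetic import make_pose_fixture, make_toy_complex


@pytest.fixture(scope="module")
def reference():
    _, _, cplx = make_toy_complex(
        [(BWPosition(3, 32), "Hbond", 2.9), (BWPosition(6, 55), "Distance", 4.2)],
        seed=2,
    )
    return cplx


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _shift_complex(cplx, delta):
    def move(atom):
        return Atom(atom.name, atom.element, tuple(np.asarray(atom.xyz) + delta),
                    atom.formal_charge)

    return replace(
        cplx,
        residues=[replace(r, atoms=[move(a) for a in r.atoms]) for r in cplx.residues],
        ligand=Ligand(
            cplx.ligand.ligand_id,
            [move(a) for a in cplx.ligand.atoms],
            cplx.ligand.bonds,
        ),
    )


def test_identity_superposition(reference):
    tf, report = superpose_ca(reference, reference)
    assert report["ca_rmsd"] == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(tf.translation, 0.0, atol=1e-9)


def test_translation_recovered(reference):
    moved = _shift_complex(reference, np.array([5.0, 0.0, 0.0]))
    tf, report = superpose_ca(moved, reference)
    assert report["ca_rmsd"] == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(tf.translation, [-5.0, 0.0, 0.0], atol=1e-9)


def _horn_quaternion_rmsd(mobile, reference):
    """Independent superposition oracle (Horn's quaternion method)."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    m = mc.T @ rc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (mc ** 2).sum() + (rc ** 2).sum()
    return math.sqrt(max(0.0, e0 - 2 * lam) / len(mobile))


def test_kabsch_matches_quaternion_oracle(reference):
    rng = np.random.default_rng(9)
    ca = np.array(
        [r.atom("CA").coord for r in reference.residues[:10]]
    )
    noisy = ca + rng.normal(scale=1.0, size=ca.shape)
    # wrap the noisy coordinates into a minimal complex for superpose_ca
    mobile = replace(
        reference,
        residues=[
            replace(r, atoms=[Atom("CA", "C", tuple(noisy[i]))])
            for i, r in enumerate(reference.residues[:10])
        ],
    )
    ref10 = replace(reference, residues=reference.residues[:10])
    _, report = superpose_ca(mobile, ref10)
    oracle = _horn_quaternion_rmsd(noisy, ca)
    assert report["ca_rmsd"] == pytest.approx(oracle, abs=1e-6)


def test_too_few_matches(reference):
    mobile = replace(reference, residues=reference.residues[:2])
    with pytest.raises(ValueError, match="shared residues"):
        superpose_ca(mobile, reference)


# ---------------------------------------------------------------------------
# symmetry-aware RMSD
# ---------------------------------------------------------------------------

def _benzene(substituted=False):
    atoms = []
    bonds = []
    for k in range(6):
        ang = math.radians(60 * k)
        atoms.append(Atom(f"C{k+1}", "C", (1.39 * math.cos(ang), 1.39 * math.sin(ang), 0.0)))
        bonds.append((k, (k + 1) % 6, 1))
    if substituted:
        # para substituents at C1 (+x) and C4 (-x)
        atoms.append(Atom("O1", "O", (2.8, 0.0, 0.0)))
        atoms.append(Atom("O2", "O", (-2.8, 0.0, 0.0)))
        bonds += [(6, 0, 1), (7, 3, 1)]
    return Ligand("BNZ", atoms, bonds)


def test_identical_coordinates_zero(reference):
    coords = reference.ligand.coords()
    assert ligand_rmsd(coords, coords, reference.ligand) == 0.0


def test_single_atom_displacement():
    lig = Ligand("ONE", [Atom("C1", "C", (0.0, 0.0, 0.0))], [])
    assert ligand_rmsd(
        np.array([[2.0, 0.0, 0.0]]), np.array([[0.0, 0.0, 0.0]]), lig
    ) == pytest.approx(2.0)


def test_para_flip_is_symmetric():
    lig = _benzene(substituted=True)
    coords = lig.coords()
    # 180 degree flip about the C1-C4 (x) axis: (x, y, z) -> (x, -y, -z)
    flipped = coords * np.array([1.0, -1.0, -1.0])
    identity_rmsd = math.sqrt(np.mean(np.sum((flipped - coords) ** 2, axis=1)))
    assert identity_rmsd > 1.0
    assert ligand_rmsd(flipped, coords, lig) == pytest.approx(0.0, abs=1e-12)


def test_symmetry_never_exceeds_identity():
    rng = np.random.default_rng(3)
    lig = _benzene(substituted=True)
    coords = lig.coords()
    for _ in range(20):
        perturbed = coords + rng.normal(scale=1.0, size=coords.shape)
        identity_rmsd = math.sqrt(np.mean(np.sum((perturbed - coords) ** 2, axis=1)))
        assert ligand_rmsd(perturbed, coords, lig) <= identity_rmsd + 1e-12


def test_atom_count_mismatch():
    lig = _benzene()
    with pytest.raises(ValueError, match="atom count"):
        ligand_rmsd(np.zeros((3, 3)), lig.coords(), lig)


def test_automorphism_cap_falls_back():
    lig = _benzene()
    coords = lig.coords()
    with pytest.warns(UserWarning, match="automorphisms"):
        val = ligand_rmsd(coords, coords, lig, cap=2)
    assert val == 0.0


def test_rigid_motion_invariance_of_rmsd(reference):
    rng = np.random.default_rng(4)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=7.0, size=3)
    lig = _benzene(substituted=True)
    ref = lig.coords()
    pose = ref + rng.normal(scale=0.7, size=ref.shape)
    before = ligand_rmsd(pose, ref, lig)
    after = ligand_rmsd(pose @ q.T + t, ref @ q.T + t, lig)
    assert after == pytest.approx(before, abs=1e-9)


# ---------------------------------------------------------------------------
# categories and summaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rmsd,category",
    [
        (1.5, "successful"),
        (2.5, "acceptable"),
        (3.5, "unsuccessful"),
        (2.0, "acceptable"),
        (3.0, "acceptable"),
        (0.0, "successful"),
    ],
)
def test_categorize(rmsd, category):
    assert categorize(rmsd) == category


def test_categorize_negative():
    with pytest.raises(ValueError):
        categorize(-0.1)


def test_pose_fixture_translation_rmsd(reference):
    pose_set = make_pose_fixture(reference, [(0.0, 0.0), (0.0, 2.0)], seed=6)
    report = evaluate_pose_set(pose_set)
    assert report.rmsds[0] == pytest.approx(0.0, abs=1e-9)
    assert report.rmsds[1] == pytest.approx(2.0, abs=1e-9)


def test_summarize_counts(reference):
    # 2 of 4 fixtures with best pose < 2 A -> sampling successful 50%
    reports = []
    for t in (0.5, 1.0, 2.5, 4.0):
        ps = make_pose_fixture(reference, [(0.0, t)], seed=1)
        reports.append(evaluate_pose_set(ps))
    table = summarize(reports)
    assert table.loc["sampling", "successful"] == pytest.approx(50.0)
    assert table.loc["sampling", "acceptable"] == pytest.approx(25.0)
    assert table.loc["sampling", "successful+acceptable"] == pytest.approx(75.0)
    assert table.loc["sampling", "unsuccessful"] == pytest.approx(25.0)


def test_all_identical_poses_fully_successful(reference):
    ps = make_pose_fixture(reference, [(0.0, 0.0)] * 5, seed=0)
    table = summarize([evaluate_pose_set(ps)])
    assert table.loc["sampling", "successful"] == 100.0
    assert table.loc["scoring", "successful"] == 100.0


def test_scoring_never_beats_sampling(reference):
    rng = np.random.default_rng(12)
    reports = []
    for _ in range(10):
        perturbations = [(float(rng.uniform(0, 30)), float(rng.uniform(0, 5))) for _ in range(8)]
        ps = make_pose_fixture(reference, perturbations, seed=int(rng.integers(1000)))
        ps.n_top = 3
        reports.append(evaluate_pose_set(ps))
    table = summarize(reports)
    assert table.loc["scoring", "successful"] <= table.loc["sampling", "successful"]
    for r in reports:
        assert r.best_in_all <= r.best_in_top_n


def test_best_in_all_le_best_in_top(reference):
    ps = make_pose_fixture(reference, [(0.0, 3.0), (0.0, 1.0)], seed=2)
    report = evaluate_pose_set(ps)
    assert report.best_in_all <= report.best_in_top_n
    ps.n_top = 1
    report = evaluate_pose_set(ps)
    assert report.best_in_top_n == pytest.approx(3.0, abs=1e-9)
    assert report.best_in_all == pytest.approx(1.0, abs=1e-9)


def test_summarize_empty():
    with pytest.raises(ValueError):
        summarize([])
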