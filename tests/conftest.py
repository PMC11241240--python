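import pytest

from gifp.bw import BWPosition
from gifp.synthetic import SyntheticSpec, make_profile_dataset, make_toy_complex


@pytest.fixture(scope="session")
def toy_planted():
    return [
        (BWPosition(3, 32), "Hbond", 2.9),
        (BWPosition(6, 55), "Ionic", 3.8),
        (BWPosition(5, 46), "Arene", 3.6),
        (BWPosition(2, 53), "Metal", 2.2),
        (BWPosition(7, 39), "Covalent", 1.6),
        (BWPosition(4, 50), "Distance", 4.2),
    ]


@pytest.fixture(scope="session")
def toy_complex(toy_planted):
    """One annotated toy complex exercising every interaction type."""
    _, _, cplx = make_toy_complex(toy_planted, seed=1)
    return cplx


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory, toy_planted):
    """The same toy complex written to disk (PDB + BW annotation TSV)."""
    pdb_text, tsv_text, _ = make_toy_complex(toy_planted, seed=1)
    d = tmp_path_factory.mktemp("toy")
    pdb = d / "toy.pdb"
    tsv = d / "toy_bw.tsv"
    pdb.write_text(pdb_text)
    tsv.write_text(tsv_text)
    return pdb, tsv


def strong_signal_spec(seed: int = 0, n_receptors: int = 30,
                       complexes_per_receptor: int = 20) -> SyntheticSpec:
    """Four well-separated classes: planted energies >> noise."""
    positions = [BWPosition(s, o) for s in range(1, 8) for o in (40, 45, 50, 55)]
    sig = {
        "agonist": [(BWPosition(3, 40), "Hbond", -9.0)],
        "antagonist": [(BWPosition(5, 45), "Ionic", -9.0)],
        "inverse_agonist": [(BWPosition(6, 50), "Arene", -9.0)],
        "inactive": [(BWPosition(7, 55), "Distance", -9.0)],
    }
    return SyntheticSpec(
        n_receptors=n_receptors,
        complexes_per_receptor=complexes_per_receptor,
        positions=positions,
        class_signatures=sig,
        noise_sd=0.5,
        contact_prob_background=0.05,
        na_fraction=0.1,
        seed=seed,
    )


@pytest.fixture(scope="session")
def strong_dataset():
    return make_profile_dataset(strong_signal_spec(seed=11))
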