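"""Shared fixtures: parsed/charged fixture molecules, embedded subsets, and
random regression problems for the statistics oracle checks."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from gaqsar.molecule_io import Molecule, embed_conformer
from gaqsar.synthetic import fixture_molecules, make_planted_bench


@pytest.fixture(scope="session")
def fixture_mols():
    """All fixture molecules, perceived and Gasteiger-charged, keyed by name."""
    return {m.id: m for m in fixture_molecules()}


@pytest.fixture(scope="session")
def embedded_mols(fixture_mols):
    """Fixture molecules with a seeded 3D conformer (surface tests)."""
    return {
        name: embed_conformer(mol, seed=42)
        for name, mol in fixture_mols.items()
    }


@pytest.fixture(scope="session")
def small_bench():
    """A small planted bench for quick model-search tests."""
    return make_planted_bench(n=60, p=12, subset_size=3, noise_sd=0.3, seed=5)


@pytest.fixture(scope="session")
def study_bench():
    """The study-scale planted bench: n=157, 50 descriptors, 6 signal columns,
    noise sd 0.5."""
    return make_planted_bench(n=157, p=50, subset_size=6, noise_sd=0.5, seed=7)


def make_xyz_molecule(symbols, coords):
    """Build a Molecule from bare atoms + coordinates (no bonds) — used to
    test surface areas against closed-form sphere geometry."""
    rw = Chem.RWMol()
    for sym in symbols:
        atom = Chem.Atom(sym)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    mol = rw.GetMol()
    conf = Chem.Conformer(len(symbols))
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    return Molecule(id="xyz", rdmol=mol, rdmol_h=mol)


def random_regression_problem(rng, n=None, p=None, with_external=True):
    """A random well-conditioned OLS problem (and external block) for oracle
    comparisons."""
    n = n or int(rng.integers(30, 80))
    p = p or int(rng.integers(2, 7))
    X = rng.normal(size=(n, p)) * rng.uniform(0.5, 3.0, size=p)
    beta = rng.normal(size=p)
    y = rng.normal() + X @ beta + rng.normal(scale=rng.uniform(0.2, 1.5), size=n)
    if not with_external:
        return X, y
    n_ex = int(rng.integers(8, 20))
    X_ex = rng.normal(size=(n_ex, p)) * rng.uniform(0.5, 3.0, size=p)
    y_ex = rng.normal() + X_ex @ beta + rng.normal(scale=rng.uniform(0.2, 1.5), size=n_ex)
    return X, y, X_ex, y_ex
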