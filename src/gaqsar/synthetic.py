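"""Synthetic inputs: fixture molecules, planted regression benches and an
emulated kinase-inhibitor modelling set plus screening library.

Nothing here is downloaded: fixture molecules are small hand-checkable
structures with hand-derived descriptor values; the modelling set is a
combinatorial family of azine/biaryl structures whose activity is planted as
an affine function of six real topological/charge descriptors plus Gaussian
noise, scaled so Ki spans 0.146-100000 nM (pKi 4.0-9.84) over 197 compounds;
the screening library is a disjoint 161-compound slice of the same family.
All generators are deterministic per seed.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import CompoundRecord
from .descriptors import compute_matrix, parse_descriptor_name
from .molecule_io import Molecule, assign_gasteiger_charges, parse_smiles

__all__ = [
    "FIXTURES",
    "FIXTURE_EXPECTED",
    "fixture_molecules",
    "PlantedBench",
    "make_planted_bench",
    "make_modelling_set",
    "make_screening_library",
    "PLANTED_DESCRIPTORS",
    "PLANTED_WEIGHTS",
]

# ---------------------------------------------------------------------------
# fixture molecules with hand-derived descriptor values

#: name -> SMILES of the hand-verifiable fixture set
FIXTURES: dict[str, str] = {
    "pyridine": "c1ccncc1",
    "benzene": "c1ccccc1",
    "2-phenylpyridine": "c1ccc(-c2ccccn2)cc1",
    "nicotinamide": "NC(=O)c1cccnc1",
    "pyrimidine": "c1cncnc1",
    "quinoline": "c1ccc2ncccc2c1",
    "acetic_acid": "CC(=O)O",
    "n-butane": "CCCC",
    "hexane": "CCCCCC",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "pyrrole": "c1cc[nH]c1",
    "sodium_acetate": "CC(=O)[O-].[Na+]",  # salt pair: parser keeps the anion
    "glycerol": "OCC(O)CO",
}

#: hand-derived expected descriptor values, asserted exactly by the test suite.
#
# Derivations (heavy-atom graph geodesics):
# * pyridine N1..C: ortho C2/C6 at 1 bond, C3/C5 at 2, C4 at 3 -> fringNaroC1B=2,
#   2B=2, 3B=1, 5B=0 (ring diameter 3).
# * 2-phenylpyridine: from ring N the phenyl ipso C is 2 bonds, ortho 3,
#   meta 4, para 5 -> exactly one aromatic C at 5 bonds. Within the pyridine
#   ring no C is 5 bonds away, so fringNaroC5B = 1.
# * nicotinamide: ring N to aromatic carbons: C2 1 bond, C3 2 (x2), C4/C6 3...
#   geodesics within a 6-ring give 2+2+1 at k=1,2,3; carbonyl C (sp2, not
#   aromatic) sits 3 bonds from N via C2 or 4 via the other direction (shortest
#   3). faroNsp2O5B: carbonyl O and amide N are 4 bonds from ring N -> 0 at 5.
# * pyrimidine: each N sees the other N at 2 bonds; aromatic C at 1 (x2 per N).
# * hexane/butane: nitrogen-free -> every N-involving descriptor is 0.
FIXTURE_EXPECTED: dict[str, dict[str, int]] = {
    "pyridine": {
        "fringNaroC1B": 2,
        "fringNaroC2B": 2,
        "fringNaroC3B": 1,
        "fringNaroC5B": 0,
        "faroNaroC2B": 2,
        "n_ringN": 1,
        "n_aroC": 5,
    },
    "benzene": {
        "fringNaroC2B": 0,
        "faroCaroC1B": 12,  # 6 bonds, ordered pairs
        "faroCaroC2B": 12,
        "faroCaroC3B": 6,   # 3 para pairs, both orderings
        "n_aroC": 6,
    },
    "2-phenylpyridine": {
        "fringNaroC5B": 1,
        "fringNaroC4B": 2,
        "fringNaroC3B": 3,  # pyridine C4 plus the two phenyl ortho carbons
        "n_ringN": 1,
        "n_aroC": 11,
    },
    "nicotinamide": {
        "fringNaroC1B": 2,
        "fringNaroC2B": 2,
        "fringNaroC3B": 1,
        "faroNsp2O5B": 0,
        "faroNsp2O4B": 1,
        "n_N": 2,
        "n_aroN": 1,
    },
    "pyrimidine": {
        "fringNaroC1B": 4,
        "faroNaroN2B": 2,
        "n_ringN": 2,
    },
    "quinoline": {"n_ringN": 1, "n_aroC": 9},
    "acetic_acid": {
        "n_sp2O": 1,
        "n_sp3O": 1,
        "n_N": 0,
        "fringNaroC5B": 0,
        "fsp2Osp3O2B": 1,  # one (carbonyl O, hydroxyl O) ordered pair at 2 bonds
    },
    "n-butane": {"fringNaroC5B": 0, "n_N": 0, "n_O": 0, "n_notringC": 4},
    "hexane": {"fringNaroC5B": 0, "faroNsp2O5B": 0, "n_N": 0, "n_notringC": 6},
    "toluene": {"n_aroC": 6, "n_notringC": 1},
    "phenol": {"n_O": 1, "n_sp3O": 1},
    "pyrrole": {"n_ringN": 1, "n_acc": 0},  # pyrrole N donates its lone pair
    "sodium_acetate": {"n_O": 2, "n_N": 0},
    "glycerol": {"n_sp3O": 3, "n_notringC": 3},
}


def fixture_molecules(with_charges: bool = True) -> list[Molecule]:
    """The hand-verifiable fixture set, parsed (and charged by default)."""
    mols = []
    for name, smi in FIXTURES.items():
        mol = parse_smiles(smi, id=name)
        if with_charges:
            mol = assign_gasteiger_charges(mol)
        mols.append(mol)
    return mols


# ---------------------------------------------------------------------------
# planted regression bench


@dataclass
class PlantedBench:
    """A descriptor-like regression problem with a known sparse truth."""

    X: pd.DataFrame
    y: np.ndarray
    true_subset: list[str]
    true_coefficients: dict[str, float]
    intercept: float
    noise_sd: float
    seed: int


def make_planted_bench(
    n: int = 157,
    p: int = 50,
    subset_size: int = 6,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> PlantedBench:
    """Generate a planted-signal bench emulating a pruned descriptor pool.

    Columns mimic descriptor marginals: two thirds are count-like
    (Poisson-distributed non-negative integers, rates 0.5-6) and one third
    ratio-like (Beta-distributed in (0, 1)). A random ``subset_size`` subset
    carries the signal; coefficients are scaled so the signal variance is
    ~1.0, giving a true-model R2 of about 1 / (1 + noise_sd^2) — around 0.8
    at the default noise, matching a realistic well-fit QSAR. Half of the
    remaining columns are decoys correlated at most ~0.5 with a signal
    column; the rest are independent.
    """
    if n <= subset_size + 1:
        raise ValueError("need n > subset_size + 1")
    if p < subset_size:
        raise ValueError("need p >= subset_size")
    rng = np.random.default_rng(seed)
    names = [f"d{j:03d}" for j in range(p)]
    X = np.empty((n, p))
    kind = rng.random(p)
    for j in range(p):
        if kind[j] < 2 / 3:
            X[:, j] = rng.poisson(rng.uniform(0.5, 6.0), size=n)
        else:
            X[:, j] = rng.beta(rng.uniform(2, 6), rng.uniform(2, 6), size=n)
    signal_idx = sorted(rng.choice(p, size=subset_size, replace=False).tolist())
    decoy_pool = [j for j in range(p) if j not in signal_idx]
    rng.shuffle(decoy_pool)
    for j in decoy_pool[: len(decoy_pool) // 2]:
        s = X[:, rng.choice(signal_idx)]
        s_std = (s - s.mean()) / (s.std() or 1.0)
        mix = 0.45 * s_std + np.sqrt(1 - 0.45**2) * rng.standard_normal(n)
        # re-discretize to stay count-like while capping correlation ~0.45
        X[:, j] = np.round(2.0 + 1.5 * mix).clip(min=0)
    # coefficients: equal standardized weight, alternating-free random signs
    sds = X[:, signal_idx].std(axis=0)
    sds[sds == 0] = 1.0
    raw_w = rng.uniform(0.8, 1.2, size=subset_size) / sds
    sig = X[:, signal_idx] @ raw_w
    scale = 1.0 / (sig.std() or 1.0)
    coefs = raw_w * scale
    intercept = 6.5 - float((X[:, signal_idx] @ coefs).mean())
    y = intercept + X[:, signal_idx] @ coefs + rng.normal(0.0, noise_sd, size=n)
    Xdf = pd.DataFrame(X, columns=names,
                       index=pd.Index([f"c{i:03d}" for i in range(n)],
                                      name="compound_id"))
    true_names = [names[j] for j in signal_idx]
    return PlantedBench(
        X=Xdf,
        y=y,
        true_subset=true_names,
        true_coefficients=dict(zip(true_names, coefs.tolist())),
        intercept=intercept,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# emulated modelling set and screening library

# Scaffold templates ({A}/{B} substitution points) spanning azines, biaryls,
# amides and five-membered heterocycles, crossed with small substituents.
_SCAFFOLDS = [
    "c1ccc({A})nc1{B}",
    "c1cc({A})cnc1{B}",
    "{A}c1ccc(-c2ccncc2{B})cc1",
    "{A}c1ccc(-c2ccccn2)cc1{B}",
    "{A}c1cnc({B})nc1",
    "{A}c1ccc2ncccc2c1{B}",
    "{A}c1ccc(C(=O)N{B})cc1",
    "{A}c1ccc(-n2cccc2)cc1{B}",
    "{A}c1ccc(Oc2ccncc2)cc1{B}",
    "{A}c1ccc(CNc2ccncc2)cc1{B}",
    "{A}c1nc({B})cs1",
    "{A}c1ccc(S(=O)(=O)N{B})cc1",
    "{A}C1CCN(C(=O)c2ccncc2)CC1",
    "{A}c1noc({B})c1",
]
_SUBSTITUENTS = ["", "C", "O", "N", "F", "C(=O)O", "C(=O)N", "OC", "NC(C)=O",
                 "C#N", "CO", "CC(=O)O", "c2ccccc2", "Cl"]

#: descriptor names carrying the planted activity signal of the emulated set
PLANTED_DESCRIPTORS = [
    "fringNaroC5B",
    "N_hy1",
    "faroNsp2O5B",
    "fsp2Oacc6B",
    "faccsp2C4B",
    "faccaroC3B",
]
#: relative (per-standard-deviation) weights of the planted descriptors
PLANTED_WEIGHTS = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]

_PKI_MIN, _PKI_MAX = 4.0, 9.0 - np.log10(0.146)  # Ki 100000 .. 0.146 nM


@functools.lru_cache(maxsize=1)
def _family_smiles() -> tuple[str, ...]:
    """All valid, distinct structures of the combinatorial family (canonical,
    deterministic enumeration order)."""
    from rdkit import Chem, RDLogger

    # many template/substituent combos are syntactically invalid by design;
    # suppress the parse-error chatter while enumerating
    RDLogger.DisableLog("rdApp.error")
    try:
        out, seen = [], set()
        for sc in _SCAFFOLDS:
            for a, b in itertools.product(_SUBSTITUENTS, repeat=2):
                smi = sc.format(A=a, B=b)
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                can = Chem.MolToSmiles(mol)
                if can not in seen:
                    seen.add(can)
                    out.append(can)
    finally:
        RDLogger.EnableLog("rdApp.error")
    return tuple(out)


def make_modelling_set(
    seed: int = 0,
    n: int = 197,
    include_problem_records: bool = True,
) -> list[CompoundRecord]:
    """Emulated modelling table: ``n`` compound records with planted activity.

    Structures are drawn from the combinatorial family; pKi is an affine
    function of the six :data:`PLANTED_DESCRIPTORS` plus Gaussian noise
    (sd 0.5 before rescaling), affinely mapped so the extremes sit exactly at
    Ki = 100000 nM (pKi 4.0) and Ki = 0.146 nM (pKi 9.84) — activity is
    uniform-ish in pKi, i.e. log-uniform in Ki. With
    ``include_problem_records`` a handful of records are replaced by
    duplicates, ambiguous-Ki entries, a salt form and a metal complex so the
    curation filters have work to do; the list length stays ``n``.
    """
    rng = np.random.default_rng(seed)
    family = _family_smiles()
    if n > len(family):
        raise ValueError(f"family has only {len(family)} structures")
    pick = rng.choice(len(family), size=n, replace=False)
    smiles = [family[i] for i in sorted(pick.tolist())]
    mols = [
        assign_gasteiger_charges(parse_smiles(smi, id=f"M{i + 1:03d}"))
        for i, smi in enumerate(smiles)
    ]
    specs = [parse_descriptor_name(name) for name in PLANTED_DESCRIPTORS]
    X = compute_matrix(mols, specs).to_numpy()
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0
    raw = X @ (np.asarray(PLANTED_WEIGHTS) / sds)
    raw = (raw - raw.mean()) / (raw.std() or 1.0)
    score = raw + rng.normal(0.0, 0.5, size=n)
    lo, hi = score.min(), score.max()
    pki = _PKI_MIN + (score - lo) * (_PKI_MAX - _PKI_MIN) / (hi - lo)
    records = [
        CompoundRecord(id=m.id, smiles=s, ki=float(10.0 ** (9.0 - v)))
        for m, s, v in zip(mols, smiles, pki)
    ]
    if include_problem_records and n >= 20:
        # overwrite a few interior records with curation exercise cases
        records[10] = CompoundRecord(id="M011_dup", smiles=records[5].smiles,
                                     ki=records[5].ki)
        records[11] = CompoundRecord(id="M012_amb", smiles=records[11].smiles,
                                     ki=">10000")
        records[12] = CompoundRecord(id="M013_salt",
                                     smiles=records[6].smiles + ".[Na+].[Cl-]",
                                     ki=records[6].ki)
        records[13] = CompoundRecord(id="M014_metal", smiles="CC(=O)O.[Pt+2]",
                                     ki=50.0)
    return records


def make_screening_library(seed: int = 1, n: int = 161) -> list[Molecule]:
    """An ``n``-compound screening library from the same structural family,
    disjoint from the default modelling set draw for the same seed offset."""
    rng = np.random.default_rng(seed + 10_000)
    family = _family_smiles()
    pick = rng.choice(len(family), size=n, replace=False)
    return [
        parse_smiles(family[i], id=f"S{j + 1:03d}")
        for j, i in enumerate(sorted(pick.tolist()))
    ]
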