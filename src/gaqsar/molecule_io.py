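"""Structure input, perception, partial charges, conformers and atomic surfaces.

A :class:`Molecule` wraps a perceived RDKit molecule (heavy atoms only) and,
optionally, an explicit-hydrogen copy carrying a single embedded 3D conformer.
Topological descriptors operate on the heavy-atom graph; surface areas are
computed on the explicit-hydrogen conformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "Molecule",
    "MoleculeError",
    "ParseError",
    "EmbedError",
    "BONDI_RADII",
    "parse_smiles",
    "assign_gasteiger_charges",
    "embed_conformer",
    "shrake_rupley_areas",
    "read_smiles_file",
    "read_sdf",
    "write_sdf",
]

# Bondi (1964) van der Waals radii, Angstrom.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

# Single-atom alkali/alkaline-earth counterions are ordinary salt formers and
# are simply stripped; any other metal marks a metal-based inhibitor and flags
# the record for exclusion downstream.
_COUNTERIONS = frozenset("Li Na K Rb Cs Be Mg Ca Sr Ba".split())
_METALS = frozenset(
    "Al Ga In Sn Pb Bi "
    "Sc Ti V Cr Mn Fe Co Ni Cu Zn Y Zr Nb Mo Tc Ru Rh Pd Ag Cd "
    "Hf Ta W Re Os Ir Pt Au Hg".split()
) | _COUNTERIONS


class MoleculeError(ValueError):
    """Base class for structure-handling failures."""


class ParseError(MoleculeError):
    """SMILES/SDF input could not be parsed or sanitized.

    Carries the offending input text so batch callers can report it.
    """

    def __init__(self, message: str, text: str = ""):
        super().__init__(message)
        self.text = text


class EmbedError(MoleculeError):
    """3D embedding failed after the bounded retry budget."""


@dataclass
class Molecule:
    """A perceived molecular structure.

    Attributes
    ----------
    id : str
        Caller-supplied compound identifier.
    rdmol : rdkit.Chem.Mol
        Heavy-atom molecule with aromaticity/ring/hybridization perceived.
    rdmol_h : rdkit.Chem.Mol or None
        Explicit-hydrogen copy with one 3D conformer (set by
        :func:`embed_conformer` or an SDF reader).
    charges : numpy.ndarray or None
        Gasteiger partial charge per heavy atom (e).
    h_charges : numpy.ndarray or None
        Summed partial charge of the implicit hydrogens of each heavy atom.
    contains_metal : bool
        True when any input fragment contained a metal atom; such records are
        flagged for exclusion downstream, never silently dropped here.
    """

    id: str
    rdmol: Chem.Mol
    rdmol_h: Chem.Mol | None = None
    charges: np.ndarray | None = None
    h_charges: np.ndarray | None = None
    contains_metal: bool = field(default=False)

    @property
    def n_atoms(self) -> int:
        """Number of heavy atoms."""
        return self.rdmol.GetNumAtoms()

    @property
    def smiles(self) -> str:
        """Canonical SMILES of the (largest-fragment) heavy-atom structure."""
        return Chem.MolToSmiles(self.rdmol)

    @property
    def net_formal_charge(self) -> int:
        return Chem.GetFormalCharge(self.rdmol)

    def coords(self) -> np.ndarray:
        """All-atom coordinates (explicit H), shape (n_all_atoms, 3), Angstrom."""
        if self.rdmol_h is None or self.rdmol_h.GetNumConformers() == 0:
            raise MoleculeError(
                f"molecule {self.id!r} has no 3D conformer; run embed_conformer first"
            )
        return np.asarray(self.rdmol_h.GetConformer().GetPositions(), dtype=float)


def _largest_organic_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Strip salts: keep the largest fragment containing carbon.

    Returns (fragment, contains_metal) where the flag refers to *any* fragment
    of the original input.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)

    def is_counterion(frag):
        return frag.GetNumAtoms() == 1 and frag.GetAtomWithIdx(0).GetSymbol() in _COUNTERIONS

    has_metal = any(
        atom.GetSymbol() in _METALS
        for frag in frags
        if not is_counterion(frag)
        for atom in frag.GetAtoms()
    )
    if len(frags) == 1:
        return mol, has_metal
    organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    pool = organic if organic else list(frags)
    best = max(pool, key=lambda f: f.GetNumAtoms())
    return best, has_metal


def parse_smiles(text: str, id: str = "") -> Molecule:
    """Parse a SMILES string into a perceived :class:`Molecule`.

    Multi-fragment inputs (salts) are reduced to the largest organic fragment;
    if any fragment contains a metal atom the record is flagged via
    ``contains_metal`` so curation can exclude it with a reason.

    Raises
    ------
    ParseError
        On syntax or valence errors; the exception carries the input text.
    """
    mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {text!r}", text)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several sanitization subclasses
        raise ParseError(f"invalid structure {text!r}: {exc}", text) from exc
    frag, has_metal = _largest_organic_fragment(mol)
    if frag is not mol:
        Chem.SanitizeMol(frag)
    return Molecule(id=id or text, rdmol=frag, contains_metal=has_metal)


def assign_gasteiger_charges(mol: Molecule, n_iterations: int = 8) -> Molecule:
    """Assign Gasteiger-Marsili partial equalization charges.

    The iterative scheme damps each electronegativity-equalization transfer by
    ``(1/2)**k`` at iteration ``k``; ``n_iterations`` rounds (default 8) are
    enough for convergence to ~1e-3 e on organic molecules.

    Returns a new :class:`Molecule` with per-heavy-atom charges and the summed
    implicit-hydrogen charges; the total equals the net formal charge.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rdmol = Chem.Mol(mol.rdmol)
    AllChem.ComputeGasteigerCharges(rdmol, nIter=n_iterations)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in rdmol.GetAtoms()])
    qh = np.array([a.GetDoubleProp("_GasteigerHCharge") for a in rdmol.GetAtoms()])
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qh))):
        bad = [
            a.GetSymbol()
            for a, qi in zip(rdmol.GetAtoms(), q)
            if not np.isfinite(qi)
        ]
        raise MoleculeError(
            f"no Gasteiger parameters for element(s) {sorted(set(bad))} "
            f"in molecule {mol.id!r}"
        )
    total = float(q.sum() + qh.sum())
    if abs(total - mol.net_formal_charge) > 1e-3:
        raise MoleculeError(
            f"charge conservation violated for {mol.id!r}: "
            f"sum {total:.5f} vs formal {mol.net_formal_charge}"
        )
    return replace(mol, rdmol=rdmol, charges=q, h_charges=qh)


def embed_conformer(mol: Molecule, seed: int = 42, max_attempts: int = 5) -> Molecule:
    """Embed a single 3D conformer (ETKDG) on an explicit-hydrogen copy.

    Deterministic for a fixed ``seed``. No force-field refinement is applied:
    distance-geometry coordinates are adequate for surface-area ratios, and
    skipping minimization keeps the result exactly reproducible.
    """
    if mol.rdmol.GetNumAtoms() > 200:
        raise MoleculeError(f"{mol.id!r}: more than 200 heavy atoms")
    molh = Chem.AddHs(Chem.Mol(mol.rdmol))
    params = AllChem.ETKDGv3()
    last = -1
    for attempt in range(max_attempts):
        params.randomSeed = int(seed) + attempt
        last = AllChem.EmbedMolecule(molh, params)
        if last == 0:
            break
    if last != 0:
        raise EmbedError(
            f"embedding failed for {mol.id!r} after {max_attempts} attempts; "
            f"try a different seed"
        )
    coords = np.asarray(molh.GetConformer().GetPositions())
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 0.5:
        raise EmbedError(f"degenerate geometry for {mol.id!r}: atoms closer than 0.5 A")
    return replace(mol, rdmol_h=molh)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle spiral)."""
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    theta = golden * i
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def vdw_radii(rdmol: Chem.Mol) -> np.ndarray:
    """Bondi van der Waals radius per atom; unknown elements raise."""
    radii = []
    for atom in rdmol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in BONDI_RADII:
            raise MoleculeError(f"no van der Waals radius for element {sym!r}")
        radii.append(BONDI_RADII[sym])
    return np.array(radii)


def shrake_rupley_areas(
    mol: Molecule,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom Shrake-Rupley surface area (A^2) on the embedded conformer.

    Each atom is inflated to ``r_vdw + probe_radius`` and sampled with a
    deterministic Fibonacci point set; a sample point is exposed when it lies
    outside every other inflated sphere. ``probe_radius = 0`` gives the van
    der Waals molecular surface, ``1.4`` the water-probe SASA.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_sphere_points < 96:
        raise ValueError("n_sphere_points must be >= 96")
    coords = mol.coords()  # raises if no conformer
    radii = vdw_radii(mol.rdmol_h) + probe_radius
    points = _fibonacci_sphere(n_sphere_points)
    n = len(coords)
    areas = np.zeros(n)
    # neighbour cutoff: only spheres within r_i + max(r_j) can occlude
    rmax = radii.max()
    for i in range(n):
        sphere = coords[i] + radii[i] * points
        dij = np.linalg.norm(coords - coords[i], axis=1)
        nbrs = np.nonzero((dij < radii[i] + rmax) & (np.arange(n) != i))[0]
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in nbrs:
            d2 = np.einsum("ij,ij->i", sphere - coords[j], sphere - coords[j])
            r2 = radii[j] ** 2
            # a point exactly on a coincident sphere boundary is credited to
            # the lower-indexed atom, so degenerate overlaps count once
            if j < i:
                exposed &= d2 > r2 * (1.0 + 1e-9)
            else:
                exposed &= d2 > r2 * (1.0 - 1e-9)
            if not exposed.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return areas


# ---------------------------------------------------------------------------
# readers / writers


def read_smiles_file(path) -> list[Molecule]:
    """Read SMILES, one per line, optionally followed by an id (whitespace-split)."""
    mols = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            mols.append(parse_smiles(smi, id=mol_id))
    return mols


def read_sdf(path) -> list[Molecule]:
    """Read a V2000 SDF; 3D coordinates, when present, are kept as the conformer."""
    mols = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ParseError(f"unreadable SDF record #{i + 1} in {path}")
        mol_id = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"sdf{i + 1}"
        heavy = Chem.RemoveHs(Chem.Mol(rdmol))
        has3d = rdmol.GetNumConformers() > 0 and rdmol.GetConformer().Is3D()
        mols.append(
            Molecule(id=mol_id or f"sdf{i + 1}", rdmol=heavy,
                     rdmol_h=rdmol if has3d else None)
        )
    return mols


def write_sdf(mols: list[Molecule], path) -> None:
    """Write molecules to SDF; partial charges go into an atom-property field."""
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            out = Chem.Mol(mol.rdmol_h if mol.rdmol_h is not None else mol.rdmol)
            out.SetProp("_Name", mol.id)
            if mol.charges is not None:
                out.SetProp(
                    "gasteiger_charges",
                    " ".join(f"{q:.6f}" for q in mol.charges),
                )
            writer.write(out)
    finally:
        writer.close()
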