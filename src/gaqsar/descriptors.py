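"""Topological atom-pair, charge-bin and surface molecular descriptors.

The descriptor grammar has five variants:

* ``f<A><B><k>B`` — frequency of ordered atom pairs (a, b), a in class A,
  b in class B, a != b, at shortest-path distance exactly k bonds on the
  heavy-atom graph (e.g. ``fringNaroC5B``);
* charge-bin counts — atoms of a class whose Gasteiger partial charge lies in
  an open interval (``N_hy1``: nitrogens with charge in (-0.199, -0.100));
* ``rsa`` — ratio of the probe-0 molecular surface area to the probe-1.4
  solvent-accessible surface area;
* ``<class>_MSA`` — probe-0 surface area summed over a class, hydrogens
  folded into their parent heavy atom;
* ``n_<class>`` — plain atom counts.

Atom classes are pure predicates over perceived heavy atoms, registered by
name. Pair counting is symmetric by construction:
``pair_frequency(A, B, k) == pair_frequency(B, A, k)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from rdkit import Chem

from .molecule_io import Molecule, MoleculeError, shrake_rupley_areas

__all__ = [
    "ATOM_CLASSES",
    "UNREACHABLE",
    "DescriptorSpec",
    "PairFrequency",
    "ChargeBinCount",
    "SurfaceRatio",
    "ClassSurfaceArea",
    "AtomCount",
    "SurfaceSummary",
    "topological_distances",
    "pair_frequency",
    "charge_bin_count",
    "surface_descriptors",
    "compute_matrix",
    "parse_descriptor_name",
    "default_descriptor_pool",
]

UNREACHABLE = -1


def _is_acceptor(atom: Chem.Atom) -> bool:
    # H-bond acceptor: any oxygen; nitrogen unless quaternary/cationic or an
    # aromatic N donating its lone pair into the ring (pyrrole-type N, which
    # has three sigma connections).
    sym = atom.GetSymbol()
    if sym == "O":
        return True
    if sym != "N":
        return False
    if atom.GetFormalCharge() > 0 or atom.GetTotalDegree() >= 4:
        return False
    if atom.GetIsAromatic() and atom.GetTotalDegree() == 3:
        return False
    return True


def _hyb(atom: Chem.Atom) -> str:
    return str(atom.GetHybridization())


def _oxygen_sp2(atom: Chem.Atom) -> bool:
    # Oxygen hybridization follows the sigma/pi bonding pattern, not RDKit's
    # conjugation-aware perception: a double (or aromatic) bond makes the O
    # sp2 (carbonyl-type), two single bonds make it sp3 (hydroxyl/ether-type).
    return any(
        b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.AROMATIC)
        for b in atom.GetBonds()
    )


ATOM_CLASSES: dict[str, Callable[[Chem.Atom], bool]] = {
    "ringN": lambda a: a.GetSymbol() == "N" and a.IsInRing(),
    "aroN": lambda a: a.GetSymbol() == "N" and a.GetIsAromatic(),
    "aroC": lambda a: a.GetSymbol() == "C" and a.GetIsAromatic(),
    "ringC": lambda a: a.GetSymbol() == "C" and a.IsInRing(),
    "notringC": lambda a: a.GetSymbol() == "C" and not a.IsInRing(),
    "sp2C": lambda a: a.GetSymbol() == "C" and _hyb(a) == "SP2",
    "sp3C": lambda a: a.GetSymbol() == "C" and _hyb(a) == "SP3",
    "sp2O": lambda a: a.GetSymbol() == "O" and _oxygen_sp2(a),
    "sp3O": lambda a: a.GetSymbol() == "O" and not _oxygen_sp2(a),
    "acc": _is_acceptor,
    "N": lambda a: a.GetSymbol() == "N",
    "O": lambda a: a.GetSymbol() == "O",
}


def class_members(mol: Molecule, cls: str) -> list[int]:
    """Heavy-atom indices belonging to a registered atom class."""
    if cls not in ATOM_CLASSES:
        raise KeyError(
            f"unknown atom class {cls!r}; available: {sorted(ATOM_CLASSES)}"
        )
    pred = ATOM_CLASSES[cls]
    return [a.GetIdx() for a in mol.rdmol.GetAtoms() if pred(a)]


def topological_distances(mol: Molecule) -> np.ndarray:
    """Shortest-path bond counts between heavy atoms.

    Symmetric integer matrix, 0 on the diagonal; atom pairs in different
    fragments are marked :data:`UNREACHABLE`.
    """
    d = Chem.GetDistanceMatrix(Chem.Mol(mol.rdmol), force=True)
    out = np.where(d > 1e7, UNREACHABLE, d).astype(int)
    return out


def pair_frequency(mol: Molecule, class_a: str, class_b: str, k: int) -> int:
    """Count ordered atom pairs (a in A, b in B, a != b) exactly k bonds apart.

    Both role-orderings are counted when the classes overlap, which makes the
    count symmetric in (A, B). Pairs in disconnected fragments contribute 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dist = topological_distances(mol)
    ia = class_members(mol, class_a)
    ib = class_members(mol, class_b)
    return int(sum(1 for i in ia for j in ib if i != j and dist[i, j] == k))


def charge_bin_count(
    mol: Molecule,
    cls: str,
    q_low: float,
    q_high: float,
    inclusive: bool = False,
) -> int:
    """Count class atoms with partial charge in (q_low, q_high).

    Bounds are strict (open interval) by default; ``inclusive=True`` switches
    to a closed interval for callers who read the bin as a range.
    """
    if q_low >= q_high:
        raise ValueError("q_low must be < q_high")
    if mol.charges is None:
        raise MoleculeError(
            f"molecule {mol.id!r} has no partial charges; "
            "run assign_gasteiger_charges first"
        )
    members = class_members(mol, cls)
    q = mol.charges[members]
    if inclusive:
        return int(np.count_nonzero((q >= q_low) & (q <= q_high)))
    return int(np.count_nonzero((q > q_low) & (q < q_high)))


class _MolContext:
    """Per-molecule cache of distance matrix, class members and surfaces,
    so a batch of specs does not recompute shared intermediates."""

    def __init__(self, mol: Molecule):
        self.mol = mol
        self._dist: np.ndarray | None = None
        self._members: dict[str, list[int]] = {}
        self._areas: dict[float, np.ndarray] = {}

    @property
    def dist(self) -> np.ndarray:
        if self._dist is None:
            self._dist = topological_distances(self.mol)
        return self._dist

    def members(self, cls: str) -> list[int]:
        if cls not in self._members:
            self._members[cls] = class_members(self.mol, cls)
        return self._members[cls]

    def areas(self, probe: float, n_sphere_points: int) -> np.ndarray:
        if probe not in self._areas:
            self._areas[probe] = shrake_rupley_areas(
                self.mol, probe_radius=probe, n_sphere_points=n_sphere_points
            )
        return self._areas[probe]

    def pair_frequency(self, class_a: str, class_b: str, k: int) -> int:
        ia, ib, dist = self.members(class_a), self.members(class_b), self.dist
        return int(sum(1 for i in ia for j in ib if i != j and dist[i, j] == k))


@dataclass(frozen=True)
class SurfaceSummary:
    """Total surfaces and per-class molecular surface areas (A^2)."""

    msa: float
    sasa: float
    rsa: float
    class_msa: dict[str, float]


def _fold_h_areas(mol: Molecule, per_atom: np.ndarray) -> np.ndarray:
    """Fold explicit-hydrogen areas into their parent heavy atoms; returns a
    heavy-atom-indexed array matching ``mol.rdmol`` atom order."""
    rdmol_h = mol.rdmol_h
    heavy = np.zeros(mol.n_atoms)
    heavy_index = {}
    hi = 0
    for atom in rdmol_h.GetAtoms():
        if atom.GetAtomicNum() != 1:
            heavy_index[atom.GetIdx()] = hi
            hi += 1
    for atom in rdmol_h.GetAtoms():
        idx = atom.GetIdx()
        if atom.GetAtomicNum() == 1:
            parent = atom.GetNeighbors()[0].GetIdx()
            heavy[heavy_index[parent]] += per_atom[idx]
        else:
            heavy[heavy_index[idx]] += per_atom[idx]
    return heavy


def surface_descriptors(
    mol: Molecule,
    n_sphere_points: int = 960,
    probe_sasa: float = 1.4,
    classes: tuple[str, ...] = ("notringC",),
    ctx: "_MolContext | None" = None,
) -> SurfaceSummary:
    """Molecular surface (probe 0), SASA (probe ``probe_sasa``) and their ratio.

    Hydrogens' areas are assigned to their parent heavy atom, so per-class
    areas are expressed over heavy-atom classes.
    """
    if ctx is not None:
        per_atom_msa = ctx.areas(0.0, n_sphere_points)
        per_atom_sasa = ctx.areas(probe_sasa, n_sphere_points)
    else:
        per_atom_msa = shrake_rupley_areas(mol, probe_radius=0.0,
                                           n_sphere_points=n_sphere_points)
        per_atom_sasa = shrake_rupley_areas(mol, probe_radius=probe_sasa,
                                            n_sphere_points=n_sphere_points)
    msa = float(per_atom_msa.sum())
    sasa = float(per_atom_sasa.sum())
    if sasa <= 0:
        raise MoleculeError(f"zero SASA for molecule {mol.id!r}")
    heavy_msa = _fold_h_areas(mol, per_atom_msa)
    class_msa = {
        cls: float(heavy_msa[class_members(mol, cls)].sum()) for cls in classes
    }
    return SurfaceSummary(msa=msa, sasa=sasa, rsa=msa / sasa, class_msa=class_msa)


# ---------------------------------------------------------------------------
# descriptor specs and the naming grammar


class DescriptorSpec:
    """Base class: a named, computable molecular descriptor."""

    name: str

    def compute(self, mol: Molecule, ctx: "_MolContext | None" = None) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    needs_charges = False
    needs_coords = False

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.name!r})"

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self.name == other.name

    def __hash__(self) -> int:
        return hash((type(self).__name__, self.name))


class PairFrequency(DescriptorSpec):
    def __init__(self, class_a: str, class_b: str, k: int):
        if k < 1:
            raise ValueError("k_bonds must be >= 1")
        for c in (class_a, class_b):
            if c not in ATOM_CLASSES:
                raise KeyError(
                    f"unknown atom class {c!r}; available: {sorted(ATOM_CLASSES)}"
                )
        self.class_a, self.class_b, self.k = class_a, class_b, k
        self.name = f"f{class_a}{class_b}{k}B"

    def compute(self, mol: Molecule, ctx: "_MolContext | None" = None) -> float:
        if ctx is not None:
            return float(ctx.pair_frequency(self.class_a, self.class_b, self.k))
        return float(pair_frequency(mol, self.class_a, self.class_b, self.k))


class ChargeBinCount(DescriptorSpec):
    needs_charges = True

    def __init__(self, cls: str, q_low: float, q_high: float,
                 name: str | None = None, inclusive: bool = False):
        if q_low >= q_high:
            raise ValueError("q_low must be < q_high")
        self.cls, self.q_low, self.q_high = cls, q_low, q_high
        self.inclusive = inclusive
        self.name = name or f"n{cls}q({q_low:g},{q_high:g})"

    def compute(self, mol: Molecule, ctx: "_MolContext | None" = None) -> float:
        return float(
            charge_bin_count(mol, self.cls, self.q_low, self.q_high,
                             inclusive=self.inclusive)
        )


class SurfaceRatio(DescriptorSpec):
    needs_coords = True
    name = "rsa"

    def __init__(self, n_sphere_points: int = 960, probe_sasa: float = 1.4):
        self.n_sphere_points = n_sphere_points
        self.probe_sasa = probe_sasa

    def compute(self, mol: Molecule, ctx: "_MolContext | None" = None) -> float:
        s = surface_descriptors(mol, self.n_sphere_points, self.probe_sasa,
                                classes=(), ctx=ctx)
        return s.rsa


class ClassSurfaceArea(DescriptorSpec):
    needs_coords = True

    def __init__(self, cls: str, n_sphere_points: int = 960):
        if cls not in ATOM_CLASSES:
            raise KeyError(f"unknown atom class {cls!r}")
        self.cls = cls
        self.n_sphere_points = n_sphere_points
        self.name = f"{cls}_MSA"

    def compute(self, mol: Molecule, ctx: "_MolContext | None" = None) -> float:
        s = surface_descriptors(mol, self.n_sphere_points, classes=(self.cls,),
                                ctx=ctx)
        return s.class_msa[self.cls]


class AtomCount(DescriptorSpec):
    def __init__(self, cls: str):
        if cls not in ATOM_CLASSES:
            raise KeyError(f"unknown atom class {cls!r}")
        self.cls = cls
        self.name = f"n_{cls}"

    def compute(self, mol: Molecule, ctx: "_MolContext | None" = None) -> float:
        if ctx is not None:
            return float(len(ctx.members(self.cls)))
        return float(len(class_members(mol, self.cls)))


# The partial-charge bin used by the published nitrogen descriptors. The two
# names are verbally identical in the source nomenclature; both map to the
# same computation here (strict open interval by default, see charge_bin_count).
_NAMED_SPECS: dict[str, Callable[[], DescriptorSpec]] = {
    "N_hy1": lambda: ChargeBinCount("N", -0.199, -0.100, name="N_hy1"),
    "N_MSA1": lambda: ChargeBinCount("N", -0.199, -0.100, name="N_MSA1"),
    "rsa": SurfaceRatio,
}

# class tokens sorted longest-first for unambiguous greedy tokenization
_CLASS_TOKENS = sorted(ATOM_CLASSES, key=len, reverse=True)


def parse_descriptor_name(name: str) -> DescriptorSpec:
    """Parse a canonical descriptor name into its spec (case-sensitive).

    Grammar: ``f<A><B><k>B`` pair frequencies, ``<class>_MSA`` class surface
    areas, ``n_<class>`` atom counts, plus the named descriptors ``N_hy1``,
    ``N_MSA1`` and ``rsa``. Unknown tokens fail loudly.
    """
    if name in _NAMED_SPECS:
        return _NAMED_SPECS[name]()
    if name.startswith("n_"):
        return AtomCount(name[2:])
    if name.endswith("_MSA"):
        return ClassSurfaceArea(name[: -len("_MSA")])
    if name.startswith("f") and name.endswith("B"):
        body = name[1:-1]
        for tok_a in _CLASS_TOKENS:
            if not body.startswith(tok_a):
                continue
            rest = body[len(tok_a):]
            for tok_b in _CLASS_TOKENS:
                if not rest.startswith(tok_b):
                    continue
                knum = rest[len(tok_b):]
                if knum.isdigit() and int(knum) >= 1:
                    return PairFrequency(tok_a, tok_b, int(knum))
        raise ValueError(
            f"cannot tokenize pair-frequency name {name!r}; "
            f"known class tokens: {sorted(ATOM_CLASSES)}"
        )
    raise ValueError(f"unrecognized descriptor name {name!r}")


def default_descriptor_pool(
    k_max: int = 7,
    include_surface: bool = False,
) -> list[DescriptorSpec]:
    """The default candidate pool: all class-pair frequencies for k = 1..k_max,
    charge-bin nitrogen count, atom counts, and (optionally) surface terms.

    Pair specs are emitted once per unordered class pair since the count is
    symmetric in the two classes.
    """
    specs: list[DescriptorSpec] = []
    classes = sorted(ATOM_CLASSES)
    for i, a in enumerate(classes):
        for b in classes[i:]:
            for k in range(1, k_max + 1):
                specs.append(PairFrequency(a, b, k))
    specs.append(_NAMED_SPECS["N_hy1"]())
    for cls in classes:
        specs.append(AtomCount(cls))
    if include_surface:
        specs.append(SurfaceRatio())
        specs.append(ClassSurfaceArea("notringC"))
    return specs


def compute_matrix(
    mols: list[Molecule],
    specs: list[DescriptorSpec],
    strict: bool = True,
) -> pd.DataFrame:
    """Assemble the compounds x descriptors matrix.

    Row index is the compound id (input order preserved); columns follow the
    spec order. In strict mode any per-molecule failure aborts; in lenient
    mode the failing compound's row is dropped and the error is recorded on
    ``df.attrs['dropped']``.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate descriptor names: {dupes}")
    ids = [m.id for m in mols]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in molecule list")
    rows, kept_ids, dropped = [], [], []
    for mol in mols:
        try:
            ctx = _MolContext(mol)
            rows.append([spec.compute(mol, ctx) for spec in specs])
            kept_ids.append(mol.id)
        except Exception as exc:
            if strict:
                raise MoleculeError(
                    f"descriptor computation failed for {mol.id!r}: {exc}"
                ) from exc
            dropped.append((mol.id, str(exc)))
    df = pd.DataFrame(rows, index=pd.Index(kept_ids, name="compound_id"),
                      columns=names, dtype=float)
    df.attrs["dropped"] = dropped
    return df
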