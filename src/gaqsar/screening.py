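"""Ligand-based virtual screening: predict, domain-flag and rank a library."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import pki_to_ki
from .descriptors import DescriptorSpec, compute_matrix, parse_descriptor_name
from .model_search import MLRModel
from .molecule_io import Molecule, assign_gasteiger_charges, embed_conformer
from .validation import williams_domain

__all__ = ["predict", "screen", "featurize_library", "pair_contrast"]


def predict(model: MLRModel, matrix: pd.DataFrame) -> pd.Series:
    """Affine model evaluation over a descriptor matrix (order preserved)."""
    values = model.predict(matrix)
    return pd.Series(values, index=matrix.index, name="pki_pred")


def featurize_library(
    library: list[Molecule],
    model: MLRModel,
    conformer_seed: int = 42,
    lenient: bool = True,
) -> pd.DataFrame:
    """Compute exactly the model's descriptors for each library compound.

    Charges and a conformer are prepared only when a descriptor requires them.
    In lenient mode compounds that fail featurization are dropped and listed
    in ``df.attrs['dropped']``; strict mode raises.
    """
    specs: list[DescriptorSpec] = [
        parse_descriptor_name(n) for n in model.descriptor_names
    ]
    needs_charges = any(s.needs_charges for s in specs)
    needs_coords = any(s.needs_coords for s in specs)
    prepared = []
    dropped = []
    for mol in library:
        try:
            m = mol
            if needs_charges and m.charges is None:
                m = assign_gasteiger_charges(m)
            if needs_coords and (m.rdmol_h is None or m.rdmol_h.GetNumConformers() == 0):
                m = embed_conformer(m, seed=conformer_seed)
            prepared.append(m)
        except Exception as exc:
            if not lenient:
                raise
            dropped.append((mol.id, str(exc)))
    df = compute_matrix(prepared, specs, strict=not lenient)
    df.attrs["dropped"] = dropped + df.attrs.get("dropped", [])
    return df


def screen(
    model: MLRModel,
    library: list[Molecule],
    training_reference: tuple[pd.DataFrame, np.ndarray],
    conformer_seed: int = 42,
    lenient: bool = True,
) -> pd.DataFrame:
    """Rank a compound library by predicted pKi with applicability-domain flags.

    Returns one row per successfully featurized compound with columns
    ``pki_pred``, ``ki_nM_pred`` (= 10^(9 - pKi)), ``leverage``, ``in_domain``
    and ``rank`` (1 = most potent; ties broken by compound id). Out-of-domain
    compounds are flagged, never dropped.
    """
    if not library:
        raise ValueError("empty screening library")
    X_tr, y_tr = training_reference
    matrix = featurize_library(library, model, conformer_seed, lenient=lenient)
    pki = predict(model, matrix)
    domain = williams_domain(model, X_tr, matrix, y_tr)
    out = pd.DataFrame(
        {
            "pki_pred": pki,
            "ki_nM_pred": [pki_to_ki(v) for v in pki],
            "leverage": domain["leverage"],
            "in_domain": domain["in_domain"],
        }
    )
    # stable two-pass sort: id ascending first, then pki descending,
    # so equal predictions rank in id order
    out = out.sort_index(kind="mergesort").sort_values(
        "pki_pred", ascending=False, kind="mergesort"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["dropped"] = matrix.attrs.get("dropped", [])
    out.attrs["h_star"] = domain.attrs.get("h_star")
    return out


def pair_contrast(
    record_a: tuple[str, float],
    record_b: tuple[str, float],
) -> tuple[float, float]:
    """Potency contrast between two compounds given as (id, pKi).

    Returns ``(delta_pki, fold_change)`` where ``delta_pki = pKi_a - pKi_b``
    and ``fold_change = 10 ** delta_pki`` is the ratio of inhibition
    constants Ki_b / Ki_a.
    """
    _, pki_a = record_a
    _, pki_b = record_b
    if not (np.isfinite(pki_a) and np.isfinite(pki_b)):
        raise ValueError("pKi values must be finite")
    delta = float(pki_a - pki_b)
    return delta, float(10.0 ** delta)
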