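"""Modelling-table construction: activity transform, curation, train/test split.

Inhibition constants arrive in nanomolar; the modelling response is
``pKi = -log10(Ki [M]) = 9 - log10(Ki [nM])``. The transform is applied on the
molar scale even when Ki is tabulated in nM — the only reading consistent with
a 0.146 nM compound having pKi 9.84.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .molecule_io import ParseError, parse_smiles

__all__ = [
    "CompoundRecord",
    "ki_to_pki",
    "pki_to_ki",
    "curate",
    "split",
    "records_to_frame",
    "read_records_csv",
    "write_records_csv",
]


@dataclass
class CompoundRecord:
    """One row of the modelling table."""

    id: str
    smiles: str
    ki: float | str  # nM when numeric; a string marks an ambiguous entry
    pki: float | None = None
    split: str = "unassigned"  # train | external | unassigned
    exclusion_reason: str | None = None

    def __post_init__(self):
        if isinstance(self.ki, (int, float)) and self.pki is None:
            self.pki = ki_to_pki(float(self.ki))

    @property
    def ki_is_numeric(self) -> bool:
        return isinstance(self.ki, (int, float))


def ki_to_pki(ki_nm: float) -> float:
    """pKi from Ki in nM: ``pKi = -log10(Ki * 1e-9)``."""
    if not isinstance(ki_nm, (int, float)) or not math.isfinite(ki_nm) or ki_nm <= 0:
        raise ValueError(f"Ki must be a positive number in nM, got {ki_nm!r}")
    return 9.0 - math.log10(ki_nm)


def pki_to_ki(pki: float) -> float:
    """Inverse transform: Ki in nM from pKi."""
    return 10.0 ** (9.0 - pki)


def curate(records: list[CompoundRecord]) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Apply the curation filters; returns (kept, excluded).

    Exclusion reasons: ``ambiguous_ki`` (non-numeric Ki), ``unparseable``,
    ``metal`` (any input fragment contains a metal atom) and ``duplicate``
    (identical canonical structure after salt stripping; first occurrence
    wins). Salts are reduced to their largest organic fragment before
    duplicate detection, so a salt form of an earlier compound is a duplicate.
    """
    if not records:
        raise ValueError("empty record list")
    kept: list[CompoundRecord] = []
    excluded: list[CompoundRecord] = []
    seen: dict[str, str] = {}
    for rec in records:
        if not rec.ki_is_numeric:
            excluded.append(replace(rec, exclusion_reason="ambiguous_ki"))
            continue
        try:
            mol = parse_smiles(rec.smiles, id=rec.id)
        except ParseError as exc:
            excluded.append(replace(rec, exclusion_reason=f"unparseable: {exc}"))
            continue
        if mol.contains_metal:
            excluded.append(replace(rec, exclusion_reason="metal"))
            continue
        canonical = mol.smiles
        if canonical in seen:
            excluded.append(
                replace(rec, exclusion_reason=f"duplicate of {seen[canonical]}")
            )
            continue
        seen[canonical] = rec.id
        kept.append(replace(rec, exclusion_reason=None))
    return kept, excluded


def split(
    records: list[CompoundRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> list[CompoundRecord]:
    """Assign train/external membership uniformly at random.

    Training size is ``floor(train_fraction * n)`` — 197 compounds at 0.8
    give the canonical 157/40 partition. Reproducible for a fixed seed.
    """
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(math.floor(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"degenerate split: {n_train} train / {n - n_train} external"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = set(order[:n_train].tolist())
    return [
        replace(rec, split="train" if i in train_idx else "external")
        for i, rec in enumerate(records)
    ]


def records_to_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "ki_nM": [r.ki for r in records],
            "pki": [r.pki for r in records],
            "split": [r.split for r in records],
            "exclusion_reason": [r.exclusion_reason for r in records],
        }
    )


def read_records_csv(path) -> list[CompoundRecord]:
    """Read a modelling table CSV with columns id, smiles, ki_nM."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "smiles", "ki_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            ki: float | str = float(row.ki_nM)
        except (TypeError, ValueError):
            ki = str(row.ki_nM)
        rec = CompoundRecord(id=str(row.id), smiles=str(row.smiles), ki=ki)
        if "split" in df.columns and isinstance(getattr(row, "split", None), str):
            rec.split = row.split
        records.append(rec)
    return records


def write_records_csv(records: list[CompoundRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
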