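"""End-to-end pipeline: curate -> featurize -> OFS -> GA-MLR -> validate -> screen.

Every stage writes its artifact under ``config.out_dir`` together with a
manifest carrying the config hash, the seed set and a checksum per file, so a
rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .dataset import (CompoundRecord, curate, read_records_csv, split,
                      write_records_csv)
from .descriptors import compute_matrix, default_descriptor_pool
from .model_search import GAParams, MLRModel, ga_select, objective_filter
from .molecule_io import (Molecule, assign_gasteiger_charges, embed_conformer,
                          parse_smiles, read_smiles_file)
from .screening import screen
from .synthetic import make_modelling_set, make_screening_library
from .validation import (ValidationReport, check_thresholds, plot_predicted_vs_observed,
                         plot_williams, validate_model, williams_domain)

log = logging.getLogger("gaqsar")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """In-memory handles to every pipeline artifact."""

    config: RunConfig
    records: list[CompoundRecord]
    matrix: pd.DataFrame
    removal_log: list[tuple[str, str]]
    selected: list[str]
    model: MLRModel
    report: ValidationReport
    threshold_flags: dict[str, bool]
    screen_results: pd.DataFrame
    out_dir: Path


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _prepare_molecules(records, cfg: RunConfig) -> list[Molecule]:
    mols = []
    for rec in records:
        mol = parse_smiles(rec.smiles, id=rec.id)
        mol = assign_gasteiger_charges(mol, n_iterations=cfg.charge_iterations)
        if cfg.include_surface:
            mol = embed_conformer(mol, seed=cfg.seeds.conformer)
        mols.append(mol)
    return mols


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full QSAR workflow described by ``config``.

    Raises on the first stage failure with the stage name in the message; no
    partial outputs are left behind except those already completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash,
        "seeds": config.to_dict()["seeds"],
        "files": {},
    }
    config.to_yaml(out / "config.yaml")
    manifest["files"]["config.yaml"] = _checksum(out / "config.yaml")

    # -- stage: dataset ------------------------------------------------------
    try:
        if config.modelling_csv is not None:
            records = read_records_csv(config.modelling_csv)
        else:
            records = make_modelling_set(
                seed=config.seeds.synth, n=config.n_synthetic_compounds
            )
        kept, excluded = curate(records)
        kept = split(kept, config.train_fraction, seed=config.seeds.split)
    except Exception as exc:
        raise RuntimeError(f"stage 'curate' failed: {exc}") from exc
    write_records_csv(kept + excluded, out / "curated.csv")
    log.info("curated: %d kept, %d excluded", len(kept), len(excluded))

    # -- stage: featurize ----------------------------------------------------
    try:
        mols = _prepare_molecules(kept, config)
        pool = default_descriptor_pool(
            k_max=config.descriptor_k_max, include_surface=config.include_surface
        )
        matrix = compute_matrix(mols, pool)
    except Exception as exc:
        raise RuntimeError(f"stage 'featurize' failed: {exc}") from exc
    matrix.to_csv(out / "matrix_full.csv")
    log.info("featurized: %s", matrix.shape)

    # -- stage: objective feature selection ---------------------------------
    try:
        reduced, removal_log = objective_filter(
            matrix,
            near_constant_tol=config.near_constant_tol,
            corr_max=config.corr_max,
            identical_fraction=config.identical_fraction,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'objective_filter' failed: {exc}") from exc
    pd.DataFrame(removal_log, columns=["descriptor", "reason"]).to_csv(
        out / "ofs_removals.csv", index=False
    )
    log.info("OFS: %d -> %d descriptors", matrix.shape[1], reduced.shape[1])

    # -- stage: GA-MLR -------------------------------------------------------
    y = np.array([r.pki for r in kept], dtype=float)
    is_train = np.array([r.split == "train" for r in kept])
    X_tr, X_ex = reduced[is_train], reduced[~is_train]
    y_tr, y_ex = y[is_train], y[~is_train]
    try:
        params = GAParams(seed=config.seeds.ga, **{
            k: getattr(config.ga, k)
            for k in ("population_size", "generations", "crossover_prob",
                      "mutation_prob", "elitism", "subset_size", "patience")
        })
        selected, model, trace = ga_select(X_tr, y_tr, params)
    except Exception as exc:
        raise RuntimeError(f"stage 'ga_select' failed: {exc}") from exc
    model.metadata.update(
        {"config_hash": config.config_hash, "selected": selected,
         "n_train": int(is_train.sum()), "n_external": int((~is_train).sum())}
    )
    model.to_json(out / "model.json")
    np.savetxt(out / "ga_trace.txt", np.asarray(trace))
    log.info("GA selected %s (Q2_LOO=%.4f)", selected, trace[-1])

    # -- stage: validate -----------------------------------------------------
    try:
        report = validate_model(
            model,
            X_tr[selected], y_tr,
            X_ex[selected], y_ex,
            lmo_fraction=config.lmo_fraction,
            lmo_iterations=config.lmo_iterations,
            n_scrambles=config.n_scrambles,
            seed=config.seeds.lmo,
        )
        flags = check_thresholds(report)
    except Exception as exc:
        raise RuntimeError(f"stage 'validate' failed: {exc}") from exc
    report.to_json(out / "validation.json")
    with open(out / "thresholds.json", "w") as fh:
        json.dump(flags, fh, indent=2)

    # -- stage: screen -------------------------------------------------------
    try:
        if config.library_smiles is not None:
            library = read_smiles_file(config.library_smiles)
        else:
            library = make_screening_library(
                seed=config.seeds.synth, n=config.n_synthetic_library
            )
        results = screen(model, library, (X_tr[selected], y_tr),
                         conformer_seed=config.seeds.conformer)
    except Exception as exc:
        raise RuntimeError(f"stage 'screen' failed: {exc}") from exc
    results.to_csv(out / "screen.csv")

    if config.make_plots:
        yhat_all = model.predict(reduced[selected])
        plot_predicted_vs_observed(
            y, yhat_all, out / "predicted_vs_observed.svg",
            split_labels=["train" if t else "external" for t in is_train],
        )
        domain = williams_domain(model, X_tr[selected], reduced[selected], y_tr, y)
        plot_williams(domain, out / "williams.svg")

    for name in ("curated.csv", "matrix_full.csv", "ofs_removals.csv",
                 "model.json", "validation.json", "thresholds.json", "screen.csv"):
        manifest["files"][name] = _checksum(out / name)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        config=config,
        records=kept + excluded,
        matrix=reduced,
        removal_log=removal_log,
        selected=selected,
        model=model,
        report=report,
        threshold_flags=flags,
        screen_results=results,
        out_dir=out,
    )
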