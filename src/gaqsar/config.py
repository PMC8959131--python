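"""Run configuration: every seed and threshold of the pipeline in one record.

The config serializes to YAML; unknown keys are rejected on load so a typo
cannot silently fall back to a default. A short hash of the canonical dump is
embedded in every output's metadata for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["Seeds", "GAConfig", "RunConfig"]


@dataclass
class Seeds:
    split: int = 11
    ga: int = 17
    lmo: int = 23
    scramble: int = 29
    conformer: int = 42
    synth: int = 101


@dataclass
class GAConfig:
    population_size: int = 64
    generations: int = 300
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1
    elitism: int = 2
    subset_size: int = 6
    patience: int | None = None


@dataclass
class RunConfig:
    """Full pipeline configuration (defaults reproduce the synthetic study)."""

    # inputs; None means "generate synthetically with seeds.synth"
    modelling_csv: str | None = None
    library_smiles: str | None = None
    out_dir: str = "gaqsar_run"

    seeds: Seeds = field(default_factory=Seeds)
    ga: GAConfig = field(default_factory=GAConfig)

    # dataset
    train_fraction: float = 0.8
    n_synthetic_compounds: int = 197
    n_synthetic_library: int = 161

    # descriptors
    descriptor_k_max: int = 7
    include_surface: bool = False
    charge_iterations: int = 8
    surface_n_points: int = 960
    surface_probe_sasa: float = 1.4

    # objective feature selection
    corr_max: float = 0.90
    near_constant_tol: float = 1e-8
    identical_fraction: float = 0.95

    # validation
    lmo_fraction: float = 0.3
    lmo_iterations: int = 1000
    n_scrambles: int = 1000
    make_plots: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload or {})
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, sub in (("seeds", Seeds), ("ga", GAConfig)):
            if key in payload and isinstance(payload[key], dict):
                sub_known = {f.name for f in fields(sub)}
                sub_unknown = set(payload[key]) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown config key(s) under {key!r}: {sorted(sub_unknown)}"
                    )
                payload[key] = sub(**payload[key])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
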