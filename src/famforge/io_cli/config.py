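"""Run configuration: flat key-value sections with strict key checking.

Defaults equal the pipeline's canonical parameters: search E-value and
inclusion threshold 1e-2, 10 iterations, redundancy clustering at 0.8,
duplicate clustering at 0.9, 200 kb tandem window, k = 10 expression
clusters.
"""
from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    seed: int = 1

    # [synth] family proteome
    n_background_proteins: int = 470
    n_family_members: int = 30
    domain_length: int = 48
    domain_identity: float = 0.8
    # [synth] duplicates
    n_dup_pairs: int = 12
    dup_omega: float = 0.5
    dup_identity: float = 0.9
    tandem_fraction: float = 0.6
    n_chromosomes: int = 12
    dup_codons: int = 200
    # [synth] expression
    n_expr_genes: int = 100
    n_expr_samples: int = 20
    expr_dispersion: float = 0.02
    # [synth] grades
    n_plants: int = 10
    grade_probs: tuple[float, ...] = (0.1, 0.2, 0.3, 0.2, 0.2)

    # [search]
    evalue: float = 1e-2
    inclusion: float = 1e-2
    max_iter: int = 10
    pseudocount: float = 1.0
    # [cluster]
    redundancy_identity: float = 0.8
    # [domains]
    domain_evalue: float = 1e-2
    # [dups]
    duplicate_identity: float = 0.9
    tandem_max_gap: int = 200_000
    # [expression]
    k_clusters: int = 10
    row_scaling: str = "zscore"
    expressed_threshold: float = 1.0
    ubiquitous_fraction: float = 1.0
    tau_specific: float = 0.85

    _SECTIONS = {
        "synth": {
            "seed", "n_background_proteins", "n_family_members", "domain_length",
            "domain_identity", "n_dup_pairs", "dup_omega", "dup_identity",
            "tandem_fraction", "n_chromosomes", "dup_codons", "n_expr_genes",
            "n_expr_samples", "expr_dispersion", "n_plants", "grade_probs",
        },
        "search": {"evalue", "inclusion", "max_iter", "pseudocount"},
        "cluster": {"redundancy_identity"},
        "domains": {"domain_evalue"},
        "dups": {"duplicate_identity", "tandem_max_gap"},
        "expression": {
            "k_clusters", "row_scaling", "expressed_threshold",
            "ubiquitous_fraction", "tau_specific",
        },
    }

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(f"config file not found: {path}")
        kwargs: dict = {}
        known_fields = {f.name: f for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        for section in parser.sections():
            if section not in cls._SECTIONS:
                raise ValueError(f"unknown config section [{section}]")
            for key, raw in parser.items(section):
                if key not in cls._SECTIONS[section]:
                    raise ValueError(f"unknown key {key!r} in section [{section}]")
                f = known_fields[key]
                if key == "grade_probs":
                    kwargs[key] = tuple(float(x) for x in raw.split(","))
                elif f.type in ("int", int):
                    kwargs[key] = int(raw)
                elif f.type in ("float", float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["grade_probs"] = list(out["grade_probs"])
        return out

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()
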