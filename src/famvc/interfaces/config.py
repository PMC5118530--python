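"""Run configuration: schema, YAML loading, validation, provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..errors import ConfigurationError
from ..simdata import ALL_TRAITS, PedigreeTemplate, SimConfig


@dataclass
class RunConfig:
    """Everything a full pipeline run needs besides the seed and out dir.

    Either ``simulate`` holds keyword overrides for :class:`SimConfig` (a
    synthetic dataset is generated), or the three input paths must resolve
    to existing files.
    """

    simulate: dict | None = None
    pedigree: str | None = None
    genotypes: str | None = None
    phenotypes: str | None = None
    traits: list[str] = field(default_factory=lambda: list(ALL_TRAITS))
    mga_alpha: float = 0.05
    interaction_alpha: float = 0.2
    ps_threshold: float = 4.3010
    msa_snps: list[str] | None = None  # explicit candidate set for model search
    msa_max: int = 11
    n_pcs: int = 4
    ne: str | float = "auto"
    snp_sets: dict[str, list[str]] = field(default_factory=dict)
    modifiers: list[str] = field(default_factory=lambda: ["age45", "sex"])
    run_interactions: bool = True
    run_bqtn: bool = True
    run_burden: bool = True

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("pedigree", "genotypes", "phenotypes"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigurationError(
                        f"either 'simulate' or input path {name!r} is required"
                    )
                if not Path(p).exists():
                    raise ConfigurationError(f"{name} path does not exist: {p}")
        for alpha, name in (
            (self.mga_alpha, "mga_alpha"),
            (self.interaction_alpha, "interaction_alpha"),
        ):
            if not 0.0 < alpha < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.ps_threshold < 0:
            raise ConfigurationError("ps_threshold must be >= 0")
        if self.ne != "auto" and float(self.ne) <= 1:
            raise ConfigurationError("ne must be 'auto' or a number > 1")
        if not self.traits:
            raise ConfigurationError("trait list is empty")

    # ------------------------------------------------------------ simulation
    def sim_config(self, seed: int) -> SimConfig:
        kwargs = dict(self.simulate or {})
        tpl = kwargs.pop("pedigree_template", None)
        if isinstance(tpl, dict):
            if "grandchildren_choices" in tpl:
                tpl["grandchildren_choices"] = tuple(tpl["grandchildren_choices"])
            tpl = PedigreeTemplate(**tpl)
        cfg = SimConfig(rng_seed=seed, **kwargs)
        if tpl is not None:
            cfg.pedigree_template = tpl
        cfg.validate()
        return cfg

    # ------------------------------------------------------------ provenance
    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: top-level YAML must be a mapping")
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg
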