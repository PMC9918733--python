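"""Run-level configuration: every stage's parameters in one YAML-loadable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cell_calling import CellCallingParams
from .genotyping import GenotypeParams, VariantFilterParams
from .ploidy import PloidyParams
from .qc import SnpSelectionParams
from .types import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All stage parameters with defaults, a random seed, and I/O paths.

    Stage defaults are the workflow's standard thresholds; any subset can be
    overridden in the YAML file, e.g.::

        seed: 7
        genotyping: {min_depth: 5, min_alt: 3}
        variant_filter: {whitelist_genes: [SMAD4, CDKN2A]}
    """

    seed: int = 0
    input_path: str | None = None
    output_dir: str | None = None
    cell_calling: CellCallingParams = field(default_factory=CellCallingParams)
    genotyping: GenotypeParams = field(default_factory=GenotypeParams)
    variant_filter: VariantFilterParams = field(default_factory=VariantFilterParams)
    snp_selection: SnpSelectionParams = field(default_factory=SnpSelectionParams)
    ploidy: PloidyParams = field(default_factory=PloidyParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        sections = {
            "cell_calling": CellCallingParams,
            "genotyping": GenotypeParams,
            "variant_filter": VariantFilterParams,
            "snp_selection": SnpSelectionParams,
            "ploidy": PloidyParams,
        }
        kwargs: dict[str, object] = {}
        for key, value in raw.items():
            if key in sections:
                if not isinstance(value, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                if key == "variant_filter" and "whitelist_genes" in value:
                    value = dict(value, whitelist_genes=frozenset(value["whitelist_genes"]))
                kwargs[key] = sections[key](**value)
            elif key in ("seed", "input_path", "output_dir"):
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown config key {key!r}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["variant_filter"]["whitelist_genes"] = sorted(
            self.variant_filter.whitelist_genes
        )
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
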