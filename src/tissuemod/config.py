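"""Pipeline configuration: one object holding every stage threshold.

Defaults are the study's stated operating points where it states one
(deg_alpha 0.05, module |r| > 0.6 with p < 0.05, |GS| > 0.6, |kME| > 0.8,
rra_alpha 0.05, +/-20 kb GWAS window, 98th-percentile TOM scaling, soft
powers 1-20) and documented conventions elsewhere (min module size 30,
eigengene merge cut 0.25, dendrogram cut height 0.995).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import yaml

from .dataset import ConfigError

log = logging.getLogger("tissuemod")


@dataclass(frozen=True)
class PipelineConfig:
    deg_alpha: float = 0.05
    confounder_alpha: float = 0.05
    covariates: tuple = ()
    confounders: tuple = (("age", "continuous"), ("sex", "binary"))
    module_r: float = 0.6
    module_alpha: float = 0.05
    gs_min: float = 0.6
    kme_min: float = 0.8
    rra_alpha: float = 0.05
    gwas_window: int = 20_000
    quantile: float = 0.98
    powers: tuple = tuple(range(1, 21))
    power_override: int | None = None  # fixed soft power instead of the scan
    fit_target: float = 0.8
    signed_network: bool = False
    min_module_size: int = 30
    merge_cut: float = 0.25
    cut_height: float = 0.995
    combine_mode: str = "union"
    evidence_require_both: bool = False
    case_only: bool = True
    seed: int = 0
    log_level: str = "INFO"

    _DOMAINS = {
        "deg_alpha": (0.0, 1.0), "confounder_alpha": (0.0, 1.0),
        "module_r": (0.0, 1.0), "module_alpha": (0.0, 1.0),
        "gs_min": (0.0, 1.0), "kme_min": (0.0, 1.0), "rra_alpha": (0.0, 1.0),
        "quantile": (0.0, 1.0), "fit_target": (-1.0, 1.0),
        "merge_cut": (0.0, 1.0), "cut_height": (0.0, 1.0),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._DOMAINS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")
        if self.gwas_window < 0:
            raise ConfigError("gwas_window must be >= 0")
        if self.min_module_size < 1:
            raise ConfigError("min_module_size must be >= 1")
        if any(p < 1 for p in self.powers):
            raise ConfigError("soft powers must be >= 1")
        if self.combine_mode not in ("union", "intersect"):
            raise ConfigError("combine_mode must be 'union' or 'intersect'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["powers"] = list(self.powers)
        d["covariates"] = list(self.covariates)
        d["confounders"] = [list(c) for c in self.confounders]
        return d

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed (< 2**31) from the root seed so every
        stage is independently reproducible.  Uses a stable CRC of the
        stage name (process-salted ``hash`` would break determinism)."""
        import zlib

        key = zlib.crc32(stage.encode("utf-8"))
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % 2**31)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from an optional YAML file plus keyword
    overrides (CLI flags win over file values).  Every default filling an
    unset field is logged."""
    values = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - valid
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    for name in ("powers", "covariates"):
        if name in values and isinstance(values[name], list):
            values[name] = tuple(values[name])
    if "confounders" in values:
        values["confounders"] = tuple(tuple(c) for c in values["confounders"])
    cfg = replace(PipelineConfig(), **values)
    cfg.validate()
    for f in fields(PipelineConfig):
        if f.name not in values:
            log.debug("config: %s defaulted to %r", f.name, getattr(cfg, f.name))
    return cfg
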