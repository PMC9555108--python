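"""Run configuration: YAML schema, defaults, validation.

A run config names either a synthetic design (``simulate:`` block, keys of
:class:`~cfhydroxy.simulate.SimConfig`) or an existing ``sample_sheet``
plus ``genome`` table, the region-universe and threshold conventions, and
optional named contrasts (e.g. IP = PT-DLBCL + PCNS-DLBCL vs the rest).
Unknown keys are rejected and cross-references (contrast groups, file
paths) are checked before any compute starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .simulate import SimConfig

__all__ = ["RunConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """A configuration problem, reported before any pipeline stage runs."""


_TOP_KEYS = {
    "seed",
    "universe",
    "preset",
    "alpha",
    "fc_min",
    "adjustment",
    "pseudocount",
    "min_replicates",
    "bin_size",
    "contrasts",
    "simulate",
    "sample_sheet",
    "genome",
    "exclude_groups",
}


@dataclass
class RunConfig:
    seed: int = 0
    universe: str = "merged_hmr"  # consensus_hmr | merged_hmr | tiles_1kb
    preset: str | None = "methods"  # methods | results | None (explicit thresholds)
    alpha: float = 0.05
    fc_min: float = 2.0
    adjustment: str = "bonferroni"
    pseudocount: float = 0.5
    min_replicates: int = 2
    bin_size: int = 1000
    contrasts: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    simulate: SimConfig | None = None
    sample_sheet: str | None = None
    genome: str | None = None
    exclude_groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.universe not in ("consensus_hmr", "merged_hmr", "tiles_1kb"):
            raise ConfigError(f"unknown universe {self.universe!r}")
        if self.preset not in (None, "methods", "results"):
            raise ConfigError(f"unknown preset {self.preset!r}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigError(f"alpha out of range: {self.alpha}")
        if self.fc_min < 1.0:
            raise ConfigError(f"fc_min must be >= 1, got {self.fc_min}")
        if self.adjustment not in ("bonferroni", "none"):
            raise ConfigError(f"unknown adjustment {self.adjustment!r}")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        if self.min_replicates < 1:
            raise ConfigError("min_replicates must be >= 1")
        if self.simulate is None and self.sample_sheet is None:
            raise ConfigError("config needs either a 'simulate' block or a 'sample_sheet'")
        groups = self._known_groups()
        for cname, sides in self.contrasts.items():
            if set(sides) - {"focal", "other"}:
                raise ConfigError(
                    f"contrast {cname!r}: keys must be 'focal' and optional 'other'"
                )
            if "focal" not in sides or not sides["focal"]:
                raise ConfigError(f"contrast {cname!r}: non-empty 'focal' required")
            if groups is not None:
                for g in sides.get("focal", []) + sides.get("other", []):
                    if g not in groups:
                        raise ConfigError(
                            f"contrast {cname!r} references unknown group {g!r}"
                        )
        if groups is not None:
            for g in self.exclude_groups:
                if g not in groups:
                    raise ConfigError(f"exclude_groups names unknown group {g!r}")

    def _known_groups(self) -> list[str] | None:
        if self.simulate is not None:
            return list(self.simulate.group_names)
        return None  # resolved against the sample sheet at run time

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = self.simulate.to_dict() if self.simulate else None
        return d


def validate_config(source: str | Path | Mapping) -> RunConfig:
    """Parse and validate a YAML file (or mapping) into a RunConfig."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    raw = dict(raw)
    sim_raw = raw.pop("simulate", None)
    sim = None
    if sim_raw is not None:
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        unknown_sim = set(sim_raw) - sim_fields
        if unknown_sim:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown_sim)}")
        try:
            sim = SimConfig.from_dict(sim_raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid simulate block: {exc}") from exc
    try:
        cfg = RunConfig(simulate=sim, **raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    # the synthetic seed follows the run seed unless set explicitly
    if cfg.simulate is not None and sim_raw is not None and "seed" not in sim_raw:
        cfg.simulate = dataclasses.replace(cfg.simulate, seed=cfg.seed)
    return cfg
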