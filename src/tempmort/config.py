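"""Run configuration: model variant, lag length, trend smoothness, Monte
Carlo settings and the decade grid, loadable from a YAML document."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

Decade = tuple[int, int]

DEFAULT_DECADES: tuple[Decade, ...] = tuple((y, y + 9) for y in range(2010, 2100, 10))


@dataclass
class RunConfig:
    model_variant: str = "fixed_knots"
    max_lag: int = 21
    trend_df_per_year: int = 7
    mc_draws: int = 1000
    seed: int = 0
    decades: tuple[Decade, ...] = DEFAULT_DECADES

    def __post_init__(self) -> None:
        if self.model_variant not in ("fixed_knots", "qaic_knots"):
            raise ValueError(f"unknown model_variant {self.model_variant!r}")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.mc_draws < 100:
            raise ValueError("mc_draws must be >= 100")
        decades = tuple((int(a), int(b)) for a, b in self.decades)
        for a, b in decades:
            if b - a != 9:
                raise ValueError(f"decade ({a}, {b}) must span 10 calendar years")
        for (a1, b1), (a2, b2) in zip(decades, decades[1:]):
            if a2 <= b1:
                raise ValueError("decades must be non-overlapping and sorted")
        self.decades = decades


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are a schema error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    allowed = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)} (allowed: {sorted(allowed)})")
    if "decades" in raw:
        raw["decades"] = tuple(tuple(d) for d in raw["decades"])
    return RunConfig(**raw)
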