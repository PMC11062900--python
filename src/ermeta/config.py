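"""Run configuration shared across the pipeline stages.

A single :class:`RunConfig` object carries the growing-season definition,
the outlier rule, the Monte Carlo settings for the spatial upscaling and
the mineral-soil classification thresholds, plus the root random seed from
which every stage derives its substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

#: Growing-season months used when a site has no explicit override
#: (June-August; southern-hemisphere sites override, e.g. October-February).
DEFAULT_SEASON = frozenset({6, 7, 8})


@dataclass
class RunConfig:
    """Pipeline configuration.

    Parameters
    ----------
    growing_season_months
        Mapping from site_id to the set of calendar months that count as
        growing season for that site. Sites not listed use ``default_season``.
    outlier_k
        Half-width of the outlier band in units of the within-dataset
        standard deviation (observations outside mean +/- k*sd are dropped).
    mc_draws
        Number of Monte Carlo soil samples per grid cell in the upscaling.
    truncation_fraction
        Lower truncation bound for soil sampling, as a fraction of the cell
        mean (avoids non-positive TN/SOC draws).
    tn_soc_correlation
        Correlation of the bivariate normal used to sample TN and SOC.
    tn_max, soc_max, bd_min
        Mineral-layer classification thresholds in g/g, g/g and g/cm3: a
        depth interval is mineral iff TN <= tn_max, SOC <= soc_max and
        BD >= bd_min.
    depth_max
        Bottom of the soil profile considered, in cm.
    seed
        Root seed; all stage-level generators are spawned from it.
    """

    growing_season_months: Mapping[str, frozenset] = field(default_factory=dict)
    default_season: frozenset = DEFAULT_SEASON
    outlier_k: float = 3.0
    mc_draws: int = 100
    truncation_fraction: float = 0.05
    tn_soc_correlation: float = 0.8273
    tn_max: float = 0.01
    soc_max: float = 0.1
    bd_min: float = 1.0
    depth_max: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mc_draws < 2:
            raise ValueError("mc_draws must be >= 2")
        if not 0.0 < self.truncation_fraction < 1.0:
            raise ValueError("truncation_fraction must be in (0, 1)")
        if not abs(self.tn_soc_correlation) < 1.0:
            raise ValueError("|tn_soc_correlation| must be < 1")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be > 0")
        self.growing_season_months = {
            str(k): frozenset(int(m) for m in v)
            for k, v in dict(self.growing_season_months).items()
        }

    def season_for(self, site_id: str) -> frozenset:
        """Growing-season month set for ``site_id``."""
        return self.growing_season_months.get(str(site_id), self.default_season)

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the root seed.

        Each pipeline stage names itself (e.g. ``"upscale"``) so that adding
        draws in one stage never perturbs another.
        """
        ss = np.random.SeedSequence(self.seed, spawn_key=(abs(hash(stage)) % (2**31),))
        return np.random.default_rng(ss)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["growing_season_months"] = {
            k: sorted(v) for k, v in self.growing_season_months.items()
        }
        d["default_season"] = sorted(self.default_season)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "default_season" in d:
            d["default_season"] = frozenset(d["default_season"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
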