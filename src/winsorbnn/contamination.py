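"""Heavy-tailed contamination: additive i.i.d. Cauchy noise at chosen sites.

The contamination design has four sites — ``none``, ``target``,
``features``, ``both`` — and operates on designated splits (by default the
training and validation rows; adding ``test`` gives the contaminated
test-set condition).  Draws come from independent per-row streams keyed by
(seed, row index, site), so whether a row's split is contaminated never
shifts the draws any other row receives, and the draws for the target are
independent of the draws for the features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet

import numpy as np

from .datasets import Dataset, SPLIT_LABELS

NOISE_SITES = ("none", "target", "features", "both")


@dataclass(frozen=True)
class NoiseConfig:
    """Where, how strongly and under which seed to contaminate."""

    site: str = "none"
    location: float = 0.0
    scale: float = 1.0            # 1.0 => standard Cauchy
    subsets: FrozenSet[str] = frozenset({"train", "val"})
    seed: int = 0

    def __post_init__(self):
        if self.site not in NOISE_SITES:
            raise ValueError(f"unknown noise site {self.site!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not set(self.subsets) <= set(SPLIT_LABELS):
            raise ValueError("subsets must be within {train, val, test}")

    def to_dict(self) -> dict:
        return {"site": self.site, "location": self.location,
                "scale": self.scale, "subsets": sorted(self.subsets),
                "seed": self.seed}

    @staticmethod
    def from_dict(d: dict) -> "NoiseConfig":
        return NoiseConfig(site=d.get("site", "none"),
                           location=d.get("location", 0.0),
                           scale=d.get("scale", 1.0),
                           subsets=frozenset(d.get("subsets", ("train", "val"))),
                           seed=d.get("seed", 0))


def _row_draws(seed: int, row: int, stream: int, size: int,
               location: float, scale: float) -> np.ndarray:
    rng = np.random.default_rng([seed, row, stream])
    return location + scale * rng.standard_cauchy(size)


def add_cauchy_noise(ds: Dataset, cfg: NoiseConfig) -> Dataset:
    """Return a new Dataset with Cauchy noise added at ``cfg.site``.

    Rows outside ``cfg.subsets`` are bit-identical to the input; the input
    Dataset is never modified.  Noise is added on the raw (unstandardized)
    scale.
    """
    out = ds.copy()
    if cfg.site == "none":
        return out
    rows = np.flatnonzero(ds.mask(*cfg.subsets))
    for r in rows:
        if cfg.site in ("target", "both"):
            out.target[r] += _row_draws(cfg.seed, int(r), 0, 1,
                                        cfg.location, cfg.scale)[0]
        if cfg.site in ("features", "both"):
            out.features[r] += _row_draws(cfg.seed, int(r), 1, ds.p,
                                          cfg.location, cfg.scale)
    return out
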