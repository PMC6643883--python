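"""Run configuration for the reconstruction pipeline.

Configuration files are plain ``KEY = value`` text (``#`` comments allowed)
using the upper-case keys listed in :data:`CONFIG_KEYS`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass
class ReconstructionConfig:
    """All tunable parameters of a reconstruction run.

    The segregation cutoffs are the verification thresholds on the fraction
    of 2:2 (tetrad) and 2:1 (triplet) markers; the noisy-data profiles relax
    them because genotyping errors push observed fractions below 1.
    """

    cen_calling: bool = True  # estimate crossover density from the data
    clustering: bool = True  # centromere clustering before the search
    cos_per_mega: float = 6.0  # used when cen_calling is off / fails
    similarity_coefficient: float = 0.2
    d4_pvalue: float = 0.05
    d3_pvalue: float = 0.01
    mi_pvalue: float = 0.05
    seg_cutoff_d4: float = 0.9
    seg_cutoff_d3: float = 0.95
    dup_cutoff: float = 0.05
    max_missing: float = 0.5
    n_permutations: int = 10000
    seed: int = 0
    direct_search_limit: int = 2_000_000  # max 4-combinations for a direct pass
    shadow_seed_limit: int = 20_000  # strongest seed triples extended per shadow pass

    def __post_init__(self) -> None:
        for name in ("d4_pvalue", "d3_pvalue", "mi_pvalue"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        for name in (
            "similarity_coefficient",
            "seg_cutoff_d4",
            "seg_cutoff_d3",
            "dup_cutoff",
            "max_missing",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_permutations < 1000:
            raise ValueError("n_permutations must be >= 1000")

    def replace(self, **kwargs) -> "ReconstructionConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path) -> "ReconstructionConfig":
        values = {}
        known = {f.name.upper(): f for f in fields(cls)}
        with Path(path).open() as fh:
            for i, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path} line {i}: expected KEY = value")
                key, raw = (s.strip() for s in line.split("=", 1))
                f = known.get(key.upper())
                if f is None:
                    raise ValueError(f"{path} line {i}: unknown key {key!r}")
                if f.type == "bool":
                    low = raw.lower()
                    if low in ("true", "yes", "1", "on"):
                        values[f.name] = True
                    elif low in ("false", "no", "0", "off"):
                        values[f.name] = False
                    else:
                        raise ValueError(f"{path} line {i}: bad boolean {raw!r}")
                elif f.type == "int":
                    values[f.name] = int(raw)
                else:
                    values[f.name] = float(raw)
        return cls(**values)

    @classmethod
    def profile(cls, name: str, **overrides) -> "ReconstructionConfig":
        """Named presets for common noise regimes."""
        presets = PROFILES.get(name)
        if presets is None:
            raise ValueError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
        merged = dict(presets)
        merged.update(overrides)
        return cls(**merged)


#: documented presets: noisy genotypes need laxer segregation cutoffs and a
#: slightly higher similarity threshold (larger clusters)
PROFILES: dict[str, dict] = {
    "default": {},
    "noise5": {
        "similarity_coefficient": 0.2,
        "seg_cutoff_d4": 0.75,
        "seg_cutoff_d3": 0.88,
    },
    "noise10": {
        "similarity_coefficient": 0.24,
        "seg_cutoff_d4": 0.6,
        "seg_cutoff_d3": 0.83,
    },
}

CONFIG_KEYS = tuple(f.name.upper() for f in fields(ReconstructionConfig))
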