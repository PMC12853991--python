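"""Central pipeline configuration.

Every numeric threshold used anywhere in the pipeline lives here, so a
run is fully described by one config object (echoed into the run log):
the read-alignment E-value cutoff, scan-hit coverage and E-value
cutoffs, the alignment gap cutoff, genome completeness and clade-size
requirements, prevalence class bounds, taxon abundance thresholds, the
significance level and cross-cohort consistency quota, and the family
delimitation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class PipelineConfig:
    e_max_reads: float = 1e-10          # read-vs-gene E-value cutoff (strict <)
    e_max_scan: float = 0.01            # scan full-sequence E-value (strict <)
    ie_max_scan: float = 0.01           # scan independent E-value (strict <)
    cov_min: float = 0.90               # profile coverage (strict >)
    gap_max: float = 0.30               # alignment gap fraction (>= removed)
    completeness_min: float = 95.0      # genome completeness percent (strict >)
    prevalence_core: float = 0.80       # core above this (strict >)
    prevalence_accessory_low: float = 0.20  # accessory from here (inclusive)
    genus_abundance_min: float = 0.5    # percent, strict >
    species_abundance_min: float = 0.2  # percent, strict >
    clade_min_genomes: int = 100        # strict >
    alpha: float = 0.05
    min_significant_cohorts: int = 2
    d_max: float = 0.6                  # leaf-to-reference path distance
    length_frac_bounds: tuple[float, float] = (0.5, 1.5)
    rpksm_basis: str = "mean"
    seed: int = 0
    cohort_exemptions: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["length_frac_bounds"] = list(self.length_frac_bounds)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "length_frac_bounds" in data:
            data["length_frac_bounds"] = tuple(data["length_frac_bounds"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)


def validate_config(config: PipelineConfig) -> list[str]:
    """Check every invariant; returns a list of violations (empty = ok)."""
    v: list[str] = []
    c = config

    def _unit(name, value, lo=0.0, hi=1.0, strict_lo=False):
        if not (lo < value if strict_lo else lo <= value) or value > hi:
            v.append(f"{name}={value} outside {'(' if strict_lo else '['}{lo}, {hi}]")

    if c.e_max_reads <= 0:
        v.append(f"e_max_reads={c.e_max_reads} must be > 0")
    if c.e_max_scan <= 0:
        v.append(f"e_max_scan={c.e_max_scan} must be > 0")
    if c.ie_max_scan <= 0:
        v.append(f"ie_max_scan={c.ie_max_scan} must be > 0")
    _unit("cov_min", c.cov_min)
    _unit("gap_max", c.gap_max, strict_lo=True)
    if not 0 <= c.completeness_min <= 100:
        v.append(f"completeness_min={c.completeness_min} outside [0, 100]")
    _unit("prevalence_core", c.prevalence_core)
    _unit("prevalence_accessory_low", c.prevalence_accessory_low)
    if c.prevalence_accessory_low > c.prevalence_core:
        v.append("prevalence_accessory_low exceeds prevalence_core")
    if c.genus_abundance_min < 0 or c.species_abundance_min < 0:
        v.append("taxon abundance thresholds must be >= 0")
    if c.clade_min_genomes < 0:
        v.append(f"clade_min_genomes={c.clade_min_genomes} must be >= 0")
    _unit("alpha", c.alpha, strict_lo=True)
    if c.min_significant_cohorts < 1:
        v.append("min_significant_cohorts must be >= 1")
    if c.d_max < 0:
        v.append(f"d_max={c.d_max} must be >= 0")
    lo, hi = c.length_frac_bounds
    if not 0 < lo <= hi:
        v.append(f"length_frac_bounds={c.length_frac_bounds} require 0 < lo <= hi")
    if c.rpksm_basis not in {"mean", "total"}:
        v.append(f"rpksm_basis={c.rpksm_basis!r} must be 'mean' or 'total'")
    return v
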