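"""Configuration objects for the synthetic-data generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


class ConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic survey substrate.

    Defaults mirror a genome-wide family survey at desk scale: a 12-chromosome
    genome carrying 200 family genes, nine tandem clusters (one triple, eight
    pairs), twelve segmentally duplicated pairs, a 24-tissue developmental
    series with two biological replicates, and a phytohormone experiment with
    an untreated control plus NAA, GA3 and KT treatments whose time points are
    pooled at harvest.
    """

    n_chromosomes: int = 12
    genes_per_chromosome: int = 150
    n_family_genes: int = 200
    n_tandem_groups: int = 9
    tandem_gap_bp: Tuple[int, int] = (3_000, 35_000)
    n_segmental_pairs: int = 12
    segmental_offset_bp: int = 500_000
    n_tissues: int = 24
    n_replicates: int = 2
    n_modules: int = 4
    module_size: int = 15
    module_noise_sd: float = 0.15
    de_fraction: float = 0.15
    de_fold: float = 4.0
    hormone_treatments: Tuple[str, ...] = ("NAA", "GA3", "KT")
    seed: int = 0

    # signal model (natural-log scale unless stated); chosen to mimic the
    # magnitude of Affymetrix summary signals so the SE > 500 seed filter and
    # the absent/marginal/present thresholds are meaningful.
    baseline_log_mean: float = 6.7   # exp(6.7) ~ 810 signal units
    baseline_log_sd: float = 1.0
    module_baseline_log_mean: float = 8.0  # exp(8.0) ~ 3000, highly expressed
    module_baseline_log_sd: float = 0.4
    tissue_effect_sd: float = 0.5
    module_profile_sd: float = 1.0
    replicate_noise_sd: float = 0.1
    absent_threshold: float = 100.0
    marginal_threshold: float = 300.0
    promoter_length: int = 2000

    def validate(self) -> "SimConfig":
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "genes_per_chromosome": self.genes_per_chromosome,
            "n_family_genes": self.n_family_genes,
            "n_tandem_groups": self.n_tandem_groups,
            "n_segmental_pairs": self.n_segmental_pairs,
            "n_tissues": self.n_tissues,
            "n_replicates": self.n_replicates,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.module_noise_sd < 0:
            raise ConfigError("module_noise_sd must be >= 0")
        if self.de_fold <= 1:
            raise ConfigError("de_fold must be > 1")
        if not (0 <= self.de_fraction <= 1):
            raise ConfigError("de_fraction must lie in [0, 1]")
        lo, hi = self.tandem_gap_bp
        if not (0 < lo <= hi):
            raise ConfigError("tandem_gap_bp must be an increasing positive range")
        if self.segmental_offset_bp > 500_000:
            raise ConfigError("segmental_offset_bp may not exceed 500000")
        return self

    def to_dict(self) -> dict:
        return asdict(self)
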