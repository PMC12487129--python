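"""Domain types and fixed analysis constants.

The pipeline works on microcosm manipulation experiments: seawater incubated
under six treatments (CL/CD controls, PL/PD predator-reduced, DL diluted,
VL virus-reduced) across four seasons, with genome-resolved relative
abundances measured at the initial (t0) and final (tf) timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import math

SEASONS = ("winter", "spring", "summer", "fall")
TREATMENTS = ("CL", "CD", "PL", "PD", "DL", "VL")
TIMEPOINTS = ("t0", "tf")

#: Experiment duration in hours by season: 36 h incubations in winter and
#: summer, 48 h in spring and fall.
DEFAULT_DURATIONS_H = {"winter": 36.0, "summer": 36.0, "spring": 48.0, "fall": 48.0}

GROWTH_CLASSES = ("fast", "medium", "slow")
IMPUTATION_FLAGS = ("none", "disappeared", "appeared", "absent_both")


class FormatError(ValueError):
    """A file does not conform to the expected tabular/FASTA dialect."""


class ValidationError(ValueError):
    """Parsed values violate a type invariant (range, sign, uniqueness)."""


class ConfigError(ValueError):
    """A configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class Thresholds:
    """Every fixed constant of the analysis, in one place.

    Attributes
    ----------
    breadth_presence : fraction of genome positions that must be covered for
        a genome to count as present in a sample (>= 0.25).
    fedt_fast_h, fedt_slow_h : growth-class boundaries; fast-growers have
        FEDT < 12 h, slow-growers > 120 h, medium in between (inclusive).
    emdt_copio_h : copiotrophs have estimated minimum doubling times < 5 h.
    bloom_abundance_pct : a bloomer crosses this relative abundance (1 %)
        between t0 and tf.
    fu_min_sum_pct : functional units whose percentages summed over all
        genomes fall below 5 are filtered out before testing.
    alpha : significance level for adjusted p-values.
    fc_disappeared, fc_appeared : imputed fold-changes for populations that
        vanish (0.1) or appear (100) between the two timepoints.
    fedt_imputed_h : doubling-time ceiling (500 h) assigned to disappeared
        populations and to any non-positive inferred doubling time.
    asv_min_doubling_h : isolate selection requires a matched ASV doubling
        time of at most one day (24 h).
    intersection_min_size : exclusive treatment intersections smaller than
        this (3) are dropped from the upset-style report.
    """

    breadth_presence: float = 0.25
    fedt_fast_h: float = 12.0
    fedt_slow_h: float = 120.0
    emdt_copio_h: float = 5.0
    bloom_abundance_pct: float = 1.0
    fu_min_sum_pct: float = 5.0
    alpha: float = 0.05
    fc_disappeared: float = 0.1
    fc_appeared: float = 100.0
    fedt_imputed_h: float = 500.0
    asv_min_doubling_h: float = 24.0
    intersection_min_size: int = 3

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ConfigError(f"threshold {name!r} must be positive, got {value}")
        if not self.fedt_fast_h < self.fedt_slow_h:
            raise ConfigError(
                "fedt_fast_h must be below fedt_slow_h "
                f"({self.fedt_fast_h} >= {self.fedt_slow_h})"
            )


@dataclass
class GenomeRecord:
    """Per-genome metadata (quality, size, taxonomy, predicted doubling time).

    ``gene_count`` is the CheckM-predicted number of genes and is the
    denominator for all functional-unit percentages.  ``emdt_h`` is the
    codon-usage-based estimated minimum doubling time; it may be missing
    (``None``), in which case the genome is excluded from trophic
    comparisons.
    """

    genome_id: str
    source: str = "mag"  # isolate | mag
    taxonomy: str = ""
    completeness: float = 100.0
    contamination: float = 0.0
    genome_size: int = 1
    gc: float = 50.0
    gene_count: int = 1
    emdt_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source not in ("isolate", "mag"):
            raise ValidationError(
                f"{self.genome_id}: source must be 'isolate' or 'mag', got {self.source!r}"
            )
        if not 0.0 <= self.completeness <= 100.0:
            raise ValidationError(
                f"{self.genome_id}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0:
            raise ValidationError(
                f"{self.genome_id}: contamination {self.contamination} negative"
            )
        if not 0.0 <= self.gc <= 100.0:
            raise ValidationError(f"{self.genome_id}: G+C {self.gc} outside [0, 100]")
        if self.genome_size <= 0:
            raise ValidationError(f"{self.genome_id}: genome_size must be positive")
        if self.gene_count < 1:
            raise ValidationError(f"{self.genome_id}: gene_count must be >= 1")
        if self.emdt_h is not None:
            if isinstance(self.emdt_h, float) and math.isnan(self.emdt_h):
                self.emdt_h = None
            elif not self.emdt_h > 0:
                raise ValidationError(f"{self.genome_id}: emdt_h must be positive")


@dataclass(frozen=True)
class ExperimentKey:
    """One experiment: a season x treatment incubation of known duration."""

    season: str
    treatment: str
    duration_h: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(f"unknown season {self.season!r}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        if self.duration_h == 0.0:
            object.__setattr__(self, "duration_h", DEFAULT_DURATIONS_H[self.season])
        if not self.duration_h > 0:
            raise ValidationError("duration_h must be positive")
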