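"""Fold-change growth rates and doubling-time classification.

From two-timepoint relative abundances the pipeline infers, per genome and
experiment, a fold-change FC = abundance(tf)/abundance(t0), a growth rate
mu = ln(FC)/T (T the incubation length in hours) and a fold-change-based
experimental doubling time FEDT = ln(2)/mu.  Populations that vanish
between the timepoints receive an arbitrary FC of 0.1 and an FEDT of
500 h; populations that appear receive FC = 100.  Genomes are then called
fast- (< 12 h), medium- (12-120 h) or slow-growers (> 120 h) from the
minimum FEDT over seasons within each treatment.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .types import DEFAULT_DURATIONS_H, Thresholds, ValidationError

GROWTH_COLUMNS = [
    "genome_id",
    "season",
    "treatment",
    "abund_t0_pct",
    "abund_tf_pct",
    "present_t0",
    "present_tf",
    "fold_change",
    "rate_per_h",
    "fedt_h",
    "imputation",
    "fedt_ceiling",
]


def call_presence(
    abundance_pct: float, breadth: float, thresholds: Thresholds = Thresholds()
) -> bool:
    """A genome is present in a sample iff its breadth of coverage is at
    least the presence threshold (default 25 %, inclusive)."""
    if not 0.0 <= breadth <= 1.0:
        raise ValidationError(f"breadth {breadth} outside [0, 1]")
    if abundance_pct < 0:
        raise ValidationError(f"negative abundance {abundance_pct}")
    return breadth >= thresholds.breadth_presence


def compute_fold_change(
    ab_t0: float,
    ab_tf: float,
    present_t0: bool,
    present_tf: bool,
    thresholds: Thresholds = Thresholds(),
) -> tuple[float, str]:
    """Fold-change with the imputation conventions for appearing and
    disappearing populations.

    Returns ``(fold_change, imputation_flag)``; the fold-change is NaN with
    flag ``absent_both`` when the genome is present at neither timepoint.
    """
    if present_t0 and ab_t0 <= 0:
        raise ValidationError(
            f"genome flagged present at t0 with abundance {ab_t0}; inconsistent inputs"
        )
    if present_t0 and present_tf:
        return ab_tf / ab_t0, "none"
    if present_t0 and not present_tf:
        return thresholds.fc_disappeared, "disappeared"
    if present_tf and not present_t0:
        return thresholds.fc_appeared, "appeared"
    return math.nan, "absent_both"


def compute_fedt(
    fold_change: float,
    duration_h: float,
    imputation: str = "none",
    thresholds: Thresholds = Thresholds(),
) -> tuple[float, float]:
    """Growth rate and doubling time from a fold-change over ``duration_h``.

    rate = ln(FC)/T and FEDT = ln(2)/rate.  A disappeared population, and
    any fold-change <= 1 (for which the doubling time would be negative or
    infinite), maps to the 500 h ceiling; the rate is still reported.
    """
    if not fold_change > 0:
        raise ValidationError(f"fold_change must be positive, got {fold_change}")
    if not duration_h > 0:
        raise ValidationError(f"duration_h must be positive, got {duration_h}")
    rate = math.log(fold_change) / duration_h
    if imputation == "disappeared" or fold_change <= 1.0:
        return rate, thresholds.fedt_imputed_h
    return rate, math.log(2.0) / rate


def growth_table(
    abundance: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    durations_h: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """One growth record per genome x season x treatment.

    Replicates are first averaged (arithmetic mean of relative abundance
    and of breadth) within each (season, treatment, timepoint); presence is
    called on the replicate-mean breadth.  A genome missing entirely from a
    sample counts as absent with zero abundance.
    """
    durations = dict(DEFAULT_DURATIONS_H)
    if durations_h:
        durations.update(durations_h)
    if abundance.empty:
        return pd.DataFrame(columns=GROWTH_COLUMNS)

    mean = (
        abundance.groupby(["genome_id", "season", "treatment", "timepoint"])[
            ["abundance_pct", "breadth"]
        ]
        .mean()
        .reset_index()
    )
    wide = mean.pivot_table(
        index=["genome_id", "season", "treatment"],
        columns="timepoint",
        values=["abundance_pct", "breadth"],
    )

    records = []
    for (genome, season, treatment), row in wide.iterrows():
        ab0 = row.get(("abundance_pct", "t0"), math.nan)
        abf = row.get(("abundance_pct", "tf"), math.nan)
        br0 = row.get(("breadth", "t0"), math.nan)
        brf = row.get(("breadth", "tf"), math.nan)
        ab0 = 0.0 if pd.isna(ab0) else float(ab0)
        abf = 0.0 if pd.isna(abf) else float(abf)
        br0 = 0.0 if pd.isna(br0) else float(br0)
        brf = 0.0 if pd.isna(brf) else float(brf)
        p0 = call_presence(ab0, br0, thresholds)
        pf = call_presence(abf, brf, thresholds)
        fc, flag = compute_fold_change(ab0, abf, p0, pf, thresholds)
        if flag == "absent_both":
            rate, fedt = math.nan, math.nan
            ceiling = False
        else:
            rate, fedt = compute_fedt(fc, durations[season], flag, thresholds)
            ceiling = fedt == thresholds.fedt_imputed_h
        records.append(
            {
                "genome_id": genome,
                "season": season,
                "treatment": treatment,
                "abund_t0_pct": ab0,
                "abund_tf_pct": abf,
                "present_t0": p0,
                "present_tf": pf,
                "fold_change": fc,
                "rate_per_h": rate,
                "fedt_h": fedt,
                "imputation": flag,
                "fedt_ceiling": ceiling,
            }
        )
    return pd.DataFrame(records, columns=GROWTH_COLUMNS)


def min_fedt_per_treatment(growth: pd.DataFrame) -> pd.DataFrame:
    """Minimum FEDT over seasons for every (genome, treatment).

    Pairs whose FEDT is undefined in every season (absent at both
    timepoints everywhere) get NaN and are later reported unclassified.
    """
    if growth.empty:
        return pd.DataFrame(columns=["genome_id", "treatment", "min_fedt_h"])
    out = (
        growth.groupby(["genome_id", "treatment"])["fedt_h"]
        .min()  # NaN-skipping: all-NaN groups stay NaN
        .reset_index()
        .rename(columns={"fedt_h": "min_fedt_h"})
    )
    return out


def classify_growth(
    min_fedt_h: float, thresholds: Thresholds = Thresholds()
) -> str:
    """fast iff FEDT < 12 h, slow iff > 120 h, medium otherwise (boundaries
    inclusive to medium); NaN is unclassified."""
    if min_fedt_h is None or (isinstance(min_fedt_h, float) and math.isnan(min_fedt_h)):
        return "unclassified"
    if min_fedt_h < thresholds.fedt_fast_h:
        return "fast"
    if min_fedt_h > thresholds.fedt_slow_h:
        return "slow"
    return "medium"


def classify_growth_table(
    growth: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Per genome x treatment growth classes from the seasonal minimum FEDT."""
    table = min_fedt_per_treatment(growth)
    table["growth_class"] = table["min_fedt_h"].map(
        lambda v: classify_growth(v, thresholds)
    )
    return table


def growth_class_map(
    classes: pd.DataFrame, treatment: str
) -> dict[str, str]:
    """genome_id -> growth class for one treatment, skipping unclassified."""
    sub = classes[
        (classes["treatment"] == treatment)
        & (classes["growth_class"] != "unclassified")
    ]
    return dict(zip(sub["genome_id"], sub["growth_class"]))
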