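"""ASV growth-rate estimation and bloomer-candidate isolate selection.

Amplicon time series give pseudoabundances (relative abundance multiplied
by the flow-cytometry total cell count); the maximal exponential growth
rate of an ASV is the steepest significant slope among ordinary
least-squares fits of ln(pseudoabundance) against time over every
contiguous window of at least three timepoints.  Isolates whose 16S V4-V5
region is string-identical to an ASV that rose from < 1 % to > 1 %
relative abundance with a doubling time of at most one day are selected
as bloomer candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import Thresholds, ValidationError

logger = logging.getLogger("bloomics")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class GrowthFit:
    """The selected log-linear window for one ASV series."""

    asv_id: str
    start_index: int  # indices into the surviving (positive) timepoints
    end_index: int  # inclusive
    slope_per_h: float
    intercept: float
    p_value: float

    @property
    def doubling_time_h(self) -> float:
        """ln(2)/slope; NaN for non-growing (non-positive slope) fits."""
        if self.slope_per_h > 0:
            return math.log(2.0) / self.slope_per_h
        return math.nan


def pseudoabundance(
    relative_abundance: Sequence[float], total_cells: Sequence[float]
) -> np.ndarray:
    """Relative abundances scaled by total cell counts (cells/mL)."""
    rel = np.asarray(relative_abundance, dtype=float)
    tot = np.asarray(total_cells, dtype=float)
    if np.any(tot <= 0):
        raise ValidationError("total cell counts must be positive")
    if np.any(rel < 0):
        raise ValidationError("relative abundances must be non-negative")
    return rel * tot


def fit_max_growth(
    times_h: Sequence[float],
    pseudo: Sequence[float],
    alpha: float = 0.05,
    asv_id: str = "",
) -> Optional[GrowthFit]:
    """Steepest significant log-linear slope over contiguous windows.

    Zero-pseudoabundance points are excluded first; windows are contiguous
    runs of at least three surviving points.  Among windows whose slope has
    a two-sided t-test p below ``alpha``, the one with the maximum slope is
    returned (ties: smaller p, then earlier start).  Returns ``None`` when
    no window qualifies; an all-zero series yields ``None`` with a warning.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(pseudo, dtype=float)
    if len(t) != len(y):
        raise ValidationError("times and pseudoabundances differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("timepoints must be strictly increasing")
    keep = y > 0
    if not keep.any():
        logger.warning("ASV %s: all-zero series, no fit", asv_id)
        return None
    t, y = t[keep], y[keep]
    if len(t) < 3:
        return None
    lny = np.log(y)

    best: Optional[GrowthFit] = None
    for start in range(0, len(t) - 2):
        for stop in range(start + 3, len(t) + 1):
            res = stats.linregress(t[start:stop], lny[start:stop])
            p = float(res.pvalue)
            if not p < alpha:
                continue
            candidate = GrowthFit(
                asv_id=asv_id,
                start_index=start,
                end_index=stop - 1,
                slope_per_h=float(res.slope),
                intercept=float(res.intercept),
                p_value=p,
            )
            if best is None or _better(candidate, best):
                best = candidate
    return best


def _better(a: GrowthFit, b: GrowthFit) -> bool:
    if a.slope_per_h != b.slope_per_h:
        return a.slope_per_h > b.slope_per_h
    if a.p_value != b.p_value:
        return a.p_value < b.p_value
    return a.start_index < b.start_index


def fit_asv_table(
    asv_table: pd.DataFrame,
    cytometry: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every (asv_id, experiment) series of a long-format ASV table.

    ``asv_table`` columns: asv_id, experiment, time_h, rel_abundance_pct;
    ``cytometry`` columns: experiment, time_h, total_cells.
    """
    totals = cytometry.set_index(["experiment", "time_h"])["total_cells"]
    rows = []
    for (asv, experiment), group in asv_table.groupby(["asv_id", "experiment"]):
        group = group.sort_values("time_h")
        t = group["time_h"].to_numpy(dtype=float)
        tot = totals.loc[[(experiment, ti) for ti in t]].to_numpy(dtype=float)
        pseudo = pseudoabundance(group["rel_abundance_pct"].to_numpy(), tot)
        fit = fit_max_growth(t, pseudo, alpha=alpha, asv_id=asv)
        rows.append(
            {
                "asv_id": asv,
                "experiment": experiment,
                "slope_per_h": fit.slope_per_h if fit else math.nan,
                "p_value": fit.p_value if fit else math.nan,
                "doubling_time_h": fit.doubling_time_h if fit else math.nan,
                "window_start": fit.start_index if fit else -1,
                "window_end": fit.end_index if fit else -1,
            }
        )
    return pd.DataFrame(rows)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def match_isolates_to_asvs(
    isolate_seqs: Mapping[str, str],
    asv_seqs: Mapping[str, str],
    region: Optional[tuple[int, int]] = None,
    check_reverse_complement: bool = True,
) -> pd.DataFrame:
    """Exact-identity matches between isolate V4-V5 regions and ASVs.

    ``region`` gives (start, end) coordinates (0-based, end-exclusive) used
    to trim each isolate sequence to the V4-V5 region; ``None`` compares
    the full sequences.  A match requires 100 % string identity, optionally
    after reverse complementing.
    """
    rows = []
    for iso_id, iso_seq in isolate_seqs.items():
        if not iso_seq:
            raise ValidationError(f"isolate {iso_id}: empty sequence")
        trimmed = iso_seq[region[0] : region[1]] if region else iso_seq
        if not trimmed:
            raise ValidationError(f"isolate {iso_id}: empty V4-V5 region after trim")
        rc = reverse_complement(trimmed)
        for asv_id, asv_seq in asv_seqs.items():
            if not asv_seq:
                raise ValidationError(f"ASV {asv_id}: empty sequence")
            if trimmed == asv_seq or (check_reverse_complement and rc == asv_seq):
                rows.append({"isolate_id": iso_id, "asv_id": asv_id})
    return pd.DataFrame(rows, columns=["isolate_id", "asv_id"])


def select_bloomer_isolates(
    matches: pd.DataFrame,
    asv_experiment_abund: pd.DataFrame,
    fits: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> set[str]:
    """Isolates whose matched ASV bloomed in at least one experiment.

    ``asv_experiment_abund`` columns: asv_id, experiment, abund_t0_pct,
    abund_tf_pct; ``fits`` is the output of :func:`fit_asv_table`.  An ASV
    qualifies in an experiment when its abundance rose from < 1 % to > 1 %
    and its fitted doubling time is at most 24 h.
    """
    doubling = fits.set_index(["asv_id", "experiment"])["doubling_time_h"]
    qualifying: set[str] = set()
    for _, row in asv_experiment_abund.iterrows():
        key = (row["asv_id"], row["experiment"])
        dt = doubling.get(key, math.nan)
        if (
            row["abund_t0_pct"] < thresholds.bloom_abundance_pct
            and row["abund_tf_pct"] > thresholds.bloom_abundance_pct
            and not math.isnan(dt)
            and dt <= thresholds.asv_min_doubling_h
        ):
            qualifying.add(row["asv_id"])
    return set(
        matches.loc[matches["asv_id"].isin(qualifying), "isolate_id"]
    )
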