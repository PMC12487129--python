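"""Bloomer identification and comparison against the rest of the copiotrophs.

A genomic population "bloomed" in a given experiment if it was a
fast-grower there (FEDT < 12 h) and became abundant, rising from below 1 %
relative abundance at the initial time to above 1 % at the final time
(both inequalities strict).  A genome is a bloomer overall if it bloomed
in at least one experiment.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .enrichment import bh_adjust, run_enrichment, wilcoxon_rank_sum
from .types import Thresholds

logger = logging.getLogger("bloomics")

TRAITS = ("genome_size", "gc", "emdt_h", "cub")


def call_bloomers(
    growth: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Per genome x season x treatment bloom decisions.

    Input is the growth-record table (with per-experiment replicate-mean
    abundances and FEDTs); output adds an ``is_bloomer`` column.
    """
    calls = growth[
        [
            "genome_id",
            "season",
            "treatment",
            "fedt_h",
            "abund_t0_pct",
            "abund_tf_pct",
        ]
    ].copy()
    calls["is_bloomer"] = (
        (calls["fedt_h"] < thresholds.fedt_fast_h)
        & (calls["abund_t0_pct"] < thresholds.bloom_abundance_pct)
        & (calls["abund_tf_pct"] > thresholds.bloom_abundance_pct)
    ).fillna(False)
    return calls


def bloomer_genomes(calls: pd.DataFrame) -> set[str]:
    """Genomes that bloomed in at least one experiment."""
    return set(calls.loc[calls["is_bloomer"], "genome_id"])


def compare_bloomers_to_copiotrophs(
    bloomers: Iterable[str],
    trophic: pd.DataFrame,
    genomes: pd.DataFrame,
    fu_table: Optional[pd.DataFrame] = None,
    thresholds: Thresholds = Thresholds(),
) -> dict[str, pd.DataFrame]:
    """Genomic-trait and functional comparison of bloomers vs the
    non-blooming copiotrophs.

    Traits (genome size, G+C, EMDT, CUB) are compared with Wilcoxon
    rank-sum tests, BH-corrected across the traits; FU enrichment reuses
    :func:`run_enrichment` with the ``bloomer_vs_copio`` comparison.
    Returns ``{"traits": ..., "enrichment": ...}``; either frame is empty,
    with a warning, if a group has fewer than two members.
    """
    bloomer_set = set(bloomers)
    copio = set(trophic.loc[trophic["strategy"] == "copiotroph", "genome_id"])
    rest = copio - bloomer_set
    merged = genomes.merge(
        trophic[["genome_id", "cub"]], on="genome_id", how="left"
    ).set_index("genome_id")

    traits = pd.DataFrame(
        columns=["trait", "mean_bloomer", "mean_copio", "delta", "p_raw", "p_adj"]
    )
    in_table = [g for g in merged.index]
    g1 = [g for g in in_table if g in bloomer_set]
    g2 = [g for g in in_table if g in rest]
    if len(g1) < 2 or len(g2) < 2:
        logger.warning(
            "bloomer comparison skipped: %d bloomers vs %d other copiotrophs",
            len(g1),
            len(g2),
        )
    else:
        rows = []
        for trait in TRAITS:
            x = merged.loc[g1, trait].astype(float).dropna().to_numpy()
            y = merged.loc[g2, trait].astype(float).dropna().to_numpy()
            if len(x) < 2 or len(y) < 2:
                logger.warning("trait %s: too few values; skipped", trait)
                continue
            rows.append(
                {
                    "trait": trait,
                    "mean_bloomer": float(np.mean(x)),
                    "mean_copio": float(np.mean(y)),
                    "delta": float(np.mean(x) - np.mean(y)),
                    "p_raw": wilcoxon_rank_sum(x, y),
                }
            )
        if rows:
            traits = pd.DataFrame(rows)
            traits["p_adj"] = bh_adjust(traits["p_raw"].to_numpy())

    if fu_table is not None:
        group_map = {g: "bloomer" for g in bloomer_set}
        group_map.update({g: "copio" for g in rest})
        enrichment = run_enrichment(
            fu_table,
            group_map,
            "bloomer",
            "copio",
            comparison="bloomer_vs_copio",
            thresholds=thresholds,
        )
    else:
        enrichment = pd.DataFrame()
    return {"traits": traits, "enrichment": enrichment}
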