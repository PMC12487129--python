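"""Functional-unit percentage tables and rank-sum enrichment testing.

Gene counts per functional unit (FU: a COG, Pfam, KEGG Ortholog or CAZY
identifier; COG and CAZY categories are aggregated the same way) are
normalised by each genome's CheckM-predicted gene count and expressed as
percentages.  Group differences (fast vs slow growers, copiotrophs vs
oligotrophs, bloomers vs the rest of the copiotrophs) are tested per FU
with two-sided Wilcoxon rank-sum tests under Benjamini-Hochberg FDR
control; the direction of enrichment is read off the sign of the group
mean difference.

The rank-sum p-value is exact whenever the smaller group has at most
eight members: the null distribution of the midrank sum is built by
dynamic programming over all label assignments, which handles ties
correctly and agrees with brute-force enumeration.  Larger samples use
the tie- and continuity-corrected normal approximation.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.special import comb

from .types import Thresholds, ValidationError

logger = logging.getLogger("bloomics")

SYSTEMS = ("COG", "Pfam", "KO", "CAZY", "COG_category", "CAZY_category")

_SYSTEM_COLUMNS = {
    "COG": "cog_ids",
    "Pfam": "pfam_ids",
    "KO": "ko_ids",
    "CAZY": "cazy_ids",
}

#: Biogeochemical marker genes named in the screen, mapped to KEGG
#: Orthologs.  The map is a default; callers may extend or override it.
DEFAULT_BIOGEO_MARKERS: dict[str, tuple[str, ...]] = {
    "pstS": ("K02040",),
    "phoA": ("K01077",),
    "phoD": ("K01113",),
    "pit": ("K03306",),
    "ptxD": ("K18916",),
    "coxL": ("K03520",),
    "gdhA": ("K00262",),
    "coxA": ("K02274",),
    "cyoA": ("K02297",),
    "amt": ("K03320",),
    "pufM": ("K08929",),
    "prd": ("K07883",),
}

ENRICHMENT_COLUMNS = [
    "fu_id",
    "system",
    "treatment",
    "comparison",
    "mean_pct_g1",
    "mean_pct_g2",
    "delta",
    "p_raw",
    "p_adj",
    "direction",
    "significant",
]


# ---------------------------------------------------------------------------
# percentage tables


def _fu_lists(annotations: pd.DataFrame, system: str) -> pd.Series:
    if system in _SYSTEM_COLUMNS:
        return annotations[_SYSTEM_COLUMNS[system]]
    if system == "COG_category":
        # a gene with category string "KT" counts once for K and once for T
        return annotations["cog_categories"].map(lambda s: list(s) if s else [])
    if system == "CAZY_category":
        # CAZY class = leading letters of the family accession (GH13 -> GH)
        def classes(ids: list[str]) -> list[str]:
            out = []
            for fam in ids:
                prefix = "".join(itertools.takewhile(str.isalpha, fam))
                if prefix:
                    out.append(prefix)
            return out

        return annotations["cazy_ids"].map(classes)
    raise ValueError(f"unknown annotation system {system!r}; expected one of {SYSTEMS}")


def build_percent_table(
    annotations: pd.DataFrame,
    genomes: pd.DataFrame,
    system: str,
) -> pd.DataFrame:
    """Genome x FU matrix of gene percentages for one annotation system.

    Each gene contributes one count to every FU it maps to within the
    system; percentage = 100 * count / gene_count (CheckM-predicted).
    The result carries ``.attrs['system']``.
    """
    gene_counts = dict(zip(genomes["genome_id"], genomes["gene_count"]))
    unknown = set(annotations["genome_id"]) - set(gene_counts)
    if unknown:
        raise ValidationError(
            f"annotated genomes missing from metadata: {sorted(unknown)[:10]}"
        )
    fus = _fu_lists(annotations, system)
    expanded = pd.DataFrame(
        {
            "genome_id": annotations["genome_id"].repeat(fus.str.len()),
            "fu_id": list(itertools.chain.from_iterable(fus)),
        }
    )
    if expanded.empty:
        counts = pd.DataFrame(index=pd.Index(sorted(gene_counts), name="genome_id"))
    else:
        counts = (
            expanded.groupby(["genome_id", "fu_id"])
            .size()
            .unstack(fill_value=0)
            .reindex(index=sorted(gene_counts), fill_value=0)
        )
        counts.index.name = "genome_id"
    denom = pd.Series(gene_counts).reindex(counts.index).astype(float)
    table = counts.div(denom, axis=0) * 100.0
    table = table[sorted(table.columns)]
    table.attrs["system"] = system
    return table


def filter_low_fus(
    table: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Drop FUs whose percentages summed over all genomes fall below the
    5 % noise floor (boundary inclusive: a sum of exactly 5 is kept)."""
    keep = table.columns[table.sum(axis=0) >= thresholds.fu_min_sum_pct]
    out = table[keep]
    out.attrs.update(table.attrs)
    return out


# ---------------------------------------------------------------------------
# rank-sum test and FDR control

_EXACT_MIN_N = 8


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for the midrank sum of ``x``.

    Counts, by dynamic programming over the C(n1+n2, n1) label assignments,
    the probability of a rank sum at least as far from its null mean as the
    observed one.  Midranks make the enumeration valid under ties.
    """
    n1 = len(x)
    pooled = np.concatenate([x, y])
    n = len(pooled)
    doubled = np.rint(2.0 * stats.rankdata(pooled)).astype(int)
    w_obs = int(doubled[:n1].sum())
    mu = n1 * (n + 1)  # mean of the doubled-rank sum
    dev = abs(w_obs - mu)

    # subset-sum DP: table[k, s] = number of k-subsets with doubled-rank sum s
    max_sum = int(doubled.sum())
    table = np.zeros((n1 + 1, max_sum + 1))
    table[0, 0] = 1.0
    for value in doubled:
        for k in range(n1, 0, -1):
            table[k, value:] += table[k - 1, : max_sum + 1 - value]
    counts = table[n1]
    sums = np.arange(max_sum + 1)
    extreme = np.abs(sums - mu) >= dev - 1e-9
    total = comb(n, n1, exact=True)
    return min(1.0, float(counts[extreme].sum()) / total)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation distribution when min(|x|, |y|) <= 8 (ties handled by
    midranks); otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if min(len(x), len(y)) <= _EXACT_MIN_N:
        return _exact_ranksum_p(x, y)
    result = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(result.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# enrichment drivers


def _test_frame(
    table: pd.DataFrame,
    g1_ids: list[str],
    g2_ids: list[str],
    comparison: str,
    treatment: str,
) -> pd.DataFrame:
    system = table.attrs.get("system", "")
    sub1 = table.loc[g1_ids]
    sub2 = table.loc[g2_ids]
    rows = []
    for fu in table.columns:
        x = sub1[fu].to_numpy()
        y = sub2[fu].to_numpy()
        p = wilcoxon_rank_sum(x, y)
        m1, m2 = float(x.mean()), float(y.mean())
        rows.append(
            {
                "fu_id": fu,
                "system": system,
                "treatment": treatment,
                "comparison": comparison,
                "mean_pct_g1": m1,
                "mean_pct_g2": m2,
                "delta": m1 - m2,
                "p_raw": p,
            }
        )
    return pd.DataFrame(rows)


def run_enrichment(
    table: pd.DataFrame,
    group_map: Mapping[str, str],
    group1: str,
    group2: str,
    comparison: str = "",
    treatment: str = "all",
    thresholds: Thresholds = Thresholds(),
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Per-FU rank-sum tests between two genome groups with BH correction.

    The BH family is all FUs of the table (one annotation system) within
    this treatment x comparison.  Genomes not labelled ``group1``/``group2``
    (e.g. medium-growers in a fast-vs-slow comparison) are excluded.
    Returns an empty frame, with a warning, if either group has fewer than
    two members.  Results are sorted by |delta| descending (stable).
    """
    comparison = comparison or f"{group1}_vs_{group2}"
    g1 = [g for g in table.index if group_map.get(g) == group1]
    g2 = [g for g in table.index if group_map.get(g) == group2]
    if len(g1) < 2 or len(g2) < 2:
        logger.warning(
            "comparison %s (%s): group sizes %d vs %d below 2; skipped",
            comparison,
            treatment,
            len(g1),
            len(g2),
        )
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out = _test_frame(table, g1, g2, comparison, treatment)
    if out.empty:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["direction"] = np.sign(out["delta"]).astype(int)
    decisive = out["p_adj"] if use_adjusted else out["p_raw"]
    out["significant"] = decisive < thresholds.alpha
    out = out.sort_values(
        by=["delta", "fu_id"],
        key=lambda col: -col.abs() if col.name == "delta" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    return out[ENRICHMENT_COLUMNS]


def significant_fus(results: pd.DataFrame, enriched_in_g1: bool = True) -> set[str]:
    """FUs significantly enriched in group 1 (positive delta) or group 2."""
    if results.empty:
        return set()
    sign = results["delta"] > 0 if enriched_in_g1 else results["delta"] < 0
    return set(results.loc[results["significant"] & sign, "fu_id"])


def pairwise_wilcoxon(
    table: pd.DataFrame,
    group_map: Mapping[str, str],
    treatment: str = "all",
    thresholds: Thresholds = Thresholds(),
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """All unordered pairwise comparisons among three or more groups.

    BH correction is applied across every FU x pair test of the call (one
    family per annotation system).  Pairs with a group below two members
    are skipped with a warning.
    """
    labels = sorted({v for g, v in group_map.items() if g in table.index})
    frames = []
    for a, b in itertools.combinations(labels, 2):
        g1 = [g for g in table.index if group_map.get(g) == a]
        g2 = [g for g in table.index if group_map.get(g) == b]
        if len(g1) < 2 or len(g2) < 2:
            logger.warning(
                "pair %s vs %s (%s): group below 2 members; skipped", a, b, treatment
            )
            continue
        frames.append(_test_frame(table, g1, g2, f"{a}_vs_{b}", treatment))
    if not frames:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["direction"] = np.sign(out["delta"]).astype(int)
    decisive = out["p_adj"] if use_adjusted else out["p_raw"]
    out["significant"] = decisive < thresholds.alpha
    return out[ENRICHMENT_COLUMNS]


# ---------------------------------------------------------------------------
# set intersections and screens


def significant_set_intersections(
    sets: Mapping[str, Iterable[str]],
    thresholds: Thresholds = Thresholds(),
) -> tuple[dict[tuple[str, ...], set[str]], dict[str, int]]:
    """Upset-style exclusive intersections of per-treatment significant sets.

    For every non-empty combination of treatments, collects the FUs found in
    exactly those treatments; combinations with fewer members than the
    minimum size (default 3) are dropped.  Also returns per-treatment
    totals.
    """
    named = {k: set(v) for k, v in sets.items()}
    if not named:
        raise ValidationError("at least one set required")
    membership: dict[str, set[str]] = {}
    for name, members in named.items():
        for fu in members:
            membership.setdefault(fu, set()).add(name)
    exclusive: dict[tuple[str, ...], set[str]] = {}
    for fu, in_sets in membership.items():
        key = tuple(sorted(in_sets))
        exclusive.setdefault(key, set()).add(fu)
    kept = {
        combo: members
        for combo, members in exclusive.items()
        if len(members) >= thresholds.intersection_min_size
    }
    totals = {name: len(members) for name, members in named.items()}
    return kept, totals


def biogeo_screen(
    ko_table: pd.DataFrame,
    growth_classes: pd.DataFrame,
    marker_map: Optional[Mapping[str, Sequence[str]]] = None,
    thresholds: Thresholds = Thresholds(),
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Screen biogeochemical marker genes for growth-class enrichment.

    For each marker gene (the percentages of its KO(s) summed) and each
    treatment, runs pairwise fast/medium/slow rank-sum tests with BH
    correction per treatment; a gene is labelled ``fast_enriched`` or
    ``slow_enriched`` by the sign of the significant fast-vs-slow delta,
    ``neither`` otherwise, and ``not_testable`` when its KOs are absent
    from the table.
    """
    markers = dict(marker_map or DEFAULT_BIOGEO_MARKERS)
    rows = []
    for treatment in sorted(growth_classes["treatment"].unique()):
        sub = growth_classes[
            (growth_classes["treatment"] == treatment)
            & (growth_classes["growth_class"] != "unclassified")
        ]
        class_of = dict(zip(sub["genome_id"], sub["growth_class"]))
        members = {
            cls: [g for g in ko_table.index if class_of.get(g) == cls]
            for cls in ("fast", "medium", "slow")
        }
        treatment_rows = []
        for gene, kos in markers.items():
            present = [k for k in kos if k in ko_table.columns]
            if not present or not ko_table[present].to_numpy().any():
                rows.append(
                    {
                        "gene": gene,
                        "treatment": treatment,
                        "pair": "",
                        "delta": math.nan,
                        "p_raw": math.nan,
                        "p_adj": math.nan,
                        "label": "not_testable",
                    }
                )
                continue
            values = ko_table[present].sum(axis=1)
            for a, b in itertools.combinations(("fast", "medium", "slow"), 2):
                if len(members[a]) < 2 or len(members[b]) < 2:
                    continue
                x = values.loc[members[a]].to_numpy()
                y = values.loc[members[b]].to_numpy()
                treatment_rows.append(
                    {
                        "gene": gene,
                        "treatment": treatment,
                        "pair": f"{a}_vs_{b}",
                        "delta": float(x.mean() - y.mean()),
                        "p_raw": wilcoxon_rank_sum(x, y),
                    }
                )
        if not treatment_rows:
            continue
        frame = pd.DataFrame(treatment_rows)
        frame["p_adj"] = bh_adjust(frame["p_raw"].to_numpy())
        decisive = frame["p_adj"] if use_adjusted else frame["p_raw"]
        frame["label"] = "neither"
        fvs = frame["pair"] == "fast_vs_slow"
        sig = decisive < thresholds.alpha
        frame.loc[fvs & sig & (frame["delta"] > 0), "label"] = "fast_enriched"
        frame.loc[fvs & sig & (frame["delta"] < 0), "label"] = "slow_enriched"
        rows.extend(frame.to_dict("records"))
    return pd.DataFrame(
        rows, columns=["gene", "treatment", "pair", "delta", "p_raw", "p_adj", "label"]
    )


def taxon_fu_matrix(
    table: pd.DataFrame,
    selected_fus: Sequence[str],
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Genome x selected-FU matrix with deterministic clustering orders.

    Rows and columns are ordered by hierarchical clustering (Euclidean
    distance, complete linkage); a single-FU matrix is ordered by value.
    Returns (ordered matrix, row order, column order).
    """
    unknown = [fu for fu in selected_fus if fu not in table.columns]
    if unknown:
        raise ValidationError(f"unknown FU IDs: {unknown}")
    matrix = table[list(selected_fus)]
    if matrix.shape[1] == 1:
        row_order = list(matrix.sort_values(by=matrix.columns[0]).index)
        col_order = list(matrix.columns)
    else:
        row_order = list(matrix.index[_cluster_order(matrix.to_numpy())])
        col_order = list(matrix.columns[_cluster_order(matrix.to_numpy().T)])
    ordered = matrix.loc[row_order, col_order]
    return ordered, row_order, col_order


def _cluster_order(data: np.ndarray) -> np.ndarray:
    if data.shape[0] < 2:
        return np.arange(data.shape[0])
    linkage = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    return hierarchy.leaves_list(linkage)
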