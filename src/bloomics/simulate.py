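"""Synthetic microcosm experiments with planted ground truth.

The generator emulates the statistical structure of the real study:
copiotrophic genomes respond to the manipulations with fast growth
(planted FEDT below 12 h, intensifying from the control treatments to the
virus-reduced one), oligotrophs grow slowly (FEDT above 120 h), a planted
subset of fast copiotrophs blooms (rising from below 1 % to above 1 %
relative abundance), chosen functional units are enriched in the fast
genomes by a fixed percentage-point difference, and copiotroph highly
expressed genes carry a skewed codon usage.

Emitted relative abundances satisfy tf = t0 * exp(r*T) * lognormal-noise
exactly; final abundances are planted first and the initial values derived
from them, so per-sample sums stay within the 0-100 percent scale even for
the large fold-changes that sub-12-hour doubling times imply over a
36-48 h incubation.  Abundances are not renormalised after noise (the
mapped-read-fraction need not sum to 100).

All randomness flows from a single integer seed through one
``numpy.random.Generator``; equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as bio
from .trophic import FAMILIES, _CODONS
from .types import (
    DEFAULT_DURATIONS_H,
    ConfigError,
    GenomeRecord,
    SEASONS,
    TREATMENTS,
    Thresholds,
)

#: Response multipliers dividing the base doubling time of responders;
#: ordered CL = CD <= PL = PD <= DL <= VL like the manipulation gradient.
DEFAULT_TREATMENT_RESPONSE = {
    "CL": 1.0,
    "CD": 1.0,
    "PL": 1.1,
    "PD": 1.1,
    "DL": 1.3,
    "VL": 1.5,
}


@dataclass
class SimulationConfig:
    """Knobs of the community generator; defaults define the study
    conditions every recovery and power check runs under."""

    n_genomes: int = 40
    fraction_copiotroph: float = 0.5
    n_fus: int = 300
    n_enriched_fus: int = 10
    enriched_fu_ids: Optional[tuple[str, ...]] = None
    enrichment_delta_pct: float = 1.0
    treatment_response: dict = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_RESPONSE)
    )
    n_bloomers: int = 3
    cub_bias_theta: float = 0.9
    noise_sd: float = 0.2
    seed: int = 0
    seasons: tuple[str, ...] = SEASONS
    treatments: tuple[str, ...] = TREATMENTS
    replicates: int = 2
    fast_fedt_range_h: tuple[float, float] = (7.0, 11.0)
    slow_fedt_range_h: tuple[float, float] = (200.0, 500.0)
    copio_emdt_range_h: tuple[float, float] = (1.0, 4.5)
    oligo_emdt_range_h: tuple[float, float] = (5.5, 30.0)
    mean_gene_count: int = 3000
    baseline_fu_pct_range: tuple[float, float] = (0.05, 0.5)
    genes_per_genome: int = 120
    gene_length_codons: int = 200
    n_highly_expressed: int = 15
    # amplicon experiment
    asv_timepoints_h: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0)
    n_asvs: int = 12
    n_growing_asvs: int = 3
    asv_slope_range_per_h: tuple[float, float] = (0.06, 0.14)
    v4v5_length: int = 373

    def __post_init__(self) -> None:
        for name in ("fraction_copiotroph", "cub_bias_theta"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.n_genomes < 2:
            raise ConfigError("need at least 2 genomes")
        n_copio = self._n_copiotrophs()
        if self.n_bloomers > n_copio:
            raise ConfigError(
                f"n_bloomers ({self.n_bloomers}) exceeds the number of fast "
                f"copiotrophs ({n_copio})"
            )
        universe = self.fu_universe()
        if self.enriched_fu_ids is None:
            self.enriched_fu_ids = tuple(universe[: self.n_enriched_fus])
        if not set(self.enriched_fu_ids) <= set(universe):
            raise ConfigError("enriched_fu_ids must be drawn from the FU universe")
        if len(self.asv_timepoints_h) < 3:
            raise ConfigError("at least 3 ASV timepoints required")
        if self.n_growing_asvs > self.n_asvs:
            raise ConfigError("n_growing_asvs exceeds n_asvs")

    def _n_copiotrophs(self) -> int:
        return int(round(self.n_genomes * self.fraction_copiotroph))

    def fu_universe(self) -> list[str]:
        return [f"COG{i:04d}" for i in range(1, self.n_fus + 1)]


@dataclass
class SimulationTruth:
    """Planted ground truth, consistent with the emitted tables."""

    trophic: dict  # genome -> copiotroph | oligotroph
    growth_class: dict  # genome -> treatment -> fast | slow
    fedt_h: dict  # genome -> season -> treatment -> planted FEDT
    bloomers: list
    enriched_fus: list
    cub_theta: dict  # genome -> planted codon-bias skew
    highly_expressed: dict  # genome -> list of gene IDs

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1, sort_keys=True)


class Community(NamedTuple):
    genomes: list  # list[GenomeRecord]
    abundance: pd.DataFrame  # io.ABUNDANCE_COLUMNS layout
    annotations: pd.DataFrame
    cds: dict  # genome -> {gene_id: sequence}
    truth: SimulationTruth


class AsvExperiment(NamedTuple):
    asv_table: pd.DataFrame  # asv_id, experiment, time_h, rel_abundance_pct
    cytometry: pd.DataFrame  # experiment, time_h, total_cells
    asv_seqs: dict
    isolate_seqs: dict
    v4v5_region: tuple  # (start, end) coordinates within isolate sequences
    truth: dict


# ---------------------------------------------------------------------------
# community generator


_TAXA_COPIO = (
    "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Alteromonadaceae;g__Alteromonas;s__",
    "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Vibrionaceae;g__Vibrio;s__",
    "d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;o__Rhodobacterales;"
    "f__Rhodobacteraceae;g__Nereida;s__",
    "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Flavobacteriales;"
    "f__Flavobacteriaceae;g__Polaribacter;s__",
)
_TAXA_OLIGO = (
    "d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;o__Pelagibacterales;"
    "f__Pelagibacteraceae;g__Pelagibacter;s__",
    "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;o__Pseudomonadales;"
    "f__Halieaceae;g__Luminiphilus;s__",
    "d__Bacteria;p__Verrucomicrobiota;c__Verrucomicrobiae;o__Opitutales;"
    "f__Puniceicoccaceae;g__Coraliomargarita;s__",
)


def generate_community(config: SimulationConfig) -> Community:
    """Generate genomes, abundances, annotations and CDS with planted truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genomes
    n_copio = config._n_copiotrophs()
    genome_ids = [f"G{i:03d}" for i in range(1, n + 1)]
    is_copio = np.array([i < n_copio for i in range(n)])

    base_fedt = np.where(
        is_copio,
        rng.uniform(*config.fast_fedt_range_h, size=n),
        rng.uniform(*config.slow_fedt_range_h, size=n),
    )
    emdt = np.where(
        is_copio,
        rng.uniform(*config.copio_emdt_range_h, size=n),
        rng.uniform(*config.oligo_emdt_range_h, size=n),
    )
    gene_counts = np.maximum(
        500, rng.normal(config.mean_gene_count, config.mean_gene_count * 0.1, n)
    ).astype(int)

    copio_ids = [g for g, c in zip(genome_ids, is_copio) if c]
    bloomers = sorted(
        rng.choice(np.array(copio_ids), size=config.n_bloomers, replace=False)
    )
    bloomer_mask = np.array([g in set(bloomers) for g in genome_ids])

    genomes = []
    for i, gid in enumerate(genome_ids):
        taxa = _TAXA_COPIO if is_copio[i] else _TAXA_OLIGO
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                source="isolate" if i % 10 == 0 else "mag",
                taxonomy=taxa[i % len(taxa)],
                completeness=float(rng.uniform(80, 100)),
                contamination=float(rng.uniform(0, 4)),
                genome_size=int(gene_counts[i] * rng.uniform(950, 1100)),
                gc=float(rng.uniform(32, 62)),
                gene_count=int(gene_counts[i]),
                emdt_h=float(emdt[i]),
            )
        )

    thresholds = Thresholds()
    abundance_rows: list[dict] = []
    fedt_truth: dict = {g: {} for g in genome_ids}
    class_truth: dict = {g: {} for g in genome_ids}
    for season in config.seasons:
        duration = DEFAULT_DURATIONS_H[season]
        for treatment in config.treatments:
            mult = config.treatment_response[treatment]
            eff_fedt = np.where(is_copio, base_fedt / mult, base_fedt)
            fold = np.power(2.0, duration / eff_fedt)
            # plant final abundances, derive initial ones from the planted rate
            tf_target = np.empty(n)
            tf_target[bloomer_mask] = rng.uniform(2.0, 4.0, bloomer_mask.sum())
            fast_rest = is_copio & ~bloomer_mask
            # keep non-blooming fast growers well below the 1 % bloom line
            # so the planted bloomer set stays meaningful under noise
            tf_target[fast_rest] = rng.uniform(0.1, 0.45, fast_rest.sum())
            t0 = np.empty(n)
            t0[is_copio] = tf_target[is_copio] / fold[is_copio]
            t0[~is_copio] = rng.uniform(1.0, 3.0, (~is_copio).sum())
            tf_target[~is_copio] = t0[~is_copio] * fold[~is_copio]
            for i, gid in enumerate(genome_ids):
                fedt_truth[gid].setdefault(season, {})[treatment] = float(eff_fedt[i])
                class_truth[gid][treatment] = (
                    "fast" if eff_fedt[i] < thresholds.fedt_fast_h else "slow"
                )
            for rep in range(1, config.replicates + 1):
                noise = (
                    np.exp(rng.normal(0.0, config.noise_sd, n))
                    if config.noise_sd > 0
                    else np.ones(n)
                )
                tf_obs = tf_target * noise
                for i, gid in enumerate(genome_ids):
                    for timepoint, value in (("t0", t0[i]), ("tf", tf_obs[i])):
                        abundance_rows.append(
                            {
                                "genome_id": gid,
                                "season": season,
                                "treatment": treatment,
                                "timepoint": timepoint,
                                "replicate": f"r{rep}",
                                "abundance_pct": float(value),
                                "breadth": 0.95,
                            }
                        )
    abundance = pd.DataFrame(abundance_rows, columns=bio.ABUNDANCE_COLUMNS)

    annotations = _generate_annotations(config, rng, genome_ids, is_copio, gene_counts)
    cds, he_ids = _generate_cds(config, rng, genome_ids, is_copio)

    truth = SimulationTruth(
        trophic={
            g: ("copiotroph" if c else "oligotroph")
            for g, c in zip(genome_ids, is_copio)
        },
        growth_class=class_truth,
        fedt_h=fedt_truth,
        bloomers=[str(b) for b in bloomers],
        enriched_fus=sorted(config.enriched_fu_ids),
        cub_theta={
            g: (config.cub_bias_theta if c else 0.0)
            for g, c in zip(genome_ids, is_copio)
        },
        highly_expressed=he_ids,
    )
    return Community(genomes, abundance, annotations, cds, truth)


_CATEGORY_LETTERS = "STKNPVJCHIOF"


def _generate_annotations(
    config: SimulationConfig,
    rng: np.random.Generator,
    genome_ids: Sequence[str],
    is_copio: np.ndarray,
    gene_counts: np.ndarray,
) -> pd.DataFrame:
    universe = config.fu_universe()
    enriched = set(config.enriched_fu_ids)
    base_pct = rng.uniform(*config.baseline_fu_pct_range, size=len(universe))
    category = {fu: _CATEGORY_LETTERS[i % len(_CATEGORY_LETTERS)] for i, fu in enumerate(universe)}

    frames = []
    for gi, gid in enumerate(genome_ids):
        target = base_pct.copy()
        if is_copio[gi]:
            target += np.array(
                [config.enrichment_delta_pct if fu in enriched else 0.0 for fu in universe]
            )
        counts = rng.poisson(target * gene_counts[gi] / 100.0)
        total = int(counts.sum())
        if total == 0:
            continue
        fu_col = np.repeat(universe, counts)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": [f"{gid}_g{j:05d}" for j in range(total)],
                    "genome_id": gid,
                    "cog_ids": [[fu] for fu in fu_col],
                    "cog_categories": [category[fu] for fu in fu_col],
                    "ko_ids": [[] for _ in range(total)],
                    "pfam_ids": [[] for _ in range(total)],
                    "cazy_ids": [[] for _ in range(total)],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "genome_id",
                "cog_ids",
                "cog_categories",
                "ko_ids",
                "pfam_ids",
                "cazy_ids",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def _codon_distribution(theta: float) -> np.ndarray:
    """Codon sampling probabilities: uniform over degenerate families, and
    within each family a fraction ``theta`` of the mass moves onto one
    preferred codon (theta = 0 is uniform within the family)."""
    p = np.zeros(64)
    n_fams = len(FAMILIES)
    for aa in sorted(FAMILIES):
        members = FAMILIES[aa]
        r = len(members)
        within = np.full(r, (1.0 - theta) / r)
        within[0] += theta
        for idx, w in zip(members, within):
            p[idx] = w / n_fams
    return p


def _generate_cds(
    config: SimulationConfig,
    rng: np.random.Generator,
    genome_ids: Sequence[str],
    is_copio: np.ndarray,
) -> tuple[dict, dict]:
    codons = np.array(_CODONS)
    background = _codon_distribution(0.0)
    biased = _codon_distribution(config.cub_bias_theta)
    cds: dict[str, dict[str, str]] = {}
    he_ids: dict[str, list[str]] = {}
    length = config.gene_length_codons
    n_he = config.n_highly_expressed
    n_bg = config.genes_per_genome - n_he
    for gi, gid in enumerate(genome_ids):
        he_dist = biased if is_copio[gi] else background
        he_idx = rng.choice(64, size=(n_he, length), p=he_dist)
        bg_idx = rng.choice(64, size=(n_bg, length), p=background)
        all_idx = np.vstack([he_idx, bg_idx]) if n_bg else he_idx
        genes = {
            f"{gid}_gene{j:04d}": "".join(codons[all_idx[j]])
            for j in range(config.genes_per_genome)
        }
        cds[gid] = genes
        he_ids[gid] = [f"{gid}_gene{j:04d}" for j in range(n_he)]
    return cds, he_ids


# ---------------------------------------------------------------------------
# amplicon experiment generator

_DNA = np.array(list("ACGT"))


def generate_asv_experiment(config: SimulationConfig) -> AsvExperiment:
    """ASV time series, flow-cytometry totals and isolate sequences.

    Planted growers have exactly log-linear pseudoabundance before noise;
    one isolate copies a blooming ASV's V4-V5 region exactly, one carries a
    single mismatch, and one is unrelated.
    """
    rng = np.random.default_rng(config.seed + 1)
    times = np.asarray(config.asv_timepoints_h, dtype=float)
    n = config.n_asvs
    n_grow = config.n_growing_asvs
    asv_ids = [f"ASV{i:03d}" for i in range(1, n + 1)]
    slopes = np.zeros(n)
    slopes[:n_grow] = rng.uniform(*config.asv_slope_range_per_h, size=n_grow)
    p0 = rng.uniform(800, 1200, size=n)
    # growers: most start rare (possible bloomers), the last one abundant
    if n_grow:
        p0[: max(1, n_grow - 1)] = rng.uniform(20, 60, size=max(1, n_grow - 1))
        p0[n_grow - 1] = rng.uniform(400, 700)

    pseudo = p0[:, None] * np.exp(slopes[:, None] * times[None, :])
    if config.noise_sd > 0:
        pseudo = pseudo * np.exp(rng.normal(0.0, config.noise_sd, pseudo.shape))
    totals = pseudo.sum(axis=0)
    rel_pct = 100.0 * pseudo / totals[None, :]

    experiment = "summer_VL"
    asv_table = pd.DataFrame(
        {
            "asv_id": np.repeat(asv_ids, len(times)),
            "experiment": experiment,
            "time_h": np.tile(times, n),
            "rel_abundance_pct": rel_pct.ravel(),
        }
    )
    cytometry = pd.DataFrame(
        {"experiment": experiment, "time_h": times, "total_cells": totals * 1000.0}
    )

    asv_seqs = {
        asv: "".join(rng.choice(_DNA, size=config.v4v5_length)) for asv in asv_ids
    }

    bloom_threshold = Thresholds().bloom_abundance_pct
    max_doubling = Thresholds().asv_min_doubling_h
    bloom_asvs = [
        asv_ids[i]
        for i in range(n)
        if rel_pct[i, 0] < bloom_threshold
        and rel_pct[i, -1] > bloom_threshold
        and slopes[i] > 0
        and math.log(2.0) / slopes[i] <= max_doubling
    ]
    source = bloom_asvs[0] if bloom_asvs else asv_ids[0]
    pad_left = "".join(rng.choice(_DNA, size=120))
    pad_right = "".join(rng.choice(_DNA, size=90))
    region = (len(pad_left), len(pad_left) + config.v4v5_length)
    exact = pad_left + asv_seqs[source] + pad_right
    mutated = list(asv_seqs[source])
    pos = int(rng.integers(0, len(mutated)))
    mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
    mismatch = pad_left + "".join(mutated) + pad_right
    unrelated = (
        pad_left + "".join(rng.choice(_DNA, size=config.v4v5_length)) + pad_right
    )
    isolate_seqs = {
        "ISO_exact": exact,
        "ISO_mismatch": mismatch,
        "ISO_unrelated": unrelated,
    }

    truth = {
        "slopes_per_h": dict(zip(asv_ids, slopes.tolist())),
        "bloomer_asvs": bloom_asvs,
        "isolate_source_asv": {"ISO_exact": source},
        "expected_selected_isolates": ["ISO_exact"] if bloom_asvs else [],
    }
    return AsvExperiment(asv_table, cytometry, asv_seqs, isolate_seqs, region, truth)


# ---------------------------------------------------------------------------
# emission in the dialects io reads


def write_community(community: Community, outdir: str | Path) -> None:
    """Emit a community as the TSV/FASTA files the readers consume,
    alongside the ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bio.write_genome_metadata(community.genomes, outdir / "genomes.tsv")

    ab = community.abundance
    table = pd.DataFrame(
        {
            "genome": ab["genome_id"],
            "sample": ab["season"]
            + "_"
            + ab["treatment"]
            + "_"
            + ab["timepoint"]
            + "_"
            + ab["replicate"],
            "relative_abundance": ab["abundance_pct"],
            "covered_fraction": ab["breadth"],
        }
    )
    table.to_csv(outdir / "abundance.tsv", sep="\t", index=False)

    ann = community.annotations.copy()
    for col in ("cog_ids", "ko_ids", "pfam_ids", "cazy_ids"):
        ann[col] = ann[col].map(lambda ids: ",".join(ids) if ids else "-")
    ann["cog_categories"] = ann["cog_categories"].replace("", "-")
    ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    for gid, genes in community.cds.items():
        bio.write_fasta(genes, outdir / f"{gid}_cds.fasta")
    with open(outdir / "highly_expressed.txt", "w") as handle:
        for gid in sorted(community.truth.highly_expressed):
            for gene in community.truth.highly_expressed[gid]:
                handle.write(gene + "\n")
    community.truth.to_json(outdir / "truth.json")


def write_asv_experiment(data: AsvExperiment, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.asv_table.to_csv(outdir / "asv_table.tsv", sep="\t", index=False)
    data.cytometry.to_csv(outdir / "cytometry.tsv", sep="\t", index=False)
    bio.write_fasta(data.asv_seqs, outdir / "asv_seqs.fasta")
    bio.write_fasta(data.isolate_seqs, outdir / "isolates.fasta")
    with open(outdir / "asv_truth.json", "w") as handle:
        json.dump(
            {"v4v5_region": list(data.v4v5_region), **data.truth},
            handle,
            indent=1,
            sort_keys=True,
        )
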