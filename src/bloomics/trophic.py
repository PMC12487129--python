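"""Codon usage bias (MILC) and copiotroph/oligotroph classification.

Fast-growing bacteria bias the codon usage of their highly expressed genes
(ribosomal proteins and the like) towards translationally efficient codons.
The bias is quantified per gene with MILC (Measure Independent of Length
and Composition): a Kullback-Leibler-type distance between the gene's
within-family codon frequencies ``f_c`` and reference frequencies ``g_c``
estimated from the whole gene set,

    MILC = (sum_a sum_{c in a} o_c * ln(f_c / g_c)) / L  -  C,
    C    = (sum_{a present} (r_a - 1)) / L,

where ``o_c`` are the gene's codon counts, ``L`` its length in counted
codons, ``a`` runs over synonymous codon families of size ``r_a`` >= 2
(stop codons and the single-codon families Met and Trp are excluded) and C
corrects for the finite-length inflation of the distance term.  A genome's
codon usage bias (CUB) is the mean MILC of its highly expressed genes
against the genome-wide reference.

Trophic strategy is classified from the estimated minimum doubling time
(EMDT, taken as an input column): copiotrophs have EMDT < 5 h, oligotrophs
>= 5 h.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data import CodonTable

from .types import Thresholds, ValidationError

logger = logging.getLogger("bloomics")

_BASES = "TCAG"
_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
CODON_INDEX = {codon: i for i, codon in enumerate(_CODONS)}

_TABLE = CodonTable.unambiguous_dna_by_id[11]  # bacterial code
STOP_CODONS = tuple(_TABLE.stop_codons)

def _build_families() -> dict[str, tuple[int, ...]]:
    by_aa: dict[str, list[int]] = {}
    for codon, aa in _TABLE.forward_table.items():
        by_aa.setdefault(aa, []).append(CODON_INDEX[codon])
    # only degenerate families take part in MILC
    return {
        aa: tuple(sorted(idx)) for aa, idx in by_aa.items() if len(idx) >= 2
    }

#: amino acid -> codon indices, degenerate (size >= 2) families only.
FAMILIES = _build_families()

#: codon index -> family key ('' for stops and single-codon families).
_FAMILY_OF = np.full(64, -1, dtype=int)
_FAMILY_KEYS = sorted(FAMILIES)
for _fi, _aa in enumerate(_FAMILY_KEYS):
    for _ci in FAMILIES[_aa]:
        _FAMILY_OF[_ci] = _fi

_STOP_IDX = np.array([CODON_INDEX[c] for c in STOP_CODONS])

# byte lookup: A,C,G,T -> 0..3, everything else -> 4 (ambiguous)
_BASE_LUT = np.full(256, 4, dtype=np.int64)
for _b, _v in zip(b"TCAG", range(4)):
    _BASE_LUT[_b] = _v
for _b, _v in zip(b"tcag", range(4)):
    _BASE_LUT[_b] = _v


def codon_counts(sequence: str) -> np.ndarray:
    """Count codons of a CDS into a length-64 vector.

    The sequence is read in frame from position 0; a trailing partial codon
    is trimmed; codons containing ambiguous bases are ignored.
    """
    arr = _BASE_LUT[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    n = len(arr) - len(arr) % 3
    if n == 0:
        return np.zeros(64, dtype=np.int64)
    triplets = arr[:n].reshape(-1, 3)
    valid = (triplets < 4).all(axis=1)
    idx = triplets[valid] @ np.array([16, 4, 1])
    return np.bincount(idx, minlength=64).astype(np.int64)


def has_internal_stop(sequence: str) -> bool:
    """True if a stop codon occurs before the final codon position."""
    seq = sequence.upper()
    n = len(seq) - len(seq) % 3
    for i in range(0, n - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return True
    return False


@dataclass
class CodonProfile:
    """Per-gene codon counts plus the reference frequencies to test against."""

    counts: np.ndarray  # length-64 observed codon counts o_c
    reference: np.ndarray  # length-64 within-family reference frequencies g_c

    @classmethod
    def from_sequence(cls, sequence: str, reference: np.ndarray) -> "CodonProfile":
        return cls(counts=codon_counts(sequence), reference=reference)


def reference_frequencies(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Within-family reference frequencies g_c from pooled codon counts.

    Each codon of a degenerate family receives a pseudocount before the
    family-wise normalisation, so g_c > 0 for every codon MILC can observe.
    """
    g = np.zeros(64, dtype=float)
    for aa, members in FAMILIES.items():
        idx = np.array(members)
        fam = counts[idx].astype(float) + pseudocount
        g[idx] = fam / fam.sum()
    return g


def compute_milc(
    profile: CodonProfile | np.ndarray, reference: Optional[np.ndarray] = None
) -> float:
    """MILC statistic of one gene against reference codon frequencies.

    Accepts a :class:`CodonProfile`, or a raw length-64 count vector plus
    the ``reference`` frequencies.
    """
    if isinstance(profile, CodonProfile):
        counts, g = profile.counts, profile.reference
    else:
        if reference is None:
            raise ValueError("reference frequencies required with raw counts")
        counts, g = profile, reference

    distance = 0.0
    length = 0
    correction_numerator = 0
    for aa, members in FAMILIES.items():
        idx = np.array(members)
        o = counts[idx].astype(float)
        total = o.sum()
        if total == 0:
            continue
        f = o / total
        gref = g[idx]
        observed = o > 0
        if np.any(gref[observed] <= 0):
            raise ValidationError(
                f"reference frequency zero for an observed codon of family {aa}"
            )
        distance += float(np.sum(o[observed] * np.log(f[observed] / gref[observed])))
        length += int(total)
        correction_numerator += len(members) - 1
    if length == 0:
        raise ValidationError(
            "gene has no codons from a degenerate synonymous family"
        )
    correction = correction_numerator / length
    return distance / length - correction


def compute_cub(
    cds: Mapping[str, str],
    highly_expressed_ids: Sequence[str],
) -> float:
    """Genome codon usage bias: mean MILC of highly expressed genes against
    the codon usage of the full gene set.

    Genes with an internal stop codon are skipped with a warning.  Raises
    if none of the highly expressed IDs are found in ``cds``.
    """
    missing = [gid for gid in highly_expressed_ids if gid not in cds]
    found = [gid for gid in highly_expressed_ids if gid in cds]
    if not found:
        raise ValidationError(
            f"no highly expressed gene found in CDS set; missing IDs: {missing[:10]}"
        )
    if missing:
        logger.warning("%d highly expressed IDs absent from CDS set", len(missing))

    pooled = np.zeros(64, dtype=np.int64)
    for seq in cds.values():
        pooled += codon_counts(seq)
    g = reference_frequencies(pooled)

    values = []
    for gid in found:
        seq = cds[gid]
        if has_internal_stop(seq):
            logger.warning("gene %s has an internal stop codon; skipped", gid)
            continue
        values.append(compute_milc(codon_counts(seq), g))
    if not values:
        raise ValidationError("all highly expressed genes were skipped")
    return float(np.mean(values))


def classify_trophic(
    emdt_h: Optional[float], thresholds: Thresholds = Thresholds()
) -> str:
    """Copiotroph iff EMDT < 5 h; oligotroph iff >= 5 h; unclassified if
    the EMDT is missing."""
    if emdt_h is None or (isinstance(emdt_h, float) and math.isnan(emdt_h)):
        return "unclassified"
    if not emdt_h > 0:
        raise ValidationError(f"emdt_h must be positive, got {emdt_h}")
    return "copiotroph" if emdt_h < thresholds.emdt_copio_h else "oligotroph"


def trophic_table(
    genomes: pd.DataFrame,
    cub: Optional[Mapping[str, float]] = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-genome trophic calls (genome_id, cub, emdt_h, strategy)."""
    out = pd.DataFrame(
        {
            "genome_id": genomes["genome_id"],
            "cub": [
                (cub or {}).get(gid, math.nan) for gid in genomes["genome_id"]
            ],
            "emdt_h": genomes["emdt_h"],
        }
    )
    out["strategy"] = out["emdt_h"].map(lambda v: classify_trophic(v, thresholds))
    return out


def correlate_emdt_fedt(
    emdt_h: Sequence[float], min_fedt_h: Sequence[float]
) -> tuple[float, float, float]:
    """Pearson correlation between estimated and experimental minimum
    doubling times.  Returns (r, r^2, p)."""
    x = np.asarray(emdt_h, dtype=float)
    y = np.asarray(min_fedt_h, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValidationError("need at least 3 genomes with both EMDT and FEDT")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in doubling times")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r * r), float(p)
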