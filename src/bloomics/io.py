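"""Readers and writers for the tabular and sequence formats the pipeline uses.

All tables are UTF-8, tab-separated with a header row.  Relative abundances
are kept on the 0-100 percent scale throughout; breadth of coverage is a
0-1 fraction.  Sample labels follow ``{season}_{treatment}_{timepoint}_{replicate}``
(e.g. ``summer_VL_tf_r1``) and the pattern is configurable by regex.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import sys
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .types import (
    FormatError,
    GenomeRecord,
    Thresholds,
    ValidationError,
)

logger = logging.getLogger("bloomics")

#: Default sample-label grammar: season_treatment_timepoint_replicate.
DEFAULT_SAMPLE_PATTERN = (
    r"^(?P<season>winter|spring|summer|fall)_"
    r"(?P<treatment>CL|CD|PL|PD|DL|VL)_"
    r"(?P<timepoint>t0|tf)_"
    r"(?P<replicate>r\d+)$"
)

#: Default column names of a CoverM-style abundance table.
DEFAULT_ABUNDANCE_DIALECT = {
    "genome": "genome",
    "sample": "sample",
    "abundance": "relative_abundance",
    "breadth": "covered_fraction",
}

ABUNDANCE_COLUMNS = [
    "genome_id",
    "season",
    "treatment",
    "timepoint",
    "replicate",
    "abundance_pct",
    "breadth",
]

#: Tolerance on the per-sample abundance sum (unmapped fraction is allowed,
#: sums above 100 are not, up to rounding slack).
SAMPLE_SUM_TOLERANCE = 1.0

_ANNOTATION_LIST_COLUMNS = ("cog_ids", "ko_ids", "pfam_ids", "cazy_ids")
_MISSING_TOKENS = ("", "-")


def setup_logging(verbose: bool = False) -> None:
    """Route pipeline log messages to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def read_abundance_table(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    sample_pattern: str = DEFAULT_SAMPLE_PATTERN,
) -> pd.DataFrame:
    """Read a genome-by-sample relative-abundance table.

    Returns a long-format frame with columns ``genome_id, season, treatment,
    timepoint, replicate, abundance_pct, breadth``.  Rows whose sample label
    does not match ``sample_pattern`` are reported and skipped.

    Raises
    ------
    FormatError
        if a mandatory column is missing.
    ValidationError
        if an abundance is negative, a breadth falls outside [0, 1], or a
        sample's abundances sum past 100 plus tolerance.
    """
    cols = dict(DEFAULT_ABUNDANCE_DIALECT)
    if dialect:
        cols.update(dialect)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("genome", "sample", "abundance", "breadth"):
        if cols[key] not in raw.columns:
            raise FormatError(
                f"{path}: missing mandatory column {cols[key]!r} (for {key})"
            )
    if raw.empty:
        logger.warning("%s: header-only abundance table, no rows parsed", path)
        return pd.DataFrame(columns=ABUNDANCE_COLUMNS)

    pattern = re.compile(sample_pattern)
    rows = []
    for idx, row in raw.iterrows():
        label = str(row[cols["sample"]])
        m = pattern.match(label)
        if m is None:
            logger.warning(
                "%s row %d: sample label %r does not match the sample pattern; skipped",
                path,
                idx + 2,
                label,
            )
            continue
        try:
            abundance = float(row[cols["abundance"]])
            breadth = float(row[cols["breadth"]])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} row {idx + 2}: non-numeric value ({exc})")
        if abundance < 0:
            raise ValidationError(
                f"{path} row {idx + 2}: negative relative abundance {abundance}"
            )
        if not 0.0 <= breadth <= 1.0:
            raise ValidationError(
                f"{path} row {idx + 2}: breadth {breadth} outside [0, 1]"
            )
        rows.append(
            {
                "genome_id": str(row[cols["genome"]]),
                "season": m.group("season"),
                "treatment": m.group("treatment"),
                "timepoint": m.group("timepoint"),
                "replicate": m.group("replicate"),
                "abundance_pct": abundance,
                "breadth": breadth,
            }
        )
    out = pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)
    _check_sample_sums(out, path)
    return out


def _check_sample_sums(table: pd.DataFrame, path: object) -> None:
    if table.empty:
        return
    sums = table.groupby(["season", "treatment", "timepoint", "replicate"])[
        "abundance_pct"
    ].sum()
    bad = sums[sums > 100.0 + SAMPLE_SUM_TOLERANCE]
    if not bad.empty:
        key = bad.index[0]
        raise ValidationError(
            f"{path}: abundances of sample {'_'.join(key)} sum to "
            f"{bad.iloc[0]:.2f} > 100"
        )


def _split_multi(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    text = str(cell).strip()
    if text in _MISSING_TOKENS:
        return []
    return [part for part in re.split(r"[,|]", text) if part and part != "-"]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-gene functional annotation table (eggNOG-mapper style).

    Expected columns: ``gene_id, genome_id, cog_ids, cog_categories, ko_ids,
    pfam_ids, cazy_ids``.  Multi-valued cells are comma- or pipe-delimited;
    ``-`` and the empty string mean "no annotation" and become empty lists.
    Multi-letter COG category strings (e.g. ``KT``) are preserved verbatim.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene_id", "genome_id"]
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    dupes = raw["gene_id"][raw["gene_id"].duplicated()].unique()
    if len(dupes):
        raise FormatError(
            f"{path}: duplicate gene_id values: {', '.join(sorted(dupes)[:10])}"
        )
    out = pd.DataFrame(
        {
            "gene_id": raw["gene_id"],
            "genome_id": raw["genome_id"],
            "cog_categories": raw.get(
                "cog_categories", pd.Series([""] * len(raw))
            ).map(lambda s: "" if str(s).strip() in _MISSING_TOKENS else str(s).strip()),
        }
    )
    for col in _ANNOTATION_LIST_COLUMNS:
        source = raw[col] if col in raw.columns else pd.Series([""] * len(raw))
        out[col] = source.map(_split_multi)
    return out


def read_genome_metadata(path: str | Path) -> list[GenomeRecord]:
    """Read per-genome metadata into validated :class:`GenomeRecord` objects."""
    raw = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {
        "genome_id",
        "source",
        "taxonomy",
        "completeness",
        "contamination",
        "genome_size",
        "gc",
        "gene_count",
    }
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    seen: set[str] = set()
    for _, row in raw.iterrows():
        gid = str(row["genome_id"])
        if gid in seen:
            raise ValidationError(f"{path}: duplicate genome_id {gid!r}")
        seen.add(gid)
        emdt = row.get("emdt_h")
        records.append(
            GenomeRecord(
                genome_id=gid,
                source=str(row["source"]),
                taxonomy=str(row["taxonomy"]),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                genome_size=int(row["genome_size"]),
                gc=float(row["gc"]),
                gene_count=int(row["gene_count"]),
                emdt_h=None if pd.isna(emdt) else float(emdt),
            )
        )
    return records


def write_genome_metadata(records: Iterable[GenomeRecord], path: str | Path) -> None:
    frame = genomes_to_frame(records)
    frame.to_csv(path, sep="\t", index=False)


def genomes_to_frame(records: Iterable[GenomeRecord]) -> pd.DataFrame:
    """Tabular view of genome records (one row per genome, indexable frame)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: uppercase sequence}`` map.

    Raises :class:`FormatError` on duplicate sequence IDs.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate sequence ID {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write any result frame as a TSV with header."""
    table.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> tuple[Thresholds, dict]:
    """Load a flat JSON configuration.

    Keys matching :class:`Thresholds` fields override the defaults; all
    other keys (file paths, sample pattern, marker maps ...) are returned
    as a plain dict.
    """
    with open(path) as handle:
        data = json.load(handle)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: configuration must be one JSON object")
    field_names = {f.name for f in dataclasses.fields(Thresholds)}
    overrides = {k: v for k, v in data.items() if k in field_names}
    extras = {k: v for k, v in data.items() if k not in field_names}
    return Thresholds(**overrides), extras
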