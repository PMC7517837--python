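"""Readers and writers for the plain-text formats used across the pipeline.

All tables are tab-separated. Formats:

* peptide table — header ``dog_id timepoint sample_id protein_accession
  peptide_id abundance``; one row per *detected* peptide in one sample
  (undetected measurements are absent rows, never empty cells).
* mapping table — 2 or 3 columns (source, target[, confidence]); ``#``
  comment lines ignored.
* GMT — one gene set per line: name, description, then members.
* .rnk — two columns ``gene_id<TAB>score``, no header, sorted by score
  descending; duplicate gene ids are rejected.

Every reader validates strictly and raises :class:`~canprot.errors.FormatError`
with the offending file and 1-based line number.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .errors import FormatError

PEPTIDE_COLUMNS = [
    "dog_id",
    "timepoint",
    "sample_id",
    "protein_accession",
    "peptide_id",
    "abundance",
]

TIMEPOINTS = ("D0", "D7")

RESULT_COLUMNS = [
    "protein_accession",
    "comparison",
    "fc",
    "log2_fc",
    "p_value",
    "n_peptide_groups",
    "detection_class",
    "direction",
]


def read_peptide_table(path) -> pd.DataFrame:
    """Read and validate a long-format peptide abundance table."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"dog_id": str, "sample_id": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse peptide table: {exc}", path) from exc
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"peptide table missing columns {missing}", path, 1)
    df = df[PEPTIDE_COLUMNS]
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        i = int(df.index[bad_tp][0])
        raise FormatError(
            f"timepoint must be one of {TIMEPOINTS}, got {df['timepoint'].iloc[i]!r}",
            path,
            i + 2,
        )
    bad_ab = ~(df["abundance"] > 0) | ~df["abundance"].apply(math.isfinite)
    if bad_ab.any():
        i = int(df.index[bad_ab][0])
        raise FormatError("abundance must be a positive finite real", path, i + 2)
    dup = df.duplicated(subset=["sample_id", "protein_accession", "peptide_id"])
    if dup.any():
        i = int(df.index[dup][0])
        raise FormatError(
            "duplicate (sample_id, protein_accession, peptide_id) row", path, i + 2
        )
    return df


def write_peptide_table(df: pd.DataFrame, path) -> None:
    df[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_mapping_table(path) -> list[tuple[str, str, float | None]]:
    """Read a 2- or 3-column mapping table as (source, target, confidence) rows."""
    path = Path(path)
    rows: list[tuple[str, str, float | None]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise FormatError(
                    f"mapping line must have 2 or 3 tab-separated fields, got {len(fields)}",
                    path,
                    lineno,
                )
            src, tgt = fields[0].strip(), fields[1].strip()
            if not src or not tgt:
                raise FormatError("empty identifier in mapping line", path, lineno)
            conf: float | None = None
            if len(fields) == 3:
                try:
                    conf = float(fields[2])
                except ValueError as exc:
                    raise FormatError(
                        f"confidence must be numeric, got {fields[2]!r}", path, lineno
                    ) from exc
            rows.append((src, tgt, conf))
    return rows


def write_mapping_table(rows, path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            if len(row) == 3 and row[2] is not None:
                fh.write(f"{row[0]}\t{row[1]}\t{row[2]:g}\n")
            else:
                fh.write(f"{row[0]}\t{row[1]}\n")


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT gene-set collection as {name: (description, members)}."""
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    "GMT line must have at least 3 fields (name, description, >=1 member)",
                    path,
                    lineno,
                )
            name, desc = fields[0], fields[1]
            members = [f for f in fields[2:] if f]
            if not members:
                raise FormatError("GMT set has no members", path, lineno)
            if name in sets:
                raise FormatError(f"duplicate gene-set name {name!r}", path, lineno)
            sets[name] = (desc, members)
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_rnk(path) -> pd.DataFrame:
    """Read a ranked gene list; columns ``gene_id``, ``score``."""
    path = Path(path)
    genes: list[str] = []
    scores: list[float] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f".rnk line must have exactly 2 fields, got {len(fields)}",
                    path,
                    lineno,
                )
            gene = fields[0].strip()
            if gene in seen:
                raise FormatError(f"duplicate gene id {gene!r} in .rnk", path, lineno)
            seen.add(gene)
            try:
                score = float(fields[1])
            except ValueError as exc:
                raise FormatError(
                    f"score must be numeric, got {fields[1]!r}", path, lineno
                ) from exc
            if not math.isfinite(score):
                raise FormatError("score must be finite", path, lineno)
            genes.append(gene)
            scores.append(score)
    return pd.DataFrame({"gene_id": genes, "score": scores})


def write_rnk(df: pd.DataFrame, path) -> None:
    """Write a ranked gene list with scores printed to 6 significant digits."""
    with open(path, "w") as fh:
        for gene, score in zip(df["gene_id"], df["score"]):
            fh.write(f"{gene}\t{score:.6g}\n")


def write_results_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
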