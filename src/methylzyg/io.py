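"""Readers and writers for the tabular and interval inputs.

Conventions
-----------
* Beta matrices are TSV with probe ids in the first column and sample ids in
  the header; values are bulk methylation fractions in [0, 1], with empty
  cells or a configurable token (default ``NA``) marking missing values.
* CpG islands are BED: 0-based, half-open, strand ignored. Probe positions in
  the annotation TSV are 1-based; a probe at 1-based position ``p`` lies in an
  island ``(start, end)`` iff ``start < p <= end``.
* All readers reject invalid values with an error naming the offending
  row/column; nothing is silently clamped or repaired.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

DEFAULT_MISSING_TOKENS = ("", "NA")

#: Column order required in a probe annotation TSV.
ANNOTATION_COLUMNS = ["probe_id", "chromosome", "position", "gene", "tss_distance"]

#: Mandatory sample-sheet columns; extra columns are preserved as labels.
SAMPLE_COLUMNS = ["sample_id", "role", "cancer_type", "purity"]

#: Mandatory copy-number table columns.
CN_COLUMNS = ["sample_id", "gene", "total_copies", "loh"]


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

def validate_beta_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    """Validate a probes x samples beta matrix.

    Checks duplicate-free labels and that every non-missing value lies in
    [0, 1]. Returns the (float-typed) matrix unchanged.
    """
    if beta.index.duplicated().any():
        dup = beta.index[beta.index.duplicated()][0]
        raise ValidationError(f"duplicate probe id {dup!r} in beta matrix")
    if beta.columns.duplicated().any():
        dup = beta.columns[beta.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r} in beta matrix")
    values = beta.to_numpy(dtype=float)
    bad = np.where(~np.isnan(values) & ((values < 0) | (values > 1)))
    if bad[0].size:
        i, j = bad[0][0], bad[1][0]
        raise ValidationError(
            f"beta value {values[i, j]!r} outside [0, 1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    return beta.astype(float)


def read_beta_matrix(
    path,
    delimiter: str = "\t",
    missing_tokens=DEFAULT_MISSING_TOKENS,
) -> pd.DataFrame:
    """Read a beta-value matrix (probes x samples) from a delimited file."""
    try:
        beta = pd.read_csv(
            path,
            sep=delimiter,
            index_col=0,
            na_values=list(missing_tokens),
            keep_default_na=False,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"malformed beta matrix {path}: {exc}") from exc
    if beta.index.name is None or beta.columns.isna().any():
        raise FormatError(f"malformed header in beta matrix {path}")
    try:
        beta = beta.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric beta value in {path}: {exc}") from exc
    beta.index = beta.index.astype(str)
    beta.index.name = "probe_id"
    beta.columns = beta.columns.astype(str)
    return validate_beta_matrix(beta)


def write_beta_matrix(beta: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a beta matrix; missing values become empty cells."""
    validate_beta_matrix(beta)
    out = beta.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep=delimiter, na_rep="")


# ---------------------------------------------------------------------------
# CpG islands (BED)
# ---------------------------------------------------------------------------

def read_cpg_islands(path) -> pd.DataFrame:
    """Read CpG-island intervals from BED (0-based, half-open).

    Returns a frame with columns ``chromosome, start, end`` sorted by
    (chromosome, start). Strand is ignored.
    """
    import pyranges as pr

    try:
        ranges = pr.read_bed(str(path))
    except Exception as exc:  # pyranges raises various parse errors
        raise FormatError(f"malformed BED file {path}: {exc}") from exc
    df = ranges.df if hasattr(ranges, "df") else pd.DataFrame(ranges)
    if df.empty:
        return pd.DataFrame(columns=["chromosome", "start", "end"])
    islands = pd.DataFrame(
        {
            "chromosome": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
        }
    )
    bad = islands[islands["start"] >= islands["end"]]
    if not bad.empty:
        row = bad.iloc[0]
        raise FormatError(
            f"BED interval with start >= end: {row['chromosome']}:"
            f"{row['start']}-{row['end']} in {path}"
        )
    return islands.sort_values(["chromosome", "start"], kind="stable").reset_index(
        drop=True
    )


def write_cpg_islands(islands: pd.DataFrame, path) -> None:
    islands[["chromosome", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def probes_in_islands(
    positions: pd.DataFrame, islands: pd.DataFrame
) -> pd.Series:
    """Boolean membership of 1-based probe positions in 0-based BED islands.

    ``positions`` needs columns ``chromosome`` and ``position``. Membership:
    interval start < position <= interval end.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in islands.groupby("chromosome"):
        # shift to make the half-open BED interval queryable with 1-based
        # points: position p is inside iff start < p <= end, i.e. p - 1 in
        # [start, end) under 0-based half-open semantics.
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub.index)
        )
    result = np.zeros(len(positions), dtype=bool)
    for i, (chrom, pos) in enumerate(
        zip(positions["chromosome"].astype(str), positions["position"].astype(int))
    ):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps_point(pos - 1):
            result[i] = True
    return pd.Series(result, index=positions.index, name="in_island")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def read_probe_annotation(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a probe annotation TSV (probe_id, chromosome, position, gene,
    tss_distance)."""
    ann = pd.read_csv(path, sep=delimiter)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation {path} missing columns {missing}")
    if ann["probe_id"].duplicated().any():
        dup = ann.loc[ann["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"duplicate probe_id {dup!r} in annotation")
    if (ann["position"] < 1).any():
        row = ann[ann["position"] < 1].iloc[0]
        raise ValidationError(
            f"probe {row['probe_id']!r} has non-positive position {row['position']}"
        )
    ann = ann.copy()
    ann["probe_id"] = ann["probe_id"].astype(str)
    ann["chromosome"] = ann["chromosome"].astype(str)
    ann["gene"] = ann["gene"].astype(str)
    ann["position"] = ann["position"].astype(int)
    ann["tss_distance"] = ann["tss_distance"].astype(int)
    return ann


# ---------------------------------------------------------------------------
# sample sheet and copy-number table
# ---------------------------------------------------------------------------

_ROLE_ALIASES = {"tumor": "tumour", "tumour": "tumour", "normal": "normal"}


def read_sample_sheet(
    path, delimiter: str = "\t", missing_tokens=DEFAULT_MISSING_TOKENS
) -> pd.DataFrame:
    """Read a sample sheet. Mandatory columns: sample_id, role, cancer_type,
    purity; any further columns are kept as labels."""
    sheet = pd.read_csv(
        path, sep=delimiter, na_values=list(missing_tokens), keep_default_na=False
    )
    missing = [c for c in SAMPLE_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet {path} missing columns {missing}")
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    sheet = sheet.copy()
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r} in sample sheet")
    roles = sheet["role"].astype(str).str.lower().map(_ROLE_ALIASES)
    if roles.isna().any():
        bad = sheet.loc[roles.isna(), ["sample_id", "role"]].iloc[0]
        raise ValidationError(
            f"sample {bad['sample_id']!r} has unknown role {bad['role']!r}"
        )
    sheet["role"] = roles
    sheet["purity"] = pd.to_numeric(sheet["purity"], errors="coerce")
    tumours = sheet["role"] == "tumour"
    bad_purity = tumours & sheet["purity"].notna() & (
        (sheet["purity"] <= 0) | (sheet["purity"] > 1)
    )
    if bad_purity.any():
        row = sheet[bad_purity].iloc[0]
        raise ValidationError(
            f"sample {row['sample_id']!r} has purity {row['purity']} outside (0, 1]"
        )
    # purity is a tumour-only concept; drop it for normals
    sheet.loc[~tumours, "purity"] = np.nan
    return sheet


def read_gene_cn(
    path, delimiter: str = "\t", missing_tokens=DEFAULT_MISSING_TOKENS
) -> pd.DataFrame:
    """Read a gene-level copy-number/LOH table (sample_id, gene,
    total_copies, loh)."""
    cn = pd.read_csv(
        path, sep=delimiter, na_values=list(missing_tokens), keep_default_na=False
    )
    missing = [c for c in CN_COLUMNS if c not in cn.columns]
    if missing:
        raise FormatError(f"copy-number table {path} missing columns {missing}")
    cn = cn.copy()
    cn["sample_id"] = cn["sample_id"].astype(str)
    cn["gene"] = cn["gene"].astype(str)
    if cn.duplicated(["sample_id", "gene"]).any():
        row = cn[cn.duplicated(["sample_id", "gene"])].iloc[0]
        raise ValidationError(
            f"duplicate copy-number entry for sample {row['sample_id']!r}, "
            f"gene {row['gene']!r}"
        )
    cn["total_copies"] = pd.to_numeric(cn["total_copies"], errors="coerce")
    neg = cn["total_copies"].notna() & (cn["total_copies"] < 0)
    if neg.any():
        row = cn[neg].iloc[0]
        raise ValidationError(
            f"negative total_copies {row['total_copies']} for sample "
            f"{row['sample_id']!r}, gene {row['gene']!r}"
        )
    cn["loh"] = cn["loh"].map(_parse_bool)
    return cn


def _parse_bool(value):
    if pd.isna(value):
        return pd.NA
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "t", "1", "yes"}:
        return True
    if text in {"false", "f", "0", "no"}:
        return False
    raise ValidationError(f"cannot interpret {value!r} as boolean LOH flag")


def write_table(table: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write any record table as TSV with empty cells for missing values."""
    table.to_csv(path, sep=delimiter, index=False, na_rep="")
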