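"""Canonical annotated-variant table.

A variant table is a :class:`pandas.DataFrame` with one row per called
variant per sample.  Positions are 1-based (VCF convention); VAF is a
fraction in [0, 1]; missing annotation scores are NaN/None, never 0-coded —
a SIFT score of 0 means "deleterious with maximal confidence", not absent.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

#: Columns of the canonical variant table, in order.
VARIANT_COLUMNS: list[str] = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt",
    "vaf", "depth",
    "base_change", "protein_change", "consequence",
    "sift_score", "sift_call",
    "polyphen_score", "polyphen_call",
    "revel_score", "cosmic_id",
    "gnomad_af", "dbsnp_common_maf",
    "artifact_flag", "duplicate_flag",
]

VALID_CONSEQUENCES = frozenset({"missense", "frameshift", "splice_donor", "nonsense", "other"})
TRUNCATING_CONSEQUENCES = frozenset({"frameshift", "splice_donor", "nonsense"})
VALID_SIFT_CALLS = frozenset({"deleterious", "tolerated"})
VALID_POLYPHEN_CALLS = frozenset({"PRD", "POD", "B"})

#: The five continental super-populations used for common-SNP frequencies
#: (gnomAD / 1000 Genomes convention).
SUPER_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]


def empty_variant_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in VARIANT_COLUMNS})


def as_variant_table(records: Iterable[dict]) -> pd.DataFrame:
    """Build a canonical table from record dicts, filling absent fields."""
    rows = []
    for rec in records:
        row = {c: rec.get(c, np.nan) for c in VARIANT_COLUMNS}
        row["artifact_flag"] = bool(rec.get("artifact_flag", False))
        row["duplicate_flag"] = bool(rec.get("duplicate_flag", False))
        extra = set(rec) - set(VARIANT_COLUMNS)
        for c in extra:  # carry e.g. truth_* columns through
            row[c] = rec[c]
        rows.append(row)
    if not rows:
        return empty_variant_table()
    df = pd.DataFrame(rows)
    ordered = VARIANT_COLUMNS + [c for c in df.columns if c not in VARIANT_COLUMNS]
    return df[ordered]


def validate_variants(df: pd.DataFrame, context: str = "variant table") -> pd.DataFrame:
    """Enforce the table invariants; raise ``ValueError`` with row context."""
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{context}: missing columns {missing}")
    vaf = pd.to_numeric(df["vaf"], errors="coerce")
    bad = df.index[(vaf < 0) | (vaf > 1)]
    if len(bad):
        raise ValueError(f"{context}: VAF outside [0,1] at rows {list(bad[:5])}")
    depth = pd.to_numeric(df["depth"], errors="coerce")
    bad = df.index[depth < 0]
    if len(bad):
        raise ValueError(f"{context}: negative depth at rows {list(bad[:5])}")
    cons = df["consequence"].dropna()
    unknown = cons[~cons.isin(VALID_CONSEQUENCES)]
    if len(unknown):
        raise ValueError(
            f"{context}: unknown consequence {unknown.iloc[0]!r} at row {unknown.index[0]}"
        )
    dup = df.duplicated(subset=["sample_id", *KEY_COLUMNS], keep=False) & ~df["duplicate_flag"].fillna(False).astype(bool)
    # duplicated genomic keys within a sample are only legal when flagged
    if dup.any() and df.loc[dup, "pos"].notna().any():
        first = df.index[dup][0]
        raise ValueError(f"{context}: duplicate genomic key within sample at row {first}")
    return df


def variant_keys(df: pd.DataFrame) -> set[tuple]:
    """Genomic keys (chrom, pos, ref, alt) of a table, as a set."""
    return set(map(tuple, df[KEY_COLUMNS].itertuples(index=False, name=None)))
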