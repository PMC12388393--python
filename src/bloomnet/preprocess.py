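"""Table I/O, validation, and post-annotation cleanup of ASV tables.

Count tables are plain :class:`pandas.DataFrame` objects with sample ids on
the index and ASV ids on the columns; taxonomy is a DataFrame indexed by ASV
id with columns domain..genus; sample metadata is indexed by sample id.
Cleanup follows standard amplicon practice: drop organellar reads from the
16S table, metazoan/plant reads from the 18S table, and anything
unclassified at phylum rank, then normalise library sizes by random
subsampling to the minimum sequencing depth.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .simulate import RANKS

__all__ = [
    "read_count_table", "read_taxonomy", "read_metadata",
    "filter_taxonomy", "rarefy_min_depth", "relative_abundance",
    "shared_asv_summary", "classify_bloom",
    "PROK_EXCLUDE_TOKENS", "EUK_EXCLUDE_TOKENS",
]

#: rank tokens removed from the prokaryotic (16S) table — organellar reads
PROK_EXCLUDE_TOKENS = frozenset({"chloroplast", "mitochondria"})
#: rank tokens removed from the eukaryotic (18S) table — metazoa and plants
EUK_EXCLUDE_TOKENS = frozenset(
    {"metazoa", "rhodophyta", "streptophyta", "trebouxiophyceae", "ulvophyceae"})

VALID_REGIONS = ("BR", "NR")
VALID_LAYERS = ("S", "M", "B")


def read_count_table(path) -> pd.DataFrame:
    """Read a sample x ASV count TSV (first column sample id) and validate."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate ASV ids {dupes}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number) or (vals % 1 != 0).any():
            bad = vals.index[~np.isfinite(pd.to_numeric(vals, errors="coerce"))
                             if not np.issubdtype(vals.dtype, np.number)
                             else (vals % 1 != 0)][0]
            raise ValueError(f"{path}: non-integer count at sample {bad!r}, ASV {col!r}")
        if (vals < 0).any():
            bad = vals.index[vals < 0][0]
            raise ValueError(f"{path}: negative count at sample {bad!r}, ASV {col!r}")
    return df.astype(np.int64)


def read_taxonomy(path) -> pd.DataFrame:
    """Read an ``asv_id<TAB>lineage`` TSV; lineage is ``d__X;p__Y;...``."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate ASV ids {dupes}")
    if "lineage" not in raw.columns:
        raise ValueError(f"{path}: missing 'lineage' column")
    parsed = []
    for asv, lineage in raw["lineage"].items():
        parts = [p.split("__", 1)[-1] if "__" in p else p
                 for p in str(lineage).split(";")]
        parts = (parts + ["Unclassified"] * len(RANKS))[: len(RANKS)]
        parsed.append(parts)
    tax = pd.DataFrame(parsed, index=raw.index, columns=RANKS)
    tax.index.name = "asv_id"
    return tax


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata; region/layer validated, numerics coerced."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    for col in ("region", "layer"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        if df[col].isna().any():
            bad = df.index[df[col].isna()][0]
            raise ValueError(f"{path}: missing {col} for sample {bad!r}")
    bad_region = ~df["region"].isin(VALID_REGIONS)
    if bad_region.any():
        sample = df.index[bad_region][0]
        raise ValueError(
            f"{path}: unknown region {df.loc[sample, 'region']!r} for sample "
            f"{sample!r} (expected one of {VALID_REGIONS})")
    bad_layer = ~df["layer"].isin(VALID_LAYERS)
    if bad_layer.any():
        sample = df.index[bad_layer][0]
        raise ValueError(
            f"{path}: unknown layer {df.loc[sample, 'layer']!r} for sample "
            f"{sample!r} (expected one of {VALID_LAYERS})")
    for col in df.columns:
        if col in ("region", "layer", "site"):
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if np.isinf(df[col]).any():
            bad = df.index[np.isinf(df[col])][0]
            raise ValueError(f"{path}: non-finite {col} for sample {bad!r}")
    return df


def cross_check_samples(counts: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Ensure every counted sample has metadata."""
    missing = set(counts.index) - set(metadata.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")


def filter_taxonomy(table: pd.DataFrame, tax: pd.DataFrame,
                    mode: Literal["prokaryote", "eukaryote"]) -> pd.DataFrame:
    """Drop unwanted lineages from a count table.

    ``prokaryote`` removes ASVs whose lineage contains Chloroplast or
    Mitochondria at any rank; ``eukaryote`` removes Metazoa and plant
    lineages (Rhodophyta, Streptophyta, Trebouxiophyceae, Ulvophyceae).
    Both modes drop ASVs unclassified at phylum rank.  Matching is
    case-insensitive on whole rank tokens so e.g. "Chloroplastida" does
    not false-hit.  Column order of survivors is preserved.
    """
    if mode not in ("prokaryote", "eukaryote"):
        raise ValueError(f"mode must be 'prokaryote' or 'eukaryote', got {mode!r}")
    tokens = PROK_EXCLUDE_TOKENS if mode == "prokaryote" else EUK_EXCLUDE_TOKENS
    missing = [a for a in table.columns if a not in tax.index]
    if missing:
        raise ValueError(f"ASVs missing from taxonomy: {missing[:5]}")
    keep = []
    for asv in table.columns:
        lineage = [str(v).strip().lower() for v in tax.loc[asv, RANKS]]
        if lineage[1] == "unclassified":
            continue
        if any(tok in tokens for tok in lineage):
            continue
        keep.append(asv)
    if not keep:
        raise ValueError("all ASVs filtered; check taxonomy table and mode")
    return table[keep]


def rarefy_min_depth(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Subsample every sample without replacement to the minimum library size.

    Vegan-style rarefaction: each row is drawn from a multivariate
    hypergeometric distribution at ``d_min`` = min row sum, so every row sum
    of the result equals ``d_min`` exactly.  Deterministic given ``seed``.
    """
    sums = table.sum(axis=1)
    d_min = int(sums.min())
    if d_min <= 0:
        empty = sums.index[sums <= 0][0]
        raise ValueError(f"sample {empty!r} has zero reads; cannot rarefy")
    rng = np.random.default_rng(seed)
    out = np.empty(table.shape, dtype=np.int64)
    values = table.to_numpy()
    for i in range(table.shape[0]):
        if sums.iloc[i] == d_min:
            out[i] = values[i]
        else:
            out[i] = rng.multivariate_hypergeometric(values[i], d_min)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise counts to proportions (each row sums to 1)."""
    sums = table.sum(axis=1)
    if (sums <= 0).any():
        empty = sums.index[sums <= 0][0]
        raise ValueError(f"sample {empty!r} has zero total; cannot normalise")
    return table.div(sums, axis=0)


def shared_asv_summary(table_a: pd.DataFrame, table_b: pd.DataFrame
                       ) -> tuple[int, int, float]:
    """Venn-style shared/total ASV summary between two regions.

    An ASV is "present" in a region when it has at least one read in at
    least one sample of that region's table.  Returns
    ``(n_shared, n_total, percent_shared)`` with the percentage of the
    union rounded to one decimal.
    """
    present_a = set(table_a.columns[(table_a > 0).any(axis=0)])
    present_b = set(table_b.columns[(table_b > 0).any(axis=0)])
    n_shared = len(present_a & present_b)
    n_total = len(present_a | present_b)
    if n_total == 0:
        raise ValueError("both tables are empty; no ASVs present")
    return n_shared, n_total, round(100.0 * n_shared / n_total, 1)


def classify_bloom(density_cells_per_l: float, threshold: float = 3e3) -> str:
    """Classify a cell density against the red-tide monitoring threshold.

    Returns ``"bloom"`` iff the density strictly exceeds ``threshold``
    (default 3x10^3 cells/L); equality is classified ``"no_bloom"``.
    """
    if density_cells_per_l < 0:
        raise ValueError(f"density must be >= 0, got {density_cells_per_l!r}")
    return "bloom" if density_cells_per_l > threshold else "no_bloom"
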