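"""Input/output: raw allele-count tables, parental polarization, result tables.

The scan's input is a tab-delimited table with one row per biallelic SNP per
bulk per replicate, carrying REF/ALT read counts (the GATK ``VariantsToTable``
convention). Loading proceeds in three steps: parse (:func:`read_counts_table`),
drop loci with too many alternate alleles (:func:`filter_biallelic`), and
re-express REF/ALT counts as Oak/Wine parental counts using a parent map
(:func:`polarize_alleles`). Coordinates are 1-based (VCF convention);
``snp_index`` is the dense 0-based rank of a position within its chromosome.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column -> default file column name (GATK VariantsToTable-ish)
DEFAULT_SCHEMA = {
    "chrom": "CHROM",
    "pos": "POS",
    "bulk_id": "bulk_id",
    "selection": "selection",
    "background": "background",
    "replicate": "replicate",
    "ref_reads": "ref_reads",
    "alt_reads": "alt_reads",
    "n_alt_alleles": "n_alt_alleles",
}

RAW_COLUMNS = list(DEFAULT_SCHEMA)

#: columns of a polarized variant table
VARIANT_COLUMNS = [
    "chrom", "pos", "selection", "background", "replicate",
    "oak_reads", "wine_reads", "snp_index",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A field could not be parsed (reported with its line number)."""


class DataError(ValueError):
    """Input rows are internally inconsistent (e.g. conflicting parent map)."""


def read_counts_table(path: str | os.PathLike, schema: dict | None = None) -> pd.DataFrame:
    """Read a per-locus, per-bulk allele-count table.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    schema
        Mapping from canonical column names (keys of :data:`DEFAULT_SCHEMA`)
        to the column names used in the file. Unmapped canonical names fall
        back to the defaults, so both GATK-style exports and the synthetic
        generator's output load with ``schema=None``.

    Returns
    -------
    pandas.DataFrame
        One row per (locus, bulk, replicate) with canonical column names,
        sorted by (chrom, pos); counts are integers.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(DEFAULT_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown canonical columns in schema: {sorted(unknown)}")
        colmap.update(schema)

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [file_col for file_col in colmap.values() if file_col not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")

    out = df[[colmap[c] for c in RAW_COLUMNS]].copy()
    out.columns = RAW_COLUMNS

    for col in ("pos", "replicate", "ref_reads", "alt_reads", "n_alt_alleles", "selection"):
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() | (parsed != parsed.round())
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"non-integer value in column '{col}' at line {line} of {path}")
        out[col] = parsed.astype(int)

    if (out[["ref_reads", "alt_reads"]] < 0).any().any():
        raise ParseError(f"negative read count in {path}")

    dup = out.duplicated(subset=["chrom", "pos", "bulk_id", "replicate"])
    if dup.any():
        raise DataError(f"{int(dup.sum())} duplicate (chrom, pos, bulk, replicate) rows in {path}")

    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def filter_biallelic(rows: pd.DataFrame, max_alt_alleles: int = 2) -> pd.DataFrame:
    """Drop loci with more than ``max_alt_alleles`` alternate alleles.

    The default keeps loci with up to two alternate alleles (the mapping-QC
    rule applied upstream of polarization); pass ``max_alt_alleles=1`` for a
    strictly biallelic filter, since a locus with two alternate alleles
    cannot always be polarized cleanly onto two parents.
    """
    keep = rows["n_alt_alleles"] <= max_alt_alleles
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_biallelic: removed %d of %d locus rows", n_removed, len(rows))
    out = rows[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_biallelic: no loci retained")
    return out


def _parent_map_frame(parent_map) -> pd.DataFrame:
    """Normalize a parent map to a (chrom, pos, wine_allele) frame."""
    if isinstance(parent_map, pd.DataFrame):
        pm = parent_map.copy()
    else:  # mapping {(chrom, pos): "REF"|"ALT" wine allele}
        pm = pd.DataFrame(
            [(c, p, a) for (c, p), a in parent_map.items()],
            columns=["chrom", "pos", "wine_allele"],
        )
    required = {"chrom", "pos", "wine_allele"}
    if not required.issubset(pm.columns):
        raise SchemaError(f"parent map needs columns {sorted(required)}")
    bad = ~pm["wine_allele"].isin(["REF", "ALT"])
    if bad.any():
        raise DataError("parent map wine_allele must be 'REF' or 'ALT'")
    conflicts = pm.groupby(["chrom", "pos"])["wine_allele"].nunique()
    if (conflicts > 1).any():
        where = conflicts[conflicts > 1].index.tolist()[:5]
        raise DataError(f"conflicting parent assignment at {where}")
    return pm.drop_duplicates(["chrom", "pos"])


def polarize_alleles(rows: pd.DataFrame, parent_map) -> pd.DataFrame:
    """Convert REF/ALT counts to Oak/Wine parental counts.

    ``parent_map`` gives, per (chrom, pos), which allele is the Wine allele
    (``"REF"`` or ``"ALT"``); the other allele is Oak. Accepts a DataFrame
    with columns (chrom, pos, wine_allele) or a ``{(chrom, pos): allele}``
    mapping. Loci absent from the map are dropped and logged. Read totals are
    conserved row-wise: ``oak_reads + wine_reads == ref_reads + alt_reads``.

    Returns a variant table with columns :data:`VARIANT_COLUMNS`, sorted by
    position within chromosome, with a dense per-chromosome ``snp_index``.
    """
    pm = _parent_map_frame(parent_map)
    merged = rows.merge(pm[["chrom", "pos", "wine_allele"]], on=["chrom", "pos"], how="left")

    unmapped = merged["wine_allele"].isna()
    if unmapped.any():
        n_loci = merged.loc[unmapped, ["chrom", "pos"]].drop_duplicates().shape[0]
        logger.info("polarize_alleles: dropped %d unmapped loci (%d rows)",
                    n_loci, int(unmapped.sum()))
        merged = merged[~unmapped]

    alt_is_wine = merged["wine_allele"].to_numpy() == "ALT"
    ref = merged["ref_reads"].to_numpy()
    alt = merged["alt_reads"].to_numpy()
    out = merged[["chrom", "pos", "selection", "background", "replicate"]].copy()
    out["oak_reads"] = np.where(alt_is_wine, ref, alt)
    out["wine_reads"] = np.where(alt_is_wine, alt, ref)

    out = out.sort_values(["chrom", "pos", "background", "selection", "replicate"],
                          kind="mergesort").reset_index(drop=True)
    out["snp_index"] = assign_snp_index(out)
    return out


def assign_snp_index(table: pd.DataFrame) -> np.ndarray:
    """Dense 0-based rank of each position within its chromosome."""
    return (
        table.groupby("chrom")["pos"]
        .transform(lambda p: p.rank(method="dense").astype(int) - 1)
        .to_numpy()
    )


# ---------------------------------------------------------------------------
# result tables (shapes mirror the published per-SNP z-score and peak tables)

def write_results(trace_long: pd.DataFrame | None,
                  additive_peaks: pd.DataFrame | None,
                  interaction_peaks: pd.DataFrame | None,
                  calls: pd.DataFrame | None,
                  out_dir: str | os.PathLike,
                  fixed_chrom: str = "") -> dict[str, str]:
    """Write the per-SNP z-score table, peak tables and epistasis calls.

    ``trace_long`` must carry columns (label, chr, CHROM, POS, zscore, q5);
    peak frames carry (CSS, CHROM, POS, zscore). Empty inputs produce
    header-only files. Returns a mapping of logical name -> path written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame | None, columns: list[str]) -> None:
        path = os.path.join(out_dir, name)
        if df is None or df.empty:
            df = pd.DataFrame(columns=columns)
        df.to_csv(path, sep="\t", index=False, columns=columns)
        paths[name] = path

    _write("s1_zscores.tsv", trace_long, ["label", "chr", "CHROM", "POS", "zscore", "q5"])
    peak_cols = ["CSS", "CHROM", "POS", "zscore"]
    for name, peaks in (("s2_additive_peaks.tsv", additive_peaks),
                        ("s3_interaction_peaks.tsv", interaction_peaks)):
        if peaks is not None and not peaks.empty and "CSS" not in peaks.columns:
            peaks = peaks.rename(columns={"chrom": "CHROM", "pos": "POS"})
            peaks = peaks.assign(CSS=fixed_chrom)
        _write(name, peaks, peak_cols)
    if calls is not None:
        path = os.path.join(out_dir, "epistasis_calls.tsv")
        calls.to_csv(path, sep="\t", index=False)
        paths["epistasis_calls.tsv"] = path
    return paths


def read_s1_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-SNP z-score table with columns label/chr/CHROM/POS/zscore/q5."""
    df = pd.read_csv(path, sep="\t")
    required = ["label", "chr", "CHROM", "POS", "zscore", "q5"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    return df
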