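"""Reading GWAS summary statistics, aligning two studies, writing results.

Inputs are delimited text (TSV by default) with a header naming at least
``snp_id``, ``chrom``, ``pos`` and one of ``pvalue`` / ``zvalue``.  Two
studies are aligned by intersecting SNP identifiers; within each chromosome
sites are ordered by position ascending, which defines the Markov-chain
neighbourhood used by the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ZMatrix
from .multitest import DecisionResult, pvalues_to_z

__all__ = ["StudyTable", "read_summary_stats", "align_studies", "write_results"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("snp_id", "chrom", "pos")


@dataclass
class StudyTable:
    """Validated per-study summary statistics.

    ``value_type`` declares whether the table carries p-values or z-values
    (exactly one of the two columns is present).
    """

    df: pd.DataFrame
    label: str
    value_type: str  # "pvalue" | "zvalue"

    @property
    def n_sites(self) -> int:
        return len(self.df)


def read_summary_stats(
    path,
    delimiter: str = "\t",
    label: Optional[str] = None,
    column_map: Optional[Dict[str, str]] = None,
) -> StudyTable:
    """Read and validate one study's summary statistics.

    ``column_map`` renames file columns onto the expected names, e.g.
    ``{"SNP": "snp_id", "P": "pvalue"}``.  Malformed rows (non-numeric or
    out-of-range p-values, negative positions) are reported with their
    1-based file line numbers and the read fails hard.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"chrom": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    has_p = "pvalue" in df.columns
    has_z = "zvalue" in df.columns
    if has_p == has_z:
        raise ValueError(f"{path}: exactly one of pvalue/zvalue must be present")
    value_col = "pvalue" if has_p else "zvalue"
    # line numbers: header is line 1
    lines = np.arange(2, len(df) + 2)
    vals = pd.to_numeric(df[value_col], errors="coerce")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = vals.isna() | pos.isna() | (pos < 0)
    if has_p:
        bad |= ~((vals > 0) & (vals <= 1))
    else:
        bad |= ~np.isfinite(vals)
    if bad.any():
        bad_lines = lines[bad.to_numpy()][:10].tolist()
        raise ValueError(
            f"{path}: {int(bad.sum())} malformed row(s), e.g. at line(s) {bad_lines} "
            f"(non-numeric, {value_col} out of range, or negative pos)"
        )
    dup = df["snp_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: {int(dup.sum())} duplicate snp_id(s), "
            f"e.g. {df.loc[dup, 'snp_id'].iloc[0]!r}"
        )
    df = df.assign(**{value_col: vals, "pos": pos.astype(np.int64)})
    df["chrom"] = df["chrom"].astype(str)
    return StudyTable(
        df=df[["snp_id", "chrom", "pos", value_col]].reset_index(drop=True),
        label=label or str(path),
        value_type=value_col,
    )


def _zvalues(table: StudyTable, df: pd.DataFrame) -> np.ndarray:
    if table.value_type == "pvalue":
        return pvalues_to_z(df["pvalue"].to_numpy())
    return df["zvalue"].to_numpy(dtype=float)


def align_studies(t1: StudyTable, t2: StudyTable) -> List[ZMatrix]:
    """Inner-join two studies on snp_id and return one ZMatrix per
    chromosome, sites sorted by position ascending (the chain order).

    SNPs present in only one study are dropped (counts logged); a shared
    snp_id with conflicting chromosome or position is an error.
    """
    merged = t1.df.merge(t2.df, on="snp_id", suffixes=("_1", "_2"), how="inner")
    if merged.empty:
        raise ValueError("the two studies share no snp_id")
    conflict = (merged["chrom_1"] != merged["chrom_2"]) | (
        merged["pos_1"] != merged["pos_2"]
    )
    if conflict.any():
        offenders = merged.loc[conflict, "snp_id"].head(10).tolist()
        raise ValueError(
            f"{int(conflict.sum())} snp_id(s) with conflicting chrom/pos, "
            f"e.g. {offenders}"
        )
    logger.info(
        "aligned %d shared SNPs (dropped %d from %s, %d from %s)",
        len(merged),
        t1.n_sites - len(merged),
        t1.label,
        t2.n_sites - len(merged),
        t2.label,
    )
    vcol1 = t1.value_type + "_1" if t1.value_type == t2.value_type else t1.value_type
    vcol2 = t2.value_type + "_2" if t1.value_type == t2.value_type else t2.value_type
    out: List[ZMatrix] = []
    for chrom in sorted(merged["chrom_1"].unique()):
        sub = merged[merged["chrom_1"] == chrom].sort_values(
            ["pos_1", "snp_id"], kind="stable"
        )
        z1 = (
            pvalues_to_z(sub[vcol1].to_numpy())
            if t1.value_type == "pvalue"
            else sub[vcol1].to_numpy(dtype=float)
        )
        z2 = (
            pvalues_to_z(sub[vcol2].to_numpy())
            if t2.value_type == "pvalue"
            else sub[vcol2].to_numpy(dtype=float)
        )
        out.append(
            ZMatrix(
                z=np.column_stack([z1, z2]),
                site_ids=sub["snp_id"].to_numpy(),
                chrom=np.full(len(sub), chrom, dtype=object),
                pos=sub["pos_1"].to_numpy(),
            )
        )
    return out


def write_results(
    decision: DecisionResult,
    zmats: Sequence[ZMatrix],
    path,
    delimiter: str = "\t",
) -> pd.DataFrame:
    """Write the pooled result table: one row per site with snp_id, chrom,
    pos, z1, z2, replis, rank, rejected — sorted by rank (repLIS ascending,
    ties by pooled site index).  Floats are printed at 12 significant
    digits so a read-back reproduces them losslessly."""
    total = sum(zm.m for zm in zmats)
    if total != decision.statistic.size:
        raise ValueError("decision and site annotations have different lengths")
    ids = np.concatenate(
        [
            zm.site_ids
            if zm.site_ids is not None
            else np.array([f"site_{k}_{j}" for j in range(zm.m)], dtype=object)
            for k, zm in enumerate(zmats)
        ]
    )
    chrom = np.concatenate(
        [
            zm.chrom if zm.chrom is not None else np.full(zm.m, str(k), dtype=object)
            for k, zm in enumerate(zmats)
        ]
    )
    pos = np.concatenate(
        [
            zm.pos if zm.pos is not None else np.arange(1, zm.m + 1)
            for zm in zmats
        ]
    )
    z = np.vstack([zm.z for zm in zmats])
    rank = np.empty(total, dtype=np.int64)
    rank[decision.order] = np.arange(1, total + 1)
    df = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chrom,
            "pos": pos,
            "z1": z[:, 0],
            "z2": z[:, 1],
            "replis": decision.statistic,
            "rank": rank,
            "rejected": decision.delta,
        }
    ).sort_values("rank", kind="stable")
    df.to_csv(path, sep=delimiter, index=False, float_format="%.12g")
    return df
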