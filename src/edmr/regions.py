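"""Segmentation of CpGs into candidate regions and the three DMR filters.

A region is a maximal run of same-chromosome CpGs in which every adjacent
gap is <= D bp (strictly greater than D splits). Candidate DMRs are the
regions surviving three independent, adjustable filters:

1. at least ``min_dmcs`` differentially methylated cytosines (DMC: qvalue
   below ``dmc_qvalue`` and absolute methylation difference of at least
   ``dmc_diff`` percentage points),
2. at least ``min_cpgs`` member CpGs,
3. absolute unweighted mean methylation difference strictly greater than
   ``min_abs_mean_diff`` percentage points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REGION_COLUMNS = ["region_id", "chrom", "start", "end", "cpg_count", "dmc_count",
                  "mean_diff", "direction"]

DEFAULT_DMC_QVALUE = 0.01
DEFAULT_DMC_DIFF = 25.0


def segment_regions(cpgs: pd.DataFrame, dist_cutoff: int) -> pd.DataFrame:
    """Label each CpG with a ``region_id`` under the gap rule.

    Returns a copy of ``cpgs`` sorted by (chrom, pos) with an integer
    ``region_id`` column; ids increase along the genome and a chromosome
    change always starts a new region. A gap exactly equal to the cutoff
    stays within one region.
    """
    if dist_cutoff < 1:
        raise ValueError(f"dist_cutoff must be >= 1, got {dist_cutoff}")
    out = cpgs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True).copy()
    if out.empty:
        out["region_id"] = pd.Series(dtype="int64")
        return out
    pos = out["pos"].to_numpy()
    chrom = out["chrom"].to_numpy()
    new_region = np.ones(len(out), dtype=bool)
    same_chrom = chrom[1:] == chrom[:-1]
    new_region[1:] = ~same_chrom | (np.diff(pos) > dist_cutoff)
    out["region_id"] = np.cumsum(new_region) - 1
    return out


def is_dmc(cpgs: pd.DataFrame, dmc_qvalue: float = DEFAULT_DMC_QVALUE,
           dmc_diff: float = DEFAULT_DMC_DIFF) -> pd.Series:
    """Boolean mask of CpGs passing the per-site DMC definition."""
    return (cpgs["qvalue"] < dmc_qvalue) & (cpgs["meth_diff"].abs() >= dmc_diff)


def count_dmcs(members: pd.DataFrame, dmc_qvalue: float = DEFAULT_DMC_QVALUE,
               dmc_diff: float = DEFAULT_DMC_DIFF) -> int:
    """Number of member CpGs that qualify as DMCs."""
    return int(is_dmc(members, dmc_qvalue, dmc_diff).sum())


def summarize_regions(labelled_cpgs: pd.DataFrame,
                      dmc_qvalue: float = DEFAULT_DMC_QVALUE,
                      dmc_diff: float = DEFAULT_DMC_DIFF) -> pd.DataFrame:
    """Aggregate labelled CpGs into one row per region.

    ``mean_diff`` is the unweighted arithmetic mean of member methylation
    differences; ``direction`` is ``hyper`` iff it is positive. Region
    start/end are the first/last member CpG positions (no padding).
    """
    if labelled_cpgs.empty:
        return pd.DataFrame(columns=REGION_COLUMNS)
    df = labelled_cpgs.copy()
    df["_dmc"] = is_dmc(df, dmc_qvalue, dmc_diff)
    agg = df.groupby("region_id", sort=True).agg(
        chrom=("chrom", "first"),
        start=("pos", "min"),
        end=("pos", "max"),
        cpg_count=("pos", "size"),
        dmc_count=("_dmc", "sum"),
        mean_diff=("meth_diff", "mean"),
    ).reset_index()
    agg["dmc_count"] = agg["dmc_count"].astype("int64")
    agg["direction"] = np.where(agg["mean_diff"] > 0, "hyper", "hypo")
    return agg[REGION_COLUMNS]


def filter_regions(regions: pd.DataFrame, min_dmcs: int = 1, min_cpgs: int = 3,
                   min_abs_mean_diff: float = 20.0) -> pd.DataFrame:
    """Apply the three DMR filters; order of surviving regions is preserved.

    The mean-difference test is strict (> ``min_abs_mean_diff``); the count
    tests are inclusive (>=).
    """
    keep = (
        (regions["dmc_count"] >= min_dmcs)
        & (regions["cpg_count"] >= min_cpgs)
        & (regions["mean_diff"].abs() > min_abs_mean_diff)
    )
    return regions[keep].reset_index(drop=True)
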