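"""Readers/writers for per-CpG differential-methylation tables, interval
tracks, gene models and DMR results.

Internal coordinates are 1-based inclusive everywhere; BED (0-based
half-open) and refFlat conventions are converted at the file boundary only.
Chromosome names are compared verbatim; pass ``strip_chr=True`` to opt in to
removing a leading ``chr`` prefix.

The per-CpG differential table is the methylKit-style differential output:
tab-delimited with a header ``chr  start  end  strand  pvalue  qvalue
meth.diff`` where ``start == end`` is the 1-based cytosine position and
``meth.diff`` is the methylation difference (treatment − control) in
percentage points. An optional ``coverage`` column is carried through when
present.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import FeatureTrack, GeneModel
from .exceptions import ParseError, ValidationError

log = logging.getLogger(__name__)

#: canonical column order of the in-memory per-CpG frame
CPG_COLUMNS = ["chrom", "pos", "strand", "coverage", "meth_diff", "pvalue", "qvalue"]

#: canonical column order of the in-memory DMR frame
DMR_COLUMNS = [
    "chrom", "start", "end", "cpg_count", "dmc_count",
    "mean_diff", "direction", "p_combined", "q_value",
]

_METHYLDIFF_REQUIRED = ["chr", "start", "end", "strand", "pvalue", "qvalue", "meth.diff"]
_BED_DMC_COLUMNS = ["chrom", "start", "end", "strand", "pvalue", "qvalue", "meth_diff"]
_VALID_STRANDS = {"+", "-", "."}


def _apply_strip_chr(series: pd.Series) -> pd.Series:
    return series.str.replace("^chr", "", regex=True)


def _validate_cpgs(df: pd.DataFrame, path, header_lines: int) -> None:
    """Raise ValidationError naming the first offending file line."""

    def bad_line(mask: pd.Series) -> int:
        return int(df.index[mask][0]) + header_lines + 1

    for col, lo, hi in (("pvalue", 0.0, 1.0), ("qvalue", 0.0, 1.0), ("meth_diff", -100.0, 100.0)):
        vals = df[col]
        mask = ~vals.between(lo, hi) | vals.isna()
        if mask.any():
            raise ValidationError(
                f"{path}: {col}={vals[mask].iloc[0]!r} outside [{lo}, {hi}] at line {bad_line(mask)}"
            )
    mask = df["pos"] < 1
    if mask.any():
        raise ValidationError(f"{path}: position < 1 at line {bad_line(mask)}")
    bad_strand = ~df["strand"].isin(_VALID_STRANDS)
    if bad_strand.any():
        raise ValidationError(f"{path}: invalid strand at line {bad_line(bad_strand)}")
    dup = df.duplicated(subset=["chrom", "pos", "strand"], keep=False)
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (chrom, pos, strand) record at line {bad_line(dup)}; "
            "destrand or deduplicate the input upstream"
        )


def read_dmc_table(path, format_hint: str = "methyldiff", strip_chr: bool = False) -> pd.DataFrame:
    """Read a per-CpG differential-methylation table.

    Parameters
    ----------
    path
        Tab-delimited file. ``format_hint='methyldiff'`` expects a header
        ``chr start end strand pvalue qvalue meth.diff`` with 1-based
        ``start == end``; ``format_hint='bed'`` expects headerless 0-based
        half-open rows ``chrom start end strand pvalue qvalue meth.diff``.
    strip_chr
        Remove a leading ``chr`` from chromosome names.

    Returns
    -------
    DataFrame with columns :data:`CPG_COLUMNS`, sorted by (chrom, pos).
    """
    path = Path(path)
    if format_hint not in ("methyldiff", "bed"):
        raise ValueError(f"unknown format_hint {format_hint!r}")
    try:
        if format_hint == "methyldiff":
            raw = pd.read_csv(path, sep="\t")
            header_lines = 1
        else:
            raw = pd.read_csv(path, sep="\t", header=None)
            header_lines = 0
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    if raw.empty:
        raise ParseError(f"{path}: no data rows")

    if format_hint == "methyldiff":
        missing = [c for c in _METHYLDIFF_REQUIRED if c not in raw.columns]
        if missing:
            raise ParseError(f"{path}: missing required columns {missing}")
        df = pd.DataFrame({
            "chrom": raw["chr"].astype(str),
            "pos": raw["start"],
            "strand": raw["strand"].astype(str),
            "coverage": raw["coverage"] if "coverage" in raw.columns else 0,
            "meth_diff": raw["meth.diff"],
            "pvalue": raw["pvalue"],
            "qvalue": raw["qvalue"],
        })
        mismatch = raw["start"] != raw["end"]
        if mismatch.any():
            line = int(raw.index[mismatch][0]) + header_lines + 1
            raise ValidationError(f"{path}: start != end at line {line} (per-base table expected)")
    else:
        if raw.shape[1] < 7:
            raise ParseError(f"{path}: BED DMC input needs 7 columns, got {raw.shape[1]}")
        raw = raw.iloc[:, :7]
        raw.columns = _BED_DMC_COLUMNS
        df = pd.DataFrame({
            "chrom": raw["chrom"].astype(str),
            "pos": raw["start"] + 1,  # 0-based half-open -> 1-based position
            "strand": raw["strand"].astype(str),
            "coverage": 0,
            "meth_diff": raw["meth_diff"],
            "pvalue": raw["pvalue"],
            "qvalue": raw["qvalue"],
        })
        mismatch = raw["end"] - raw["start"] != 1
        if mismatch.any():
            line = int(raw.index[mismatch][0]) + 1
            raise ValidationError(f"{path}: BED row not a single base at line {line}")

    for col in ("pos", "coverage"):
        try:
            df[col] = df[col].astype("int64")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-integer {col}: {exc}") from None
    for col in ("meth_diff", "pvalue", "qvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["coverage"] < 0).any():
        raise ValidationError(f"{path}: negative coverage")
    if strip_chr:
        df["chrom"] = _apply_strip_chr(df["chrom"])
    _validate_cpgs(df, path, header_lines)
    df = df[CPG_COLUMNS].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def write_dmc_table(cpgs: pd.DataFrame, path) -> None:
    """Write a per-CpG frame back to the methyldiff dialect (round-trippable)."""
    out = pd.DataFrame({
        "chr": cpgs["chrom"], "start": cpgs["pos"], "end": cpgs["pos"],
        "strand": cpgs["strand"], "coverage": cpgs["coverage"],
        "pvalue": cpgs["pvalue"], "qvalue": cpgs["qvalue"], "meth.diff": cpgs["meth_diff"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_interval_track(path, name: str, strip_chr: bool = False) -> FeatureTrack:
    """Read a BED3+/BED6 file into a 1-based inclusive :class:`FeatureTrack`."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        log.warning("interval track %s (%s) is empty", name, path)
        return FeatureTrack(name)
    raw = raw[~raw[0].astype(str).str.startswith(("track", "browser"))]
    if raw.empty:
        log.warning("interval track %s (%s) is empty", name, path)
        return FeatureTrack(name)
    if raw.shape[1] < 3:
        raise ParseError(f"{path}: BED needs >= 3 columns")
    df = pd.DataFrame({
        "chrom": raw[0].astype(str),
        "start": raw[1].astype("int64") + 1,  # BED half-open -> 1-based inclusive
        "end": raw[2].astype("int64"),
        "strand": raw[5].astype(str) if raw.shape[1] >= 6 else ".",
        "name": raw[3].astype(str) if raw.shape[1] >= 4
        else [f"{name}_{i}" for i in range(len(raw))],
    })
    if strip_chr:
        df["chrom"] = _apply_strip_chr(df["chrom"])
    bad = df["end"] < df["start"]
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise ValidationError(f"{path}: interval with end < start at line {line}")
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return FeatureTrack(name, df)


def read_gene_model(path, strip_chr: bool = False) -> list[GeneModel]:
    """Read a refFlat-style gene table into :class:`GeneModel` records.

    Expected columns: geneName, name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds (0-based half-open,
    comma-terminated block lists). ``cdsStart == cdsEnd`` marks a non-coding
    transcript.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if raw.shape[1] < 11:
        raise ParseError(f"{path}: refFlat needs 11 columns, got {raw.shape[1]}")
    models: list[GeneModel] = []
    for i, row in raw.iterrows():
        line = i + 1
        gene, transcript, chrom, strand = (str(row[0]), str(row[1]), str(row[2]), str(row[3]))
        if strip_chr and chrom.startswith("chr"):
            chrom = chrom[3:]
        tx_start, tx_end = int(row[4]) + 1, int(row[5])
        cds_start0, cds_end0 = int(row[6]), int(row[7])
        n_exons = int(row[8])
        ex_starts = [int(v) + 1 for v in str(row[9]).rstrip(",").split(",") if v != ""]
        ex_ends = [int(v) for v in str(row[10]).rstrip(",").split(",") if v != ""]
        if len(ex_starts) != n_exons or len(ex_ends) != n_exons:
            raise ValidationError(f"{path}: exonCount mismatch at line {line}")
        exons = sorted(zip(ex_starts, ex_ends))
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValidationError(f"{path}: overlapping exon blocks at line {line}")
        if cds_start0 == cds_end0:
            cds_start = cds_end = None
        else:
            cds_start, cds_end = cds_start0 + 1, cds_end0
            if cds_start < tx_start or cds_end > tx_end or cds_start > cds_end:
                raise ValidationError(f"{path}: CDS outside transcript bounds at line {line}")
        if tx_start > tx_end:
            raise ValidationError(f"{path}: txStart > txEnd at line {line}")
        models.append(GeneModel(gene, transcript, chrom, strand, tx_start, tx_end,
                                cds_start, cds_end, tuple(exons)))
    return models


def _bed_score(q: float) -> int:
    if q <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(q))))


def write_dmr_output(dmrs: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write finalized DMRs.

    ``tsv``: all :data:`DMR_COLUMNS`, round-trippable via
    :func:`read_dmr_table`. ``bed``: BED6 with 0-based half-open coordinates,
    name = ``hyper``/``hypo`` and score = ``min(1000, round(-10*log10(q)))``.
    Rows are emitted sorted by (chrom, start).
    """
    if format not in ("tsv", "bed"):
        raise ValueError(f"unknown DMR output format {format!r}")
    dmrs = dmrs.sort_values(["chrom", "start"], kind="mergesort")
    if format == "tsv":
        dmrs[DMR_COLUMNS].to_csv(path, sep="\t", index=False)
        return
    with open(path, "w") as fh:
        for row in dmrs.itertuples():
            fh.write(
                f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\t{row.direction}\t"
                f"{_bed_score(float(row.q_value))}\t.\n"
            )


def read_dmr_table(path) -> pd.DataFrame:
    """Read back a DMR TSV written by :func:`write_dmr_output`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "direction": str})
    missing = [c for c in DMR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing DMR columns {missing}")
    for col in ("start", "end", "cpg_count", "dmc_count"):
        df[col] = df[col].astype("int64")
    return df[DMR_COLUMNS]
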