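"""Small 1-based inclusive interval helpers (merge / subtract / overlap).

All frames use columns ``chrom`` (str), ``start`` and ``end`` (int, 1-based
inclusive, start <= end). These helpers are internal plumbing for shore
derivation and annotation; the public interval container is
:class:`edmr.annotation.FeatureTrack`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def empty_intervals(extra: list[str] | None = None) -> pd.DataFrame:
    cols = INTERVAL_COLUMNS + (extra or [])
    return pd.DataFrame({c: pd.Series(dtype="int64" if c in ("start", "end") else "object") for c in cols})


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended (adjacent) intervals per chromosome."""
    if df.empty:
        return empty_intervals()
    out = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + 1:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Return the parts of intervals in ``a`` not covered by any interval in ``b``.

    Non-coordinate columns of ``a`` are propagated to every surviving piece.
    """
    if a.empty or b.empty:
        return a.copy()
    b_merged = merge_intervals(b)
    pieces = []
    extra_cols = [c for c in a.columns if c not in INTERVAL_COLUMNS]
    for _, row in a.iterrows():
        segs = [(int(row["start"]), int(row["end"]))]
        blockers = b_merged[b_merged["chrom"] == row["chrom"]]
        for _, blk in blockers.iterrows():
            nxt = []
            for s, e in segs:
                if blk["end"] < s or blk["start"] > e:
                    nxt.append((s, e))
                    continue
                if blk["start"] > s:
                    nxt.append((s, int(blk["start"]) - 1))
                if blk["end"] < e:
                    nxt.append((int(blk["end"]) + 1, e))
            segs = nxt
            if not segs:
                break
        for s, e in segs:
            rec = {"chrom": row["chrom"], "start": s, "end": e}
            for c in extra_cols:
                rec[c] = row[c]
            pieces.append(rec)
    if not pieces:
        return empty_intervals(extra_cols)
    return pd.DataFrame(pieces, columns=list(a.columns))


def overlap_length(s1: int, e1: int, s2: int, e2: int) -> int:
    """Overlap in bp between two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def total_length(df: pd.DataFrame) -> int:
    """Total covered bases of a (possibly overlapping) interval set."""
    merged = merge_intervals(df)
    if merged.empty:
        return 0
    return int((merged["end"] - merged["start"] + 1).sum())


def intersect_length(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total bases covered by both interval sets."""
    am, bm = merge_intervals(a), merge_intervals(b)
    if am.empty or bm.empty:
        return 0
    tot = 0
    for chrom, asub in am.groupby("chrom"):
        bsub = bm[bm["chrom"] == chrom]
        for _, r1 in asub.iterrows():
            lo = np.maximum(bsub["start"].to_numpy(), r1["start"])
            hi = np.minimum(bsub["end"].to_numpy(), r1["end"])
            tot += int(np.clip(hi - lo + 1, 0, None).sum())
    return tot
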