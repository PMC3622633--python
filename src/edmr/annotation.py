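"""Annotation of DMRs against gene models, CpG islands/shores and user tracks.

Gene bodies are decomposed into promoter, 5'UTR, CDS, intron and 3'UTR parts
derived from refFlat-style transcript models; CpG-island shores are the 2-kb
flanks of each island with island bases subtracted. A DMR is reported against
every feature class it overlaps (no precedence) unless an explicit precedence
order is requested.

All coordinates here are 1-based inclusive; conversion from BED/refFlat
conventions happens in :mod:`edmr.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._intervals import (
    INTERVAL_COLUMNS,
    empty_intervals,
    merge_intervals,
    overlap_length,
    subtract_intervals,
)

GENE_PART_NAMES = ("promoter", "5utr", "cds", "intron", "3utr")

#: precedence order used by ``annotate_dmrs(..., precedence=True)``
DEFAULT_PRECEDENCE = ("promoter", "5utr", "3utr", "cds", "intron")


@dataclass(frozen=True)
class GeneModel:
    """One transcript: bounds, CDS bounds and exon blocks, 1-based inclusive.

    ``cds_start``/``cds_end`` are ``None`` for non-coding transcripts.
    """

    gene: str
    transcript: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None
    cds_end: int | None
    exons: tuple[tuple[int, int], ...]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


@dataclass
class FeatureTrack:
    """Named collection of genomic intervals used for annotation."""

    name: str
    intervals: pd.DataFrame = field(default_factory=lambda: empty_intervals(["strand", "name"]))

    def __post_init__(self) -> None:
        if self.intervals.empty and list(self.intervals.columns) != INTERVAL_COLUMNS + ["strand", "name"]:
            self.intervals = empty_intervals(["strand", "name"])

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_records(cls, name: str, records: Iterable[tuple]) -> "FeatureTrack":
        """Build a track from (chrom, start, end[, strand[, name]]) tuples."""
        rows = []
        for i, rec in enumerate(records):
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            strand = rec[3] if len(rec) > 3 else "."
            label = rec[4] if len(rec) > 4 else f"{name}_{i}"
            rows.append((chrom, start, end, strand, label))
        if not rows:
            return cls(name)
        df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS + ["strand", "name"])
        return cls(name, df.sort_values(["chrom", "start", "end"]).reset_index(drop=True))


def _clip1(start: int) -> int:
    return max(1, start)


def derive_gene_parts(
    models: Sequence[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 1000,
) -> dict[str, FeatureTrack]:
    """Decompose transcripts into promoter/5utr/cds/intron/3utr tracks.

    The promoter is the window ``[TSS - promoter_up, TSS + promoter_down]``
    around the strand-aware transcription start site, clipped at position 1.
    UTRs are the exonic sequence outside the CDS bounds (strand-aware: the
    tx_start side is the 5' end on ``+``, the 3' end on ``-``); CDS is exonic
    sequence within the CDS bounds; introns are the gaps between consecutive
    exons. Non-coding transcripts contribute only promoter and introns.
    """
    parts: dict[str, list[tuple]] = {n: [] for n in GENE_PART_NAMES}
    for m in models:
        tss = m.tx_start if m.strand == "+" else m.tx_end
        if m.strand == "+":
            prom = (_clip1(tss - promoter_up), tss + promoter_down)
        else:
            prom = (_clip1(tss - promoter_down), tss + promoter_up)
        parts["promoter"].append((m.chrom, prom[0], prom[1], m.strand, m.transcript))

        exons = sorted(m.exons)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 > e1 + 1:
                parts["intron"].append((m.chrom, e1 + 1, s2 - 1, m.strand, m.transcript))

        if not m.is_coding:
            continue
        cs, ce = m.cds_start, m.cds_end
        left_utr, right_utr = [], []
        for s, e in exons:
            if min(e, ce) >= max(s, cs):
                parts["cds"].append((m.chrom, max(s, cs), min(e, ce), m.strand, m.transcript))
            if s <= cs - 1 and e >= m.tx_start:
                lo, hi = s, min(e, cs - 1)
                if lo <= hi:
                    left_utr.append((m.chrom, lo, hi, m.strand, m.transcript))
            if e >= ce + 1:
                lo, hi = max(s, ce + 1), e
                if lo <= hi:
                    right_utr.append((m.chrom, lo, hi, m.strand, m.transcript))
        if m.strand == "+":
            parts["5utr"].extend(left_utr)
            parts["3utr"].extend(right_utr)
        else:
            parts["5utr"].extend(right_utr)
            parts["3utr"].extend(left_utr)
    return {name: FeatureTrack.from_records(name, rows) for name, rows in parts.items()}


def derive_shores(islands: FeatureTrack, shore_width: int = 2000) -> FeatureTrack:
    """CpG-island shores: the ``shore_width``-bp flanks of each island.

    Shores are clipped at position 1 and any base falling inside an island
    (including a neighbouring one) is subtracted, so shores and islands are
    disjoint by construction.
    """
    if islands.intervals.empty:
        return FeatureTrack("shore")
    rows = []
    for _, isl in islands.intervals.iterrows():
        s, e = int(isl["start"]), int(isl["end"])
        if s - 1 >= 1:
            rows.append({"chrom": isl["chrom"], "start": _clip1(s - shore_width), "end": s - 1,
                         "strand": ".", "name": f"{isl['name']}_left"})
        rows.append({"chrom": isl["chrom"], "start": e + 1, "end": e + shore_width,
                     "strand": ".", "name": f"{isl['name']}_right"})
    raw = pd.DataFrame(rows, columns=INTERVAL_COLUMNS + ["strand", "name"])
    clean = subtract_intervals(raw, islands.intervals)
    clean = clean.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return FeatureTrack("shore", clean)


def _build_trees(track: FeatureTrack) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in track.intervals.groupby("chrom"):
        # half-open tree coordinates: [start, end + 1)
        trees[chrom] = IntervalTree.from_tuples(
            (int(r.start), int(r.end) + 1, r.name) for r in sub.itertuples()
        )
    return trees


def annotate_dmrs(
    dmrs: pd.DataFrame,
    tracks: Sequence[FeatureTrack],
    precedence: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap DMRs with feature tracks.

    Returns ``(rows, counts)``: one row per (DMR, feature interval) pair with
    at least 1 bp of overlap, and a per-feature table counting distinct DMRs
    (plus an ``intergenic`` tally of DMRs overlapping no track at all).
    Strand is ignored. Without ``precedence`` a DMR counts in every feature
    class it overlaps; with a precedence order, only in the first listed
    feature it overlaps (features absent from the order are always reported).
    """
    trees = {t.name: _build_trees(t) for t in tracks}
    order = list(tracks)
    rows: list[dict] = []
    hit_features: dict[int, set[str]] = {}
    for dmr in dmrs.itertuples():
        dmr_id = f"{dmr.chrom}:{dmr.start}-{dmr.end}"
        feats: set[str] = set()
        for track in order:
            tree = trees[track.name].get(dmr.chrom)
            if tree is None:
                continue
            for iv in sorted(tree.overlap(int(dmr.start), int(dmr.end) + 1)):
                ol = overlap_length(int(dmr.start), int(dmr.end), iv.begin, iv.end - 1)
                if ol >= 1:
                    feats.add(track.name)
                    rows.append({"dmr_id": dmr_id, "chrom": dmr.chrom, "start": int(dmr.start),
                                 "end": int(dmr.end), "feature": track.name,
                                 "interval_name": iv.data, "overlap_bp": ol})
        hit_features[dmr.Index] = feats
    rows_df = pd.DataFrame(rows, columns=["dmr_id", "chrom", "start", "end", "feature",
                                          "interval_name", "overlap_bp"])

    if precedence is not None:
        keep: dict[int, set[str]] = {}
        ranked = list(precedence)
        for idx, feats in hit_features.items():
            chosen = next((f for f in ranked if f in feats), None)
            keep[idx] = {f for f in feats if f not in ranked or f == chosen}
            hit_features[idx] = keep[idx]
        keep_pairs = {
            (f"{dmr.chrom}:{dmr.start}-{dmr.end}", f)
            for dmr in dmrs.itertuples()
            for f in keep[dmr.Index]
        }
        if not rows_df.empty:
            mask = [
                (r.dmr_id, r.feature) in keep_pairs for r in rows_df.itertuples()
            ]
            rows_df = rows_df[mask].reset_index(drop=True)

    counts = []
    for track in order:
        n = sum(1 for feats in hit_features.values() if track.name in feats)
        counts.append({"feature": track.name, "n_dmrs": n})
    n_intergenic = sum(1 for feats in hit_features.values() if not feats)
    counts.append({"feature": "intergenic", "n_dmrs": n_intergenic})
    counts_df = pd.DataFrame(counts, columns=["feature", "n_dmrs"])
    return rows_df, counts_df


def gene_part_partition(model: GeneModel) -> pd.DataFrame:
    """Union of UTR/CDS/intron parts of one coding transcript (diagnostic).

    Used to verify that the derived parts tile ``[tx_start, tx_end]`` exactly.
    """
    tracks = derive_gene_parts([model])
    frames = [tracks[n].intervals for n in ("5utr", "cds", "intron", "3utr")]
    allp = pd.concat(frames, ignore_index=True)
    return merge_intervals(allp[INTERVAL_COLUMNS])
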