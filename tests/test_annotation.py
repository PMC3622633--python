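import numpy as np
import pandas as pd
import pytest

from edmr._intervals import merge_intervals, overlap_length, subtract_intervals
from edmr.annotation import (
    DEFAULT_PRECEDENCE,
    FeatureTrack,
    GeneModel,
    annotate_dmrs,
    derive_gene_parts,
    derive_shores,
    gene_part_partition,
)

from conftest import make_dmrs

PLUS_TX = GeneModel("G1", "T1", "chr1", "+", 1001, 2000, 1201, 1800,
                    ((1001, 1400), (1601, 2000)))
MINUS_TX = GeneModel("G1", "T1m", "chr1", "-", 1001, 2000, 1201, 1800,
                     ((1001, 1400), (1601, 2000)))


def track_tuples(track):
    return sorted((r.chrom, r.start, r.end) for r in track.intervals.itertuples())


class TestGeneParts:
    def test_plus_strand_decomposition(self):
        parts = derive_gene_parts([PLUS_TX])
        assert track_tuples(parts["5utr"]) == [("chr1", 1001, 1200)]
        assert track_tuples(parts["cds"]) == [("chr1", 1201, 1400), ("chr1", 1601, 1800)]
        assert track_tuples(parts["intron"]) == [("chr1", 1401, 1600)]
        assert track_tuples(parts["3utr"]) == [("chr1", 1801, 2000)]
        assert track_tuples(parts["promoter"]) == [("chr1", 1, 2001)]  # clipped at 1

    def test_minus_strand_swaps_utr_ends(self):
        parts = derive_gene_parts([MINUS_TX])
        assert track_tuples(parts["3utr"]) == [("chr1", 1001, 1200)]
        assert track_tuples(parts["5utr"]) == [("chr1", 1801, 2000)]
        # promoter around the tx end on the minus strand
        assert track_tuples(parts["promoter"]) == [("chr1", 1000, 3000)]

    def test_noncoding_single_exon_contributes_only_promoter(self):
        nc = GeneModel("G2", "T2", "chr1", "+", 5001, 6000, None, None, ((5001, 6000),))
        parts = derive_gene_parts([nc])
        assert len(parts["promoter"]) == 1
        for name in ("5utr", "cds", "intron", "3utr"):
            assert len(parts[name]) == 0

    @staticmethod
    def random_coding_model(rng, idx):
        n_exons = int(rng.integers(1, 6))
        bounds = np.sort(rng.choice(np.arange(1000, 50_000), 2 * n_exons, replace=False))
        exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)]
        tx_start, tx_end = exons[0][0], exons[-1][1]
        exonic = [b for s, e in exons for b in (s, e)]
        cds_start = int(rng.integers(tx_start, tx_end))
        cds_end = int(rng.integers(cds_start, tx_end + 1))
        # snap CDS bounds into exonic sequence so the model is well-formed
        cds_start = min(max(cds_start, tx_start), tx_end)
        strand = "+" if rng.random() < 0.5 else "-"
        return GeneModel(f"G{idx}", f"T{idx}", "chr1", strand, tx_start, tx_end,
                         cds_start, max(cds_start, cds_end), tuple(exons))

    def test_partition_property_on_random_models(self, rng):
        # 5'UTR + CDS + introns + 3'UTR tile [tx_start, tx_end] with no overlap
        for idx in range(100):
            m = self.random_coding_model(rng, idx)
            merged = gene_part_partition(m)
            assert track_tuples(FeatureTrack("m", merged.assign(strand=".", name="x"))) == [
                (m.chrom, m.tx_start, m.tx_end)]
            parts = derive_gene_parts([m])
            total = sum(int((t.intervals.end - t.intervals.start + 1).sum())
                        for n, t in parts.items() if n != "promoter")
            assert total == m.tx_end - m.tx_start + 1


class TestShores:
    def test_flanks_of_isolated_island(self):
        islands = FeatureTrack.from_records("cpg_island", [("chr1", 10001, 11000)])
        shores = derive_shores(islands)
        assert track_tuples(shores) == [("chr1", 8001, 10000), ("chr1", 11001, 13000)]

    def test_inter_island_shores_trimmed(self):
        islands = FeatureTrack.from_records(
            "cpg_island", [("chr1", 10001, 11000), ("chr1", 12001, 13000)])
        shores = derive_shores(islands)
        # no shore base inside any island
        for r in shores.intervals.itertuples():
            assert overlap_length(r.start, r.end, 10001, 11000) == 0
            assert overlap_length(r.start, r.end, 12001, 13000) == 0
        # inter-island gap fully covered by trimmed shores
        assert ("chr1", 11001, 12000) in track_tuples(shores)

    def test_island_at_origin_has_no_left_shore(self):
        islands = FeatureTrack.from_records("cpg_island", [("chr1", 1, 500)])
        shores = derive_shores(islands)
        assert track_tuples(shores) == [("chr1", 501, 2500)]

    def test_total_shore_length_bounded(self, rng):
        starts = np.sort(rng.choice(np.arange(3000, 10_000_000, 100), 30, replace=False))
        islands = FeatureTrack.from_records(
            "cpg_island", [("chr1", int(s), int(s + rng.integers(200, 2000))) for s in starts])
        shores = derive_shores(islands)
        assert int((shores.intervals.end - shores.intervals.start + 1).sum()) \
            <= 2 * 2000 * len(islands)


class TestAnnotateDmrs:
    def test_overlap_length_example(self):
        dmrs = make_dmrs([("chr1", 150, 250, 3, 1, 30.0, 0.001, 0.01)])
        promoter = FeatureTrack.from_records("promoter", [("chr1", 100, 200, "+", "p1")])
        rows, counts = annotate_dmrs(dmrs, [promoter])
        assert len(rows) == 1
        assert rows.iloc[0].overlap_bp == 51
        assert counts.set_index("feature").loc["promoter", "n_dmrs"] == 1

    def test_no_overlap_goes_to_intergenic(self):
        dmrs = make_dmrs([("chr1", 10, 20, 3, 1, 30.0, 0.001, 0.01)])
        track = FeatureTrack.from_records("cds", [("chr2", 10, 20)])
        rows, counts = annotate_dmrs(dmrs, [track])
        assert len(rows) == 0
        c = counts.set_index("feature")["n_dmrs"]
        assert c["intergenic"] == 1 and c["cds"] == 0

    def test_multi_feature_dmr_counts_in_each(self):
        dmrs = make_dmrs([("chr1", 1395, 1610, 4, 2, 30.0, 0.001, 0.01)])
        parts = derive_gene_parts([PLUS_TX])
        rows, counts = annotate_dmrs(dmrs, [parts["cds"], parts["intron"]])
        c = counts.set_index("feature")["n_dmrs"]
        assert c["cds"] == 1 and c["intron"] == 1

    def test_precedence_assigns_single_gene_part(self):
        dmrs = make_dmrs([("chr1", 1395, 1610, 4, 2, 30.0, 0.001, 0.01)])
        parts = derive_gene_parts([PLUS_TX])
        tracks = [parts[n] for n in ("cds", "intron")]
        rows, counts = annotate_dmrs(dmrs, tracks, precedence=DEFAULT_PRECEDENCE)
        c = counts.set_index("feature")["n_dmrs"]
        assert c["cds"] == 1 and c["intron"] == 0

    def test_matches_all_pairs_oracle(self, rng):
        dmr_rows = []
        for _ in range(60):
            s = int(rng.integers(1, 100_000))
            dmr_rows.append(("chr1", s, s + int(rng.integers(1, 2000)), 3, 1, 25.0, 0.01, 0.02))
        dmrs = make_dmrs(dmr_rows)
        feats = []
        for i in range(80):
            s = int(rng.integers(1, 100_000))
            feats.append(("chr1", s, s + int(rng.integers(1, 3000)), ".", f"f{i}"))
        track = FeatureTrack.from_records("feat", feats)
        rows, counts = annotate_dmrs(dmrs, [track])
        got = {(r.dmr_id, r.interval_name, r.overlap_bp) for r in rows.itertuples()}
        expected = set()
        hit_dmrs = set()
        for d in dmrs.itertuples():
            for chrom, s, e, _, name in feats:
                ol = overlap_length(d.start, d.end, s, e)
                if ol >= 1:
                    expected.add((f"{d.chrom}:{d.start}-{d.end}", name, ol))
                    hit_dmrs.add(d.Index)
        assert got == expected
        assert counts.set_index("feature").loc["feat", "n_dmrs"] == len(hit_dmrs)


class TestIntervalHelpers:
    def test_merge_joins_adjacent(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [1, 11], "end": [10, 20]})
        merged = merge_intervals(df)
        assert merged.iloc[0].tolist() == ["chr1", 1, 20]

    def test_subtract_splits_interval(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [100]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [40], "end": [60]})
        out = subtract_intervals(a, b)
        assert sorted(map(tuple, out[["start", "end"]].to_numpy())) == [(1, 39), (61, 100)]
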