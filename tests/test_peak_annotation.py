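import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfinduce.peak_annotation import (
    read_bed,
    filter_by_score,
    match_across_samples,
    score_transcript,
    assign_peak,
    annotate_peaks,
    bound_gene_sets,
    _TranscriptIndex,
)


def _peaks(rows, sample="s1"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    df["name"] = [f"p{i}" for i in range(len(df))]
    df["sample_id"] = sample
    return df


def _models(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "chrom", "strand",
                                       "tss", "symbol", "symbol_score"])


def consensus_brute_force(peak_sets, min_samples):
    """Oracle: explicit connected components of the >=1bp overlap graph."""
    pooled = []
    for sid, df in peak_sets.items():
        for _, r in df.iterrows():
            pooled.append((r["chrom"], int(r["start"]), int(r["end"]),
                           float(r["score"]), sid))
    n = len(pooled)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = pooled[i], pooled[j]
            if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(pooled[i])
    out = []
    for members in comps.values():
        if len({m[4] for m in members}) >= min_samples:
            out.append((members[0][0], min(m[1] for m in members),
                        max(m[2] for m in members),
                        max(m[3] for m in members)))
    return sorted(out)


class TestFilterByScore:
    def test_boundary_inclusive(self):
        peaks = _peaks([("c1", 0, 10, 7), ("c1", 20, 30, 8),
                        ("c1", 40, 50, 9)])
        kept = filter_by_score(peaks, 8)
        assert kept["score"].tolist() == [8, 9]

    def test_zero_threshold_is_identity(self):
        peaks = _peaks([("c1", 0, 10, 7)])
        assert len(filter_by_score(peaks, 0)) == 1

    def test_empty_input(self):
        assert filter_by_score(_peaks([]), 5).empty


class TestMatchAcrossSamples:
    def test_identical_peak_in_all_samples(self):
        sets = {s: _peaks([("c1", 100, 200, 10)], s)
                for s in ("s1", "s2", "s3")}
        cons = match_across_samples(sets, 3)
        assert len(cons) == 1
        assert cons.iloc[0][["start", "end"]].tolist() == [100, 200]

    def test_singleton_dropped(self):
        sets = {"s1": _peaks([("c1", 0, 10, 1)], "s1"),
                "s2": _peaks([("c1", 100, 110, 1)], "s2")}
        assert match_across_samples(sets, 2).empty

    def test_overlap_chain_merges_transitively(self):
        # A-B overlap, B-C overlap, A-C do not: one consensus spanning A..C
        sets = {"s1": _peaks([("c1", 0, 100, 5)], "s1"),
                "s2": _peaks([("c1", 90, 200, 7)], "s2"),
                "s3": _peaks([("c1", 190, 300, 6)], "s3")}
        cons = match_across_samples(sets, 3)
        assert len(cons) == 1
        row = cons.iloc[0]
        assert (row["start"], row["end"], row["score"]) == (0, 300, 7.0)

    def test_min_samples_exceeds_samples_errors(self):
        with pytest.raises(ValueError, match="min_samples"):
            match_across_samples({"s1": _peaks([])}, 2)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 3))
    @settings(max_examples=30, deadline=None)
    def test_matches_union_find_oracle(self, seed, min_samples):
        rng = np.random.default_rng(seed)
        sets = {}
        for s in range(3):
            starts = rng.integers(0, 500, size=rng.integers(1, 15))
            widths = rng.integers(1, 80, size=len(starts))
            chroms = rng.choice(["c1", "c2"], size=len(starts))
            sets[f"s{s}"] = _peaks(
                [(c, int(a), int(a + w), float(rng.integers(1, 100)))
                 for c, a, w in zip(chroms, starts, widths)], f"s{s}")
        cons = match_across_samples(sets, min_samples)
        got = sorted((r["chrom"], r["start"], r["end"], r["score"])
                     for _, r in cons.iterrows())
        assert got == consensus_brute_force(sets, min_samples)


class TestScoreTranscript:
    @pytest.mark.parametrize("mid,tss,symbol_score,expected", [
        (1300, 1000, 3, 3.0),       # 300 bp -> floored at 1 kb
        (11000, 1000, 1, 0.1),      # 10 kb, predicted symbol
        (2000, 1000, 3, 3.0),       # exactly 1 kb, floor boundary
        (3000, 1000, 3, 1.5),       # 2 kb
    ])
    def test_floor_rule(self, mid, tss, symbol_score, expected):
        assert score_transcript(mid, tss, symbol_score) == pytest.approx(expected)

    def test_monotone_in_distance(self):
        scores = [score_transcript(1000 + d, 1000, 3)
                  for d in range(0, 50_000, 500)]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))


class TestAssignPeak:
    def _index(self, rows):
        return _TranscriptIndex(_models(rows))

    def test_second_transcript_above_quarter_included(self):
        # S1=3.0 (valid, <1kb), S2=0.8 (>25% of 3.0)
        idx = self._index([("txA", "c1", "+", 10_000, "A", 3),
                           ("txB", "c1", "+", 13_750, "B", 3)])
        peak = {"chrom": "c1", "start": 9_800, "end": 10_200, "name": "p"}
        a = assign_peak(peak, idx)
        assert [h.symbol for h in a.hits] == ["A", "B"]
        assert a.hits[1].score == pytest.approx(0.8)

    def test_exactly_quarter_excluded(self):
        # S2 = 0.75 = exactly 25% of 3.0 -> strict '>' excludes
        idx = self._index([("txA", "c1", "+", 10_000, "A", 3),
                           ("txB", "c1", "+", 14_000, "B", 3)])
        peak = {"chrom": "c1", "start": 9_800, "end": 10_200, "name": "p"}
        a = assign_peak(peak, idx)
        assert [h.symbol for h in a.hits] == ["A"]

    def test_beyond_window_unannotated(self):
        idx = self._index([("txA", "c1", "+", 100_000, "A", 3)])
        peak = {"chrom": "c1", "start": 39_800, "end": 40_200, "name": "p"}
        assert assign_peak(peak, idx).hits == []

    def test_exactly_50kb_excluded(self):
        idx = self._index([("txA", "c1", "+", 60_000, "A", 3)])
        peak = {"chrom": "c1", "start": 9_900, "end": 10_100, "name": "p"}
        assert assign_peak(peak, idx).hits == []

    def test_classes_by_distance(self):
        idx = self._index([("txA", "c1", "+", 10_000, "A", 3)])
        prom = assign_peak({"chrom": "c1", "start": 10_100, "end": 10_500,
                            "name": "p"}, idx)
        assert prom.hits[0].reg_class == "promoter"
        enh = assign_peak({"chrom": "c1", "start": 12_000, "end": 12_400,
                           "name": "p"}, idx)
        assert enh.hits[0].reg_class == "enhancer"

    def test_score_tie_broken_by_transcript_id(self):
        idx = self._index([("txB", "c1", "+", 10_300, "B", 3),
                           ("txA", "c1", "+", 9_700, "A", 3)])
        a = assign_peak({"chrom": "c1", "start": 9_800, "end": 10_200,
                         "name": "p"}, idx)
        assert a.hits[0].transcript_id == "txA"

    def test_translation_invariance(self):
        rows = [("txA", "c1", "+", 10_000, "A", 3),
                ("txB", "c1", "+", 22_000, "B", 1)]
        peak = {"chrom": "c1", "start": 11_000, "end": 11_400, "name": "p"}
        base = assign_peak(peak, self._index(rows))
        shift = 1_000_000
        moved = assign_peak(
            {"chrom": "c1", "start": peak["start"] + shift,
             "end": peak["end"] + shift, "name": "p"},
            self._index([(t, c, s, tss + shift, sym, sc)
                         for t, c, s, tss, sym, sc in rows]))
        assert [(h.symbol, h.score, h.distance, h.reg_class)
                for h in base.hits] == \
               [(h.symbol, h.score, h.distance, h.reg_class)
                for h in moved.hits]

    def test_brute_force_all_pairs_equivalence(self):
        rng = np.random.default_rng(17)
        n_tx, n_peaks = 300, 400
        models = _models([
            (f"tx{i:04d}", f"c{rng.integers(1, 4)}", "+",
             int(rng.integers(0, 2_000_000)), f"S{i:04d}",
             int(rng.choice([1, 3]))) for i in range(n_tx)])
        idx = _TranscriptIndex(models)
        for k in range(n_peaks):
            start = int(rng.integers(0, 2_000_000))
            peak = {"chrom": f"c{rng.integers(1, 4)}", "start": start,
                    "end": start + int(rng.integers(100, 1000)), "name": "p"}
            mid = (peak["start"] + peak["end"]) // 2
            cand = []
            for _, r in models[models["chrom"] == peak["chrom"]].iterrows():
                d = abs(int(r["tss"]) - mid)
                if d < 50_000:
                    cand.append((-(r["symbol_score"] / max(d, 1000) * 1000),
                                 r["transcript_id"], r["symbol"], d))
            cand.sort()
            expected = []
            if cand:
                expected.append(cand[0])
                if len(cand) > 1 and -cand[1][0] > 0.25 * -cand[0][0]:
                    expected.append(cand[1])
            got = assign_peak(peak, idx)
            assert [h.transcript_id for h in got.hits] == \
                   [c[1] for c in expected]
            for h, c in zip(got.hits, expected):
                assert h.score == pytest.approx(-c[0])
                assert h.distance == c[3]


class TestBoundGeneSets:
    def test_gene_in_both_classes(self):
        idx = _TranscriptIndex(_models([("txA", "c1", "+", 10_000, "A", 3)]))
        prom = assign_peak({"chrom": "c1", "start": 9_900, "end": 10_100,
                            "name": "p1"}, idx)
        enh = assign_peak({"chrom": "c1", "start": 15_000, "end": 15_400,
                           "name": "p2"}, idx)
        bound = bound_gene_sets([prom, enh], "T")
        assert bound.promoter_genes == {"A"}
        assert bound.enhancer_genes == {"A"}
        assert bound.any_genes == {"A"}

    def test_empty_assignments(self):
        bound = bound_gene_sets([], "T")
        assert bound.any_genes == set()


class TestReadBed:
    def test_bed5_round_trip(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("c1\t10\t20\tp1\t5.0\nc2\t0\t7\tp2\t9.5\n")
        df = read_bed(p, sample_id="s1")
        assert df["score"].tolist() == [5.0, 9.5]
        assert df["sample_id"].unique().tolist() == ["s1"]

    def test_narrowpeak_score_column(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("c1\t10\t20\tp1\t0\t.\t12.5\t3\t2\t5\n")
        df = read_bed(p, score_col=7)
        assert df["score"].tolist() == [12.5]

    def test_invalid_interval_errors(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("c1\t20\t10\tp\t1\n")
        with pytest.raises(ValueError, match="start >= end"):
            read_bed(p)
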