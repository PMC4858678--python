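"""ChIP-seq peak filtering, replicate matching, and transcript assignment.

Peaks (BED-style 0-based half-open intervals with a score) are first filtered
by score, then matched across replicate samples: a consensus peak is a
maximal group of peaks connected by >= 1 bp overlap that spans at least the
required number of distinct samples; its interval is the union of the members
and its score the member maximum.

Each consensus peak is assigned to at most two transcripts within 50 kb of
its midpoint, scored by symbol quality over TSS distance:

    S = symbol_score / max(d, 1000) * 1000

i.e. the symbol score (3 for a valid gene symbol, 1 for clones/predicted
genes) divided by the distance in kb, floored at 1 kb.  The top-scoring
transcript is always assigned; the runner-up is included only if its score
exceeds 25% of the top score (strict).  Binding with midpoint-to-TSS distance
< 500 bp is promoter class; 500 bp to < 50 kb is enhancer class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_bed",
    "filter_by_score",
    "match_across_samples",
    "score_transcript",
    "assign_peak",
    "annotate_peaks",
    "bound_gene_sets",
    "BoundGeneSet",
    "TranscriptHit",
    "PeakAssignment",
]

PROMOTER_MAX_BP = 500
WINDOW_BP = 50_000
DIST_FLOOR_BP = 1000
SECOND_FRACTION = 0.25

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "sample_id"]


def read_bed(path: str | Path, sample_id: str | None = None,
             score_col: int | None = None) -> pd.DataFrame:
    """Read peaks from BED3/BED5 or narrowPeak.

    ``score_col`` is the 1-based column holding the peak score (5 for BED5,
    7 for narrowPeak signalValue); by default column 5 is used when present,
    else score 0.  Coordinates are 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >=3 columns")
    out = pd.DataFrame({
        "chrom": df[0].astype(str),
        "start": df[1].astype(int),
        "end": df[2].astype(int),
        "name": df[3].astype(str) if df.shape[1] > 3 else [
            f"peak{i}" for i in range(len(df))],
    })
    if score_col is None:
        score_col = 5 if df.shape[1] >= 5 else 0
    out["score"] = (df[score_col - 1].astype(float)
                    if score_col else 0.0)
    if (out["start"] >= out["end"]).any():
        bad = out[out["start"] >= out["end"]].iloc[0]
        raise ValueError(f"{path}: invalid interval {bad['chrom']}:"
                         f"{bad['start']}-{bad['end']} (start >= end)")
    out["sample_id"] = sample_id if sample_id is not None else Path(path).stem
    return out


def filter_by_score(peaks: pd.DataFrame, min_score: float) -> pd.DataFrame:
    """Drop low-score peaks; a peak is kept iff score >= min_score."""
    return peaks[peaks["score"] >= min_score].reset_index(drop=True)


def match_across_samples(peak_sets: dict[str, pd.DataFrame],
                         min_samples: int) -> pd.DataFrame:
    """Consensus peaks supported by >= min_samples replicate samples.

    Peaks from all samples are pooled per chromosome; connected components of
    the >= 1 bp overlap graph are found by a sorted sweep (for intervals,
    overlap-connectivity is contiguous in start order).  A component spanning
    at least ``min_samples`` distinct samples yields one consensus peak: the
    union interval, the maximum member score, and the supporting sample count.
    """
    if min_samples > len(peak_sets):
        raise ValueError(f"min_samples={min_samples} exceeds number of "
                         f"samples ({len(peak_sets)})")
    frames = []
    for sid, df in peak_sets.items():
        f = df.copy()
        f["sample_id"] = sid
        frames.append(f)
    pooled = pd.concat(frames, ignore_index=True)
    consensus = []
    for chrom, grp in pooled.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="stable")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        scores = grp["score"].to_numpy()
        sids = grp["sample_id"].to_numpy()
        i = 0
        while i < len(grp):
            j = i + 1
            comp_end = ends[i]
            while j < len(grp) and starts[j] < comp_end:
                comp_end = max(comp_end, ends[j])
                j += 1
            members = slice(i, j)
            n_samp = len(set(sids[members]))
            if n_samp >= min_samples:
                consensus.append({
                    "chrom": chrom,
                    "start": int(starts[members].min()),
                    "end": int(comp_end),
                    "score": float(scores[members].max()),
                    "n_samples": n_samp,
                })
            i = j
    out = pd.DataFrame(consensus,
                       columns=["chrom", "start", "end", "score", "n_samples"])
    out["name"] = [f"consensus{i}" for i in range(len(out))]
    return out[["chrom", "start", "end", "name", "score", "n_samples"]]


def score_transcript(peak_mid: int, tss: int, symbol_score: int) -> float:
    """Transcript score: symbol quality over TSS distance in kb, floor 1 kb."""
    d = abs(int(peak_mid) - int(tss))
    return symbol_score / max(d, DIST_FLOOR_BP) * DIST_FLOOR_BP


@dataclass
class TranscriptHit:
    transcript_id: str
    symbol: str
    score: float
    distance: int

    @property
    def reg_class(self) -> str:
        return "promoter" if self.distance < PROMOTER_MAX_BP else "enhancer"


@dataclass
class PeakAssignment:
    chrom: str
    start: int
    end: int
    peak_name: str
    hits: list[TranscriptHit] = field(default_factory=list)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class _TranscriptIndex:
    """Per-chromosome TSS arrays sorted for windowed candidate lookup."""

    def __init__(self, models: pd.DataFrame):
        self.by_chrom: dict[str, pd.DataFrame] = {}
        for chrom, grp in models.groupby("chrom", sort=False):
            self.by_chrom[chrom] = (
                grp.sort_values(["tss", "transcript_id"], kind="stable")
                .reset_index(drop=True))

    def candidates(self, chrom: str, mid: int, window: int) -> pd.DataFrame:
        grp = self.by_chrom.get(chrom)
        if grp is None:
            return pd.DataFrame(columns=["transcript_id", "tss", "symbol",
                                         "symbol_score"])
        tss = grp["tss"].to_numpy()
        lo = np.searchsorted(tss, mid - window, side="right")
        hi = np.searchsorted(tss, mid + window, side="left")
        sub = grp.iloc[lo:hi]
        return sub[abs(sub["tss"] - mid) < window]


def assign_peak(peak: pd.Series | dict, index: _TranscriptIndex
                ) -> PeakAssignment:
    """Assign one consensus peak to its one or two best-scoring transcripts.

    Candidates are transcripts with midpoint-to-TSS distance < 50 kb on the
    peak's chromosome.  Ties in the top score are broken by transcript_id.
    Peaks with no candidate are returned unannotated (empty hit list).
    """
    mid = (int(peak["start"]) + int(peak["end"])) // 2
    assignment = PeakAssignment(peak["chrom"], int(peak["start"]),
                                int(peak["end"]),
                                str(peak.get("name", "")))
    cand = index.candidates(peak["chrom"], mid, WINDOW_BP)
    if cand.empty:
        return assignment
    scored = sorted(
        (TranscriptHit(row.transcript_id, row.symbol,
                       score_transcript(mid, row.tss, row.symbol_score),
                       abs(int(row.tss) - mid))
         for row in cand.itertuples()),
        key=lambda h: (-h.score, h.transcript_id))
    assignment.hits.append(scored[0])
    if len(scored) > 1 and scored[1].score > SECOND_FRACTION * scored[0].score:
        assignment.hits.append(scored[1])
    return assignment


def annotate_peaks(consensus: pd.DataFrame, models: pd.DataFrame
                   ) -> list[PeakAssignment]:
    """Assign every consensus peak against a transcript model table."""
    index = _TranscriptIndex(models)
    return [assign_peak(row, index) for _, row in consensus.iterrows()]


@dataclass
class BoundGeneSet:
    """Genes bound by a TF, split by regulatory class of the binding."""

    tf: str
    promoter_genes: set[str] = field(default_factory=set)
    enhancer_genes: set[str] = field(default_factory=set)

    @property
    def any_genes(self) -> set[str]:
        return self.promoter_genes | self.enhancer_genes

    def to_json_obj(self) -> dict:
        return {"tf": self.tf,
                "promoter_genes": sorted(self.promoter_genes),
                "enhancer_genes": sorted(self.enhancer_genes)}

    @classmethod
    def from_json_obj(cls, obj: dict) -> "BoundGeneSet":
        return cls(obj["tf"], set(obj["promoter_genes"]),
                   set(obj["enhancer_genes"]))


def bound_gene_sets(assignments: list[PeakAssignment], tf: str
                    ) -> BoundGeneSet:
    """Collect bound genes by class; a gene may be in both classes."""
    out = BoundGeneSet(tf)
    for a in assignments:
        for hit in a.hits:
            if hit.reg_class == "promoter":
                out.promoter_genes.add(hit.symbol)
            else:
                out.enhancer_genes.add(hit.symbol)
    return out


def assignments_to_frame(assignments: list[PeakAssignment]) -> pd.DataFrame:
    """Flatten assignments to a tidy table (one row per peak-transcript link)."""
    rows = []
    for a in assignments:
        if not a.hits:
            rows.append({"chrom": a.chrom, "start": a.start, "end": a.end,
                         "peak": a.peak_name, "transcript_id": "",
                         "symbol": "", "score": np.nan, "distance": np.nan,
                         "reg_class": "unannotated", "rank": 0})
        for k, h in enumerate(a.hits, 1):
            rows.append({"chrom": a.chrom, "start": a.start, "end": a.end,
                         "peak": a.peak_name, "transcript_id": h.transcript_id,
                         "symbol": h.symbol, "score": h.score,
                         "distance": h.distance, "reg_class": h.reg_class,
                         "rank": k})
    return pd.DataFrame(rows)
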