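"""Parametric Analysis of Gene set Enrichment (PAGE) on expression quartiles.

PAGE scores a gene set against a per-gene score distribution (here induction
logratios) with

    z = (Sm - mu) * sqrt(m) / delta

where Sm is the mean score of the m set members found among the analyzed
genes and (mu, delta) are the mean and SD of the background score
distribution.  Under the null of a randomly drawn set, z is approximately
standard normal for moderate m (central limit theorem), which is what makes
the parametric shortcut a good stand-in for an explicit resampling null.

Enrichment is evaluated separately on the top quartile of genes sorted by
logratio (direction "up") and on the bottom quartile (direction "down"),
with a Benjamini-Hochberg FDR across sets within each pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "page_z",
    "enrich_collection",
]

M_MIN = 5  # minimum overlap for a set to be testable


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets with GMT semantics.

    Symbols are uppercase-normalized on construction so matching against
    profiles is case-insensitive.  Set names must be unique; empty sets are
    dropped with a warning.
    """

    sets: dict[str, set[str]]
    source: str = "custom"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, set[str]] = {}
        for name, members in self.sets.items():
            up = {str(m).upper() for m in members if str(m).strip()}
            if not up:
                warnings.warn(f"gene set {name!r} is empty; skipped")
                continue
            cleaned[name] = up
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, name TAB description TAB members..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name "
                                 f"{name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, source=str(path), descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT (members sorted for determinism)."""
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, collection.source)
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


@dataclass
class EnrichmentResult:
    """PAGE score of one set in one direction pass."""

    name: str
    direction: str            # "up" | "down"
    m: int                    # overlap with analyzed genes
    Sm: float                 # mean score of the overlap
    mu: float                 # background mean
    delta: float              # background SD
    z: float
    tested: bool              # False when m < M_MIN
    fdr: float = math.nan

    def as_dict(self) -> dict:
        return {"set": self.name, "direction": self.direction, "m": self.m,
                "Sm": self.Sm, "z": self.z, "fdr": self.fdr,
                "tested": self.tested}


def page_z(analyzed: pd.Series, members: set[str],
           background: pd.Series | None = None,
           name: str = "", direction: str = "up",
           m_min: int = M_MIN) -> EnrichmentResult:
    """PAGE z-score of one gene set.

    ``analyzed`` holds the scores (logratios) of the genes in the analyzed
    fraction, indexed by uppercase gene symbol; ``background`` the scores the
    null mean/SD are taken from (defaults to ``analyzed``).  Sets overlapping
    the analyzed genes in fewer than ``m_min`` members are returned with
    ``tested=False`` and z = NaN rather than an unstable score.
    """
    if background is None:
        background = analyzed
    mu = float(background.mean())
    delta = float(background.std(ddof=1))
    overlap = analyzed.index.intersection(pd.Index(sorted(members)))
    m = len(overlap)
    if m < m_min or delta == 0.0:
        return EnrichmentResult(name, direction, m, math.nan, mu, delta,
                                math.nan, tested=False)
    Sm = float(analyzed.loc[overlap].mean())
    z = (Sm - mu) * math.sqrt(m) / delta
    return EnrichmentResult(name, direction, m, Sm, mu, delta, z, tested=True)


def _quartile(scores: pd.Series, fraction: float, top: bool) -> pd.Series:
    """Top or bottom ceil(fraction*N) genes by score, ties broken by gene id."""
    k = math.ceil(fraction * len(scores))
    df = scores.rename("score").reset_index()
    df.columns = ["gene", "score"]
    df = df.sort_values(["score", "gene"], ascending=[not top, True],
                        kind="stable")
    sel = df.head(k)
    return sel.set_index("gene")["score"]


def enrich_collection(profile: pd.DataFrame, collection: GeneSetCollection,
                      fraction: float = 0.25,
                      background: str = "analyzed") -> pd.DataFrame:
    """Score every set of a collection on the top and bottom score quartiles.

    Parameters
    ----------
    profile : induction profile with a ``logratio`` column indexed by gene
    fraction : analyzed fraction per direction (0.25 = quartiles)
    background : "analyzed" (default) computes the null mean/SD over the
        analyzed quartile, so a random set scores z ~ N(0, 1); "all" uses
        every gene's logratio, which inflates z for any set because the
        analyzed genes are selected for extreme logratios.

    Returns a DataFrame (set, direction, m, Sm, z, fdr, tested) with a BH FDR
    across tested sets within each direction pass.
    """
    if len(collection) == 0:
        return pd.DataFrame(
            columns=["set", "direction", "m", "Sm", "z", "fdr", "tested"])
    if len(profile) < 4 / fraction:
        raise ValueError(
            f"profile covers {len(profile)} genes; need >= {4 / fraction:.0f} "
            f"for fraction={fraction}")
    scores = profile["logratio"].copy()
    scores.index = scores.index.astype(str).str.upper()
    results: list[EnrichmentResult] = []
    for direction, top in (("up", True), ("down", False)):
        analyzed = _quartile(scores, fraction, top=top)
        bg = scores if background == "all" else analyzed
        batch = [page_z(analyzed, collection[name], background=bg,
                        name=name, direction=direction)
                 for name in sorted(collection.sets)]
        tested = [r for r in batch if r.tested]
        if tested:
            p = [2.0 * _norm_sf(abs(r.z)) for r in tested]
            fdr = multipletests(p, method="fdr_bh")[1]
            for r, q in zip(tested, fdr):
                r.fdr = float(q)
        results.extend(batch)
    return pd.DataFrame([r.as_dict() for r in results])


def _norm_sf(x: float) -> float:
    return 0.5 * math.erfc(x / math.sqrt(2.0))
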