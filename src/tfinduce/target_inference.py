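"""Direct-target inference from induction profiles plus binding evidence.

A gene is called a regulated direct target of a TF if it is (a) bound by the
TF within 50 kb of its TSS (promoter or enhancer class), (b) induced in the
expected direction with a fold change >= 1.5, and (c) has an Expected
Proportion of False Positives (EPFP) <= 0.5.  EPFP is a q-value-like quantity
computed by the Benjamini-Hochberg step-up rule within the candidate set:
candidates are ranked by ascending p-value and EPFP(rank r) is the cumulative
minimum, taken from the largest rank downward, of p(r) * n_candidates / r.
By default the candidate set is the bound-gene subset, since target calling
conditions on binding; a genome-wide candidate pool is available via
``scope="all"``.

Rank plots visualize the same signal nonparametrically: genes are sorted by
logratio descending and the proportion of bound genes is traced in a sliding
window (300 genes by default, step 1).  An enriched promoter/enhancer class
shows as an elevated left end of the curve; PAGE supplies the significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tfinduce.geneset_enrichment import GeneSetCollection, enrich_collection
from tfinduce.peak_annotation import BoundGeneSet

__all__ = [
    "epfp",
    "call_targets",
    "rank_plot",
    "RankPlotCurve",
    "binding_enrichment_test",
]


def epfp(profile: pd.DataFrame, candidate_genes) -> pd.Series:
    """EPFP per candidate gene (BH step-up within the candidate subset).

    ``candidate_genes`` must be a subset of the profile index.  Returns a
    Series indexed by candidate gene; empty candidates give an empty Series.
    NaN p-values (insufficient replicates) propagate as NaN EPFP.
    """
    candidates = pd.Index(sorted(set(candidate_genes)))
    missing = candidates.difference(profile.index)
    if len(missing):
        raise KeyError(f"candidate genes absent from profile: "
                       f"{sorted(missing)[:5]}...")
    if len(candidates) == 0:
        return pd.Series(dtype=float, name="epfp")
    p = profile.loc[candidates, "p"]
    order = np.argsort(p.to_numpy(), kind="stable")
    n = len(candidates)
    ranks = np.arange(1, n + 1)
    raw = p.to_numpy()[order] * n / ranks
    monotone = np.minimum.accumulate(raw[::-1])[::-1]
    monotone = np.minimum(monotone, 1.0)
    out = pd.Series(np.empty(n), index=candidates[order], name="epfp")
    out[:] = monotone
    return out.reindex(candidates)


def call_targets(profile: pd.DataFrame, bound: BoundGeneSet,
                 epfp_max: float = 0.5, min_fold: float = 1.5,
                 direction: str = "up", scope: str = "bound") -> pd.DataFrame:
    """Call regulated direct targets of one TF.

    Returns a table over the bound genes present in the profile with columns
    gene, logratio, fold, epfp, bound_class (promoter/enhancer/both) and
    ``regulated`` — True iff EPFP <= epfp_max, fold >= min_fold and the
    logratio sign matches ``direction`` ("up" or "down").  ``scope`` selects
    the EPFP candidate pool: "bound" (default) or "all" genes.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    in_profile = sorted(bound.any_genes & set(profile.index))
    if not in_profile:
        warnings.warn(f"no bound gene of {bound.tf} overlaps the profile")
        return pd.DataFrame(columns=["gene", "logratio", "fold", "epfp",
                                     "bound_class", "regulated"])
    if scope == "bound":
        q = epfp(profile, in_profile)
    elif scope == "all":
        q = epfp(profile, profile.index).loc[in_profile]
    else:
        raise ValueError(f"scope must be 'bound' or 'all', got {scope!r}")

    rows = []
    for g in in_profile:
        lr = float(profile.loc[g, "logratio"])
        fold = float(profile.loc[g, "fold"])
        cls = ("both" if g in bound.promoter_genes and g in bound.enhancer_genes
               else "promoter" if g in bound.promoter_genes else "enhancer")
        sign_ok = lr > 0 if direction == "up" else lr < 0
        regulated = bool(q.loc[g] <= epfp_max and fold >= min_fold and sign_ok)
        rows.append({"gene": g, "logratio": lr, "fold": fold,
                     "epfp": float(q.loc[g]), "bound_class": cls,
                     "regulated": regulated})
    return pd.DataFrame(rows)


@dataclass
class RankPlotCurve:
    """Sliding-window proportion of bound genes along the logratio ranking."""

    centers: np.ndarray       # 1-based rank of each window's center
    proportion: np.ndarray    # bound fraction per window, in [0, 1]
    window: int
    n_genes: int
    n_bound: int

    @property
    def baseline(self) -> float:
        """Expected proportion for a random bound set."""
        return self.n_bound / self.n_genes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center_rank": self.centers,
                             "proportion": self.proportion})


def rank_plot(profile: pd.DataFrame, bound_genes, window: int = 300,
              step: int = 1) -> RankPlotCurve:
    """Proportion of bound genes in a window sliding down the logratio ranking.

    Genes are sorted by logratio descending (ties broken by gene id); the
    value at window position k is |bound ∩ window(k)| / window.
    """
    if window < 10:
        raise ValueError(f"window must be >= 10, got {window}")
    if window > len(profile):
        raise ValueError(f"window ({window}) exceeds gene count "
                         f"({len(profile)})")
    order = (pd.DataFrame({"gene": profile.index.astype(str),
                           "logratio": profile["logratio"].to_numpy()})
             .sort_values(["logratio", "gene"], ascending=[False, True],
                          kind="stable"))
    bound = set(bound_genes)
    indicator = order["gene"].isin(bound).to_numpy(dtype=float)
    counts = np.convolve(indicator, np.ones(window), mode="valid")
    prop = counts / window
    centers = np.arange(len(prop)) + (window + 1) // 2
    if step > 1:
        prop = prop[::step]
        centers = centers[::step]
    return RankPlotCurve(centers=centers, proportion=prop, window=window,
                         n_genes=len(profile), n_bound=int(indicator.sum()))


def binding_enrichment_test(profile: pd.DataFrame, bound: BoundGeneSet,
                            fraction: float = 0.25) -> pd.DataFrame:
    """PAGE enrichment of promoter- and enhancer-bound genes per direction.

    The two bound-gene classes are scored as a two-set collection against the
    top and bottom logratio quartiles; a class too small to test is flagged
    untested in the result.
    """
    sets = {}
    if bound.promoter_genes:
        sets[f"{bound.tf}_promoter"] = bound.promoter_genes
    if bound.enhancer_genes:
        sets[f"{bound.tf}_enhancer"] = bound.enhancer_genes
    if not sets:
        raise ValueError(f"both binding classes of {bound.tf} are empty")
    collection = GeneSetCollection(sets, source="chipseq")
    return enrich_collection(profile, collection, fraction=fraction)
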