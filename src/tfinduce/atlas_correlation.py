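"""Correlation of induction profiles with a tissue-expression atlas.

A tissue atlas is reduced to per-gene logratios of each tissue versus the
per-gene median across tissues, with a significance flag (FDR <= 0.05 and
fold >= 2; the fold bar is higher than the 1.5 used for induction profiles
because expression differences between adult tissues are much larger than
induction responses).  Each TF's induction logratios are then Pearson-
correlated with each tissue's atlas logratios over a shared gene universe —
genes significant in both datasets — and the correlation's significance is
expressed as a Fisher z:  z = atanh(r) * sqrt(n - 3).  Cells with z < 2 are
treated as non-significant in the heatmap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from tfinduce.induction_profiles import welch_test, significant_genes

__all__ = [
    "AtlasMatrix",
    "CorrelationResult",
    "atlas_from_replicates",
    "correlate",
    "shared_significant_universe",
    "correlation_matrix",
    "CorrelationMatrix",
]

Z_CAP = 50.0  # |z| clamp as r -> +-1 (atanh diverges)


@dataclass
class AtlasMatrix:
    """Tissue atlas reduced to logratios vs the per-gene median.

    ``logratio``: genes x tissues, per-gene median across tissues is 0 by
    construction.  ``significant``: same shape, True where the tissue's
    deviation passes FDR <= fdr_max and fold >= min_fold.
    """

    logratio: pd.DataFrame
    significant: pd.DataFrame

    @property
    def tissues(self) -> list[str]:
        return list(self.logratio.columns)

    def significant_genes(self) -> set[str]:
        """Genes significant in at least one tissue."""
        mask = self.significant.any(axis=1)
        return set(self.logratio.index[mask])


def _tissue_groups(raw: pd.DataFrame) -> dict[str, list]:
    """Map tissue -> columns, from MultiIndex or 'tissue__rep' flat names."""
    groups: dict[str, list] = {}
    if isinstance(raw.columns, pd.MultiIndex):
        for col in raw.columns:
            groups.setdefault(col[0], []).append(col)
    else:
        for col in raw.columns:
            tissue = str(col).rsplit("__", 1)[0]
            groups.setdefault(tissue, []).append(col)
    return groups


def atlas_from_replicates(raw: pd.DataFrame, fdr_max: float = 0.05,
                          min_fold: float = 2.0) -> AtlasMatrix:
    """Reduce a replicate-level atlas to logratios with significance flags.

    ``raw`` is genes x (tissue, replicate) log10 intensities; replicate
    columns are grouped by MultiIndex level 0 or by a ``tissue__replicate``
    naming convention.  The logratio of gene g in tissue t is the tissue's
    replicate mean minus the per-gene median of tissue means.  Significance
    tests each tissue's replicates against the pooled replicates of all other
    tissues (Welch), with a BH FDR across genes within each tissue, plus the
    fold requirement on the logratio.  With fewer than 2 replicates in some
    tissue, all flags are set with a warning.
    """
    groups = _tissue_groups(raw)
    if len(groups) < 2:
        raise ValueError(f"need >=2 tissues, got {len(groups)}")
    means = pd.DataFrame(
        {t: raw[cols].mean(axis=1) for t, cols in groups.items()})
    logratio = means.sub(means.median(axis=1), axis=0)

    if min(len(cols) for cols in groups.values()) < 2:
        warnings.warn("fewer than 2 replicates in some tissue; "
                      "flagging all entries significant")
        significant = pd.DataFrame(True, index=logratio.index,
                                   columns=logratio.columns)
        return AtlasMatrix(logratio, significant)

    log_min_fold = math.log10(min_fold)
    sig = {}
    for t, cols in groups.items():
        others = [c for cs in groups.values() for c in cs if c not in cols]
        _, p = welch_test(raw[cols].to_numpy(dtype=float),
                          raw[others].to_numpy(dtype=float))
        fdr = multipletests(p, method="fdr_bh")[1]
        sig[t] = (fdr <= fdr_max) & (logratio[t].abs() >= log_min_fold)
    significant = pd.DataFrame(sig, index=logratio.index)
    return AtlasMatrix(logratio, significant[logratio.columns])


@dataclass
class CorrelationResult:
    tf: str
    tissue: str
    r: float
    n: int
    z: float


def fisher_z(r: float, n: int) -> float:
    """Fisher-transform significance of a Pearson r at sample size n."""
    if n <= 3 or not np.isfinite(r):
        return 0.0
    if abs(r) >= 1.0:
        return math.copysign(Z_CAP, r)
    z = math.atanh(r) * math.sqrt(n - 3)
    return float(np.clip(z, -Z_CAP, Z_CAP))


def correlate(profile: pd.DataFrame, atlas: AtlasMatrix, tissue: str,
              genes=None, tf: str = "") -> CorrelationResult:
    """Pearson correlation of one TF's logratios with one tissue's signature.

    ``genes`` fixes the gene universe (normally the shared significant
    universe); by default the plain index intersection is used.  With n < 4
    genes the z-score is 0 and a warning is issued.
    """
    if tissue not in atlas.logratio.columns:
        raise KeyError(f"tissue {tissue!r} not in atlas")
    universe = pd.Index(sorted(genes)) if genes is not None else None
    if universe is None:
        universe = profile.index.intersection(atlas.logratio.index)
    else:
        universe = universe.intersection(profile.index)
        universe = universe.intersection(atlas.logratio.index)
    n = len(universe)
    if n < 4:
        warnings.warn(f"only {n} shared genes; z set to 0")
        r = float("nan") if n < 2 else float(np.corrcoef(
            profile.loc[universe, "logratio"],
            atlas.logratio.loc[universe, tissue])[0, 1])
        return CorrelationResult(tf, tissue, r, n, 0.0)
    x = profile.loc[universe, "logratio"].to_numpy(dtype=float)
    y = atlas.logratio.loc[universe, tissue].to_numpy(dtype=float)
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(tf, tissue, r, n, fisher_z(r, n))


def shared_significant_universe(profiles: dict[str, pd.DataFrame],
                                atlas: AtlasMatrix,
                                fdr_max: float = 0.05,
                                min_fold: float = 1.5) -> set[str]:
    """Genes significant in both datasets.

    Induction side: significant (FDR <= fdr_max, fold >= min_fold) for at
    least one TF.  Atlas side: significant for at least one tissue.  The
    intersection gives one shared universe used for every correlation cell.
    """
    induction_sig: set[str] = set()
    for prof in profiles.values():
        up, down = significant_genes(prof, fdr_max, min_fold)
        induction_sig.update(up, down)
    return induction_sig & atlas.significant_genes()


@dataclass
class CorrelationMatrix:
    """All TF x tissue correlations with a clustering-derived display order."""

    r: pd.DataFrame           # TFs x tissues
    z: pd.DataFrame
    n: int                    # shared gene universe size
    row_order: list[str]
    col_order: list[str]
    z_min: float = 2.0

    def significant(self) -> pd.DataFrame:
        """Boolean mask of cells with z >= z_min (Fig-2 style display)."""
        return self.z >= self.z_min

    def ordered(self, which: str = "z") -> pd.DataFrame:
        df = self.z if which == "z" else self.r
        return df.loc[self.row_order, self.col_order]


def _leaf_order(df: pd.DataFrame) -> list[str]:
    """Average-linkage leaf order of the rows of ``df`` on (1 - r) distance."""
    if len(df) < 2:
        return list(df.index)
    d = pdist(df.to_numpy(dtype=float), metric="correlation")
    d = np.nan_to_num(d, nan=1.0)
    link = hierarchy.linkage(d, method="average")
    return [df.index[i] for i in hierarchy.leaves_list(link)]


def correlation_matrix(profiles: dict[str, pd.DataFrame], atlas: AtlasMatrix,
                       fdr_max: float = 0.05, min_fold: float = 1.5,
                       z_min: float = 2.0) -> CorrelationMatrix:
    """Full TF x tissue correlation matrix over the shared gene universe.

    Rows (TFs) and columns (tissues) are ordered by average-linkage
    hierarchical clustering on correlation distance between their r-vectors;
    cells with z < z_min are flagged non-significant.
    """
    if len(profiles) < 2 or len(atlas.tissues) < 2:
        raise ValueError("need >=2 profiles and >=2 tissues")
    universe = shared_significant_universe(profiles, atlas, fdr_max, min_fold)
    tfs = list(profiles)
    r = pd.DataFrame(index=pd.Index(tfs, name="tf"),
                     columns=pd.Index(atlas.tissues, name="tissue"),
                     dtype=float)
    z = r.copy()
    for tf in tfs:
        for tissue in atlas.tissues:
            res = correlate(profiles[tf], atlas, tissue, genes=universe, tf=tf)
            r.loc[tf, tissue] = res.r
            z.loc[tf, tissue] = res.z
    return CorrelationMatrix(r=r, z=z, n=len(universe),
                             row_order=_leaf_order(r),
                             col_order=_leaf_order(r.T),
                             z_min=z_min)


def plot_heatmap(cm: CorrelationMatrix, path) -> None:
    """Write a clustered z-value heatmap; non-significant cells blanked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    zo = cm.ordered("z")
    masked = np.ma.masked_where(zo.to_numpy() < cm.z_min, zo.to_numpy())
    fig, ax = plt.subplots(figsize=(1 + 0.5 * zo.shape[1],
                                    1 + 0.4 * zo.shape[0]))
    cmap = plt.get_cmap("Reds").copy()
    cmap.set_bad("white")
    im = ax.imshow(masked, cmap=cmap, aspect="auto")
    ax.set_xticks(range(zo.shape[1]), zo.columns, rotation=90)
    ax.set_yticks(range(zo.shape[0]), zo.index)
    fig.colorbar(im, ax=ax, label="Fisher z")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
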