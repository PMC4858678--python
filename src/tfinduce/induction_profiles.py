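"""Normalization and per-TF induction profiles.

The induction profile of a TF is the per-gene logratio (difference of mean
log10 intensities, induced minus control) together with a p-value from a
Welch two-sample t-test on the replicate intensities and a Benjamini-Hochberg
FDR across genes.  Responders are genes with FDR <= 0.05 and a fold change
>= 1.5 (fold = 10^|logratio|); both thresholds are inclusive.

Two normalization steps precede profiling.  Control-channel normalization
maps each induced array onto its paired control:

    x'_i = x_i - c_i + Median(c_i)

so that the normalized value keeps the induced-vs-control difference while
recentering on the control array's overall level.  Batch normalization makes
each gene's median agree across batches by an additive per-gene shift on the
log scale.
"""

from __future__ import annotations

import math
import warnings
from functools import reduce

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_to_control",
    "batch_normalize",
    "welch_test",
    "moderated_test",
    "compute_induction_profile",
    "significant_genes",
    "count_responders",
    "pca_profiles",
    "read_matrix",
    "read_samples",
]

#: per-group variance floor on log10 intensities, guards against the
#: zero-variance degeneracy of small replicate groups
VAR_FLOOR = 1e-4


def normalize_to_control(x, c):
    """Normalize an induced array to its paired control array.

    x'_i = x_i - c_i + Median(c), elementwise over features of one array.
    Accepts array-likes of equal length; returns an ndarray (or Series if
    ``x`` is a Series, preserving its index).
    """
    x_arr = np.asarray(x, dtype=float)
    c_arr = np.asarray(c, dtype=float)
    if x_arr.shape != c_arr.shape:
        raise ValueError(
            f"length mismatch: x has {x_arr.shape}, control has {c_arr.shape}")
    if not (np.isfinite(x_arr).all() and np.isfinite(c_arr).all()):
        raise ValueError("non-finite values in input intensities")
    out = x_arr - c_arr + np.median(c_arr)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


def batch_normalize(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine expression batches, equalizing per-gene medians across batches.

    Genes are intersected across batches.  Each gene's values within a batch
    are shifted additively so that its within-batch median equals its global
    median (computed over all samples of all batches).  After the operation
    every gene's median is identical in every batch.
    """
    if not matrices:
        raise ValueError("no batches given")
    if len(matrices) == 1:
        return matrices[0].copy()
    common = reduce(lambda a, b: a.intersection(b),
                    (m.index for m in matrices))
    if len(common) == 0:
        raise ValueError("empty gene intersection across batches")
    common = matrices[0].index[matrices[0].index.isin(common)]
    mats = [m.loc[common] for m in matrices]
    combined = pd.concat(mats, axis=1)
    global_med = combined.median(axis=1)
    shifted = [m.add(global_med - m.median(axis=1), axis=0) for m in mats]
    return pd.concat(shifted, axis=1)


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test over rows of two replicate blocks.

    ``a`` and ``b`` are (genes x replicates) arrays.  Per-group variances are
    floored at VAR_FLOOR.  Returns (t, p); rows where either group has fewer
    than 2 replicates get p = NaN.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    if n1 < 2 or n2 < 2:
        return np.full(a.shape[0], np.nan), np.full(a.shape[0], np.nan)
    v1 = np.maximum(a.var(axis=1, ddof=1), VAR_FLOOR)
    v2 = np.maximum(b.var(axis=1, ddof=1), VAR_FLOOR)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes hyperparameters (d0, s0^2) for gene-wise variances.

    Method-of-moments fit on log variances (Smyth 2004): under the hierarchy
    s2_g | sigma2_g ~ sigma2_g * chi2(df)/df, sigma2_g ~ s0^2 * df0/chi2(df0),
    the statistic e_g = log(s2_g) - digamma(df/2) + log(df/2) has mean
    log(s0^2) + digamma(d0/2) - log(d0/2) and variance trigamma(df/2) +
    trigamma(d0/2).  d0 = inf (complete pooling) when the observed spread of
    log variances does not exceed its sampling floor.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(max(s2.mean(), VAR_FLOOR))
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e.mean()))
    # invert trigamma(d0/2) = e_var by Newton on x = d0/2
    x = 0.5 + 1.0 / e_var
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        delta = tri * (1.0 - tri / e_var) / float(special.polygamma(2, x))
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0_2 = float(np.exp(e.mean() + special.digamma(x) - math.log(x)))
    return d0, s0_2


def moderated_test(a: np.ndarray, b: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Moderated two-sample t-test with empirical-Bayes variance shrinkage.

    The pooled within-group variance of each gene (df = n1 + n2 - 2) is
    shrunk toward a global prior fitted across genes,

        s~2_g = (d0 * s0^2 + df * s2_g) / (d0 + df),

    and the t statistic is referred to a t distribution on d0 + df degrees of
    freedom.  With a handful of replicates per condition this borrowing of
    strength across genes is what makes gene-level inference feasible; it is
    the standard microarray approach (limma's eBayes) and mirrors the pooled
    error models of dedicated expression-analysis servers.
    """
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        return np.full(a.shape[0], np.nan), np.full(a.shape[0], np.nan)
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    df = float(n1 + n2 - 2)
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1)
          + (n2 - 1) * b.var(axis=1, ddof=1)) / df
    d0, s0_2 = _fit_f_dist(s2, df)
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    s2_tilde = np.maximum(s2_tilde, VAR_FLOOR)
    t = (m1 - m2) / np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p


def compute_induction_profile(matrix: pd.DataFrame, samples: pd.DataFrame,
                              tf: str, method: str = "moderated"
                              ) -> pd.DataFrame:
    """Per-gene induction profile for one TF.

    Returns a DataFrame indexed by gene with columns ``logratio`` (mean
    induced minus mean control log10 intensity), ``p``, ``fdr``
    (Benjamini-Hochberg across genes) and ``fold`` (10^|logratio|).
    ``method`` selects the per-gene test: "moderated" (default,
    empirical-Bayes shrunk variances — essential at 2-3 replicates per
    condition) or "welch" (unmoderated).  With fewer than 2 replicates in
    either condition the logratio is still computed but p and fdr are NaN.
    """
    sub = samples[samples["tf"] == tf]
    if sub.empty:
        raise KeyError(f"tf {tf!r} absent from sample table")
    ind = sub.loc[sub["condition"] == "induced", "sample_id"].tolist()
    ctl = sub.loc[sub["condition"] == "control", "sample_id"].tolist()
    if not ind or not ctl:
        raise ValueError(f"tf {tf!r} lacks induced or control samples")
    a = matrix[ind].to_numpy(dtype=float)
    b = matrix[ctl].to_numpy(dtype=float)
    logratio = a.mean(axis=1) - b.mean(axis=1)
    if method not in ("moderated", "welch"):
        raise ValueError(f"unknown method {method!r}")
    test = moderated_test if method == "moderated" else welch_test
    _, p = test(a, b)
    if np.isnan(p).all():
        fdr = p
    else:
        fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"logratio": logratio, "p": p, "fdr": fdr,
         "fold": 10.0 ** np.abs(logratio)},
        index=matrix.index.rename("gene"))


def significant_genes(profile: pd.DataFrame, fdr_max: float = 0.05,
                      min_fold: float = 1.5) -> tuple[list[str], list[str]]:
    """Responder genes: FDR <= fdr_max and fold >= min_fold, both inclusive.

    Returns (upregulated, downregulated) gene lists, split by the sign of the
    logratio.
    """
    if profile["fdr"].isna().all():
        raise ValueError("profile has no FDR values; need >=2 replicates "
                         "per condition")
    sig = (profile["fdr"] <= fdr_max) & (profile["fold"] >= min_fold)
    up = profile.index[sig & (profile["logratio"] > 0)].tolist()
    down = profile.index[sig & (profile["logratio"] < 0)].tolist()
    return up, down


def count_responders(profiles: dict[str, pd.DataFrame],
                     fdr_max: float = 0.05,
                     min_fold: float = 1.5) -> pd.DataFrame:
    """Responder counts per TF: columns tf, n_up, n_down, n_total."""
    rows = []
    for tf, prof in profiles.items():
        up, down = significant_genes(prof, fdr_max, min_fold)
        rows.append({"tf": tf, "n_up": len(up), "n_down": len(down),
                     "n_total": len(up) + len(down)})
    return pd.DataFrame(rows)


def pca_profiles(profiles: dict[str, pd.DataFrame],
                 fdr_max: float = 0.05, min_fold: float = 1.5,
                 n_components: int | None = None
                 ) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of TF induction profiles on the shared significant-gene space.

    The logratio matrix (TFs x genes) is restricted to genes significant in
    at least one profile, then decomposed.  Components are ordered by
    explained variance with a deterministic sign convention: the loading with
    the largest absolute value is made positive.

    Returns (coordinates TFs x PCs, explained variance array,
    loadings PCs x genes).
    """
    if len(profiles) < 2:
        raise ValueError("need >=2 profiles for PCA")
    sig_union: set[str] = set()
    for prof in profiles.values():
        up, down = significant_genes(prof, fdr_max, min_fold)
        sig_union.update(up)
        sig_union.update(down)
    if not sig_union:
        raise ValueError("no gene is significant in any profile; "
                         "PCA space is empty")
    genes = sorted(sig_union)
    tfs = list(profiles)
    X = np.vstack([profiles[tf].loc[genes, "logratio"].to_numpy()
                   for tf in tfs])
    k = n_components or min(len(tfs), len(genes))
    pca = PCA(n_components=min(k, len(tfs), len(genes)), svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_
    # deterministic sign: largest-|loading| element positive per component
    for j in range(loadings.shape[0]):
        i_max = np.argmax(np.abs(loadings[j]))
        if loadings[j, i_max] < 0:
            loadings[j] *= -1.0
            coords[:, j] *= -1.0
    pcs = [f"PC{j + 1}" for j in range(loadings.shape[0])]
    return (pd.DataFrame(coords, index=pd.Index(tfs, name="tf"), columns=pcs),
            pca.explained_variance_,
            pd.DataFrame(loadings, index=pcs, columns=genes))


def read_matrix(path) -> pd.DataFrame:
    """Read a gene x sample log10 expression matrix TSV (first column gene)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    if m.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    if not np.isfinite(m.to_numpy(dtype=float)).all():
        raise ValueError("non-finite values in expression matrix")
    return m


def read_samples(path) -> pd.DataFrame:
    """Read a sample table TSV: sample_id, tf, condition, replicate, batch."""
    s = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tf": str})
    required = {"sample_id", "tf", "condition", "replicate"}
    missing = required - set(s.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if "batch" not in s.columns:
        s["batch"] = "b1"
    bad = set(s["condition"]) - {"induced", "control"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    return s
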