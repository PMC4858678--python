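"""Synthetic inputs with planted ground truth.

Everything the analysis consumes — a log10-intensity expression matrix with an
induced/control replicate design, a tissue-expression atlas, gene-set
collections, transcript models and per-sample ChIP-seq peak files — is
generated here with a known truth record (which genes respond to which TF, by
how much, which tissues share a signature, which genes carry planted binding
sites and of what regulatory class).  Recovery tests compare every downstream
stage against that record.

The replicate design mirrors the screen being emulated: each TF line is split
into induced (doxycycline withdrawn) and control (doxycycline kept) wells,
three replicates per condition by default.  Intensities are on a log10 scale;
induced samples carry the planted per-gene effect on top of a shared baseline,
and both conditions receive i.i.d. Gaussian replicate noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SyntheticTruth",
    "simulate_experiment",
    "make_transcript_models",
    "simulate_atlas",
    "simulate_peaks",
    "simulate_gene_sets",
    "write_experiment",
]

LOG10_MIN_FOLD = math.log10(1.5)

#: spacing between consecutive TSSs on a synthetic chromosome (bp); wide
#: enough that a 50 kb annotation window around one TSS never reaches the next
TSS_SPACING = 200_000
GENES_PER_CHROM = 100
FIRST_TSS = 60_000


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    All intensities and effects are log10-scale.  ``effect_loc`` is the mean
    absolute planted logratio; magnitudes are drawn as log10(1.5) plus an
    exponential excess so nearly every planted effect clears the 1.5-fold
    responder threshold and is recoverable in principle.
    """

    n_genes: int = 2000
    n_tfs: int = 4
    reps_per_condition: int = 3
    frac_affected: float = 0.05
    effect_loc: float = 0.35
    min_effect_fold: float = 1.5
    noise_sd: float = 0.05
    n_tissues: int = 6
    atlas_reps: int = 3
    alignment_strength: float = 1.0
    frac_bound: float = 0.5
    peak_width_bp: int = 400
    promoter_frac: float = 0.3
    n_peak_samples: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_tfs", "reps_per_condition", "n_tissues",
                     "atlas_reps", "peak_width_bp", "n_peak_samples"):
            if int(getattr(self, name)) < 1:
                raise SimConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("frac_affected", "frac_bound", "promoter_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if not self.noise_sd > 0:
            raise SimConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.min_effect_fold < 1.0:
            raise SimConfigError(
                f"min_effect_fold must be >= 1, got {self.min_effect_fold}")
        if self.alignment_strength < 0:
            raise SimConfigError(
                f"alignment_strength must be >= 0, got {self.alignment_strength}")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated experiment.

    ``effects`` maps (tf, gene) to the true logratio (absent pairs are null);
    ``tissue_alignment`` maps each TF to the atlas tissue sharing its
    signature; ``bound_genes`` maps each TF to {gene: "promoter"|"enhancer"}
    for genes given a planted peak.
    """

    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    tissue_alignment: dict[str, str] = field(default_factory=dict)
    bound_genes: dict[str, dict[str, str]] = field(default_factory=dict)

    def effects_for(self, tf: str) -> dict[str, float]:
        return {g: e for (t, g), e in self.effects.items() if t == tf}

    def to_json(self, path: str | Path) -> None:
        obj = {
            "effects": {f"{t}|{g}": e for (t, g), e in self.effects.items()},
            "tissue_alignment": self.tissue_alignment,
            "bound_genes": self.bound_genes,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        effects = {tuple(k.split("|", 1)): v for k, v in obj["effects"].items()}
        return cls(effects=effects,
                   tissue_alignment=obj["tissue_alignment"],
                   bound_genes=obj["bound_genes"])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _tf_names(n: int) -> list[str]:
    return [f"TF{i + 1:02d}" for i in range(n)]


def _draw_effects(rng: np.random.Generator, n: int, effect_loc: float,
                  min_log_fold: float = LOG10_MIN_FOLD) -> np.ndarray:
    """Signed log10 effects: magnitude = min_log_fold + Exp(excess)."""
    excess = max(effect_loc - min_log_fold, 1e-6)
    mag = min_log_fold + rng.exponential(excess, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * mag


def simulate_experiment(config: SimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate the expression matrix, sample table and truth record.

    Returns
    -------
    matrix : DataFrame, genes x samples, log10 intensities
    samples : DataFrame with columns sample_id, tf, condition, replicate, batch
    truth : SyntheticTruth with exactly the planted nonzero effects
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    tfs = _tf_names(config.n_tfs)

    baseline = rng.normal(2.5, 0.7, size=config.n_genes)
    n_affected = round(config.frac_affected * config.n_genes)

    truth = SyntheticTruth()
    columns: dict[str, np.ndarray] = {}
    rows = []
    for tf in tfs:
        effect = np.zeros(config.n_genes)
        if n_affected:
            idx = rng.choice(config.n_genes, size=n_affected, replace=False)
            vals = _draw_effects(rng, n_affected, config.effect_loc,
                                 math.log10(config.min_effect_fold))
            effect[idx] = vals
            for i, v in zip(idx, vals):
                truth.effects[(tf, genes[i])] = float(v)
        for cond, shift in (("induced", effect), ("control", 0.0)):
            for r in range(1, config.reps_per_condition + 1):
                sid = f"{tf}_{'ind' if cond == 'induced' else 'ctl'}_r{r}"
                noise = rng.normal(0.0, config.noise_sd, size=config.n_genes)
                columns[sid] = baseline + shift + noise
                rows.append({"sample_id": sid, "tf": tf, "condition": cond,
                             "replicate": r, "batch": "b1"})

    matrix = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    samples = pd.DataFrame(rows)
    return matrix, samples, truth


def make_transcript_models(n_genes: int, seed: int = 0,
                           frac_predicted: float = 0.2) -> pd.DataFrame:
    """Transcript models on synthetic chromosomes, one transcript per gene.

    TSSs are spaced 200 kb apart (100 genes per chromosome) so peak-to-gene
    attribution is unambiguous unless deliberately confounded.  A fraction of
    symbols are marked predicted/clone-like (symbol_score 1 instead of 3) to
    exercise the symbol-quality scoring rule.
    """
    rng = np.random.default_rng(seed + 1)
    genes = _gene_ids(n_genes)
    n_pred = round(frac_predicted * n_genes)
    pred = set(rng.choice(n_genes, size=n_pred, replace=False).tolist()) if n_pred else set()
    rows = []
    for i, g in enumerate(genes):
        chrom = f"chrS{i // GENES_PER_CHROM + 1:02d}"
        tss = FIRST_TSS + (i % GENES_PER_CHROM) * TSS_SPACING
        rows.append({
            "transcript_id": f"tx_{g}",
            "chrom": chrom,
            "strand": "+" if rng.random() < 0.5 else "-",
            "tss": tss,
            "symbol": g,
            "symbol_score": 1 if i in pred else 3,
        })
    return pd.DataFrame(rows)


ATLAS_GAIN = 2.0  # amplifies induction effects into tissue signatures so they
                  # clear the atlas 2-fold significance threshold


def simulate_atlas(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Raw tissue atlas: gene x (tissue, replicate) log10 intensities.

    Tissue ``i`` is aligned with TF ``i`` (recorded in
    ``truth.tissue_alignment``): its profile carries
    ``alignment_strength * ATLAS_GAIN`` times the TF's planted effects, so the
    aligned tissue's median-subtracted logratios correlate positively with the
    induction profile.  Every tissue additionally receives its own set of
    strong tissue-specific genes, giving the atlas significant structure that
    is independent of the induction data.
    """
    config.validate()
    if config.n_tissues < config.n_tfs:
        raise SimConfigError(
            f"n_tissues ({config.n_tissues}) < number of requested "
            f"alignments ({config.n_tfs})")
    rng = np.random.default_rng(config.seed + 10_000)
    genes = _gene_ids(config.n_genes)
    tfs = _tf_names(config.n_tfs)
    tissues = [f"tissue{i + 1:02d}" for i in range(config.n_tissues)]

    base = rng.normal(2.5, 0.7, size=config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_specific = max(round(config.frac_affected * config.n_genes), 1)

    signal = np.zeros((config.n_genes, config.n_tissues))
    for j, tissue in enumerate(tissues):
        # tissue-own specific genes
        idx = rng.choice(config.n_genes, size=n_specific, replace=False)
        signal[idx, j] += _draw_effects(rng, n_specific, math.log10(3.0))
        if j < len(tfs):
            tf = tfs[j]
            truth.tissue_alignment[tf] = tissue
            for g, e in truth.effects_for(tf).items():
                signal[gene_pos[g], j] += config.alignment_strength * ATLAS_GAIN * e

    cols = {}
    for j, tissue in enumerate(tissues):
        for r in range(1, config.atlas_reps + 1):
            noise = rng.normal(0.0, config.noise_sd, size=config.n_genes)
            cols[(tissue, f"r{r}")] = base + signal[:, j] + noise
    atlas = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    atlas.columns = pd.MultiIndex.from_tuples(atlas.columns,
                                              names=["tissue", "replicate"])
    return atlas


def simulate_peaks(config: SimConfig, truth: SyntheticTruth,
                   models: pd.DataFrame) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-TF, per-sample BED-style peak tables with planted binding.

    For each TF a fraction ``frac_bound`` of its upregulated planted genes
    receives a peak; ``promoter_frac`` of those are placed with midpoint
    < 500 bp from the TSS (promoter class), the rest at 500-50,000 bp
    (enhancer class).  Placement keeps a safety margin to the class boundary
    so replicate jitter cannot flip the class.  Planted peaks are replicated
    (with +/-30 bp edge jitter) in every sample; decoy peaks are placed
    > 50 kb from all TSSs.  Classes are recorded in ``truth.bound_genes``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 20_000)
    tss_by_symbol = models.set_index("symbol")[["chrom", "tss"]]
    half = config.peak_width_bp // 2
    out: dict[str, dict[str, pd.DataFrame]] = {}

    for tf in _tf_names(config.n_tfs):
        up = sorted(g for g, e in truth.effects_for(tf).items() if e > 0)
        n_bound = round(config.frac_bound * len(up))
        chosen = (list(rng.choice(up, size=n_bound, replace=False))
                  if n_bound else [])
        n_prom = round(config.promoter_frac * n_bound)
        truth.bound_genes[tf] = {}
        placements = []  # (chrom, midpoint, gene or None)
        for k, g in enumerate(chosen):
            rec = tss_by_symbol.loc[g]
            if k < n_prom:
                d = int(rng.integers(0, 401))          # < 500 with margin
                cls = "promoter"
            else:
                d = int(rng.integers(700, 49_000))     # in [500, 50000) with margin
                cls = "enhancer"
            side = 1 if rng.random() < 0.5 else -1
            mid = int(rec["tss"]) + side * d
            if mid - half < 0:
                raise SimConfigError(
                    f"peak_width_bp: chromosome too short to place a peak at "
                    f"{rec['chrom']}:{mid}")
            truth.bound_genes[tf][g] = cls
            placements.append((rec["chrom"], mid, g))
        # decoys: midway between TSSs, 100 kb from the nearest
        n_decoy = max(n_bound // 2, 5)
        for _ in range(n_decoy):
            row = models.iloc[int(rng.integers(0, len(models)))]
            mid = int(row["tss"]) + TSS_SPACING // 2
            placements.append((row["chrom"], mid, None))

        samples = {}
        for s in range(1, config.n_peak_samples + 1):
            recs = []
            for i, (chrom, mid, gene) in enumerate(placements):
                j1, j2 = rng.integers(-30, 31, size=2)
                start = mid - half + int(j1)
                end = mid + half + int(j2)
                name = f"{tf}_peak{i}" if gene else f"{tf}_decoy{i}"
                recs.append({"chrom": chrom, "start": start, "end": end,
                             "name": name,
                             "score": float(rng.uniform(100, 1000))})
            samples[f"{tf}_chip_s{s}"] = (
                pd.DataFrame(recs, columns=["chrom", "start", "end", "name", "score"])
                .sort_values(["chrom", "start"], kind="stable")
                .reset_index(drop=True))
        out[tf] = samples
    return out


def simulate_gene_sets(config: SimConfig, truth: SyntheticTruth,
                       n_random_sets: int = 10, random_set_size: int = 30
                       ) -> dict[str, set[str]]:
    """Gene-set collection: one planted set per TF direction + random decoys.

    ``{tf}_up`` holds the TF's upregulated planted genes (enriched among high
    logratios by construction), ``{tf}_down`` the downregulated ones; random
    sets are uniform draws from the gene universe and should score near null.
    """
    rng = np.random.default_rng(config.seed + 30_000)
    genes = _gene_ids(config.n_genes)
    sets: dict[str, set[str]] = {}
    for tf in _tf_names(config.n_tfs):
        eff = truth.effects_for(tf)
        up = {g for g, e in eff.items() if e > 0}
        down = {g for g, e in eff.items() if e < 0}
        if up:
            sets[f"{tf}_up"] = up
        if down:
            sets[f"{tf}_down"] = down
    for i in range(n_random_sets):
        members = rng.choice(genes, size=min(random_set_size, len(genes)),
                             replace=False)
        sets[f"random{i + 1:02d}"] = set(members.tolist())
    return sets


def write_experiment(config: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """Run the full generator and write every artifact as text files.

    Produces the expression matrix and sample table (TSV), atlas (TSV with
    tissue__replicate columns), gene sets (GMT), transcript models
    (refFlat-like TSV), per-sample peak files (BED5) and the truth JSON.
    Returns a manifest of file paths.  Deterministic for a fixed config.
    """
    from tfinduce.geneset_enrichment import GeneSetCollection, write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, samples, truth = simulate_experiment(config)
    models = make_transcript_models(config.n_genes, seed=config.seed)
    atlas = simulate_atlas(config, truth)
    peaks = simulate_peaks(config, truth, models)
    sets = simulate_gene_sets(config, truth)

    paths: dict[str, str] = {}

    def _save(key: str, name: str, writer) -> None:
        p = out / name
        writer(p)
        paths[key] = str(p)

    _save("matrix", "expression.tsv",
          lambda p: matrix.to_csv(p, sep="\t", float_format="%.6f"))
    _save("samples", "samples.tsv",
          lambda p: samples.to_csv(p, sep="\t", index=False))
    flat = atlas.copy()
    flat.columns = [f"{t}__{r}" for t, r in atlas.columns]
    _save("atlas", "atlas.tsv",
          lambda p: flat.to_csv(p, sep="\t", float_format="%.6f"))
    _save("models", "transcripts.tsv",
          lambda p: models.to_csv(p, sep="\t", index=False))
    _save("gene_sets", "gene_sets.gmt",
          lambda p: write_gmt(GeneSetCollection(sets, source="synthetic"), p))
    _save("truth", "truth.json", truth.to_json)
    peak_paths: dict[str, dict[str, str]] = {}
    for tf, by_sample in peaks.items():
        peak_paths[tf] = {}
        for sid, df in by_sample.items():
            p = out / f"peaks_{sid}.bed"
            df.to_csv(p, sep="\t", header=False, index=False,
                      float_format="%.1f")
            peak_paths[tf][sid] = str(p)
    (out / "peak_manifest.json").write_text(json.dumps(peak_paths, indent=1,
                                                       sort_keys=True))
    paths["peak_manifest"] = str(out / "peak_manifest.json")
    (out / "sim_config.json").write_text(json.dumps(asdict(config), indent=1,
                                                    sort_keys=True))
    paths["config"] = str(out / "sim_config.json")
    return paths
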