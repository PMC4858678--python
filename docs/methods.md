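# Methods

## Experimental design being modelled

Each TF line is an ESC clone with a Tet-Off transgene: withdrawing
doxycycline (Dox−) induces the TF, keeping it (Dox+) is the isogenic
control. Expression is measured on log10-intensity arrays in replicate wells
per condition (3+3 by default; the machinery supports arbitrary counts,
including the 2+2 hybridization designs common in practice). All analysis is
logratio-based, so absolute intensity scale is irrelevant downstream.

## Normalization

Control-channel normalization maps an induced array onto its paired control:
`x'_i = x_i − c_i + Median(c)`, where the median runs over all features of
the array. The transform preserves every pairwise difference of the
control-corrected signal `x − c` and merely re-centres it at the control
array's overall level; a constant control channel leaves the data unchanged.
Batch combination equalizes each gene's median across batches by an additive
per-gene shift on the log scale (no scaling), with the global median taken
over all samples of all batches. Genes are intersected across batches;
an empty intersection is an error.

## Differential test

The induction logratio is `L_g = mean(induced) − mean(control)` on log10
intensities; fold change is `10^|L_g|`. The default per-gene test is a
moderated t: the pooled within-group variance (df = n1 + n2 − 2) is shrunk
toward a prior fitted across all genes,

    s~²_g = (d0·s0² + df·s²_g) / (d0 + df),

with (d0, s0²) estimated by the method of moments on log variances (the
scaled-F hierarchy of Smyth 2004), and t referred to d0 + df degrees of
freedom. With 2–3 replicates per condition an unmoderated test is severely
underpowered — at 2-fold effects, 5% affected genes and replicate SD 0.05
log10 units, plain Welch + BH recovers under 15% of planted effects, while
the moderated test recovers ≥ 99% at the same realized FDR. The moderated
p-values were cross-checked against Bioconductor limma's `eBayes` on the
same data (log p agreement within 5%; the check lives in the test suite).
Plain Welch remains available (`method="welch"`), with a per-group variance
floor of 1e−4 against zero-variance degeneracies. Multiple testing is
Benjamini–Hochberg across genes. Responder thresholds (FDR ≤ 0.05, fold
≥ 1.5) are inclusive.

PCA of induction profiles is computed on the logratio matrix restricted to
genes significant in at least one profile, with a deterministic sign
convention (largest-|loading| element of each component made positive).

## Atlas correlation

The tissue atlas is reduced to `A_gt = mean_t(log10 x) − median over
tissues`, so each gene's tissue profile is centred at zero. Atlas
significance is FDR ≤ 0.05 and fold ≥ 2 (a higher bar than the induction
1.5, since between-tissue differences are much larger than induction
responses); the test contrasts one tissue's replicates against the pooled
replicates of all other tissues. The correlation gene universe — "genes
significant in both datasets" — is the intersection of (genes significant
for ≥ 1 TF) with (genes significant in ≥ 1 tissue); one shared universe is
used for every cell of the matrix. Correlation significance is the Fisher
transform `z = atanh(r)·√(n−3)`, clamped at |z| = 50 as r → ±1 and set to 0
for n < 4. Cells with z < 2 are displayed as non-significant. Matrix rows
and columns are ordered by average-linkage hierarchical clustering on
correlation distance between r-vectors; no manual re-ordering is applied.
The Fisher z assumes independent genes; co-regulation inflates it, which is
why it is used as a display/ranking score rather than a calibrated p-value.

## PAGE enrichment

`z = (S_m − μ)·√m / δ` with S_m the mean logratio of the m set members among
the analyzed genes. Enrichment is run separately on the top and bottom
`ceil(0.25·N)` genes by logratio (ties broken by gene id for determinism).
The null mean and SD (μ, δ) are computed over the analyzed fraction by
default: because the quartile is selected for extreme logratios, an all-gene
background makes every set's quartile overlap look enriched (uniformly
random sets reach z ≥ 2 in essentially every simulation), whereas the
quartile background gives random sets z ~ N(0, 1). The all-gene background
remains available (`background="all"`); in PAGE's original whole-ranking
formulation the two coincide. Sets overlapping the analyzed genes in fewer
than 5 members are flagged untested. BH FDR is applied across tested sets
within each direction pass.

## Peak annotation

Peak score filtering keeps `score ≥ threshold` (the thresholds are
per-dataset inputs). Replicate matching pools all samples' peaks per
chromosome and takes connected components of the ≥ 1 bp overlap graph
(computed by a sorted sweep — for intervals, overlap-connectivity is
contiguous in start order); a component spanning at least the required
number of distinct samples becomes a consensus peak with the union interval
and maximum member score. Transcript scoring uses the peak midpoint (no
summit information is assumed; narrowPeak summits can be used upstream by
re-centring), unstranded absolute distance, and
`S = symbol_score / max(d, 1000) · 1000`; candidate transcripts lie within
50 kb. The top transcript is always assigned, the runner-up only if
`S₂ > 0.25·S₁` (strict); top-score ties break on transcript id. Classes are
half-open and disjoint: promoter d < 500 bp, enhancer 500 ≤ d < 50,000 bp.
A gene bound by both peak kinds appears in both class sets.

## EPFP target calling

EPFP is the BH step-up q-value computed within the candidate set: candidates
ranked by ascending p, `EPFP(r) = min_{j ≥ r} p(j)·n/j`, capped at 1. The
candidate set defaults to the bound genes (target calling conditions on
binding; `scope="all"` gives the genome-wide alternative). A regulated
target satisfies EPFP ≤ 0.5, fold ≥ 1.5 and the expected direction
(upregulation by default). Rank plots sort genes by logratio descending and
trace the proportion of bound genes in a fully sliding window (default 300
genes, step 1); the PAGE machinery supplies the significance of
promoter/enhancer bound-set enrichment.

## Synthetic data

The generator emulates the screen's structure, not array physics. Baseline
log10 intensities are N(2.5, 0.7) per gene — a plausible microarray scale
whose value is irrelevant to the logratio-based analysis. Per TF, a fraction
`frac_affected` (default 5%) of genes receives a signed effect with
magnitude `log10(min_effect_fold) + Exp(excess)` (defaults: min fold 1.5,
mean |effect| 0.35 log10 units ≈ 2.2-fold), so essentially all planted
effects clear the responder fold threshold and recovery is well defined.
Replicate noise is i.i.d. N(0, 0.05) log10 units, a typical within-array
replicate SD for expression arrays. Tissue `i` of the atlas is aligned with
TF `i`: it carries the TF's effects amplified ×2 (so they clear the atlas
2-fold bar) scaled by `alignment_strength`, plus its own tissue-specific
genes at ~3-fold so the atlas has structure independent of the induction
data. Transcript models place one TSS per 200 kb (100 genes per synthetic
chromosome), making peak attribution unambiguous by construction; 20% of
symbols are marked predicted/clone-like (symbol score 1). Planted peaks are
placed with a safety margin inside their class window (promoter ≤ 400 bp,
enhancer 700 bp–49 kb) so the ±30 bp replicate jitter cannot flip the class;
decoy peaks sit 100 kb from the nearest TSS. Everything is driven by one
seed through `numpy.random.default_rng`; identical configs produce
byte-identical files.

What the simulations do **not** model: probe-level effects, dye bias,
intensity-dependent variance, correlated gene modules, cascade (indirect)
regulation, and peak-calling noise. Passing recovery tests therefore
demonstrates the correctness of the computational pipeline under its stated
assumptions, not the biological error rates to expect on real arrays, where
variance moderation assumptions and gene–gene correlation matter more.

## Problem sizes and determinism

The verification script and test suite run at desk scale: 1,000–2,000 genes,
1–4 TFs, 3–20 simulation seeds per property, 10,000 resampling draws for the
PAGE null and 1,000 × 500 peak-by-transcript brute-force comparisons —
large enough for the binomial tolerances used, and chosen once as part of
the study design. All randomness flows from explicit seeds; reruns are
byte-identical, and the pipeline manifest records the config hash and seed.

## Known limitations

- The moderated test assumes roughly exchangeable gene variances on the log
  scale; strongly heteroscedastic designs may prefer `method="welch"`.
- Fisher z on correlated genes is anti-conservative; the z ≥ 2 display
  cutoff should not be read as a 2σ guarantee.
- EPFP within the bound subset inherits BH's behaviour at very small
  candidate sets (a single candidate's EPFP is its p-value).
- Peak matching is the most permissive deterministic reading of replicate
  "matching" (any overlap, transitively); stricter reciprocal-overlap rules
  would shrink consensus sets.
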