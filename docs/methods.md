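# Methods

This note documents the models and procedures implemented in `metacompare`,
the assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices made where the design was genuinely open.

## Data model

The unit of analysis is a genus-level integer count vector per sample and
sequencing strategy (16S amplicon or shotgun), with a phylum lineage per
genus and sample metadata giving the gut compartment (caeca/crop), sampling
day (1/14/35) and a pair id linking the two strategies' profiles of the
same biological sample. Genus identity is by exact name string; the two
strategies' reference databases are assumed pre-harmonized, as no general
mapping between taxonomies exists at this layer. Zero-count genera are kept
on a dataset-wide genus axis so that all samples share one coordinate
system for beta diversity.

## Synthetic paired communities

The simulator's defaults mirror a paired chicken-gut study layout: 40 caeca
samples (4/16/20 at days 1/14/35) and 38 crop samples (5/15/18), each
sequenced by both strategies.

* **Community**: 400 genera over 14 phyla with lognormal relative
  abundances, σ = 2.5 on the natural-log scale (≈ 3.6 Preston octaves).
  This spread places a substantial fraction of genera near or below the
  detection limit of either strategy at realistic depths, which is what
  makes depth effects (RSA truncation, strategy-exclusive genera)
  observable at all.
* **Depths**: 16S ~ Uniform[150,000; 200,000] reads (the nominal per-sample
  yield of a 15M-read MiSeq v2 run split 80 ways); shotgun ~
  LogUniform[200,000; 5,000,000]. A fraction 28/78 of shotgun samples is
  forced below the 500,000-read quality threshold, assigned preferentially
  to the day-1 and early crop cells — low-biomass samples in gut studies
  are exactly the ones that sequence shallowly.
* **Read sampling** is multinomial over genus proportions. There is no
  genome-size weighting and no separate 16S copy-number term: read counts
  are treated directly as abundance proxies, and every systematic 16S
  distortion is folded into one per-genus amplification bias factor b_g ~
  LogNormal(0, 0.5). b_g = 0 encodes primer dropout (10% of genera by
  default), making those genera shotgun-exclusive in expectation.
* **Phantom genera** (5% by default, ~2% of 16S reads) are observable only
  in 16S, standing in for reference-database disagreement. No mechanistic
  model of such genera is attempted; they are a labelled stand-in. Their
  sampling weights live in the *unperturbed mass space* and are divided by
  the community's post-perturbation total mass, so their absolute abundance
  is condition-independent: after median-of-ratios normalization they
  behave like unaffected real genera and carry no condition signal beyond
  sampling noise. (Holding their *read share* fixed instead would leak an
  anti-signal through normalization, because size factors track the
  rescaling of the real community.)
* **Condition effects**: 50% of real genera receive a compartment effect
  and 25% a day effect, each multiplying the genus proportion by 2^LFC
  with LFC ~ Normal(0, 2) in the alternative level (crop; day 35), followed
  by renormalization. The recorded per-genus LFC is the ground truth;
  renormalization makes realized compositional fold changes differ slightly
  from it, as in any relative-abundance experiment. Phantom genera never
  receive effects.
* **Reproducibility**: one dataset seed; per-sample substreams derived
  deterministically from (seed, sample id) via CRC32, so generation order
  does not matter and outputs are byte-identical under a fixed seed.

What the simulator does **not** emulate: sequence-level error, chimeras,
OTU clustering, contamination and host DNA, genome-size effects, and any
correlation structure between genera. Tests passing on these synthetic
data therefore demonstrate correctness of the statistical machinery and
qualitative reproduction of depth/bias mechanisms, not quantitative
fidelity to any particular real dataset.

## RSA diagnostics

Preston histograms bin detected taxa by octave floor(log2 c) — a taxon
with count c in [2^k, 2^(k+1)) lands in octave k — with no half-split of
boundary counts; the simple rule is exactly reproducible. Skewness is the
population Fisher–Pearson g1 (no small-sample correction) of the log2
counts of detected taxa only, with no pseudocount: the RSA is defined over
detected taxa. Fewer than 3 detected taxa or zero variance yield a flagged
undefined value, never a silent 0. The paired skewness test is the
classical paired Student's t on per-pair (16S − shotgun) skewness, df =
n − 1; a zero-variance difference vector is reported as t = ±inf, p = 0
(or t = 0, p = 1 when all differences vanish) rather than erroring.

Rarefaction uses the exact hypergeometric expectation computed via
log-gamma; terms with N − N_g < n are exactly zero. The curve is exact at
the endpoints (E[S_1] = 1, E[S_N] = S_obs) and verified against both
1,000-draw Monte-Carlo subsampling and `scipy.stats.hypergeom`.

The quality filter excludes shotgun samples with total reads strictly
below the threshold (default 500,000, configurable) and propagates the
exclusion to the paired 16S sample so both strategies retain the same
biological samples. The filter is idempotent.

## Differential abundance engine

A deliberately self-contained NB engine in the DESeq2 family, simplified
where the full procedure adds machinery the comparison does not need:

* **Size factors**: median-of-ratios to a geometric-mean reference over
  genera positive in all samples, rescaled to unit geometric mean (the
  rescaling constant cancels in fold changes). Datasets with no
  all-positive genus raise an explicit error rather than silently changing
  estimator.
* **Dispersion**: per genus, method of moments within condition groups —
  α̂ = (s² − μ·mean(1/s_j))/μ² on normalized counts, pooled across groups by
  degrees of freedom and floored at 1e-8 — then shrunk toward a
  least-squares trend a0 + a1/μ by an equal-weight geometric average. The
  trend shrinkage tames the noisy per-genus moments at ~10 samples per
  group; null simulations at α = 0.1 give a raw-p type-I rate of ~0.05.
* **Wald test**: per genus, an NB model with log link, size factors as
  offsets and a two-level condition. Because the design is saturated per
  group, the two group means are profiled out independently by a monotone
  Newton solve of the score equation; the log2 fold change SE comes from
  the observed Fisher information Σ μ/(1+αμ) per group, and the two-sided
  p-value from the normal reference. Genera with zero counts in one group
  have an unbounded MLE; their group mean is clamped at half a count over
  the group's total size factor and the genus flagged `boundary` — such
  partially-absent genera are exactly the interesting near-detection-limit
  cases and must stay in the analysis. All-zero genera get p = NA and are
  excluded from the multiple-testing family.
* **BH adjustment** is the standard step-up over non-NA p-values.
* **Shrinkage**: empirical-Bayes normal prior N(0, τ²) with τ² moment
  matched as max(var(LFC) − mean(SE²), 1e-6); the posterior mean
  LFC·τ²/(τ²+SE²) never increases a magnitude or flips a sign.

Omitted relative to the full DESeq2 procedure: Cook's-distance outlier
handling, independent filtering, the parametric gamma-GLM dispersion trend
and its MAP estimate, and multi-factor designs. The engine is cross-checked
against `pydeseq2` on strongly changed genera in the test suite.

Concordance classifies the genera common to both strategies' result tables
by adjusted significance (threshold 0.05, configurable) into both /
16S-only / shotgun-only / neither, counts sign agreement of the shrunken
LFCs (a raw-LFC flag exists; zero LFC on either side counts as
discordant), and reports Pearson r plus a least-squares line over the
"both" category.

## Pair comparison

Correlation and regression use raw read counts on the log2 scale over
common genera (all counts ≥ 1, so no pseudocount is needed). The
detection-limit fit is ordinary least squares — not ranged major axis —
because the design explicitly designates 16S abundance as the independent
variable; the intercept CI is t-quantile × SE at the 95% level
(configurable), and the detection threshold is reported as the continuous
value 2^intercept. The intercept-vs-depth correlation deliberately
includes low-depth pairs: the dependence on depth is the phenomenon.

## Ordination and stratification

Bray–Curtis Σ|x−y|/Σ(x+y) on normalized counts; classical PCoA by Gower
double-centering and symmetric eigendecomposition, dropping
negative-eigenvalue axes (possible under Bray–Curtis) and reporting their
total magnitude, with no Cailliez/Lingoes correction. Silhouettes are
computed on the Bray–Curtis distances restricted to each genus subset
rather than on a truncated PCoA embedding: with all positive axes kept the
two are identical, and the full-distance version avoids an arbitrary axis
cut. Strategy-exclusivity is defined at dataset level (detected in ≥ 1
sample of one strategy, 0 of the other). Day silhouettes are computed
within each compartment; with the default layout the crop day-14 cell is
removed by the read filter, so the crop day labelling is reported as NA —
an honest reflection of what the filter leaves.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
50 replicate communities for the skewness–depth curve, 20 replicate pairs
for the detection-limit recovery, 2,000 genera × 20 samples for the null
calibration, two 20-sample datasets for power, and one full 78-pair study
for stratification. These sizes give Monte-Carlo errors comfortably inside
the asserted tolerances while keeping a full run to seconds.

## Known limitations

* The NB Wald test with normal reference is mildly anticonservative at
  very small sample sizes (< 4 per group); the engine refuses groups of 1
  but does not switch to a t reference.
* The dispersion trend is a two-term 1/μ curve; heavy-tailed mean–dispersion
  relationships in real data may be under-fit.
* Boundary (one-group-zero) fold changes depend on the half-count clamp;
  their magnitudes are reported but should be read as lower-bounded, not
  estimated.
* Exact-name genus matching between strategies will under-count common
  genera on real exports whose taxonomies were not harmonized upstream.
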