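# metacompare

Compare genus-level taxonomic profiles obtained by **16S rRNA amplicon
sequencing** and **whole-genome shotgun metagenomic sequencing** of the same
biological samples.

Microbiome studies routinely choose between the two strategies: amplicon
sequencing is cheap and targeted but biased by primer choice and limited by
its modest read depth (a MiSeq v2 run yields roughly 187,500 reads per
sample), while shotgun sequencing at millions of reads per sample resolves
rarer taxa — provided enough reads survive quality control. `metacompare` is
a toolkit for paired-design comparisons of the two, aimed at anyone deciding
whether the extra depth of shotgun sequencing buys biologically meaningful
information for their system. It implements:

* **RSA depth diagnostics** — per-sample relative species abundance
  distributions as Preston plots (taxa binned by log2 read-count octave),
  the Fisher–Pearson skewness g1 = m3/m2^(3/2) of the log2-transformed
  nonzero counts, a paired t-test of per-sample skewness between
  strategies, analytic rarefaction E[S_n] = S_obs − Σ_g C(N−N_g, n)/C(N, n),
  and a read-depth quality filter (shotgun samples under 500,000 reads are
  excluded together with their 16S mates). Under-sampling truncates the
  rare tail of the RSA and inflates its skewness, so skewness doubles as a
  depth-adequacy diagnostic.
* **Differential abundance + concordance** — a self-contained
  negative-binomial engine in the DESeq2 family (median-of-ratios size
  factors, method-of-moments dispersion shrunk to a mean–dispersion trend,
  per-genus NB Wald test, Benjamini–Hochberg adjustment, empirical-Bayes
  fold-change shrinkage), and a cross-strategy concordance analysis that
  classifies common genera by significance pattern (both / 16S-only /
  shotgun-only / neither) and sign agreement of their log2 fold changes.
* **Detection-limit regression** — per pair, OLS of log2(shotgun count) on
  log2(16S count) over common genera; the intercept is the expected number
  of shotgun reads for a genus mapped by one 16S read, so 2^intercept acts
  as the 16S detection limit expressed in shotgun reads, and across pairs
  the intercept tracks shotgun sequencing depth.
* **Silhouette-scored ordination** — Bray–Curtis distances on normalized
  counts, classical PCoA, and mean silhouette scores quantifying how well
  experimental factors (gut compartment, sampling day) stratify samples,
  computed on four genus subsets: all shotgun-detected (SHOTGUN), all
  16S-detected (16S), and the strategy-exclusive subsets (SHOTGUNex, 16Sex).
* **A paired-community simulator** — lognormal communities sampled
  multinomially at realistic depths, with per-genus 16S amplification bias,
  primer dropout, 16S-only "phantom" genera and condition-dependent fold
  changes, all recorded as ground truth so every stage of the pipeline is
  testable without downloads.

## Worked example

```python
from metacompare import SimulationDesign, generate_paired_dataset, StrategyComparison

design = SimulationDesign(seed=1)           # 78 paired samples, 400 genera
pset, truth = generate_paired_dataset(design)
results = StrategyComparison(pset).fit()    # filter -> RSA -> diff -> detect -> ordinate
print(results.summary())
```

prints (abridged):

```
Paired 16S vs shotgun strategy comparison
=========================================
retained pairs: 50 (excluded 56 profiles below 500000 shotgun reads, with paired propagation)
paired RSA skewness t-test (16S - shotgun): t = 20.335, p = 1.56e-25 (n = 50)

contrast 'compartment': significant genera 16S = 162, shotgun = 216
...
detection-limit intercept vs shotgun depth: r = 0.967 (p = 4.1e-30)

Sample stratification (mean silhouette scores)
==============================================
   subset   labelling  mean_silhouette  n_samples  n_genera
  SHOTGUN compartment            0.797         50       380
      16S compartment            0.729         50       360
SHOTGUNex   day:caeca            0.921         36        40
    16Sex   day:caeca            0.041         36        20
```

Reading the output: 28 of the 78 simulated shotgun samples fall below the
500,000-read threshold and are excluded with their 16S mates, leaving 50
pairs. The strongly positive paired skewness t statistic says 16S RSAs are
systematically more right-skewed than their shotgun mates — the signature
of shallower sampling. Shotgun sequencing calls more significant genera
than 16S for the same contrast, and the detection-limit intercept rises
with shotgun depth (r ≈ 0.97). In the stratification block, compartment
separates well under both strategies; genera seen *only* by shotgun still
separate sampling days (mean silhouette 0.92) while the 16S-only genera do
not (0.04, i.e. no better than random labelling) — the simulator's phantom
genera carry no condition signal, and the pipeline correctly says so.

The same workflow is available from the shell:

```
metacompare simulate --seed 1 --out data/
metacompare run --config run.yaml
metacompare rsa / diff / concordance / detect / ordinate ...
```

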