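# Methods

## The statistic

The pipeline quantifies how readily a gene's expression is perturbed by
pooling dispersion evidence over many independent expression datasets.
Within one dataset, dispersion is the coefficient of variation
CV = SD/mean (sample SD, n−1 denominator) of the gene's preprocessed
expression across that dataset's samples. CVs from different studies are
not comparable in absolute terms — platforms, labs and conditions shift
both mean and spread — so each dataset contributes only the *ranking* of
its genes by CV (ascending; rank 1 = most stable; ties get the average of
the tied positions, which preserves the rank-sum Σr = n(n+1)/2). The
sensitive value SV of a gene is the mean of its CV ranks over the datasets
in which it is measured. Rank-averaging is the entire cross-study
harmonisation: no batch correction, scaling or distributional assumption
beyond "ranks within a study are meaningful" is made.

Assumptions worth stating: datasets are treated as exchangeable replicates
of "some perturbation of the transcriptome" — SV has no notion of which
condition a dataset probes, only that many different ones are sampled; a
gene's stability is taken to be a reproducible property, i.e. rank noise is
independent across datasets and averages out as M grows; and the input
intensities are assumed pre-normalised within each dataset.

## Preprocessing

Fixed stage order: **filter → floor/log → collapse**.

* Datasets with fewer than `min_samples` arrays (default 6) are discarded —
  below that, a per-gene SD is too noisy to rank usefully (and undefined
  below 2). Each discard is logged with the dataset ID and its count.
* Raw intensities below `floor_value` (default 10) are raised to it, then
  values are log-transformed (`log_base` 2). The floor bounds the log away
  from −∞ on background-level intensities and guarantees strictly positive
  means (minimum possible value log2(10) ≈ 3.3219), which is what keeps
  CV = SD/mean well defined everywhere. Applying the transform twice is a
  state error, not a silent no-op.
* Multiple probes for one gene are collapsed by taking, per sample, the
  maximum over the gene's probes (`per_sample_max`). The sentence "take the
  maximum expression value as the gene's value" admits a second reading —
  keep the whole row of the probe with the highest mean — which is offered
  as `collapse_method: max_mean_probe`; the per-sample maximum is the
  default as the more literal reading. Because log2 is monotone, the
  per-sample maximum commutes with the transform, so the floor/log →
  collapse order is not load-bearing for the default method. Probes with no
  gene annotation are dropped (with a logged count) rather than kept as
  singleton genes: the analysis is about genes, and an unannotated probe
  cannot join a gene group anyway.

## CV scale

Whether CV should be computed on the log2 values or on the (floored) raw
intensities is genuinely open: the preprocessing order suggests log-scale,
but CV on log-transformed data is unconventional (on a log scale the SD
alone is already a relative-dispersion measure). Both are implemented
(`cv_scale: log` — default, following the stated operation order — and
`raw`). The choice matters little for the ranking: raw-scale CV is exactly
invariant to rescaling a dataset, and log-scale CV ranks are empirically
stable under rescaling (tested at ×2 and ×10 on floor-free data; rank
correlation > 0.95, not exact equality, because the rescaling shifts the
log-mean denominator).

## Coverage generalisation

On a single platform every gene is measured in every dataset and SV is a
mean over all M datasets. When datasets over different gene universes are
mixed, ranks are computed within each dataset over its own measured genes
and SV divides by the gene's own coverage M_i; genes measured in fewer than
`min_coverage_fraction` (default 0.5) of the datasets are excluded from the
SV ranking rather than scored on thin evidence. In the single-platform case
M_i = M and both rules are vacuous. Rank magnitudes do depend on universe
size, so mixing datasets with very different gene counts makes SVs a
compromise; the default pipeline never encounters this.

## Tails and enrichment

The robust and sensitive classes are the extreme `cutoff_fraction` (default
5%) tails of the SV distribution. Tail size is round-half-up of
fraction × universe — 31835 genes at 5% gives 1591.75 → 1592 per tail.
SV ties at a tail boundary are broken lexicographically by gene symbol, so
the tail size is always exact and the classification deterministic.

Enrichment of a gene group in a tail is the upper-tail hypergeometric
probability P(X ≥ k) of drawing at least the observed overlap k when K
genes (the tail) are drawn from the N-gene universe and n of them belong to
the group. The universe is the set of classified genes (everything with an
SV): it is the only set on which both margins of the 2×2 table are defined
without further curation choices. Every group is tested against both tails
(over-representation only — depletion is not tested), and
Benjamini–Hochberg adjusted p-values are computed across the full
group × tail list; raw p-values remain the primary column so results stay
comparable with unadjusted reporting. Groups sharing no genes with the
universe are skipped with a warning.

A single-gene case/control profile (per-condition means, Welch two-sample
t, two-sided p) is included for the qualitative check that motivates the
robust class: a low-SV disease gene typically shows no significant change
in its own disease cohort. When both groups have zero variance the test is
taken at its limit: t = 0, p = 1 for equal means; ±∞, p = 0 otherwise.

## Synthetic data generator

The generator emulates the data regime the analysis is designed for —
many moderately sized, pre-normalised intensity matrices over one gene
universe — with planted ground truth:

* per-gene log2 mean μ_g ~ Normal(`baseline_mean_log2` = 8, 1.5), clipped
  at 4.5 so ordinary genes stay clear of the intensity floor;
* per-gene base log2 SD s_g lognormal with median 0.25 and σ = 0.2 —
  a deliberately moderate spread of intrinsic variability, so that planted
  multipliers (×4 for sensitive, ×0.25 for robust, 5% of genes each by
  default) dominate gene-to-gene SD variation;
* per dataset: a baseline shift ~ Normal(0, 0.3) shared by all genes, then
  per-sample values Normal(μ_g + shift, s_g × multiplier) on the log2
  scale, exported as raw intensities 2^x;
* 2% of background genes get a low mean (~Normal(3.2, 0.4) log2 ≈ raw 9)
  so a realistic share of raw values falls below the floor of 10 and the
  flooring rule is genuinely exercised;
* multi-probe genes (1–3 probes by default): secondary probes are the gene
  signal attenuated by 1 log2 unit per step with extra Normal(0, 0.1)
  noise, so the per-sample max-collapse has a defined correct answer (the
  primary probe);
* gene groups: `n_enriched_groups` (default 5) alternate between the
  sensitive and robust planted sets, drawing each member from the planted
  set with probability `group_tail_bias` (default 0.9) and from background
  otherwise, without duplicates; the remaining groups draw uniformly.

All randomness derives from one seed via `numpy.random.SeedSequence`
substreams (gene parameters / each dataset / groups), so every output is
bit-identical across runs and `simulate_groups` is reproducible on its own.

What the generator does **not** emulate: probe-level summarisation
artefacts (MAS5 internals, spatial chip effects), heavy-tailed or
mean-dependent variance structure, correlated gene modules, missing
values, or annotation noise in probe→gene maps. Passing recovery tests
therefore shows the statistic does what it claims under a clean
dispersion-separated regime; it does not certify behaviour under real-array
artefacts.

One emergent (and realistic) generator behaviour: genes sitting almost
entirely below the intensity floor become near-constant after clamping and
thus maximally "robust", occupying a few robust-tail slots ahead of planted
robust genes. Aggregate planted-robust recovery stays ≈ 95% under the
default conditions; per-seed it can dip just below 90%.

## Problem sizes and numerical conventions

The recovery analyses run at 2000 genes × 20 datasets × 20 samples
(multipliers 4 / 0.25) over 20 seeds, and group-enrichment recovery at the
same scale with 20 groups of 30 (bias 0.9) over 10 seeds — large enough
that planted structure is unambiguous, small enough that the whole suite
and the reproduction script run in seconds on one core. Oracle-equivalence
checks (CV, ranks, SV, tail selection, hypergeometric tail) use ≥200 random
small instances each against independent brute-force implementations at
1e-10, with exact rational enumeration for the hypergeometric at N ≤ 30.

Conventions: sample SD uses n−1; ranks tie-average; tail size rounds half
up; tail-boundary ties break by gene symbol; result tables sort by
(SV, gene) or (p, group, tail); floats are written in shortest round-trip
form so written tables re-read exactly and reruns are byte-identical.

## Known limitations

* SV is a mean of within-dataset ranks, so its scale depends on universe
  size; SVs from runs over different universes are not comparable.
* The hypergeometric test treats genes as exchangeable; correlated gene
  families inflate significance as in any over-representation analysis.
* Gene symbols are opaque, case-sensitive strings — no alias resolution;
  identifier curation is upstream of this package.
* No normalisation is performed; garbage-in applies to un-normalised
  intensity matrices.
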