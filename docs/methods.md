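# Methods

This note records the models, conventions, and design choices behind
`gutsig`, in the spirit of a methods appendix: what each stage assumes, what
the defaults mean, and what the synthetic evaluation does and does not show.

## Data model

The central object is a samples × genera abundance table (counts or
relative abundances), validated at construction: non-negative values,
unique ids, and — in relative mode — unit row sums within 1e-6. Counts are
total-sum scaled to proportions before any dissimilarity or correlation is
computed; no rarefaction is applied by default because read-depth
normalization is a contested choice, but a seeded rarefy-to-depth step is
available (`gutsig.diversity.rarefy`). Genus names are opaque,
case-sensitive strings; no taxonomy parsing is attempted.

CARS metadata carries 15 items on the legal grid {1, 1.5, …, 4}; the total
must equal the item sum exactly. `ados_total` and brain volumes may be
missing; any analysis needing a missing value drops that sample and reports
the n it actually used.

## CARS domains and severity

Domain scores are sums of item subsets: distorted sensory response =
cars7 + cars8 + cars9; negative emotionality = cars3 + cars6 + cars10;
social impairment defaults to the ten items cars1, cars2, cars4, cars5,
cars10–cars15. The item sets are configuration, not constants, because
published domain definitions vary (and cars10 legitimately appears in two
domains under the grouping adopted here). Severity is a threshold label:
severe ⇔ CARS total ≥ 36, with the threshold configurable.

## Signature discovery

The discovery procedure is a two-stage heuristic:

1. **Screen.** Spearman correlation (average ranks) of every genus against
   every behavioral variable supplied (CARS total and domain scores by
   default, ADOS total when present). Per variable, p-values are
   Benjamini–Hochberg adjusted across genera. The top `pool` (default 30)
   genera by best |rho| are the candidates. Constant columns get rho = 0
   and a degenerate flag.
2. **Greedy forward selection.** The search is seeded with the screen's top
   genus: a singleton subset is uninformative under subset renormalization
   (every sample becomes the unit composition), so the first step cannot be
   scored by clustering. From size two onward, each remaining candidate g
   is scored by the Kruskal–Wallis H of the CARS total across the two
   UPGMA/Bray–Curtis clusters of S ∪ {g}; degenerate clusterings (singleton
   cluster, all-zero distances) score 0. The best candidate is accepted
   while the objective does not decrease — ties are frequent once the
   partition stabilizes and are broken by larger marginal |rho|, then by
   genus id — and the search stops at the target size (default 12) or when
   every candidate strictly decreases the objective. The objective trace is
   therefore non-decreasing by construction.

H (not its p-value) is the objective so the inner loop stays
permutation-free; significance of the final signature's severity
separation is assessed once at the end by label permutation.

A known behavior of this objective is *saturation*: H is bounded for a
fixed cohort, and once the two-cluster partition is as severity-separated
as the data allow, additional genera tie or slightly decrease the
objective. Ties are resolved toward genera with real marginal association;
a strictly-decreasing step ends the search, which is why discovered
signatures are occasionally shorter than the target size. When the
behavioral separation between latent subpopulations is weak relative to
within-group spread, an early overfit partition can beat the
truth-aligned partition and stall the search — a limitation to bear in
mind on noisy cohorts.

## Subtyping and classification

Subtyping restricts the (relative) table to the signature genera,
renormalizes rows to the subset, computes Bray–Curtis dissimilarity, and
cuts an average-linkage (UPGMA) dendrogram at exactly two clusters. Two
subpopulations are a modeling commitment, not an inference; no gap
statistic is consulted. The cluster with the lower mean CARS total is
labelled `mp1` (ties: the larger cluster), so `mp2` is by construction the
more severe subpopulation.

The kNN classifier stores the subset-renormalized training rows and votes
among the k nearest under the same Bray–Curtis metric (Euclidean
optional). k must be odd (default 3, appropriate for cohorts of tens of
samples); distance ties are broken by training-row order and vote ties by
the single nearest neighbor, making predictions fully deterministic.
LOOCV holds the cluster labels fixed — matching the usual practice of
evaluating a classifier against the full-cohort clustering — which leaks
the left-out sample's influence on its own label; the report shows LOOCV
for k ∈ {1, 3, 5, 7} so the k choice is transparent.

## Diversity and ordination

Shannon entropy uses natural logs (a base-2 flag exists for comparability
with amplicon toolchains); Pielou evenness = H / ln(richness) is undefined
(NaN, never 0) for single-taxon samples so group means are not deflated.
Faith PD follows the rooted convention — total branch length on the union
of root-to-leaf paths of observed taxa — computed by a single postorder
pass that accepts multifurcations (a star tree with m observed unit
branches scores exactly m). PCoA is classical scaling: double-center
−D²/2, eigendecompose, scale eigenvectors by √λ; negative eigenvalues
(Bray–Curtis is non-Euclidean) are recorded and dropped, proportions
explained are over the positive spectrum, and requesting more axes than
positive eigenvalues truncates with a warning.

## Permutation inference

All permutation p-values use the add-one estimator (1 + #extreme)/(1 + B),
bounded below by 1/(B+1), with B = 5000 by default. Kruskal–Wallis H is
computed on average ranks with the standard tie correction; the
permutation null shuffles labels (vectorized over all B draws), and the
asymptotic chi-square p is reported alongside. Spearman permutation tests
are two-sided on |rho|. Comparisons of permuted statistics against the
observed value use a 1e-12 slack so exact ties under rank arithmetic count
as extreme. Every result records its seed and B and reruns bit-identically.

Odds ratios use the Haldane–Anscombe +0.5 correction only when a zero cell
is present (flagged in the result); the Fisher exact p is always computed
on the uncorrected counts. The opposite-pattern test classifies each
sample by whether (a + ε)/(b + ε) > 1, with ε equal to half the smallest
nonzero relative abundance in the table — a pseudocount convention needed
because zeros are common in genus tables — and cross-tabulates dominance
against subtype. Clinical contrasts are reported at raw permutation p;
only the brain-region family is BH-adjusted, and regions surviving
adjustment are correlated (Spearman, permutation p) with the sensory
domain score within each subtype.

## Synthetic cohort generator

The generator emulates the assumed data-generating process, not any real
dataset. Per cohort: latent labels are stratified draws with mixing
proportion π = 0.6; genus log-intensities are Normal(μ_g, σ) with
per-genus baselines μ_g ~ Normal(0, 1); softmax converts intensities to
proportions; counts are multinomial at depth 20 000 (rows sum exactly to
depth). Twelve signature genera get ±δ log-shifts in subpopulation 2
(alternating signs; δ = 1.5 by default), and the first two — given a
common baseline — form the opposite-pattern pair. The evenness gap is
implemented as extra per-sample log-abundance spread in subpopulation 2
(noise sd × (1 + 0.5)): scaling the baseline *means* instead would make
nearly every genus consistently differential and destroy the
identifiability of the planted signature, whereas per-sample spread lowers
expected evenness without planting new per-genus contrasts. CARS items are
Normal(2.3, 0.4) on the latent scale, shifted by +0.5 on the sensory and
social items in subpopulation 2, then rounded to the half-point grid and
clipped to [1, 4], with totals computed after rounding; the implied cohort
mean ± SD of the CARS total (~37 ± 3.5) matches published pediatric ASD
cohorts. ADOS totals are coupled to the CARS total; three designated brain
regions get volume = baseline − 110 mm³ × (sensory − mean) + Normal(0, 300),
giving a within-subtype Spearman r near −0.25. The phylogeny is a random
bifurcating join with exponential branch lengths — it carries no
relationship to the planted effects, so Faith PD contrasts between
subtypes are weak by design.

Noise scales were fixed once, in a calibration pass at δ = 1.5, so that
the planted two-block structure is recoverable by the pipeline (clean
UPGMA clusters without outlier singletons, near-ceiling behavioral
separation); they were not revisited afterwards. One global seed fans out
to named substreams (structure, tree, and per-cohort labels/abundance/
behavior/brain), so drawing a held-out cohort from the same planted
structure never perturbs the discovery draw.

What passing on this generator shows: the pipeline recovers planted
subpopulations, signatures, and effect directions under its own
assumptions at realistic sample sizes. What it does not show: robustness
to real-data features the generator omits — zero-inflation beyond
multinomial sampling, age/sex confounding, uneven sequencing depth,
phylogenetically clustered effects, batch structure, and behavioral
separations weaker than the planted one. The severity × subtype odds
ratio on synthetic cohorts is far more extreme than published values
because the planted behavioral separation is strong; directions, not
magnitudes, are the emulation target. The evenness contrast is the
weakest planted effect: the signature shifts themselves perturb evenness
in a structure-dependent direction, so individual cohorts can show a null
or even reversed Pielou gap while the average direction is as designed.

## Problem sizes

Default evaluations use 78-sample discovery cohorts, 50-sample held-out
cohorts, 60 genera with a 12-genus signature, B = 5000 permutations for
reported statistics (1000 for the type-I-error sweep), and 10 seeds for
recovery summaries — sizes chosen to mirror a single-site pediatric study
while keeping a full run interactive on one CPU.
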