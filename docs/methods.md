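# Methods

`msatabc` implements demographic inference for diploid microsatellite
(SSR) data by approximate Bayesian computation with random forests
(ABC-RF), together with the classical diversity and differentiation
statistics usually reported alongside such analyses. This note documents
the models, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Demographic model and coalescent simulator

A *scenario* is a set of sampled lineages, each a panmictic population of
constant diploid effective size Ne, joined backward in time by
instantaneous events: a **split** moves all gene lineages of the derived
population(s) into the ancestor; an **admixture** sends each gene lineage
of the target to the first source with probability *ra*, otherwise to the
second. Between events, each pair of lineages within a population
coalesces at rate 1/(2Ne) per generation; waiting times are exponential
(the continuous-time approximation, adequate for the Ne range used here).
Time is measured in generations before present; multiplying by a
generation time (100 years for long-lived trees such as sweet chestnut)
converts to calendar ages.

Mutations follow the generalized stepwise model (GSM): on a branch of
length *t* the mutation count is Poisson(µ·t); each mutation changes the
repeat count by ±s with s geometric, Pr(s = k) = (1 − P)·P^(k−1), sign
equiprobable. P = 0 is the strict stepwise model (SMM). Each locus has 40
contiguous allelic states centred on its ancestral repeat count; mutations
that would leave the window reflect at the boundary. The bounded ladder
keeps the Garza–Williamson ratio well defined; with the priors used here
the boundary is rarely touched (verified: single-population SMM gene
diversity matches the Ohta–Kimura closed form 1 − 1/√(1 + 2θ) to < 0.01
at θ up to 8, and allele-frequency distributions are indistinguishable
from msprime's SMM implementation by a KS test).

Per-locus rate heterogeneity: the dataset-level means µ̄ and P̄ are drawn
from their priors; each locus then draws µ_l and P_l from gamma
distributions with shape 2 and those means (P_l clipped at 0.99). Shape 2
is the common ABC convention for microsatellite batteries; it is
configurable in `PriorSet`.

Diploid genotypes pair consecutive gene copies within each population;
exchangeability of copies makes the pairing harmless. One master seed
drives everything; per-locus seeds are drawn up-front from the dataset
stream, so changing the locus count never perturbs earlier loci. The
simulation core is numba-compiled (~0.2 ms per locus at the 532-copy study
design; a full 266-individual × 9-locus dataset plus its 130 statistics
costs ≈ 4 ms).

## Study design fixture

`scenarios_caucasus.cfg` encodes five sampled lineages — Lesser Caucasus
(I, 62 diploids), Greater Caucasus (II, 72), West+East Greater Caucasus
(III, 65), East Greater Caucasus (IV, 40), Europe (V, 27) — at nine SSR
loci, and eight scenarios for their ancestry. Scenarios 1–4 follow the
study design's verbal descriptions: 1 (split of I/IV/V at t2, II from I at t1,
III an admixture of II and IV at ta), 2 (as 1 but II a t2-level lineage),
3 (a single five-way divergence), 4 (II from I and IV from III at one
depth t1, after a deeper I/III/V split). The topologies of scenarios 5–7
are specified in the study design only as alternative hierarchies; they are
chosen here as a family of nested bifurcations over the same groups — 5
and 6 differ only in the parent of lineage III (II vs IV), 6 and 7 only in
the order of the same two splits — on the reasoning that the scenarios reported hardest to
classify in the reference analysis of this design (7, 6, and 2) must be near
neighbours of other scenarios, which constrains what they can look like.
Scenario 8 makes lineage IV ancestral to all Caucasian lineages, as the
reference analysis states.

Default priors (the exact supplementary ranges are not in the main text):
Ne ~ U(100, 30 000) per lineage; event times U(10, 10 000) generations
with ta < t1 < t2 enforced by rejection (with transitive closure, so a
scenario that omits t1 still honours ta < t2); ra ~ U(0.001, 0.999);
µ̄ ~ U(10⁻⁵, 10⁻³); P̄ ~ U(0.1, 0.3). Rejection resampling redraws the
full scalar vector, which provably leaves unconstrained marginals
untouched (KS-tested). These priors are deliberately broad; see
"Honest accounting" below for the consequence.

## The 130 summary statistics

For n populations the feature vector has 4n one-sample, 8·C(n,2)
two-sample and n·C(n−1,2)/1 three-sample entries — 130 for n = 5,
matching the standard DIYABC microsatellite battery. All statistics are
averaged over loci; loci with fewer than two gene copies of data are
skipped. Definitions: NAL (distinct alleles), HET (unbiased gene
diversity (n/(n−1))(1 − Σp²) with n gene copies), VAR (sample variance of
repeat counts), MGW (k/(range + 1)); pooled NAL2/HET2/VAR2; Weir–Cockerham
F_ST as the ratio of variance-component sums over loci and alleles; DAS
(1 − mean shared-allele proportion over inter-population individual
pairs, alleles shared 0/0.5/1); δµ² (squared difference of mean repeat
counts); LIK (directed mean multilocus genotype log-likelihood of one
population's individuals under the other's allele frequencies, unseen
alleles floored at 1/(2n + k)); AML (maximum-likelihood admixture
coefficient of a target between two parents, golden-section search on the
concave multinomial log-likelihood to 10⁻⁴, boundary candidates checked).
A comparison that is degenerate at every locus yields a 0.0 sentinel with
a warning. The feature order is fixed and documented in
`sumstats.feature_names`.

Note one analytic subtlety: the Weir–Cockerham point estimate on two
*identical* samples is not 0 but a small negative value (s² = 0 leaves
the −1/(n−1) correction term); tests assert this exact behaviour.

## ABC-RF engine

The reference table holds one row per simulated dataset (scenario label,
parameter draw, 130 statistics), balanced across scenarios and shuffled.
Scenario choice appends min(k − 1, rank) linear-discriminant axes (fitted
on the whole table, the convention of the standard ABC-RF workflow; constant columns are
dropped with a warning) and trains a classification forest on statistics
plus axes. Votes are per-tree predictions at the observed vector; ties
break to the lowest scenario id with a flag. The global prior error rate
is the out-of-bag (OOB) misclassification frequency; class errors are its
per-scenario decomposition; the posterior probability of the selected
scenario is 1 − E[error | observed], from a regression forest fit to the
OOB misclassification indicators (the regression-on-OOB-errors
construction), and the local error is its complement.

Parameter estimation restricts the table to the chosen scenario and
trains one regression forest per parameter on the statistics plus the
first five PLS components computed against that parameter (components are
per-parameter, not shared). Point estimates are the forest mean and the
weighted median of training responses under quantile-forest leaf weights
(in-bag multiplicity weighting); the 90 % interval uses the same weights
with midpoint-interpolated weighted quantiles. Global NMAE is
mean(|estimate − truth|/truth) over OOB evaluation rows (default 1 000);
the local NMAE reweights those rows by their similarity to the observed
vector; coverage is the fraction of evaluation rows whose own 90 %
interval (built from the trees in which the row was out of bag) contains
its true value.

Forest hyperparameters: mtry = ⌊√p⌋ and unlimited depth throughout. Two
defaults depart from full-bootstrap, single-observation-leaf forests, as
this package's own tractability choices: trees grow on a 25 % bootstrap
subsample for classification (50 % for regression) and leaves hold at
least five observations. At the study scale (40 000 rows, 2 000 trees)
these cut training from ~17 min and ~3 GB of trees to ~4 min and a few
hundred MB while moving OOB accuracy by about one percentage point; both
are exposed as parameters for users who want the textbook settings. The
posterior-probability regression forest defaults to 500 trees for the
same reason. "Replicate analysis" reruns the forest stages with fresh
seeds on a fixed table and reports means and SDs, mirroring the reference
analysis's replication protocol.

## Diversity and differentiation layer

Per population: A (mean distinct alleles per locus), Pa (alleles observed
in exactly one population, counted over loci), Ho (mean heterozygous
fraction), uHe (Nei's unbiased gene diversity), Fis = 1 − Ho/uHe from the
per-population means, and rarefied allelic richness Ar by hypergeometric
rarefaction at g gene copies (default: the smallest genotyped count over
populations × loci). Multi-locus F-statistics are Weir–Cockerham ratios
of variance components summed over loci and alleles; missing data are
deleted locus-wise within each estimator.

Null alleles: per population × locus, an EM under the null-allele model
with Hardy–Weinberg proportions (apparent homozygote aa: p_a² + 2p_a r;
blank: r²; blanks optionally treated as technical failures instead).
Because the EM map near the r = 0 boundary is r ← r(1 − r) —
sublinear — the iteration alone cannot reach machine-zero on null-free
data; after EM the likelihood at the boundary is compared and the global
maximum taken, restoring exact zeros. The ENA ("excluding null alleles")
F_ST treats the null as an extra allelic state: visible frequencies are
the EM estimates (summing to 1 − r, not renormalised), the null class is
excluded from the component sums, and apparent homozygotes hiding a null
are added back to the per-allele heterozygote counts (they are
heterozygous for their visible allele; the term vanishes at r = 0, so the
zero-null case reduces *exactly* to the uncorrected estimate). In the
generative check where the null is a segregating variant hidden from
observation — the actual biological mechanism — raw F_ST is inflated and
the ENA estimate removes roughly two thirds of the bias; on data with
modest nulls the corrected global value sits slightly below the raw one,
the pattern such surveys report. Bootstrap CIs resample loci (percentile
method, default 10⁴ replicates, 95 %).

Group contrasts permute whole populations between two groups; the
statistic is the difference of group means (He, Ar, Fis) or of
within-group multi-locus F_ST, with the two-sided p-value
(1 + #{|perm| ≥ |obs|})/(n_perm + 1); with 9 999 permutations the floor is
10⁻⁴. With few populations per group the discrete permutation
distribution bounds the attainable p — a 2 + 2 design cannot go below
~1/3.

## What the generator emulates, and what it does not

The synthetic data reproduce the study design exactly: sample sizes,
locus count, diploidy, missing-data injection, and the priors above.
They do not include genotyping artefacts beyond null alleles and uniform
missingness (no stutter, no large-allele dropout gradients), no departure
from panmixia within lineages, no migration after divergence, no
selection or linkage, and the eight topologies cover only
instantaneous-event histories with constant sizes. Passing tests
therefore demonstrate the estimators and the inference machinery, not
that real chestnut data were reproduced — the study's genotype matrix is
unpublished, and every accuracy claim here conditions on simulated truth.

## Honest accounting of study-scale behaviour

With the broad default priors, the eight scenarios overlap far more than
under the original analysis's supplementary priors, which were never
released:
at 5 000 simulations per scenario the OOB prior error rate measures
≈ 0.47–0.50, roughly double the 0.23942 the reference analysis reports, and scenario 4 joins
2, 6 and 7 among the frequently confused topologies. Diagnostics show the
machinery is sound — statistics respond to the generating parameters,
sister topologies produce mirrored F_ST asymmetries, the separable
two-scenario control reaches < 0.05 error, and the confusion matrix is
checked for diagonal dominance — so the gap is a property of the prior
breadth and of the reconstructed scenario 5–7 topologies, not of the
estimator. The priors are deliberately left as configured rather than
narrowed to chase the reported number.

## Problem sizes used by the shipped studies

The acceptance study uses 5 000 simulations per scenario (40 000 rows),
2 000 trees, 500 fresh test sets per scenario for the confusion matrix,
200 scenario-1 test sets for parameter recovery, 2 000 replicate loci per
θ for the mutation-model check, and 500 + 500 rows for the separable toy —
sizes chosen so the full recomputation completes in well under half an
hour on one CPU while keeping Monte-Carlo error comfortably inside the
stated tolerances.
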