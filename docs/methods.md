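# Methods

`metaevol` re-implements a comparative metabolomics workflow that asks how
fast the metabolome of each tissue has evolved on each branch of the
human–chimpanzee–macaque–mouse species tree, and whether the human lineage
shows an excess of change in particular tissues (prefrontal cortex and
skeletal muscle being the candidates of interest). This note documents the
models, the statistical procedures, the synthetic-data generator that stands
in for the original tissue samples, and the design choices made where the
procedure was genuinely open.

## Study design and data model

The design is four species (human, chimpanzee, rhesus macaque, mouse), five
tissues (prefrontal cortex PFC, primary visual cortex V1, cerebellar cortex
CBC, kidney cortex, thigh skeletal muscle), and ~14 individuals per species.
The measured object is a peak table: a peaks × samples matrix of mass-
spectrometry feature intensities in arbitrary units (AU), with per-peak
metadata (m/z or nominal mass, retention time, acquisition dataset ∈
{posLC, negLC, GC}) and per-sample metadata (species, tissue, individual,
sex, age, RNA integrity, condition, postmortem delay, pooled flag). Zero
intensity means "not detected" — a value censored at the instrument's
detection limit, not a measured zero.

Three special macaque groups support artifact control: two individuals
sampled with 4–6 h postmortem delay (to find decay-affected peaks), and two
six-animal groups kept for a month under altered environments (condition 1:
confinement; condition 2: confinement plus a cooked, high-sugar/fat diet) to
bound how much of the human-specific signal a lifestyle change could
produce. Pooled quality-control samples (per-tissue mixtures re-injected
periodically) accompany the LC datasets.

## Peak filtering and normalization

LC peaks pass four ordered criteria: retention time ≥ 0.6 min; ≥ 1,000 AU
in ≥ 80% of pooled samples; consistent level in the first two pooled
injections (operationalized as |log2 ratio| ≤ 1 — no numeric threshold is
standard, so it is configurable); and ≥ 10,000 AU in ≥ 50% of the samples
of at least one (species, tissue) group. GC peaks pass five: distinct from
background (an upstream peak-shape property, accepted as a metadata flag);
per-sample retention times within ±2 min of the peak median (accepted as
`rt_min`/`rt_max` metadata when available); retention time ≥ 0.75 min away
from every internal standard (≥ 1.5 min if the peak shares the standard's
mass); ≥ 3,000 AU in ≥ 50% of some group's samples; and removal of whole
groups of peaks sharing a mass with retention times ≤ 0.5 min apart
(minutes assumed — the unit is not standard anywhere). The filter report
attributes each removed peak to the first criterion it fails, so
per-criterion counts partition the removals.

Outlier samples are detected before the last filter criterion: PCA on the
log2 matrix, flagging samples more than k = 5 robust SDs (1.4826 × MAD)
from the median score on either of the first two components. k = 5 is
deliberately conservative; the choice of threshold is ours.

Intensities are then log2 transformed and quantile normalized within each
tissue's sample group. Zeros become missing values and are excluded from
the reference distribution; with unequal missingness the per-sample
empirical quantile functions are interpolated onto a common grid, which
reduces exactly to the classical sort/average/reorder algorithm for
complete data. A single-sample tissue group is only log transformed.

Postmortem-affected peaks are flagged per tissue from the macaque contrast
(delayed vs. standard): peaks whose mean difference falls in the top or
bottom 5% of the per-tissue difference distribution are excluded downstream
(~10% of peaks per tissue by construction). An alternative mode flags
peaks with Benjamini–Hochberg q < 0.01 in a per-tissue Welch test; the two
rules are not equivalent and both are provided.

Accurate-mass annotation matches LC peak m/z values against a metabolite
mass table at 5 ppm tolerance, allowing [M+H]+, [M+NH4]+ and [M+Na]+ in
positive mode and [M−H]− and [M+HCOO]− in negative mode. The adduct mass
offsets live in one constants table and are cross-checked in tests against
independently computed values.

## Permutation ANOVA and the significance rule

Each peak's variation is decomposed by a sequential (Type I) linear model
with factors tissue, species, species×tissue, sex, age and RIN, in two
modes: all four species, and primates only. The primate mode exists because
a peak shifted only on the mouse lineage should not qualify peaks for
primate-specific testing. Inference is by permutation: species labels are
permuted within tissue (tissue labels within species for the tissue term),
the conditional F is recomputed, and the per-peak permutation p is the
add-one estimator (1 + #{F_perm ≥ F_obs}) / (n_perm + 1). Censored zeros
are imputed with within-tissue means — imputing within the permutation
stratum keeps the label-permutation null valid, whereas cell-mean
imputation was measured to inflate the observed species F several-fold
relative to its permutation distribution.

The FDR at a nominal level c is estimated as (mean permuted discovery
count at c) / (observed discovery count at c), clipped to [0, 1]. The
significance rule "p below the nominal cutoff with FDR within the bound"
is applied adaptively: the largest level c ≤ 0.01 with estimated FDR ≤ 5%
is selected per test family, and peaks below it are significant. A fixed
all-or-nothing rule at c = 0.01 makes families with modest signal (e.g.
chimpanzee-specific changes, expected at only a few percent of peaks)
either fully accepted at ~20% realized FDR or fully rejected; scanning the
level is what makes the per-lineage proportions estimable at a controlled
error rate.

## Lineage classification

Within each of seven tissue categories — the five sampled tissues plus the
composites cortex (PFC∪V1) and brain (PFC∪V1∪CBC), which trade
independence for power and are never compared against the individual
tissues — ANOVA-significant peaks are assigned to lineages. Each primate
is compared against the other two primates, mouse against all primates,
with a two-sided Welch t-test (pooled-variance is available as an option);
direction is the sign of the focal-minus-comparison mean difference. The
acceptance rule is the same adaptive permutation-FDR rule, with species
labels permuted within the tissue category.

One condition is added to the pure one-vs-rest contrast: the comparison
species must agree with each other (no comparison pair significantly
different at the nominal cutoff). This is what "lineage-specific" means —
the change is placed on the branch where it occurred. It also matters
quantitatively: a strong human-lineage shift displaces the pooled
human+macaque comparison mean in the chimpanzee test by half the effect,
and without the homogeneity condition such leakage dominates the
chimpanzee call set whenever human divergence is large (planted 8:1
human:chimp ratios collapse to ~1.5:1). With the condition, a peak shifted
equally in human and chimpanzee is assigned to the macaque lineage (the
branch where the change actually happened), with macaque-relative
direction.

For analyses of changes unique to one tissue, calls repeated with the same
lineage and direction across tissues of a redundancy group — (i) PFC+V1,
(ii) cortex+CBC, (iii) brain+kidney+muscle — are excluded; composite-level
calls are never removed themselves but count as counterparts.

## Divergence versus phylogenetic distance

Per (tissue category, lineage), divergence is the proportion of tested
peaks called significant. The 3 nonhuman lineages × 7 categories = 21
points are regressed on branch length (ordinary least squares), with branch
lengths human = chimp = 6.5 million years (MY), macaque ancestor 23 MY
(29.5 MY split minus the shared 6.5), mouse ancestor 101 MY (130 MY total
minus 29.5) — the deeper two are documented defaults, configurable, not an
inference of anyone's exact values. Per tissue the summary reports the
human proportion, the regression prediction at 6.5 MY, their ratio, the
human:chimpanzee fold excess, and a one-sided p for the human point from
its studentized prediction residual (t with n−2 df). A zero chimpanzee
proportion yields an infinite fold excess with an explicit flag.

## Clustering, enrichment, expression agreement, functional units

Cross-tissue behavior is summarized per peak as the mean normalized value
in each (species, tissue) cell (≤ 20 values); peaks are clustered by
complete linkage on correlation distance (1 − Pearson r), the cluster count
k ∈ [2, 30] is chosen by maximal mean silhouette (smallest k on ties),
clusters are dropped smallest-first while the cumulative dropped mass stays
below 10% of all peaks, and each cluster is labeled by the tissue in which
its mean profile deviates most from the cross-tissue mean.

Pathway enrichment of a metabolite set uses the dual rule: upper-tail
hypergeometric p and a permutation p from size-matched random metabolite
draws, both thresholded (0.05 for species-specific groups). Peaks are
collapsed to metabolites first (a metabolite is in the test set if any of
its peaks is). Two backgrounds are used: all measured metabolites for the
species-specific groups, and, for tissue-cluster enrichment, the
metabolites of clusters specific to other tissues. No multiplicity
adjustment is applied across pathways — both raw p values are thresholded,
as is conventional for this dual rule.

Environment-affected peaks are found per tissue by comparing condition
macaques (n = 6) with all standard-condition macaques, requiring t-test
p < 0.01, permutation p < 0.01, and the same direction of change in humans
versus control macaques. The overlap of human-specific changes with the
environment-enriched pathways is tested by drawing equally many random
pathways and recounting.

Enzyme expression is quantified as reads per 100 bp of exon,
N·100/(L−99) — the denominator is the number of valid start positions for
100-bp reads on exons of total length L, hence the requirement L ≥ 100. A
global floor (5% quantile of all nonzero values; a gene passes if some
(species, tissue) mean exceeds it) precedes classification. Genes are
tissue-specific (species-specific within a tissue) when their mean
difference versus all other tissues (species) falls in the same 10% (5%)
tail of the corresponding pairwise difference distribution; distributions
are per comparison pair, pooled across genes. Throughout, the thresholds
are read as tail quantiles. Agreement between species-specific metabolites
and their enzymes is tested two ways: per enriched pathway, the count of
pathway enzymes with a matching specificity label against size-matched
random enzyme draws from the measured-gene universe; and per metabolite
group, the proportion of matching enzymes among all directly linked
enzymes against size-matched random metabolite sets drawn from metabolites
with at least one measured linked enzyme.

Metabolites in ≥ 2 overrepresented pathways are merged into functional
units while some pair shares "more than two-thirds" of its pathways —
operationalized as Jaccard similarity > 2/3 by default (a min-fraction
variant is provided; the original criterion is ambiguous between the two
and neither is claimed to be authoritative). Merging is deterministic:
highest similarity first, lexicographic tie-break, union pathway sets.

## The synthetic-data generator

`synthio` emulates the study: per peak a log2 baseline ~ N(15, 2²) AU with
per-tissue offsets ~ N(0, 1); per (lineage, tissue) an independent
fraction min(1, rate · branch-length · acceleration) of peaks receives a
±δ log2 shift in all samples of the corresponding species (δ = 1,
rate = 0.002/MY by default, acceleration a per-tissue multiplier on the
human lineage); i.i.d. N(0, 0.5²) log2 noise; detection-limit censoring to
zero (default limit 1,000 AU, ~1% zeros); pooled per-tissue mean samples
with 0.1 log2-unit noise for LC peaks; postmortem shifts (5% of peaks,
±1 log2) in delayed samples; and condition shifts (0.5%/1% of peaks for
conditions 1/2) of which half are concordantly applied to human samples,
emulating lifestyle-overlapping changes — these concordant shifts are
recorded in the truth ledger as genuine human-specific effects. Matched
expression tables plant concordant enzyme shifts with a configurable
probability (one draw per enzyme target) plus an independent background.

What the generator does not emulate: within-species effect heterogeneity
(shifts are species-wide), retention-time drift and isotope structure,
peak–peak intensity correlation beyond what quantile normalization
induces, heavy-tailed measurement noise, and missingness mechanisms other
than left-censoring. Passing calibration on this generator therefore shows
the procedures are correct under the design's idealized statistical
structure, not that real-data artifact rates are as low.

## Numerical and scale choices

Permutation counts default to 200 in the standard experiments (the add-one
estimator resolves p < 0.01 at n_perm = 200; estimates are coarser than at
1,000 but unbiased), and the calibration/recovery experiments use 2,000 or
5,000 peaks — sizes chosen so the binomial error of the measured rates is
well below the tolerances being checked. The calibration experiments
measured here: null ANOVA rejection ~1% at the 1% cutoff; classification
false-discovery proportion ~4% at the 5% target with 10% planted effects;
enrichment pass rate ~2% under random test sets at the dual 5% thresholds;
planted 8:1 (muscle) and 4:1 (PFC) human:chimp accelerations recovered
within ~16% relative error. Known residual biases: multi-lineage peaks are
excluded by the homogeneity condition (slightly deflating all lineage
counts), and the composite tissue categories reuse samples, so their
proportions are not independent of the constituent tissues'.
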