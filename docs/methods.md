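# Methods

`clonotrack` implements the computational chain linking checkpoint-blockade–
induced B-cell-receptor (BCR) clonotype diversification to T-cell activation
and survival, together with a synthetic cohort generator that plants every
effect the chain is supposed to detect. This note describes the models, the
defaults and why they were chosen, what the generator does and does not
emulate, and the numerical conventions.

## Repertoire diversity

A clonotype is keyed by `(locus, V gene, CDR3 nucleotide junction)` at the
cell level. V+CDR3nt is the conventional single-chain clonotype definition
and is robust to missing J calls. Before counting, a **dominant-chain
filter** keeps one chain per `(sample, cell, locus)` — the highest UMI
(`duplicate_count`), ties broken by lexicographic junction — so doublets and
ambient chains cannot inflate cell-level diversity. "Clonal diversity" is
the number of distinct clonotype keys in a sample; BCR counts pool
IGH/IGK/IGL keys (each key carries its locus), while spatial BCR tracking
uses IGH only (see below).

**Induced diversity** is a strictly greater unique clonotype count in the
post-treatment sample than in the pre-treatment sample of the same patient;
ties are not an increase. The **static** alternative labels a sample
high-diversity iff its count strictly exceeds the cohort median.

**V-gene usage** is the cell-level frequency vector over a fixed V-gene
universe (one vote per cell after the dominant-chain filter); out-of-universe
calls are bucketed as `other` and excluded from correlation support. Usage
vectors from two modalities are compared by Spearman correlation over the
union support (≥ 3 genes required) — Spearman because probe counts and
transcript counts live on different compositional scales. Only the IG heavy
chain carries a reliable matched signal across modalities, so IGH is the
default for BCR tracking.

## Survival

Kaplan–Meier estimation and the two-group log-rank test (hypergeometric
variance, chi-square with 1 df) are delegated to lifelines. The two-group
Cox model is a one-dimensional Breslow partial likelihood maximized by
bounded scalar optimization (`|log HR| ≤ 15`, tolerance 1e-10), with a Wald
95% CI from the observed information `Σ_events p(1-p)` where `p` is the
group-1 hazard share of the risk set. Breslow tie handling is adequate
because ties are rare at cohort scale; a 1e-4 grid search over log-HR serves
as the independent oracle in tests. A group with no events gives a monotone
likelihood; the fit is flagged `diverged` with a one-sided bound rather than
a spurious estimate.

## Cluster-blinded correlation attribution

Per-sample **pseudobulk** profiles are the mean over cells of
library-size-normalized (fixed target 10,000 counts/cell), log1p-transformed
expression — the dominant convention for 5′ scRNA-seq. Each gene's
pseudobulk values are Pearson-correlated with the per-sample unique-BCR
count across ≥ 4 samples; Benjamini–Hochberg q-values are computed across
tested genes and zero-variance genes are flagged and excluded.

Attribution blinds one cluster at a time and recomputes the correlation:

    delta(gene, cluster) = |R_full| − |R_blinded(cluster)|

Positive delta means the cluster carries the correlation. A gene whose
blinded profile has zero variance lost all of its expression with the
blinded cluster; its remaining correlation strength is taken as 0 (flagged).
Clusters whose blinding empties more than half the samples are skipped with
a warning; a declared-but-empty cluster is a no-op with delta 0.

**Statistical power note.** A correlation of ~0.4 measured across ~30
specimens has a two-sided p ≈ 0.03; under BH across a 480-gene panel such a
gene cannot reach q < 0.05 (that would need per-gene p ≲ 3e-4, i.e. R ≳
0.6). The blinding delta, not the FDR call, is the informative readout at
this cohort size, which is why the acceptance checks emphasize delta
localization. The q-values are still reported.

## Spatial pseudoclones

A **pseudoclone** groups spatial cells by their maximal-count V-gene probe
(lexicographic tie-break; all-zero cells unassigned; cells of the wrong type
for the locus class are skipped and counted) — a measurable proxy for a
clonotype where CDR3-level mapping is unavailable. Proximity uses an
inclusive 20 µm Euclidean radius on continuous micron coordinates (no
binning); the KD-tree graph is tested against an all-pairs scan.

**Neighborhood enrichment** compares the observed count of proximal
type-a/type-b cell pairs with a null from seeded shuffles of the type labels
over fixed positions (default 1,000 permutations), reported as a z-score.
**Pseudoclone-pair colocalization** applies the same logic to (T, B) V-gene
pair member links, permuting pseudoclone labels within each type class; a
pair is called colocalized at z ≥ 2 (a conventional, configurable cutoff).
**Compartment sharing** takes the lymph-node clone pairs and reports the
fraction also detected in the paired tumor (both member pseudoclones with
≥ 1 cell), separately for colocalized and noncolocalized pairs, plus their
ratio. The shared-vs-exclusive expression comparison uses log1p probe
counts and a Wilcoxon rank-sum test per compartment.

## Triad Occurrence

For types A, B, C and radius r: enumerate unordered proximal A–B pairs; the
occurrence probability is the fraction of pairs with at least one C cell
(distinct from both members) within r of **either** member. This
operationalization is a reconstruction — the defining supplementary formula
was not available — so a strict **both**-members mode is also exposed and
every result records the mode used. Enrichment uses the label-permutation
null with add-one-smoothed upper-tail empirical p. The statistic is
invariant to rigid motions, symmetric in A/B, monotone in radius, and tested
exactly against an O(n³) enumeration.

## Trajectory predictor

Differential expression between pretreatment samples of
eventually-increasing vs non-increasing patients uses a Wilcoxon rank-sum
test per gene with BH correction; selection at q < 0.05 and |log2 fold
change of group means| ≥ 1 (both configurable). The classifier is a single
hidden layer of width 32 (ReLU, logistic output) on gene-wise standardized
inputs, trained with a seeded stratified 20% withheld split and early
stopping on a validation slice — the smallest architecture adequate for a
~100-gene signature. Models serialize to a versioned JSON weight manifest
and reload bit-stably; prediction is a pure numpy forward pass.

Cross-cohort harmonization standardizes external cohorts gene-wise within
their own cohort before prediction. Model genes missing externally are
imputed at the training mean (standardized zero) up to 20% of the
signature; beyond that, prediction is refused. Evaluation joins predictions
with survival and runs the log-rank test and two-group Cox per treatment
arm; the non-PD-1 control arm is the specificity check — a signature
specific to checkpoint blockade must not stratify patients who never
received it.

## The synthetic cohort generator

The generator emulates every input the pipeline consumes, with planted
ground truth stored alongside:

* **Repertoires.** Unique clonotype counts are Poisson: pre-treatment mean
  40, post-treatment mean 80 for "increased" patients and 40 for "flat"
  ones (tens of unique intratumoral BCR clonotypes per biopsy is the
  observed scale). Because the induced-diversity label is *defined* by the
  observed phenotype (post > pre), each patient's (pre, post) pair is
  rejection-sampled until it is consistent with the planted arm — truth
  labels therefore coincide with what the classifier must recover. Clone
  sizes follow a discrete power law with exponent 2.5 truncated at 1,000
  (heavy tails are the standard repertoire assumption). V-gene usage per
  patient-timepoint is symmetric-Dirichlet (concentration 1 for IG loci;
  8× flatter for TR loci, whose usage is less clonally skewed on this
  panel), shared between the single-cell and spatial modality of the same
  patient-timepoint and independent otherwise — exactly the structure the
  matched/mismatched validation exploits.
* **Expression.** 480 genes (the panel scale), 400 cells/sample, negative
  binomial (mean 1, dispersion 2) with 8 clusters and 5 marker genes per
  cluster (4× up-shift). The planted correlation module is 12 activation
  genes headed by CD69/IFNG/TNF, expressed exclusively in the planted
  cluster ("confined to one cluster" read strictly). The per-sample latent
  shift is the sum of a monotone component in the sample's BCR count and a
  latent component orthogonalized against it in-sample, mixed so the latent
  correlation equals the planted strength exactly (a purely monotone shift
  would realize R ≈ 1, not 0.4); the realized pseudobulk correlation is
  recomputed post hoc and stored in the truth record.
* **Spatial maps.** 1,000 µm square fields with 800 background cells placed
  by complete spatial randomness (8 cell types at fixed frequencies). In
  treated maps, each B cell of a paired pseudoclone seeds a partner
  activated-CD8 T cell within the 20 µm radius with probability 0.8; in
  treated lymph-node maps, each B cell anchors a planted B/Tfh/activated-CD8
  triad with probability 0.5. Untreated maps carry no planted structure
  regardless of the rates. Dominant-gene probe counts are 1+Poisson(3) with
  a 10% single-count off-target noise rate. Lymph-node/tumor pairs plant
  clone-pair sharing at 0.5 (colocalized) vs 0.1 (noncolocalized) — the 5×
  regime inside the reported 2–10× range — and give shared T clones a
  two-fold marker elevation. The paper-scale effect sizes for these spatial
  structures are not published; these are the package's calibration
  choices, fixed once.
* **Survival.** Exponential times with hazard 0.002/day ×
  0.46^(increased), right-censored at 1,825 days (five-year follow-up
  horizon); noninformative censoring stands in for clinical follow-up.
* **Predictor arm.** Bulk-style log-normal pretreatment matrices (600
  genes, sample noise sd 0.3 log-units) with 117 genes shifted 2.5-fold in
  "increase" patients; a 60-sample training cohort and 120-sample external
  PD-1 and control arms (noise sd 0.4), the external scale of the published
  validation cohorts. Survival benefit (HR 0.46) is planted only in the
  PD-1 arm.

Randomness is a hierarchical seed tree (cohort → domain → patient →
sample) over `numpy.random.SeedSequence`: identical configurations are
byte-identical and subsetting patients never changes other patients'
draws.

**What the generator does not emulate** — and hence what green tests do not
show about real data: raw reads, UMI collapsing, or receptor assembly
(generation starts at clonotype calls); somatic hypermutation and isotypes;
segmentation errors and cell-boundary ambiguity in spatial data; batch
effects between cohorts beyond gene-wise scale; informative censoring and
clinical covariates; spatial tissue architecture beyond planted proximity
(no tertiary lymphoid structures, vessels, or tumor-island geometry).

## Numerical conventions and problem sizes

Permutation statistics default to 1,000 permutations and are fully seeded;
tests and the acceptance script use 150–300 permutations on 350–800-cell
maps, 100–200 replicate cohorts for hazard recovery, 50–100 seeded cohorts
for the frequency-based checks, and a 15-patient (30-sample) cohort for
attribution — sizes at which every planted effect is comfortably detectable
while the whole suite stays desk-scale. Proximity boundaries are inclusive;
ties break lexicographically everywhere a winner must be named (V genes,
junctions, display genes); degenerate inputs (empty groups, zero variance,
absent types, zero proximal pairs) return flagged results rather than
raising, except where the contract demands an error (wrong grouping, too
few samples, unknown labels).

## Known limitations

* The Cox model is unadjusted two-group; no multivariable adjustment for
  cancer type, no time-varying covariates, no competing risks.
* Pseudoclones collapse clonal identity to a dominant V gene; distinct
  clones sharing a V gene are merged, so spatial clone statistics are
  conservative proxies.
* The Triad Occurrence definition is a reconstruction (see above); both
  proximity modes are reported for transparency.
* The attribution q-values are under-powered at 30-sample scale by
  construction (see the power note); conclusions should rest on the
  blinding deltas at that scale.
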