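# clonotrack

Analysis pipeline linking checkpoint-blockade–induced B-cell-receptor (BCR)
clonotype diversification to T-cell activation and patient survival — for
computational immunologists working with paired pre/post-treatment
single-cell repertoires, targeted spatial transcriptomics of tumors and
draining lymph nodes, and survival follow-up. Because the interesting
effects are subtle and the real cohorts are small, the package ships a
synthetic cohort generator that plants every effect with known ground
truth, so the whole chain is testable end to end.

## What it computes

* **Repertoire diversity** — unique clonotype counts per sample (clonotype
  key: locus + V gene + CDR3nt, cell-level after a dominant-chain filter),
  the induced-diversity trajectory Δ = N_post − N_pre with
  `increased ⇔ Δ > 0`, above-median static splits, and V-gene usage
  fingerprints with matched/mismatched cross-modality validation
  (Spearman ρ over the union support; IGH only for BCR tracking).
* **Survival** — Kaplan–Meier curves, the two-group log-rank test, and a
  two-group Cox model: h(t | x) = h₀(t)·e^{βx} maximized by Breslow
  partial likelihood, HR = e^β with Wald 95% CI.
* **Cluster-blinded attribution** — per-sample pseudobulk expression
  correlated with unique-BCR counts (Pearson R, BH q-values), then
  Δ(gene, cluster) = |R_full| − |R_blinded(cluster)| to locate which cell
  cluster carries each correlation.
* **Spatial pseudoclones** — dominant-V-gene pseudoclone assignment,
  inclusive 20 µm proximity graphs, permutation-null neighborhood
  enrichment (z-scores over seeded label shuffles at fixed positions),
  T/B pseudoclone-pair colocalization, clone-size coupling by treatment
  and colocalization stratum, and tumor/lymph-node clone-pair sharing.
* **Triad Occurrence** — the fraction of proximal A–B cell pairs with a
  third cell type within the radius of a pair member, with a permutation
  null.
* **Trajectory predictor** — Wilcoxon/BH differential expression between
  induced-diversity groups in pretreatment samples, a one-hidden-layer
  network (width 32) on the selected signature, and survival
  stratification of external cohorts with a non-PD-1 control arm as the
  specificity check.

See `docs/methods.md` for the models, defaults, and design decisions.

## Worked example

```python
import clonotrack as ct

cfg = ct.CohortConfig(n_patients=40, seed=7)
cohort = ct.generate_cohort(cfg, include=("repertoire", "survival"))

pre = ct.build_repertoire(cohort.clonotypes, "pt000_pre")
post = ct.build_repertoire(cohort.clonotypes, "pt000_post")
traj = ct.classify_trajectory(pre, post, "BCR")
print(f"pt000: pre={traj.pre_count} post={traj.post_count} "
      f"delta={traj.delta:+d} increased={traj.increased}")

lr = ct.logrank_test(cohort.survival)
cox = ct.cox_two_group(cohort.survival)
print(f"log-rank chi2={lr.chi_square:.2f} p={lr.p_value:.4f}")
print(f"Cox HR={cox.hazard_ratio:.2f} "
      f"(95% CI {cox.ci_low:.2f}-{cox.ci_high:.2f})")
```

prints

```
pt000: pre=40 post=33 delta=-7 increased=False
log-rank chi2=8.17 p=0.0043
Cox HR=0.38 (95% CI 0.19-0.75)
```

Patient `pt000`'s post-treatment tumor carried fewer unique BCR clonotypes
than its pre-treatment tumor, so it is not an induced-diversity patient.
Across the 40-patient cohort, patients whose diversity did increase have
less than half the death hazard of the rest (HR 0.38), a planted effect
the generator seeded at HR 0.46 — the estimate and its CI are what the
pipeline recovers from the realized event times.

A command-line interface mirrors the library
(`clonotrack simulate | diversity | trajectory | survive | attribute |
spatial | triad | predict-train | predict-apply | predict-eval`); run any
subcommand with `--help`.

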