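# Methods

## The analysis model

For each taxon *t* with counts *y_tj* in sample *j*, the package fits
count GLMs with a log link and a per-sample offset log *s_j*, where the
*s_j* are DESeq2-style size factors:

    E[y_tj] = s_j · exp(β0 + Σ_k β_k x_jk)

Two designs are compared. The **adjusted** model ("IBDCC") regresses on
the group label plus all identified covariates and confounders; its
reduced counterpart drops only the group term. The **unadjusted** model
("IBD") regresses on the group label alone; its reduced counterpart is
intercept-only. In both cases the group effect is tested by a
likelihood-ratio test (statistic clipped at 0, χ² reference with df =
the number of extra parameters), and p-values are Benjamini–Hochberg
adjusted across taxa within each model run, separately per run.

Four distribution families compete per taxon:

* **Poisson** — no overdispersion; 1 + p parameters.
* **Negative binomial (NB2)** — quadratic mean–variance
  Var = μ + αμ²; the dispersion α is estimated by ML and counted as a
  parameter.
* **Zero-inflated NB** — a logit-intercept structural-zero mass mixed
  with NB2. The inflation component is intercept-only: the zero-mass
  probability is a free parameter but does not depend on covariates.
  This keeps small-cohort fits estimable; a covariate-dependent
  inflation would double the design dimension for 150-sample cohorts.
* **Hurdle** — a binomial GLM on the zero/nonzero indicator plus a
  zero-truncated NB on the positive counts, both parts using the same
  design. The parts are orthogonal in parameters, so the
  log-likelihoods (and parameter counts) add. Quasi-separated zero
  parts (|coef| > 15) are flagged non-converged rather than reported.

Family selection minimises BIC = −2·loglik + (#params)·log(n) of the
**full** fit; the winning family is reused for the reduced fit so the
LRT compares nested models within one family. Ties within 10⁻⁹ go to
the simplest family (Poisson < NB < ZINB < hurdle). If the selected
family fails on the reduced design, the next-best converged family is
used for both fits and the event logged. Selecting on the full model and
conditioning the test on that choice mildly inflates the finite-sample
type-I error (measured ≈ 0.06 at a nominal 0.05 on 60-sample null
cohorts, see the calibration test) — a property of the select-then-test
procedure itself, since each family's LRT is well calibrated when fit
unconditionally.

Counts enter the GLMs raw, with the normalization carried by the
log-size-factor offset, because the count likelihoods are defined on
integers; dividing counts by size factors and rounding would discard
the mean–variance information the families differ on.

## Screening and covariate selection

**Confounder screen.** A variable is a potential confounder when its
distribution differs across the target groups: Kruskal–Wallis for
numeric variables, Fisher's exact test for categorical ones, flagging
p < 0.05. For 2 × k tables the Fisher p-value is computed by exact
enumeration of all tables with the observed margins (two-sided: total
probability of tables no more probable than observed); tables with more
than 2 × 10⁶ enumerable states fall back to a seeded margin-conditional
Monte-Carlo estimate and are labelled as such. The exact enumeration is
used rather than scipy's r × c implementation because the latter is
Monte-Carlo (and nondeterministic) for anything beyond 2 × 2.

**Covariate selection.** Each candidate's marginal effect on a
β-diversity matrix is tested by PERMANOVA: with G the Gower-centered
−½D² and H_X the hat matrix of a design X, SS(model) = tr(H_X G),
SS_t = SS(full) − SS(full − t), pseudo-F_t = (SS_t/df_t)/(SS_res/df_res).
Significance comes from whole-row/column permutations of D with the
add-one estimator (1 + #{F* ≥ F})/(1 + n_perm), so p is never exactly
zero and its resolution is 1/(n_perm + 1). Permuted statistics within
10⁻⁸ (relative) of the observed one count as exceedances so that
relabellings equivalent to the observed one are not lost to summation
rounding. Backward elimination runs per metric: the non-target term
with the largest marginal p is dropped (ties drop the term later in
candidate order) until every survivor has p < α; the target is never
dropped. The covariate set is the union of survivors across metrics.
Elimination is per metric, not joint, because a variable shaping even a
single aspect of community structure is worth adjusting for; the union
rule implements exactly that.

**Attribution of discrepant taxa.** Taxa significant under exactly one
of the two models are probed in both directions: approach 1 tests the
group term in `group + v` vs `v` for each single variable *v*; approach
2 tests it in `group + (all − v)` vs `(all − v)`. A variable is
*attributed* only when both directions agree — adding it alone destroys
the group signal (p ≥ α) **and** excluding it alone restores the signal
(p < α). Single-direction hits are reported but not flagged.

## Diversity estimators

Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) and is
computed on **raw** counts: singleton/doubleton frequencies are
meaningless after fractional normalization. Shannon (natural log) and
Gini–Simpson are computed on proportions and are scale-invariant, so the
raw/normalized distinction does not affect them. Groups are compared by
tie-corrected Kruskal–Wallis; an all-tied input returns (H = 0, p = 1)
rather than an error.

Bray–Curtis is Σ|x−y| / Σ(x+y). Canberra is normalized by the number of
taxon pairs with x+y > 0, keeping it in [0, 1]. The UniFrac family is
computed from the branch × taxon incidence of the tree sheared to the
table's taxa: unweighted UniFrac is unique/total branch length over
branches with descendants in either sample; weighted UniFrac is the
normalized form Σ l|a−b| / Σ l(a+b) with a, b the branch-wise
descendant proportions; generalized UniFrac weights branches by
(a+b)^α, recovering the weighted-normalized form at α = 1. The default
α = 0.5 is the customary compromise between sensitivity to rare and
abundant lineages. Both Canberra and generalized UniFrac are available
because practice varies on the fourth metric; the pipeline default uses
Bray–Curtis, Canberra and the two classical UniFracs. Unrooted input
trees are midpoint-rooted (UniFrac needs a root); extra tips are pruned
lazily per call.

## The synthetic cohort generator

The generator emulates a three-group faecal 16S study at the taxonomic
rank of analysis: 42 controls and 52 + 58 patients by default, with
Montreal-style subgroup labels (B1/B2/B3, E1/E2/E3; labels that do not
cover a group are filled with "unclassified"), age truncated to [19, 72],
gender, and 16 binary diet/lifestyle variables with per-group "yes"
probabilities — four of them (dairy, fruit/vegetables, cereals, legumes)
imbalanced between controls and cases. Counts are ZINB: library sizes
are log-normal (median ≈ 2 × 10⁴ reads, σ_log = 0.35) entering as
multiplicative offsets; per-taxon baselines are drawn N(−6.5, 1.5) on
the log relative-abundance scale (mean counts ~1–10³); NB size is drawn
U[0.3, 2]; the structural-zero probability defaults to 0.15. A config
switch replaces the mixture zero with a hurdle zero mass and
zero-truncated NB positives, so the BIC stage can be exercised against
all four families it fits.

Confounding is planted by giving a variable group-dependent prevalence
**and** a taxon effect while the taxon has no direct group effect. In
the dedicated recovery scenario the confounder is deliberately strong —
cereals prevalence 0.80 in controls vs 0.15 in cases, taxon effect 2.5
log units — so the induced marginal group effect (≈ 1.6 log units)
matches or exceeds the planted direct effects (±1.2): the confounded
taxon is unambiguously "disease-associated" until the model adjusts for
diet, which is precisely the behaviour the two-model comparison must
detect. A weak confounder whose induced effect no test could see would
leave the property untestable.

What the generator does **not** emulate: taxon–taxon correlations
(counts are conditionally independent given the design), compositional
closure, phylogenetic signal in abundances (the tree is random Yule,
independent of the count model), read-level noise, and longitudinal
structure. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated count model, not robustness to
every property of real sequencing data.

## Numerical choices and problem sizes

* Permutations: 9999 by default in the pipeline; the bundled
  acceptance script uses 999 for the study-scale run and the test suite
  uses 199–9999 depending on the resolution a check needs.
* Null calibration is measured over 100 effect-free cohorts of 60
  samples × 40 taxa (4000 taxon-level LRTs); screen uniformity over 25
  such cohorts (400 Fisher p-values) and PERMANOVA uniformity over 100
  cohorts × 3 balanced variables. The Fisher uniformity check is
  one-sided (no anti-conservatism): exact-test p-values are discrete and
  therefore stochastically conservative under the null.
* Confounded-taxon recovery is scored over 100 replicate cohorts of
  50 samples/group × 12 taxa.
* Random seeds fan out from a single global seed through
  `numpy.random.SeedSequence`, so every stage is individually
  reproducible and reruns are byte-identical.
* Degenerate inputs: all-zero taxa are skipped with a logged reason;
  all-tied Kruskal–Wallis returns p = 1; rank-deficient GLM designs are
  flagged non-converged; aliased PERMANOVA terms raise an error naming
  the pair; an empty prevalence-filter result raises rather than
  returning an empty table.

## Known limitations

* The intercept-only ZINB inflation cannot capture group-dependent
  structural zeros; such taxa tend to select the hurdle family instead.
* Post-selection LRT inflation (≈ 0.01 above nominal at n = 60) is
  inherent to BIC-select-then-test; users needing exact error control
  should fix the family a priori.
* Backward elimination inherits the usual instabilities of stepwise
  procedures under collinear candidates; the elimination trace is
  retained so a human can audit every drop.
* Fisher's exact test is implemented for 2 × k contingency tables
  (binary questionnaire variables); categorical variables with three or
  more levels would need the Monte-Carlo path.
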