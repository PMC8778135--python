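# microconfound

Confounder- and covariate-aware differential abundance analysis for
microbiome count tables.

Case–control microbiome studies routinely report taxa whose abundance
differs between patients and healthy controls. Lifestyle and dietary
habits, however, shape the gut microbiota too — and when a habit (say,
eating cereals several days per week) is unevenly distributed between the
study groups, a taxon that responds only to that habit will masquerade as
disease-associated. `microconfound` implements the full workflow for
separating these cases in a three-group design (healthy controls plus two
patient groups, e.g. Crohn's disease and ulcerative colitis):

1. **Preprocessing** — taxonomic agglomeration, prevalence filtering
   (taxa present in ≥ 10 % of samples), and DESeq2-style median-of-ratios
   size factors (sparse-table `poscounts` variant by default).
2. **Diversity** — Chao1, Shannon and Gini–Simpson α-diversity with a
   Kruskal–Wallis group test; Bray–Curtis, normalized Canberra and
   unweighted / weighted / generalized UniFrac β-diversity.
3. **Variable screening** — potential *confounders* are variables
   unbalanced across groups (Kruskal–Wallis for numeric, Fisher's exact
   test for categorical variables, p < 0.05); *covariates* are variables
   explaining β-diversity variance, selected per metric by
   marginal-effects PERMANOVA with backward elimination and pooled by the
   union rule (significant for at least one metric).
4. **Differential abundance** — per taxon, count GLMs with a log
   size-factor offset under two designs:

       Taxon ~ group + covariates + confounders    (adjusted, "IBDCC")
       Taxon ~ group                               (unadjusted, "IBD")

   Four families compete — Poisson, negative binomial, zero-inflated NB
   and a hurdle model — and the lowest-BIC family of the full fit is kept
   for a full-vs-reduced likelihood-ratio test of the group term, with
   Benjamini–Hochberg correction across taxa.
5. **Attribution** — taxa significant under exactly one model
   ("non-overlapping" taxa) are probed variable by variable: adding a
   single variable to the unadjusted model and removing it from the
   adjusted model identifies the habit responsible for the discrepancy.

Because real cohorts of this design are rarely public, the package ships
a first-class synthetic cohort generator (`microconfound.synthetic_data`)
that plants group effects, diet effects and group-imbalanced diet
variables into overdispersed zero-inflated counts, together with a
ground-truth ledger for scoring recovery.

## Worked example

```python
from microconfound import (
    SyntheticConfig, generate_cohort, prevalence_filter, size_factors,
    run_model_suite, identify_nofs, attribute_nof, unbalance_screen,
)

# a cohort where taxon fam003 responds ONLY to the "cereals" habit,
# which is far more common in controls than in cases
cfg = SyntheticConfig.confounded(seed=2)
table, meta, taxonomy, tree, truth = generate_cohort(cfg)
table, removed = prevalence_filter(table)
s = size_factors(table)

screen = unbalance_screen(meta, seed=0)
print(screen.confounders)
# ['gender', 'dairy', 'cereals', 'legumes', 'alcohol']

ibd = run_model_suite(table, meta, s=s, mode="IBD")
ibdcc = run_model_suite(table, meta, covariates=screen.confounders,
                        confounders=[], s=s, mode="IBDCC")
nofs = identify_nofs(ibd, ibdcc)
print(nofs.ibd_only)   # ['fam003']  — flagged only without adjustment
print(nofs.both)       # ['fam001', 'fam002']  — truly group-driven

att = attribute_nof("fam003", table, meta,
                    variables=screen.confounders, s=s)
print(att.round(4))
#            approach1_p  approach2_p  attributed
# variable
# gender          0.0000       0.1412       False
# dairy           0.0000       0.1079       False
# cereals         0.1683       0.0000        True
# legumes         0.0000       0.1022       False
# alcohol         0.0000       0.1255       False
```

Reading the attribution table: adding `cereals` to the unadjusted model
destroys the group signal (approach-1 p = 0.17 ≥ 0.05) and removing it
from the adjusted model restores the signal (approach-2 p < 0.05) — both
directions point at `cereals`, so the taxon's apparent disease
association is explained by that single habit. The genuinely
group-driven taxa `fam001`/`fam002` stay significant under both models.

A command-line interface mirrors the library
(`microconfound simulate | preprocess | diversity | screen | da | run`);
`microconfound run --out results/ --seed 42` executes the whole pipeline
on a simulated cohort and persists every stage artifact as TSV/JSON.

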