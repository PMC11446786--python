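# irpipe

Intron retention (IR) — an intron surviving splicing into the mature
transcript — behaves as a sensitive, qualitative stress readout in blood
transcriptomes, and differential IR has been proposed as a biomarker layer
for depression that complements ordinary differential expression. `irpipe`
is a reusable implementation of that analysis for anyone working from
junction-level counts: it quantifies intron ratios, calls differential IR
and differentially expressed genes (DEGs) under dual p/FDR significance
rules, classifies drug-induced IR recovery across a control/pre-/post-
treatment design, tests whether a gene set is preferentially wired to a
functional module in a protein–protein interaction (PPI) network, and
scores cross-study gene-set overlap — together with a seeded synthetic-data
generator that reproduces the statistical structure each stage assumes, so
every stage is testable end to end without access to raw sequencing data.

## The statistics at the core

**Intron ratio.** For an intron event with `I` inclusion-supporting and `S`
skipping-junction reads and effective form lengths `LI`, `LS`:

    psi = (I/LI) / (I/LI + S/LS)

A cell contributes only when its junction coverage `I + S` is strictly
above `coverage_min` (default 10 reads).

**Differential IR.** Inclusion counts per sample are modeled as
beta-binomial with intra-class correlation `rho` (alpha = psi(1−rho)/rho,
beta = (1−psi)(1−rho)/rho). A likelihood-ratio test compares a common-psi
null against group-specific psi (shared `rho`, profiled by maximum
likelihood), with 2(l1 − l0) referred to chi-square with 1 df. An event is
IncIR/DecIR when
(p < 0.05 or BH-FDR < 0.1) and |Δpsi| > 0.05; a gene with both IncIR and
DecIR events is "Mixed".

**Differential expression.** Trimmed mean of M-values (TMM, 30%/5% double
trim) gives per-sample scaling factors; a per-gene negative-binomial LRT
with common dispersion (Cox–Reid adjusted profile likelihood on a grid) and
effective-library-size offsets tests equal means. A DEG requires fold
change > 1.2 (|log2FC| > 0.263) and (p < 0.05 or FDR < 0.1).

**Recovery.** Across (control, pre-treatment, post-treatment), a locus that
is IncIR in leg 1 and DecIR in leg 2 shows reverse-V recovery; the converse
is V recovery. Trajectories can additionally be tested by one-way ANOVA
with Tukey HSD.

**Network enrichment.** In a score-filtered interactome (score ≥ 0.7,
STRING 0–1000 scores auto-scaled), the observed statistic is the total
number of distinct query→target links; the null is K equal-size random
gene sets, p = (#{null ≥ obs} + 1)/(K + 1).

**Overlap.** Two gene sets of sizes n_a, n_b sharing k genes on a
background of N genes enrich by FE = k·N/(n_a·n_b), with upper-tail
hypergeometric (one-sided Fisher) significance.

## Worked example

```bash
irpipe overlap --na 497 --nb 346 --k 94 --background 4546
```

prints

```
overlap k=94 of 497 x 346 on background 4546
expected=37.83 fold_enrichment=2.5 fisher_p=9.79e-19 (greater)
```

i.e. two IR-gene sets of 497 and 346 genes sharing 94 members on a
4,546-gene background overlap 2.5-fold more than chance, and that excess is
decisive under the hypergeometric null. The full synthetic pipeline:

```bash
irpipe demo --seed 7 --out-dir demo_out
```

```
# irpipe 0.1.0 demo
# seed=7
diff_ir CON vs BMT: 300 events tested, 38 IncIR, 40 DecIR
recovery: reverse_V=31 V=28 none=241
deg CON vs BMT: 1000 genes tested, 73 up, 64 down
network: observed links=194 empirical_p=0.005 (K=199)
overlap worked example: fold_enrichment=2.5 fisher_p=9.79e-19
```

Here 300 intron events were simulated for 6 control, 8 pre- and 8
post-treatment samples with 10% planted psi increases and 10% decreases of
0.3 in the pre-treatment arm; the differential test recovers them (38 + 40
calls against 60 planted at depth 100, the excess being borderline events
passing the dual rule), the recovery classifier finds the
planted reverse-V and V trajectories, and the link-count test flags the
planted excess connectivity (194 observed links, above all 199 random
sets). Re-running with the same seed reproduces every file byte for byte.

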