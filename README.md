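# dgekit

Tag-based (SAGE/DGE-style) expression profiling and prognostic-marker
analysis for paired tumor/normal studies, exercised end to end on
synthetic data.

## The problem

Digital gene expression (DGE) sequencing quantifies a transcriptome by
counting short 3'-anchored tags: each transcript is represented by the
21-bp sequence at its 3'-most NlaIII restriction site — the palindromic
recognition site `CATG` plus the 17 bases downstream. Comparing tag
counts between a tumor library and its matched normal library, across a
cohort of patients, yields recurrently deregulated genes; candidate
markers are then validated on an independent cohort by
immunohistochemistry (IHC) scoring and survival analysis. `dgekit`
implements the full desk-scale analytical chain for this design:

1. **tag catalog** (`dgekit.reference`) — scan a genome for every
   virtual tag (`CATG` + 17 bp, both strands), annotate tags to
   transcripts, flag each transcript's canonical (3'-most sense-strand)
   tag and catalog-wide sequence uniqueness;
2. **quantification** (`dgekit.quant`) — map observed 21-bp tags with at
   most one substitution (exact-match priority, ambiguous tags
   discarded), normalize to TPM (tags per million), and compute
   gene-detection saturation curves;
3. **differential expression** (`dgekit.diffexpr`) — the Audic–Claverie
   exact test per gene and patient pair,

   P(y | x) = (N₂/N₁)^y · (x+y)! / [ x!·y!·(1+N₂/N₁)^(x+y+1) ],

   with two-sided p = min(1, 2·min(P(Y≤y|x), P(Y≥y|x))) computed in log
   space, Benjamini–Hochberg FDR per pair, deregulation calls at
   |log₂ratio| > 1 and FDR < 0.1%, and cohort aggregation into
   recurrent genes (deregulated in ≥ half the pairs with average fold
   > 1), plus qPCR −ΔΔCt sign-concordance checks;
4. **cross-cohort comparison** (`dgekit.crosscohort`) — hypergeometric
   overlap tests between deregulated-gene lists and two-way hierarchical
   clustering with average linkage on the uncentered Pearson
   dissimilarity (the Cluster 3.0 metric), with TreeView-compatible
   export;
5. **prognosis** (`dgekit.prognosis`) — IHC staining index
   (proportion score 0–5 × intensity grade 0–3, dichotomized at ≥ 5),
   Fisher/chi-square association tests, Kaplan–Meier curves, the
   Mantel–Haenszel log-rank test, univariate/multivariate Cox
   proportional hazards (Efron ties), and combined-marker risk strata;
6. **synthetic data** (`dgekit.simulate`) — generators for genomes,
   paired negative-binomial count studies with planted effects, noisy
   tag libraries, and survival cohorts with correlated dichotomized
   markers, used to validate every stage against known truth.

## Worked example

The default synthetic study plants 50 differentially expressed genes
(|log₂FC| = 3, effect present in 7 of 10 patients) among 500 genes at
5×10⁴ clean tags per library, and a 103-patient survival cohort whose
three markers (ALDH2-, CCNE1- and SMAD3-like; adverse states low, high,
high) each carry a log hazard ratio of 1.0:

```bash
$ dgekit run-all --seed 1 --outdir run1
recurrent genes: 48 (23 up, 25 down); planted recovery 0.960, empirical FDR 0.000
reports in run1
```

48 of the 500 genes pass the recurrence filter (deregulated at
FDR < 0.1% and fold > 1 in ≥ 5 of 10 pairs, |mean log₂ratio| > 1); they
recover 96% of the 50 planted genes with no false positives. The
survival stage prints the multivariate Cox fit on the scored cohort:

```bash
$ dgekit survival --seed 1 --outdir surv1
  sex[Female vs Male]: HR 0.902 (0.52-1.57), p 0.713
  age: HR 0.994 (0.979-1.01), p 0.435
  t_stage[T1 vs T3]: HR 1.32 (0.719-2.42), p 0.371
  t_stage[T2 vs T3]: HR 1.65 (0.771-3.53), p 0.197
  ALDH2_group[high vs low]: HR 0.243 (0.127-0.463), p 1.7e-05
  CCNE1_group[high vs low]: HR 4.96 (2.7-9.12), p 0
  SMAD3_group[high vs low]: HR 3.67 (1.97-6.85), p 4.3e-05
```

All three markers are independent predictors in the direction planted
(high ALDH2 protective, HR < 1; high CCNE1/SMAD3 adverse, HR ≈ e¹·⁰ ≈
2.7 up to sampling noise), while sex, age and T stage — which carry no
direct effect in the generator — stay non-significant. Output
directories contain the genome (FASTA), annotation (BED), tag libraries
(TSV), TPM matrix, per-pair DE tables, recurrent-gene list, clustered
matrices (`.cdt`/`.gtr`/`.atr`), Kaplan–Meier tables, and JSON run
reports; reports are byte-identical under a fixed seed.

Individual stages are available as `dgekit simulate`, `build-ref`,
`quantify`, `de`, `recur`, `overlap`, `cluster`, `survival` — see
`dgekit --help` — and every stage is importable as a library function.

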