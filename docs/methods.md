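# Methods

This note documents the statistical models, the synthetic-data
generators, and the numerical and design choices behind `dgekit`.

## Tag model and catalog

A DGE library tags transcripts at NlaIII sites. Because `CATG` is its
own reverse complement, every genomic occurrence defines two potential
virtual tags: the plus-strand tag reads the site plus the 17 bases to
its right; the minus-strand tag reads the reverse complement of the 17
bases to its left plus the site. The catalog records every such 21-mer
(tags containing `N` are dropped rather than wildcarded), assigns a tag
to a transcript only when the full 21-mer lies inside the transcript on
the matching strand, and flags per transcript the canonical tag — the
sense-strand site closest to the 3' end (largest genomic coordinate on
`+` transcripts, smallest on `-`). Uniqueness is evaluated over the
full catalog sequence multiset; both strands are scanned so that
antisense duplicates correctly mark ambiguity even though
quantification uses sense canonical tags. Coordinates are 0-based
half-open internally (BED convention).

## Mapping and normalization

Observed tags are matched with at most one substitution by enumerating
the 63 single-base variants against an exact-match hash index — exact
(no heuristics) and fast at desk scale. An exact hit pre-empts the
1-mismatch search (best-hit semantics). Tags whose best-level hits span
two or more genes are counted ambiguous and discarded; hits on
gene-less catalog entries do not contribute counts. The partition
`mapped + unmapped + ambiguous = clean tags` holds exactly; wrong-length
tags are excluded from the clean total and tracked separately.

TPM uses the uniquely mapped tag total as denominator by default, since
expression is quantified from uniquely mapping tags; "per million clean
tags" is also defensible and is available via
`tpm_denominator="clean"`. Saturation curves subsample the tag multiset
without replacement (a single shuffle, prefix depths) and report the
fraction of annotated genes detected with ≥ 1 uniquely mapped tag.

## Differential expression

For counts x (normal, library size N₁) and y (tumor, N₂) the
Audic–Claverie conditional distribution

    P(y | x) = r^y (x+y)! / [ x! y! (1+r)^(x+y+1) ],   r = N₂/N₁

is evaluated from log-gamma terms; tails are accumulated with
`logsumexp` over a window of ±45 standard deviations around the
dominant terms (truncation error below double precision), so counts up
to 10⁷ neither overflow nor lose the small tail. The two-sided p-value
doubles the smaller tail and caps at 1; sidedness is not stated in the
source protocols, and deregulation is reported in both directions, so
the symmetric doubled-tail convention is used. Note the test
conditions on x: p(x, y, N₁, N₂) and p(y, x, N₂, N₁) differ slightly —
only the per-outcome probabilities are exchange-symmetric (at N₁ = N₂),
a known property of this test.

FDR control is Benjamini–Hochberg step-up, applied per patient pair
across all genes (the cited FDR procedure is not spelled out in the
protocol; BH is the standard choice). Calls use |log₂ratio| > 1 and
q < 0.001 ("fold > 1 and FDR < 0.1%"). The signed log₂ ratio is
computed from TPM with a pseudocount equivalent to one tag in each
library, so zero counts remain defined; the p-value always uses raw
counts, which handle zeros natively.

Recurrence requires deregulation in at least ⌈n/2⌉ pairs (the "≥ 5 of
10 cases" rule, scaled to the cohort) and |mean signed log₂ratio| > 1.
The mean runs over **all** patients by default — this reading of
"average fold" yields a single direction per gene — with the
alternative (mean over deregulated pairs only) exposed as
`recurrence_over="de"`. Genes whose deregulated pairs disagree in sign
are flagged `mixed` but classified by the mean.

qPCR concordance treats −ΔΔCt = −(ΔCt_tumor − ΔCt_normal) as an
independent estimate of the log₂ expression ratio; a gene × patient
cell is concordant when its sign matches the sequencing log₂ratio.

## Cross-cohort comparison

Overlap between deregulated-gene lists uses the hypergeometric upper
tail P(X ≥ k) over a universe of genes assayable in both cohorts (the
universe is configurable; the intersection of detected genes is the
default because only mutually measurable genes are comparable).
Up-with-up, down-with-down, and combined overlaps are computed
separately. Clustering uses the uncentered Pearson similarity
s = (1/n) Σ (xᵢ/σₓ)(yᵢ/σᵧ) with σ the root-mean-square about zero — the
Gene Cluster 3.0 metric, which rewards proportionality rather than
covariation about the mean — converted to the dissimilarity d = 1 − s,
under average (UPGMA) linkage; ties resolve to the lowest pair index.
Missing values are not supported (synthetic data is complete; the
Cluster 3.0 missing-value weighting scheme is out of scope). Two-way
clustering runs rows and columns independently; results export as
TreeView-compatible `.cdt`/`.gtr`/`.atr` files.

## IHC scoring and survival

The staining index multiplies the stained-cell proportion score (0:
none; 1: ≤ 5%; 2: ≤ 25%; 3: ≤ 50%; 4: ≤ 75%; 5: > 75%) by the
intensity grade (0–3), giving the standard immunoreactive-score range
0–15 on which the published high/low threshold (≥ 5) is a meaningful
split; a sum variant is available. The published bins leave (5%, 6%)
uncovered; right-closed bins assign that gap to score 2. Marker–marker
and marker–sex associations (2×2) use Fisher's exact test; associations
with the three-level T stage use the Pearson chi-square without
continuity correction, matching the convention of the tabulated
associations.

Kaplan–Meier estimation and the two-group Mantel–Haenszel log-rank test
are delegated to `lifelines`; Cox proportional hazards to statsmodels'
`PHReg` with Efron tie handling by default (month-resolution times tie
often; Breslow is available and agrees to 10⁻¹⁰ when no ties exist).
Categorical covariates are dummy-coded against the lexicographically
last level, which places T1 and T2 each against the T3 reference and
Female against Male, the published contrast layout; age enters as a
continuous covariate. Wald 95% CIs are exp(β ± 1.96·SE); two-sided
α = 0.05 throughout. Monotone likelihood (complete separation) is
flagged via diverging coefficients or non-finite standard errors rather
than reported as a converged fit. The combined-marker stratum is the
conjunction of all three adverse states (ALDH2 low, CCNE1 high, SMAD3
high) against all other patients.

## Synthetic-data generators

The generators reproduce the statistical structure of the paired design
at desk scale. Default: 500 genes × 5×10⁴ tags per library for 10
patients (instead of ~17,000 genes × ~3.5 M tags), with 10% of genes
planted at |log₂FC| = 3 and a 103-patient survival cohort. Runtime
scales linearly in tags; the structure — not the size — is what the
tests exercise.

**Genomes.** Uniform random DNA; transcripts placed without overlap on
random strands, lengths capped so occupancy stays below about half the
genome. Any transcript lacking a usable sense-strand site gets one
planted, so every gene can carry a canonical tag.

**Paired counts.** Relative abundances are log-normal
(meanlog 0, sdlog 1), reproducing the heavy-tailed tag-count spectra of
DGE libraries, and scaled so expected library totals equal the
configured size. Marginal counts are negative binomial with size
k = 10 (variance μ + μ²/k, a moderate biological dispersion), realized
as gamma–Poisson with the gamma draw **shared** between the tumor and
normal library of a pair: under the null the two counts are Poisson
with a common rate, which is exactly the sampling model the
Audic–Claverie test assumes for technical tag sampling, while biological
variation appears across patients. Planted genes receive a fixed sign
and a 2^±3 factor in ⌈0.7·n⌉ randomly chosen patients (7 of 10 —
deliberately above the ≥ 5-case rule so sampling exercises both sides
of the recurrence filter). Tumor means are renormalized per library to
the configured size, so planted effects induce the compositional shift
real libraries show (null genes drift slightly opposite to the net
planted direction, by about −0.3 log₂ units at the defaults — visible
in per-pair ratios but well below the fold threshold).

**Tag libraries.** Each gene's canonical tag is emitted with
multiplicity equal to its count; every base substitutes independently
with probability 0.002, giving ~4% of tags one error and almost none
two or more — consistent with a "≤ 1 sequencing error" clean-tag
regime. Adapter chemistry, digestion kinetics, PCR duplicates, and
quality scores are not modeled.

**Survival cohorts.** One standard-normal latent risk factor per
patient loads on each marker's staining read-out with loading √ρ
(ρ = 0.5 by default; the ALDH2 analogue loads negatively so its low
state tracks risk), producing the marker–marker correlation the
validation cohort shows, and on T stage (loading 0.6), making stage
univariately prognostic without a direct effect. Staining percentages
and intensity grades are derived from the latent percentile so the
high/low split lands near the median. The event hazard is exponential,
baseline 0.008/month (median ~7 years for a fully low-risk patient)
times e^(1.0) per adverse marker state; censoring is independent
exponential calibrated to a ~30% censor fraction (approximate, since
the calibration uses the mean hazard). Times are rounded to 0.01
month and floored at one day.

What passing tests show — and do not. The generators share the
analysis's distributional assumptions (NB counts, exponential
survival, proportional hazards, complete data), so green tests
demonstrate correctness of the statistical machinery and recovery under
the stated model, not robustness to the violations real data bring
(zero-inflation, batch effects, non-proportional hazards, informative
censoring, mapping artifacts from repetitive genomes).

## Numerical and testing choices

- Determinism: every generator takes an explicit seed
  (`numpy.random.default_rng`); pipeline reports are byte-identical
  under a fixed config and seed, with no timestamps.
- The Audic–Claverie implementation is verified against two independent
  routes: direct per-outcome summation via a multiplicative recurrence
  (agreement to 10⁻¹²) and the closed-form negative-binomial identity
  P(·|x) = NB(x+1, N₁/(N₁+N₂)).
- BH is verified against the reference step-up implementation in
  statsmodels; Fisher, hypergeometric and chi-square against counting
  enumeration and the textbook formula; clustering against a naive
  O(n³) UPGMA; the log-rank p against a 10⁴-permutation oracle; Cox
  against a partial-likelihood grid search.
- Test problem sizes (10⁴ null pairs, 200 Cox replicates at n = 500,
  10⁴ permutations) were chosen so the whole suite runs in about a
  minute on one core while keeping Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

- The ≤ 1-mismatch mapper is exact but quadratic in tag length per
  probe; it targets desk-scale catalogs, not genome-scale alignment.
- Overlapping transcripts: a tag inside several same-strand transcripts
  is assigned to the first by sorted coordinates; fine for the
  non-overlapping synthetic annotations, simplistic for real ones.
- The censoring-rate calibration is approximate under strong hazard
  heterogeneity.
- The deposited expression dataset of the motivating study and external
  cohort lists (bladder-UC, ccRCC) are not bundled; the cross-cohort
  machinery is exercised on detected-vs-planted gene lists instead.
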