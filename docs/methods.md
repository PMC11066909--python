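# Methods

`rosette-omics` re-implements, as a tested pipeline, an integrated
proteome–transcriptome–methylome analysis of embryonal brain tumors with
multilayered rosettes (ETMR) against AT/RT and medulloblastoma comparators:
normalization and cohort integration, subgroup-aware differential ranking,
preranked GSEA and over-representation analysis (ORA), semantic-redundancy
pruning of ontology terms, promoter-methylation–protein correlation ORA,
consensus clustering, and 4PL dose–response fitting.  Because the underlying
patient data cannot ship with the package, every stage is exercised against a
synthetic multi-omics generator whose planted effects are known exactly.

## Synthetic study conditions

The generator's defaults mirror the real case series: 40 tumors — 16 ETMR
split into 8 ETANTR and 8 EBL/MEPL, 9 AT/RT, 15 MB — with optional
microdissection pairs (one neuropil-rich and one primitive area of the same
tumor sharing a `pair_id`).

* **Proteome.** Feature baselines μ_g ~ N(0, 1) on the log2 scale; planted
  gene sets are shifted by their effect size (default +1.5 log2, i.e. ~2.8-fold)
  in the ETMR samples their scope covers; residual noise is additive Gaussian
  with SD 0.5 log2 units — a mid-range value for FFPE label-free proteomics.
* **Transcriptome.** Tracks the proteome signal with attenuation 0.7 plus its
  own 0.5-SD noise, emulating partial RNA–protein concordance.
* **Methylome.** Promoter CpGs of linked genes are generated on a latent
  Gaussian correlated with the gene's (standardized) protein level at the
  configured strength and sign, then squashed to a beta value in \[0, 1\]
  through a logistic transform.  This is the simplest generative model that
  supports the Spearman-based analysis; it makes no claim about realistic beta
  distributions.
* **Batches and references.** A per-batch location/scale effect is applied
  after the signal.  Reference samples are replicate-like draws present in
  every batch with small (0.05 SD) independent noise, emulating aliquots of
  the same tumors measured in two cohorts.
* **Gene sets.** Planted sets occupy dedicated feature blocks; background
  sets are drawn from features carrying no planted effect, so the
  false-positive behavior of downstream calls is interpretable.  Planted sets
  sharing more than half their members trigger a confounded-design warning in
  the truth record.
* **Determinism.** All randomness flows through `numpy.random.default_rng`
  (PCG64); a fixed seed reproduces every matrix bit for bit.

What the generator does **not** emulate: peptide-level quantification and
missingness structure, TMT reporter-ion artifacts, realistic CpG genomic
spacing or array normalization, and the topology of the real Gene Ontology.
Passing tests therefore demonstrate algorithmic correctness and planted-effect
recoverability under idealized noise, not performance on real cohorts.

## Normalization and integration

Per-sample **median centering** (median log2 abundance → 0) is the default
proteome normalization.  For cross-dataset work, **median/MAD
standardization** scales each sample to median 0 and median absolute
deviation 1.  MAD is the plain median absolute deviation without the 1.4826
normal-consistency constant: the transform is then exactly idempotent and the
"MAD = 1" contract can be checked directly.

**Batch adjustment** follows the parametric empirical-Bayes location/scale
scheme (the ComBat model) with no covariates: features are standardized using
batch-size-weighted grand means and the pooled residual variance; per-batch
location (γ̂) and scale (δ̂²) estimates are shrunk toward batch-level
hyperpriors — a normal prior for γ (moments across features) and an
inverse-gamma prior for δ² (method of moments) — by fixed-point iteration,
and the pooled scale is restored.  Two deliberate numerical choices:

* δ̂² uses ddof = 0 variances, so two statistically identical batches give
  δ̂² = 1 exactly and the adjustment collapses to the identity to machine
  precision (a contract the tests assert).
* Degenerate hyperpriors (zero across-feature spread of γ̂ or δ̂²) fall back
  to the unshrunk estimates instead of dividing by zero.

Features with missing values are mean-imputed for estimation and re-masked
afterwards; zero-variance features pass through with a warning.  Note that EB
shrinkage deliberately does not force observed batch means equal: the residual
between-batch mean difference after adjustment is of the order of the
batch-mean sampling noise times the retained-noise fraction (≈ 0.5 at these
batch sizes).  The batch-correction checks therefore use fixtures with
within-batch SD 0.2 log2 units, for which the residual stays well under
0.1 log2 units.

**Reference-anchored integration** (the COCONUT idea) estimates the same EB
parameters with cohort as the batch, but **only on the shared reference
samples**, then applies each cohort's adjustment to all of its samples.  The
merged matrix covers the feature intersection and drops every reference
sample.  When the references are the full cohorts this coincides with plain
two-batch adjustment (asserted in tests).

**Probe filtering** removes CpGs flagged as sex-chromosomal, SNP-overlapping
or cross-reactive, and — when detection p-values are supplied — probes with
detection p at or above 0.01 in any sample (the boundary fails).

## Differential statistics and ranking

Fold change is a difference of group means on the log2 scale (case −
reference), so |fc| > 1 means two-fold.  Welch's t (Welch–Satterthwaite df)
is the unpaired test; microdissection pairs use the paired t on differences.
Zero-variance situations return p = 1 with a `degenerate` flag rather than
aborting.  One-way ANOVA feature ranking guards against rounding noise on
constant features (sums of squares below 1e−12 of the data scale count as
zero).

The GSEA rank statistic is **score = fc × (−log10 p)**; p = 0 is clamped to
the smallest positive float with a warning.  Histomorphology-independent
ranks average the ETANTR and EBL/MEPL scores per gene (genes present in only
one list are dropped with a logged count); averaging rank positions instead
is available behind a flag since the combination rule is a genuinely open
design point.  The histomorphology-independent **selection rule** requires
|fc| > 1 and p ≤ .05 in both subgroup comparisons *with concordant sign* —
the concordance requirement resolves what "significant in both" should mean
for opposite-direction changes.

## Enrichment

**Preranked GSEA** uses the weighted Kolmogorov–Smirnov running sum: in-set
genes add |score|^weight (normalized to the in-set total N_R), out-of-set
genes subtract 1/(N−K); ES is the extremum of largest magnitude.  Positive
extrema occur immediately after hits and negative ones immediately before, so
the implementation evaluates only those 2K candidates in closed form (the
test oracle walks the full sum).  On a magnitude tie within 1e−12 the
positive extremum wins.  The null permutes gene-set membership (phenotype
permutation does not exist for a preranked list): K positions are redrawn
uniformly per permutation, 1000 by default, with a mandatory seed.  NES
divides ES by the mean |ES| of same-sign null scores; the nominal p is the
same-sign permutation tail with a +1 pseudocount; BH adjustment runs across
the retained sets of one analysis (one ranked list × one collection), and
sets are retained when their overlap with the ranked genes lies in
\[10, 250\] for proteins (\[10, 600\] for RNA).

**ORA** computes the upper hypergeometric tail P(X ≥ k) within the detection
universe and calls a term over-represented at p < 0.05 **and** overlap count
> 4.  **ssGSEA** scores one sample as the integrated gap between the
rank-weighted in-set ECDF (rank^0.25, top gene carrying rank N) and the
unweighted out-of-set ECDF.

**Semantic redundancy.**  Information content derives from propagated gene
annotations, IC(t) = −log(n(t)/n(root)).  Resnik similarity (IC of the most
informative common ancestor) is normalized by the namespace's maximum IC so
the shared 0.4 threshold is meaningful on \[0, 1\]; Lin similarity is
2·IC(MICA)/(IC(t1)+IC(t2)).  The filter scans terms by ascending p (ties by
term id) and drops a term only when **both** similarities to an already-kept
term exceed 0.4 — the dual-measure rule is read as a conjunction.  Terms
whose similarity cannot be computed are kept.

## Methylome link

Promoter association means TSS200, TSS1500 or 5′UTR.  Each promoter
(CpG, gene) pair is tested by Spearman correlation across the tumor samples;
for n < 10 the two-sided p comes from exact enumeration of all n! rank
assignments (the t approximation is unreliable at case-series scale), with
ties handled by average ranks throughout.  The Benjamini–Yekutieli step-up
(p·m·c(m)/i, monotone, capped at 1) is applied over **all tested pairs
jointly** — the conservative family choice, valid under the arbitrary
dependence of CpGs within a promoter.  A gene is methylation-linked when at
least one of its promoter CpGs reaches adjusted p ≤ .05 (the boundary
passes).  The methylation ORA runs within the universe of significantly
differential proteins, sizes 5–150, and calls a set by the count rule: at
least 2 **and** strictly more than 10% of its in-universe members linked; the
hypergeometric p is reported alongside for transparency.

## Clustering

Samples are clustered on the 1000 most variant features (ties by feature id)
with the ward.D2 convention — Ward's minimum-variance criterion with squared
Euclidean distances inside the Lance–Williams update, i.e. scipy's `ward`
linkage on the observations.  Consensus clustering follows the Monti
procedure with the standard defaults (1000 resamples at fraction 0.8, both
exposed): per resample, samples are subsampled without replacement and
clustered; consensus(i,j) is the co-clustered count over the co-sampled
count; the final partition per k cuts a ward tree on 1 − consensus, and the
reported k maximizes mean within-cluster consensus.  Missing values are
imputed by the feature median before distances.  A sample pair never
co-sampled is an error advising more resamples.

## Dose–response

Viability follows the four-parameter logistic
y = bottom + (top − bottom)/(1 + (x/IC50)^hill), fitted by least squares on
log10 concentration with data-quantile initialization (bottom/top from the
extreme per-dose means, IC50 from the dose nearest half-maximum, hill = 1)
and three perturbed restarts before declaring non-convergence.  The reported
IC50 is the curve's midpoint parameter (relative EC50 convention); parameters
are canonicalized so top ≥ bottom.  Standard errors come from the covariance
of the fit (delta method for IC50).  The comparison table ranks converged
fits by IC50 with fold differences versus the most potent line, ties broken
by cell-line id; responses are fitted raw, with normalization to the maximum
available as an option since vehicle normalization is a genuinely open choice.

## Problem sizes in the test-suite and acceptance script

The recovery checks run at deliberately desk-sized scale: 200 features, the
40-sample (or 28/30-sample) layouts above, 20 seeded replicates per rate,
2000 GSEA permutations, 500 consensus resamples, and 20-seed IC50 recovery at
5% CV.  Exhaustive oracles (hypergeometric enumeration up to N = 30, all 720
rank permutations at n = 6, all 56 memberships of a 3-gene set in an 8-gene
list) are small enough to enumerate exactly.

## Known limitations

* Non-parametric ComBat, ComBat-seq and covariate designs are out of scope.
* The enrichment null is membership permutation only; sample-label
  permutation GSEA is not implemented.
* Ontology support is the is_a subset of OBO; other relationship types are
  ignored and similarity is Resnik/Lin only.
* The consensus-clustering summary is the mean within-cluster consensus; item
  consensus and CDF-delta diagnostics are not computed.
* Absolute IC50 (response = 50% of control) is not computed; only the
  midpoint-parameter convention is reported.
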