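# Methods

This note documents the models, defaults and numerical choices behind
mmclonetrack, and what the synthetic cohorts do and do not demonstrate.

## Mutation catalogs (mutcat)

Single-base substitutions are classified into the standard 96 channels:
six pyrimidine-normalized substitution classes (C>A, C>G, C>T, T>A, T>C,
T>G) × 16 flanking-base pairs, ordered class-major with flanks
lexicographic — the de-facto layout of published signature matrices, so
external references load without permutation. Purine-reference mutations
are reverse-complemented; channel assignment is an exact involution under
reverse complement (tested exhaustively over all 192 raw cases).

Coordinates: mutation positions are 1-based (VCF/TSV native); transcript
intervals are BED-style 0-based half-open. Conversion happens only at file
boundaries. Records whose context contains N, sits at a contig edge, or
mismatches the reference are counted *unclassifiable*, never dropped
silently: classifiable + unclassifiable always equals the input size.

Transcriptional strand: a pyrimidine-channel mutation inside a gene is
*untranscribed* when the pyrimidine lies on the coding (sense) strand,
*transcribed* when on the template strand. Mutations overlapping genes on
both strands are ambiguous and excluded, which biases neither stratum;
intergenic mutations are excluded by definition.

## Signature refitting (sigfit)

Known-signature refitting is multinomial maximum likelihood over the convex
mixture of profile rows, solved by EM: uniform initial weights, convergence
at 1e-8 change in mean per-mutation log-likelihood, cap 10⁴ iterations.
EM monotonicity and the analytic solution on disjoint supports anchor the
tests. Weights are scale-invariant in the catalog total.

A parsimony pass then removes signatures greedily (least pooled weight
first) whenever removal costs less than ε = 0.01 reconstruction cosine,
refitting after each removal. The point fit protects SBS-MM1 from
elimination so its weight and CI are always reported; its presence is
judged by the bootstrap CI, not by pruning.

Uncertainty: the catalog is resampled multinomially (same total) and each
replicate refit *including parsimony*, so a replicate's weight for an
unsupported signature is exactly zero and the percentile CI can reach 0.
This is what makes the "95% CI > 0" presence rule meaningful: without
per-replicate elimination, EM weights at finite n are almost surely
positive and the rule would fire always. Defaults: 1000 bootstraps, level
0.95, seeded. Calibration on simulated catalogs (500 mutations, true
SBS-MM1 weight 0.15): ~95% CI coverage; false-presence rate ~0% with the
signature absent.

At small pooled sizes (a few hundred mutations with a ~10% melphalan
contribution) the presence call is genuinely borderline — a few bootstrap
replicates may prune the signature and pull the CI lower bound to zero.
The packaged toy reference (four random sparse background profiles plus an
SBS-MM1-like profile concentrating 70% of its mass on C>T in CCA, GCA,
GCC, GCG, GCT) is for tests and simulation; real analyses should supply a
published reference matrix as TSV.

Strand bias: conditioning two Poisson strand rates on their total makes
the transcribed count Binomial(n, ½) under symmetry, so the exact
conditional binomial test (two-sided by minimum-likelihood summation) is
used. Its discreteness makes the achieved size conservative: ≈ 3.7% at
α = 0.05 for totals around 60.

## Clonal evolution (clonevo)

CCF transform as in the README; CCFs above 1.5 are capped and flagged as
likely multiplicity/copy-number errors (uncapped values destabilize
clustering). Missing covering segments fall back to CNt = 2 with a flag.

Subclonal structure is approximated by 2-D Gaussian mixtures on paired
(early, late) CCFs: diagonal covariances, reg_covar 1e-4, k = 1..6, ten
seeded restarts each, model order by BIC. A Dirichlet-process
reconstruction would give the same downstream inputs — the classification
layer consumes only cluster means and weights — at far higher cost.
Variants private to one timepoint enter with CCF 0 at the other; they are
the signal for emergence/vanishing. Below 10 shared variants the solution
degrades to a single cluster with a warning.

Classification thresholds (config-exposed defaults): τ_shift = 0.3 (rise or
fall that counts as a dominance shift), τ_new = 0.25 (late CCF that counts
as an emerged clone), τ_minor = 0.1 (absence / minor move). Rules, with
precedence differential > linear > stable making the mapping total:

* **differential** — one cluster falls by ≥ τ_shift while another rises by
  ≥ τ_shift, or a cluster vanishes (≥ τ_new → < τ_minor) while a distinct
  one emerges (< τ_minor → ≥ τ_new);
* **linear** — an emerging cluster without any such reciprocal fall;
* **stable** — otherwise.

The published descriptions of these patterns are qualitative; the numeric
defaults are explicit stand-ins, recorded in output metadata, and scenario
recovery in simulation is robust to moderate threshold changes. RAS shifts
apply the same fall/rise logic to labeled KRAS/NRAS mutations, requiring
the falling and rising mutations to differ.

## Transcriptomic scores (exprscore)

Rank/z-based scores standardize log2(TPM+1) per gene across samples
(population sd; zero-variance genes become 0 and are flagged). Threshold
scores (CGA counts, fold changes) use raw TPM.

ssGSEA is the weighted running sum with exponent 0.25 by default
(exponent 0 gives a purely rank-based score used by the invariance tests);
ties break on (−z, gene id), deterministically. Scores are raw running
sums — relative comparisons across samples are unaffected by the scale
constant; a divide-by-gene-count mode exists for cross-set comparability.
An independent brute-force implementation in the test suite pins the
vectorized one to 1e-9.

The proliferation index sums the 11 panel genes' z values (a mean mode is
config-exposed; sum is the default because observed "high PI" values on
the natural scale exceed 3, which a mean of z-scores cannot). At least 8 of
the 11 genes must be present. Panel indices (NFκB, HLA-I/II) are panel
means of z values. Gene identifiers are plain case-sensitive symbols;
aliasing is the caller's job. The shipped GMT panels (11 proliferation
genes, 27 hematological CGAs, NFκB index, HLA-I/II, ABC transporters,
exportins) are *reconstructed* lists from the cited literature and are
data files meant to be edited, not code.

Spearman summaries report raw p plus Benjamini–Hochberg q side by side and
highlight |ρ| ≥ 0.45.

## Synthetic cohorts (simdata)

The generator emulates a paired WES + RNA-seq myeloma cohort at desk
scale; its defaults are the study conditions the tests run under:

* 12 patients, evolution scenarios allocated 58/23/19%
  differential/linear/stable (largest remainder), purity uniform in the
  0.80–1.00 inclusion window;
* ~100 variants per pair at mean depth 100, binomial read noise, CCF
  cluster jitter σ = 0.05; planted layouts per scenario (the differential
  layout includes a late-private subclone — newly acquired mutations —
  inside the rising clone);
* signature mixtures: four background signatures for ancestral variants;
  newly acquired variants of high-dose-melphalan patients draw SBS-MM1
  with weight 0.6 (after high-dose exposure the melphalan signature
  dominates the novel-mutation spectrum; low-dose and unexposed groups
  carry none by default), with 2:1 transcribed:untranscribed odds in the
  five typical contexts;
* expression: per-gene cohort mean N(2, 1) on log2, per-(gene, patient)
  baseline N(0, 0.5) shared by the pair, paired technical noise sd 0.02 —
  so paired deltas are quiet unless an effect is planted; PI effects shift
  panel genes by +1 between-patient sd in late samples; CGA effects switch
  on 5 antigens (TPM 10–60) late; ~28% of mutations get RNA alt-read
  support.

Everything is deterministic under a seed, emitted files round-trip through
the package readers, and the ground-truth JSON (scenarios, RAS flags,
realized per-sample signature draws, effect flags) suffices to score every
downstream stage.

What passing these simulations does **not** show: robustness to purity or
copy-number estimation error (segments are clean diploid by default),
subclonal copy number, multi-sample (>2 timepoint) reconstruction,
gene-identifier mismatches, batch effects or realistic expression
covariance between panels. The simulated strand-bias per patient is as
underpowered as real per-patient counts — pooled analyses carry the
signal, mirroring practice.

## Pipeline

QC retains samples with purity ≥ 0.80 (inclusive); patients left with
fewer than 2 samples drop out of paired analyses but keep per-sample
outputs, with reasons logged. Default pairing is first retained timepoint
vs latest retained sample ("first_pd" selects the first PD-labelled
sample instead). Treatment labels are pass-through annotations, never
inferred. All stage seeds derive from one config seed (SeedSequence), and
reruns are byte-identical; the manifest records config, seeds and
thresholds. Problem sizes in the test suite (200-replicate calibrations,
500 bootstraps, 30 simulations per scenario class, a 12-patient e2e
cohort) were chosen as the smallest designs whose pass/fail bands are
statistically meaningful.
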