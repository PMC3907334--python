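# Methods

This note documents the models, conventions and numerical choices behind
`riskenhancer`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Coordinates and file formats

Internal coordinates are 0-based half-open throughout. VCF positions are
1-based and converted on ingest; BED is consumed natively. A SNP at a track
interval's `end` coordinate is **not** a member (half-open convention).
Phased genotypes are required: r² is computed by direct haplotype counting,
which is exact for phased data, and unphased input is rejected rather than
silently EM-estimated. Monomorphic and multi-allelic sites are skipped with
a logged warning, not an abort.

## Linkage-disequilibrium stage

For two biallelic variants with haplotype frequency p_AB and allele
frequencies p_A, p_B,

    D = p_AB − p_A p_B,    r² = D² / (p_A (1−p_A) p_B (1−p_B)).

The proxy scan takes "a 1 Mb window" to mean index ± 500 kb (centering; the
total span is 1 Mb). This is configurable (`window=` is the total width).
The r² cutoff defaults to 0.5 and the index SNP is always retained in its
own proxy list. Two-population intersection flags proxies at two tiers:
`shared` (r² ≥ 0.5 in every requested population) and `shared_high`
(r² ≥ 0.8).

Functional classification applies a fixed precedence so class counts
partition the SNP set: coding_exon > mir_utr > promoter > enhancer >
unclassified. `mir_utr` requires a microRNA target-site interval *inside* a
5′ or 3′ UTR. Promoter windows are strand-aware, spanning −1000 bp to
+100 bp around each TSS in the direction of transcription. The precedence
order is a package choice — multi-class SNPs need a deterministic
assignment rule, and published per-class counts in this field do not pin
one down — and both the order and the window are arguments.

Locus merging is a union-find over index SNPs: two indexes join when their
pairwise r² reaches `merge_r2` (default 0.5) in any shared reporting
population, or when they share at least `shared_min` (default 3) correlated
SNPs; loci are numbered in genomic order. Both thresholds are exposed
because no authoritative values exist for them.

Biofeature clustering uses Jaccard distance with average linkage
(scipy), after label-sorting rows and columns so the dendrogram is
deterministic under input reordering.

## Motif model

The match score of a length-L sequence against a PWM with column
frequencies f and positional weights w is

    s(seq) = ∏ᵢ ( fᵢ[seqᵢ] / maxᵦ fᵢ[b] )^{wᵢ},   wᵢ = ICᵢ / maxⱼ ICⱼ,
    ICᵢ = 2 + Σᵦ fᵢ[b] log₂ fᵢ[b]   (bits, after pseudocount).

Properties: s ∈ [0, 1]; the consensus sequence scores exactly 1; a base of
frequency zero at a positively weighted position annihilates the score to 0
when pseudocounts are disabled; substituting a lower-frequency base can
never raise the score; and the score is invariant under simultaneous
reverse complementation of sequence and matrix. A position with w = 0
contributes nothing (0⁰ = 1 by convention), so completely uninformative
columns cannot annihilate. The weighting scheme (`ic` or `uniform`) and the
exact functional form are deliberate, documented package choices: they are
pinned down by the published properties of such scores (bounded in [0, 1],
weights reflecting positional importance) rather than by a uniquely
recoverable formula, and both are configurable. The pseudocount defaults to
1e-3 (added and renormalised); exact-zero semantics require setting it
to 0.

Allele-aware disruption calling restricts the scan to the placements (both
strands) that cover the variant, computes the best hit per allele, and
flags `is_match` when max(s_ref, s_alt) ≥ τ_match (default 0.8) and
`is_disruption` when additionally |s_ref − s_alt| ≥ τ_delta (default 0.2).
The thresholds are reported in output tables; no published values exist for
them, so they are explicit configuration.

## Enrichment

Backgrounds are built by drawing `draw_size` SNPs (default 663, the size of
the enhancer-SNP set being tested) uniformly **without replacement within a
draw**, draws independent of each other, `n_draws` = 200 by default; the
restricted background samples only SNPs inside ≥ 1 biofeature track. Per
PWM, z = (n − μ)/σ with the sample sd (n−1 denominator); σ = 0 yields an
explicit NaN flag, never a silent drop. Empirical intervals use linear
interpolation (Hyndman–Fan type 7, numpy's default) at probabilities
α/2 and 1 − α/2, or α/(2m) and 1 − α/(2m) with a Bonferroni correction
over the m PWMs tested. The published description pairs a "2.75%" lower
quantile with 97.5% for "the 95% confidence interval"; this package reads
the lower value as a typo for 2.5% (both are reachable through `alpha`).
The Shapiro–Wilk normality check on the z vector is reported only — it
never gates the pipeline.

Null behaviour (observed set drawn from its own universe) is verified by
`null_calibration`: containment of the uncorrected 95% interval ≈ 95% and
mean z ≈ 0. Note the z variance under the null is slightly above 1
(≈ 1 + 1/n_draws) because the background mean is itself estimated.

## Peak utilities

`rank_and_cut` offers an explicit top-n cutoff (ties broken by genomic
order, hence idempotent and order-invariant) and a knee detector: peaks are
ranked by descending height, and the elbow of the natural-log height vs
rank curve is the point of maximum perpendicular distance to the chord
joining its endpoints; peaks strictly above the elbow are kept. The log
scale reflects tag counts growing geometrically over background. Constant
heights make the knee undefined and raise an error pointing to top-n.
Peak-set overlap counts a peak as matched when it intersects ≥ 1 bp of the
other set (reported in both directions); a reciprocal-fraction mode is
available. Motif-center profiles average hits (score ≥ threshold, both
strands) in fixed-width bins of motif-midpoint distance from the peak
center.

## Luciferase model

Each well's log luminescence is

    log yᵢ ~ Normal(μᵢ, σ_g(i)),
    μᵢ = L0 + E_e(i) + A_e(i)·Dᵢ + P_p(i) + T_t(i) + B_b(i),

with natural logs throughout. An enhancer *level* is one allelic construct.
Priors (Exp(m) is the exponential with **mean** m):

| block | prior | hyperpriors |
|---|---|---|
| E (enhancer) | t(ν_E, 0, s_E) | ν_E ~ Exp(20), s_E ~ Exp(8) |
| A (androgen) | Cauchy(0, s_A) | s_A ~ Exp(1/2) |
| P (prep) | Normal(0, s_P) | s_P ~ Exp(1) |
| T (transfection) | t(ν_T, 0, s_T) | ν_T ~ Exp(3), s_T ~ Exp(1/2) |
| B (batch) | Normal(0, s_B) | s_B ~ Exp(1) |
| σ_g (noise) | Half-Normal(τ) | τ ~ Exp(1) |

The batch prior mirrors the prep prior — no published prior exists for B,
and a weakly regularising zero-centered normal with its own Exp(1) scale is
the natural choice in this family. The noise sd is shared within
enhancer × condition groups by default ("exchangeable" σ with an Exp(1)
hyperprior admits more than one reading; a global-σ switch is provided).
L0 is implemented as a hard constraint: it is fixed to the empirical mean
of the log negative-control measurements, and the two negative-control
levels have E and A pinned at 0. This keeps the posterior proper and makes
all contrasts invariant to adding a constant to every log measurement.

### Sampling

The sampler works on a transformed space: positive parameters on the log
scale, and the weakly identified nuisance blocks non-centered (P = s_P·P̃
with P̃ ~ Normal(0,1), T = s_T·T̃ with T̃ ~ t(ν_T, 1), B likewise,
σ_g = τ·s̃_g with s̃ ~ Half-Normal(1)). Non-centering removes the
hierarchical funnels that stall samplers when the data barely constrain a
block; E and A stay centered because the plate data identify them directly.

The default backend is Hamiltonian Monte Carlo with an analytic gradient
(verified against finite differences in the test suite), dual-averaged step
size targeting 80% acceptance, jittered path length (1–16 leapfrog steps),
and a diagonal mass matrix re-estimated twice during warmup with
regularisation toward unit mass so a coordinate that barely moved early
cannot freeze itself. Two extra move families are interleaved per
iteration: (a) scalar Metropolis shifts along the design's exact
likelihood-invariant ridges (an enhancer effect against its own preps, a
prep against its transfections, a batch against its transfections), which
traverse in one step directions that short HMC trajectories cross slowly;
and (b) component-wise adaptive Metropolis sweeps over the hyperparameters
and noise scales. A blockwise adaptive random-walk Metropolis backend
(`method="metropolis"`) satisfies the same contract but needs far longer
chains for the same effective sample size.

Convergence is reported, never assumed: split-chain R-hat and ESS (via
arviz) are attached to every posterior, and any reported quantity with
R-hat > 1.05 marks the fit `converged=False`. Chains are seeded from a
single root seed; identical seeds reproduce draws bit-for-bit.

### Contrasts

Basal allelic activity is summarised per draw as exp(E₁ − E₂), DHT
induction as exp(A_e), and the allelic induction ratio as exp(A₁ − A₂);
reports give the posterior mean and the 2.5th/97.5th percentiles on the
fold scale.

## Synthetic data: what it emulates

The haplotype simulator uses a template-copy LD model: all variants of a
block are noisy copies of one template haplotype, each entry independently
resampled with probability m at the template's allele frequency. Two copies
then have correlation (1−m_u)(1−m_v), so a common m gives within-block
r² = (1−m)⁴ and m = 1 − ρ^{1/4} hits a target ρ in expectation; blocks are
independent. The template frequency is drawn once per block from
`maf_range`, so variants within a block share a frequency — a deliberate
simplification that keeps the r² target analytic. Two-population panels
plant (index, proxy) pairs at r² ≈ 0.9 in one or both populations
(`ld_divergence` sets the split), recorded in a `TruthTable`.

Biofeature tracks are Poisson-count uniform intervals; `track_covering`
builds tracks centered on chosen variants so biofeature membership itself
can be planted. PWM libraries draw Dirichlet columns (sharp, flat or
mixed); disruption planting places a variant at a PWM's maximal-weight
position so the matching allele completes the consensus (score exactly 1)
and the alternate allele has frequency ≤ 0.05 there, with flanks
rejection-sampled until the call verifies at the configured thresholds.
Luciferase data are generated from the model's own linear predictor; with
all nuisance effects and noise at zero the log measurements equal it
exactly. The default plate layout is 6 preps per enhancer, 4 transfections
per prep per batch, duplicate wells, both treatment conditions per
transfection, and negative + positive controls on every batch.

What passing these tests shows: the implementation is internally correct
(oracle-equal LD, exact planted recovery, calibrated intervals under the
model's own assumptions). What it does not show: performance under real
human LD (variable block structure, allele-frequency spectra), real
chromatin track statistics, PWM misspecification, or reporter-assay
non-normality — none of which the generators emulate.

## Problem sizes and calibration experiments

The packaged experiments run at sizes chosen to keep the full suite on one
CPU comfortable while leaving estimates precise enough to be meaningful:
LD-oracle comparison on 100 random panels (≤ 50 variants, ≤ 202
haplotypes); end-to-end planted recovery on a 20 Mb genome with 20 proxy
pairs at 1,200 haplotypes; bootstrap-null calibration with 500 replicates
of 200 draws × 663 SNPs on a 20,000-SNP universe with 20 PWMs; and
simulation-based calibration with 50 replicates at a reduced plate design
(two allelic constructs, 3 preps, 2 transfections, 2 batches, duplicates),
2 chains × 1,000 iterations each. Heavy-tailed prior draws in the SBC are
redrawn beyond fixed caps (|A| ≤ 8, |E| ≤ 15, scale caps of a few units) so
simulated luminescence stays finite; the caps sit far out in the tails and
the generative-versus-inference prior mismatch they introduce is small
relative to the binomial error of a 50-replicate coverage estimate.

## Known limitations

- The r² estimator requires phased biallelic data; no EM fallback.
- Motif scores are not calibrated to p-values; thresholds are score-scale.
- Short HMC chains at the reduced design can leave R-hat above 1.05 for
  group noise scales in extreme prior-drawn regimes; such fits are flagged
  rather than hidden, and coverage of the reported contrasts is verified by
  the calibration experiment.
- The L0 constraint treats negative-control variability as noise around a
  fixed reference rather than propagating it; allelic contrasts are
  unaffected by construction.
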