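# riskenhancer

Post-GWAS functional annotation of **risk enhancers** — the regulatory
variants that tag along with disease-associated index SNPs. Most GWAS hits
for solid tumours (the motivating case is prostate cancer) fall outside
coding sequence; the causal variant is usually not the reported index SNP
but one of its linkage-disequilibrium proxies sitting in cell-type-specific
enhancer chromatin, where a single-base change can rewire a transcription
factor response element. `riskenhancer` implements that annotation chain as
a tested, importable Python library:

1. **LD proxies** (`riskenhancer.ld_annotation`) — for each index SNP, scan
   a 1 Mb window (index ± 500 kb) of a phased haplotype panel per reporting
   population and keep variants with r² ≥ 0.5, where
   r² = D²/(p_A p_a p_B p_b) is computed by direct haplotype counting.
   Intersect survivors with chromatin biofeature tracks (DNase I, histone
   marks, TF ChIP-seq peaks), classify them (coding exon > miR-target UTR >
   promoter [−1000, +100] bp around a TSS, strand-aware > enhancer), merge
   index SNPs into risk loci, and cluster the SNP × biofeature matrix.
2. **Motif disruption** (`riskenhancer.pwm`) — a positionally-weighted,
   consensus-normalised PWM match score
   `s(seq) = ∏ᵢ (fᵢ[seqᵢ] / maxᵦ fᵢ[b])^{wᵢ}` in [0, 1], with weights
   `wᵢ = ICᵢ / max ICⱼ` from per-position information content. A SNP
   *disrupts* a response element when one allele scores ≥ τ_match and the
   allelic score difference is ≥ τ_delta — separating functional candidates
   from SNPs that merely fall inside a binding site.
3. **Enrichment** (`riskenhancer.enrichment`) — per-PWM z statistic
   `z_f = (n_f − μ_f)/σ_f` against backgrounds built from 200 random draws
   of 663 SNPs (unrestricted, or restricted to the same biofeatures),
   empirical 95% bootstrap intervals on each PWM's count, and a Bonferroni
   correction applied to the quantile probabilities.
4. **Reporter-assay model** (`riskenhancer.luciferase`) — a hierarchical
   Bayesian model of log luciferase luminescence,
   `log yᵢ ~ Normal(L0 + E_e + A_e·Dᵢ + P_p + T_t + B_b, σ_g)`,
   with enhancer (E), androgen-response (A), plasmid-prep (P), transfection
   (T) and plate-batch (B) effects; E has a Student-t prior with
   exponentially distributed df (mean 20) and scale (mean 8), A a Cauchy
   prior with Exp(1/2) scale, and L0 is pinned to the mean of the
   negative-control data. Fitting is by Hamiltonian Monte Carlo with an
   analytic gradient (an adaptive-Metropolis backend is also provided);
   allelic effects are reported as posterior fold contrasts
   `exp(E₁ − E₂)` and `exp(A₁ − A₂)` with 95% credible intervals.

`riskenhancer.synthetic` generates every input with known ground truth
(block-LD haplotype panels, two-population panels with planted proxy pairs,
biofeature tracks, PWM libraries with planted allele-disrupting SNPs,
plate-structured luciferase data), and `riskenhancer.peaks` covers the
ChIP-seq peak-list utilities (top-n / knee tag-density cutoffs, peak-set
overlap, motif-density profiles around peak centers).

## Worked example

`examples/05_luciferase_model.py` simulates a two-allele enhancer plate
experiment (6 preps, 4 transfections per prep per batch, 2 batches,
duplicate wells, negative and PSA positive controls) and fits the model:

```
simulated 480 wells (5 constructs, 2 conditions, duplicates)
max split R-hat 1.060 (NOT converged)
basal JAZF1_G / JAZF1_A            1.31-fold  (95% CI 1.25-1.37)
induction JAZF1_G                  5.56-fold  (95% CI 5.35-5.78)
induction JAZF1_A                  6.86-fold  (95% CI 6.59-7.14)
induction ratio JAZF1_A / JAZF1_G   1.23-fold  (95% CI 1.17-1.30)

empirical basal contrast in this dataset: 1.31-fold (generative value 1.40)
```

The G allele is 1.31× more active than A at baseline in this dataset
(matching the empirical geometric-mean contrast of the simulated wells);
both alleles respond strongly to androgen, and the A allele's induction
exceeds G's by 1.23× — the same style of allele-specific readout used to
characterise regulatory GWAS variants. The R-hat line is an honest
convergence flag: any reported quantity above 1.05 marks the posterior as
not fully converged. The other scripts in `examples/` walk through LD-proxy
discovery, functional classification, motif-disruption calling, enrichment,
and peak utilities in the same style; each prints what it computes and what
the numbers mean.

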