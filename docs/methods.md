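# Methods

## Scope and model

`cubkit` analyses codon usage bias in sets of protein-coding sequences,
typically one organellar genome's filtered CDS complement at a time. The
analysis set is the 59 synonymous codons of the 18 amino-acid families with
degeneracy ≥ 2; Met (ATG), Trp (TGG) and the stops (TAA/TAG/TGA) carry no
synonymous choice and are excluded. Six-codon amino acids (Leu, Ser, Arg)
are treated as single six-fold families, so the degeneracy classes are
9 × 2-fold, 1 × 3-fold (Ile), 5 × 4-fold, 3 × 6-fold. The standard code and
the bacterial/plastid code (NCBI table 11) are identical over these
assignments; alternative start codons permitted by table 11 are irrelevant
because filtering demands an ATG start.

## CDS filtering

A sequence passes if it is ≥ 300 nt, divisible by 3, starts with ATG, ends
with a stop, contains no internal stop and no ambiguous base. GenBank CDS
features are spliced and strand-corrected; fuzzy-boundary features are
rejected as partial (FASTA entries carry no location metadata and skip this
check). A multiply-faulty sequence is tallied under the first failing check
in the fixed order partial → frame → length → start → stop → internal stop →
ambiguity, so rejection tallies are well defined. Genes duplicated by
repeat regions are not deduplicated: counts are feature-level. The terminal
stop contributes to sequence length and to the all-codon GC dialect but
never to the 59-codon statistics.

## Composition dialects

Two conventions coexist deliberately, matching the two tool families used
in this literature. Third-position base fractions A3/T3/C3/G3 and GC3s are
computed over the 59 synonymous codons (codonW convention; a flag switches
to raw third positions). Positional GC (GC, GC1, GC2, GC3) is computed over
all codons of the CDS including start, stop, Met and Trp (EMBOSS cusp
convention). GC12 = (GC1 + GC2)/2. Genome-level values are computed on
pooled filtered-CDS codon counts, not on whole-genome sequence, and equal
the count-weighted means of per-gene values.

## Indices

**RSCU.** For codon j in a family of degeneracy k with family total N:
RSCU_j = x_j /(N/k). Observed families sum to k; unobserved families carry
an all-zero sentinel and are flagged.

**ENC.** Per family with n ≥ 2 codons, the bias-corrected homozygosity is
F̂ = (n Σp̂² − 1)/(n − 1). Class means F̄_k over usable families (n ≥ 2 and
F̂ > 0) enter ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61. A fully
missing three-fold class is imputed as the mean of the available two- and
four-fold means; any other fully missing class falls back to the pooled
mean of all usable family homozygosities (the number of such imputations is
reported). If no family is usable the statistic is undefined.

**CAI.** Geometric mean of relative adaptiveness w over the gene's analysis
codons. The reference set defaults to the genome's own low-ENC decile:
pooled RSCU scaled so each family's maximum is 1, with a floor of w = 0.01
for unobserved codons. No foreign-organism reference is bundled — reported
CAI values are therefore self-contained and comparable within a genome, not
across published tables that used external references.

**CBI.** With N_tot the codons in families containing at least one
designated optimal codon, N_opt the optimal-codon occurrences, and N_ran
the expectation under uniform within-family usage,
CBI = (N_opt − N_ran)/(N_tot − N_ran) ∈ [−1, 1]. The optimal set defaults
to the genome's own identified optimal codons.

**Optimal codons.** Genes are ranked by ENC with lexical tie-breaks; each
decile group holds ⌈0.10 n⌉ genes. The low-ENC decile is read as the
putative high-expression group (strong bias ⇒ high expression), which makes
ΔRSCU = RSCU_high − RSCU_low positive for preferred codons; a switch
reverses the mapping. Optimal codons satisfy RSCU > 1 in the high group's
pooled RSCU (a switch evaluates whole-genome RSCU instead) and
ΔRSCU > 0.08. Pooled-group RSCU is used rather than means of per-gene RSCU.

An identifiability caveat worth knowing: in extremely AT-rich genomes
(GC3s ≈ 0.08) mutation alone pushes two-fold-family RSCU near 2.0, leaving
less headroom than the 0.08 ΔRSCU threshold, so genuinely preferred codons
in two-fold families can be undetectable over decile sampling noise. The
recovery experiments therefore run at moderate composition (GC3s 0.30).

## Selection diagnostics

The ENC plot compares per-gene ENC with the mutation-only expectation
ENC_exp(s) = 2 + s + 29/(s² + (1 − s)²) at s = GC3s; the rendered curve is
sampled at 0.001 steps. The ENC ratio (ENC_exp − ENC_obs)/ENC_exp is
histogrammed in half-open bins aligned to zero (default width 0.05). PR2
plots A3/(A3 + T3) against G3/(G3 + C3); the default uses the synonymous-59
third-position fractions, with the classical four-fold-degenerate-site
variant available (only the four-fold variant is exactly centred at
(0.5, 0.5) under symmetric mutation, because two-fold families constrain
which third bases can occur). Genes with a zero PR2 denominator are
excluded from the plot and flagged, not errored.

The neutrality regression is OLS of GC3 on GC12 (x = GC12), following the
axis assignment this literature states; the conventional reversed
orientation is available and recorded in output metadata, since the two
slopes differ. 100 × slope is reported as the mutational share of the
influence and the remainder as selection.

## Correspondence analysis

CA of the genes × 59 RSCU matrix (a switch accepts raw counts): with P the
matrix scaled to sum 1 and margins r, c, the residual
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2} is decomposed by SVD; principal
coordinates are the singular vectors scaled by D^{−1/2} and the singular
values; axis k carries inertia σ_k², and total inertia equals the matrix
chi-square over its grand total. All-zero columns are dropped with a log
entry. Axes are sign-indeterminate: the default orientation makes the
largest-magnitude column loading positive, and the pipeline additionally
reflects Axis 1 so its correlation with GC3s is non-negative, making
correlation signs reproducible. Axis-1 correlations against GC1, GC2, GC3,
GC3s, GC, CAI, CBI, ENC and protein length are reported with both Spearman
(default, robust to the non-normal indices) and Pearson coefficients, raw
two-sided p values, and Benjamini-Hochberg adjusted p values alongside.

## Synthetic genomes

The generator emulates the statistical structure the diagnostics read,
with defaults chosen as the conditions of AT-rich green-algal chloroplast
genomes: 44 genes (typical filtered complements run 37–46), lengths
300–1503 nt, GC3s target 0.08, GC12 target 0.33, a planted neutrality
slope of 0.37, uniform amino-acid family frequencies and 2% Met/Trp.
Selection features default to off and are planted explicitly.

Each gene is ATG + sense codons + a uniform-random stop, so generated data
pass every filter by construction. A per-gene latent mutational drive
u ~ U(−1, 1) sets targets GC12 = μ₁₂ + σ·u and GC3 = μ₃ + slope·σ·u. The
GC12 target is hit by an exponential tilt on family frequencies (solved by
bisection on the exact expectation; family counts are then fixed by
largest-remainder rounding so realized GC12 carries almost no sampling
noise), and the GC3 target by a third-base weight t shared by all families
(again bisected on the exact expectation, which absorbs the restricted
third-base alphabet of Ile). High-bias genes multiply a planted codon's
weight by e^bias on top of this mutational background — deliberately not
re-solved, so selection shifts composition away from the mutational
expectation exactly as the diagnostics assume.

What the generator does not emulate: real gene-length/function
correlations, amino-acid composition differences between genes, strand
asymmetry, or evolutionary covariance along a phylogeny. Passing tests
demonstrate correctness of the statistics and recoverability of planted
structure, not that real genomes satisfy the diagnostics' assumptions.
Two known small artefacts: the fixed codons (start, stop, Met, Trp) give
the all-codon GC dialects a weak common dependence on gene length, which
adds a few-hundredths negative offset to recovered neutrality slopes at
mixed gene lengths (within two standard errors at the tested sizes); and
realized GC3s at the extreme AT-rich default wanders ±0.01 from target at
genome scale.

## Numerical choices and problem sizes

Bisections run 60 halvings (residuals ≪ sampling noise). ENC-curve
consistency is asserted within 2.5 effective codons, covering multinomial
sampling noise plus the known approximation gap between the analytic curve
and finite-length null genes (the three-fold family and the 61-cap each
contribute up to ~1 unit). Slope recovery uses 20 replicate genomes of 44
genes (900–1500 nt) per planted value and asserts agreement within two
standard errors of the replicate mean. Optimal-codon recovery uses one
44-gene genome, 20% high-bias class, bias strength 8 — conditions under
which exact recovery was observed across a 30-seed scan. CA equivalence is
checked to 1e-8 against a brute-force eigendecomposition of SᵀS on 6 × 8
matrices. Decile ties are broken lexically; all random processes run on
seeded NumPy generators, and a fixed seed reproduces outputs byte for byte.
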