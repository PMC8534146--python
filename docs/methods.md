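# Methods

## The model

The genome is treated as a 1D sequence of alternating forest (F, CGI-dense)
and prairie (P, CGI-poor) domains; chromatin organization is summarized by
how much same-type domains contact each other in cis Hi-C relative to
cross-type contact. All statistics are ratios of sums of normalized
contacts, so they are invariant under global scaling of the matrix and
insensitive to sequencing depth to first order.

### Contact preprocessing

Matrices are dense, symmetric, per-chromosome. Bins with a zero raw
marginal are masked before balancing (standard practice). ICE iterates
`b_i ← b_i · s_i / mean(s)` on unmasked row sums until the maximum relative
deviation of row sums is below `tol` (default 1e-5, ≤ 200 iterations),
then rescales to mean unmasked row sum 1; non-convergence is returned with
a flag and a warning rather than an error. Distance normalization divides
each diagonal by its mean over unmasked pairs; zero-mean diagonals stay
zero, making the operation idempotent. Normalization states form a one-way
chain raw → ICE → distance and are enforced: segregation ratios consume
ICE matrices, compartment statistics consume distance-normalized ones.

### Pair-counting conventions

The defining index ranges are read literally: same-type numerators run
over ordered pairs (each unordered F–F pair counts twice), cross-type sums
count each unordered pair once. Because every downstream comparison is
ratio- or rank-based, the convention only needs to be fixed, and it is.
Domain lengths in the `D_ij` denominator are counted in unmasked bins of
the matrix grid, so `D_ij` is a mean per-bin-pair contact; intra-domain
entries are stored but flagged and excluded from all ratios. The overall
ratio ORs uses the cancelled form (same-type sum over cross-type sum):
the shared denominator of the published two-step definition cancels
exactly, regardless of whether it includes intra-domain terms. Sums pool
across chromosomes before division when multi-chromosome tables are
concatenated; only cis matrices are processed.

### TC10 and the critical distance

At each offset d the ⌈0.1·n_d⌉ largest diagonal entries are selected among
pairs whose endpoints are both labeled and unmasked, with ties at the
cutoff broken by ascending bin index (deterministic output). If any
selected entry is zero the triple is (0,0,0). The critical genomic
distance is the largest offset with a nonzero triple; if zero triples
occur below it (interleaving), the result carries an `interleaved` flag
rather than a silent choice between readings.

### Threshold calibration and seg/mix calls

`T = max(|Q(0.975)|, |Q(0.025)|)` of replicate DRs log-ratios with linear
quantile interpolation, over domains with positive DRs in both replicates
(≥ 40 required). Calls use the symmetric band: seg above +T, mix below −T,
neutral inside, undefined when either DRs is zero or missing; undefined
domains are excluded from fractions, calibration and Ror counts. The
calibration's *false-positive rate* is defined per call direction: the
threshold sits at the 2.5% tail of the very null distribution the calls
are compared against, so the per-direction null call rate is nominally
2.5% (and the two-sided rate 5% by construction — a two-sided bound below
5% would be incoherent for a 2.5%-tail threshold).

### Compartments

PC1 is the leading eigenvector of the Pearson correlation matrix of the
distance-normalized matrix (masked and zero-variance bins removed, ≥ 20
usable bins required), sign-oriented so above-median-CpG bins have
positive mean PC1; A = PC1 > 0. The C-index includes all defined bins j in
its sums (self included, as the definition is written); bins with zero
contact to either class are undefined. Domain-level compartment assignment
for multi-bin prairie domains is the majority of member-bin calls with
ties going to B — the conservative default, since B is the silent
environment; this majority rule is this package's choice, as no rule for
multi-bin domains is implied by the per-bin definitions.

### Methylation

Open sea = genome minus CGIs padded by 2 kb shore + 2 kb shelf per side
(field convention). Per-domain q is the unweighted mean methylation
fraction over open-sea CpGs with coverage ≥ 3; at least 10 such CpGs are
required (coverage weighting is deliberately not used — the coverage
filter already removes low-confidence calls). MDI is undefined at
chromosome ends, when any flank's q is undefined, and when the q triple is
all zero. Per-sample summaries report mean |MDI| per domain type, with
signed means alongside for transparency; group comparisons use two-sided
two-sample t-tests and aging trends a least-squares slope of mean |MDI| vs
age.

### Expression

Entropy is computed in bits over relative expression across the given
samples (0·log 0 ≡ 0). Selection uses H < 1.7, FPKM_target ≥ 1
(non-strict), relative expression > 1/7 (strict) and target > reference
(strict), matching the stated inequalities exactly; gene→domain assignment
is by TSS point-in-interval, with genes outside all domains dropped and
counted. Relative expression is the same p vector the entropy uses.

## The synthetic world

The generator's defaults are the stated analysis regime, fixed a priori:
20 alternating domains of 5–15 bins at 40 kb; contact decay exponent
α = 1; same-type affinity s = 1 (expected contact ∝ (d+1)^(−α)·(1+s) for
same-type pairs); negative-binomial dispersion 0.1 (Hi-C overdispersion;
Poisson at 0); depth 10⁶ expected counts; CGIs every 20 kb in forests and
every 500 kb in prairies; methylation Beta-distributed with concentration
50 around m_F = 0.75 / m_P = 0.55 and Poisson(30) coverage at 2-kb CpG
spacing; 8 expression samples, 500 genes, 10% tissue-restricted at 10×
background with 78.5% of genes in forests (the genomic gene distribution).

Tissue-restricted genes keep only a 2% leakage fraction of background
expression off-target. This is what "lineage-specific" means operationally:
a gene with full background expression in all 8 samples and a 10× boost in
one has entropy ≈ 2.1 bits and would *never* pass the 1.7-bit threshold —
restriction, not amplification, is what the entropy filter detects. The
multiplier → ∞ limit still drives H → 0 either way.

What the generator does not emulate: TADs and loops, trans contacts,
mappability and GC bias, replicate-structure in coverage, realistic gene
length/isoform structure, or CpG-density variation within a domain type.
A green recovery test therefore establishes correctness of the statistics
under the stated block model, not robustness to every artifact of real
embryo data; the published embryo-scale values themselves require the
original GEO datasets and are out of desk-scale reach.

## Numerical choices

- Ror is computed as `ln(n_ij) − ln(n_ji)` so antisymmetry under sample
  swap holds to the last ulp; one-sided counts give ±inf with a warning.
- Bin labeling uses majority overlap with exact ties going to the domain
  containing the bin start.
- Median splits for CpG/SINE classes are strict (> median); all-equal
  tracks are rejected as degenerate rather than split arbitrarily.
- Short-domain merging in the CGI partition absorbs the shortest offender
  into its longer neighbor, coalescing same-label runs, until all domains
  reach the minimum length.
- LAD membership requires ≥ 50% bp overlap (unstated in the source
  analyses; fixed here and exposed as a parameter).
- Degenerate inputs fail loudly: all-zero matrices, zero cross-type
  contact, single-compartment tracks and < 40-domain calibrations raise
  errors instead of returning silent zeros.

## Known limitations

- Only cis matrices; no sub-compartments, TAD calling or saddle analysis.
- The CGI-gap partition heuristic (50 kb gap, 1 Mb minimum) is a
  reproducible stand-in for the original published partition, not a
  re-derivation of its exact coordinates; precomputed F/P BED files are
  the authoritative input path.
- Matrix I/O is text-based (sparse triplets / dense); binary cooler
  containers are not read in this environment.
- Functional enrichment of gene sets and 3D structure modeling are out of
  scope.
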