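# Methods

This note records the statistical models the package implements, the
defaults it fixes where the field's tooling conventions leave choices open,
and what the synthetic-data generators do and do not emulate.

## Data model

Genotypes are diploid biallelic dosages x ∈ {0, 1, 2} counting copies of
allele B, with a dedicated missing code (never NaN or −9 inside the data
model; PED serialization writes `0 0`). Allele B is the minor allele at
load time; every downstream statistic recomputes allele frequencies on the
current sample subset, so the arbitrary orientation is harmless. Coordinates
are 1-based (PLINK convention). Merging two panels reconciles codings by
allele-set comparison: identical sets keep or swap-recode (x → 2−x);
sets that match only after complementation are strand-flipped;
A/T and C/G SNPs are dropped because PED/MAP carries no strand column and
their orientation is undecidable; anything else is dropped as
irreconcilable. Every drop is reported.

## Quality control

The cascade order is fixed and documented so removal counts are
reproducible: (1) genotype-score masking (GC/GT < 0.5 → missing),
(2) autosomes only (labels "1".."26" for sheep), (3) sample call rate
≥ 0.9, (4) SNP call rate ≥ 0.9, (5) MAF ≥ 0.05, (6) exact HWE p ≥ 10⁻⁶ on
the pooled sample, (7) LD pruning. Rates are recomputed after each step,
never cached, which makes the cascade idempotent. For merged multi-breed
("worldwide") panels the HWE step is disabled: strong Wahlund effect would
otherwise discard large numbers of genuinely polymorphic markers.

The HWE test is the exact conditional test: given allele counts, the
probability of a heterozygote count h is ∝ n!·2ʰ/(n_AA!·h!·n_aa!), and the
two-sided p-value sums the masses of all h no more probable than observed.
Log-gamma arithmetic keeps it stable at any n; it matches full rational
enumeration to < 10⁻¹² on every table with 2n ≤ 30 (tested).

LD pruning follows the sliding-window convention (window 50 SNPs, step 5,
r² > 0.5): within each window, while any kept pair exceeds the threshold,
the member with the smaller MAF is removed (tie → the SNP later in map
order; pairs scanned in map order). The removal rule is our determinism
choice; the window/step/threshold triple is standard.

## Relatedness

The relationship matrix is the frequency-standardized (GRM/UAR) estimator:
off-diagonal A_jk = mean over SNPs of (x_j−2p)(x_k−2p)/(2p(1−p)), diagonal
A_jj = 1 + mean of (x²−(1+2p)x+2p²)/(2p(1−p)). Under missingness a SNP
contributes to a pair only when both genotypes are present and each pair is
averaged over its own usable-SNP count (per-pair, not global — the
alternative convention is noted as equally defensible). Monomorphic SNPs
are rejected with a pointer to MAF filtering.

Pruning removes one member of each pair with relationship > 0.25: greedily,
from the worst pair, the member with more above-threshold partners (ties:
lower call rate, then later input order). Exhaustive search on small
matrices confirms the greedy result is near-minimal.

Outlier flagging is deliberately simple and exposed as a parameter because
no standard definition exists: a sample is flagged when its terminal branch
on the NJ tree of 1−IBS distances exceeds k (default 3) times the median
terminal branch of its own population; populations with < 3 members are
skipped with a warning.

## Diversity and differentiation

- Unbiased expected heterozygosity uses the small-sample correction
  H_E = (2n/(2n−1))·(1−Σp²) per locus (n = genotyped diploids), averaged
  over loci.
- Rarefied allelic richness is the hypergeometric expectation
  A_R = Σ_alleles [1 − C(N−N_i, g)/C(N, g)] at a common draw depth g,
  defaulting to the minimum per-population per-locus allele count so a
  single g serves the whole table. For biallelic arrays 1 ≤ A_R ≤ 2.
- FST is Weir & Cockerham's θ from the a/b/c variance components, combined
  across loci as a ratio of sums (the estimator's recommended form).
  Small negative values are retained everywhere except as network input.
- Nei's distance is the 1972 standard form D = −ln(J_xy/√(J_x·J_y)) with
  gene identities summed over loci; J_xy = 0 yields +∞ with a warning,
  never a silent clamp.

On Balding–Nichols simulations with two populations (n = 50, L = 5000) the
mean θ over 20 replicates recovers target F ∈ {0.01…0.2} within 10 %
relative error (tested).

## Structure

IBS distance is 1 − mean[(2−|x_i−x_j|)/2] over pairwise-complete loci.
Classical (Torgerson) MDS double-centers the squared distances and embeds
on the top positive eigenpairs (default 4 dimensions). Variance fractions
divide each eigenvalue by the sum of **positive** eigenvalues only;
negative eigenvalues of non-Euclidean IBS matrices are excluded from the
denominator — stated explicitly because tool conventions differ. Each
dimension's sign is fixed (largest-magnitude loading positive) so output is
reproducible.

## Admixture

The model: x_il ~ Binomial(2, Σ_k Q_ik F_kl) with Q rows on the simplex.
We maximize the likelihood by exact EM rather than quasi-Newton block
relaxation: the same model and stationary points, with guaranteed monotone
log-likelihood, which makes correctness testable. Defaults: tolerance 10⁻⁶
log-likelihood units, max 2000 iterations, F clamped to [10⁻⁶, 1−10⁻⁶],
seeded Dirichlet/uniform initialization (the seed is mandatory for every
stochastic entry point). K = 1 is solved in closed form. Cluster labels
carry no inherent order; `align_labels` provides the exhaustive
permutation alignment consumers need.

Cross-validation masks individual non-missing genotype entries (seeded fold
assignment, 5 folds by default), refits on the remainder, and scores masked
entries by squared deviation from the fitted expectation 2·Σ_k Q_ik F_kl.
The loss is our fixed choice; loci left with no training data in a fold are
skipped with a warning. On two-population data CV error at K = 2 beats
K = 1, and on strongly drifted K = 3 data the sweep's argmin selects 3
(tested across seeds).

## LD-based Ne and NeC

Adjusted LD is r²_adj = r² − 1/n (unphased-genotype sample-size
correction, n = pairwise-complete samples), averaged within physical
distance bins (default: 30 log-spaced bins, 50 kb–10 Mb, ≥ 30 pairs per
bin; intra-chromosomal pairs only). Each bin inverts
E[r²_adj] = 1/(α + 4·Ne·f(c)) to Ne = (1/(4·f(c)))·(1/r̄²_adj − α), with
α = 2.2 absorbing mutation and c the genetic distance at the bin midpoint;
the bin is assigned to t = 1/(2·f(c)) generations before present, so 1 Mb
at the default 1 cM/Mb probes ~50 generations (the Ne50 convention; Ne5 is
the point nearest t = 5). The inversion is exact: feeding the model
expectation recovers Ne to 10⁻⁹. The distance → recombination-rate mapping
f is pluggable; identity is the default and Haldane's map function is
provided as an alternative. Non-positive Ne estimates (r̄²_adj ≥ 1/α) are
dropped with a log message.

NeC divides each neighboring-segment slope (Ne_{i+1}−Ne_i)/(t_{i+1}−t_i)
by the median Ne of the (default 20) most recent estimates; positive values
mean decline toward the present. Segments ranked by |nec| (ties → earlier
generation) localize sudden size changes. The statistic is exactly
scale-equivariant and a planted 50 % step between generations 8 and 9 puts
the top segment at t_mid = 8.5 on deterministic trajectories.

For bottleneck scans on real-scale data, LD at genetic distance c reflects
an exponentially weighted harmonic mean of historical Ne centered near
t = 1/(2c), so a sharp step appears as a smooth rise and single-chromosome
trajectories are slope-noisy. The package's convention for NeC scans is
therefore: pool LD bins across replicate chromosomes
(`pool_ld_bins`; chromosomes are simulated or analyzed as separate runs),
and place trajectory points on a 2-generation grid across the recent window
(t ≈ 5–21). With 10 pooled 1-Morgan chromosomes of ~2500 SNPs and 60
sampled diploids, an 80 % crash at generation 8–9 (N 500 → 100) puts the
top |nec| segment within t ∈ [6, 11] in the large majority of seeds
(tested, majority of 5 required). Finer grids divide a nearly linear rise
into segments whose ranking is decided by noise — a real limitation of
slope-based change detection on LD trajectories, inherited from the
smoothing in the LD–Ne relation itself.

## Synthetic data

Balding–Nichols: population k's frequency at each locus is
Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) around an ancestral p ~ U(0.05, 0.95);
dosages are Binomial(2, p_kl), or Binomial(2, Σ_k Q_ik·p_kl) for admixed
individuals with Dirichlet or user-supplied Q. F = 0 uses p directly. The
generator matches the target moments (mean p, variance F·p(1−p)) and the
realized θ tracks F (tested). It produces unlinked loci, so it exercises
FST/MDS/admixture but not LD-based stages.

Forward Wright–Fisher: discrete generations, uniform biparental choice with
selfing, Haldane (Poisson) crossovers on one chromosome, piecewise-constant
N(t) schedules, optional symmetric mutation, loci initialized at uniform
frequencies and filtered to those segregating at sampling. Forward (not
coalescent) simulation was chosen so abrupt schedule steps in the last ~15
generations are exactly controllable. Default scales (N ≤ 500, L ≤ 3000,
≤ 300 generations, 1-Morgan chromosome) keep every check desk-sized;
heterozygosity decays as H₀(1−1/(2N))ᵗ and constant-N runs recover N within
a factor of 2 from LD (tested).

Neither generator emulates ascertainment bias of real SNP chips, mutation
model realism, migration, or sex chromosomes — passing tests demonstrate
estimator correctness under the assumed models, not robustness to those
real-data features.

## Networks

Neighbor joining is the standard Q-criterion agglomeration with
deterministic tie-breaking (lexicographically smallest cluster-id pair) and
deterministic Newick output (children ordered by smallest descendant leaf);
negative branch lengths are retained unless clamping is requested. It is
exact on additive metrics (tested, 100 random 8-taxon trees, 10⁻⁹).

Neighbor-net agglomerates clusters of one or two linked nodes: cluster
pairs by the NJ Q-criterion on average distances, node pairs within the
chosen clusters by the analogous node-level criterion, with the 3-point
reduction d(u,·) = ⅔d(a,·)+⅓d(b,·), d(v,·) = ⅔d(c,·)+⅓d(b,·) recorded and
later expanded to the circular taxon ordering. Split weights are estimated
by non-negative least squares of all n(n−1)/2 circular splits against the
input distances (active-set NNLS); unconstrained least squares with
truncation was rejected because it breaks distance reproduction.
Zero-weight splits are dropped; negative input entries (FST artifacts) are
clamped to 0 with a warning at network input only. On tree metrics the
splits equal the tree's with weights equal to branch lengths; on circularly
decomposable metrics the induced distances reproduce the input (both
tested, 10⁻⁶). NEXUS output uses TAXA + SPLITS blocks with the CYCLE
statement, loadable by split-network viewers, and round-trips through the
bundled parser.

## Pipeline

`popgen run` executes QC → relatedness → diversity/FST → MDS → admixture
sweep → Ne/NeC → networks from one YAML config. All stage randomness
derives from a single seed via per-stage sub-seeds, making the whole run a
pure function of (inputs, config, seed); two runs with the same seed are
byte-identical in their numeric outputs (tested). Worldwide-merge mode
switches the HWE step off automatically. The run report echoes the config
and per-stage record counts.

## Known limitations

- The rarefaction depth g and several upstream-tool conventions (MDS
  variance denominator, SNeP's exact binning and corrections, SplitsTree's
  least-squares variant) are not uniquely standardized across tools; this
  package fixes and documents its own defaults, so numeric agreement with
  any particular external tool is approximate.
- The Ne estimator assumes drift–recombination equilibrium within each
  bin's time horizon; very recent estimates (t < ~4) are biased by sample
  size, and trajectory smoothing limits the time resolution of NeC peaks
  (see above).
- Admixture EM converges to local optima; multiple seeded restarts are the
  caller's responsibility for difficult K.
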