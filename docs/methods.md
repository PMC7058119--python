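# Methods

This note documents the statistical model, the algorithmic choices made
where the design was genuinely open, the synthetic-data generator, and
the known limitations. Notation: a segment j has tumor read count Dˢⱼ,
normal read count Dᴺⱼ, GC fraction gⱼ, and Kⱼ heterozygous SNPs with
B-allele count bⱼₖ out of depth dⱼₖ; φⱼ is its subclonal frequency, Cᵀⱼ
its absolute copy number with allele genotype (n_P, n_M), and
C̄ⱼ = φⱼCᵀⱼ + (1−φⱼ)·2 its population-average copy number.

## Observation model

**Read counts.** Tumor counts are Poisson conditioned on the observed
normal count:

    Dˢⱼ | Dᴺⱼ ~ Poisson( Φ⁻¹(C̄ⱼ/2 · ϑ, gⱼ) · Dᴺⱼ )

where ϑ is the baseline ratio anchor (below) and Φ/Φ⁻¹ the GC-bias
correction pair. Φ is log-linear: log ratio shifts by slope·(g − g₀)
around a length-weighted reference GC g₀; slope and intercept come from
one ordinary least-squares pass on log(Dˢ/Dᴺ) against GC over all
segments with one round of 3-MAD residual trimming (copy-altered
segments are outliers of the trend; trimming keeps them from tilting
the slope). Φ and Φ⁻¹ are exact algebraic inverses. The model is
deliberately minimal — one slope — because ratio *differences* between
segments are what inference consumes; wave/mappability effects are out
of scope.

**B-allele frequencies.** The expected BAF is
μ̄ = (φ·Cᵀ·μᵀ + (1−φ))/C̄ with μᵀ = n_M/Cᵀ (for Cᵀ = 0 the tumor term
vanishes; the code encodes that explicitly rather than defining μᵀ).
Because the B allele sits on either haplotype with probability 1/2 and
no phasing is attempted, the observable is the *folded* count
b̂ = min(b, d−b), modelled by the folded binomial

    P(b̂ = x) = Bin(x; d, p) + Bin(d−x; d, p)   (x < d/2;  single term at x = d/2)

with p = min(μ̄, 1−μ̄). Two remarks. First, this is exactly the
per-SNP orientation mixture ½Bin(d, μ̄) + ½Bin(d, 1−μ̄) pushed through
the folding map, i.e. the two BAF orientations are summed per locus.
Second, the folding matters quantitatively: the folded count's mean
lies *below* p (≈ 0.43 at p = 1/2 and 30× depth), so scoring the folded
count with a plain binomial systematically rewards solutions with
smaller folded BAF — measured at ~9 nats of spurious preference for a
wrong low-frequency solution on a benchmark segment. The sampler's hot
path evaluates the per-segment folded-binomial sum through a cached
4001-point table in p with linear interpolation (absolute error below
~1e−6); scalar entry points compute it exactly.

**Copy-number support and priors.** The corrected ratio against ϑ gates
the support: {0, 1, 2} below ϑ, {2, …, C_max} at or above it (both
branches contain the neutral Cᵀ = 2, so the equality convention is
unbiased; C_max defaults to 15). Cᵀ is uniform on its support. Given
Cᵀ, the genotype is uniform over the Cᵀ+1 multisets of P/M alleles —
an *unweighted* genotype sum would act as an improper prior
proportional to Cᵀ+1 and measurably drag near-diploid segments toward
large-Cᵀ, tiny-φ solutions. Mirrored genotypes are both retained (they
give identical folded likelihood; the ladder stays literal).

**Marginal segment likelihood.** At a given φ the read-count and BAF
terms are summed over the (Cᵀ, genotype) lattice in log-sum-exp form.
A segment with no SNPs contributes its read-count marginal alone.

## Baseline detection and ϑ

A segment is copy-neutral when (i) its mean folded BAF matches the
*finite-depth null* — the exact expectation of min(b, d−b)/d under
Binomial(dₖ, 1/2) computed from its own SNP depths — within `baf_tol`
(default 0.03), and (ii) its mean SNP depth is within `depth_tol`
(default 0.05, relative) of the expected copy-neutral depth. The null
comparison is essential: testing the folded statistic against 0.5
directly rejects every true baseline at realistic depth. The depth
criterion removes balanced non-neutral states (a diluted homozygous
deletion, PPMM, …) whose BAF is also 1/2; 0.05 keeps true baselines
(per-segment mean-depth SE is ~1–2% at whole-genome coverage) at >3σ
margin while excluding the nearest confusable states, which sit ≥10%
away at subclonal frequency ≥ 0.1. ϑ is the geometric mean of the
baseline segments' corrected ratios; inference runs on the non-baseline
segments only.

## Solution space

For one segment the two observables (C̄, μ̄̂) determine (φ, Cᵀ, μᵀ)
only up to the family of curves μ̄̂(C̄) = ξ(1 − 2/C̄) + 1/C̄ indexed by
ξ = (Cᵀμ̂ᵀ − 1)/(Cᵀ − 2): observations with C̄ < 2, or C̄ > 2 with
C̄ < 1/μ̄̂, have a unique solution; otherwise every curve member
(Cᵀ, μ̂ᵀ) with Cᵀ ≥ 3 and C̄ < Cᵀ contributes its own
φ = (C̄−2)/(Cᵀ−2). Curves are grouped by exact rational ξ (floating
grouping would split equal curves). The family's domain convention —
homozygous deletion (Cᵀ = 0, μ̂ := 0) included, hemizygous deletion
(Cᵀ = 1) excluded, μ̂ = 0 members included — is pinned by the census at
C_max = 15: 43 distinct curves, 7 multi-solution; including Cᵀ = 1
would add a 44th curve (ξ = 1). `classify_solutions` enumerates the
full solution list by brute force over the (Cᵀ, genotype) lattice and
is cross-checked in the tests against an independent dense-grid oracle.

## False-breakpoint filter

Fragments created by an over-sensitive segmenter share the ratio and
BAF profile of their parent region, so the filter (a) Ward-clusters
segments on the scalar log corrected ratio, cutting the dendrogram at
the largest merge-height gap with the cluster count capped at
c_max·τ (τ = assumed number of subclonal populations, default 5; the
cap is a ceiling, not a target — cutting at exactly c_max·τ would
shatter every group into near-singletons and make re-merging
impossible); (b) mean-shift-clusters the pooled folded BAFs within each
ratio cluster, labelling each segment by the majority label of its own
SNPs (ties to the lowest label; SNP-free segments form their own
subcluster); and (c) merges same-chromosome neighbours with gap < ρ
(default 1 bp: book-ended fragments only) within each (ratio, BAF)
cell, summing counts, concatenating SNPs, length-weighting GC and
recomputing the corrected ratio from the summed counts.

The mean-shift bandwidth defaults to Silverman's rule **floored at
2·√(0.25/median depth)**, the sampling SD of a single folded BAF
observation. Silverman's rule alone, applied to ~10⁴ pooled SNPs,
shrinks to ~0.01 and resolves sampling noise (SD ~0.09 at 30×) into
spurious modes that shatter sibling fragments. The floor means that at
WGS depths the BAF stage only separates modes ≳ 0.18 apart; this is an
honest statement of its resolution — the stage becomes informative for
high-depth (amplicon/exome) data or gross allelic imbalance.

Under-clustering at either stage is safe by construction: merging
additionally requires adjacency within ρ, so the only way to destroy a
true breakpoint is two book-ended true segments agreeing in both ratio
and BAF — exactly the configuration the solution-space analysis shows
is indistinguishable anyway.

## Clone-tree prior and sampler

Subpopulation frequencies (node weights) live on the simplex together
with the unallocated remainder (the normal-cell fraction), under a flat
Dirichlet prior; a segment assigned to node v has
φ = Σ weights over v's subtree, so φ decreases monotonically along
every branch. Tree shape and assignments follow the TSSB process with
stop sticks ν ~ Beta(1, α·λᵈ) (depth decay λ = 0.5), branch sticks
ψ ~ Beta(1, γ), and α = γ = 1.

The sampler alternates per sweep:

* **Conjugate stick resampling** from assignment counts.
* **Assignment sweep.** Each segment is re-placed by a categorical draw
  over (i) every instantiated node at its current φ and (ii) *funded
  birth* candidates: a fresh child of any node X whose weight is taken
  from X's own weight on a grid over [0, w_X] (plus a residual-funded
  root child). Funding a child from its parent leaves every subtree sum
  unchanged except the moving segment's own φ, so the candidate scores
  involve one segment's likelihood only. Assignment probabilities use
  the *collapsed* (stick-integrated) TSSB predictive with Beta
  posterior-mean sticks given leave-one-out counts — plugging in
  sampled sticks instead lets densely occupied configurations drive the
  fresh-node mass to zero and become absorbing. Fresh nodes get
  prior-drawn sticks on instantiation (Neal's algorithm-8 device).
  Without funded births a new clone frequency could never exceed the
  unallocated remainder and the chain would freeze in its initial
  clustering.
* **Weight moves.** Grid-Gibbs mass exchanges — node ↔ remainder for
  every node, parent ↔ child along every edge, plus random node pairs —
  sampling the transferred mass from its discretized conditional on a
  coarse-to-fine grid (101 points plus refinement around the coarse
  optimum, width-weighted). Random-walk Metropolis is hopeless here:
  with counts of order 10⁴ the per-segment likelihood peaks have width
  ~0.005 in φ. The two-node case is validated against a dense numerical
  posterior (KS < 0.05) in the tests.

Empty leaves are pruned, returning their weight to the remainder. Each
recorded state stores the per-segment (Cᵀ, genotype) maximizing the
joint likelihood at its current φ (ties toward smaller Cᵀ, then fewer
M copies), the data log-likelihood, and the assignment-pattern log
prior computed *sequentially* (segments inserted one at a time into the
fixed structure, multiplying collapsed predictives) — a leave-one-out
pseudo-marginal would hand every cluster member full join credit while
charging node creation to no one, overstating clustering. The reported
state is the one with maximal posterior (likelihood + assignment
prior); on degenerate data the likelihood alone cannot rank states (see
limitations) and only the prior separates them. Edge probabilities
between clones are fractions of recorded trees containing a directed
occupied-ancestor relation, with node identity matched across states by
maximal Jaccard overlap of assigned-segment sets against the reported
state's clusters.

**Flat mode.** For samples violating the infinite-sites assumption
(each clone carrying many SCNAs, e.g. mixed cell-line data), the tree
prior is replaced by a uniform one and each segment's marginal
likelihood is profiled on a φ grid (step 0.01 over (0,1)); the argmax
and the copy-number MAP at it are reported, with the full profile
available for population-level grouping.

## Synthetic data

The generator works at count level — the model consumes only segment
counts and SNP allele counts, so read-level (BAM) realism adds nothing
at desk scale. Given a clone tree, each segment draws
normal ~ Poisson(coverage·length), tumor ~ Poisson(e^(slope·gc+intercept)·(C̄/2)·normal)
(conditioned on the realized normal count, matching the inference
model's form), and per SNP a depth ~ Poisson(snp_depth·C̄/2) floored at
1 and a B count ~ Binomial(depth, m) with m the expected BAF on a
uniformly random haplotype orientation. GC is uniform on [0.3, 0.6].
Defaults: coverage 0.03 reads/bp (~15 000 normal reads per 500-kb
segment), het-SNP rate 1/2000 bp (~250 per segment, typical human
heterozygosity after genotype filtering), SNP depth 30 (standard WGS),
no injected GC bias (bias recovery is exercised separately with
injected slopes). False breakpoints are injected by splitting each
segment at Poisson-many uniform interior points, apportioning counts
binomially by length so children sum exactly to their parent.

The benchmark scenario places six SCNAs on chromosome 21 — a homozygous
deletion at φ 0.95, gains of 3/4/5/7 copies and a hemizygous deletion
at φ 0.30/0.10/0.50/0.10/0.30 — on a six-clone lineage
A → {D → B → C, E → F} with subpopulation frequencies 0.15/0.20/0.20/
0.20/0.10/0.10 and 5% normal cells, plus 20 copy-neutral 500-kb
segments spaced 10 kb apart (so no merging rule can bridge them).

What the generator does **not** emulate: mappability and replication-
timing waves, segmentation boundary error (splits are exact), allele-
specific mapping bias, sequencing error in allele counts, and
overdispersion beyond Poisson/binomial. Passing tests therefore
demonstrate correctness of the inference machinery under the model's
own assumptions, not robustness to real-data artifacts beyond the
injected GC trend and false breakpoints.

## Identifiability: what recovery means here

All four multi-copy SCNAs of the benchmark carry exactly one minority
allele, so they lie on the ξ = 0 curve, where the folded BAF prediction
collapses to 1/C̄ for *every* member: the likelihood of, e.g., the
five-copy gain at φ = 0.50 is identical — to machine precision, and
robustly to observation noise, since every member absorbs a common
perturbation through its own φ — to that of (7, 0.30), (8, 0.25),
(4, 0.75), … . For such segments the posterior is decided by the prior
alone, and the DP clustering prior (α = 1) prefers configurations in
which degenerate segments share nodes: the reported MAP places d at an
exact alternative solution sharing a clone with e, rather than at the
generating (5, 0.50). This is the correct Bayesian answer to an
under-determined question, and it is why the package ships the
solution-space module: `classify_solutions` tells the user *which*
segments' frequencies are trustworthy. Unique-solution segments (all
deletions, and amplifications with folded BAF < 1/C̄ such as LOH
states) are recovered reliably — the benchmark's homozygous deletion to
within 0.005 of its true frequency, and both deletion copy numbers
exactly, across all tested seeds.

## Numerical choices and scales

Natural logs throughout; log-sum-exp for all mixtures; Poisson pmf via
log-gamma. Ratio of a zero-tumor-count segment is regularized to
0.5/Dᴺ before the log. Grid resolutions: 4001 points in p for the BAF
table, 101(+refinement) for weight conditionals, 25 fractions per
funded-birth candidate, φ step 0.01 in flat mode. Default chain length
50 burn-in + 300 recorded sweeps. The shipped benchmark uses 26
segments (~6 500 SNPs); a full pipeline run takes ~30–60 s on one CPU,
and the whole test suite under two minutes.
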