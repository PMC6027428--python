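# Methods

## Model and life cycle

Each generation applies, in order: migration (each individual moves to the
other deme with probability *m*), fitness evaluation and effective-migration
bookkeeping, soft-selection reproduction with recombination, mutation, and
loss/fixation pruning.  Generations do not overlap; each deme always
contributes exactly `deme_size = N/2` offspring, so mean fitness affects
only *who* reproduces, never how many offspring a deme leaves (soft
selection).  Both parents of an offspring are drawn fitness-proportionally
with replacement across offspring; selfing is excluded by redrawing the
second parent (obligate outcrossing).

Fitness is multiplicative across segregating selected loci and additive
within a locus: the locally favored homozygote contributes 1 + s_i, the
heterozygote 1 + s_i/2, the other homozygote 1.  By default every derived
allele is favored in deme 2 and every ancestral allele in deme 1, giving a
symmetric two-allele barrier architecture; `random_favored_deme=True`
randomizes the favored deme per mutation.  A mutation may arise in the deme
where it is disadvantageous.  There is no epistasis, no global positive
selection, and no standing variation at the start.

Fixed selected loci are dropped from the fitness product: within a deme
they multiply every individual's fitness by the same constant, which
cancels under soft selection, in parent sampling, and in the effective
migration rate (a ratio of fitness sums within a deme).  This also licenses
the *deferred pruning* used by the run loop (below).

## Recombination

Chromosomes assort independently (the starting parental haplotype of each
chromosome is a fair coin) and crossover counts are Poisson with mean equal
to the map length in Morgans, positions uniform.  With the default genome
(4 × 0.5 M) a gamete carries on average two crossovers.  A site lying
exactly on a switch point takes the post-switch haplotype; switch positions
are continuous, so this is a measure-zero tie rule.  Two implementations
ship and are tested for exact agreement: a numpy reference that evaluates
the switch-point parity at every site, and the production numba kernel that
copies one parental haplotype verbatim and re-evaluates parity only at the
parent's heterozygous columns (the only columns where the choice matters).

## Mutation

Exactly `mutations_per_generation` (default 10) new sites per generation,
each on one haplotype of a uniformly chosen offspring at a uniform genome
position (infinite sites; positions are continuous doubles and collisions
have probability zero).  Kind is Bernoulli: neutral with probability 10/11,
else selected with s_i ~ Exponential(mean `s_mean`).  The 10:1 ratio and
the count of 10 per generation are the standard study conditions; they are
deliberate defaults, not tuned values.

## Summary statistics

* Allele frequencies are exact per-deme counts (no sampling).
* AFD is signed for selected sites (favored-deme frequency minus the other
  deme's; negative values occur early) and |p1 − p2| for neutral sites;
  class means run over segregating sites only.
* FST per site is (HT − HS)/HT with HT from the pooled frequency; pooled-
  monomorphic sites are skipped and flagged.
* LD is the squared Pearson correlation of 0/1 allelic states on phased
  haplotypes; "between-deme" pools both demes, "within-deme" uses one.
  Pairs are capped (default 125,000 in the library; runs use a smaller
  configurable cap) by seeded uniform subsampling of the pair index space;
  sites monomorphic in the evaluated scope are excluded and counted.
  An `|r|` variant is exposed behind a flag; r² is the default and is what
  the empirical module uses.

## Coupling statistics

θ = s̄/r̄, where s̄ is the arithmetic mean selection coefficient of
*segregating* selected sites and r̄ the mean map distance between
consecutive selected sites (cross-chromosome neighbours contribute 0.5 M —
free recombination; a Haldane-transformed variant is exposed behind a
flag).  θ is a dynamic variable: s̄ moves because establishment favors
large-effect mutations, r̄ shrinks as barrier loci accumulate.

L_e = s*/s̄.  s* solves the single-locus migration–selection balance for
the observed mean favored-deme frequency p̄ of segregating barrier alleles:

    s* = m (p̄ − 1/2) / [ (1/4)(1 − p̄) p̄ + m (1/2 + p̄ (p̄ − 3/2)) ]

The equilibrium itself (`single_locus_equilibrium`) is the root in
(0.5, 1] of the quadratic obtained by setting s*(p) = s_i; it agrees to
~1e-10 with an independent oracle that iterates the exact deterministic
two-deme recursion (genotype pools tracked through migration and selection,
Hardy–Weinberg within natal demes).  Both code paths ship; the recursion is
the arbiter.  The inverse pair s*(p_eq(s, m), m) = s holds to machine
precision, so L_e = 1 exactly under uncoupled single-locus balance.

Interpretation caveats: p̄ averages over *all* segregating barrier alleles,
including young rare ones.  Early in a run, or in swamped regimes, p̄ < 1/2
and s* (hence L_e) is negative — meaningful only as "no coupling".  Once
p̄ exceeds the largest frequency any finite single-locus s can sustain, the
denominator above is non-positive; s* and L_e are then reported as +inf
with a `beyond_balance` flag.  Fixed barrier alleles are excluded from p̄,
matching the s̄ convention.

## Transition fits

Two- and three-parameter logistics are fitted by multi-start nonlinear
least squares (scipy `least_squares`, analytic Jacobians; LM for the
unbounded two-parameter form, TRF with 0 < z ≤ 1 for the asymptote form).
Starts span the x-quantiles in b and ±1, ±10 plus range-scaled values in a;
the best of all converged starts by residual sum of squares wins.
Noiseless curves are recovered to ≤1e-6; degenerate (constant) data are
flagged non-converged rather than fitted.  The transition report gives the
lag b_neutral − b_selected on the shared axis and the divergence gap
evaluated at the selected inflection.

Pooling convention: AFD-vs-log10(θ) fits pool the (x, y) points of all
replicate runs of a parameter combination; LD-vs-time fits use the
per-generation median across runs.

## Empirical LD pipeline

Genotype likelihoods (VCF GL/PL or a dosage table) become posterior-mean
dosages in [0, 2] under a Hardy–Weinberg prior at the EM allele-frequency
estimate (prior from current p̂, posterior ∝ likelihood × prior, p̂ ← mean
posterior dosage / 2, to |Δp̂| < 1e-6 or 200 iterations).  Between-taxon
differentiation per locus uses Hudson's two-population FST estimator on
estimated frequencies with sample-size correction (negative values are kept;
quantiles are taken on raw values; a Nei/GST variant sits behind a flag)
or |AFD|.  Outliers are loci strictly above the per-chromosome 99th
quantile (numpy's linear-interpolation quantile, so thresholds are
bit-reproducible); chromosomes with < 100 usable loci trigger a warning.

Within-taxon r² is sampled in six groups (outlier/non-outlier ×
same/other chromosome).  Groups 1–2 take the full upper triangle after
capping each SNP set at 5000 by seeded subsampling.  Groups 3–6 sample
Lo partner loci, compute the cross-correlation matrix, and keep every
second value in row-major order until (Lo² − Lo)/2 values are collected
(Lo = capped outlier count of the chromosome) — exactly the upper-triangle
count of groups 1–2.  Correlations use pairwise-complete individuals;
pairs with < 4 complete observations are skipped.  log(r²) densities are
Gaussian-KDE on a fixed grid, with the bandwidth capped at 0.75 log-units:
Scott's rule over-smooths small samples whose modes sit several log-units
apart, which would merge a genuinely bimodal sample into one mode.  Exact
zeros are floored at r² = 1e-8 (count reported).  "Upper mode present" is
a tool-defined heuristic: a local density maximum above r² = 0.5 carrying
≥ 1% of the sample.

## Synthetic two-taxon fixture

The generator emulates the structure relevant to the outlier/LD analysis:
background loci share Uniform(0.05, 0.95) frequencies across taxa
(independent Hardy–Weinberg draws); each chromosome carries a fixed small
number of barrier loci at between-taxon AFD 0.9 (p = 0.95/0.05) that copy a
per-haplotype latent ancestry state with probability
coupling_strength^(1/4), making their pairwise within-taxon dosage r² ≈
coupling_strength; the latent ancestry pool is conditioned to carry at
least three minor-ancestry haplotypes (a few admixed individuals — with
only 20 haplotypes an unconditioned Bernoulli(0.95) pool is occasionally
near-monomorphic and the correlations degenerate); genotype likelihoods
come from Poisson(8×) read depth with 1% symmetric read error.  Defaults (10 individuals/taxon, 5
chromosomes, 0.5% barrier fraction) mirror a small resequencing design
while keeping the barrier fraction below the 1% outlier quantile so
recovery is possible.  What the fixture does **not** emulate: genuine
linkage maps and physical clustering of barriers, demographic history,
shared drift, missing-data structure, or indirect selection on the
background — so passing tests demonstrate the pipeline's statistical
machinery, not inference validity on any real system.

## Problem sizes and run protocols

The replicated end-to-end experiments (tests and `scripts/acceptance.py`)
run at N = 1000 with 10 replicates per parameter combination: the m = 0.01
set (s = 0.01) runs until mean selected AFD exceeds 0.95 and the low-gene-
flow set (s = 0.02, m = 0.0002) until mean neutral AFD exceeds 0.8, each
with a generation cap (18–20 thousand) as numerical safety; transitions
complete well before the caps.  These runs record every 100 generations,
skip LD columns, and disable the N·m_e stopping rule so the transition is
fully sampled.  Full-scale behaviour (N = 5000, the nine-combination grid
at 50 replicates) is reachable through `congeal batch` but is an overnight
computation, not part of the default suite.

Scaling N from 5000 to 1000 preserves the mutation influx (10/generation)
and therefore roughly preserves θ's trajectory in generations, but drift
within demes runs five times faster.  Consequences observed: the selected-
site transition location in θ is close to full-scale expectations, while
*neutral* differentiation by drift begins at smaller θ than at N = 5000
(the median neutral AFD crosses 0.05 around θ ≈ 0.1 rather than above
0.3).  The neutral inflection (θ ≥ 1) and the half-order-of-magnitude lag
between selected and neutral transitions are robust to the rescaling.

## Numerical choices

* One seeded numpy Generator per run drives every stochastic step; replays
  are bit-identical.  Batch runs derive per-replicate seeds from a master
  seed via `SeedSequence(master, spawn_key=(cell, replicate))`.
* The production fitness path evaluates log W as a quadratic in allele
  dosage (two matrix–vector products) in float32, normalized within demes
  (the per-deme constant cancels in soft selection and m_e); it agrees
  with the direct per-locus product to ~1e-6 relative.
* Loss/fixation pruning may be deferred up to 16 generations inside
  `run_simulation` (resolved columns are inert; statistics always see a
  compacted, position-sorted matrix because pruning runs before every
  record).  Records of resolved mutations then carry the compaction
  generation, an upper bound on the true loss/fixation time.
* The N·m_e stopping rule uses a trailing 100-generation mean of m_e to
  avoid stopping on a single-generation fluctuation; window and threshold
  are configurable, and threshold 0 disables the rule.
* Time series are written as TSV at 10 significant digits; round-trips
  are lossless at that precision.

## Known limitations

Two demes only; no epistasis, background or positive selection; soft
selection only; selection coefficients constant in time; the empirical
module assumes biallelic sites and unstructured taxa.  L_e interpretation
degrades when most barrier alleles are young (see above).  The scaled-down
default experiments inherit the drift-speed caveat described in the
problem-sizes section.
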