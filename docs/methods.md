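# Methods

This note documents the models and procedures implemented in `poolld`, the
parameter choices that matter, what the simulators do and do not emulate,
and the numerical decisions made where the design was open.

## Two-locus haplotype tables from pooled reads

Every sequencing template (single read or mate pair) derives from one
chromosome of the pool. For each pair of polymorphic sites closer than the
library's maximum template span, templates yielding base calls at *both*
sites ("intersecting" templates) are cross-tabulated into 2×2 haplotype
counts `x_ij`. Base calls require base quality strictly above the threshold
(default 20); overlapping mates that agree at a site are counted once
(keeping the higher quality), and mates that disagree drop that site for
the template — a conservative rule that avoids inventing a tie-break.
Reads flagged unmapped, secondary or supplementary are skipped; duplicates
are kept unless `--drop-duplicates` is set, and mapping quality is not
filtered by default (`--min-mapq` exposes it). Positions under deletions,
skips or clips yield no call, as do non-ACGT bases.

At loci with more than two observed alleles the two most frequent are
retained (ties broken by fixed base order A<C<G<T for determinism);
templates carrying a third allele at either site are excluded from the
table *and* from the intersecting depth `n`, so the four cells always sum
to `n`. Pairs are estimated only if `n` is at least `min_intersecting`
(default 10), both loci have all-read minor allele frequency at least
`maf_cutoff` (default 1%), and — optionally, for empirical data where copy
number variants inflate coverage — each locus depth is below a multiple of
the mean depth (off by default).

## Estimators

**Direct.** `pA = (x11+x12)/n`, `pB = (x11+x21)/n`, `D = x11/n − pA·pB`,
`r² = D²/(pA(1−pA)pB(1−pB))`. Undefined (NaN, flagged) when either locus is
monomorphic among the intersecting templates; this happens often for
low-frequency pairs at low depth and is the source of the method's upward
bias: sparse tables that happen to sample only two haplotype classes
report r² = 1.

**Approximate maximum likelihood.** All-read frequencies `pA′, pB′` are
more precise than the intersecting-read marginals, so they are fixed at
their observed values (a full 3-parameter maximization is deliberately not
attempted; it is poorly behaved, which is why the method is "approximate").
The table is multinomial with cell proportions `f_ij(pA′, pB′, D)`, leaving
a one-dimensional concave log-likelihood in D over the feasible interval
`[max(−pA′pB′, −(1−pA′)(1−pB′)), min(pA′(1−pB′), (1−pA′)pB′)]`. The
likelihood is maximized over *signed* D (r² does not identify the coupling
phase; the sign is reported separately as `d_hat`), using a 1001-point grid
followed by bounded local refinement — concavity makes this exact to the
refinement tolerance, and the test suite verifies agreement with a dense
100k-point scan to 1e-4 in r². When the maximizer lies at an interval
endpoint the estimate is boundary-flagged: the table is incongruent with
the all-read frequencies, which typically happens when true r² is high but
not 1 (only part of the table was sampled) and produces the method's
downward bias mode. Limit conventions at the boundary: `0·log 0 = 0`,
`x·log 0 = −∞` for `x > 0`. Floating-point clamping keeps r² in [0, 1].

**Effective observations.** A pooled experiment samples twice: `c`
chromosomes into the pool, then reads from chromosomes. Composing the two
binomial variances gives an effective sample size
`n_eff = n·c/(n + c) < min(n, c)`. The cell counts are rescaled by
`n_eff/n` before entering the log-likelihood; this leaves the maximizer
unchanged (so point estimates are invariant to the rescaling) but flattens
the likelihood, widening the confidence interval to reflect the double
sampling. For a pool of fully inbred strains, `c` is the number of strains;
`--n-chrom` has no default because it is an experimental fact.

**Confidence interval.** The interval is `{D : ℓ(D) ≥ ℓ(D̂) − 1.96}` —
1.96 log-likelihood units, as conventionally printed for this method (not
the χ²₁/2 value 1.92) — found by root-bracketing on each side of the
maximum and mapped through `r² = D²/denom`. Because two signs of D can map
to one r², the mapped set's lower end is 0 whenever the D-interval
straddles 0. The interval always contains the point estimate. Coverage is
approximate by construction; simulation at `n_eff = 100` with interior D
shows ≳95% empirical coverage (the count rescaling makes the interval
conservative when reads, not chromosomes, limit information).

## Simulators

**Panel generator** (`generate_panel`): independent site columns with a
uniform or neutral (1/k) frequency spectrum, plus optional injection of
site pairs with exact two-locus haplotype counts — used to place pairs with
known r² by construction. Independent columns carry *no* linkage structure,
which makes such panels useful for unit-level fixtures but meaningless for
estimator-accuracy studies: true r² between independent columns is pure
sampling noise of order 1/n_hap.

**Wright–Fisher forward simulator**: discrete generations, `M` haplotypes,
per-base mutation (infinite-sites-like on a finite grid; colliding
positions are skipped), single-crossover recombination at rate ρ per bp per
generation, multinomial resampling, with fixed/lost columns pruned. An
equilibrium sample (`wf_equilibrium_panel`, burn-in 10·M generations)
provides panels with genuine genealogical LD that decays with distance —
the structure a real inbred-line reference panel has — and is what the
validation experiments sequence. Defaults: per-bp θ = 0.002–0.004
(Drosophila-like autosomal diversity), ρ/θ = 7.

**Pooled read simulator** (`simulate_reads`): `depth·L/(2·read_length)`
templates; each draws a haplotype uniformly (the pooling process), an
insert length ~ Normal(insert_mean, insert_sd) rounded and clamped to
[2·read_length, L], a uniform start, and i.i.d. base errors substituting a
uniform different base. Output is valid coordinate-sorted SAM with proper
FR mate fields, plus a per-site truth table of sampled allele counts.
Defaults follow short-read pooled libraries of the early-2010s design the
method targets: 93 bp paired-end reads, insert 450 ± 45 bp, error 10⁻³.
Base qualities are emitted constant (Q40) so the quality filter is
exercised by dedicated low-quality fixtures rather than entangled with the
error model. Alignment is known-truth placement — mapping error, indels and
quality miscalibration are out of scope, so passing tests say nothing about
mapper artefacts in real data.

## Validation experiments

**Depth sweep.** One 100-haplotype equilibrium panel over 50 kb
(θ = 0.002 → ≈500–600 segregating sites, a realistic autosomal SNP
density of ~1/85 bp) is sequenced at 10×, 40×, 100× and 200×;
`min_intersecting` is relaxed to 5 at 10×, where almost no pair reaches ten
intersecting templates. Two summaries per depth: the fraction of enumerated
pairs that pass the filters (strictly increasing with depth), and the
Pearson correlation between estimated and true r². The correlation is
reported both over each depth's own estimable pairs and over the pairs
estimable at *every* depth; the common-pair version is the one that
isolates accuracy, because deeper libraries rescue rarer and harder pairs
and the changing pair composition otherwise masks the depth effect.

**Bias modes.** At low depth (median intersecting depth ≈ 7–10), the
fraction of direct estimates exactly at 1 exceeds the truth's fraction
(sparse-table upward bias), and a large fraction of ML estimates are
boundary-flagged (incongruence downward bias) while the truth contains
none.

**MAF stratification.** Accuracy rises with minor allele frequency —
high-frequency pairs expose all four haplotypes to sampling — measured as
truth correlation within bins of the pair's smaller all-read MAF
([0.01, 0.05), [0.05, 0.1), [0.1, 0.5]).

**LD decay.** Ordinary least squares of r² on log(distance) (natural log,
distance in bp), recombination rate (cM/Mb) and their interaction — the
standard decay-with-distance model. The recombination terms need rate
variation, so the decay experiment pools pairs from two equilibrium panels
simulated at different crossover rates and labelled with nominal rates. On
noiseless synthetic data the fit is exact (an OLS identity); on recombining
panels the distance slope is negative. Empirical decay coefficients from
real population data are not reproduced here — they require the external
panel — but serve as plausible ground-truth generators in
regression-recovery tests.

**Demographic discrimination.** Two demographic histories can leave the
same nucleotide diversity π yet different LD. The reference trajectory is
an out-of-Africa-style bottleneck: equilibrium at N0, contraction to Nb,
recovery, sampling 20 individuals. Times are in units of 4·Ne generations
*of their own phase* — the bottleneck lasts 4·Nb·t generations and the
recovery 4·N0·t_recovery. Under this scaling, the severity variants
(Nb/2 with 2t; 2Nb with t/2) hold the absolute bottleneck duration fixed
while halving/doubling its size, so all three lose only a few percent
heterozygosity — expected decays (1−1/(2Nb))^T of 0.92/0.96/0.98 at the
default Nb = 47, T ≈ 4 generations — while the LD the bottleneck generates
scales with 1/Nb. The experiment runs the trio from shared equilibrium
snapshots (spaced 2·M generations along one long simulation), computing
sampled-panel π and mean pairwise r² (singleton sites excluded, as their
r² is dominated by sampling noise), and compares per-replicate mean r²
across models with Welch t-tests. At the experiment scale used
(N0 = 500, Nb = 23.5 — half the defaults at identical ratios, since the
decay exponents are scale-invariant — 10 kb loci, 50 replicates), mean π
agrees across models within ~5–7% while the severe-vs-mild r² contrast is
significant at α = 0.05, with ordering severe > reference > mild. No
specific r² magnitudes are asserted: the forward simulator is minimal
machinery (no selection, no gene conversion, single crossover per meiosis)
and is not a replica of any particular coalescent or forward engine.

## Numerical and interface decisions

- Coordinates are 1-based inclusive everywhere; 0-based arithmetic exists
  only at the pysam boundary.
- Output floats are formatted to 6 significant digits for byte-stable
  diffs; missing values print as `NA`; runs are deterministic given inputs
  and a seed, with output ordered by (chrom, pos_a, pos_b).
- `--max-distance` defaults to the largest |TLEN| among the first 10k
  alignment records (the template span); it must be given explicitly when
  the alignment carries no mate information.
- Degenerate inputs: empty site lists warn and produce empty (but
  well-formed) output; monomorphic loci are excluded with a log count;
  zero-variance validation vectors yield NaN correlations rather than
  errors.

## Known limitations

- LD is estimable only within the template span; nothing beyond the insert
  size can be phased from pooled data.
- The boundary-pinned ML estimates for rare–rare pairs (intersecting table
  monomorphic at both loci) report r² near 1 with near-flat likelihood;
  consumers should respect the boundary flag and CI rather than the point
  estimate.
- The simulators emulate sequencing and genealogy, not mapping: repetitive
  regions, indel misalignment and reference bias in real data are outside
  what passing tests demonstrate.
- The effective-observation formula treats both sampling stages as
  binomial and ignores unequal individual contributions to the pool.
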