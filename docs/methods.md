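# Methods

`mtpop` analyses haplotypes typed on a panel of mitochondrial SNPs. An
individual's mtDNA is effectively non-recombining, so the alleles carried at
the assayed positions travel as a single haplotype; the package represents a
haplotype as the set of differences to the rCRS reference (tokens such as
`16362C`), with two length polymorphisms — the COII/tRNA-Lys 9-bp deletion and
the D-loop (CA)n repeat — carried as opaque categorical extensions. This note
records the statistical models, the numerical conventions, and the design
choices that were genuinely open.

## Haplotype identity and distance

Two identity modes exist because published tables use both. *Base* mode
(the default) compares the SNP variant sets only; *extended* mode also
compares the 9-bp state and the (CA)n repeat count. The 9-bp labels
NORM/DEL are copied verbatim from input and never interpreted biologically:
the study table's footnote defines them in the direction opposite to the
natural reading, so attaching meaning to them would bake in a guess.

The distance between two haplotypes is the number of panel positions at
which their implied alleles differ (positions absent from both variant sets
share the reference allele and contribute 0). At the one triallelic locus
(9824, T/A/C) a haplotype is a single categorical allele, so an A-carrier
and a C-carrier differ by exactly 1 at that position. This count is a
metric on base haplotypes; the extensions never enter it.

## Diversity statistics

With haplotype counts c_i, n = Σc_i, x_i = c_i/n:

* match probability P = Σx_i² = (Σc_i²)/n², the chance two random
  individuals share a haplotype; discrimination power DP = 1 − P. Both are
  computed in exact rational arithmetic, so P + DP = 1 holds exactly before
  rounding.
* haplotype diversity H = n/(n−1) · (1 − Σx_i²). The n/(n−1) factor makes
  the estimator unbiased for 1 − Σp_i² under multinomial sampling (verified
  by simulation in the test suite); a `unbiased=False` flag gives the
  plug-in form. The standard error uses the usual large-sample variance
  V(H) = 2[2(n−2)(Σx³ − (Σx²)²) + Σx² − (Σx²)²]/(n(n−1)); the source table
  this package ships as a fixture prints an SE without naming its formula,
  so no attempt is made to match it.
* nucleotide diversity π = n/(n−1) · Σ_{i<j} 2 x_i x_j d_ij / L: the
  average per-site difference count between two randomly drawn individuals.
  The per-site denominator L defaults to the full panel size (54 for the
  packaged study panel, monomorphic loci included) and can be switched to
  the segregating-site count or an explicit integer, because printed tables
  rarely state which convention their software used.

Rounding of reported tables is half-up (2 decimals for allele frequencies,
4 for diversity statistics), matching how such tables are printed.

### Documented discrepancies on the packaged study data

The packaged fixtures transcribe a published 54-locus study of 137 Xibe
individuals (64 base haplotypes). Recomputation reproduces the printed
allele-frequency table exactly (all 54 loci at 2 decimals), the haplotype
censuses in both modes (modal 15/12, 37 extended singletons), and
P = 565/18769 → 0.0301 / DP = 0.9699. Four printed values are *not*
reproducible from the printed haplotype table under any implemented
estimator variant, and the pipeline annotates rather than matches them:

* haplotype diversity: printed 0.9800 ± 0.004; base-mode unbiased
  evaluation gives 0.9770, extended-mode 0.9819;
* nucleotide diversity: printed 0.1875; L=54 unbiased gives 0.1802
  (biased 0.1789, L=49 unbiased 0.1986);
* polymorphic sites: printed 51; the printed haplotypes segregate at 49 of
  the 54 loci (3348, 4491, 6446, 8684, 13104 are monomorphic);
* transition share: printed 83.93% with no recoverable denominator; over
  the 50 observed alternate alleles the fraction is 46/50 = 0.92.

These annotations appear in a "documented discrepancies" section of the
summary report; mismatches are reported, never silently repaired.

## Pairwise Fst

Φst (default) is the two-group molecular-variance decomposition with
haplotype difference counts as squared distances: SSD_total = Σ_{i<j} d_ij/N
over the pooled individuals, SSD_within the analogous per-group sums,
σ²_w = SSD_within/(N−2), σ²_a = (SSD_among − σ²_w)/n_c with
n_c = N − (n₁²+n₂²)/N, and Φst = σ²_a/(σ²_a+σ²_w). Estimates can be
negative (an under-dispersed pair — notably, a sample compared against an
exact copy of itself gives a negative value, since its among-group sum of
squares is zero while the null expectation is σ²_w); raw values are kept,
and only the distance-matrix export floors them at zero. The implementation
is vectorised over distinct haplotypes but is checked to 1e-12 against an
exhaustive individual-pair summation in the tests.

The FREQUENCY method is the Hudson/Nei-style haplotype-frequency form
1 − H_w/H_b with H_w the mean unbiased within-population heterozygosity
(n/(n−1)-corrected) and H_b = 1 − Σ_h p̂₁(h)p̂₂(h). The unbiased H_w keeps
the estimator centred at 0 under the null (the plug-in form carries a +1/n
bias, visible at the simulation sizes used here); the price is that a
self-comparison returns −1/(n−1) rather than exactly 0. Under the
Balding–Nichols divergence model it recovers the divergence parameter F in
expectation.

Significance uses the standard permutation null: pooled individuals are
reassigned to the two groups holding sizes fixed, and
p = (1 + #{Fst_perm ≥ Fst_obs})/(n_perm + 1). The +1 correction keeps p
positive; default 999 permutations, significance threshold α = 0.05, no
multiple-testing correction (matrix scans report raw p-values). Each pair
in a matrix gets its own seed substream, so results are reproducible
bit-for-bit and independent of pair order. Note a subtlety exercised in the
tests: for two small fixed samples the permutation p does not reach the
1/(n_perm+1) floor, because a random reassignment recreates the perfect
split with probability 2/C(n₁+n₂, n₁).

## Trees and ordination

Neighbor-Joining is implemented directly (Saitou–Nei agglomeration,
Studier–Keppler criterion Q(i,j) = (r−2)d(i,j) − R_i − R_j). Ties in Q go
to the lexicographically smallest cluster pair (a cluster is labelled by its
smallest member leaf), making output deterministic. On additive matrices the
method recovers the generating topology and branch lengths exactly
(tested to 1e-9 over random 4–8 leaf trees); on non-additive Fst matrices
negative branch lengths can arise and are clamped to zero with a logged
warning. Topology claims are always tested as split sets, never as plotted
coordinates, and the study-matrix tree is cross-checked against an
independent NJ implementation (scikit-bio) in the test suite.

Ordination of an Fst matrix defaults to principal components of the row
profiles (each population's vector of distances to all populations,
column-centred, eigendecomposed) — mirroring the common "PCA on Fst"
recipe; classical metric MDS (Torgerson double-centering of squared
distances) is available via `method="mds"`. Axes are ordered by explained
fraction, coordinates are centred, and per-axis sign is fixed by making the
largest-magnitude loading (or coordinate, for MDS) positive. Since the
original plot's axes and loadings are not published, only cluster-membership
properties are asserted against it.

## Synthetic data

The generators exist so every estimator has a ground truth:

* `multinomial_sample(p, n, seed)` draws haplotype counts multinomially
  from a known spectrum.
* `divergent_pair(config)` implements Balding–Nichols divergence: each
  population's frequencies are Dirichlet draws with mean p and
  concentration (1−F)/F, then multinomial samples; the expected
  frequency-method Fst is F. Defaults mirror the calibration used in the
  tests: K = 20 haplotypes, uniform ancestral spectrum, n = 500 per
  population.
* `additive_matrix_from_tree` / `random_additive_tree` build exact
  path-length matrices from Newick trees (dendropy), optionally with
  symmetric jitter, as the NJ recovery harness.

Synthetic haplotype k carries a single variant at generated position k+1,
so all distinct haplotypes sit at a uniform distance of 2 and frequency- and
distance-based estimators coincide up to scale; `tree_structured_haplotypes`
instead accumulates variants along a random genealogy, giving the
heterogeneous distances needed to exercise Φst specifically. All generators
are pure functions of (parameters, seed) via named seed substreams.

What the synthetic data does *not* emulate: mutation (haplotype sets are
fixed), selection, migration beyond a single ancestral split, linkage to a
real mtDNA phylogeny, or genotyping error. Passing calibration tests
therefore demonstrates estimator correctness under the stated sampling
models, not robustness to real-data artefacts.

## Problem sizes and tolerances

Oracle-equivalence tests use exact rational arithmetic (no tolerance) or
1e-12 for float pipelines; NJ additive recovery uses 1e-9. Calibration
checks use 200 replicates for Fst recovery (2 Monte-Carlo SEs) and for
permutation type-I error (binomial error at α = 0.05, 199 permutations per
replicate), and 1000 replicates for the H-unbiasedness check — sizes chosen
to give decisive intervals while keeping the whole suite in seconds.

## Known limitations

* No hierarchical (multi-level) AMOVA; only two-group pairwise Φst.
* No bootstrap supports, rooted-tree inference, or haplogroup nomenclature.
* Distance matrices for comparison populations must be supplied (the
  packaged one transcribes the published 19-population matrix); raw
  haplotype data for those populations is not available, so their Fst
  values cannot be recomputed here — the estimators are instead validated
  on synthetic data with known F.
* The haplotype-table dialect is substitution-only plus the two fixed
  extensions; arbitrary indels are out of scope (`No. of indels` is 0 by
  construction).
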