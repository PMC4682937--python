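# Methods

## Scope and model assumptions

`octodart` implements the computational chain used to analyse dominant
presence/absence (DArT / DArTseq) markers in an allo-octoploid crop:
classification and filtering of SNP allele scorings from a pseudo-testcross
F1 family, diversity and structure statistics for a cultivar panel, LOD
linkage grouping with map summaries, and comparison of a genetic map
against a diploid reference assembly. All statistical machinery assumes:

- **Dominant scoring.** Every marker is a band (restriction fragment or
  sequenced allele) scored present (1) / absent (0) with missing calls.
  SNPs are handled as *pairs of independent allele scorings* rather than
  codominant genotypes, because in an octoploid the reference and
  alternative alleles may reside in different sub-genomes.
- **Disomic inheritance.** Chromosomes pair strictly within homologous
  pairs; each sub-genome behaves as a diploid. A single-dose (simplex)
  marker carried by one parent therefore segregates 1:1 in the F1
  (testcross) and one carried by both parents segregates 3:1 (intercross).
  Higher dosages give the one-parent presence ratios 3:1 (duplex) and
  7:1 (triplex); when doses are spread over both parents the attainable
  ratios include 7:1, 13:3 and 15:1. These two sets are the default
  multiplex alternatives in the classifier and are configurable.

## The filtering cascade

Stages, in order, with their default thresholds (all in `RunConfig`):

1. **Monomorphic** — all non-missing progeny calls equal. Columns with
   *no* calls at all are deliberately left to the next stage, so the two
   exclusion sets stay disjoint.
2. **Missing** — excluded when missing in more than `floor(0.10 * n)`
   progeny (strictly more than 9 of 94), or missing in either parent, or
   scored 0 in both parents. The denominator counts progeny only.
3. **Segregation classification** — the expected simplex ratio is fixed by
   the parental pattern ((1,0)/(0,1) → 1:1; (1,1) → 3:1) and tested with a
   1-df chi-square without continuity correction. The simplex ratio is
   tested first at `alpha_simplex = 0.001`; only on rejection are the
   pattern-consistent multiplex ratios tried at `alpha_multiplex = 0.01`
   (best-fitting ratio reported); alleles rejecting everything are
   distorted. Testing simplex before multiplex is a genuine design choice:
   it favours retaining mapping-grade simplex markers and treats multiplex
   as the departure hypothesis, which matches how the stage counts are
   reported (multiplex and distorted as departures from the simplex
   expectation).
4. **Row-sum filter** — intercross alleles only (they are the least
   informative class, so only deep-coverage ones are kept): keep when the
   allele's total read count is `>= 600`.
5. **Redundancy collapse** — column similarity is the fraction of equal
   calls over pairwise-complete progeny, with a minimum-overlap guard of
   20 progeny below which a pair is skipped (similarity under heavy
   missingness is otherwise undefined). Pairs with similarity `> 0.99`
   collapse, as do exactly complementary columns of the two alleles of one
   SNP (one locus scored from both sides); the representative is the
   allele with fewest missing calls, ties to the lexicographically smaller
   id. The collapse happens *after* the selection count is reported, so
   `final_selected` reflects the classification stages and `mapping_set`
   the post-collapse set — mirroring a workflow where redundancy is
   resolved during map construction.

`CascadeReport` carries the raw counts; derived stages are properties so
partition sums reconcile by construction, and percentages are computed on
the stage-appropriate denominators and rounded to one decimal.

## Diversity statistics

- **PIC.** For a dominant biallelic marker with band frequency *f*,
  PIC = 1 − f² − (1−f)² = 2f(1−f), bounded by 0.5 at f = ½. Summaries
  report the panel mean and the conventional bins (<0.10, 0.10–0.30,
  0.30–0.40, 0.40–0.50).
- **Nei–Li fragment distance.** For accessions x, y over markers scored in
  both: F = 2·n_xy/(n_x + n_y). The per-site fragment retention G solves
  F = G⁴/(3 − 2G); we use a damped fixed-point iteration
  G ← ½(G + [F(3−2G)]^¼) from G₀ = F^¼ to |ΔG| < 1e-12 (the damping keeps
  the map contractive over the whole F range). The distance is
  D = −(2/r)·ln G with r the recognition-site length of the rare-cutting
  enzyme (default 6, the PstI site used to build DArT representations).
  F = 1 gives D = 0; D is monotone decreasing in F; doubling r halves D
  exactly. Pairs sharing no bands are flagged saturated and capped
  (default +inf, configurable); pairs with no bands at all are undefined.
- **Neighbor joining.** Saitou–Nei agglomeration with the Q criterion,
  implemented directly so tie-breaking is deterministic (ties in Q resolve
  toward the smallest sorted label pair). Exactly additive matrices are
  recovered with their generating topology and branch lengths to 1e-9.
  Negative branch-length estimates are clamped to 0 on output with the raw
  value retained on the node (`raw_length`), matching common
  PHYLIP-style behaviour. Outgroup rooting is available with midpoint as
  the fallback.
- **Bootstrap.** Marker columns are resampled with replacement B times
  (protocol default 1,000); supports are the percentage of usable
  replicates containing each original internal bipartition. Replicates
  whose resampled matrix yields non-finite distances are dropped and the
  effective replicate count reported.
- **PCoA.** Classical Gower double-centering of −½D², symmetric
  eigendecomposition, embedding on positive eigenvalues only; percent
  variance per axis uses the positive-eigenvalue sum as denominator, and
  negative eigenvalues are reported but never enter the embedding or the
  denominator. (The "standardized covariance" variant popularised by
  GenAlEx is not reconstructed; classical PCoA satisfies the same
  recovery property for Euclidean inputs.)
- **Evanno ΔK.** From replicate log-probabilities L(K) over a contiguous K
  range with ≥2 replicates per K:
  ΔK = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)) with the
  sample sd; endpoints are undefined and a zero sd raises a
  degenerate-divisor error rather than returning an infinite peak. The
  MCMC clustering that produces L(K) is out of scope; ΔK consumes a table
  from any source, including the synthetic curve generator.

## Linkage

Two-point estimation applies to same-parent testcross columns: with d
mismatching of n jointly scored progeny, r̂ = min(d, n−d)/n, the phase is
coupling when mismatches are the minority, and
LOD = k·log₁₀(2r̂) + (n−k)·log₁₀(2(1−r̂)) with k recombinants under the
chosen phase (0·log 0 = 0). Grouping uses the independence LOD
G²/(2 ln 10) on the 2×2 progeny table, which is defined for any marker
pair (cross-parent pairs share no meioses under the pseudo-testcross
model, so only the independence form applies to them), followed by
single-linkage closure above LOD 5 with deterministic group numbering
(size, then smallest member). On complete testcross data with balanced
margins the two LOD formulas coincide exactly; with unbalanced margins
they differ at second order in the imbalance, which is why the
equivalence test uses balanced tables. Any pairwise statistic requires 20
jointly scored progeny. Multipoint marker *ordering* is intentionally not
implemented (the reference workflow uses a proprietary ML ordering);
`map_stats` consumes externally supplied or simulator-truth orders and
reports per-LG spans, total length, gaps above 8 cM, and both common
per-marker density definitions (total length / marker count, and mean
adjacent interval), since published "average distance" figures are
ambiguous between the two.

## Synteny

Linkage groups named with a Roman homoeology prefix (I-1 … VII-4) expect
the reference pseudochromosome of their prefix; concordance is the
fraction of anchored markers on the expected chromosome (markers without a
physical anchor are excluded from the denominator and counted separately).
For order comparison within an LG, markers are sorted by cM (ties by bp
then id) and the longer of the longest strictly increasing / decreasing
subsequences of bp is the colinear backbone, fixing the LG's orientation.
Off-backbone markers are rearrangement candidates; adjacent runs
containing at least three candidates that are monotone against the
backbone orientation are reported as inverted blocks, extended over
neighbouring backbone markers while the reversed order continues (so a
block bounded by one backbone marker that completes the run is reported
whole). Kendall τ is reported per LG. The LIS tie-break prefers the
lexicographically smallest index sequence, making output deterministic.
Single-marker long-range discrepancies remain candidates; deciding between
assembly error and transposition is not attempted. Physical positions in
Mbp are scaled ×4 by default for co-plotting against cM.

## Synthetic data

The generators exist so every stage is testable with known truth; their
defaults are the study conditions.

- **Octoploid cross** (`CrossSimConfig`): 94 progeny; dosage-class counts
  default to ~1/10 of the observed post-filter composition of the real
  family (184/153 testcross, 340 intercross, 200 duplex, 100 triplex);
  7 linkage groups of 75 cM (the real map averages ≈75 cM per LG);
  missing rate 0.10, error rate 0.01 (symmetric 0↔1 flips applied after
  inheritance — the simplest mechanism that produces the double-crossover
  artifacts seen in dense maps); per-allele depth lognormal with log-mean
  6.0 and log-sd 1.0 (median ≈400 reads, so a realistic majority of
  intercross alleles fall under the 600 row-sum threshold). Simplex-class
  markers are placed on the map and inherit through shared per-chromosome
  meiosis paths with Haldane recombination (no interference); duplex and
  triplex doses are independent unlinked homolog pairs, which is adequate
  because multiplex alleles are discarded before mapping. Noise is applied
  to progeny only; the parental-line clauses of the missing filter are
  exercised by direct unit tests instead. Note one deliberate consequence:
  with a flat 10% per-call missing rate, the "more than 10% missing"
  exclusion sits at the centre of the binomial distribution, so roughly
  half the simulated alleles are excluded at that stage — the synthetic
  panel stresses the boundary rather than reproducing the real data's
  per-marker missingness profile (real missingness is concentrated in a
  minority of markers).
- **Diversity panel** (`PanelSimConfig`): 62 accessions × 603 markers,
  K = 2 subpopulations, Balding–Nichols-style drift (F_ST-like divergence
  0.15) around uniform ancestral band frequencies in [0.05, 0.95], and
  admixture 0.10 mixing each accession's unit membership with a Dirichlet
  draw. Membership truth is returned for validation. The generator does
  not emulate marker ascertainment, linkage between markers, or
  missingness, so panel-level tests validate the statistics, not the
  platform's error profile.
- **Log-probability curves**: piecewise-linear mean L(K) rising steeply
  (+100 per K) to the true K then flattening (+5 per K), Gaussian
  replicate noise (sd 10), 20 replicates over K = 1…10 — the canonical
  knee shape ΔK targets, at the protocol's replication scale.

All generators take a single integer seed and are byte-reproducible.

## Numerical and engineering choices

- Chi-square tails use `scipy.stats.chi2.sf`; tests cross-check against
  the closed form p = erfc(√(x/2)) to 1e-10.
- The retention iteration tolerance is 1e-12 with a 10,000-iteration cap;
  non-convergence raises rather than returning a stale value.
- Trees are `dendropy.Tree` objects throughout; Newick round-trips
  preserve topology, lengths (1e-9) and support labels.
- Distance matrices must be symmetric to 1e-12 with a zero diagonal;
  asymmetric input is rejected rather than silently symmetrised.
- Problem sizes in the test suite and analysis scripts (hundreds to ~1,000
  markers, bootstrap 40–200 where exercised end-to-end) are chosen to keep
  the full pipeline comfortably interactive while leaving every statistic
  in its asymptotically informative regime; the protocol default of 1,000
  bootstrap replicates remains the library default.

## Known limitations

- Only disomic segregation ratios ship by default; polysomic or mixed
  inheritance requires supplying a custom ratio set.
- No imputation and no genotype-likelihood dosage calling; calls are taken
  as scored.
- Marker ordering within linkage groups and Bayesian admixture inference
  are out of scope by design (orders and log-probability tables are
  inputs).
- The redundancy collapse is transitive (union-find over flagged pairs), so
  a chain of pairwise-similar columns can collapse even when its endpoints
  fall below the threshold; with the 0.99 default this matches the
  "identical loci" use case it serves.
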