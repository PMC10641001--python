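# Methods

This note documents the models, estimators and numerical conventions behind
`noduplex`, the design choices that were genuinely open, and what the
synthetic-data generator does and does not emulate.

## The competition model and the change-factor estimator

A mixed inoculant of S tagged reference strains is applied to a legume
variety; n colonies plated from the inoculant and n isolates from surface-
sterilized nodules are typed per biological experiment. The generator and
the estimator share one model:

* the realized starter mix `p*` is a Dirichlet draw around equal
  proportions with concentration `c` (default 100, i.e. a realized share of
  1/7 wanders with SD ≈ 0.035 — the mix is made volumetrically to equal
  optical density but is never exactly equal);
* inoculum colony counts are multinomial(n_colonies, `p*`);
* nodule counts are multinomial(n_nodules, q) with `q ∝ p* × w`, where `w`
  is the per-strain relative nodulation competitiveness. The weights are the
  quantity of scientific interest.

Because `q_s / p*_s ∝ w_s`, the normalized enrichment ratios recover `w`
exactly in the infinite-data limit, independent of the realized mix — this
is what the correction factor buys.

**Estimator.** Per experiment, the inoculum proportion is estimated with a
pseudocount (default 0.5): `p̂_s = (k_s + 0.5) / (n + S/2)`. A 1/7-share
strain is missed entirely by a 21-colony plating with probability ≈ 3.6%,
which would otherwise leave a zero denominator. The enrichment ratio is
`r_s = p̂_nod,s / p̂_s`; the **change factor** is `V_s = r_s` for enriched
strains (`r ≥ 1`) and 0 for depleted ones — the zero-truncation is a
reporting convention. The **percent of mix** averages the *untruncated*
ratios over the k experiments first and normalizes once:
`percent_s = 100 · r̄_s / Σ_t r̄_t`. The SE is the sample SD of the
per-experiment percentage vectors divided by √k.

Two alternatives are implemented behind flags and deliberately not default:

* `truncate_percents=True` normalizes the truncated V instead. Truncation
  removes the depleted strains' mass from the denominator and inflates the
  dominant strain's percentage (simulation at the default study size: a
  0.60-weight strain reports ≈ 66% instead of ≈ 60%), so the truncated
  percentage is not a consistent estimator of `w`; it exists because some
  presentations zero the depleted strains everywhere.
* `per_experiment=True` normalizes within each experiment before averaging.
  Each experiment's bars then sum to 100 individually; the point estimate
  acquires a small extra ratio-noise bias relative to average-then-normalize.

Remaining small-sample bias: with n = 21 the ratio `r_s` has a heavy right
tail whenever an inoculum count is low, which inflates minor strains'
percentages and deflates the dominant strain's by roughly 1–2 points at the
default study size. The estimator is consistent — the bias vanishes as n and
the number of experiments grow — and the Monte-Carlo recovery tests bound it
within 3 SE at 200 simulated studies.

Unassigned isolates (typing below threshold) are dropped and the nodule
sample size reduced; their count is recorded on the count table.

## Fingerprint typing

Band profiles are fragment-size lists (bp). Similarity is a Dice coefficient
over a maximum one-to-one matching of bands within a size tolerance
(two-pointer sweep over the sorted lists; for points on a line with a fixed
tolerance the greedy sweep is maximum, hence similarity is symmetric and
monotone in the tolerance). Defaults: tolerance 10 bp, minimum similarity
0.8, minimum margin over the runner-up 0.05 — conservative values for
agarose-gel rep-PCR; there is no published numeric rule to inherit, so all
three are configurable. Exact ties are broken alphabetically by tag and
necessarily carry margin 0, so any positive margin threshold reports them
unassigned.

The generator plants band structure matching how the two primer systems
behaved in practice: every pair of ERIC profiles is disjoint (Dice 0), while
one designated pair of reference strains (tags B and E) shares a
near-identical BOX profile (Dice ≈ 0.94) — so ERIC discriminates the whole
library and BOX leaves exactly one ambiguous pair.

## ITS phylogeny

Distances: p-distance, Jukes–Cantor 69 (`d = −¾ ln(1 − 4p/3)`, saturation
error at p ≥ 0.75) and Kimura 2-parameter from transition/transversion
proportions. The distance model used by the original MEGA analysis (Maximum
Composite Likelihood) is not implemented: it requires joint estimation
across all pairs, and no result here depends on reproducing its values;
JC69 is the default. Gap/N handling is pairwise deletion by default
(complete deletion available).

Neighbor-Joining is the classical algorithm: join the pair minimizing
`Q(i,j) = (m−2) d(i,j) − R_i − R_j`; branch lengths
`l_i = d_ij/2 + (R_i − R_j)/(2(m−2))`; new-node distances
`d(u,k) = (d_ik + d_jk − d_ij)/2`. Ties in Q are broken by the
lexicographically smallest pair of cluster keys (a cluster's key is its
smallest leaf label), making the topology deterministic. Negative branch
lengths — possible on non-additive input — are truncated to zero with the
deficit moved to the sister branch so the joined pair's path length is
preserved. On additive matrices NJ is exact; the tests verify topology and
branch lengths to 1e-12 against exhaustive least-squares fits over all
topologies (4–6 taxa).

Bootstrap: columns resampled with replacement to the original length;
support of each internal bipartition of the *original-data* tree is the
percentage of replicate NJ trees containing it (supports are displayed on a
single tree, not a consensus). Replicates whose distances saturate are
skipped, warned about, and removed from the denominator. Each replicate's
RNG stream is seeded by (master seed, replicate index), so supports are
reproducible and independent of evaluation order. Edges below the support
threshold (default 50%) are contracted into polytomies; rooting places the
root at the midpoint of the outgroup's pendant edge.

Cluster calls: an isolate aligned to the library coordinates is assigned to
the nearest reference by model distance, or called "novel" when the minimum
distance exceeds the novelty cutoff. The cutoff (default 0.05
substitutions/site) is ours: it sits between the within-clade distances of
the default library (≈ 0.03) and the indigenous cluster's divergence
(≳ 0.15), and it is configurable because no published threshold exists.

## The synthetic generator

ITS sequences evolve by per-site Jukes–Cantor substitution along a fixed
known tree: two reference clades (stems d/2, tip branches d/6), a
deep-branching indigenous cluster (stem 1.2·d) and an outgroup (pendant
3·d), everything scaled by the clade-divergence parameter d (default 0.10;
0 yields identical sequences). JC was chosen because its pairwise distances
have a closed form, giving the tests an analytic oracle. The generator
verifies that the outgroup is farther from every library member than any
within-library pair. Alignments are gapless and equal-length (no indel
process — the alignment step is out of scope), default 461 columns.

Band observations perturb the true strain's bands by uniform integer jitter
(default ±3 bp); pool bands are spaced 30 bp apart so the default tolerance
can never cross-match distinct bands. True strain labels travel in a
separate `true_tag` column used only for evaluation — the typing stage
never reads it.

Trait tables are balanced variety × treatment × block × experiment draws
from a linear model (grand mean + main effects + interaction + Gaussian
block effect + Gaussian residual). The default cell means are the package's
greenhouse scenario (three varieties × uninoculated/single/mixed
treatments); residual SDs derive from that scenario's per-trait CVs
(sd = CV/100 × grand mean) and block SD is half the residual SD (a
moderate block-to-residual ratio; no published value exists). Nodule counts
are rounded truncated Gaussians — means were published without a dispersion
model, so a count distribution would be an invention — with structural
zeros: uninoculated red and cream varieties never nodulate (no compatible
indigenous rhizobia), and those cells are exactly 0.

Default competitiveness weights per variety follow the published
rankings (red: C 0.60, G 0.16, A 0.15, E 0.05, F 0.04, B = D = 0; brown led
by E with B and F close behind and G last; cream led by E then A with B and
D weak); shares not printed were chosen to sum to 1 while preserving the
stated order.

What passing tests on synthetic data do **not** show: real gels have
partial digests, intensity differences and co-migrating bands rather than
clean size lists; real ITS alignments have indels and rate heterogeneity;
real trait data have non-Gaussian errors and missing pots. The suite
validates the estimators under the stated model, not robustness to those
artifacts.

## ANOVA conventions

The RCBD factorial ANOVA is the classical balanced decomposition by
deviation sums of squares; the implementation refuses unbalanced tables
(no Type-II/III machinery). Several biological experiments are folded into
the block stratum by combining (experiment, block) into one block label, so
r = 9 complete replicates per cell at the default 3 × 3 layout; a
two-stratum split-plot analysis was considered and rejected because the
published design description does not identify a second error stratum.
`SED = √(2·MSE/r)` applies to equal replication only, matching the single
LSD per trait convention. Letters use insert-and-absorb on descending
means: every maximal run whose members are mutually within LSD shares a
letter, so two cells share a letter iff they differ by less than LSD (with
MSE = 0 nothing separates and all cells share 'a'). Tukey letters reuse the
same run construction on the Tukey rejection pattern. Percent changes are
rounded to the nearest integer by default, the precision at which such
gains are usually quoted.

## Problem sizes and determinism

Default study sizes are the real protocol's: 21 colonies and 21 nodules per
experiment, 3 biological experiments, 3 × 3 factorial with 3 blocks × 3
experiments, 1000 bootstrap replicates in production configs. The validation
suites use 100-replicate bootstraps, 100-run clade-recovery simulations,
200-study recovery ensembles and 10,000-rep null calibrations — sizes at
which the Monte-Carlo error of each checked quantity is well below the
tolerance being asserted. Every stochastic component takes an explicit
integer seed (numpy Generator); the pipeline manifest records seeds,
parameters and output checksums, and identical configs reproduce
byte-identical outputs.

## Known limitations

* The change-factor percentage carries the small-sample ratio bias
  described above; at n = 21 it is within ±2 points for a dominant strain.
* MCL distances, maximum-likelihood/Bayesian trees and multiple sequence
  alignment are out of scope; pre-aligned input is assumed.
* The LSD letter display presumes equal replication; unbalanced data are
  rejected rather than approximated.
* K2P saturates earlier than JC69 on short alignments with extreme
  transition skew; saturated pairs raise errors rather than returning
  clipped distances.
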