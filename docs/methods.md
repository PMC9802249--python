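# Methods

`yamori` reconstructs the demographic side of a human-mediated dispersal
study: how Schlegel's Japanese gecko (*Gekko japonicus*) spread from mainland
China across the Japanese archipelago, dated from genome-wide SNPs. The
package implements the three quantitative stages of that analysis — a
structured-coalescent SNP simulator, stairway-style effective-size inference
from site-frequency spectra, and approximate Bayesian computation for
divergence times and model choice — plus a synthetic-data generator shaped
like the study's ddRAD SNP matrices, so the whole pipeline is testable
without sequencing data.

## Demographic models

A `DemographicModel` is a rooted population tree. Backward in time, each
`SplitEvent` merges a derived population into its ancestor at a fixed time
(in generations); populations have diploid effective sizes `Ne`, optionally
piecewise-constant via `SizeChange` steps; `MigrationSpec` entries are
backward per-lineage migration probabilities per generation. Validity is
enforced at construction: the splits form a single rooted tree, and every
split predates the next split along its ancestral lineage.

Two presets encode the study's scenarios. `M1` has ten populations (Nanjing,
Fukue, Kyushu, Chugoku, Shikoku, Kinki, Hokuriku, Tohoku, Tokai, Kanto) and
nine splits at the estimated median divergence times (6,506 generations for
Nanjing–Fukue down to 80 for Tokai–Kanto); `M2` is the same tree plus one
shared symmetric migration rate on every parent–child pair — the minimal
one-parameter gene-flow extension. Sizes are not published numerically, so
every population defaults to Ne = 10,000 diploids (a neutral round figure in
the middle of the stairway estimates; every preset accepts overrides). Times
are kept in generations internally; the mutation rate 3.75e-8 per site per
generation and the 1.5-year generation time (2.5e-8 per site per year × 1.5)
convert to calendar years only at reporting time.

## Coalescent simulation of SNPs

The simulator runs the structured Kingman coalescent in continuous time:
within a population of size Ne every lineage pair coalesces at rate
1/(2Ne) per generation (adequate for Ne ≫ sample size), splits teleport all
lineages of the derived population into the ancestor, and migration moves
single lineages at their backward rates. The event loop is a numba kernel;
identical inputs and seed give bit-identical output.

SNPs are unlinked: each polymorphic site gets its own genealogy, with exactly
one infinite-sites mutation on a branch chosen proportionally to branch
length, so every emitted site segregates in the total sample — the
ascertainment of SNP-count-parameterized simulation. One subtlety matters:
real SNPs arise from mutations, so the genealogy *carrying* a SNP is
length-biased (`P(tree) ∝ L·f(tree)`), not `f`-distributed. Conditioning each
independently drawn tree on one mutation would instead weight frequencies by
`E[L_i/L]` and visibly distort the spectrum (for n = 4 the singleton class
rises from 0.545 to ≈ 0.58). The simulator therefore draws trees from an
independence-Metropolis chain whose stationary law is the length-biased
distribution (acceptance `min(1, L_new/L_cur)`, 16 burn-in proposals): the
marginal law of every site is exactly the low-mutation-rate limit, at the
cost that a rejected proposal re-uses the current tree for the next SNP with
a freshly drawn branch. The resulting weak between-SNP dependence (a few
percent of adjacent sites share a genealogy, much like multi-SNP ddRAD loci)
leaves all means unbiased and only mildly inflates Monte-Carlo variance;
tests that form standard errors account for it with modest slack or
block-wise error estimates.

Diploid genotypes pair consecutive lineages (random union of gametes under
exchangeability). `ascertained=False` is refused with an explanatory error:
under one-mutation-per-genealogy there is no monomorphic site to emit.

## Summary statistics

Per-population allele counts (alternate-allele dosage among called genotypes,
with 2 × called diploids as the per-site sample size) are the shared
substrate. Spectra are projected to a smaller haploid size by the expected
(fractional) hypergeometric mass — deterministic, and it absorbs missing
genotypes; the default projection is 2N−1. Folding to minor-allele spectra is
the default representation since no outgroup polarization is assumed;
re-folding a folded spectrum is a typed error.

Pairwise differentiation:

* **Hudson F_ST**, multi-locus ratio of averages,
  `1 − mean(H_w)/mean(H_b)`, with unbiased within-population heterozygosity
  `2d(n−d)/(n(n−1))`. A pure function of allele counts. Note the unbiased
  form makes two literally identical count vectors score slightly negative —
  the price of unbiasedness under resampling.
* **Weir–Cockerham θ** (diploid, two populations): per-site a/b/c variance
  components from genotype frequencies, summed before the ratio.
* **Φ_ST**: the two-level AMOVA fixation index with per-site allelic
  mismatch as the distance, haploid alleles as units; per-site sums of
  squares and degrees of freedom are accumulated across sites, which for
  complete data reproduces the textbook AMOVA on the summed distance matrix
  exactly (pinned against an independently coded oracle in the tests).

The ABC summary vector is all pairwise F_ST values then all pairwise Φ_ST
values in a fixed population order. It defaults to the Hudson estimator
because the simulated fast path produces allele counts, not genotypes, and
ABC is only valid when observed and simulated sides share one estimator —
the vector carries the estimator as metadata and mismatches are structural
errors. Pairs with no usable sites yield NaN with a logged diagnostic, never
a silent zero.

## Stairway inference

With `k` ancestral lineages the coalescent interval has expected length
`4·N_k/(k(k−1))` when the size during the interval is `N_k`, and a mutation
arising then is carried by `i` of `n` samples with probability
`p(i|k,n) = C(n−i−1,k−2)/C(n−1,k−1)`. Writing `θ_k = 4·N_k·μ·L` the expected
unfolded spectrum is linear, `E[ξ_i] = Σ_k θ_k · p(i|k,n)/(k−1)`, reducing to
`θ/i` for constant size (the analytic anchor, verified to <1%). Folded
expectations sum the mirrored bins. For arbitrary time-based trajectories,
`expected_sfs` computes `E[T_k]` by fixed-seed Monte Carlo on the rescaled
clock `τ(t) = ∫dt/2N(t)` (200,000 replicates, ≈0.3% relative error).

`fit_stairway` maximizes the Poisson composite log-likelihood over per-
interval θ grouped into contiguous blocks (`nrand + 1` blocks over the
`n−1` intervals, oldest first), by box-constrained quasi-Newton on log θ with
three starts around the Watterson scale. Two estimation choices are worth
stating plainly:

* **Smoothness ridge.** A weak fixed penalty (default 1.0) on squared
  differences of adjacent block log-θ is added to the objective. Folded
  spectra at small n leave the saturated fit on an exact likelihood ridge —
  families of trajectories with identical expected spectra — and the
  unpenalized optimizer returns degenerate histories (θ → 0 epochs, no
  ancient epoch). The ridge selects the smoothest member of the ridge family,
  is data-independent (so it washes out as counts grow; constant-size
  recovery stays exact to <0.1% noise-free), and costs exact Poisson
  scale-equivariance, which then holds only approximately (tested both ways).
* **Model-dimension selection.** The four `nrand` candidates
  `(nseq−2)·(¼, ½, ¾, 1)` (rounded half-up, deduplicated) are scored by a
  50/50 multinomial train/validation split of the SFS: fit on the train half,
  evaluate the validation half's Poisson log-likelihood under the trained
  rates, keep the best.

Uncertainty comes from multinomial bootstrap of the SFS (default 200
replicates, refit at the chosen nrand); the fit reports pointwise median and
central 75%/95% envelopes of Ne on a common log-time grid (nesting is
guaranteed by construction). The envelopes are pointwise bands, not
simultaneous confidence regions: on any single dataset a 95% band may exclude
the truth over a short stretch of the grid even when the fit is sound, so
coverage claims should be read per time point. The absolute Ne and time scales enter through
`n_sites` (the callable length behind the SFS) via `θ = 4·Ne·μ·L` — for
SNP-only synthetic spectra the experiments calibrate `n_sites` so the
expected SNP count matches the simulated one. The bottleneck date is read off
as the geometric midpoint of the median curve's minimal plateau
(`ne_minimum_time`), in generations or years.

## ABC

Priors are noninformative: log-uniform Ne per population, uniform split
times with hierarchical top-down sampling (root time from its own bounds,
each descendant uniform below its parent's drawn value — constraints hold by
construction, never by rejection), log-uniform shared migration rate for the
gene-flow scenario. The default Ne bounds are log-uniform on [10³, 10⁵]
diploids. This choice carries real weight: F_ST and Φ_ST are invariant under
a joint rescaling of all sizes and times, so nothing in the summary vector
pins the absolute scale — the posterior time scale is inherited from the Ne
prior's location. Centering the prior (geometric mean 10⁴) on the scale of
the study system is therefore a modelling statement, not a tuning knob;
bounds a decade lower would simply halve every inferred age. All bounds are
configurable per analysis.

`build_sim_table` draws parameters, simulates `n_snps` SNPs per draw
(default 250 — summary noise at this count is small against prior spread)
and records the summary vector; row seeds derive from (master seed, row), so
tables are deterministic and resumable. Failed rows are flagged NaN, never
aborted. Rejection ABC standardizes each statistic by its median absolute
deviation across the table (robust to the heavy-tailed prior-predictive
distributions; zero-MAD columns are dropped with a warning), takes Euclidean
distances, and accepts exactly `⌈tolerance·n⌉` rows (ties by row index).
Posterior summaries are type-7 empirical quantiles.

Model choice pools the candidate tables, accepts jointly, and either reports
per-model shares ("rejection") or fits a multinomial logistic regression of
the model label on the standardized statistics within the accepted set and
evaluates it at the observed vector ("mnlogistic", scikit-learn with a small
ridge; probabilities clipped to [1e-6, 1−1e-6] and renormalized). A
single-model accepted set falls back to rejection with a warning.

## Synthetic data

`study_design()` reproduces the study's sampling frame: 11 regional groups
(182 diploids; Tohoku 15, Kanto 15, Tokai 31, Hokuriku 39, Kinki 16, Chugoku
16, Shikoku 12, Kyushu-T 16, Fukue 6, Kyushu-F 13, Nanjing 3), 30,477 SNPs,
2.43% missing genotypes, generated under the M1 preset. The two Kyushu
groups are drawn from the single Kyushu model population (the second is not
a distinct divergence-scenario deme). Missingness is independent Bernoulli
per genotype — real ddRAD missingness is locus-structured, so tests passing
under this generator say nothing about locus dropout patterns — and a mask
that would empty a site is redrawn. What the generator does emulate:
sample-size imbalance across groups, ascertained biallelic SNPs, folded-MAF
spectra, and divergence-graded differentiation. What it does not: linkage
within loci beyond the weak genealogy sharing noted above, sequencing error,
allele-dropout-driven heterozygote deficits, and paralog collapse.

## Calibration experiments and problem sizes

Two recovery experiments (in `yamori.experiments`, rerun by
`scripts/acceptance.py`) measure the estimators at the package's chosen desk
scale:

* **Root-split recovery**: one dataset under M1 at the median split times
  (Ne 10,000, study sample sizes, 5,000 SNPs); a 20,000-row M1 table at 250
  SNPs per row; rejection at tolerance 0.01. The posterior median of the
  root split is compared with the generating 6,506 generations. Across seeds
  the median lands within roughly ±20–30% — the spread reflects 200 accepted
  draws in a 19-parameter space, and the scale anchoring discussed above.
* **Bottleneck dating**: a 12-lineage folded SFS (≈20,000 SNPs) under a
  50-fold crash spanning [1,400, 2,000] generations with onset 2,000
  generations = 3,000 years; stairway with 200 bootstraps. The fitted
  Ne-minimum time lands near 2,000–2,500 years, within a factor two of the
  onset. The sharp-crash design is deliberate: with a gradual recovery the
  Ne minimum is smeared across the whole recovery window and "the
  bottleneck's time" stops being a well-defined estimand.

## Known limitations

* Absolute ABC time scales are prior-anchored (scale-free summaries); treat
  inferred ages as conditional on the Ne prior's location.
* The stairway ridge slightly smooths sharp size changes; envelopes at the
  very recent and very ancient grid edges are unstable (few coalescent
  events inform them), which is why summaries focus on the central range.
* No recombination within loci, no finite-sites mutation, no sequence
  output; migration-heavy scenarios (rates ≳10⁻²) are markedly slower to
  simulate because each genealogy accumulates many migration events.
* The mnlogistic step is a point evaluation at the observed vector; with
  strongly separable scenarios it saturates at the probability clip.
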