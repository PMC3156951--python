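# Methods

## The patient-oriented model

For patient i and gene set s, let z_is = 1 if at least one gene of s
carries a somatic event in tumor i (multiple events in one gene collapse
to a single alteration). The set statistic is T_s = Σ_i w_i z_is. With
unit weights this is simply the number of altered patients — the quantity
the exclusivity principle makes informative, since driver hits within one
pathway tend to occupy different tumors.

Inference conditions on per-patient null alteration probabilities π_is and
treats the z_is as independent across patients:

* **Permutation null.** Patient i's n_i events are placed on n_i distinct
  genes chosen uniformly from the G-gene universe, giving the
  hypergeometric complement π_is = 1 − C(G−m_s, n_i)/C(G, n_i) for a set
  of m_s (post-intersection) genes. Computed in log space (`gammaln`), so
  exome-scale G loses no precision; π = 1 exactly when n_i > G − m_s.
  This null needs no coverage or rate information, which is why it is the
  recommended default.
* **Passenger null.** Gene j in patient i accumulates passenger events as
  Poisson with mean λ_ij = f_i · Σ_c L_jc r_c, where L_jc counts the
  successfully sequenced nucleotides of context class c in gene j, r_c is
  the per-nucleotide passenger rate, and f_i is an optional per-patient
  multiplier (default 1). Independence across genes gives
  π_is = 1 − Π_{j∈s} exp(−λ_ij), accumulated through `log1p`. The Poisson
  form was chosen over a per-nucleotide binomial; at realistic exome rates
  (~1e-6/nt) the two agree to ~1e-9 and Poisson composes cleanly across
  context classes.

With unit weights T_s is Poisson-binomial; `poisson_binomial_tail` runs the
O(n²) convolution and reports P(T ≥ t_obs) *including* the observed point
mass, which guarantees validity (P(P ≤ α) ≤ α) for this discrete statistic.
Weighted tails are exact sums over the 2^n outcome space, evaluated by a
meet-in-the-middle split (two 2^{n/2} half-enumerations joined through a
sorted tail-probability scan), feasible up to n = 25 patients; beyond that
the add-one Monte-Carlo estimator (1 + #{replicates ≥ t})/(B + 1) is used,
which is never exactly zero. Outcome sums within 1e-9·(1+|t|) of the
threshold count as ties so the observed outcome's mass is never dropped to
floating-point re-association.

**Heterogeneity weights.** The default weight is the self-information
w_i = −log π_is: an alteration in a patient unlikely to be altered by
chance is stronger evidence, which automatically down-weights hypermutated
tumors. Patients with π = 0 (no events under the permutation null) or
π = 1 (saturated) get weight 0; a set with π = 1 in every patient carries
no information and is reported with P = 1 and flagged `untestable` rather
than dropped. The weight function is a named, pluggable strategy
(`neglog`, `unit`, `one_minus_pi`) so alternatives can be swapped without
touching the inference code.

## Gene-oriented comparator

Genes are scored with a one-sided Poisson LRT of the observed total count
n_j against the cohort passenger expectation λ_j = Σ_i f_i Σ_c L_jc r_c:
LRT_j = 2[n_j log(n_j/λ_j) − (n_j − λ_j)] when n_j > λ_j, else 0; a gene
with events but λ_j = 0 gets an infinite score, ranked first and logged.
Each set is then tested with a one-sided Wilcoxon rank-sum comparison of
in-set versus out-set score ranks (midranks for ties). The normal
approximation carries tie and continuity corrections; when the smaller
group has ≤ 10 genes *and* the rank-subset count is ≤ 2·10⁵, the exact
permutation distribution is enumerated instead. Because the scores sum
counts over patients, this pipeline is provably invariant to how a fixed
per-gene total is distributed across patients — the property the
patient-oriented score is designed to detect, and a direct unit test.

## Multiplicity and rank concordance

q-values are Benjamini–Hochberg (step-up, capped at 1; delegated to
statsmodels). The test statistics across sets are discrete, dependent and
not identically distributed, so BH is expected to be conservative here;
the calibration study below measures this rather than assuming it.
Set ranks are ascending-P midranks (ties share the average position). CAT
curves report |top-k(A) ∩ top-k(B)|/k between two methods' rankings; ties
are broken deterministically by set_id since a total order is required.

## Synthetic data generator

`synth_cohort` emulates a 21-tumor exome study over 20,661 genes with
per-patient loads drawn uniformly from 12–63 events (median ≈ 35) — the
scale of the cohorts this methodology targets. Specifically:

* gene coding lengths are log-normal (median 1.3 kb, σ = 0.6), split over
  five context classes (CpG transitions 2%, other C:G transitions 18%,
  C:G transversions 20%, T:A changes 55%, indel exposure 5%);
* relative context rates (20 : 4 : 1.5 : 1 : 0.8, CpG transitions highest)
  are scaled so the expected passenger load per tumor at multiplier 1
  equals the midpoint of the load range; each patient's multiplier f_i is
  its drawn load over that midpoint;
* observed events land on distinct genes with probability proportional to
  passenger expectation, with contexts drawn from each gene's passenger
  proportions — i.e. the shipped catalog is itself null;
* gene sets (default 3,071, sizes clipped to 3–2,096 from a log-normal
  with median 10, σ = 1.4) are sampled with preferential gene reuse
  (Gumbel-top-k with log-usage bonuses) to mimic the heavy overlap of
  curated pathway collections.

What it does **not** emulate: mutational hotspots and true drivers,
correlated coverage dropout, sample contamination, and annotation error.
Passing tests therefore demonstrate correctness of the inference under the
stated nulls, not robustness to every artifact of real exomes.

## Simulation benchmark

Benchmark datasets combine a null catalog with 12 spiked-in sets (sizes
25/100/250 × alteration probabilities 0.25/0.50/0.75/0.90) made of fresh
hypothetical genes whose context models are resampled from the real pool,
so they never collide with background sets. An altered (set, sample) pair
contributes exactly one event, on a set gene chosen proportionally to
passenger expectation (the natural choice; only the context proportions
are pinned down by the passenger model). Two null mechanisms are
available: re-permuting the cohort's events among genes weighted by
passenger expectation (optionally excluding recurrent "mountain" genes
first, contexts redrawn from passenger proportions), or sampling the
passenger model directly.

Power is the average number of spiked sets within the top-X list; the
curve is a running count, hence non-decreasing in X. Calibration sorts
each replicate's sets by q, records the realized false-discovery
proportion among the top k against q_(k), and averages both across
replicates; the package's acceptance checks compare average FDP with
average q at the 0.05/0.1/0.2 levels under a mechanism-matched analysis
null. Replicate seeds are spawned from the master seed with numpy's
`SeedSequence`, so any replicate can be reproduced in isolation.

Default problem sizes: 100 replicates at the full 3,071-set collection for
standalone runs; the shipped test suite and `scripts/acceptance.py` use 25
replicates over a 300-set background (full 20,661-gene universe — the
permutation and passenger probabilities of large sets depend directly on
G, so the universe is never shrunk), which reproduces the qualitative
contrasts in minutes on one CPU: the patient-oriented methods recover more
spiked sets in top-20 lists than the gene-oriented comparator and keep the
realized FDP at or below the average q-value, while the gene-oriented
comparator is markedly anti-conservative.

## Numerical and design notes

* P-values are P(T ≥ t_obs) with the observed mass included; combined with
  the discrete support this makes the null P-value cdf super-uniform,
  which the suite verifies empirically over 200 null datasets.
* Set sizes everywhere are counted after intersection with the gene
  universe, since every probability formula depends only on genes that can
  actually be hit; genes annotated outside the universe are intersected
  away with a logged count.
* The permutation-null sampler assigns events uniformly; a weighted mode
  (proportional to passenger expectation) backs the simulation mechanism.
  Degenerate weight vectors that cannot supply enough distinct genes fall
  back to uniform for the remainder.
* Monte-Carlo P-value mode uses the (r+1)/(B+1) estimator; the enumeration
  cutoff of 25 patients keeps a 21-tumor design exact even for weighted
  scores.
* All identifiers are case-sensitive exact strings; no gene-symbol
  aliasing is attempted.

## Known limitations

* The independence of z_is across patients is exact under both nulls but
  the analysis ignores dependence *across sets* except empirically (via
  the calibration study); BH q-values inherit that caveat.
* The heterogeneity weight family is a design choice; other reasonable
  weightings (e.g. 1 − π) are provided but the package makes no claim of
  optimality.
* Copy-number, expression and methylation alterations are out of scope;
  their null distributions would require different machinery.
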