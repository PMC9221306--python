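# Methods

## Behavioral model and estimands

The conditioned courtship suppression paradigm scores, per male, the
intervals of courtship within a 300-s observation window. The courtship
index is the percentage of the window covered by the interval *union* of
the scored bouts; merging rather than summing keeps CI ≤ 100 when scorers
record overlapping or redundant bouts, and makes CI invariant under bout
reordering and under splitting a bout into contiguous pieces (both are
property-tested). Bouts extending past the window are clipped with a
warning rather than rejected, since over-running a stopwatch is a scoring
artifact, not a data error. A male present in the file with no bout rows
has CI = 0 — an observed non-courter, distinct from a missing male. Times
are stored in seconds at millisecond resolution; interval comparisons use
a 1e-9 s tolerance.

The learning index of a strain at a time point is
LI = (1 − C̄I_tr/C̄I_na) × 100 computed from the *means* of independent
naive and trained cohorts. LI is undefined when the naive cohort did not
court (mean 0); this is reported as an explicit error, never as a
sentinel value.

## Randomization inference

The tests directly estimate α_R, the probability of rejecting H0, by
permutation. The test statistic is not dictated by the assay itself; this
package uses the difference of group means for the within-strain
trained-vs-naive test (the classical Sokal–Rohlf randomization statistic)
and T = LI_A − LI_B for between-strain and retention contrasts — i.e.
exactly the quantity the analysis reports. Two-sidedness is by |T|, and
permuted statistics within 1e-12 of |T_obs| count as extreme.

Sampled mode draws m label assignments uniformly and reports
α_R = (b+1)/(m+1); the +1 correction makes the sampled p-value strictly
positive and the test exactly valid. When the number of distinct
assignments C(n_x+n_y, n_x) is at most the `exhaustive_threshold`
(default 10,000) the two-sample test enumerates all of them and reports
the exact tail proportion with an `exhaustive` flag; a separate
`exact_randomization` entry point enumerates up to 200,000 assignments
and serves as the internal oracle for convergence tests.

LI contrasts permute under a *stratified* null: strain (or occasion)
labels are shuffled among naive males and, independently, among trained
males. Training status is never permuted, because naive and trained
cohorts are distinct groups of flies — only the strain/occasion label is
exchangeable under H0. The permutation unit is the individual male; a
plausible alternative (permuting whole cohorts) would leave almost no
permutation distribution at realistic cohort counts, so the male-level
scheme is the declared design choice. A permuted naive group with mean
CI 0 makes LI undefined; such permutations are redrawn and counted, with
a warning when more than 1% of the draws are redrawn and a hard error if
valid permutations are essentially unreachable.

Each test invocation owns one seeded NumPy generator and records its seed
in the result, so any single α_R is bit-reproducible. The timecourse
driver derives per-test child seeds from a master `SeedSequence` in a
fixed iteration order. Defaults are 10,000 permutations and rejection at
α_R < 0.05, both configurable. No multiplicity correction is applied
across behavioral contrasts by default (each contrast is reported with
its own α_R); a Bonferroni switch exists for users who want family-wise
control.

The timecourse table emits one row per strain × time point with the
within-strain α_R, an LI contrast against each configured control strain,
and a retention contrast against the strain's earliest testable time
point. Flag characters mirror common figure annotation: `*`/`&` when LI
is significantly *below* the first/second control, `#` when retention is
significantly below the immediate test. Cells with a missing cohort are
emitted with status `not_testable` rather than dropped.

## Olfactory assay

The unit of analysis is the T-maze replicate (a run of ~15 flies), not
the fly: V(%) = 100 × N_odor/N_total per replicate, and genotypes are
compared to the control by a two-sided Mann–Whitney U test. The test is
always nonparametric — no normality gate — because V from a strongly
repulsive odorant piles up near 0 and is not plausibly normal. Mode
`auto` uses the exact null distribution when the pooled sample is
tie-free and C(n+m, n) ≤ 20,000, otherwise the normal approximation with
midranks, tie-corrected variance and continuity correction; exact mode
refuses ties and falls back with a log line. The fully degenerate case
(every pooled value identical) has zero variance under any scheme and
returns p = 1 by symmetry.

## DE set concordance and enrichment

"Same pattern of change across replicate strains" is operationalized
strictly by default: a gene must be significant (FDR < 0.05, optional
direction filter) in *every* table with an identical logFC sign
throughout. A `lenient` mode (significant in ≥ 1 table, present and
sign-concordant in all) is provided because replicate-agreement wording
is genuinely ambiguous; the strict reading is the default since it can
only under-claim. Genes absent from any table are excluded and logged.

Enrichment is the one-sided Fisher exact test on the 2×2 table
(k, n−k; K−k, N−K−n+k), identical to the upper hypergeometric tail
P(X ≥ k); BH adjustment runs across the tested terms. The universe
defaults to the genes present in the DE tables (expressed-gene
background) rather than the whole annotation — the standard choice, since
unexpressed genes were never candidates. Annotation is flat (term → gene
set) with no ontology-graph propagation; term lists are taken as given.
Up- and down-regulated study sets are enriched separately, which is how a
two-directional enrichment display is produced from a one-sided test.
Dot-plot metrics per term: mean logFC over the term's significant genes
(omitted as NaN when there are none) and the fraction of the term's genes
significant at the threshold.

ΔΔCt fold change is 2^(−ΔΔCt) with
ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_control,
reference = a housekeeping gene (rp49 in fly-head qPCR); replicate Ct
arrays are averaged. The fold is invariant under any global Ct shift.

## Synthetic data generator

The generator defines the conditions every statistical claim in the test
suite is made under:

* **Courtship propensity** is Beta-distributed on [0,1] with mean = the
  strain's naive CI mean (default 50%) and one concentration parameter
  κ = 10 (sd ≈ 15 CI points at the default mean — a typical behavioral
  spread). Training multiplies the mean by a per-timepoint suppression
  multiplier m ∈ [0,1], so the expected LI is 100·(1 − m).
* **Bout placement** is an alternating exponential on/off renewal process
  rescaled so courtship covers exactly the drawn fraction of the window
  (bout count ~ Poisson around fraction × window / mean-bout-length,
  default mean bout 10 s) — the simplest process consistent with interval
  data. Endpoints are rounded to milliseconds.
* **Built-in profiles**: `control` (m = 0.33 everywhere, expected
  LI ≈ 67 — comfortably detectable at n = 20 while far from ceiling),
  `cbs_like` (m = 1, never learns), `cse_like` (m = 0.33 at early time
  points, 1 at the last — learns, then loses retention). Default layout:
  20 males per group, time points 0, 2 and 8 days.
* **Olfactory counts** are Binomial(15, p) per replicate, 31 replicates
  per genotype, p = 0.2 for every genotype by default (a strongly
  repulsive odorant affecting all strains equally).
* **DE tables** simulate per-gene z-scores: null N(0,1), planted genes
  |N(6,1)| with the sign of the planted direction (90% down by default);
  p = 2Φ(−|z|), BH-FDR within each table; logFC is N(0, 0.25) for null
  genes and sign·|N(2, 0.25)| for planted genes, with the *same* planted
  genes and signs in every replicate contrast. Planted genes are 80% of
  each designated annotation term (20 terms of 50 genes over 6,000 genes
  by default).

What the generator does **not** emulate: scorer noise and bout-detection
error, within-male temporal correlation beyond the renewal process,
courtship rhythms, batch effects or library-size artifacts in DE tables,
and correlated genes. Passing tests therefore demonstrate correctness of
the statistics under a clean, well-specified data model — not robustness
to every artifact of real recordings.

## Problem sizes and numerical choices

The validation suite uses these sizes, chosen to give tight Monte-Carlo
bands while keeping a full run around a minute: 50 datasets over ten
small size pairs for sampled-vs-exhaustive agreement (±0.02 at
n_perm = 10,000); 1,000 null experiments at n = 20/20 with n_perm = 2,000
for type-I calibration (binomial 99% band [0.032, 0.070]); 200 seeded
runs per phenotype for power, also at n_perm = 2,000; 10,000 males per
group for LI recovery (±2 LI points); full enumeration for Mann–Whitney
(n, m ≤ 7) and hypergeometric tails (1,000 random 2×2 configurations).
The permutation count for calibration/power runs is scaled down from the
10,000 default since calibration error at 2,000 permutations (±1/2001) is
negligible against the binomial band being tested.

Degenerate inputs are decided, not left to float arithmetic: empty bout
lists give CI = 0; all-tied Mann–Whitney samples give p = 1; enrichment
terms empty after universe restriction are dropped with a log line;
sampled p-values are clipped into (0, 1].

## Known limitations

* The stratified LI-contrast null assumes CI distributions differ between
  strains only through their means under H0; heavy strain-specific
  variance differences are not separately modeled.
* Exhaustive enumeration materializes the full combination matrix and is
  capped at 200,000 assignments.
* The lenient concordance rule can include genes significant in only one
  contrast; counts from the two rules are not comparable.
* The CLI echoes its effective configuration but does not hash input
  files; determinism guarantees assume unchanged inputs.
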