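# Methods

## The estimation problem

Binary physical protein–protein interaction data for *S. cerevisiae* come
from two very different sources: literature-curated (LC) interactions
distilled from low-throughput experiments, and high-throughput (HT) screens
(genome-wide yeast two-hybrid library screens and a protein-fragment
complementation assay).  Neither source is complete and neither is
error-free.  If an HT screen sampled the interactome independently of
curation, the number of HT true positives that also appear in the curated
set would follow a hypergeometric law H(N, m′, n) — N the unknown number of
genuine interactions, m′ and n the true-positive counts of the two samples —
and moment matching would give the classical two-sample capture–recapture
(Lincoln–Petersen) estimate

    Is = TP_HT · TP_LC / TP_overlap.

The independence assumption fails in a specific, measurable way: curation is
enriched in interactions that are *easy to detect* with the same widely-used
assays the screens employ (most visibly, coverage of a library screen by
curated data rises with the screen's IST hit count).  Since both samples
over-represent the same "easy" interactions, the overlap is inflated and the
naive estimate is biased low.  The package's central operation corrects this
by restricting the curated sample to interactions involving *well-studied*
proteins — proteins cited by at least a cutoff number of papers — on the
rationale that such proteins have been probed with a wide variety of
labor-intensive assays, making their curated interactions much less
detectability-selected.  The estimator then reads

    Is = TP_HT · TP_LC_WS / |HT ∩ LC_WS|.

## Error-rate accounting

**FDR chaining.**  Partition each HT dataset into true positives found in
pre-2000 curated data (A), true positives not found there (B), and false
positives (C).  Assuming the curated reference covers the same fraction of
true positives in every screen (A₁/B₁ = A₂/B₂) and that false positives
never coincide with curated pairs, the observable coverage proportions
p = A/(A+B+C) link the two FDRs:

    FDR₁ = α·FDR₂ + 1 − α,   α = p₁/p₂.

The chain is anchored on the proteome-wide CCSB-YI1 screen, whose FDR is
taken as 0.25 by default and swept over [0.15, 0.35].  The curated reference
is restricted to interactions first reported before 2000 (the publication
year of the oldest screen) so that verification studies of screen hits
cannot inflate the coverage of older screens.  Chained values that fall
outside [0, 1] — possible when rounded input proportions push α past
1/(1−FDR_ref) — are clamped with a warning rather than raised.

**True positives.**  For a screen or union of screens,
TP = |HT| − Σᵢ |HTᵢ|·FDRᵢ, with the sum over component screens at their full
sizes and |HT| the deduplicated union (no overlap correction on the
false-positive sum; this is the literal accounting convention, kept as
such).  For the curated well-studied set, TP = |LC_WS| − 0.35·|LC_WS-unique|,
where the *unique* subset contains pairs supported by exactly one paper and
absent from the screen under consideration; 0.35 is the recuration-derived
false-positive rate for single-paper curation.  Every pair in the HT/LC
intersection counts as a true positive (two independent detections).
True-positive counts stay fractional throughout; rounding (half away from
zero) happens only in reports.

## Confidence intervals

Two normal-approximation intervals are implemented, both based on the
hypergeometric overlap variance evaluated at the estimate,
Var(k) = n·(m′/Is)(1−m′/Is)(Is−n)/(Is−1):

* `transformed_overlap` (default): a normal CI on the overlap count k,
  mapped endpoint-wise through Is = m′·n/k.  Asymmetric, wider above than
  below, matching the skew of the estimator's sampling distribution.  If the
  lower k endpoint is non-positive the upper bound is reported as infinite.
* `delta`: the delta method on Is directly,
  Var(Is) ≈ m′²n²·Var(k)/k⁴; symmetric.

Neither interval propagates uncertainty in the FDRs or in the single-paper
false-positive rate; those are treated as fixed parameters (their influence
is explored by sweeps instead).  On the standard synthetic benchmark the
default interval's empirical coverage is close to nominal (checked in the
test suite over 200 replicates).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `well_studied_cutoff` | 125 papers | minimum papers citing a protein for it to count as well-studied |
| `ws_mode` | `any` | one (`any`) or both (`both`) endpoints must be well-studied |
| `reference_dataset` / `reference_fdr` | CCSB-YI1 / 0.25 | anchor of the FDR chain |
| `unique_fp_rate` | 0.35 | FP rate of single-paper curated pairs absent from HT data |
| `pre2000_year` | 2000 | strict upper year for the chaining reference |
| `ht_paper_threshold` | 100 interactions | publications supporting more distinct pairs are high-throughput and excluded from curation |
| `ci_method` / level | `transformed_overlap` / 0.95 | interval construction |

Design choices where the convention was genuinely open: the well-studied
restriction defaults to *any* endpoint (the singular phrasing "involving a
well-studied protein"); self-pairs are kept (they occur in curated data; a
flag excludes them); publication years are parsed from the author/year
source column unless a dedicated year column is configured; the
"well-studied" threshold is inclusive (≥ cutoff); evidence-code matching is
case-insensitive with the spelled-out protein-fragment complementation assay
treated as PCA.

## The synthetic benchmark

`ppisize.synthetic` generates worlds that encode exactly the premises above,
so that the estimator and its bias correction can be tested with no
external downloads:

* a ground truth of `n_true` pairs drawn with heavy-tailed per-protein
  weights (lognormal, log-sd `degree_concentration`) — degree heterogeneity
  without committing to a particular global topology;
* papers-per-protein counts produced by a Gaussian copula at rank
  correlation `study_degree_correlation` (default 0.6) with degree, mapped
  to a lognormal count (median ≈ 12 papers, heavy right tail) — the
  generator reproduces the degree/study correlation without asserting a
  mechanism for it;
* per-pair detectability in (0, 1], Beta(1, 3) by default (most
  interactions are hard, a few are easy), playing the role of IST counts;
  exports discretize it to integer pseudo-IST values.

HT sampling captures each true pair with probability proportional to
`detectability ** assay_sensitivity_exponent` and injects uniformly drawn
false pairs to a target FDR.  LC sampling is biased by
`detectability ** detectability_bias_weight` and a study factor; with
`ws_assay_agnostic` the detectability term is dropped for pairs touching a
well-studied protein.  Curation errors are modeled per record: each
single-paper record is false with probability `fp_single_rate`, keeping its
more-studied endpoint and drawing a random false partner — errors plausibly
arise in papers about a studied protein, and this convention keeps the error
rate uniform across study strata.

Two frozen condition sets define the benchmark.  `unbiased_benchmark()`:
N = 20,000 true pairs on 2,500 proteins, ~6,000 LC and ~2,500 HT pairs at
FDR 0.25, no biases, no curation errors — the estimator should recover N
(parameter-recovery check, mean within 3%, CI coverage 90–99%).
`biased_benchmark()`: HT sensitivity ∝ detectability, LC
detectability-biased except for well-studied pairs, single-paper error rate
0.30 while the estimator applies the canonical 0.35 correction.  The
deliberate 0.35-vs-0.30 gap encodes the published caveat that the
recuration-derived 35% figure is likely an overestimate, making the
corrected estimate conservative (at or slightly below truth) rather than
centered on it; with it, the expected ordering
naive mean < well-studied mean ≤ N is stable across experiment batches.

What the benchmark does *not* emulate: real curated data's evidence-code
composition beyond a three-code caricature, protein abundance/localization
confounders, assay-specific systematic artifacts, or any attempt to fit the
generator to measured yeast statistics.  Passing the benchmark shows the
estimator behaves correctly *under its own assumptions* and that the
well-studied restriction removes the modeled detectability bias; it cannot
certify the magnitude of the bias in the real data.

## Numerical conventions and degenerate inputs

* Pairs are canonicalized (upper-case, lexicographically sorted endpoints);
  dataset sizes always count distinct pairs.
* A zero HT/LC overlap makes the estimator unbounded: single fits raise an
  actionable error; sweep rows are flagged `unbounded` and reported as NaN
  rather than aborting the sweep.
* Binned log-log regression: proteins are sorted by paper count with ties
  broken by identifier; a trailing short bin merges into its predecessor;
  bins with non-positive means are dropped before taking logs (zero-degree
  proteins never enter, since degree is computed from the dataset itself);
  base-10 logs (the slope and R² are base-invariant).
* IST binning is greedy ascending: a bin closes once it holds at least the
  minimum count and the next IST value differs, so equal-IST runs are never
  split; the open-ended tail merges into the last bin.
* The two-proportion evidence-code test uses the chi-square form without
  continuity correction by default (a flag enables it).
* All simulation randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; replicate seeds are spawned from the
  experiment seed, and identical seeds reproduce results bit-for-bit.

Problem sizes used by the shipped tests and benchmark (worlds of 20,000
true interactions, 200 replicates, IST bins of at least 200–400 records)
were chosen as the standard study conditions above; smaller worlds are used
only for loader round-trips and CLI smoke runs.

## Known limitations

* The chaining assumption (equal curated coverage of true positives across
  screens) cannot hold exactly for the PCA screen, whose assay postdates the
  pre-2000 reference window; its chained FDR is best read as an upper bound.
* The expanded reference-form of the estimator is algebraically exact only
  for single screens; for unions the component-sum accounting is
  authoritative.
* Published interval bounds for the real data depend on an interval
  construction that is not fully specified upstream; this package documents
  its two constructions and checks them against each other, not against a
  canonical external value.
* Estimates inherit the residual correlation between curated and screen
  data that survives the well-studied restriction; on real data they should
  be read as lower bounds.
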