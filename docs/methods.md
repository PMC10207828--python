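# Methods

## The enrichment statistic

Given a drug list ranked by a signed, nonzero value r (a connectivity
score, a correlation coefficient, a differential-sensitivity statistic),
and a set of drugs sharing a mechanism of action (MOA), the package walks
the list sorted descending and accumulates a running sum: a member drug
("hit") at position i adds |r_i|^α / Σ_hits |r_j|^α, a non-member
("miss") subtracts 1/(N − N_h), where N is the list length and N_h the
set size.  The enrichment score ES is the running-sum value of maximum
absolute deviation from zero, signed: positive when the set crowds the top
of the list, negative when it crowds the bottom.  This is the GSEA
statistic applied to drug sets.

The weight exponent α defaults to 1 (hits weighted by rank magnitude,
the standard GSEA choice); α = 0 recovers the classic unweighted
Kolmogorov–Smirnov statistic.  It is exposed as `weight_exponent` on
`EnrichmentParams`.

**Inference.**  For each MOA set, `n_permutations` (default 1000) random
drug sets of the same size are scored on the same list, giving a null
ES distribution.  Then:

* p-value: among the null scores with the same sign as the observed ES,
  the fraction at least as extreme in magnitude, clamped below at
  1/n_permutations (an empirical p of 0 is not reportable).  If no null
  score shares the sign, p is reported at the floor and NES is not
  computable.
* NES = ES / |mean of same-signed null ES|.  The absolute value in the
  denominator preserves the sign of ES for negative enrichments.
* FDR q: null NES values from *all* tested sets are pooled; for an
  observed NES n\*, q is the fraction of same-signed pooled null NES at
  least as extreme as |n\*| divided by the fraction of same-signed
  observed NES at least as extreme, clamped to [0, 1].  If the
  same-signed null pool is empty, q = 0 (no null score is as extreme).

A MOA is flagged significant when p < 0.05 and q < 0.25 (both
configurable); the defaults follow standard GSEA practice.

**Eligibility.**  A MOA set is evaluated only if at least `min_per_set`
(default 6) of its members are present in the ranked list; sets are
intersected with the list *before* the size test.  Drugs in no set remain
in the list as background.  At least two sets must survive.  Every rank
value must be nonzero: a zero carries no direction and would make the hit
weight degenerate at α = 1.

## Numerical choices

* Sorting ties on the rank value break by drug id (lexicographic), so
  result tables are reproducible byte for byte.
* Running-sum extremum ties take the earliest list position.  The
  observed ES is computed by a sequential prefix-sum walk; the
  permutation null uses an equivalent vectorized form that evaluates the
  running sum only at hit positions and immediately before them (the only
  places extrema can occur).  The two agree to the last ulp except when
  the maximum and minimum deviations tie exactly in magnitude, where
  rounding may select either sign; such ties are measure-zero for the
  observed statistic and inconsequential inside a permutation null.
* Each MOA's null uses a dedicated random stream derived from
  (seed, MOA name) via CRC32 into a `SeedSequence`, so results are
  independent of catalog iteration order and fully reproducible.
* Result tables are written with `%.17g`, and rank CSVs are parsed with
  correctly-rounded float conversion, so read → write → read round-trips
  are bit-exact.

## Weighted gene voting pipeline

The WGV score of a sample is the dot product of a signed gene signature
(weights, e.g. log2 fold-changes) with the sample's expression over the
genes present in both; genes absent from the expression matrix are
dropped and reported.  WGV scores are Pearson-correlated with each drug's
sensitivity profile (AUC, missing values skipped pairwise); drugs with
fewer than 3 complete pairs or zero variance are excluded and reported
(Pearson r is undefined below 3 pairs).  Drugs are then ranked by r
itself and fed to the enrichment analysis.  Because low AUC means
sensitive, a *negatively* enriched MOA is a candidate for selective
toxicity toward the signature's positive phenotype.  The correlation
p-value is reported for transparency but plays no role in ranking.
Drugs with exactly zero correlation are dropped from the ranked list
(a zero rank is inadmissible and carries no direction).  Samples used to
derive the signature should be excluded via `exclude_samples` to avoid
evaluating the classifier on its own training data.

## Simulation studies

Both generators reproduce the conditions under which the method was
characterized; their defaults are fixed and are not tuning knobs.

**Ranked-list study.**  1351 drugs ranked by N(0, 0.5) draws; a planted
set of X drugs (5–50) is re-drawn from N(Y, 0.5), Y ∈ [−1, 1]; zero
draws are re-sampled (preserving the distribution up to a measure-zero
event).  The planted set is evaluated alongside a background catalog,
by default a synthetic disjoint partition of the drugs into sets of
6–50 drugs (~50 sets at N=1351).  The null and power behavior under
test depends on set sizes, not identities, so the synthetic partition
stands in for a real annotation catalog; a real GMT can be supplied.
Each grid cell runs 50 replicates and records the planted set's mean NES
and the percentage of replicates meeting both significance thresholds.

**WGV study.**  200 cell lines; AUC for 1351 drugs drawn from a
two-component normal mixture (μ = 0.83 and 1.31, both σ = 0.08, 72% mass
in the lower, sensitive component, assigned independently per draw —
only the marginal mass is constrained); expression for a planted 25-gene
set from N(0, 0.5).  A perturbation v imposes a linear gradient of mean
shifts across cell lines: cell i (0-based) is shifted by −v + i·2v/200,
i.e. −0.1 for the first cell and +0.099 for the last at v = 0.1 with a
step of 0.001.  The gradient scales with v and vanishes at v = 0; a
fixed step independent of v would impose an association even at "no
perturbation" and destroy the study's negative control.  The gradient is
applied to the planted genes (expression) and to the planted 10-drug set
(AUC), each with its own v.  The signature weight of each planted gene
is its mean expression in the top decile of cell lines (ranked by
planted-gene mean) minus the bottom decile.  Only the planted genes are
materialized: the signature and the WGV scores involve no other gene, so
unplanted genes would be inert in every downstream computation.

**What the simulations do and do not show.**  The generators emulate the
marginal distributions and effect structure of pooled-screen sensitivity
data and normalized expression data, i.i.d. across drugs and genes.  They
do not emulate correlated drug responses within chemical families,
gene–gene co-expression, heteroscedastic or batch noise, or missing AUC
values, so passing benchmarks demonstrate calibration and power under
idealized independence, not performance guarantees on real screens.

**Problem sizes.**  The shipped benchmark tests run the negative control
at 50 replicates per level with 250 permutations (the conclusion is
permutation-count-insensitive; the acceptance script uses 1000), the
null-calibration check at 2000 trials × 500 permutations, and the power
grid at 20 replicates per cell — sizes chosen so the full suite completes
in a few minutes while keeping binomial noise well inside the asserted
tolerances.

## Known limitations

* The empirical p-value and q-value have resolution 1/n_permutations and
  are conditioned on the observed sign; with very few same-signed null
  scores both are coarse.
* The tail-ratio FDR is the GSEA convention, not Benjamini–Hochberg; q
  values are comparable within a run, not across runs with different
  catalogs.
* Synonym and alias handling is a plain substitution table; no online
  identifier resolution is attempted.
* The GCT reader supports the v1.3 layout with a configurable
  quality-flag field and value set; quality semantics vary between
  sources and must be stated by the caller.
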