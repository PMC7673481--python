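# Methods

This note documents the models, parameter defaults and numerical choices
behind `foltile`, and what the synthetic-data generator does and does not
emulate.

## Tiling and the differential test

CpG observations arrive as 1-based positions with methylated/unmethylated
counts (Bismark-coverage dialect); they are converted once, at the reader
boundary, to the 0-based half-open tile grid. Tiles are 100 bp by default
and non-overlapping (`step == tile_size`); a smaller step that divides the
tile size produces sliding windows.

A tile enters testing when it contains at least 2 distinct covered CpG
positions (union across samples) and its summed CpG coverage is at least
10 in **every** sample of the contrast. Two methylation summaries are
kept deliberately:

* *tile level per sample* — the unweighted mean of CpG-level fractions,
  the conventional definition of a tile's methylation level;
* *group delta* — the difference of coverage-weighted pooled group
  proportions, which is the quantity the test actually probes and is far
  more stable at modest coverage. DMT calls gate on this delta.

With replicates in both groups the test is a binomial logistic regression
of counts on group membership, assessed by likelihood-ratio test. With a
single binary covariate the maximum-likelihood fit is the pooled
proportion of each group, so the LR statistic equals the G statistic of
the pooled 2×2 table; it is computed in closed form (and verified against
a `statsmodels` binomial GLM in the unit tests). When either group has
exactly one sample the test falls back to Fisher's exact test on pooled
counts. An optional quasi-binomial correction (Pearson dispersion of the
group-fitted model, floored at 1) is available but off by default — the
default mirrors the pooled logistic test this style of analysis
conventionally uses.

Benjamini–Hochberg adjustment is the textbook step-up rule
`q_(i) = min_{j>=i} p_(j) * m / j`, capped at 1, with NaN p-values
excluded from `m`. DMT status requires `q < 0.01` **and** `|delta| > 10`
percentage points, both strict: a tile exactly at either threshold is not
a DMT. Magnitude bins partition `|delta|` at 15 and 20 (10–15 includes
15; >20 is strictly above 20).

### Oracle checks and their design

Two independent oracles back the tile test:

1. **1 v 1 designs** are compared against a from-scratch hypergeometric
   enumeration of the two-sided Fisher probability on 1,000 unrestricted
   random tables; agreement is required to 1e-10. This covers the
   sparse/extreme-count regime exactly.
2. **Replicated designs** (6 v 6) are compared against a permutation
   oracle that redistributes the group labels of the pooled *reads* —
   the observation units of the logistic model — via 20,000
   hypergeometric draws given the tile margins, requiring agreement
   within 2-fold on 50 tiles. When an observed p sits below Monte-Carlo
   resolution (fewer than 10 expected exceedances) the oracle switches to
   exact enumeration of the same conditional null. Fixture tiles are
   drawn at mid-range methylation (20–80 %), the domain where a χ²(1)
   reference is meaningful; the extreme regime is already covered by
   oracle 1.

   Permuting *sample* labels instead is a different (replicate-aware)
   reference: with only 12 samples its conditional scale fluctuates with
   ~0.4 CV from tile to tile, so even a provably correct implementation
   disagrees with it beyond 2-fold on a few percent of tiles. That
   relationship is documented by a separate test asserting median-ratio
   agreement rather than a per-tile bound.

## Synthetic methylomes

The generator is a pure function of its `SimConfig`; the seed fully
determines every output, and each generator draws from its own seed
substream so outputs are independent of call order.

* **Genome**: 2 toy chromosomes of 1 Mb — ~20,000 tiles, large enough for
  FDR behaviour while keeping a full study under a couple of seconds.
* **CpG positions**: a clustered point process — cluster centres Poisson,
  cluster sizes geometric (mean 8), within-cluster spacing ~10 bp — at a
  genome-wide density of 10 CpGs/kb. The clustering emulates the
  CpG-dense MspI fragments an RRBS library enriches for; a uniform
  Poisson process at the same density would put only ~2 CpGs in a
  testable tile, which both misrepresents RRBS data and makes tile-level
  deltas needlessly noisy (estimator sd ~4 pp instead of ~2 pp).
* **Coverage**: negative binomial (mean 30, size 5), floored at 1; 2 % of
  CpGs drop out per sample.
* **Methylation**: per-tile baselines are Beta(0.4, 0.4) — the bimodal
  landscape typical of bulk methylomes. Counts per CpG are beta-binomial
  around the tile baseline with correlation ρ = 0.005: mild
  extra-binomial variation, consistent with the near-binomial replicate
  behaviour the pooled logistic test assumes. ρ is a config field.
* **Planted effects**: a list of (tile, delta, diets, tissues). Planted
  tiles get a baseline drawn uniformly from the range that keeps
  baseline + delta inside [2, 98] %; a delta that cannot fit raises a
  config error. The convenience planter targets tiles with ≥ 4 CpGs —
  the CpG-dense substrate where a tile-level effect is well defined — and
  by default plants 10–25 pp effects, 80 % hypermethylated, in all three
  treated diets, with 10 % of plants shared between tissues with
  concordant sign so the cross-tissue intersection sees realistic partial
  overlap. Calibration (prescribed before the main build): a +20 pp
  plant is recovered within ±5 pp in 97 % of 200 reruns.

What the generator does **not** emulate: real genome sequence and CpG
ordering, coverage biases that correlate with methylation, chromosome-
scale methylation domains, batch effects, or between-tile correlation.
Passing recovery/FDR checks on this generator demonstrates the pipeline's
statistical machinery is correct under its stated assumptions — not that
those assumptions hold for any particular real dataset.

## Reference tracks and inheritance

Sperm, GVO and ICMm tracks are generated on the same 100-bp grid. A
designated subset (default 300 regions) satisfies the maternal-
inheritance gates by construction — sperm ≤ 10 %, GVO and ICMm ≥ 25 % —
and is split evenly among gain / stable / loss dynamics with a safety
margin around the ±10 pp class boundaries (stable regions are built with
|GVO−ICM| < 8, gain/loss with ≥ 10.5) so float noise cannot flip a class.
Every non-designated region violates at least one gate. 2 % of regions
drop out of each track independently; regions missing from any track are
dropped by the classifier (matching its contract), and the recorded truth
accounts for this.

Interpretation choices, exposed as parameters: "GVO/ICM ≥ 25 %" is read
as a conjunction (both tracks) — a disjunction would admit regions with
no maternal ICM methylation; class boundaries are inclusive (a 10.0-pp
GVO→ICM change is gain/loss, not stable); `gvo_high` flags GVO ≥ 75 %.

## Targeted assays

LUMA percent methylation is `100 · (1 − (HpaII/EcoRI)/(MspI/EcoRI))` with
duplicate digestions averaged before the formula; the printed form of
this formula is ambiguous about bracket placement, and the standard
ratio-of-ratios reading is implemented. Results outside [0, 100] (noisy
peak ratios) are clipped with a warning. Group comparisons are classical
one-way ANOVA; sex comparisons are Welch t-tests by default (no
equal-variance assumption), and sexes are pooled for diet comparisons
when the sex test is non-significant at α = 0.05.

## Reproductive outcomes

Pre-implantation loss is CL − implantation sites, floored at zero with a
warning (an implantation count exceeding CL is a biologically possible
miscount, not an error). "Post-implantation loss" is reported as the
resorption count by default; the literal difference
implantation − resorptions equals the viable count, not a loss, so that
reading is provided as an explicit `literal` mode rather than guessed
silently.

Growth classification takes the mean and SD of *control litter-mean*
weights (≥ 2 control litters required) and classes an embryo restricted
below μ − 2σ, enhanced above μ + 2σ, strictly. The abnormal-litter flag
counts resorptions and abnormal-growth embryos additively and trips when
the total exceeds 1.

The control-vs-pooled-diet comparison of flagged litters uses Fisher's
exact test. On the published counts (4/10 control vs 24/34 treated
litters) the directional test gives p = 0.083 — matching the published
value of 0.08 — while the conventional two-sided sum-of-small-tables
convention gives 0.133; the published probability therefore corresponds
to the one-sided (treated-more-abnormal) alternative. Both are computed
and reported; the API default is two-sided.

Dunnett's many-to-one comparison is delegated to
`scipy.stats.dunnett` (multivariate-t integration of the joint contrast
distribution, with a pinned quasi-random state for reproducibility); the
tests verify the raw ≤ adjusted ≤ Bonferroni ordering against the
contrast statistic and detection of large shifts.

## Problem sizes used in checks

Null FDR runs use 2 × 6 Mb chromosomes (≈ 20,000+ testable tiles) over
10 seeds; recovery runs plant 50 effects per seed over 10 seeds on the
default 2 × 1 Mb genome; the oracle comparisons use 1,000 (exact) and 50
(permutation) tiles. These sizes make every check a matter of seconds
while leaving enough resolution for the stated thresholds.

## Known limitations

* The logistic/G test ignores between-replicate overdispersion by
  default; with strongly overdispersed real data the optional
  quasi-binomial correction (or a beta-binomial model, out of scope)
  should be preferred.
* Cross-tissue intersection requires exact tile identity — correct here
  because all samples share one grid; data tiled on different grids
  would need interval intersection instead.
* The annotator implements a four-category feature taxonomy; finer
  categories (CpG islands, TSS classes) would need an extended gene
  model.
* GO/pathway enrichment of DMT gene lists is intentionally out of scope
  (database-version dependent).
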