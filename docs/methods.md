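# Methods

## Regulator activity inference

The prior network is a signed edge list `regulator → target` with
`sign ∈ {activates, represses, unknown}` and positive weights (default
1.0). It stands in for a curated regulatory knowledge base; the schema is
a deliberate simplification since commercial knowledge bases do not
publish their edge semantics. Identifiers are upper-cased on input so
that symbols from different omic layers join; duplicate `(regulator,
target)` rows collapse to a single edge, with conflicting signs becoming
`unknown` (curated networks contain context-dependent edges, and the
activation score already ignores unknown signs) and the maximum weight
kept.

Evidence is a gene set over an explicit measured universe, optionally
with per-gene directions. DE evidence is thresholded at `fdr ≤ 0.05`
with no fold-change cut by default — significance alone defines the DE
set, and both thresholds are configurable. Bound-gene, interactor and
screen-hit sets carry no directions and must supply their universe
explicitly, because no measurement-based universe exists for those assays
and the overlap p-value is universe-sensitive.

For each regulator with at least one target in the universe:

* `p_overlap = P(X ≥ k)` where `X ~ Hypergeom(M, K, n)` with `M` the
  universe size, `K` the regulator's targets in the universe, `n` the
  evidence size and `k` the overlap. All edges count here, including
  unknown-sign ones: the overlap asks whether the module is enriched.
* `z = Σ w·m / √(Σ w²)` over the *signed* overlapping edges, `m = +1`
  for sign-consistent observations. `z` is undefined (reported as
  missing) when no signed edge overlaps or the evidence is
  non-directional. `|z| ≥ 2` (the conventional normal-scale call) labels
  the regulator activated/inhibited, boundary inclusive.

Rankings sort by ascending `p_overlap` (the FDR is reported but not used
for ordering), ties broken by larger `|z|` (undefined last) then
regulator name, so output is fully deterministic. Top-N truncation uses
N = 100.

## Cross-condition integration

Top-N overlap percentages are `100·|A∩B|/N` rounded half-up to integers
(exact at N = 100). The common core keeps regulators in the top-N of at
least `min_conditions` rankings. The core interaction network is the
induced subgraph of a user-supplied protein-interaction graph; regulators
tagged as chemicals/drugs are excluded from the protein map when a type
map is given but are retained in overlap matrices and cores (raw and
type-filtered core sizes are both reported). Pathway enrichment is the
same hypergeometric upper tail with BH correction; the default universe
is the interaction graph's node set, overridable (enrichment backgrounds
are never canonical and must be stated).

## Gene signatures and survival

A regulator's signature collects its contributing DE genes — the
overlapping targets that drove its ITR call — across conditions, keeping
genes observed with one consistent direction in ≥ 2 conditions and
dropping direction-conflicted genes. Patients are scored by the
direction-weighted mean of per-gene z-scored expression (population sd;
zero-variance or absent genes are skipped with warnings). This scoring
rule is declared, not inferred: it is the simplest direction-aware score.
Stratification splits at the score median (ties to the low group;
quantile configurable) and compares groups with a two-sided log-rank test
plus Kaplan–Meier curves (lifelines). Cox modelling is out of scope.

## RNAi screen normalization

Plates are 16×24; the control mask defaults to lines 1-2 and 23-24 along
the 24-position axis — a 16-row plate has no row 23, so the "rows" of the
original screen layout are interpreted as columns; the mask is
configurable. Normalization fits a locally weighted quadratic (loess)
surface of log2 signal over well coordinates using the sample fraction
only, with tricube distance weights over the nearest `span·n` wells
(span 0.5 by default) and two bisquare robustness iterations so that
strong hit wells do not drag the surface; the local quadratic basis makes
the fit exact on any global bilinear/quadratic gradient. Corrected value
= residual + grand median of the fitted sample wells, so a flat plate is
unchanged and the procedure is idempotent to numerical tolerance.
Non-positive wells are dropped with a warning. No installed package
provides a 2-D loess, so the fit is implemented here directly over
`numpy.linalg.lstsq`.

Robust z-scores are `(x − median)/(1.4826·MAD)` (the 1.4826 factor makes
MAD consistent for a normal scale; stated explicitly because screen
write-ups rarely do). MAD = 0 raises a degenerate-scale flag with all z
set to 0. z-scores are computed per plate by default; a pooled mode
exists because "the distribution of the corrected values" is ambiguous
between plate and screen. Gene-level log2FC is the corrected log2 signal
minus the plate sample median, averaged over replicate wells only (each
well already pools all siRNAs for its gene); hits are `|log2FC| ≥ 1`,
boundary inclusive.

The differentiation ratio is `D = L/W` (longest neurite length over
cell-body width) per cell; groups are summarised by mean and SEM and
compared by two-sided Welch t-tests.

## Peak context classification

Peaks are assigned by midpoint — the simplest deterministic rule — with
precedence promoter > exon > intron > immediate downstream > distal.
Defaults: promoter = 2 kb upstream / 500 bp downstream of the TSS,
strand-aware; immediate downstream = 2 kb past the TES. These windows are
explicit and configurable because no canonical definition exists; for the
same reason the distal category is sub-labelled "enhancer" only when a
user-supplied enhancer interval set overlaps the midpoint. Coordinates
are 0-based half-open; GTF input is converted by pyranges, BED12 blocks
become exons. Consequently published enhancer/promoter percentages are
not reproduction targets of this module — only self-consistency against
constructed fixtures is.

## Synthetic data

Generators emulate the downstream products of a multi-omic study at desk
scale, never raw reads/spectra, and every generator is a pure function of
(config, seed): sub-seeds hash the generator name with the master seed so
adding a generator never perturbs the other streams.

* **Network**: 200 regulators over 5,000 genes, Poisson(30) out-degrees
  (clipped to ≥ 1 so every regulator has an edge), targets uniform
  without replacement, signs 60/35/5% activating/repressing/unknown.
* **Contrasts**: DE statistics are generated directly at the summary
  level (DE calling from counts is out of scope, and the inference
  consumes only gene/direction/significance). A planted regulator with
  direction d makes each signed target DE with probability c = 0.8 in
  direction sign·d; background genes are DE at rate 0.05 with random
  direction. DE genes get `|log2FC| ~ N(1.5, 0.5)` truncated > 0.2 and
  `fdr ~ U(0, 0.01)`; non-DE genes `fdr ~ U(0.2, 1)`. The default
  scenario plants a shared 60-regulator core in three conditions and a
  disjoint 60-regulator set in a fourth, mimicking a related cell-line
  block versus an unrelated comparison.
* **Cohort**: 300 patients; a latent factor f ~ N(0,1) shifts signature
  genes by direction·f over unit noise and scales an exponential hazard
  by HR^f with HR = 3 per sd (baseline median 1,500 days). Censoring is
  Bernoulli(0.3) with censoring times uniform before the event —
  independent of the covariate, hitting the target fraction in
  expectation.
* **Plates**: log2 baseline 17 (~1.3e5 counts) + a random bilinear
  gradient of amplitude 0.5 log2 + multiplicative noise (CV 0.1, i.e.
  log2 sd ≈ 0.144) + 16 planted −1.5 log2 hit wells in the sample
  fraction.
* **Genome fixture**: 5 non-overlapping genes (10 kb, alternating
  strands, 3 exons) with 4 peaks per gene whose categories rotate through
  the 5 context classes — a 20-peak plan covering every category, each
  placed ≥ several hundred bp inside its intended window.

What the generators do **not** model: correlated noise between genes,
platform batch effects, realistic microarray distributions, cell-line
heterogeneity, LD-like structure between regulators sharing targets, or
non-exponential survival. Passing tests therefore demonstrate the
correctness and calibration of the statistics under clean planted-truth
conditions, not performance on real cohorts.

## Numerical choices and edge cases

Hypergeometric tails come from `scipy.stats.hypergeom.sf`, BH from
statsmodels; enumeration oracles in the tests recompute both from
binomial coefficients. An overlap of zero gives p = 1 exactly. Percentage
rounding is half-up. Empty signatures raise rather than propagate; a
median split leaving either group under 2 patients raises. Loess
idempotence and gradient-removal are asserted to 1e-6; oracle
equivalences to 1e-12.

Problem sizes used by the test-suite simulations (100 replicates for
recovery/power, 300–1,000 for null calibration, 20 seeds for the overlap
block structure) were chosen to keep the whole suite around a minute on
one CPU while leaving the binomial noise on each asserted rate well
inside its acceptance band.
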