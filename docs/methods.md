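# Methods

## Experimental design and data model

The analysis targets transcript-level count matrices from an 8-oxoG
RIP-seq design: two exposure conditions (CA = clean air, FA =
formaldehyde) × two fractions (input = rRNA-depleted abundance reference,
IP = anti-8-oxoG pulldown) × biological replicates (two by default).
Counts may be fractional, as produced by RSEM's `expected_count`
estimates; parsers keep them as reals and the count model decides where
integerization is needed.

Counts for transcript *i* in library *j* are modelled as negative
binomial with mean `s_j · μ_{i,g(j)}` and variance `μ + α_i μ²`, where
`s_j` is the library's size factor, `g(j)` its (condition, fraction)
cell and `α_i` the transcript's dispersion.

## The count contrast engine

A deliberately self-contained two-group NB engine backs all three
contrasts (CA_IP vs CA_IN, FA_IP vs FA_IN, FA_IN vs CA_IN). Relative to
full RNA-seq frameworks it omits fold-change shrinkage, outlier
refitting (Cook's distance) and independent filtering; this keeps every
reported number a closed-form function of the counts, at the cost of
exact numeric parity with those frameworks — a divergence that is
documented, not hidden.

**Size factors** — median-of-ratios: per library, the median over
transcripts (restricted to rows positive in every library) of
count / geometric-row-mean; lower-median convention on ties/even counts
for determinism, factors rescaled to geometric mean 1. If no row is
positive everywhere the method falls back to total-count factors with a
warning; an all-zero matrix is an error. Size factors use the fractional
counts as given. Each pairwise contrast is normalized on its own four
libraries, as when the comparisons are run as separate two-group
analyses; the factors are only meaningful up to a common scale.

**Dispersion** — per transcript, pooled method of moments on normalized
counts: within-group variances (ddof = 1) pooled by degrees of freedom,
`α = max(floor, (s² − m)/m²)` with `m` the mean over all samples of the
contrast; floor 1e-4; degenerate rows get the floor.

With two replicates per group that estimate has two degrees of freedom,
and plugging it directly into a normal-tail Wald statistic inflates the
raw type-I error to ≈ 0.17–0.20 at the nominal 0.05 level (measured on
2 000 null transcripts). The engine therefore moderates it by sharing
strength across transcripts, the conservative convention of early NB
differential-expression engines:

```
α_i(used) = max(α_i(per-transcript), α_trend)
```

where `α_trend` is the 10 %-trimmed mean of the raw (unfloored)
per-transcript estimates — an experiment-wide dispersion level the noisy
per-row values cannot fall below. The trend uses within-group
variability only, so real or planted group differences do not leak into
it. Measured null calibration with moderation: raw p < 0.05 fraction
≈ 0.05–0.065 (2v2, means 50–500, α = 0.05). The moderation assumes a
roughly common dispersion scale across transcripts; strongly
mean-dependent dispersion trends are not modelled.

**Wald test** — group means are means of normalized counts; the effect
estimate is `log2fc = log2((μ_B + c)/(μ_A + c))` with pseudocount
c = 0.5, which keeps fold changes finite when one group is all zero.
The standard error comes from the Fisher information of the NB means
model at the moderated dispersion,
`I_g = Σ_j s_j(μ_g + c) / (1 + α s_j(μ_g + c))`, and the p-value is the
two-sided normal tail of `log2fc/se`. Fractional counts are rounded
half-to-even before this step (the NB likelihood assumes integers).
Rows with zero counts in every library of the contrast are untestable
and carry absent (NA) p-values. Agreement with a grid-maximized NB
likelihood-ratio test is within a factor of two in p on small 2v2
instances (see the oracle tests).

**Multiple testing** — Benjamini–Hochberg step-up over the present
p-values (statsmodels' `fdr_bh` behind the package's NA-aware wrapper);
absent values stay absent and do not count as tests.

## The oxidation pipeline

Per condition, the IP-vs-input contrast yields `fa_log2fc` /
`ca_log2fc` and adjusted p-values. Then:

* **zero replacement** — log2FC values of exactly 0 (after signed-zero
  normalization) are raised to 0.01 before subtraction. Only exact zeros
  are touched; broad rounding would silently perturb data.
* **Δ statistic** — `delta_log2fc = zero_replace(fa) − zero_replace(ca)`.
* **candidate gate** — adjusted enrichment p < 0.05 in *at least one*
  condition (union); transcripts with absent p_adj in both conditions
  are non-candidates.
* **enriched** — candidate ∧ `delta > 2` (a 4-fold ratio between the FA
  and CA fold changes), or FA-only. The headline set is directional
  (enrichment under exposure); the symmetric `depleted` flag
  (candidate ∧ delta < −2) is reported for completeness, and
  relabelling the conditions maps one tail onto the other exactly.
* **FA-only** — count > 0 in every FA library and 0 in every CA library
  (strict default; an "any FA library" mode is configurable). Strictness
  avoids single-read artifacts; these transcripts are included in the
  enriched set by definition, since detection under exposure alone
  demonstrates enrichment.
* **differential expression** — FA_IN vs CA_IN through the same engine;
  up/down calls need p_adj < 0.05 *and* |log2FC| > 2, everything else is
  unchanged.
* **intersection** — `oxidized_down` = enriched ∧ downregulated;
  `oxidized_other` = enriched otherwise; `not_oxidized_de`; `background`.
  The four classes partition the transcript universe.
* **QC** — per branch, the minimum positive raw count among called
  transcripts (a guard against calls driven by near-zero counts),
  library sizes, size factors and call tallies.

Transcripts with zero counts in every library are dropped before
analysis by default (configurable), since they are untestable in every
branch; rows present only in some libraries are always kept so that the
FA-only rule can see them.

## Pathway reporting

Membership tabulation produces one row per (pathway, enriched transcript
whose gene symbol belongs to the pathway) with the transcript's
enrichment and DE statistics; a transcript in k pathways yields k rows.
Over-representation uses the one-sided hypergeometric tail (Fisher exact
upper tail) of the hit/universe overlap per set, BH-adjusted across
sets. ORA is universe-sensitive; the pipeline's default universe is
every analysed transcript with a mapped symbol, and callers may supply
their own. Protein-interaction network statistics (database-backed edge
enrichment, connectivity scores) are out of scope — the hypergeometric
filter reproduces the significance-gating logic on user-supplied sets
without a network dependency.

The package ships a 31-row, two-pathway report-table fixture (21
chromatin-modification rows, 10 p53-mediated DNA-damage-response rows;
one KAT5 transcript present in both sections) with matching GMT sets,
used by the worked-example tests. Adjusted p-values printed as
"< 0.0001" are parsed to their printed bound (1e-4), which preserves
every threshold comparison; the table lists the shared KAT5 transcript
with two different enrichment values (4.44 and 8.63) in its two
sections, and the deduplicated per-transcript view keeps the first. DE
fold-change signs are not part of the fixture; its DE-significance flags
key on p_adj only.

## Synthetic experiments

The generator emulates the design end to end: log-normal input
abundances (default median 200 counts, ln-sd 1.0 — a realistic bulk
dynamic range), NB noise at dispersion 0.05 (optionally
gamma-distributed across transcripts), per-library depth factors
(log-normal, ln-sd 0.15, geometric mean 1), a background pulldown
enrichment common to all transcripts (default 0 log2 units), and
disjoint planted subsets: 150 oxidation-enriched transcripts at +4 log2
units of FA-specific pulldown (the magnitude the Δ > 2 gate is designed
to detect with margin), 9 FA-only transcripts (structural zeros under
CA), and 50 + 50 up/down DE transcripts at ±5 log2 units. Enrichment is
planted multiplicatively on IP means, matching the analysis's assumption
that IP counts mirror input abundance times an enrichment factor. An
option adds sub-integer jitter to positive counts to mimic fractional
RSEM expected counts (zeros stay exact so detection rules are
unaffected); default off. A single root seed spawns named per-stage
streams, so runs are bit-reproducible and stage draws independent.

What the simulator does *not* model: sequence content, GC and positional
bias, antibody cross-reactivity beyond what input normalization absorbs,
correlated replicates, batch structure, and mean-dependent dispersion
trends. Passing recovery tests therefore demonstrates correctness of the
inference pipeline under its own model assumptions, not performance on
any particular real dataset.

## Validation surfaces and problem sizes

Dataset-scale headline counts of the original biological study depend on
its full deposited sequencing libraries and database versions and are
not recomputable at desk scale; validation instead uses (a) the packaged
report-table worked examples (exact integer counts), (b) analytic
threshold algebra (2² = 4), (c) planted-signal recovery — 10 seeds ×
5000 transcripts, sensitivity ≥ 0.90 and false-discovery proportion
≤ 0.15 for the enriched call (measured ≈ 0.998 and 0.0) — and (d) null
calibration — raw Wald p < 0.05 fraction within [0.025, 0.085] and
enriched calls below α·n with nothing planted. Statistical primitives
are checked against independent brute-force oracles: hand step-up BH on
all short vectors over a grid, exhaustive draw enumeration for the
hypergeometric tail on universes up to 12, and a grid-maximized NB
likelihood-ratio test within a factor of two of the Wald p. These sizes
keep the full suite and the acceptance script in the seconds-to-a-minute
range on one CPU.

## Numerical conventions

* lower-median for size-factor ties; factors rescaled to geometric mean 1;
* banker's rounding (half-to-even) for count integerization;
* pseudocount 0.5 on normalized group means, also inside the information
  so standard errors stay finite for empty groups;
* dispersion floor 1e-4;
* absent values written as `NA` in all result TSVs; result tables carry a
  `#` provenance line (tool version + config hash) and no timestamps, so
  identical inputs reproduce byte-identical outputs.
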