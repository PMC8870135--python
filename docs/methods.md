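# Methods

## Screen model and scope

`sslscreen` analyzes arrayed two-arm siRNA viability screens. One arm is
query-proficient; in the other a query gene is depleted screen-wide (e.g.
by an inducible shRNA), so every library siRNA is effectively a double
perturbation with the query. The readout is a per-well nucleus count.
Records are long-format: one row per well per arm per biological and
technical replicate, addressed on the standard 384-well grid (rows A–P,
columns 1–24). Arm labels are generic (`query_proficient` /
`query_depleted`) so the pipeline applies to any inducible-query screen.

## Normalization

Counts are square-root transformed and divided by the within-plate median
of the negative-control wells (mock and non-targeting pooled by default;
they are kept distinguishable in the data model so either can be used
alone). The sqrt is the classical variance stabilizer for Poisson counts;
normalization is computed per physical plate — per plate × arm ×
biological × technical replicate — so plate-to-plate multiplicative
effects cancel exactly. No B-score/median-polish or loess edge correction
is applied; spatial gradients inside a plate are deliberately left to
percent-of-control alone.

Two scales are produced:

* **within** — each plate to its own controls; control medians are 1.0 by
  construction (enforced to 1e-12 in tests). Used for QC.
* **proficient (shared)** — both arms to the matching query-proficient
  plate's control median. Normalizing the depleted arm to its *own*
  controls would cancel the query effect V_b and collapse ε toward an
  additive-within-arm score; the shared scale keeps `ε = V_ab − V_a·V_b`
  literal. The within-arm dialect remains available behind a flag for
  sensitivity analysis.

A consequence of the sqrt transform: a normalized viability is the square
root of the count-scale survival fraction. Products are preserved
(`sqrt(ab) = sqrt(a)sqrt(b)`), so the multiplicative null is unaffected,
but a count-scale interaction multiplier `(1−δ)` appears as `sqrt(1−δ)`
on the analysis scale, and the analysis-scale query-effect estimate is
`sqrt` of the count-scale one. The ground-truth tables and the parameter-
recovery checks account for this explicitly (squaring the V_b estimate
back to the count scale; closed-form expected ε
`sqrt(V_a·V_b)·(sqrt(1−δ)−1)`).

## Quality control

* **SSMD** per plate between the cytotoxic positive control (a KIF11-like
  siRNA that kills regardless of genotype) and the negative controls:
  `(μ₁−μ₂)/√(σ₁²+σ₂²)` with sample variances — the standard definition;
  a median/MAD robust variant is provided separately. Values at or below
  −3 indicate a healthy assay window. Zero-variance groups yield a signed
  infinity, reported as degenerate.
* **Replicate reproducibility**: Pearson correlation of per-siRNA
  viabilities (technical replicates averaged first) between every pair of
  biological replicates, per arm. Undefined (returned as missing) below
  3 shared siRNAs or at zero variance.
* **Cytotoxicity exclusion**: a gene is excluded when its mean normalized
  viability over its siRNAs in the query-proficient arm falls strictly
  below `threshold × overall median` (default threshold 0.20; the overall
  median is taken over all sample wells of that arm, after normalization).
  The rule reads "reduced to below 20% of the median remaining" — the
  filter exists to remove knockdowns so toxic that no interaction can be
  measured on top of them; a gene exactly at the threshold is retained.
  Evaluated on the proficient arm only, since it targets intrinsic
  cytotoxicity rather than interaction. Threshold and arm are
  configurable.

## Interaction scores

Per biological replicate: `V_a` is the mean of the siRNA's proficient-arm
viabilities over technical replicates (they share a transfection and are
not independent, so they are averaged before any cross-replicate
statistic); `V_ab` is the same for the depleted arm on the shared scale;
`V_b` is a screen-wide constant per biological replicate, the median of
that replicate's depleted-arm negative-control viabilities (or a supplied
constant). `ε = V_ab − V_a·V_b` is computed per replicate and then
averaged across biological replicates (median behind a flag). ε was
chosen to be computed per replicate and then aggregated, rather than on
replicate-averaged viabilities, so each replicate's V_b matches its own
transfection batch; for the mean aggregate the two orders differ only
through the per-replicate V_b. Missing wells propagate as a missing
replicate; siRNAs with no surviving replicate are dropped with a logged
warning.

## RSA gene ranking

siRNAs are ranked ascending by aggregate ε (most synthetic-sick first;
ties broken lexically by siRNA id for determinism). For a gene with k
siRNAs at ranks r₁<…<r_k among N ranked siRNAs, the p-value is the
minimum over i of the hypergeometric upper tail P(X ≥ i) at draw size
r_i — the probability that at least i of the gene's siRNAs land that high
by chance. Tails are computed in exact rational arithmetic
(`math.comb`-based) and converted to float once, so small-N values agree
exactly with exhaustive enumeration; scipy's hypergeometric survival
function is used as an independent cross-check in tests only.

Scoring is one-sided toward negative ε (the screen's aim); alleviating
interactions appear in the ε table but are not p-valued. N is the number
of ranked siRNAs after cytotoxicity exclusion, controls excluded. Hits
are `p < 0.05`, strict, with no multiple-testing correction — a
Benjamini–Hochberg helper is provided for reuse. The min-over-i statistic
is anti-conservative relative to a uniform null (it is a minimum over k
correlated tails), so the realized false-positive level at 0.05 exceeds
5%; the acceptance script measures and reports the observed non-planted
hit fraction rather than assuming it. No rescue/iteration heuristics from
the original RSA software are applied — only rank + minimum tail.

## Synthetic screens

The generator emulates the statistical structure the analysis assumes and
defines the default study conditions: 207 genes × 3 siRNAs arrayed on
384-well plates (each plate carries 8 mock, 8 non-targeting and 8
cytotoxic-positive wells at interleaved, spatially spread fixed positions
— real layouts vary and are rarely published, so a stable spread was
chosen to keep control medians well estimated), two arms, 3 biological ×
2 technical replicates, baseline 1500 nuclei per healthy well (a
plausible density for a 384-well at ~10× after several days of growth;
all acceptance properties are stated relative to the configuration, not
to absolute counts).

Effects compose multiplicatively on the expected count:

```
expected = baseline · plate_factor · edge(col) · well_noise
           · V_a(siRNA) · [depleted arm: V_b · (1−δ if planted)]
count    ~ Poisson(expected)
```

* `V_a = 1 − efficacy·(1−g)`: gene knockout viability g scaled by
  per-siRNA knockdown efficacy ~ Beta(8, 2) (mean 0.8 — typical of a
  validated commercial library).
* Gene effects: 35% of genes growth-impairing with g ~ U(0.3, 0.9), the
  rest near-neutral (1 − |N(0, 0.02)|) — a DNA-damage-response library is
  enriched for genes whose loss slows growth, and this mix gives the
  across-siRNA dynamic range a real screen's replicate correlation rests
  on.
* Query effect V_b = 0.6 (a strong but viable knockdown), applied to
  every well of the depleted arm including controls.
* 10 planted SSL genes; in the depleted arm only, their wells' expected
  count is multiplied by (1−δ), δ = 0.5.
* Noise: Poisson counting noise, per-well lognormal (σ = 0.1), per-plate
  lognormal (σ = 0.05), optional linear column gradient (default off).
* Controls: negative controls at V_a = 1, cytotoxic positive at
  V_a = 0.05.
* `gene_viability_overrides` pins a gene's knockout viability and sets
  its siRNAs' efficacy to 1, planting a well-level effect exactly (used
  to exercise the cytotoxicity filter at known distances from the
  threshold).
* Randomness: a single master seed; per-plate streams derived with
  `SeedSequence.spawn`, so identical configurations give byte-identical
  tables.
* `noise_free=True` fixes all stochastic factors at 1 and replaces the
  Poisson draw by its mean; counts are then floats equal to their
  closed-form expectation, and the pipeline's aggregate ε matches the
  analytic values to machine precision (asserted at 1e-9).

What the generator does **not** emulate: transfection failure patterns,
cross-well contamination, cell-cycle or imaging artifacts, correlated
off-target structure between siRNAs, or gene-specific query-effect
modulation beyond the planted multiplicative δ. Passing tests therefore
demonstrate correctness of the analysis under the stated noise model, not
robustness to every failure mode of real screens.

## Image counting

The optional front end replaces a full image-analysis suite with the
minimal faithful chain for well-separated Hoechst-like nuclei: Gaussian
smoothing (σ = 1 px) → global Otsu threshold → 8-connected components →
area filter [8, 500] px². Counts are invariant under uniform intensity
scaling (Otsu scales with the image); constant images count zero without
error. There is no watershed declumping or illumination correction —
touching nuclei under-count, a documented limitation — so the image
renderer places nuclei with rejection sampling at ≥3 radii separation,
where recovery is exact. Per-well counts are sums (not means) over the
well's fields, default 9, matching a total-count readout.

## Problem sizes and numerics

The test suite and acceptance script use the full default screen (207
genes, ~8,000 well records per screen; simulation + analysis ≈ 0.5 s),
20 seeds for parameter-recovery statistics, exhaustive enumeration grids
up to N = 12 for the hypergeometric oracle, and 50 rendered fields for
image counting. Tolerances: 1e-12 for the normalization contract, 1e-9
for noise-free ε exactness, ±0.05 for query-effect recovery (Monte-Carlo
at 20 seeds), exact equality for rational-arithmetic tail probabilities
and image counts. Ties in ranking are broken lexically; all table writers
sort deterministically (hits by ascending p, then gene symbol).
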