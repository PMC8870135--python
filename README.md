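# sslscreen

Analysis pipeline for **combinatorial (two-arm) arrayed RNAi viability
screens** that hunt for synthetic sick/lethal (SSL) genetic interactions —
gene pairs whose individual knockdowns are tolerated but whose combined
loss kills cells. The motivating design is an image-based screen of a
DNA-damage-response siRNA library (207 genes, three independent siRNAs per
gene, 384-well plates) run in parallel in query-proficient cells and in
cells where a query gene is depleted screen-wide by an inducible shRNA,
with per-well nucleus counts as the viability readout.

The package takes you from raw per-well counts (or raw per-field well
images) to a ranked candidate-gene table, and ships a fully parameterized
synthetic-screen generator with ground truth so every stage is testable
without access to any particular screen's raw data.

## The model

Let `V_a` be the relative viability of cells carrying siRNA *a* alone,
`V_b` the viability under the query knockdown alone, and `V_ab` the
viability under both. Under the multiplicative (non-interacting) null,
`V_ab = V_a · V_b`. The interaction score for each siRNA is

```
ε = V_ab − V_a · V_b
```

with `ε < 0` the synthetic sick/lethal direction. Upstream of ε, counts
are square-root transformed (the variance stabilizer for Poisson object
counts) and normalized per plate to the median of the negative-control
wells (mock and non-targeting siRNA). Both arms are placed on the shared
query-proficient control scale, so the depleted arm's own control median
estimates `V_b` rather than being forced to 1. Because the square root
distributes over products, the multiplicative null survives the transform
untouched.

Gene-level calls use **RSA (redundant siRNA activity)**: siRNAs are ranked
ascending by aggregate ε; a gene with k siRNAs at ranks r₁ < … < r_k out
of N gets

```
p = min over i of  P(X ≥ i),   X ~ Hypergeometric(N, k, r_i)
```

the chance that at least i of its siRNAs land in the top r_i by luck.
Genes with several independently well-ranking siRNAs get small p-values,
which makes the call robust to single-oligo off-target effects. Candidate
hits are genes with `p < 0.05` (strict, uncorrected; a Benjamini–Hochberg
helper is available for reuse).

Quality control: per-plate SSMD `(μ_pos − μ_neg)/√(σ²_pos + σ²_neg)`
between the cytotoxic KIF11-like positive control and the negative
controls; Pearson correlation of per-siRNA viabilities between biological
replicates; and a cytotoxicity exclusion that drops genes whose knockdown
alone reduces viability below 20% of the screen's overall median (those
wells have too few cells left for an interaction to be measurable).

## Worked example

Simulate a default screen (207 genes × 3 siRNAs, two arms, 3 biological ×
2 technical replicates, query effect 0.6, ten planted SSL genes with the
combined viability halved) and analyze it:

```
$ sslscreen simulate --seed 7 --out demo/sim
wrote 8028 well records to demo/sim

$ sslscreen analyze --library demo/sim/library.tsv \
      --measurements demo/sim/measurements.tsv --out demo/analysis
621 siRNAs ranked, 0 genes excluded, 23 candidate hits -> demo/analysis/hits.tsv

$ head -4 demo/analysis/hits.tsv
gene  n_sirnas  sirna_ids                epsilons                       best_rank_index  rsa_p         is_hit
G083  3         G083_s2,G083_s1,G083_s3  -0.234773,-0.224476,-0.218854  3                1.40983e-06   True
G183  3         G183_s2,G183_s3,G183_s1  -0.234561,-0.214796,-0.210102  3                1.14548e-05   True
G077  3         G077_s2,G077_s1,G077_s3  -0.231532,-0.209244,-0.19414   3                2.43950e-05   True
```

All three siRNAs of the top genes score strongly negative ε — the RSA
signature of a real interaction rather than an off-target singleton. For
this seed the generator's ground truth (`demo/sim/truth_genes.tsv`) marks
ten planted genes; all ten are among the 23 called hits, with the
remainder reflecting the expected false-positive level of the
uncorrected p < 0.05 cutoff. `demo/analysis/` also contains the
normalized well table, per-plate SSMD, replicate correlations, the ε
table per replicate and aggregated, and a run log of every parameter.

Images can stand in for counts: `sslscreen count-images` counts nuclei in
`<plate>_<well>_f<index>.tif` field images (Gaussian smoothing → Otsu
threshold → 8-connected components → area filter, fields summed per well)
and emits a per-well count table.

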