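# Methods

## Analysis model

All quantities are per-gene log2 fold changes (TG over WT); log2 is used
throughout because effects compose additively and the field's fold-change
plots are symmetric around zero on that scale. The proteome is the standard
layer: matching joins every transcript layer onto the proteome identifier
set (normalized gene symbols — trimmed, casefolded), transcript values
absent in a layer are recorded as missing and never imputed, and every
correlation is computed over pairwise-complete pairs with the pair count
reported alongside r, so shrinking effective sample sizes stay visible.

**Balanced top-N selection.** Ranking uses the signed protein log2 fold
change per direction (N/2 largest positive, N/2 most negative), not pooled
|fc|, so the subset is balanced by construction. Boundary ties break by
lexical identifier order, making selection invariant to input row order.
Genes with fold change exactly 0 belong to neither direction. If a sign runs
out, all genes of that sign are used and the shortfall is recorded. Ranking
happens on the full proteome; unmatched pairs are dropped per layer at
correlation time (the alternative — dropping unmatched proteins before
ranking — changes subset membership; the match report makes the unmatched
counts explicit so users can judge the difference).

**Correlation.** Pearson on log2 fold changes is the default (the effects
are modeled as additive on that scale); Spearman is available everywhere as
a method option. Fewer than 3 complete pairs or a zero-variance margin is an
*undefined correlation*, raised as a typed error by `correlate` and recorded
per cell (r = NaN plus a reason) by the sweep drivers rather than aborting.
No p-values are attached to sweep correlations: subsets are chosen by
ranking on one of the correlated variables, so nominal p-values would be
invalid. `permutation_null` provides a calibrated alternative (permute one
layer's values across genes, re-correlate the top-N subset).

**Sweep grid.** Default 700 → 100 in steps of 100 (endpoints are the
analysis's defining range; the step is configurable). The directional
decomposition uses 50 genes per direction by default.

**Overlap.** Exact set intersection after identifier normalization;
duplicates within a list are collapsed with a logged warning. The headline
percentage uses the *up-regulated list* as denominator (shared count is
symmetric, the percentage is not; reports label the denominator). The
optional hypergeometric upper tail P(X ≥ shared) requires the caller to
supply the gene universe size — no default universe is invented, because the
detected-gene universe differs by platform and any default would silently
shape the p-value. Ribosomal-protein tagging is a case-insensitive prefix
test, default prefixes (`rpl`, `rps`, `mrpl`, `mrps`) covering cytosolic and
mitochondrial RP symbols; whether mitochondrial RPs belong in an "RP count"
is study-specific, hence the set is a parameter.

**Fold changes from counts.** log2((mean normalized TG + c)/(mean normalized
WT + c)) with pseudocount c = 1 and library-size normalization by default
(each column scaled to the mean library size). This is deliberately the
simplest consistent estimator — no dispersion shrinkage or differential
testing, because the downstream analysis consumes fold changes only.
Pseudocount 0 with a zero genotype mean is an error rather than ±inf.
Duplicate identifiers within a layer are resolved by `max_abs` (keep the
strongest signal; deterministic first-occurrence tie-break), with `mean` and
`error` as alternatives.

## Synthetic data generator

The generator encodes the hypothesis the analysis is designed to detect:
scaffold overexpression changes the synaptic proteome through (i)
transcription, (ii) polysome-specific local translation biased toward
up-regulation, and (iii) direct recruitment of a small interactome. Per gene
g, latent log2 effects:

* x_g ~ Normal(0, σ_x) for a fraction f_x of genes (default 0.10, σ_x = 0.5),
  else 0 — the transcription channel, visible in every RNA layer;
* t_g = s·|Normal(0, σ_t)| for a fraction f_t of genes (default 0.10,
  σ_t = 0.8), with sign s = +1 with probability `translational_up_bias`
  (default 0.9) — the translation channel, visible only in the polysome
  layer and the proteome;
* an interactome flag for a fraction 0.05 of genes, adding `recruit_effect`
  = 0.5 to the protein fold change only — so recruitment contributes a
  minority of the up-regulated proteome, consistent with the small observed
  interactome overlap.

Layer means are `whole_tissue = syn_input = x_g`,
`syn_polysome = x_g + α·t_g`, and
`proteome = β·x_g + α·t_g + recruit·1[interactome]`, with α = 1 and β = 0.3,
plus layer-specific Gaussian measurement noise (SD 0.2 per layer) on the
log2 scale. β < α expresses that a snapshot proteome is the net outcome of
synthesis and degradation: transcription-level abundance changes are heavily
damped before they appear as steady-state protein changes, whereas the
polysome signal *is* synthesis. The value 0.3 was chosen so that the
whole-tissue/input layers correlate only weakly with the proteome and the
top-50 down-regulated proteins show no strong polysome concordance —
the qualitative regime the analysis is meant to distinguish. With β closer
to α the transcription channel alone makes even the down-regulated side
polysome-concordant and the up/down asymmetry becomes unreliable.
Degradation is not modeled kinetically; it is folded into β and noise.

Defaults of 5 000 genes and 3 replicates per genotype reflect a typical
detected-proteome scale and the three WT/TG pairs of the emulated design.

**Counts.** For any layer, replicate counts are negative-binomial with
per-gene lognormal size factors (σ = 0.5) on a baseline mean of 200, WT mean
μ_g = baseline·s_g, TG mean μ_g·2^fc, and NB shape r = 10 (variance
μ + μ²/r; large r approaches the Poisson limit). Columns are labeled
`<genotype>_<layer>_<replicate>`.

**Determinism.** One master integer seed; every consumer (latent effects,
interactome sampling, per-layer noise, per-layer counts) draws from its own
`SeedSequence` sub-stream derived from (seed, stream tag, layer name), so
adding counts for one layer never perturbs another layer's values. Identical
config + seed gives byte-identical written fixtures.

**What the generator does not emulate.** Gene-gene correlation (effects are
independent across genes), mapping/quantification artifacts, compositional
distortion of library-size normalization under massive global shifts,
proteoform- or peptide-level effects, batch structure, and any kinetic
coupling between transcription and translation. Passing recovery tests on
this generator shows the *pipeline* detects the planted causal structure at
realistic effect and noise scales; it is not evidence about any particular
mouse dataset.

## Synthetic reference lists

The published up-regulated protein list and the 793-protein scaffold
interactome are not publicly deposited. `synconcord.synthetic_reference`
provides deterministic stand-ins that carry the published *summary counts*
(63 up-regulated ids of which six are RP symbols, a 793-id interactome, 8
shared ids including shank3, hence a 12.7% overlap). They exercise and
validate the overlap/tagging machinery end to end; their membership beyond
the named scaffold genes is synthetic filler, and real analyses must supply
the genuine lists.

## Numerical and design choices

* Correlations delegate to `scipy.stats` (pearsonr/spearmanr) and the
  hypergeometric tail to `scipy.stats.hypergeom.sf`; the test suite
  cross-checks both against independent oracles (textbook covariance
  formula to 1e-12; exhaustive enumeration for universes ≤ 15).
* Monte-Carlo test sizes: recovery properties use 20 generator seeds with a
  ≥ 19/20 pass rule and a 0.02 per-step slack on sweep monotonicity; the
  zero-effect null calibration uses 50 seeds (the mean of |r| at 100 pairs
  has expectation ≈ 0.08, so a 20-seed mean is too noisy to sit reliably
  under its 0.1 bound; 50 seeds reduce the Monte-Carlo error without
  touching the bound or the conditions).
* Report bundles are byte-reproducible for a fixed config + seed: no
  timestamps inside any written file (the default bundle *directory name*
  carries a timestamp unless overridden), floats written with `%.10g`,
  JSON keys sorted.
* The pipeline's synthetic mode intersects the generated interactome with
  the top-63 up-regulated proteins by default, echoing the emulated study's
  up-regulated list size; `overlap_top_up` is configurable.

## Known limitations

* The directional up/down asymmetry is a property of strongly up-biased
  translational regimes; at the default bias of 0.9 the ~50 translational
  down-genes in a 5 000-gene dataset can dominate the top-50 down list and
  mask the asymmetry. Demonstrations and recovery tests of that specific
  contrast use `translational_up_bias = 1`.
* Identifier matching assumes gene symbols; accession-to-symbol mapping must
  happen upstream (an optional two-column remap is supported via
  `quantify.apply_remap`).
* Library-size normalization cannot distinguish a global abundance shift
  from no change; fold changes are relative to total signal, as in standard
  RNA-seq practice.
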