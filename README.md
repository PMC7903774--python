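# synconcord

Multi-omics fold-change concordance analysis for synaptosomal proteomes.

## The scientific problem

When a postsynaptic scaffolding protein such as Shank3 is overexpressed, the
synaptic proteome remodels. Two mechanisms can drive that remodeling: direct
physical recruitment of interaction partners into the postsynaptic density
(scaffolding), and increased local protein synthesis from synaptically
localized, polysome-engaged mRNAs. `synconcord` implements the comparative
analysis that separates the two using fold changes measured in four omics
layers of the same tissue — a synaptosomal **proteome** and three
transcriptomes: **whole tissue**, **synaptosome input** (all synaptosomal
RNA), and **synaptosome polysome** (ribosome-engaged RNA, a translatome
proxy) — each expressed as a per-gene log2 fold change of transgenic (TG)
over wild-type (WT) abundance.

The core procedure, for a matched table of per-gene fold changes
*(p_g, m_g^(ℓ))* with the proteome as the standard:

1. **Balanced top-N selection** — rank proteins by protein log2 fold change
   and take the N/2 most up-regulated plus N/2 most down-regulated.
2. **Ranked-subset correlation sweep** — for each N in a descending grid
   (default 700, 600, …, 100), compute the Pearson (or Spearman) correlation
   r(p, m^(ℓ)) over the subset's pairwise-complete pairs, per layer. A layer
   whose correlation climbs as N shrinks tracks the strongest protein
   changes — the signature of a causal contribution, not shared noise.
3. **Directional decomposition** — correlate the top 50 up-regulated and the
   top 50 down-regulated proteins separately per layer; a translational
   (synthesis-driven) signal appears only on the up side.
4. **Interactome overlap** — intersect the up-regulated protein list with a
   scaffold interactome; report the shared count and the percentage of the
   up-regulated list (with an optional hypergeometric upper-tail
   P(X ≥ shared) when a gene universe size is supplied). A small percentage
   means scaffolding recruitment explains only a minority of the change.
5. **Ribosomal-protein tagging** — count identifiers under RP nomenclature
   (prefixes `Rpl`/`Rps`/`Mrpl`/`Mrps`, configurable) in any list.

Because the original animal datasets are not publicly deposited, the package
includes a first-class synthetic generator (`synconcord.synthetic`) whose
causal structure mirrors the biological hypothesis — a transcription effect
shared by all RNA layers, a polysome-specific up-biased translation effect
that reaches the proteome, and interactome-restricted recruitment — plus
negative-binomial replicate count matrices (default three WT/TG pairs), so
every pipeline stage is testable with known ground truth. See
`docs/methods.md` for the generative model and its limitations.

## Worked example

Simulate a default dataset (5 000 genes, seed 1), match layers, and sweep:

```bash
concord simulate --seed 1 --n-genes 5000 --outdir fixtures
concord match --proteome fixtures/fold_changes_proteome.tsv \
  --transcriptome whole_tissue=fixtures/fold_changes_whole_tissue.tsv \
  --transcriptome syn_input=fixtures/fold_changes_syn_input.tsv \
  --transcriptome syn_polysome=fixtures/fold_changes_syn_polysome.tsv \
  --out matched.tsv
concord sweep --matched matched.tsv
```

```
layer	n	n_pairs	method	r
whole_tissue	700	700	pearson	0.149703
...
syn_input	700	700	pearson	0.185578
...
syn_polysome	700	700	pearson	0.80196
syn_polysome	600	600	pearson	0.82306
syn_polysome	500	500	pearson	0.850381
syn_polysome	400	400	pearson	0.877852
syn_polysome	300	300	pearson	0.910555
syn_polysome	200	200	pearson	0.93065
syn_polysome	100	100	pearson	0.962624
```

The polysome layer starts far above the other two (r ≈ 0.80 vs ≈ 0.15–0.19
at N = 700) and climbs monotonically to r ≈ 0.96 at N = 100, while whole
tissue and input stay flat — the generated translational signal is recovered
exactly where it was planted. With a fully up-biased translational signal
(`translational_up_bias = 1`), the directional split shows the asymmetry on
the polysome layer only:

```
layer	direction	n	n_pairs	method	r
syn_polysome	up	50	50	pearson	0.730957
syn_polysome	down	50	50	pearson	0.400898
```

Overlap statistics on the bundled synthetic reference lists (stand-ins that
carry the published summary counts; see `synconcord.synthetic_reference`):

```python
>>> from synconcord import overlap_stats, tag_ribosomal
>>> from synconcord.synthetic_reference import (
...     synthetic_upregulated_proteins, synthetic_shank3_interactome)
>>> r = overlap_stats(synthetic_upregulated_proteins(), synthetic_shank3_interactome())
>>> print(r.summary("up-regulated", "interactome"))
8 of 63 up-regulated identifiers shared with interactome (793 identifiers): 12.7% of up-regulated
>>> tag_ribosomal(synthetic_upregulated_proteins())[1]
6
```

Only 12.7% of the up-regulated proteins are scaffold interactors, and six of
them are ribosomal proteins — recruitment alone cannot account for the
proteomic change, pointing to increased synaptic protein synthesis.

A full reproducible run (`concord run-all --seed 1 --outdir out/`) writes
`matched.tsv`, `sweep.tsv`, `directional.tsv`, `overlap.tsv`, a match report,
a run log, and a `manifest.json` that suffices to reproduce the bundle
byte-for-byte.

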