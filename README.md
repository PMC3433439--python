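# spruceqtl

Genetical genomics for outbred full-sib factorial crosses.

`spruceqtl` implements the statistical machinery of a genetical-genomics
study of the kind run in forest-tree pedigrees: a small factorial of
outbred parents (e.g. a 2×2 cross of interior-spruce dams and sires
segregating for white-pine-weevil resistance), a consensus SNP linkage
map, two-color microarray expression profiles of the progeny, and field
phenotypes — tree heights plus ordinal weevil attack and oviposition
classes. The package is aimed at quantitative geneticists who want to
map expression QTLs alongside trait QTLs in such designs, and at method
developers who need a fully simulated, ground-truthed version of the
whole pipeline.

## What it computes

* **Per-parent single-marker LOD mapping** (`spruceqtl.qtlmap`). For
  each heterozygous parent, progeny are split by the transmitted allele
  at each marker; with a Gaussian two-class likelihood the score is
  LOD = (n/2)·log₁₀(RSS₀/RSS₁), where RSS₀ is the residual sum of
  squares about the grand mean and RSS₁ about the two transmission-class
  means. Records with LOD ≥ 3.84 are thinned to the best marker per
  10 cM bin, and each keeps its allele effect (m₁−m₂)/2 and percent
  variance explained 100·(1−RSS₁/RSS₀).
* **Trans-eQTL hotspots** (`spruceqtl.hotspots`). Per-marker eQTL counts
  are tested against uniformity (χ² with df = m−1); a randomization null
  scatters all N_e detected eQTLs uniformly over the m marker loci
  (1,000 replicates) to find the largest chance cluster; hotspots are
  markers whose count exceeds 1.5× the expected average N_e/m; hubs are
  hotspots carrying ≥3 phenotypic-trait QTLs in the same bin, with
  allele-effect sign concordance reported per parent.
* **Positional candidates by collocation** (`spruceqtl.colloc`). A
  transcript is a candidate for a trait when ≥40% of its eQTLs fall in
  10 cM bins containing the trait's pQTLs and a 10,000-draw permutation
  null (eQTLs placed uniformly over bins) gives p ≤ 0.05; composite
  growth/resistance candidates must be significant for every trait in
  the group. Phenotypic and "QTL" (collocation-profile) correlation
  matrices round out the analysis.
* **Distant-pair two-color design** (`spruceqtl.pairdesign`). Genetic
  distances between progeny (mismatch fraction of transmitted-allele
  combinations over shared segregating loci) feed an exact maximum-weight
  perfect matching within each cross, so co-hybridized samples are as
  genetically distant as possible; dyes are balanced across replicate
  blocks and fabrication batches, and the gain over random pairing is
  quantified.
* **Array preprocessing** (`spruceqtl.preprocess`). A robust affine-arsinh
  (generalized-log) calibration puts all channels on one scale, then a
  per-gene fixed-effect model h_i = μ + dye + block + batch + person + ε
  is fit and its residuals become the expression traits.
* **Synthetic study generator** (`spruceqtl.synth`). Simulates the whole
  design — Haldane-model transmissions on a 13-group/252-SNP map, planted
  cis/trans eQTLs, hotspot regulators, pleiotropic growth/resistance
  loci, ordinal trait liabilities, and two-channel intensities with
  technical effects — with a truth table for every planted signal.

## Worked example

```python
import spruceqtl as sq

config = sq.PipelineConfig(outdir="demo", seed=1)
summary = sq.run_pipeline(config)
```

On the default synthetic study (188 progeny in four crosses, 252 SNPs on
13 linkage groups, 300 transcripts of which 120 carry planted eQTLs)
this writes a full report bundle to `demo/` and returns:

```
n_arrays: 94                      # 188 profiled progeny paired onto 94 arrays
pairing_improvement_pct: 23.8     # distant pairs vs random pairing
n_eqtl: 639                       # significant eQTL records at LOD >= 3.84
n_pqtl: 61                        # phenotype QTL records
gof_chi2: 5407.0, gof_df: 251     # eQTL density is far from uniform
randomization_overall_max: 12     # largest chance cluster of 639 eQTLs
hotspot_cutoff: 4                 # 1.5 x expected count per marker
n_hotspots: 15, n_hubs: 12        # incl. the planted trans-regulator
```

The hotspot count far exceeds the randomization maximum because the
generator plants a master regulator driving 60 transcripts; the hubs are
markers where that eQTL cluster coincides with ≥3 planted growth and
resistance pQTLs. The same stages are available individually on the
command line (`spruceqtl simulate`, `preprocess`, `mapqtl`, `hotspots`,
`candidates`, `pairdesign`, `run`).

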