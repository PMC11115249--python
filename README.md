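# cyclodeps

Annotation of cyclic depsipeptides from high-resolution MS² spectra, plus
the environmental-metabolomics integration statistics needed to localize
them across a sampled site:

- **mass** — elemental-formula parsing (Hill notation), exact monoisotopic
  masses, adduct ion m/z with electron-mass correction, unsigned Δppm,
  and ring-plus-double-bond equivalents.
- **residues** — a residue alphabet of dehydrated amino / α-hydroxy acids
  (extensible via a CSV file) and the directed cyclic depsipeptide type
  with rotation-equivalence semantics (including the Leu/Ile/MeVal
  ambiguity code `Lxx`).
- **fragments** — theoretical MS² fragment ladders under two ring-opening
  pathways: lactone b-type cleavage at an ester, and a-type α-C/C=O
  cleavage with CO transfer onto the adjacent residue (terminal x₁ ion).
- **sequencing** — greedy fragment/peak matching and de-novo cyclic
  residue-sequence inference from neutral-loss ladders via a spectrum
  graph, with composition constraints and congener annotation by residue
  substitution (e.g. Hba↔Lac, Hda↔Hdda).
- **network** — modified-cosine molecular networking (0.7 score / 6
  matched-ion gates) and ion-identity grouping of adduct pairs by
  retention time, chromatographic peak-shape correlation (> 0.85) and
  adduct mass deltas.
- **cleaning** — MS feature-table preprocessing in fixed order: washout
  removal (RT ≥ 10 min), blank subtraction (0.3 cutoff on the blank/sample
  mean ratio), total-ion-count normalization, 10 % prevalence filter,
  center/scale.
- **stats** — Bray–Curtis dissimilarity, PCoA (Gower centering), distance
  PERMANOVA with permutation p-values, and all-pairs OTU × feature
  Spearman correlation with joint Benjamini–Hochberg FDR plus top-k
  heatmap selection.
- **simulate** — synthetic spectra, feature tables and OTU tables with
  planted ground truth for every pipeline stage (presets `demo`, `null`,
  `strong-signal`).
- **io / cli** — MGF, MZmine-style quant CSV + sample metadata, OTU CSV,
  EIC traces, GraphML/edge-list output and JSON run manifests.

## Command line

```sh
cyclodeps simulate --preset demo --seed 7 --out-dir out
cyclodeps clean    --quant out/quant.csv --metadata out/metadata.csv --out-dir out
cyclodeps network  --spectra out/spectra.mgf --out-dir out
cyclodeps annotate --spectra out/spectra.mgf --formula C44H64N4O8 --adduct M+Na --out-dir out
cyclodeps correlate --quant out/quant.csv --metadata out/metadata.csv --otus out/otus.csv --out-dir out
cyclodeps ordinate --quant out/quant.csv --metadata out/metadata.csv --out-dir out
cyclodeps all      --preset demo --seed 7 --out-dir out   # chains the above
```

Every run writes `manifest.json` (tool version, seeds, input digests,
per-stage counts). With a fixed seed the whole `all` pipeline is
byte-deterministic.

## Library example

```python
from cyclodeps import (CyclicDepsipeptide, IonSpecies, all_fragments,
                       infer_residues, parse_formula)
from cyclodeps.simulate import simulate_spectrum

peptide = CyclicDepsipeptide.from_names(["Phe", "Lxx", "Hba", "Phe", "Lxx", "Hda"])
ions = all_fragments(peptide, IonSpecies("M+Na"))          # predicted ladder
spectrum = simulate_spectrum(peptide, IonSpecies("M+Na"), ppm_sd=5, n_noise=20)
top = infer_residues(spectrum, parse_formula("C44H64N4O8"))[0]
print(top.residues)        # cyclic sequence, Lxx for Leu/Ile/MeVal
```
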