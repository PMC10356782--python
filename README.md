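# mxif3d

3D reconstruction and spatial analysis of multiplexed immunofluorescence
(MxIF) serial tissue sections.

## The problem

A fixed tissue block is cut into ~5 µm serial sections; each retained
section is imaged with DAPI, an unstained autofluorescence (AF) channel and
a panel of biomarkers (CD3/CD4/CD8/FOXP3, CD68, CD31, cytokeratins,
p53/Ki67/DDB2). Every section is independently rotated, shifted and
deformed during cutting and cyclic staining, and a 5–10 µm nucleus appears
on 1–3 consecutive sections, so per-section counting overcounts cells and
2D spatial metrics misjudge distances: a cell's nearest blood vessel is
often in the *next* section. `mxif3d` provides the full desk workflow for
researchers building or analyzing such stacks:

- **phantom** — synthetic serial-section stacks with known ground truth
  (nuclei, vessels, epidermis, skin surface, per-section deformations);
- **preprocess** — illumination correction, zero-mean/unit-variance
  normalization, AF tissue masks (Otsu + closing + largest component);
- **segment** — multiscale Laplacian-of-Gaussian nuclei detection,
  two-component Gaussian-mixture marker probabilities
  (positive class = higher-mean component; call positive iff mean nucleus
  probability ≥ 0.5 and ≥ 10% of nucleus pixels above threshold),
  structure masks and phenotype assignment
  (CD31+ → endothelial, CD3+CD4+FOXP3+ → T reg, CD3+CD4+ → T helper,
  CD3+CD8+ → T killer, CD68+ → macrophage, AE1/CK26+ → epithelial);
- **register** — block-matching affine (local NCC correspondences,
  trimmed least squares) followed by B-spline deformable refinement driven
  by mutual information, with DSC/NCC quality control, applied to every
  channel, label raster and point set; optional global 3D affine
  refinement against an external volume of the intact block;
- **reconstruct** — stacking registered sections at physical z and fusing
  per-section nuclei into 3D cells by 26-connected components
  (never across skipped-section gaps), tissue volume and cells/cm³;
- **spatial** — per-cell 2D and 3D distance to the nearest vessel voxel
  (axis-pruned exact nearest-neighbor search), distance to the skin
  surface, immune cluster density at 15/30 µm, and the accompanying
  statistics (two-sample KS, Spearman + Benjamini–Hochberg, Wilcoxon
  rank-sum).

Because each cell is referenced to its section plane, the same-section
candidate set is a subset of the 3D candidate set: per cell `d3D ≤ d2D`
and `count3D ≥ count2D` hold exactly — the mechanism by which 3D
reconstruction reveals shorter vessel distances and denser immune
neighborhoods than single-section analysis.

## Worked example

`examples/02_register_stack.py` perturbs a 6-section phantom with random
per-section affine jitter (≤3°, ≤10 px), smooth deformations (≤10 px) and
noise, then registers it back to the middle reference section:

```
$ python examples/02_register_stack.py
per-section mask DSC vs reference: 0.985 0.987 0.988 1.000 0.995 0.988
mean DSC 0.989  (>= 0.95 indicates high-quality registration; the
reference section itself scores 1.0)
mean adjacent NCC 0.912  (AF texture correlation between neighboring
registered sections; ~0.6 is typical because tissue genuinely changes
over 5 µm)
```

The DSC line reports how well each registered tissue mask overlaps the
reference mask (1.0 = perfect); the NCC line reports AF intensity
correlation between adjacent registered sections. The other example
scripts cover phantom generation, marker classification (prints
accuracy/sensitivity/specificity against ground truth), 2D-vs-3D spatial
metrics, and the full pipeline (`run_pipeline`), each printing a short
interpretation with its numbers.

A thin CLI wraps the same functions for shell use:

```bash
mxif3d phantom out_stack --n-sections 8 --seed 1
mxif3d register out_stack            # writes transforms.json + QC
mxif3d run pipeline.yaml             # full pipeline from a YAML config
```

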