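# ichdquant

3-D virtual-histology quantification of **intracellular hyperdensity (ICHD)**
in X-ray phase-contrast microCT volumes of brain tissue — with a fully
synthetic, ground-truthed test bed.

## The problem

Phase-contrast CT of unstained brain tissue shows sparse *hyperdense (HD)
particles*: cell-shaped accumulations of dense material (protein aggregates,
metal deposition) that track aging and Alzheimer's-type neurodegeneration.
Quantifying them label-free requires a chain of image-analysis steps —
automatic segmentation, 3-D object counting, size-based decomposition into
cell populations, and group statistics over an animal study.  `ichdquant`
implements that chain as a tested Python library for image-analysis and
preclinical-imaging researchers, and — because such synchrotron volumes are
rarely public — ships a phantom generator so every stage can be validated
against known ground truth.

## The pipeline

1. **Segmentation** (`segmentation`): a per-VOI intensity histogram is split
   by the maximum-entropy criterion of Kapur–Sahoo–Wong: the threshold t\*
   maximises H₀(t) + H₁(t), the summed Shannon entropies of the two classes.
   Hyperdense voxels are those strictly above t\*.
2. **3-D object counting** (`particles`): connected components
   (26-connectivity by default) are measured — voxel count, volume
   V = N·(voxel size)³, equivalent-sphere diameter d = 2·(3V/4π)^{1/3},
   centroid.  Rare large plaque-like clusters (d > 20 µm by default) are
   excluded from the cellular analysis.  The **3-D tissue load** is
   100 × (HD volume) / (VOI volume).
3. **Population model** (`populations`): equivalent-sphere diameters are
   fitted with a K-component Gaussian mixture by EM; BIC
   (−2·logL + (3K−1)·ln n) selects K.  At sub-micron voxels the distribution
   is tri-modal — nucleoli (~2 µm) < glia (~4 µm) < ICHD-bearing neurons
   (~8 µm); at 3 µm voxels nucleoli are unresolved and K = 2 wins.
4. **Group statistics** (`stats`): per-region one-way ANOVA with
   Tukey–Kramer studentized-range post hoc (unequal n) across four animal
   groups, and exact unpaired two-sided Wilcoxon rank-sum tests for
   per-cell elemental densities.
5. **XFM quantification** (`xfm`): mean intracellular elemental area density
   (ng/mm²) per labeled cell from calibrated X-ray-fluorescence maps,
   compared between ICHD-bearing and normal cells.
6. **Imaging physics** (`phase`): Fresnel forward propagation of a
   homogeneous object (n = 1 − δ + iβ) and Paganin single-distance phase
   retrieval, t = −(1/μ)·ln 𝔉⁻¹[𝔉(I_z/I₀)/(1 + (δz/μ)k²)], so the pipeline
   can start from raw near-field projections.
7. **Synthetic data** (`synthetic`): ground-truthed phantoms — three
   particle populations, plaques, vessels, PSF blur, noise, the multiscale
   voxel sizes (3.0/0.7/0.3/0.1 µm), the 4-group × 4-region study design,
   and two-class elemental maps.

## Worked example

```python
import ichdquant as iq

cfg = iq.default_phantom_config(seed=1)        # 256³ voxels @ 0.3 µm
volume, truth = iq.generate_phantom(cfg)
res = iq.process_voi(volume, "demo", min_voxels=10)

print(res.threshold)               # 113.26  (Kapur threshold, density units)
print(len(res.catalog.retained))   # 264     (planted: 265)
print(res.result.load_percent)     # 4.319   (planted: 4.301 %)
print(res.fit.k, res.fit.means)    # 3 [2.02 3.95 7.91] µm
```

The phantom planted 265 particles with a 4.30 % hyperdense load; the
pipeline recovers 264 particles, a 4.32 % load (0.4 % relative error), and a
three-component mixture with means 2.02 / 3.95 / 7.91 µm against planted
population means 2.01 / 3.93 / 7.92 µm.  Resampling the same volume to
3.0 µm voxels (`iq.resample_volume(volume, 3.0)`) collapses the fit to
K = 2: nucleoli are smaller than the point-spread of the coarse grid.

The numbered drivers under `analysis/` run each stage as a narrative —
phantom construction, phase-retrieval round trip, segmentation + counting,
population decomposition, the four-group drug study, and the XFM element
comparison — and write their tables under `results/`.

Command-line interface mirroring the library:

```bash
ichdquant simulate --seed 2 --shape 128 --out run/
ichdquant segment --volume run/phantom.tif --out run/mask.tif
ichdquant quantify --mask run/mask.tif --min-voxels 10 --out run/q/
ichdquant pipeline --config study.yaml --seed 7 --out run/study/
```

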