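# seedfrost

Hyperspectral identification of freeze damage in single corn (maize)
seeds.

Freeze-damaged seeds germinate poorly but look normal from the outside.
Visible/near-infrared hyperspectral imaging (400–1000 nm) of single
kernels, combined with chemometric wavelength selection and
classification, screens seeds nondestructively into three severity
classes (1 = normal, 2 = slightly frozen, 3 = severely frozen) — and does
so separately for the kernel's two faces, because the metabolically
active embryo (germ) face responds to freezing more strongly than the
starchy endosperm face.

The package implements the full pipeline as a tested library plus CLI:

* **Calibration** — black/white reflectance correction
  `I = (I_o − I_B)/(I_W − I_B)` of ENVI-style cubes, and trimming of the
  noisy band extremes (450–979 nm, 420 bands).
* **Segmentation** — gray band (700/500 nm), percentile contrast stretch,
  Otsu threshold, connected components, per-seed mean spectra.
* **Preprocessing** — none / SNV / Savitzky–Golay 5-point 3rd-order
  smoothing.
* **Wavelength selection** — SPA (successive projections: at each step
  keep the band with the largest norm after orthogonal projection onto
  the complement of the selected set, subsets of size 1–20 scored by
  cross-validated LDA), 2DCOS (synchronous two-dimensional correlation
  spectrum Φ(ν₁,ν₂) over the severity-ordered class means, selecting the
  autocorrelation peaks on its diagonal), and their fusion
  (SPA ∪ 2DCOS).
* **Modeling** — deterministic per-class Kennard–Stone 2:1 train/test
  split; KNN, LDA and RBF-SVM classifiers; accuracy, per-class
  sensitivity, the chance-agreement accuracy
  `Accuracy_RND = 100·Σ_c rowsum_c·colsum_c/N²` and the skill score
  `Accuracy − Accuracy_RND`.
* **Synthetic data** — a generator of per-seed spectra and full
  raw/dark/white cube triplets with known ground truth (severity-ordered
  class means, planted damage features at 730/810/880/950 nm, per-seed
  scatter and severity jitter), so every stage is testable without any
  image download.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Generate a synthetic embryo-side dataset, select wavelengths by
SPA + 2DCOS fusion, and train an LDA on a Kennard–Stone 2:1 split:

```sh
$ seedfrost simulate --side embryo --seed 7 --class-sizes 120,96,72 \
      --n-bands 120 --out embryo.csv
wrote 288 spectra x 120 bands to embryo.csv

$ seedfrost select embryo.csv --method spa+2dcos --out sel_fused.json
SPA+2DCOS: 22 wavelengths -> sel_fused.json

$ seedfrost train embryo.csv --model lda --selection sel_fused.json
{
  "train": {
    "accuracy": 93.8,
    "sensitivity": [98.8, 85.9, 95.8],
    "accuracy_rnd": 34.6,
    "accuracy_minus_rnd": 59.2
  },
  "test": {
    "accuracy": 96.9,
    "sensitivity": [100.0, 96.9, 91.7],
    "accuracy_rnd": 35.0,
    "accuracy_minus_rnd": 61.9
  }
}
```

Reading the output: 96.9% of held-out seeds are classified into the
correct severity class using only the 22 fused wavelengths (instead of
all 120 bands); per-class sensitivity shows normal seeds are detected
perfectly and severely frozen seeds are hardest (91.7%); `accuracy_rnd`
is what a marginal-matching random guesser would score (≈ 35% for these
mildly imbalanced classes), so the model's skill above chance is
61.9 points out of an ideal ≈ 66.7.

`seedfrost grid` runs the full 3 preprocessings × 4 selections ×
3 models experiment from a YAML config and writes confusion matrices,
metrics JSON and a Markdown summary; `seedfrost segment` takes ENVI
raw/dark/white cube triplets to per-seed spectra tables.

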