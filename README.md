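# stainwave

Blind stain deconvolution for multi-stained histology images by
independent component analysis in the wavelet domain.

## The problem

A haematoxylin & eosin (H&E) tissue slide mixes two dyes: haematoxylin
marks nuclei, eosin marks cytoplasm and stroma. Most histology image
analysis — nuclei detection, stain normalisation, feature extraction —
needs the per-stain channels, but the scanner only records their RGB
mixture, and the exact colour of each stain varies between labs, scanners
and staining runs. A fixed published stain matrix is therefore often wrong
for the slide at hand; the matrix has to be estimated from the image
itself.

By the Beer–Lambert law, transmitted intensity is `I = I0 · exp(-M N)`, so
in optical density `D = -log(I / I0)` the mixing is linear:

```
D = M N
```

with `M` the 3×3 stain matrix (columns = unit-norm OD absorption
directions of haematoxylin, eosin and a residual component) and `N` the
per-pixel stain densities. Estimating `M` blindly is a source-separation
problem — but plain ICA on the OD pixels assumes the stain densities are
independent, and in real tissue they are not: nuclei sit inside
eosin-stained cytoplasm, so the density fields co-vary.

## The method

Because the wavelet transform is linear, every sub-band of the mixture
obeys the same mixing model: `F(M N) = M F(N)`. The trick is to run ICA
only where the sources look most non-Gaussian — and hence most
independent and separable:

1. convert the tile to optical density;
2. decompose each OD channel with a decimated 2-D wavelet cascade
   (default `db2`, 5 levels), composing 3-channel sub-bands per level and
   orientation (approximation, horizontal, vertical, diagonal — 20 bands);
3. standardise each band and score its non-Gaussianity by the excess
   kurtosis |K| of the pooled coefficients;
4. concatenate the top-n bands (default: all 20) into a filtered
   observation matrix `D′` and estimate `M` as the (canonicalised) mixing
   matrix of fixed-point ICA on `D′`;
5. recover the density maps from the raw OD image: `N = M⁻¹ D`.

The package also ships the evaluation protocol (annotation-derived
ground-truth stain matrices, Euclidean stain-vector distance, density-map
correlation, Bland–Altman limits of agreement), a plain-ICA baseline, and
a synthetic phantom generator that renders Beer–Lambert tiles with known
stain matrix, textured density fields, controllable inter-stain
correlation and sensor noise.

## Worked example

```sh
python examples/deconvolve_phantom.py
```

```
true stain matrix (columns = H, E, residual OD vectors):
[[0.65   0.0721 0.    ]
 [0.704  0.9918 0.    ]
 [0.286  0.1052 1.    ]]

estimated stain matrix:
[[0.6485 0.0763 0.    ]
 [0.7056 0.9914 0.    ]
 [0.2855 0.1067 1.    ]]

angular error (degrees) and density-map correlation per stain:
  haematoxylin  angle  0.129 deg   r = 0.99995
  eosin         angle  0.258 deg   r = 0.99994
```

The tile was rendered from the "true" matrix; the pipeline saw only the
8-bit RGB image. The estimated OD absorption directions land within a
fraction of a degree of the generating ones, and the recovered per-pixel
stain amounts correlate with the generating density fields at r ≈ 1.

The mechanism the method exists for — robustness to correlated stains —
is shown by `examples/correlated_stains.py` (phantoms with inter-stain
density correlation 0.6):

```
  sub-band ICA : median  3.11 deg
  plain ICA    : median  7.59 deg
```

Other examples: `examples/subband_selection.py` prints the kurtosis
ranking that drives band selection; `examples/evaluate_against_annotations.py`
runs the annotation-based evaluation protocol end to end.

## Command line

```sh
stainwave deconvolve tile.png --out-dir out --wavelet db2 --levels 5 \
    --n-subbands 20 --seed 0
stainwave synth --out-dir suite --seeds 20
stainwave evaluate --est out/stain_matrix.csv --image tile.png \
    --gt-annotations annots.csv
```

`deconvolve` writes the labelled stain-matrix CSV, per-stain float-TIFF
density maps, per-stain RGB reconstructions and the kurtosis ranking
table. `--matrix M.csv` applies a precomputed matrix instead of
estimating one.

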