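# Methods

## Model

A multi-stained tissue tile is modelled with the Beer–Lambert law:
transmitted intensity `I = I0 · exp(-M N)`, where `I0` is the incident
light intensity, `M` is the 3×3 stain mixing matrix whose columns are the
RGB optical-density absorption directions of haematoxylin, eosin and a
residual/background component, and `N` (3×P) holds the per-pixel amount of
each stain. In optical density `D = -log(I/I0)` the model is linear,
`D = M N`, and stain separation is a blind source-separation problem with
three observed channels and three latent sources.

ICA identifies `M` only if the sources are (nearly) independent and
non-Gaussian. Stain densities in real tissue are neither fully independent
nor equally structured everywhere, so the estimator here works on
wavelet sub-bands of the OD image: any linear filter `F` satisfies
`F(M N) = M F(N)`, so every sub-band obeys the same mixing model, and the
bands whose coefficient statistics are furthest from Gaussian (largest
|excess kurtosis|) are the ones where the sources are sparsest and most
separable. ICA on the concatenation of those bands estimates the same `M`
that applies to the raw pixels.

## Conventions and numerical choices

* **Logarithm**: natural log. The base only rescales `D` and `N` jointly
  and leaves stain-vector directions unchanged; the natural log matches
  the `e`-exponent of the forward model.
* **Black-pixel clamp**: intensities are clamped to 1 count before the
  log (OD at most `log(i0)`), so saturated-black pixels stay finite.
* **Incident intensity**: `i0 = 255` for 8-bit data (65535 for 16-bit),
  overridable; it is not estimated from background pixels.
* **Pixel order**: row-major flattening to 3×P, fixed so density maps
  reshape deterministically.
* **Wavelet**: `db2`, 5 levels by default, configurable. A compact
  orthogonal wavelet keeps the transform energy-preserving and captures
  short-scale texture. Boundary mode is `periodization`, which makes the
  decimated transform exactly orthonormal for orthogonal wavelets: each
  level has exactly a quarter of the previous level's coefficients per
  orientation and channel energy is conserved, which the test suite
  exploits. Other pywt modes can be selected but give redundant boundary
  coefficients.
* **Band inventory**: at every level the four orientation blocks —
  including that level's running approximation — are composed into
  3-channel bands, giving 4·levels bands (20 at depth 5). The per-level
  approximations are mutually redundant in a plain cascade but are kept
  as selectable bands so that low-frequency structure can compete in the
  kurtosis ranking.
* **Band normalisation**: each 3×p band is centred **per channel row**
  and scaled by a **single pooled** standard deviation. Row-centring
  commutes with `M` (the row means of `M S` equal `M` applied to the row
  means of `S`), so the mixing model stays exact; without it the
  approximation bands carry level-dependent DC offsets into `D′` that act
  as a spurious band-indexed component along (1,1,1) and measurably bias
  the ICA estimate. The scale factor must be pooled rather than per-row:
  per-row standard deviations would rescale the channels independently
  and destroy the very matrix being estimated. The normalised band has
  pooled mean 0 and pooled variance 1.
* **Kurtosis**: excess kurtosis (fourth standardised moment minus 3) of
  all 3·p normalised coefficients pooled; zero for a Gaussian. Bands with
  pooled standard deviation below 1e-12 are flagged degenerate and never
  selected. Ties in |K| are broken by (level ascending, orientation in
  a, h, v, o order) so selection is deterministic and invariant to band
  enumeration order.
* **Selection count**: default is all 20 bands; the sweep experiment
  (5/10/15/20) is exposed to reproduce the finding that using the full
  set is at or near the best setting.
* **ICA**: scikit-learn FastICA, parallel fixed-point iteration, logcosh
  contrast, unit-variance whitening, `tol = 1e-4`, `max_iter = 400`,
  seeded. Non-convergence triggers up to three deterministic re-seeded
  restarts, then an error. Rank-deficient observations raise an error
  naming the degenerate channel.
* **Ambiguity resolution**: ICA leaves sign, scale and permutation free.
  Each mixing column is sign-flipped so its entry sum is non-negative
  (absorption cannot be negative), negative residues are clipped, and the
  column is unit-normalised. Columns are then *labelled* by proximity to
  fixed reference H and E OD directions (the widely used values
  H ≈ (0.65, 0.70, 0.29), E ≈ (0.07, 0.99, 0.11), unit-normalised),
  choosing the assignment that minimises the total angle over ordered
  column pairs; ties go to the candidate with more blue absorption for H.
  The references are used only for labelling, never in estimation. The
  third column is kept as "residual" rather than forced to a background
  colour.
* **Deconvolution**: `N = M⁻¹ D` on the raw OD image. Negative densities
  are kept in the numeric maps (information-preserving) and clipped at
  zero only for rendering; correlation metrics use the un-clipped values
  unless requested otherwise. If `cond(M) > 1e4` the pseudo-inverse is
  used with a warning.
* **Ground-truth stain matrix**: per stain, the per-channel median OD of
  the annotated pixels (numpy median: mean of the middle two for even
  counts), unit-normalised. The residual column is the cross product of
  the two stain vectors passed through the same canonicalisation as
  estimated columns — a repo convention, since annotations say nothing
  about the residual direction.
* **Bland–Altman**: bias = mean paired difference, limits = bias ±
  1.96·SD; a seeded 5000-pixel subsample by default, mirroring plots of
  randomly selected pixels.

## Synthetic phantoms

The phantom generator is the test surface: it renders tiles through the
exact forward model with a known `M` so that recovery error is measurable.

* **Stain matrix**: defaults to the reference H and E directions
  (~40° apart — deliberately non-orthogonal, like real H&E) plus the
  canonicalised cross-product residual; configurable.
* **Nuclei field** (stain 1): `blob_count` (default 150 on 256×256)
  sharp-edged discs, radial profile `exp(-(r/radius)^6)` with radius 4 px
  and amplitudes uniform in ±30% of 1.0, at uniform random positions.
  The near-flat interior with a ~1 px fall-off mimics the sharp
  nucleus/background boundary and puts genuine signal into the fine
  detail bands, which is what the kurtosis criterion feeds on.
* **Cytoplasm field** (stain 2): absolute value of white noise smoothed
  anisotropically (0.8 px across, 2·`fiber_scale` = 6 px along),
  giving directional fibrous texture with ridge-like valleys; affinely
  rescaled to be non-negative with mean OD 0.35.
* **Inter-stain correlation**: a Gaussian-smoothed copy of the nuclei
  field (σ = blob radius) is mixed into the fibrous field with gain
  calibrated from the realised fields so the density correlation hits the
  target `rho`; the realised correlation tracks the target to ±0.1 up to
  `rho ≈ 0.75`, beyond which it saturates with a warning. Because the
  shared component is low-frequency by construction, correlation
  concentrates in the coarse bands while fine detail bands stay nearly
  independent — the regime the sub-band method is designed for, matching
  the claim that filtering reduces the dependence the sources show.
  Correlation is induced in density (source) space, since source
  dependence is what breaks plain ICA.
* **Sensor noise**: additive Gaussian in the intensity domain
  (`noise_sigma` counts), then 8-bit quantisation. Everything is
  deterministic per seed.
* **Residual density**: zero — the rendered data are rank-2 plus
  quantisation noise, so the third ICA component is unconstrained and is
  reported as the residual channel.

What the phantoms do **not** emulate: chromatin texture inside nuclei,
nucleoli, tissue architecture (glands, lumina), scanner-specific colour
response, chromatic aberration, out-of-focus blur, or spatially varying
illumination. Passing recovery tests on phantoms therefore demonstrates
the estimator's correctness under the stated mixing model and texture
assumptions, not its accuracy on any particular scanner's slides.

## Experiment sizes

The recovery, comparison and sweep experiments run on 256×256 phantoms:
20 seeds for the independent-recovery and correlated-comparison
experiments, and 10 seeds × 3 conditions (rho, noise) × 4 sub-band counts
for the sweep. These sizes give stable medians (the pipeline is
sub-second per tile) while keeping the whole suite fast.

## Known limitations

* With two-stain images the data are near rank-2; the residual direction
  is numerically arbitrary and only the H and E columns are meaningful.
* Kurtosis pools the three channel rows, so bands whose channels have
  very unequal variance carry a positive kurtosis offset (a Gaussian
  scale mixture); the *ranking* is unaffected because the offset is
  nearly common across bands, but absolute |K| values should not be read
  as pure non-Gaussianity.
* The number of selected sub-bands is global, not adapted per tile.
* No stain normalisation, whole-slide pyramid handling or illumination
  correction; inputs are single tiles.
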