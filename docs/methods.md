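# Methods

This note documents the model implemented by `spinflux`, the provenance of
its default parameters, the numerical choices, and the known limitations.

## Image-formation model

A single emitter at $(\theta_x, \theta_y)$ is excited by a sequence of $K$
illumination patterns, each co-centered with a circular pinhole in the
emission path. For pixel $i$ and exposure $k$,

$$\mu_{i,k} = A\,\theta_I\,P_k\,H_i + A\,\theta_b\,B_{i,k},$$

with Poisson counts around $\mu$.

**Patterns.** Peak-normalized so that $\theta_I$ is the expected signal
photon count under maximum illumination. The Gaussian focus is
$P(r) = e^{-r^2/2\sigma_\mathrm{illum}^2}$; the donut is the
Gauss–Laguerre-like profile
$P(r) = (r^2/2\sigma_\mathrm{illum}^2)\,e^{1 - r^2/2\sigma_\mathrm{illum}^2}$
— zero at the center, unit peak on the ring $r = \sigma_\mathrm{illum}\sqrt2$,
parameterized by the same width as the Gaussian. A `uniform` kind
($P \equiv 1$) expresses the widefield reference through the same code path.

**Photon budget.** The emitter's signal budget $\theta_I$ is fixed; each
pattern takes a share proportional to its intensity at the emitter. In the
`exhaust_budget` scenario the illumination time/power suffices to spend the
full budget however weakly the emitter is lit: $A = 1/\sum_k P_k$, so
$A \sum_k P_k \equiv 1$ and the only signal loss is pinhole windowing (plus
finite-ROI truncation, < 2% at the default geometry). In `fixed_power`, each
pattern gets the widefield dose: $A = 1/K$, independent of $\theta$. When the
summed intensity at the emitter falls below $10^{-12}$ the exhaust-budget
configuration is rejected ("unilluminated") instead of producing an
unbounded amplification.

**Pinhole windowing.** The camera plane is treated as conjugate to the
pinhole plane with no additional relay blur: the pinhole is a sharp circular
mask applied to the Gaussian emission PSF (width $\sigma_\mathrm{PSF}$)
before pixel integration. $H_i$ is the PSF mass in pixel $i$ ∩ aperture:
pixels fully inside the aperture use the exact error-function pixel integral;
pixels cut by the aperture edge use midpoint quadrature on a pixel-aligned
sub-grid whose cell size follows the pinhole-mesh prescription (diameter /
`mesh_n`). Without a pinhole the closed form applies everywhere. All
gradients with respect to the emitter position are analytic inside the same
quadrature; central finite differences serve only as test oracles.

**Effective background.** A uniform in-focus fluorophore density excited by
pattern $k$ and imaged through pinhole $k$ yields
$B_{i,k} = a^{-2}\iint P_k(u,v)\,H(u,v,x_i,y_i)\,du\,dv$ ($a$ = pixel size).
Swapping the integration order reduces this exactly to the pinhole-window
integral of the pattern⊛PSF convolution, which is closed-form for all three
pattern kinds — the implementation therefore has no sample-plane truncation
parameter; the literal double integral is kept as an independent oracle in
the test suite. The normalization is anchored so that uniform illumination
with no pinhole gives $B_i = 1$: $\theta_b$ means "expected background
photons per pixel" on the same scale for every method. The
pattern-independent variant models $B_{i,k}$ as the pixel–pinhole overlap
area divided by $a^2$. Note that in the exhaust-budget scenario the
background term is amplified by the same $A$ as the signal: weakly
illuminating the emitter while spending the full budget multiplies the
background dose accordingly.

**Photon bookkeeping.** `collected_signal` sums the signal part of $\mu$ over
pixels and exposures; `blocked_signal` is the emitted budget minus that
(pinhole blocking and ROI truncation are not distinguished).
`mean_background_per_pixel` accumulates background over the whole sequence
and divides by the pixel count only — this is the quantity directly
comparable to the widefield reference, where one frame carries $\theta_b$
per pixel.

## Estimation theory

The Fisher information
$I_{uv} = \sum_{i,k}\mu_{i,k}^{-1}\,\partial_u\mu_{i,k}\,\partial_v\mu_{i,k}$
is accumulated over all pixels and exposures with a floor of $10^{-12}$
counts on $\mu$ in the denominator, so pixels whose expectation *and*
derivatives both vanish (dark pixels outside a small pinhole) contribute
exactly zero. The 4×4 matrix is inverted by a diagonally scaled solve;
degeneracy is diagnosed on the unit-free correlation-like matrix
$D I D$, $D = \mathrm{diag}(I_{uu}^{-1/2})$ (the raw condition number mixes
nm² and photon-count units), with a rejection threshold of $10^{12}$ and an
error message naming the weakest parameter combination. Parameter order is
$(\theta_x, \theta_y, \theta_I, \theta_b)$ everywhere; precisions are
$\sqrt{\text{variance}}$ in nm.

**Baselines.** `smlm_baseline` runs the widefield configuration (uniform
pattern, no pinhole, $K=1$, $A=1$, $B=1$) through the same Fisher machinery,
bit-for-bit identical to calling `crlb` on that sequence. `ism_crlb` models
localization on an image-scanning-microscopy reconstruction as the widefield
model with $\sigma_\mathrm{PSF}$ divided by $\sqrt2$ (pixel reassignment) or
2 (Fourier reweighting), photon counts unchanged; this choice reproduces the
conventional zero-background improvement limits (≈1.4 and ≈1.9) and the
finite-background improvements (≈1.48 and ≈2.10 at 2000 signal / 8
background photons).

**Closed-form baseline route.** Reference precisions for widefield SMLM and
reconstruction-based localization are conventionally quoted via the standard
closed-form approximation
$\sigma^2 = \frac{\sigma_a^2}{N}\left(1 + 4\tau + \sqrt{2\tau/(1+4\tau)}\right)$
with $\sigma_a^2 = \sigma_\mathrm{PSF}^2 + a^2/12$ and
$\tau = 2\pi b \sigma_a^2 / (N a^2)$
(`gaussian_localization_precision_approx`, `ism_precision_approx`). On the
default parameter set it gives 2.618 / 1.773 / 1.246 nm for the widefield,
plain-ISM and reweighted-ISM references; the exact Fisher route gives
2.573 / 1.742 / 1.224 nm — a uniform ≈1.8% difference, asserted in the test
suite as a dual-route consistency check. The acceptance script quotes the
closed-form values for the three reference precisions, since that is how
such baselines are defined; improvement factors use the exact Fisher
baseline, which keeps both CRLBs in the ratio on identical footing.

**MLE validation.** `mle_fit` maximizes
$\sum_{i,k} (c\,\log\mu - \mu)$ by bounded L-BFGS with the analytic Jacobian
(positions bounded to the ROI, $\theta_I \ge 10^{-3}$, $\theta_b \ge 0$).
Over 500 Poisson replicates of a centered single-pattern acquisition the
empirical std of $\hat\theta_x$ matches the CRLB $\sigma_x$ within a few
percent and never undercuts it beyond Monte-Carlo error. The intensity
parameters $(\hat\theta_I, \hat\theta_b)$ show visible finite-sample bias
(they are strongly anticorrelated and $\theta_b$ is boundary-constrained), so
bound attainment is asserted on the position parameters only.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| $\sigma_\mathrm{PSF}$ | 93.3 nm | emission PSF std ($0.21\lambda_\mathrm{em}/\mathrm{NA}$) |
| $\sigma_\mathrm{illum}$ | 85.0 nm | illumination pattern std ($0.21\lambda_\mathrm{ex}/\mathrm{NA}$) |
| pixel size | 65 nm | back-projected camera pixel |
| ROI | 10 × 10 px | emitter at the ROI center (a pixel corner) |
| $\theta_I$ | 2000 | expected signal photons |
| $\theta_b$ | 8 | expected background photons / pixel |
| pinhole radius | $3\sigma_\mathrm{PSF}$ | standard configurations |
| `mesh_n` | 100 | pinhole mesh resolution per axis |
| scenario | exhaust_budget + pattern_dependent | standard evaluation |

$\sigma_\mathrm{illum}$ deserves a note: it corresponds to an excitation line
roughly 8% bluer than the emission band and was fixed by a one-time
consistency calibration — 85.0 nm simultaneously reproduces the whole family
of pattern-dependent reference benchmark values (pair improvement 2.62,
triangle 1.94, donut-triangle 1.64, single-pattern falloff 1.14 → 0.73 over
0–130 nm, sequence background 7.75 photons/pixel at $s = 4\sigma_\mathrm{PSF}$
and 26.7 at $5\sigma_\mathrm{PSF}$) to ≈1%, whereas no other width does.
Residuals at that value: the $r_p = 4\sigma_\mathrm{PSF}$ single-pattern
background-reduction factor computes to 9.5× (reference 10.2×), the
triangle-with-center maximum to 1.43 (reference 1.44), and the ≥1.2-fold
improvement domain at $s = 3\sigma_\mathrm{PSF}$ to 185 nm (reference
175 nm). These are asserted in the tests at correspondingly documented
tolerances.

## Numerical choices

* **Pinhole quadrature.** Midpoint rule; boundary-pixel sub-grids are aligned
  to pixel edges so the only quadrature error comes from the aperture arc.
  At `mesh_n = 100` the relative CRLB error against a 400-mesh reference is
  ≈0.002% on the standard single-pattern configuration (bound: 0.02%). The
  error decreases monotonically on coarse meshes (25 → 50 → 100) and
  oscillates at the 10⁻⁵ level beyond that, as expected for
  inclusion/exclusion quadrature.
* **Donut maxima.** The improvement of the 4-donut (triangle + center)
  configuration has a sharp local *minimum* exactly at zero focus offset: at
  the donut zero both $P$ and $\nabla P$ of the center pattern vanish while
  the exhaust-budget normalization maximally amplifies the pattern-dependent
  background. The peak improvement (3.59 at the defaults, spacing
  $4\sigma_\mathrm{PSF}$) sits ≈2 nm off center; summary tables therefore
  maximize over a short (0–8 nm) focus-offset scan. For Gaussian
  configurations the maximum is the centered value.
* **Degenerate inputs.** Closed pinholes (radius 0) yield empty meshes and
  zero H/B; a donut exposure centered exactly on the emitter with zero
  background yields an all-dark stack and a diagnosed degenerate Fisher
  matrix; scans record failing grid points as flagged rows instead of
  raising.
* **Caching.** Background stacks and pinhole meshes are memoized per
  (sequence, optics, grid, mesh) — they do not depend on the emitter — which
  makes repeated CRLB evaluations and MLE iterations cheap (≈1 ms per
  configuration).

## Synthetic data

`sample_counts` draws independent Poisson counts from $\mu$ with an explicit
seed (one generator per call, no global state); stacks serialize to
multi-page TIFF plus a JSON sidecar carrying $\theta$, the sequence, optics
and seed. The generator emulates shot-noise-limited acquisition with uniform
in-focus background at the study conditions above. It does **not** emulate:
readout/EM-gain noise, emitter blinking or bleaching within a sequence,
neighboring emitters, out-of-focus background, aberrated or vectorial PSFs,
or the timing/geometry of a real rotating disk. Passing tests therefore
demonstrate correctness of the model and bound computations under the
model's own assumptions, not performance on real camera data.

## Limitations

* 2D (lateral) localization only; axially structured illumination and 3D
  background are out of scope.
* The pinhole is a sharp mask; a possible secondary diffraction blur between
  pinhole and camera is not modeled.
* The donut profile is one standard choice of vortex-beam parameterization;
  other profiles change the far-tail behavior and hence exhaust-budget
  normalization in configurations that place emitters near pattern zeros.
* The CRLB is a bound for unbiased estimators; the validation MLE attains it
  for position at the default photon counts but shows finite-sample bias in
  the intensity parameters.
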