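# spinflux

Theoretical localization-precision limits for **spinning-disk
modulation-enhanced single-molecule localization microscopy** (meSMLM on a
spinning-disk confocal, "SpinFlux"-style).

## The problem

In modulation-enhanced SMLM (MINFLUX, SIMFLUX, ...) an emitter is excited by a
sequence of structured illumination patterns, and the photon counts recorded
under each pattern carry information about the emitter's position *relative
to the pattern* on top of the ordinary PSF-shape information. A spinning-disk
confocal can realize this with minimal hardware changes: each pinhole of the
rotating disk projects a focused (Gaussian or, with a phase mask,
donut-shaped) illumination pattern, and the same pinhole windows the emission
before it reaches the camera. This package answers, for any such pattern
sequence: *what is the best localization precision any unbiased estimator
could achieve?*

## The model

For camera pixel $i$ (center $x_i, y_i$) and exposure $k$ (pattern/pinhole at
$x_{p,k}, y_{p,k}$), the expected photon count is

$$
\mu_{i,k} = A\,\theta_I\,P(\theta_x - x_{p,k},\,\theta_y - y_{p,k})\,
            H(\theta_x, \theta_y, x_i, y_i) + A\,\theta_b\,B_{i,k},
$$

with parameters $\theta = (\theta_x, \theta_y, \theta_I, \theta_b)$: emitter
position (nm), expected signal photons under maximum illumination, and
expected background photons per pixel. Here

* $P \in [0,1]$ — peak-normalized illumination pattern (Gaussian
  $e^{-r^2/2\sigma_\mathrm{illum}^2}$ or donut
  $(r^2/2\sigma^2)e^{1-r^2/2\sigma^2}$),
* $H$ — emission PSF mass passing the circular pinhole and landing in pixel
  $i$ (closed-form error-function integrals for interior pixels, midpoint
  quadrature on a pinhole mesh where the aperture cuts pixels),
* $B_{i,k}$ — effective background: the illumination pattern convolved with
  the emission PSF, integrated over pixel ∩ pinhole (or, in the
  pattern-independent variant, the geometric pixel–pinhole overlap),
* $A$ — photon-budget normalization: $1/\sum_k P_k$ when the full budget is
  exhausted across the sequence, $1/K$ at fixed per-pattern power.

Counts are Poisson, so the Fisher information is
$I_{uv} = \sum_{i,k} \mu_{i,k}^{-1}\,\partial_u \mu_{i,k}\,\partial_v \mu_{i,k}$
and the Cramér–Rao lower bound $I^{-1}(\theta)$ gives the minimum achievable
precisions $\sigma_x, \sigma_y$. Widefield SMLM ($P \equiv 1$, no pinhole)
and localization on (Fourier-reweighted) image-scanning-microscopy
reconstructions (PSF width ÷ √2 or ÷ 2) serve as baselines, and a
maximum-likelihood estimator with analytic gradients validates that the bound
is attained in simulation.

## Worked example

The optimal two-pattern configuration: two Gaussian patterns separated by
$s = 4\sigma_\mathrm{PSF}$ = 373.2 nm along x, pinhole radius
$3\sigma_\mathrm{PSF}$, focused on the emitter (2000 signal photons, 8
background photons/pixel, 65 nm pixels, 10×10 ROI):

```bash
spinflux crlb --family pair_x --spacing 373.2 --pinhole-radius 279.9
```

prints (abridged):

```
sigma_x_nm : 0.9816
sigma_y_nm : 3.1165
improvement_x : 2.621
improvement_y : 0.8255
smlm_sigma_x_nm : 2.5728
collected_signal : 1571.1
blocked_signal : 428.9
mean_background_per_pixel : 7.74
```

Reading: sharing the same 2000-photon budget between two offset patterns
improves the x-precision 2.62-fold over widefield SMLM (0.98 nm vs 2.57 nm),
at the cost of y-precision (both patterns lie on the x-axis, so they add no
y-information) and of 429 expected signal photons blocked by the disk; the
patterned, pinhole-windowed background amounts to 7.74 photons per pixel over
the sequence, slightly below the widefield 8.

The same library calls are available in Python:

```python
from spinflux import ConfigurationSpec, build_configuration, crlb
from spinflux.configurations import default_emitter, default_optical_config

config, emitter = default_optical_config(), default_emitter()
seq = build_configuration(ConfigurationSpec("pair_x", spacing=373.2, pinhole_radius=279.9))
print(crlb(emitter, seq, config).sigma_x)   # 0.9816 nm
```

`spinflux table1` summarizes the maximal x-improvement of every standard
variant (ISM 1.48, Fourier-ISM 2.10; one/two/three Gaussian patterns 1.17 /
2.62 / 1.94; four donuts 3.59); `spinflux scan`, `spinflux map` and
`spinflux converge` produce CSV sweep tables, and `spinflux simulate` writes
Poisson-sampled measurement stacks as multi-page TIFF with a JSON sidecar.

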