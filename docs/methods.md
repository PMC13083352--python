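# Methods

## Model

A multiprimary stimulator modulates each of its 3–5 primaries sinusoidally
around a mean luminance setting.  Under the principle of univariance, the
excitation of a photoreceptor class is a single number per instant — the
fundamental-weighted integral of the retinal irradiance — so the Michelson
contrast of class *p*'s excitation is a *linear* function of the per-primary
luminance contrasts:

    C_p = Σ_j w_pj c_j,   w_pj = a_pj / Σ_k a_pk,
    a_pj = Σ_λ R_p(λ) E_j(λ;L_j) Δλ,

where E_j(λ;L_j) is primary *j*'s emission spectrum scaled to its mean
luminance L_j and R_p is the corneal fundamental of class *p*.  Silent
substitution is the linear solve c = W⁻¹C with C_p = 0 for the silenced
classes.  Key consequences, all enforced as tested invariants:

- each photoreceptor row of W sums to 1, so W is invariant to any positive
  rescaling of a fundamental and to a common scale factor on all mean
  luminances;
- solutions are proportional to the request, so a stimulus can be rescaled
  after the fact ("maximize": divide by max|c_j| so the limiting primary
  sits at exactly 100% contrast);
- a device with n primaries controls exactly n classes.  The controlled
  sets are fixed as 3 → (L, M, S), 4 → (+rod), 5 → (+melanopsin); classes
  outside the set are only *evaluated* (forward product of the full 5-row
  matrix), never silenced.

Assumptions inherited from this model: primary spectra are
luminance-invariant in shape, nominal luminance equals actual luminance
(no gamma/threshold/saturation modelling), and the stimulus is a periodic
modulation around a fixed mean field.  Excitation-modulation contrast is
what is computed; photoreceptor *response* additionally depends on
adaptation and temporal frequency and is out of scope.

## Parameters and defaults

| Parameter | Default | Meaning |
|---|---|---|
| wavelength grid | 390–780 nm, 2 nm | canonical grid; all spectra resampled onto it on load |
| K_m | 683 lm/W | luminous efficacy constant converting V(λ)-weighted radiance to cd/m² |
| MPOD | 0.3 | macular pigment peak optical density embedded in the baseline fundamentals |
| lens age | 40 years | baseline of the lens density model |
| λ-max shifts | 0 nm (|δ| ≤ 20) | L/M fundamental translation for opsin polymorphisms |
| condition limit | 1e8 | controlled A-matrix blocks above this are rejected as spectrally degenerate |
| resolution warning | 0.5% | advisory threshold for very small primary contrasts |
| forward tolerance | 1e-10 | max residual allowed when verifying W·c against the request |

Observer modifications are multiplicative density corrections,
`R′ = R·10^(−ΔD(λ))`.  The macular correction scales a peak-normalized
density template by (target − 0.3).  The lens density model is
`TL1(λ)·(1 + 0.02·(A − 32)) + TL2(λ)` for ages 20–60 and
`TL1(λ)·(1.56 + 0.0667·(A − 60)) + TL2(λ)` above 60; the branches agree at
A = 60 and the model is undefined below age 20 (an error).  Because both
corrections are pointwise positive multiplications they commute, and
because contrasts are ratio quantities, any residual global scale on a
fundamental cancels — which is why modified fundamentals are not
re-normalized to unit peak.

Design choices made where the procedure was genuinely open:

- **Integration rule.** Left-Riemann sum `value·Δλ` on the uniform grid,
  the natural convention for tabulated spectra; the test oracles use the
  identical rule, so integral checks are exact rather than
  quadrature-limited.
- **Matrix orientation.** The contrast relation forces normalization over
  the primary index for each photoreceptor; with photoreceptor rows and
  primary columns that means row sums of 1.  The relation `C = W·c` is the
  contract; the layout is internal.
- **λ-max shifts at the corneal level.** The fundamental is translated
  directly rather than deconvolved to the photopigment template and
  rebuilt.  For shifts of a few nm the effect on contrast ratios is the
  same to first order; documented as an approximation.
- **Pre-receptoral corrections apply to all five classes**, including rods
  and melanopsin — the lens and macular pigment filter all light reaching
  the retina.
- **Luminance envelope with |c_j|**: min/max luminances are
  `L_j(1 ∓ |c_j|)`, so the reported envelope does not depend on modulation
  phase and counterphase stimuli report the same limits.
- **Waveform**: sine with phase 0 at t = 0; negative contrast is exact
  counterphase.  Square waves would use the same envelope and are a
  natural extension point, not implemented.
- **Contrast units**: fractions internally, percent in tables and exports.

## Synthetic data

`substim.synth` generates everything tests need, with no measured spectra:

- **LEDs** are AUC-normalized Gaussians (peak, FWHM).  The default study
  device uses blue/green/amber/red at 460/520/590/640 nm, FWHM 20 nm, mean
  luminances 4/40/100/80 cd/m² with ranges [0, 2L] — the
  short-wavelengths-low / long-wavelengths-high luminance pattern that
  yields feasible rod and cone contrasts on real Ganzfeld stimulators, for
  a total field luminance of 224 cd/m².
- **Fundamentals** are Gaussian templates (FWHM 90 nm, unit peak) at
  440/480/500/530/560 nm for S/mel/rod/M/L, i.e. nomogram-style stand-ins
  with realistic peak ordering and overlap.  V(λ) peaks at 555 nm; the
  synthetic CMFs mimic the bimodal x̄ and are scaled to equal area so an
  equal-energy spectrum maps to x = y = 1/3.
- **Density templates**: Gaussian macular absorbance peaking (OD 1) at
  460 nm; two exponentially decaying lens components.
- **Randomized devices** jitter evenly spaced peaks over 440–650 nm,
  keeping primaries well separated and A-matrices well conditioned.

What the synthetic observer does *not* reproduce: the real fundamentals'
asymmetric long-wavelength tails, their sub-percent tabulation structure,
and the exact overlap geometry of L and M.  Passing tests therefore
demonstrate the correctness of the calculation machinery (normalization,
inversion, silence, feasibility, modification algebra) — not the numeric
contrast values any particular physical device would obtain, which require
measured primary spectra and the real CVRL tables
(`scripts/build_observer_bundle.py`).

## Numerics and degenerate inputs

The linear solve uses LAPACK via `numpy.linalg.solve`, followed by a
forward check `max|W·c − C| ≤ 1e-10`.  A controlled block with condition
number above 1e8 is rejected before solving, with the most collinear
primary pair named in the error; pairwise near-identical emission spectra
are rejected at device construction.  All-zero spectra cannot be
AUC-normalized and have no chromaticity (errors); zero mean luminance is
rejected because it silently reduces the primary count.  Resampling is
linear interpolation with zero outside the source support; an import whose
wavelength range misses the canonical grid entirely is an error.  The
independent test oracle recomputes excitations with per-sample Python
loops and solves by hand-written Gaussian elimination with partial
pivoting (pivot tolerance 1e-12), sharing no numerical machinery with the
main path; agreement is required to 1e-9.

The test suite and the acceptance run use 100 randomized
silent-substitution fixtures per property; all problem sizes (196-point
grid, ≤5 primaries) run in about a second.

## Limitations

- Individual calibration (heterochromatic flicker photometry) is not
  supported: observer modification estimates errors, it does not correct
  the stimulus.
- No hardware driving, gamma correction or luminance-optimization search;
  mean luminances are user choices.
- Excel exports round-trip through the documented schema but are not
  byte-identical across writes (container metadata); JSON exports are.
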