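# substim

Silent-substitution stimulus design for multiprimary visual stimulators.

Silent substitution exchanges lights of different spectral composition so
that the excitation of selected photoreceptor classes stays constant while
a target class is modulated.  It is the standard way to record
photoreceptor-directed responses — e.g. rod- or cone-isolating full-field
ERGs — with an LED stimulator that has 3–5 spectrally distinct primaries.
`substim` computes the per-primary Michelson contrasts that realize a
desired vector of photoreceptor contrasts, checks whether the stimulus is
technically feasible on the hardware, and estimates the residual contrasts
an individual observer (different macular pigment density, lens age, or
L/M-cone λ-max) would actually experience.

## The calculation

Each primary *j* has an emission spectrum normalized to unit area
(∫E_j(λ)dλ = 1 W·m⁻²·sr⁻¹) and is scaled to its mean luminance L_j using
the photopic luminous efficiency function (K_m = 683 lm/W).  The excitation
of photoreceptor class *p* (fundamental R_p) by primary *j* at the mean
setting is

    a_pj = Σ_λ R_p(λ) · E_j(λ) · Δλ.

When every primary is modulated sinusoidally with Michelson contrast c_j
around its mean, class *p* sees the excitation contrast

    C_p = Σ_j w_pj · c_j,   w_pj = a_pj / Σ_k a_pk,

so the normalized matrix **W** maps primary contrasts to photoreceptor
contrasts.  A device with *n* primaries controls *n* classes (3 → L,M,S;
4 → +rods; 5 → +melanopsin); the solver inverts the square controlled
block, **c** = **W**⁻¹**C**, with C_p = 0 for every silenced class.
Because the relation is linear, any solution can be rescaled so the most
modulated primary sits at exactly 100% contrast ("maximize").  Validation
forward-multiplies the full five-row matrix — optionally rebuilt for
modified fundamentals — to report achieved contrasts, including the
intrusion into classes a 3- or 4-primary device cannot control.

## Worked example

The packaged demo builds a synthetic 4-primary device
(blue/green/amber/red Gaussian LEDs at 460/520/590/640 nm, mean luminances
4/40/100/80 cd/m²), solves a rod-isolating stimulus and maximizes it:

```sh
substim demo --out demo/
```

```
primary  Contrast (%)  MinLuminance (cd/m^2)  MaxLuminance (cd/m^2)  feasible
   blue     -7.872698               3.685092               4.314908      True
  green     45.618107              21.752757              58.247243      True
  amber    -80.255289              19.744711             180.255289      True
    red    100.000000               0.000000             160.000000      True
photoreceptor  Contrast (%)  controlled
            L  0.000000e+00        True
            M -4.163336e-15        True
            S  2.564816e-16        True
          rod  1.530047e+01        True
          mel  1.329727e+01       False
```

Reading the tables: the red primary limits the stimulus (it reaches 100%
contrast), blue and amber run in counterphase (negative contrasts), and
each primary's luminance envelope stays inside its configured range, so
the stimulus is feasible.  The achieved contrasts confirm silence of L-,
M- and S-cones to numerical precision while rods see 15.3% contrast;
melanopsin is not controlled by a 4-primary device and experiences a
13.3% intrusion — exactly the kind of residual the validation step is
there to expose.

The demo directory also contains the device spectra (`demo_spectra.csv`),
a device config (`demo_device.json`), an observer bundle, and the solved
stimulus as JSON and Excel.  The same calculation from the library:

```python
from substim import (ContrastRequest, build_a_matrix, solve_contrasts,
                     maximize, check_feasibility, achieved_contrasts)
from substim.synth import default_device, synthetic_observer

device, observer = default_device(), synthetic_observer()
amatrix = build_a_matrix(device, observer)
c = solve_contrasts(amatrix, ContrastRequest({"L": 0, "M": 0, "S": 0, "rod": 0.3}))
c, factor = maximize(c)
solution = check_feasibility(c, device, scale_applied=factor)
report = achieved_contrasts(device, c, observer)
```

Other CLI entry points: `substim solve` (your own spectra file, luminances
and contrast request), `substim validate` (re-evaluate a solved stimulus
under modified fundamentals, e.g. `--mpod 0.5 --lens-age 60`), and
`substim spectra` (inspect/normalize an emission-spectra file).  Exit
codes: 0 feasible, 2 computed-but-infeasible, 1 error.

## Observer data

All tests and the demo run on the synthetic observer in `substim.synth`.
To work with the real standard-observer tables (Stockman–Sharpe 10°
fundamentals, scotopic V′(λ), melanopic fundamental, CIE 1964 CMFs,
macular/lens density templates), regenerate a bundle from the public CVRL
downloads with `scripts/build_observer_bundle.py --out observer_bundle/`
and pass `--observer observer_bundle/` to the CLI.

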