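# wakekin

Tools for studying how undulatory swimmers (e.g. rainbow trout) hold
station in the wakes of multi-cylinder arrays: synthetic vortex-street
velocity fields and swimmer landmark tracks with recorded ground truth,
wake periodicity metrics, surrogate-based optimization of cylinder
spacing, midline kinematics extraction from pose-tracking exports, and
the factorial statistics used to compare hydrodynamic treatments.

## Who this is for

Biomechanics and organismal-hydrodynamics researchers who work with
cylinder-array wakes and pose-tracked swimming video, and who need a
tested, reproducible version of the standard computational chain —
without a CFD solver or live animals in the loop. Every stage consumes
and produces plain-text formats (long-format velocity CSVs, the
DeepLabCut three-header CSV dialect, tidy kinematics tables).

## The science in brief

* **Wake characterization.** The shedding frequency behind a cylinder
  of diameter *D* in flow *U* is governed by the Strouhal number
  St = *f·D/U*. In a tank of width *W* the nominal speed *U_f* is
  blockage-corrected by continuity, *U = W·U_f/(W − D)*. Wake
  *periodicity* is scored by the L-kurtosis τ₄ = l₄/l₂ (fourth L-moment
  ratio, Hosking's unbiased estimators) of the FFT amplitude spectrum of
  the cross-stream velocity *U_y* at a probe: a coherent vortex street
  concentrates spectral mass in one line (τ₄ → 1), broadband turbulence
  does not (τ₄ ≈ 0.1). Turbulent kinetic energy is the time mean of
  ½(u′ₓ² + u′_y²).
* **Spacing optimization.** Cylinder gap ratios *Lx/D*, *Ly/D* are
  sampled by Latin hypercube, screened to the co-shedding regime
  (gap ratio > 1.8), scored by τ₄, interpolated with a thin-plate RBF
  surrogate and maximized under the regime constraint.
* **Swimming kinematics.** From 14 tracked body landmarks per frame the
  package reconstructs equal-arc-length midlines, then extracts
  tail-beat frequency (extremum timing), body wavelength (crest phase
  speed along the midline divided by frequency) and lateral amplitudes
  at the snout, center of mass and tail tip, grouped into four-beat
  sequences.
* **Statistics.** Per-cell mean ± s.e.m., two-way ANOVA
  (treatment × speed, Type II SS, log-transformed amplitudes) with
  Benjamini–Hochberg FDR across responses, Tukey(-Kramer) HSD post
  hocs, and a left-tailed one-sample t-test of tail-beat frequency
  against the predicted vortex shedding frequency.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

Generate a staggered (Kármán-like) and a symmetric parallel vortex
street with identical shedding parameters and noise, and score them:

```bash
python examples/01_wake_and_metrics.py
```

```
probe at x=0.110 m downstream, y=0.000 m (centerline)

staggered:
  dominant frequency   10.00 Hz (truth 10.0 Hz)
  wake wavelength       5.08 cm (truth 5.0 cm)
  L-kurtosis (tau4)    0.644
  TKE                  0.00420 m^2/s^2

symmetric_parallel:
  ...
  L-kurtosis (tau4)    0.087

KVS array at 74 cm/s: corrected U = 0.8009 m/s, predicted shedding f = 8.85 Hz
PVS array at 74 cm/s: corrected U = 0.8009 m/s, predicted shedding f = 9.69 Hz
```

The staggered street shows the imposed 10 Hz shedding line and a
spatial wavelength of Uc/f = 5 cm; its periodicity score (0.64) dwarfs
the symmetric street's (0.09), whose cross-stream velocity cancels on
the centerline. The last two lines run the prediction chain used to
compare fish tail beats with wake vortices: at the top experimental
speed the corrected flow is 0.8009 m/s and the two arrays are predicted
to shed at 8.85 and 9.69 Hz.

The other examples follow the same pattern:

* `examples/02_spacing_optimization.py` — Latin-hypercube sampling +
  RBF surrogate recovering a known periodicity peak at
  (Lx/D, Ly/D) = (2.1, 3.0) to within ~0.05;
* `examples/03_swimmer_kinematics.py` — full landmark→kinematics chain
  on a noisy synthetic swimmer (recovers f = 3 Hz, λ = 1.1 L and the
  amplitude envelope to a few percent, with the QC report);
* `examples/04_study_statistics.py` — ANOVA/FDR/Tukey/t-test stage on a
  synthetic replica of the 3-treatment × 3-speed study.

A thin CLI wraps the same functions
(`wakekin predict-shedding --st 0.21 --d 0.019 --uf 0.74 --w 0.25`,
`wakekin kinematics ...`, `wakekin run-all --out artifacts/`); run
`wakekin --help` for the stage list.

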