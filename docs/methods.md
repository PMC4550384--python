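# Methods

This note records the models implemented in `rfivm`, their assumptions,
the defaults that matter, and what the synthetic test bed can and cannot
show about real intravital recordings.

## Dielectric heating and temperature dynamics

A lossy dielectric in a time-varying field at angular frequency
ω = 2πf converts field energy to heat at the specific-absorption rate

    HR = ω ε0 ε″ |E|² / (2 ρ c_p)      [K/s]

(`heating_rate`). The literature sometimes writes this relation without
the explicit ω factor, folding the frequency into ε″(ω); that compact
form is dimensionally short by 1/s when ε″ is read as the plain loss
factor. Both readings are implemented behind `include_omega`
(default `True`, the dimensionally consistent form); the rate is exactly
quadratic in |E| and linear in ε″ in either case. Defaults describe a
water-like tumor at 13.56 MHz: ε″ = 70, ρ = 1000 kg/m³,
c_p = 4186 J/(kg K), nominal full-power field 15 kV/m at the TX head.

The field between the transmitting and receiving heads is reconstructed
from voltage grids as E = −∇V (`efield_from_voltage`): central
differences on interior nodes, one-sided differences at the boundary —
the boundary rows are first-order accurate, which is the price of not
extrapolating beyond measured nodes.

Temperature is a single lumped compartment,

    dT/dt = HR · P(t)/P_max − h (T − T_ambient),

integrated by explicit Euler with fixed step (default dt = 0.1 s; a
tenfold-finer reference integration in the test suite bounds the step
error below 0.05 °C on pulsed schedules). The cooling law is a modelling
choice — no spatial bioheat equation is solved — with Newtonian
relaxation toward the ~30 °C of an air-conditioned operating room and a
free coefficient h (default 0.005 1/s, giving minutes-scale cool-downs).
Heating scales with commanded power as P/P_max because power, not field,
is the controlled quantity.

The set-point controller (`setpoint_controller`) emulates pulsed
hyperthermia protocols: drive at `on_power` (default 90 W of a 200 W
amplifier) until the reference probe (probe 1, the one nearest the TX
head) reaches the active set-point, off until **all** probes re-enter
the resume band, then re-arm with the next, lower set-point. Defaults:
set-points (45, 43, 41) °C, resume band (29, 31) °C. Termination is at
the last set-point; a step cap converts a protocol that cannot complete
(e.g. ambient above the resume band) into `ControllerStalledError`
rather than a hang. Peak overshoot is bounded by one Euler step of
heating. Field fall-off with distance from the TX head is represented
only through per-probe field magnitudes; no antenna model is fitted.

`compare_traces` aligns two traces by linear interpolation onto the
union of their sample times over the overlapping interval and reports
mean/max absolute deviation — the statistic used to compare contact
probes with surface (IR-camera-style) readings.

## Synthetic scene generation

The generator produces the statistical structure the quantification
assumes, not microscope physics:

* **Geometry.** The tumor is an ellipse (semi-axes 0.78/0.66 of the half
  frame) with a smooth multiplicative texture on the constitutive
  channel. Vessels are random-walk centerlines entering from the tumor
  rim (step 6 px, angular diffusion set by `tortuosity`), rasterised as
  tubes of radius 1 px and grown one vessel at a time until they cover
  8% of the tumor area — the incremental growth keeps the realised
  fraction within a few percent of the target.
* **Kinetics.** Intravascular concentration decays as
  dC/dt = −(clearance + k(T)) C using the exact exponential factor per
  sub-step (default 1 s); the extravasated share k/(clearance+k) of each
  decrement is deposited uniformly on the abluminal pixels of perfused
  vessels and spread by a Gaussian diffusion kernel (D = 2 px²/s,
  reflecting boundaries). Reflecting boundaries and exact-exponential
  transfer make the vascular + tissue + cleared budget close to
  floating-point round-off (observed ~1e-15 relative; the invariant is
  asserted at 1e-6). Extravasated tracer is never resorbed, so tissue
  accumulation is monotone — the mechanism behind perfusion continuing
  to rise after the power is switched off.
* **Permeability curve.** k(T) is piecewise: k₀ below 39 °C, α·k₀ on
  39–41 °C (a deliberate step at the lower band edge — the onset of the
  mild-hyperthermia response is treated as a regime switch, not a smooth
  dose curve), linear decline above 41 °C, zero at/above the 44 °C
  shutdown (vessel coagulation). All shape parameters are exposed in
  `TracerKinetics`.
* **Acquisition.** Photon noise is scaled-Poisson (variance =
  photon_scale × intensity; default gain 1e-3 intensity units/photon),
  read noise Gaussian (σ = 4e-3), and respiration jitter a rigid
  sinusoidal translation. Albumin and dextran channels share kinetics by
  default; per-tracer kinetics are representable but there is no
  quantitative basis for distinct defaults.

### Study presets

`treated_control_presets()` pins two scenarios at 256×256 px:

* **treated** — 48 frames / 10 s; temperature ramps from 37 °C to a
  40.5 °C plateau (τ = 40 s) 30 s into the session, holds through a
  4.5-minute exposure window, then relaxes back (τ = 60 s) while imaging
  continues; kinetics k₀ = 1.25e-4 1/s, α = 10, clearance 2e-4 1/s.
* **control** — 60 frames / 30 s over 30 minutes at 37 °C throughout,
  k₀ = 2e-6 1/s: the near-impermeable perfusion barrier of an untreated
  tumor.

The kinetic constants were calibrated once so that the paired-preset
end-point contrast reproduces the enhancement the pipeline is designed
to detect — a ≈5× positive-area-fraction ratio and a ≈2× RAIF — and then
frozen; they are deliberately not free knobs of the acceptance runs.
Treated/control pairs sharing a seed share vessel geometry (a paired
design), which removes geometric variance from between-arm ratios.

### What the generator does not emulate

No optics (PSF, confocal sectioning, depth attenuation), no hemodynamics
(RBC flow, flow-limited delivery), no deformable tissue motion, no
photobleaching, no vessel-morphology change over time. Consequently,
passing tests demonstrate that the quantification is correct *given*
threshold-separable channels and rigid motion; they do not certify
performance on recordings dominated by scattering, bleaching or
non-rigid drift.

## Quantification pipeline

Thresholds are global Otsu (`global_threshold`), computed once on a
baseline frame and reused across the time-lapse so temporal trends are
not confounded by adaptive thresholds. The returned cutoff is centred
between the two intensity classes (maximal margin); the partition is
identical to the histogram argmax, and an exhaustive between-class-
variance search serves as the oracle in tests. A constant image has no
Otsu threshold: the constant is returned with a warning.

The tumor mask thresholds the constitutive channel and applies a
dilate-then-erode closing (disc, radius 2 px default) to fill holes
smaller than the element and smooth edges; the vasculature mask applies
the same recipe to the tracer channel's baseline frame, when signal is
purely intravascular. Erosion treats out-of-frame pixels as foreground
so edge-touching regions are not eaten from outside the field of view.
The extravascular region is exact set arithmetic, `tumor AND NOT
vessels`.

Statistics: PAF counts pixels strictly above a background threshold over
the whole frame (the verbatim definition; a region-restricted variant is
a matter of passing a cropped image). For comparisons the background
threshold is computed once — median + 4 robust SDs of sub-vessel-cutoff
baseline pixels (`default_paf_threshold`) — and shared across arms,
since a per-image threshold would absorb part of the effect being
measured. RTDI divides per-frame region means by a baseline-window mean;
RAIF is the end-window/start-window ratio with windows defaulting to the
first/last 10% of frames; replicate aggregation reports mean ± SD
(ddof 1). Saturated pixels (integer dtype max) are excluded from region
means. Jitter correction estimates per-frame translation against a
reference frame by subpixel phase cross-correlation (upsampling factor
20) on the static tumor channel and applies the inverse shift to all
channels; featureless frames degrade to an identity transform with a
warning.

## Numerical and design choices

* Explicit Euler everywhere a time integration occurs; accuracy guarded
  by closed forms and fine-step references in tests rather than by
  adaptive stepping.
* Coordinates are row-major, 0-based pixel indices; masks are
  pixel-centred booleans.
* Controller and kinetics sub-stepping default to 0.1 s / 1 s; the
  preset problem sizes (256×256, 48- and 60-frame sessions, five
  replicate seeds) keep a full acceptance run under a minute on one
  core while leaving ≥10⁴-pixel regions for noise statistics.
* All stochastic entry points require a seed or `numpy` Generator;
  presets are bit-for-bit reproducible under a fixed seed.

## Known limitations

The lumped thermal model cannot express spatial temperature gradients
across the tumor, so per-probe differences are qualitative (field
fall-off only). The permeability step at 39 °C is a modelling idealised
switch; real dose-response is smooth. PAF depends on the chosen
background threshold; the default estimator assumes the baseline frame
contains a representative background population. The treated:control
accumulation ratio is defined on tracer *within* the tumor region —
tracer that diffuses beyond the tumor during long control sessions is
deliberately outside the reported quantity.
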