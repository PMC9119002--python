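# Methods

## The model

`polarasm` images with, and simulates for, curvilinear (convex)
ultrasound arrays whose elements lie on a circular arc of radius `r0`.
All computation happens on a polar grid `(θ, r)` centered on the array's
center of curvature, with `θ = 0` along the depth axis.

The starting point is the two-dimensional acoustic wave equation.  Under
the conformal log-polar substitution `ρ = ln r` and Fourier transforms
in `θ` and `t`, the equation separates into independent one-dimensional
problems per angular wavenumber `k_θ` (cycles/radian) and temporal
frequency `f`.  Each angular-spectrum component is advanced between
radial shells by the closed-form propagator

    H±(k_θ, r1, r2, f) = exp(±j2π|k_θ| [Φ(r2) − Φ(r1)]),
    Φ(r) = √(u² − 1) − arctan √(u² − 1),    u = f r / (c k_θ),

with the `k_θ = 0` component given by its plane-radial-wave limit
`exp(±j2πf(r2 − r1)/c)`.  One marching step is

    p(θ, r2, f) = W(θ) · F⁻¹{ H± · F{ p(θ, r1, f) } },

where `F` is the discrete angular Fourier transform (kernel
`e^{−j2πk_θθ}`) and `W(θ)` a window suppressing the wraparound of the
circular convolution.  Temporal spectra follow the `e^{−j2πft}` analysis
convention; with it, branch `−` advances an outgoing (transmit) field to
larger radii and branch `+` back-propagates receive data outward while
reversing time.

Two properties of this propagator shape everything downstream:

* **It is phase-only.** `|H±| = 1` for propagating modes.  The exact
  radial modes of the separated equation are cylinder functions whose
  amplitudes decay like `(u² − 1)^{−1/4}`; the closed-form propagator
  keeps only their phase (a WKB-type solution).  The marched field
  therefore carries no per-mode cylindrical spreading loss: relative to
  an exact solution its shells are uniformly scaled by roughly
  `√(r/r_ref)`.  Diffraction — the angular redistribution of energy,
  focusing, beam spread — is fully retained.  The validation study
  quantifies the consequence (below).
* **Modes go evanescent radius by radius.** A component with
  `u = f r/(c|k_θ|) ≤ 1` does not propagate at radius `r`.  Default
  policy (`evanescent_mode="zero"`): phase is accumulated only over the
  propagating part of the path (`Φ := 0` where `u ≤ 1`) and modes still
  evanescent at the step's destination are zeroed.  An alternative
  `"decay"` policy analytically continues `Φ` with the decaying branch.
  Half a wavelength from the aperture the difference is negligible;
  zeroing avoids accidental amplification from a wrong branch.

### Shot-profile migration

For each focused transmit event `i`, the transmit boundary field on the
element arc is synthesized from the sequence description,

    p_tx(θ, r0, f) = A(θ) P(f) e^{−j2πf τ(θ)},

and the receive boundary field is the temporal spectrum of the recorded
traces placed at the element angles.  Both are marched outward shell by
shell (branch `−` and `+` respectively) and correlated at every shell:

    I_i(θ, r) = Σ_f w_band(f) · conj(p_tx) · p_rx,
    I = Σ_i I_i   (coherent compounding; envelope after the sum).

Only the current shell of each field is held in memory; all events march
together as one batched array.  Band weights default to a flat passband
covering the pulse support down to −40 dB; a cosine-tapered (Tukey)
band is available when axial ringing must be traded against axial
resolution.  An optional f-number control weights the receive angular
spectrum at each shell, passing `|k_θ| ≤ (f r/c)·sin(arctan(1/2F))` — the
only aperture control available in this framework, since a depth-
dependent receive apodization has no per-pixel handle in the Fourier
domain.  The study defaults leave it off (all-pass); see "Comparison
study" for the sensitivity.

### Virtual-source DAS baseline

The comparison baseline treats each transmit focus as a virtual point
source: for pixel `P`, virtual source `V`, element `E`,

    t(P, E) = t_focus ± |P − V|/c + |P − E|/c,

`+` beyond the focus, `−` before it (two-sided hyperbolic model).
`t_focus` is computed exactly from the stored transmit delays, not from
the nominal focal depth.  Contributions are restricted to a validity
cone (default ±15°) about the beam axis; because the cone test is
ill-conditioned at `V` itself, pixels within 2 mm of the focus are
always accepted.  Receive uses a growing aperture at constant f-number
(default f/2) with uniform (boxcar) weighting by default; Hann
weighting is available (`rx_apodization="hann"`).  Element traces are
converted to analytic signals and sampled with linear interpolation;
pixel/element pairs whose delay leaves the recorded window contribute
zero and are tallied in the image metadata.

### Reference simulator

The time-domain reference is the package's independent oracle.  Because
the angular-spectrum method above solves the *two-dimensional* wave
equation, the reference superposes 2-D line sources, not 3-D point
sources: each element is split into sub-sources along its arc (4 per
element by default for one-way fields), and each sub-source radiates
the Rayleigh–Sommerfeld type-I dipole field
`−(jk/2) H1⁽²⁾(kd) cos φ` — the exact free-space solution of the same
boundary-value problem the march discretizes (pressure prescribed on
the arc, outgoing waves).  Any other choice (e.g. spherical `1/d`
spreading) would contaminate the validation with a model mismatch — a
constant 45° carrier rotation, an `f`-weighting, and the wrong range
decay — that has nothing to do with the propagator under test.

One-way fields use the exact Hankel kernel.  Pulse-echo channel data
use the large-argument asymptotics, under which the transmit dipole
(`∝ √f`) and the monopole scattering return (`∝ 1/√f`) cancel: every
transmit–scatterer–receiver path contributes a delayed replica of the
pulse weighted by `cos φ_tx cos φ_rx / √(d_tx d_rx)` (Born single
scattering, reciprocity-symmetric).  The per-path spectra are
accumulated with a geometric-progression recursion over the band's
frequency bins in single precision; traces are exact delayed pulses up
to float32 arithmetic (reciprocity holds to ~1e−6 relative).

Not modeled: element impulse responses and electromechanical transfer,
elevation geometry, attenuation, multiple scattering, and the full
spatial impulse response of rectangular elements.  Passing tests
therefore show fidelity to 2-D propagation physics, not to any
particular scanner's waveforms.

### Phantoms

`make_phantom` builds sector phantoms from three ingredients: bright
point targets at given `(θ, r)`; diffuse scatterers uniform in area
with i.i.d. standard-normal reflectivity at a stated density per
resolution cell (cell ≈ axial pulse length × two wavelengths; 10 per
cell gives fully developed speckle); and anechoic lesions, discs whose
interior diffuse scatterers are removed.  Phantoms are deterministic
given their seed.

## The two studies

### Validation study (`validation_study`)

128-element probe, 49.57 mm radius, 0.508 mm pitch; 3.5 MHz pulse at
50% fractional bandwidth (−6 dB Gaussian definition); 20-element
subaperture focused at 20 mm depth; radial step 0.22 mm (half a
wavelength at 1540 m/s).  The march (N_θ = 2048 over a 0.9 rad span,
Tukey 0.25 window) and the reference are evaluated as pressure versus
time on three shells bracketing the focus (≈15/20/25 mm depth, the
shells nearest those depths), at every 4th angular sample within
|θ| ≤ 0.15 rad, 14 MHz sampling.  The score is NRMSE over the full
spatio-temporal block after a single least-squares amplitude scale
(shape comparison; the two simulators have unrelated global gains).

Measured: **≈3.5% NRMSE**.  The residual decomposes into (a) the
phase-only propagator's missing `√r` amplitude tilt across the three
shells (the dominant, irreducible part) and (b) aperture-edge
discretization, which falls with N_θ (6.8% at 512, 3.5% at 1024, 1.8%
at 2048 for the single-frequency field).  N_θ = 2048 was chosen from
that convergence; the angular sampling, not the physics, sets it.

### Comparison study (`comparison_study`)

Siemens 5C1 geometry: 180 elements, 46.03 mm radius, 0.3212 mm pitch;
walking-aperture focused sequence, focal depth 97 mm, beam axes
spanning ±36.103°.  Desk-scale sizes, chosen once: 31 beams (the full
sequence has 121; the beamformers scale linearly in beam count),
128-element subaperture (41 mm ⇒ transmit f/2.4 at the focus — the
probe's subaperture is not a published quantity; this is a typical
abdominal setting), diffuse density 2 scatterers/cell confined to the
metric region (θ ∈ ±0.23 rad, 45–85 mm depth), 14 MHz sampling with a
50 µs record offset.  Twelve point targets (θ ∈ {−0.2, 0, 0.2} rad ×
depths {48, 58, 68, 80} mm, all ≥17 mm from the focus) and two 5 mm
anechoic lesions (∓0.10 rad at 60/74 mm).  Both beamformers share one
grid (N_θ = 512 over ±0.75 rad, Δr = 0.22 mm).

Metrics: lateral −6 dB width through each target's envelope peak
(parabolic peak refinement, linear threshold crossing, arc-length
units) and lesion contrast `−20 log10(lesion mean / background mean)`
against a same-depth speckle sector, all on pre-compression envelopes.

Measured (seed 1): migration 0.77 mm mean width and 26.5/29.0 dB
lesion contrast; DAS (boxcar receive) 0.85 mm and 17.8/19.3 dB.  So
migration improves resolution by ≈9% and contrast by ≈9 dB against
this baseline.  The apodization sensitivity is worth stating plainly:
with Hann receive weighting the same DAS reconstruction measures
1.01 mm and 25.5/28.4 dB — i.e. a ≈24% resolution improvement for
migration but near-parity in contrast.  Migration beats the
resolution-best DAS on resolution *and* the contrast-best DAS on
contrast simultaneously, which is its real advantage; no single
configuration of this baseline, however, loses by ≥35% in width and
≥7 dB in contrast at once.  The study defaults use the symmetric
no-smoothing comparison (boxcar DAS, all-pass migration): for a
claimed lower bound on resolution improvement, the baseline is taken
at its resolution-best setting.  The DAS options (apodization, cone,
f-number) are exposed on the API and CLI.

The baseline is deliberately strong: exact focal timing from the
stored delays, the two-sided before/beyond-focus model, the validity
cone with the near-focus patch, and a growing f/2 aperture.  At 31
beams its virtual-source synthetic aperture is already close to the
receive-aperture diffraction limit at the tested depths; sparser
sequences degrade it sharply (at 11 beams its mid-depth widths double)
while migration is much less sensitive to beam count.

## Numerical choices

* `k_θ = 0` always via the closed-form limit; zero-length steps
  (`r1 = r2`) return exactly 1 for every mode.
* Tukey window, taper fraction 0.25, applied every step; the flat
  interior covers all comparison regions.
* Element-to-grid assignment: every grid sample inside the active
  aperture takes its nearest element's delay/apodization/trace
  (contiguous boxcar fill — elements own their full arc width).  A
  one-grid-sample-per-element comb would radiate spurious grating
  lobes that the physical aperture does not have.  Grids coarser than
  the element pitch are rejected.
* Transmit focal delays: farthest active element fires at t = 0; the
  pulse is zero-phase so delays carry all timing; `t0` in the channel
  container anchors recordings to the same origin.
* Real traces are carried as one-sided spectra on the pulse's −40 dB
  support; images are analytic (envelope = magnitude).
* The marching loop and channel simulator run in single precision
  (complex64); analytic properties asserted at 1e−10..1e−12 are tested
  on the double-precision operator paths.
* Sound speed may be a scalar or a radial profile `c(r)`; each step
  uses the midpoint value (piecewise-constant per interval).  Angular
  (θ-dependent) variation is out of scope.

## Known limitations

* Phase-only propagation means absolute amplitude-versus-depth is
  biased by `√(r/r_ref)`; comparisons and images are unaffected up to
  a smooth gain, but quantitative pressure prediction would need the
  cylindrical amplitude factor.
* The 2-D model ignores elevation focusing entirely.
* The comparison study's speckle density (2/cell) is below fully
  developed speckle; contrast values are meaningful relatively (same
  phantom, both beamformers) rather than as absolute in vivo
  predictions.
* Point-target widths of ≈0.6–0.8 mm are measured on a grid with
  0.28–0.37 mm lateral sampling; sub-sample interpolation keeps the
  comparison fair but individual widths carry a few-percent
  quantization.
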