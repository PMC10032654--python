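# Methods

This note documents the models implemented in `thrustwake`, the default
parameters and why they were chosen, the numerical decisions that affect
results, and what the synthetic generators do and do not emulate.

## Foil kinematics

The foil is a rigid symmetric NACA 0012 section (12% thickness, closed
trailing edge, final polynomial coefficient −0.1036) driven in sway
`y_sway = a_sway sin(2πft)` and yaw `φ_yaw = a_yaw sin(2πft − π/2)` about a
pivot `r_te` ahead of the trailing edge.  Sign convention: positive yaw
deflects the trailing edge towards −y, so at the π/2 phase offset the sway
and yaw contributions to the trailing-edge excursion add constructively.
The trailing-edge position uses exact trigonometry
(`y_te = y_sway − r_te sin φ_yaw`); at a 20° yaw amplitude a small-angle
linearisation would already err by ≈2%.  Defaults (`a_sway` 1 cm, `a_yaw`
20°, `f` 2 Hz, `r_te` 48 mm, chord 67 mm, `U` 0.3 m/s, `ν` 1e−6 m²/s) give
a 3.86 cm ≈ 4 cm peak-to-peak excursion, St ≈ 0.267 and Re ≈ 2×10⁴.  Note
the analytic 12% thickness of a 67 mm chord is 8.04 mm; quoted hardware
thicknesses of ≈8.1 mm differ by <1% and the analytic definition is used.

## Synthetic swimmer

The midline is a traveling wave specified in arclength `s ∈ [0, 1]` (body
lengths):

    y(s, t) = A(s) sin(2πft − 2πs/λ + φ₀),    A(s) = a_head + (a_tail − a_head) s^q

with the axial coordinate obtained from `dx = √(dl² − dy²)`, which makes
the body exactly inextensible (marker arclengths are time-invariant to
numerical precision).  The construction requires `|dy/dl| < 1`; amplitudes
too large for the wavelength raise an error rather than folding the body.

Defaults emulate the trout trials being analysed: body length 0.19 m, nine
midline markers at 125 fps, 2 Hz beat, tail amplitude 7% BL with a head
amplitude a quarter of that, quadratic envelope (`q = 2`, a common
carangiform emulation), five-second trials.  Marker noise is i.i.d.
Gaussian per coordinate per frame; temporally correlated tracking error is
not modelled.

**What the generator does not capture.**  Real midlines have asymmetric
beats, frequency jitter, and 3-D projection error; the synthetic wave is
strictly periodic and planar.  Passing tests therefore demonstrate
correctness of the estimators, not robustness to every artefact of video
digitisation.

## Wake generator

The thrust wake is a Lamb–Oseen vortex street: vortices with tangential
speed `v_θ(r) = Γ/(2πr)(1 − exp(−r²/r_c²))` placed `λ_w` apart in x,
alternating between rows at `y = ±b/2` with alternating circulation signs,
superposed on a uniform free stream and advected at `U_c`.  With
`street_sign = +1` the upper row is counter-clockwise, which drives a
centreline jet (time-averaged centreline speed above `U_inf`, the
signature of a thrust wake); `−1` flips every sign and produces the
classical drag-wake deficit.  Vortices are recycled with spatial period
`n_vortices · λ_w` so the street is statistically stationary; the vortex
count must be even to preserve the sign alternation across the wrap.

Defaults: `U_inf` 0.3 m/s, `U_c = 1.1 U_inf` (the advection speed is not
measurable from the inputs the package consumes, so a mild jet excess is
assumed), `Γ` 0.02 m²/s, `r_c` 8 mm, `b` 30 mm, and `λ_w = U_c/f = 0.165 m`
so that the street pattern advances one inter-vortex spacing per flap
cycle of the 2 Hz foil: the shedding frequency `U_c/λ_w` then equals the
flapping frequency and wake-locked followers beat at the foil rate.  The
generator is a kinematic emulation — it satisfies neither Navier–Stokes
nor the exact vortex spacing of a real foil wake (which sheds two vortices
per cycle), but it reproduces the two features the analysis relies on:
alternating-sign cores passing at a known frequency and a centreline
mean-flow excess/deficit controlled by the street sign.

**In-line followers** place a swimmer's snout `d` metres downstream of the
foil trailing edge, beating at the shedding frequency with the body wave
delayed by `2πd/λ_w + const` — the phase relationship of a swimmer
synchronising to vortices advected at `U_c`.  By construction the
phase–distance relationship is exactly linear with slope `2π/λ_w`.

**Body blockage.**  Measured velocity fields around a real fish contain
the body's blockage of the oncoming flow, in particular the stagnation
region ahead of the snout; a free vortex street does not.
`add_body_blockage` superposes the classical half-body source flow (source
strength `Q = U_inf · width`, stagnation point at the snout) so that
head-pressure analyses on synthetic fields show the qualitative structure
seen in experiments: steady positive head pressure in uniform flow, and
pressure alternating between positive (stagnation) and negative (passing
vortex cores) phases in the thrust wake.

## Kinematic estimators

* **Resampling.**  An interpolating cubic spline (chord-length
  parametrised) through the markers of every `keyframe_stride`-th frame
  (default 6, emulating digitisation of every sixth video frame),
  evaluated at equal-arclength stations, with linear interpolation of
  station coordinates between keyframes.
* **Tail-beat frequency.**  Positive-going maxima of the lateral tail-tip
  displacement (heading removed via the principal axes), with a minimum
  prominence of 10% of the half-range, parabolic sub-frame refinement of
  peak times, and the frequency taken from the final three complete
  cycles.  The signal is low-pass filtered (zero-phase Butterworth at 3×
  the dominant spectral frequency) first; without it, tracking noise
  spawns spurious peaks.
* **Joint angles.**  N = 20 equal-arclength segments per frame; signed
  angles between consecutive segment vectors (N − 1 joints).
* **Phase lags.**  Circular cross-correlation over an integer number of
  cycles, lag restricted to `[0, T/2)`, parabolic peak interpolation, ties
  resolved to the smallest lag.  Signals are band-pass filtered
  (zero-phase, 0.6/T – 3/T) before correlating — phase-neutral for a
  traveling wave, and necessary for noisy digitisations.  An optional
  Savitzky–Golay smoother along the body (`spatial_window`, odd width)
  further suppresses marker noise; width 9 brings 1 mm marker noise within
  a few percent on ΔΦ, at the price of some edge distortion for waves
  shorter than ≈0.5 BL, so it is off by default.
* **Overall phase lag.**  Only N − 2 adjacent-joint lags are measurable.
  The default (`mode="full"`) completes the sum to full body coverage by
  extrapolating the mean adjacent lag at *each* end (equivalently scaling
  by N/(N−2)), so that a pure traveling wave of wavelength λ BL yields
  ΔΦ = 2π/λ exactly.  `"endpoint"` (a single extrapolated lag) and
  `"plain"` (the bare sum) are available; they under-cover the body by 1/N
  and 2/N respectively.
* **Amplitude and axes.**  PCA of the pooled point cloud defines forward
  (PC1) and lateral (PC2) axes; per-station amplitude is half the range of
  the lateral projection.  Within a trial the lateral sign follows the
  first tail-tip excursion; analyses comparing phases *across* trials
  instead fix the lateral sign in the laboratory frame, since a per-trial
  convention is only defined up to π.
* **Foil–fish phase difference.**  Both trailing-edge series are resampled
  onto the coarser common time base, cross-correlated circularly over
  whole cycles, and the delay expressed as `lag/T · 2π ∈ [0, 2π)`;
  a series over several distances is unwrapped in order of distance.

### Validation design and a known waveform property

Parameter-recovery tests compare recovered quantities against generator
ground truth.  Two facts shape the validation fixtures:

1. With an amplitude envelope growing towards the tail, the *curvature*
   wave genuinely lags the *displacement* wave near the head: the phase of
   the joint-angle fundamental is `−2πs/λ + χ(s)` with
   `χ = atan(2kA′/(k²A − A″))`, so the summed intersegmental lags
   under-run `2π/λ` by up to ≈10% for trout-like envelopes.  This is a
   property of the waveform, not an estimator error — ΔΦ equals `2π/λ`
   only for an unmodulated wave.  Recovery tests therefore use a uniform
   envelope, and a separate test characterises the envelope-induced bias.
2. Nine markers spatially alias waves around 0.5 BL (≈4.5 markers per
   wavelength through an interpolating spline).  Recovery tests use 41
   markers; the 9-marker emulation remains the generator default and its
   behaviour is tested at realistic wavelengths.

With those fixtures the estimators recover frequency within 0.1%, ΔΦ
within ~1% and tail amplitude within 0.1% across f ∈ {1, 2, 3} Hz and
λ ∈ {0.5, 0.8, 1.0, 1.3} BL, and stay within 2%/5% under 1 mm marker
noise.

## Pressure reconstruction

The pressure gradient on fluid nodes is the Eulerian material
acceleration, `∇p = −ρ(∂u/∂t + (u·∇)u) + μ∇²u`, with `∂u/∂t` between
consecutive frames (forward by default, central optional) and spatial
derivatives by central differences, falling back to one-sided stencils
next to domain edges and solid masks.  The viscous term defaults off: at
Re ≈ 2×10⁴–5×10⁴ its contribution is negligible against the inertial
terms, and the fluid viscosity of a given dataset is rarely known.

Integration marches straight paths inward from the domain boundary along
the eight principal grid directions (E, W, N, S and diagonals),
accumulating `∇p·dl` by the trapezoidal rule (`dl` is the cell diagonal on
diagonal families).  A path that meets a solid node is discarded for every
node beyond it.  Each fluid node takes the **median** of its surviving
candidates — corrupting a single family perturbs the median less than a
mean.  Nodes with no surviving path are marked undefined and filled from
the nearest defined neighbour; solid nodes never carry pressure, and
surface pressures are read from adjacent fluid nodes.

**Boundary reference.**  Paths initiate on the domain boundary.  The
default first integrates the *tangential* gradient around the domain edge
(closure error of the loop redistributed linearly; it vanishes for
conservative gradients) and fixes the gauge by zero mean boundary
pressure.  For a quiescent or uniform far field this coincides with
assuming zero pressure at the boundary, while remaining exact for
rotational oracle flows whose true boundary pressure varies — with a
literal zero-at-every-entry assumption the eight candidates of a node
would disagree by the spread of the true boundary pressures (≈50% of the
field range for solid-body rotation).  `boundary="zero"` provides the
literal assumption.  All pressures are relative; only differences are
meaningful.

On a 101×101 grid the reconstruction matches closed-form/ODE oracles to
≲0.1% of the pressure range for solid-body rotation and a steady
Lamb–Oseen vortex, and a uniform flow reconstructs to |p| < 1e−9·ρU².

**Head pressure** is the mean over a rectangle spanning 0.1 BL axially
from the snout along the `heading` argument and the body width laterally,
excluding solid and undefined nodes; `F = p·S` converts it to a
pressure-drag estimate.  For drag interpretation the box is placed on the
upstream side the head faces (`heading` pointing into the flow): that zone
contains the stagnation pressure loading the head, whereas a box over the
head itself is dominated by the suction lobes where flow accelerates
around the body.

## Statistics

Welch's unequal-variance t-test with Satterthwaite degrees of freedom is
applied to the two condition samples, with the one-sided direction always
an explicit argument (frequency and phase lag: "less"; amplitude:
two-sided).  Because condition samples from the same individuals are not
independent, the classical paired t-test is reported alongside whenever
samples are paired; no multiple-testing correction is applied.  The
condition report operates on per-individual means and excludes (with a
warning) individuals missing a condition.

## Problem sizes

The bundled validation uses five-second swimmer trials at 125 fps,
101×101 oracle grids, a 251×101 wake grid at 2 mm spacing with 1000 fps
frames over one shedding period (pressure evaluated every 20th frame), and
ten followers spanning 0.05–0.32 m.  These sizes resolve every feature the
estimators depend on while keeping the full suite around twenty seconds on
one core; all of them scale up by changing the spec objects.

## Known limitations

* Strictly planar: no 3-D vortex rings, tail cupping, or out-of-plane
  flow; pressure reconstruction is 2-D.
* The wake is a kinematic vortex model, not a Navier–Stokes solution; no
  shear layers, core growth, or turbulence, and the synthetic street's
  axial spacing is one vortex per flap cycle rather than two.
* Pressure boundary gauge is relative; absolute pressures are not
  recovered, and masks touching the domain boundary degrade the edge
  integration locally.
* ΔΦ from joint-angle lags inherits the envelope-induced phase drift
  described above for any real fish whose amplitude grows along the body.
* PIV measurement artefacts (peak locking, masking error near the body
  surface, out-of-plane loss) are not emulated.
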