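# thrustwake

Analysis toolkit for experiments in which fish hold station **in the thrust
wake of a flapping foil** — the in-line schooling position in which a
follower swims directly behind a leader and interacts with the reverse
Kármán vortex street the leader sheds.

The package is aimed at researchers in fish biomechanics and biological
fluid dynamics who need to go from raw trial data (digitised body midlines
and planar PIV velocity fields) to the quantities such studies report:
tail-beat frequency, body-wave phase lags and wavelength, amplitude
envelopes, foil–fish phase synchronisation, and head-pressure estimates of
pressure drag.  Because laboratory recordings are bulky and hard to share,
the package also contains first-class synthetic generators — traveling-wave
swimmers and Lamb–Oseen vortex streets — with known ground truth, so the
entire analysis chain is testable end to end on a desktop.

## What it computes

**Foil kinematics.**  The foil is driven in sway and yaw,

    y_sway(t) = a_sway sin(2π f t),      φ_yaw(t) = a_yaw sin(2π f t − π/2),

so maximal yaw coincides with zero sway.  The trailing-edge excursion
`y_te = y_sway − r_te sin(φ_yaw)`, the Strouhal number `St = A f / U` (A the
peak-to-peak amplitude) and Reynolds numbers `Re = U L / ν` characterise the
operating point.

**Midline kinematics.**  Digitised midlines are spline-resampled to
equal-arclength stations; the body is divided into N = 20 equal segments
and the joint angles φᵢ between consecutive segments form per-joint time
series.  The intersegmental phase lag Δφᵢ is the circular cross-correlation
delay between adjacent joint-angle signals as a fraction of the cycle
duration T times 2π; the overall phase lag ΔΦ = Σ Δφᵢ along the body and
the body wavelength is λ = 2π/ΔΦ (in body lengths).  Tail-beat frequency
comes from the period between same-sign tail-tip excursion maxima, and the
amplitude envelope is half the range of lateral displacement per station,
with forward/lateral axes from a PCA of the pooled midline point cloud.

**Pressure fields.**  From sequential planar velocity fields the pressure
gradient is estimated via the Eulerian material acceleration,
`∇p = −ρ(∂u/∂t + (u·∇)u)`, and integrated along eight families of straight
paths marching in from the domain boundary; each node takes the **median**
of its surviving path integrals, with solid masks blocking paths.  Head
pressure is averaged over a snout box spanning 10% of the body length
axially and the body width laterally, giving the pressure-drag estimate
`F = p·S`.

**Statistics.**  Welch t-tests (unequal variance, explicit one-sided
directions) for paired condition comparisons, and ordinary least squares
with R² for the phase-difference-versus-distance relationship.

## Worked example

```python
import math
import numpy as np
from thrustwake import (FoilParams, WakeSpec, SwimmerSpec, strouhal, reynolds,
                        trailing_edge_path, peak_to_peak,
                        simulate_inline_follower, unwrap_phases, linear_fit)
from thrustwake.pipeline import analyze_track

foil = FoilParams(a_sway=0.01, a_yaw=math.radians(20), f=2.0, U=0.3)
A = peak_to_peak(trailing_edge_path(foil, 0.5, 4000))
print(f"tail-beat amplitude {A:.4f} m, St = {strouhal(0.04, 2, 0.3):.3f}, "
      f"Re = {reynolds(0.3, 0.067, 1e-6):.0f}")

wake = WakeSpec()                       # thrust wake: 0.3 m/s free stream
swimmer = SwimmerSpec(duration=4.0, n_markers=41,
                      a_head=0.0133, a_tail=0.0133)
distances = np.linspace(0.05, 0.32, 10)
followers = simulate_inline_follower(wake, swimmer, distances)
foil_te = trailing_edge_path(FoilParams(f=wake.shedding_frequency), 4.0, 1000)
rows = [analyze_track(track, foil_te) for _, track in followers]
d, phases = unwrap_phases(distances, [r["phase_diff_rad"] for r in rows])
fit = linear_fit(d, phases)
print(f"phase-distance slope {fit.slope:.2f} rad/m "
      f"(2π/λ_w = {2 * math.pi / wake.lam_w:.2f}), R² = {fit.r_squared:.3f}")
```

prints

```
tail-beat amplitude 0.0386 m, St = 0.267, Re = 20100
phase-distance slope 38.08 rad/m (2π/λ_w = 38.08), R² = 1.000
```

i.e. the foil's trailing edge sweeps ≈4 cm peak to peak, placing it at the
Strouhal number of freely swimming fish, and wake-locked followers delay
their body wave by exactly one wake wavelength per `λ_w` of downstream
distance — the linear phase–distance relationship that signals vortex
phase matching.

The same pipeline is available from the shell:

```bash
thrustwake demo --seed 1 --out demo_out   # simulate → kinematics → pressure → report
```

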