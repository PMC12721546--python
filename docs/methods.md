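# Methods and modelling notes

This note records the models behind each module, the parameters that matter,
the numerical choices, and what the package's simulations do and do not say
about real hardware.

## Magnetostatics

### Loop kernel

The field of a circular filament loop is the exact elliptic-integral
solution (see README for the formulas). Numerics:

- K(q²) and E(q²) are evaluated with `scipy.special.ellipk/ellipe` (the
  parameter convention, m = k²); agreement with adaptive quadrature of the
  defining integrals is tested to 1e-10 relative.
- The transverse prefactor 1/ρ² cancels against a bracket that vanishes like
  ρ² near the axis; to avoid catastrophic cancellation, points with
  ρ ≤ 1e-9·a take the on-axis branch (Bx = By = 0, closed-form Bz).
- Evaluation on the filament (α² = 0) is a true singularity and raises an
  error. Coil- and array-level evaluations additionally enforce a clearance
  of one wire diameter around every filament and raise rather than clamp:
  a field value centimetres from the model's validity edge should fail
  loudly, not silently saturate.
- The implementation is validated against an independent brute-force
  Biot–Savart line integral (10⁴ straight segments, midpoint rule) on a
  seeded random point cloud; agreement is at the 1e-13 T level, far inside
  the 1e-8 T test gate.

### Windings

A winding spec (inner radius, height, turns, wire diameter, current) is
discretized one loop per turn. Turns stack vertically at a pitch equal to
the *insulated* wire diameter, filling layer ℓ at radius
`inner_radius + (ℓ + 0.5)·d_wire`; the layer pitch is the same diameter.
The effective diameter is taken as 1.107 × bare diameter (≈ 0.90 mm for
20 AWG), a typical heavy-build enamel allowance; it is configurable per
winding. Layer growth matters: for the 300-turn reference winding the mean
turn radius is 5.31 cm, not 5.00 cm, which shifts far-field comparisons by
a few percent.

### Saturable core

Two core models are provided.

1. **Uniform amplification (default).** The core multiplies the bare-coil
   field everywhere by g = min(μr, Bsat/B_ref), where B_ref is the bare-coil
   flux density at the core centroid (axis point at half the core height
   inside the bore). Rationale for the centroid: it is the conventional
   single-point evaluation of the magnetizing field H for a uniformly
   magnetized cylinder, it is the on-axis maximum of the applied field (so
   the cap g·B_ref ≤ Bsat bounds the amplified on-axis field everywhere),
   and it reproduces the observed design behaviour of the instrument — with
   a fixed 0.33 lb of 20 AWG at 10 A, cores of radius ≤ 5 cm saturate while
   6–7 cm cores do not. Referencing the pole-face centre instead (exposed as
   an option) leaves the 5 cm core marginally unsaturated, contradicting
   that ordering; the difference is the ~15 % end-effect drop of a solenoid's
   field between its mid-plane and its end.
2. **Magnetization/moment route (cross-check).** M = min(χm·H, Bsat/μ₀) with
   χm = μr − 1 and H the bare-coil field at the centroid divided by μ₀;
   moment m = M·V; on-axis far field μ₀m/(2πz³). This is used in tests to
   confirm the dipole limit (electromagnet Bz·z³ → constant) but not for
   near-field maps, where a point dipole badly misrepresents a 10 cm-wide
   core.

Known limitation: uniform amplification calibrated on the axis can exceed
Bsat in the immediate neighbourhood of the winding wires (within a few wire
diameters of the coil), where neither model is meaningful; the saturation
cap is guaranteed on the axis and at the pole-face centre.

### Arrays and maps

Arrays superpose electromagnets evaluated in their own translated frames.
The default three-coil arrangement places mutually tangent coils (centre
spacing 2a) on a circle of radius 2a/√3 about the vessel axis; the spacing
is configurable since only the triangular arrangement, not the pitch, is
fixed by the design. The total 10 A supply divides equally over the three
parallel coils (3.33 A each), preserving the N·I product of a 100-turn coil
at 10 A. Plane maps default to 81 × 81 nodes over 16 × 16 cm (the vessel
diameter); a full three-plane map takes about a second on one CPU core.
Internal consistency is property-tested: 120° rotation symmetry of the
triangular array to 1e-12 T, additivity, linearity in a global current
scale, and a central-difference ∇·B check (h = 0.1 mm) well below
1e-6·|B|/h.

## Sizing

Constants: copper resistivity 1.724e-8 Ω·m (20 °C), copper density
8960 kg/m³, 1 lb = 0.45359 kg, AWG diameters from the ASTM B258 geometric
series d = 0.127 mm · 92^((36−awg)/39); water cp = 4.1806 J/(g·K). With
these, a third of a pound of 20 AWG at 10 A needs 10.86 V (the instrument's
quoted 10.82 V to 0.4 %, within the spread of published AWG resistance
tables), and the 2.5 kg, 25→50 °C, 5 min heater sizing gives 870.96 W.
Impeller speed converts RPM → rev/s before Re = ρNiDi²/μ (water, Di = 0.1 m,
100 RPM → Re = 16667, turbulent by the standard Re > 10⁴ stirred-tank
threshold) and P = Np·ρ·Ni³·Di⁵ (Np = 5 → 0.231 W). Outside the turbulent
regime the constant-Np power law warns rather than fails.

## Control simulators

### Temperature

Plant: FOPDT with K = 1.475 °C per volt of average heater voltage, τ = 990 s,
θ = 120 s, ambient 25 °C — the identified open-loop model of the 3 L batch
under a duty-cycled 120 V line (duty 1/3 → 40 V average → +59 °C). The
first-order lag uses the exact exponential update per step with an integer
delay line, so the open-loop step response matches the analytic solution to
round-off when θ is a multiple of dt.

Controller: three modes sampled every relay period (5 s). Full line voltage
until the temperature has risen 20 % of the commanded change; then PID; off
whenever T ≥ setpoint, with PID re-engaging below it. The PID output is
interpreted in **volts** (clamped to [0, 120], duty = u/120): the gains were
tuned against the voltage-input plant model, and on duty fraction the same
numbers would saturate on a 0.3 °C error and limit-cycle several degrees
wide. The discretization is positional with trapezoidal integral,
derivative-on-measurement (no setpoint kick), and conditional-integration
anti-windup. With dead time θ = 120 s the 20 %-rise handoff still overshoots
(the delay pipeline holds two minutes of full power), but the loop settles;
simulated steady-state error at 35 °C and 50 °C is < 0.01 °C, well inside
the ±1 °C design band. Default horizon 7200 s at dt = 1 s.

### pH

An unbuffered, well-mixed strong-acid/strong-base plant: each 50 µL drop
(standard 20 drops/mL drip chamber; the drop size is a documented default,
not a measured value) of 0.47 M HCl or 0.5 M NaOH shifts the net strong-acid
concentration c, and pH follows the charge balance [H⁺] − Kw/[H⁺] = c
(alkaline branch solved via [OH⁻] to avoid cancellation). The controller
senses a noisy reading (σ = 0.05 pH) through a 5-sample trailing moving
average, dispenses a 3 s pulse at 1 drop/s whenever the filtered value
leaves the band, waits 5 s for mixing, and repeats. Volume and moles are
tracked exactly; drop counts are integers.

Because dosing is quantized (one pulse ≈ 7×10⁻⁵ mol into 3 L), the loop
terminates at the first in-band state it can reach, which for the acid
scenario (band 4.5–5.5 from pH 7) is near the acidic edge (~pH 4.63) rather
than mid-band — real working substances are buffered and land more gently.
Representative initial conditions used in tests: pH 7 for the acid band,
pH 5 for the alkaline 7–8 band.

### Stirrer

First-order motor ω̇ = (gain·u − ω)/τm with gain 130 RPM at full drive and
τm = 0.3 s — plumbing defaults chosen so that full drive exceeds the 100 RPM
rated load speed of the geared DC motor; neither value is an identified
measurement. PID(0.18, 0.8, 0.0016) acts on the moving-average-filtered
tachometer signal (Gaussian noise, σ = 2 RPM default) with drive clamped to
[0, 1]. The closed loop is overdamped and holds the ±10 RPM design band at
25/50/100 RPM; with zero noise the steady-state error is numerically zero.
Default horizon 20 s at dt = 10 ms.

### Determinism

Every stochastic element draws from `numpy.random.default_rng(seed)`; the
same configuration and seed reproduce bit-identical series. The
magnetostatics and sizing paths consume no randomness.

## What the simulations do not show

The control simulators are property-level substitutes for hardware: they
omit sensor lag, heater thermal inertia after switch-off, buffering of the
fermentation medium, stirrer load torque disturbances, and every
firmware/scheduling effect. Their purpose is to verify that the published
plant models, gains and dosing rules form stable loops that meet the stated
tolerance bands — not to reproduce measured stabilization times. Likewise
the magnetics model is filament-based magnetostatics with a lumped core:
no hysteresis, eddy currents, or finite-element fringe detail.
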