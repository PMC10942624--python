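# Methods

`flightpower` reconstructs, from wingbeat kinematics and planar aerodynamic
force recordings, how a bird's two primary flight muscles power the
downstroke and upstroke of slow flight. The package bundles an inverse
dynamics chain (kinematics → 3D force reconstruction → power and moment
balances → muscle–tendon power partitioning) with a calibrated synthetic
flight generator that emulates a ringneck dove (*Streptopelia risoria*)
during the second wingbeat after takeoff, so the whole chain is testable
without any recording hardware or data downloads.

## Coordinate conventions

World frame: x = flight direction (back→front), z = up, y = lateral
(right→left), right-handed. Angles in degrees, SI units elsewhere. The
stroke fraction runs from 0 at the start of the downstroke through 1 at the
start of the next downstroke; a dove downstroke occupies ~60.3% of it.

## Synthetic flight generator

The generator writes three time series per flight — 12 landmark
trajectories at 1000 Hz, horizontal/vertical net aerodynamic force at
2000 Hz, pectoralis fiber length and EMG envelope at 10 000 Hz — plus a
morphology record. Everything downstream treats these files exactly as it
would treat measured recordings.

**Morphology.** The `dove` preset carries the study-species means: 161.6 g
body mass, 22.58 cm wing radius, 14.66 g single pectoralis, 3.26 g single
supracoracoideus, 9.80 Hz wingbeat, 17.12 mm fascicle rest length,
690.1 mm² PCSA. Wing mass is not part of the published morphometric table;
the preset uses 4.2 g per wing with an exponentially decaying spanwise mass
profile (radius of gyration ≈ 0.37 of wing length, consistent with
published avian wing mass distributions), calibrated so the wingbeat's
upstroke-to-downstroke positive-work ratio reproduces the reported ~25%.

**Wingbeat kinematics.** The stroke angle sweeps 125° in a plane inclined
40° to the horizontal (both chosen so the advance ratio comes out at the
measured 0.14 and the x velocity component dominates wing speed). The
angular velocity profile uses quarter-sine ramps around a plateau — stroke
reversals carry peak angular acceleration, as in simple harmonic motion —
with a 28%-of-downstroke acceleration ramp and a 30% deceleration ramp, so
wing speed is broadly maximal mid-downstroke. The upstroke (40.65 ms vs
61.80 ms for the downstroke) uses near-sinusoidal ramps. The wing folds to
84% span around mid-upstroke and re-extends through the early downstroke,
so span and area peak mid-downstroke.

**Angle of attack.** A periodic monotone (PCHIP) spline through the
waveform's control points: 54.0° at 7.1% of the stroke, a dip to 30.5° at
27.7%, 68.4° at 49.4%, with moderate values at the reversals and through
the upstroke (where the in vivo angle is highly variable and the analysis
masks it anyway). The trailing-edge landmark is placed so that the chord
line recovered from the landmarks reproduces this waveform against the
local section velocity.

**Forces.** Quasi-steady strip evaluation at a reference station (70% span):
CL = 1.8 sin 2α, CD = 0.30 + 1.05 sin²α (coefficient levels in the range
reported for revolving bird wings at these Reynolds numbers), dynamic
pressure from the station speed, area scaled by the fold factor, drag
antiparallel to the span-perpendicular velocity, lift perpendicular to drag
and span. A raised attenuation envelope suppresses upstroke force to ~12%
of its quasi-steady value (feather splaying and through-flow that the rigid
polar cannot represent). The resulting net vertical force is then scaled by
one global constant so that its average over the whole recording equals
bodyweight exactly on the written grid — the calibration contract every
downstream stage and test relies on. This leaves only the lift/drag split,
not the force scale, dependent on the polar; the defaults reproduce the
published drag structure (double drag peak ≈ 1.0/1.5 bodyweights flanking a
mid-downstroke dip).

**Muscle traces.** Fiber strain is mechanically slaved to the stroke angle
during the downstroke (the pectoralis shortens as the humerus depresses, so
shortening velocity tracks wing angular speed), after a slow
quasi-isometric "creep" of 12% of the excursion that begins mid-upstroke
(strain maximum 0.23 at 80% of the stroke) — series compliance while force
develops before the turn. Shortening arrests abruptly at 88% of the
downstroke, before the wing's reversal, matching the measured
velocity zero-crossing "right before the upstroke"; re-lengthening occupies
the early upstroke, returning to strain −0.05. The peak shortening velocity
(~0.1 m/s) respects the measured 0.24 m/s bound. The EMG envelope rises at
the shortening onset and falls silent mid-downstroke.

Per-channel additive Gaussian noise is available but defaults to zero, so
generation is bit-reproducible for a given configuration and seed.

**What the generator does not emulate.** Per-individual variation,
measurement noise spectra, 3D surface geometry, tail/body forces, unsteady
aerodynamics (rotational circulation, wake capture), and any systematic
deviation of the real waveforms from the spline/ramp family between the
published control points. Passing tests therefore validate the analysis
chain's mechanics and its behaviour on a *plausible, printed-value-faithful*
stand-in — not the fidelity of any specific in vivo recording.

## Analysis chain

**Kinematics.** Landmarks are smoothed by a Whittaker difference-penalty
smoother (penalized least squares, second-order difference penalty;
`λ → 0` is the identity), then differentiated by second-order central
differences. The stroke plane is the total-least-squares plane through the
shoulder for the shoulder→wingtip vector path (smallest singular vector);
stroke and deviation angles are the in-plane and out-of-plane angles of
that vector. Stroke phases are segmented at stroke-angle extrema
(downstroke = maximum→minimum). The wing's distributed mass is discretized
as 20 point masses at fixed proportional arc positions along the
shoulder→wrist→tip path. Angle-dependent quantities are masked where the
section speed falls below 5% of its peak (stroke reversal).

**Aerodynamic reconstruction.** The platform measures only net x and z
forces. Per wing (half the net, by bilateral symmetry), the unit drag
direction is the negative span-perpendicular velocity direction and the
unit lift direction completes the right-handed triad with the span, signed
along the wing surface normal. Matching the measured x and z components of
`L·l̂ + D·d̂` is a 2×2 linear solve per sample; the lateral component then
follows, and the two wings' lateral forces cancel on the body.
Ill-conditioned samples (reversals) are masked. Forces are low-pass
filtered (8th-order Butterworth, 80 Hz, zero phase) before reconstruction.
Aerodynamic power is `−D⃗·v⃗` — lift is perpendicular to the velocity and
contributes exactly zero. The power factor CL^{3/2}/CD uses a reference
dynamic pressure at the radius-of-gyration station with instantaneous area;
its maximum's location is invariant to that reference.

**Power balance.** Total muscle power = aerodynamic power (both wings) +
rate of change of wing kinetic energy (Σᵢ mᵢ a⃗ᵢ·v⃗ᵢ over the point masses,
both wings) + trunk term (kinetic plus potential rate; the potential part
can be toggled off, and is negligible for level flight). Mass-specific
power divides by both pectorales' combined mass. Pectoralis force follows
from per-muscle power over the shortening velocity, masked below 5% of the
peak rate.

**Moment balance.** About the left shoulder: the required muscle torque is
the angular-momentum rate of the 20 point masses minus the aerodynamic
moment (force applied at a configurable center-of-pressure station, default
50% span, along the shoulder→tip line) and the gravity moment. The shoulder
reaction force drops out; the reaction moment is assumed zero. The
pectoralis pull angle θp comes from |M⊥| = |F| d sin θp with the force
magnitude from the power balance and a configurable deltopectoral-crest
moment arm (default 12 mm, order-of-magnitude anatomical); the pull
*direction* is the unique force at that arm reproducing the
perpendicular-to-humerus moment component, expressed in a body frame
(x cranial, z dorsal, y lateral-left). Only the component perpendicular to
the humerus is resolvable this way; the along-humerus (largely medial)
component of the real muscle pull is not, which is a known limitation.

**Muscle–tendon partition.** Over one wingbeat, total power is split into
five modes: pectoralis generation (downstroke positive power plus
tendon-tensioning work), pectoralis absorption (negative power),
supracoracoideus generation, tendon storage (negative, during the
downstroke window) and tendon release (upstroke). A storage scenario sets
the fraction φ ∈ [0, 1] of upstroke positive work pre-stored
(`e = φ·∫upstroke P⁺`) and the window duration as % of stroke. The window
ends where pectoralis shortening arrests — just before the wing's reversal
— because the muscle cannot load the tendon once it stops shortening; the
tendon is then held tensioned through the turn. The default `flat_force`
profile tops pectoralis output up to a constant *force* level solved by
bisection so the window integral equals `e`: the extra power peaks
mid-window where shortening velocity peaks (filling the mid-downstroke
power dip) and tapers to zero at the arrest. A constant-power variant and a
raised-cosine bump are selectable. The five modes sum to the total at every
sample by construction, and ∫storage = −∫release = −e exactly under the
shared trapezoid quadrature.

**Work loops and shape factor.** The pectoralis loop plots per-muscle force
against fiber length over one wingbeat; its signed (shoelace) area is net
work and the shape factor is area over the bounding rectangle (peak force
excursion × peak length excursion), 1 for the ideal rectangular loop and
0.5 for a triangle. Force construction uses three completion rules where
the force-from-power quotient is undefined or unphysical: (i) while
shortening, the loop force is the generation power over the fiber rate,
clamped non-negative — a shortening muscle can only pull, and simultaneous
negative wing power at the end of the downstroke is taken up by the tendon
and skeleton; (ii) late-upstroke negative power appears as positive braking
tension, with the quotient's denominator floored at the stroke-mean
shortening rate because series compliance makes the fiber rate
under-represent the muscle–tendon unit there; (iii) across electrically
active, low-power runs at the top reversal the force is interpolated — an
activated muscle develops force quasi-isometrically through the turn.

**Storage sweep.** For each (fraction, timing) cell the partition runs, the
loop is built and the shape factor and stroke-averaged positive pectoralis
power recorded; the sweep is fully deterministic. On the calibrated dove
(21 fractions × 51 timings) the tuned landscape reproduces the published
structure: maximum shape factor ≈ 0.77 (published: 0.73 ± 0.10), optimal
window duration ≈ 31% of the stroke shared across fractions above 35%,
short windows degrading the loop through a late-downstroke output spike,
full storage raising stroke-averaged positive pectoralis power by ≈ 25%
over the ≈ 193 W/kg no-storage baseline (published: +24.9% over
206 ± 50 W/kg). One feature is *not* reproduced: the published sweep has
its (very shallow, ≈ 0.01 above its neighbours against a ±0.10 SD) maximum
at 90% storage, whereas this model's shape factor rises monotonically —
about +0.01 per 10% of fraction — to 100%. With the stored-energy budget
fixed by the measured work ratio, a smooth headroom-filling profile cannot
push the loop's force plateau past the early-downstroke force shoulder, so
no interior maximum can form; resolving the discrepancy would need the
exact storage-allocation shape used for the published sweep.

**Scaling relations.** The aerodynamic parameter is x_aero = f·R (wingtip
speed scale) and the inertial parameter
x_iner = (m_wing/m_body)(r_gyr/R)²(f·R)·f with both wings' mass. The fitted
linear relations are hard-coded as named constants: mean pectoralis power
per body mass = −0.59 + 18.74·x_aero W/kg; midway timing of power
(force) exertion = 35.01 − 61.75·x_iner (31.90 − 59.06·x_iner) % of stroke.
Midway timings of arbitrary traces use the cumulative integral of the
positive part reaching half its wingbeat total, linearly interpolated.
Coefficient refitting (OLS via statsmodels) supports parameter-recovery
tests on synthetic bird populations generated on power-law allometries
anchored at the dove (masses log-spaced across a configurable range,
multiplicative lognormal noise).

## Numerical choices

- Analysis grid 1000 Hz; force and muscle channels are spline-resampled
  onto it. Integrals use the trapezoid rule with shared weights so
  conservation identities hold to rounding error.
- Problem sizes: simulations run 4 wingbeats (~0.41 s) and analyze the
  middle wingbeat, away from differentiation edge effects; the storage
  sweep uses the 21 × 51 grid above. These sizes make the full test suite
  and the acceptance script each run in seconds while leaving all reported
  quantities grid-converged to well below the comparison tolerances.
- Masking thresholds: 5% of peak speed for flow directions and strain-rate
  quotients, 1% of peak drag for aerodynamic ratios.
- Zero-width storage windows degrade to an energy-consistent impulse at the
  last pre-arrest sample; windows with no shortening fall back to a smooth
  bump (degenerate late storage at near-zero fiber velocity).
- The bisection for the flat-top level runs 200 halvings and then rescales
  the profile so the stored energy is exact.

## Known limitations

- Tail and body aerodynamic forces are attributed to the wings.
- The quasi-steady polar has no rotational or wake terms; upstroke force
  suppression is an explicit envelope rather than emergent aerodynamics.
- The pull-direction analysis resolves only the perpendicular-to-humerus
  force component, and the humerus axis is modeled from the shoulder→wrist
  landmark line.
- Muscle activation is treated as a binary envelope; there is no Hill-type
  force–velocity–activation model and no tendon constitutive law — the
  partition is pure energy accounting.
- The work-loop completion rules at the stroke reversals are modeling
  choices; alternatives would shift shape factors by a few hundredths.
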