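# Methods

## The measurement model

All analysis happens in the crank-angle domain. The crank angle θ is 0° when
the left crank arm points forward and horizontal, increases in the pedaling
direction, and the right crank sits at θ + 180°. Recordings are uniform
1 kHz streams: crank angle, per-pedal 3-axis force/torque and pedal
inclination, per-channel stimulation command state, and (in volitional
sessions) surface EMG. A revolution is a complete 360° traversal starting at
θ = 0°; partial leading/trailing revolutions are discarded. Quantities are
averaged onto a uniform angular grid (default 1° bins) by bin-averaging the
samples of the selected revolutions; per-bin sample counts are kept so
support and variance stay inspectable. Binned averaging is used rather than
interpolation-resampling because sample density per bin varies with cadence
error; at 1 kHz and 50 rpm a 1° bin holds ≥3 samples, which is why 1° is the
default (and the floor) of the grid resolution.

Pedal sensors report forces in the pedal frame together with the pedal's
inclination β relative to the crank arm. The in-plane force is rotated by β
into the crank frame: F_t (tangential, perpendicular to the crank arm,
positive when driving the motion) and F_n (along the crank arm, producing no
motion). The out-of-plane component and the pedal torques are recorded and
parsed but enter no computation; the sign convention makes "positive muscle
force profile = contributes to cycling" hold literally.

The **muscle force profile (MFP)** of a stimulated muscle group is the
per-bin difference of the tangential-force profiles of active cycling (the
group continuously stimulated) and passive cycling (motor only), both
recorded under the same seating position and cadence. Continuous stimulation
makes the stimulation delays unobservable, so the MFP is a pure
angle-domain description of where the muscle can produce force. The
**net-force** is the same subtraction when stimulation follows an
intermittent pattern; it carries the delay signature and is the basis of
both the direct shift measurement and the power computation.

## Delay compensation

Two delays separate the stimulation command from pedal force: the
stimulator's internal latency D_S (command → pulse at the electrode) and the
electromechanical delay EMD (pulse at the motor nerve → muscle tension). At
cadence ω (rpm) a delay of d seconds sweeps d·360·ω/60 degrees, so

    Δθ_start = (D_S + EMD) · 360 · ω / 60,    Δθ_stop = D_S · 360 · ω / 60.

The start must pre-empt both delays; the stop only the stimulator delay,
because force decay outlasts the EMD. Both compensation modes are
implemented; the default shifts the start only (lengthening the arc), the
mode used when the compensated pattern tables of this protocol are produced.
The acquisition chain's own ~1 ms latency (≈0.3° at 50 rpm) is ignored.

`measure_shift` measures the total delay directly from a patterned trial:
the onset is the first angle after the commanded start where the net-force
exceeds the larger of 5% of its peak and 3 baseline standard deviations
(baseline estimated on the half circle before the commanded start), with the
crossing refined by linear interpolation. The crossing must open a run of at
least 3 consecutive supra-threshold bins; without this persistence
requirement a single ~3.5σ noise bin occasionally fires a false onset. The
probe arc is placed in the first half of the MFP's positive range so the
delayed response lands where the muscle can still build force quickly.

## Pattern derivation

* `activation_interval` — supra-threshold (default 25% of peak) bins of the
  mean EMG profile on the circle; sub-threshold gaps narrower than 5° are
  bridged, the run containing the profile maximum is returned, and the
  boundaries are interpolated between bin centers. Returning the
  argmax-containing run (rather than the longest run outright) guarantees
  the interval always covers the activation peak; after gap-merging the two
  coincide except on adversarial multimodal profiles.
* `union_intervals` — exact union of overlapping/adjacent arcs; disjoint
  arcs are covered by the arc excluding the largest gap.
* `mfp_pattern` — exhaustive scan of every grid placement of a fixed-length
  window maximizing the windowed MFP sum; grid search is exact on gridded
  profiles and 1° resolution bounds the placement error. Ties break to the
  smallest start angle.
* `full_range_pattern` / `threshold_pattern` — zero transitions (or
  fraction-of-max crossings) bracketing the MFP maximum, boundaries
  interpolated; patterns for maximum power versus fatigue-limited exercise.

EMG processing is zero-phase (`sosfiltfilt`) so filtering introduces no
angular lag that would bias the intervals; "4th order" is the order of the
designed band-pass. A rectify + 100 ms moving-RMS envelope step sits between
filtering and normalization: a band-passed signal averages to ≈0, so the
threshold rule is only meaningful on a nonnegative envelope. Per-revolution
normalization (unit maximum) precedes averaging, making the profile
invariant to slow amplitude drift.

## Power

With the motor holding ω constant, the pedal's tangential speed is
v = r·ω·2π/60 (crank length r). Mean power over a cycle is the
revolution-average of F_t(θ)·v over the net-force profile. Crank length is
not a measured quantity here; it is a required configuration parameter
(default 0.17 m, the common crank size) reported with every result. Power is
summed over the two sides to give one figure per pattern. An
instantaneous-velocity mode is deliberately out of scope: the cadence
controller's error is ≤1.7% over the tested range.

## The synthetic session generator

The generator emulates the platform's streams so the full protocol runs
end-to-end without hardware:

* **Kinematics** — constant realized cadence, target × (1 − error); the
  cadence error is a constant relative offset per run (matching how the
  motor controller's accuracy is characterized, one value per target), not a
  drift. The sample at t = duration is included so an integer number of
  periods closes its last revolution.
* **Passive load** — each pedal sees a two-harmonic circular function of its
  own crank position (defaults ±~15 N tangential, compressive normal load):
  the simplest periodic stand-in for leg weight plus inertia. White noise
  (default sd 3 N) models measurement noise on every force channel.
* **Muscle response** — a raised-cosine force bump over the muscle's active
  arc (zero at the arc ends, so full-range patterns have well-defined zero
  transitions), gated by the stimulation command delayed by D_S + EMD,
  optional geometric fatigue decay per revolution (default 0: fresh muscle)
  and an optional hindering arc with flipped sign. Under continuous
  stimulation the command predates the recording, so no start-up transient
  appears and the delays are unobservable, as required for MFP recording.
* **EMG** — per-muscle bursts of band-limited (10–30 Hz) unit-RMS noise,
  amplitude-modulated by a Hann window over the activation arc, over white
  baseline noise with amplitude SNR 10 by default.

Default study conditions: stimulator D_S = 3.2 ms, 40 Hz / 350 µs / 70 mA;
quadriceps EMD 50.1 ms; peak tangential forces 25 N (right) / 22 N (left),
chosen so a wide pattern at 50 rpm with 0.17 m cranks produces ~9–10 W total
— the scale of trained paralyzed quadriceps; productive arcs 170° per side.
Each stimulated phase simulates 8 passive + 2 active revolutions (protocol
prescribes 5–10 passive + 2 active); the MFP phase runs at 30 rpm, the rest
at 50 rpm; rest periods are metadata, not simulated time. The volitional EMG
session simulates 20 revolutions at 50 rpm with the quadriceps-head arcs
deliberately placed ~40° earlier than the rider's force-productive arcs:
volitional cycling also recruits hip flexors beyond the reach of surface
stimulation, so the EMG-timed pattern starts before the stimulated
quadriceps can contribute — this mismatch is exactly what the MFP route
corrects, and it is why the MFP pattern wins the power comparison.

What the generator does **not** model: musculoskeletal dynamics, closed-loop
cadence control, spasticity, EMG physiology beyond band-limited bursts,
force–velocity/length relations, or within-run EMD growth. Passing tests
therefore demonstrate that the analysis recovers what the model injects —
correct geometry, delay handling, averaging and power arithmetic — not that
the physiological model is realistic.

## Validation experiments and numerical choices

* The EMG-recovery check simulates bursts over a known 120° arc at SNR 10
  for 160 revolutions (≈3 min of volitional cycling) and compares the
  recovered 25% interval against crossings predicted *a priori*: the Hann²
  modulation spread by the power kernel of the generator + analysis filter
  cascade and by the RMS window, plus the filtered baseline power. The long
  session keeps the stochastic endpoint scatter below ~1.7° (2-bin check);
  the prediction itself never touches pipeline output.
* Shift-measurement trials use a 50 N probe muscle so the delayed onset is a
  sharp step; measured shifts sit within 0.7° of the injected value across
  seeds, biased ≲0.5° early by the onset interpolation at a step edge.
* Binning snaps angles by 1 nano-degree before bin assignment so identical
  sample phases in different revolutions cannot straddle a bin edge through
  float rounding.
* Angles are degrees everywhere; radians appear only inside the power and
  rotation computations. All randomness flows through explicit integer
  seeds; per-phase seeds derive from the scenario seed, so a session is
  byte-reproducible.

## Known limitations

Single synthetic rider; quadriceps only (the protocol generalizes to more
groups, but synergies between simultaneously stimulated groups are not
modeled). The MFP is taken at 30 rpm and applied at 50 rpm assuming the
force–angle relation is cadence-invariant. The recording dialect is a
package-defined stand-in, not a vendor format. Whether the two active
revolutions are averaged or used separately is an analysis choice; averaging
is used.
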