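# fescycling

Analysis pipeline for designing and assessing **functional electrical
stimulation (FES) cycling patterns** on an instrumented, cadence-controlled
cycling ergometer — the workflow used to set up stimulation timing for
riders with spinal cord injury, built so every stage also runs on synthetic
sessions (no hardware required).

A stimulation pattern assigns each muscle group a crank-angle arc during
which it is stimulated once per revolution. This package implements the two
standard ways of deriving such a pattern, and the machinery to compare them:

1. **EMG pattern** — record surface EMG of an able-bodied cyclist's
   quadriceps heads during volitional cycling; band-pass filter
   ([10, 30] Hz, 4th-order Butterworth, zero-phase), extract a moving-RMS
   envelope, normalize per revolution, average over revolutions against the
   crank angle θ, and take the arc where the mean profile exceeds 25% of its
   peak. The quadriceps interval is the union over rectus femoris, vastus
   lateralis and vastus medialis; the other leg is the 180° rotation.
2. **MFP pattern** — continuously stimulate one muscle group of the rider
   during motor-assisted cycling and subtract the passive (motor-only)
   tangential pedal force:  MFP(θ) = F_t_active(θ) − F_t_passive(θ).
   Positive MFP means the contraction drives the motion. The pattern is the
   arc of the same length as the EMG pattern that maximizes ∫ MFP dθ
   (exhaustive scan over all grid placements).

Stimulation acts late: the stimulator's internal delay D_S and the muscle's
electromechanical delay (EMD) let the crank sweep past the designed arc
before force appears. At cadence ω (rpm),

    Δθ_start = (D_S + EMD) · 360 · ω / 60
    Δθ_stop  =  D_S · 360 · ω / 60

so pattern start (and optionally stop) angles are shifted earlier by these
amounts. The total shift can also be measured directly as the angle between
the commanded onset and the first noticeable net-force rise. Per-pattern
output is the mean power over a cycle, P = mean(F_t) · r · ω · 2π/60 with
crank length r.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
rider (two quadriceps channels, EMD 50.1 ms, stimulator delay 3.2 ms,
40 Hz / 350 µs / 70 mA stimulation, force noise 3 N):

```
python analysis/01_simulate_session.py --seed 1
python analysis/02_emg_pattern.py
python analysis/03_delay_compensation.py
python analysis/04_power_comparison.py
```

The first script simulates the four-phase protocol (muscle force profiles at
30 rpm; shift measurement, EMG-pattern and MFP-pattern trials at 50 rpm) and
prints, among other things:

```
measured angular shift: 15.29 deg (D_S 3.2 ms + EMD 47.8 ms)
    pattern  ...  total_power_w  vs_reference_pct
emg_pattern  ...          8.876              0.00
mfp_pattern  ...          9.570              7.83
```

The measured shift recovers the injected 53.3 ms total delay (≈16° at
50 rpm) from the net-force onset; the force-optimal placement of the same
arc length produces 7.8% more power than the EMG-timed placement — the
EMG timing of an able-bodied cyclist also reflects deep hip flexors that
surface stimulation cannot reach, so it starts too early on the crank
circle for a stimulated quadriceps. `02` prints the per-head activation
intervals behind the EMG pattern, `03` tabulates the delay-compensation
shifts over the platform's cadence range, and `04` rebuilds the comparison
from the written intermediates alone.

Recordings are plain tab-delimited text with a `#` header
(`fescycling.read_recording` / `write_recording`); all intermediates land
under `results/`.

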