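# Methods

`htsaxs` is a desk-scale, hardware-free re-creation of the control stack of
a high-throughput biological SAXS beamline: a central hub coordinating a
shutter, a hardware-binned CCD, three ion chambers, a storage-ring beam and
a 96-well liquid-handling robot, with scripted *expose* and *screening*
operations, ROI-variance bubble detection, and spreadsheet-based experiment
plans. Nothing here talks to hardware; every device is a deterministic,
seedable simulator, so the system's coordination logic — timing, dose
bookkeeping, queueing, fault recovery — can be exercised and tested on a
laptop.

## Discrete-event time

All devices share a single simulated clock held as integer microseconds.
Advancing by a robot-method duration or an exposure time is exact in ticks,
so a 5 s exposure is exactly 5 000 000 ticks of shutter-open time and the
2000 Hz trace grid never drifts against the shutter log. One simulated
second costs no wall-clock time; a full 96-well screen simulates in under a
minute of real time.

## The hub and its state machines

The hub owns sessions, devices, and operations. Sessions follow the
single-active-client rule: any number may connect and monitor, at most one
is ACTIVE and may command, and a `request_active` always succeeds by
demoting the current holder (the toggle-button model; the demoted client
receives a non-blocking UPDATE). Operations live hub-side: once a command
is accepted the submitting client can vanish and the run is unaffected,
which is asserted by comparing record lists from connected and disconnected
runs at the same seed.

Operation states are PENDING → RUNNING ↔ PAUSED → {COMPLETED, FAILED,
ABORTED}, with terminal states absorbing. PENDING → ABORTED is also legal
so a queued operation can be cancelled before it starts; without it the
"submit then abort" contract (no device commands ever issued) would be
unsatisfiable. Illegal transition requests raise and leave the state
untouched, a property checked against randomly generated event sequences.

Notifications are two-tier: PAUSE events (beam dump) only move the
operation status; SERIOUS events (robot fault) are delivered to every
registered hook exactly once, and a failing hook never affects the run. The
hooks stand where email/SMS transport would sit in production.

## Device models

**Beam** — nominal intensity with an optional multiplicative sinusoidal
drift `1 + a·sin(2πt/T)` (default period 60 s) and a schedule of dump
intervals during which intensity is zero. A 1% drift amplitude gives the
documented max/min channel ratio of ≈1.02. Real sources drift by more than
10⁻³–10⁻⁴ between a sample and its blank, which motivates dose
normalization (below).

**Ion chambers** — I_mono, I_zero and I_end scale the instantaneous beam
intensity by fixed gains (1.2 / 1.0 / 0.6); I_end sits behind the cell and
is further attenuated by its contents (transmission 0.80 sample, 0.85
water, 1.0 empty). The values are arbitrary but distinct so channel mix-ups
are caught.

**Detector** — a `base_pixels²` chip (default 64², a deliberate desk-scale
stand-in for a real CCD) with 2×2, 4×4 or 8×8 hardware binning. Charge is
accumulated per unbinned pixel as scene × dose, summed over bin×bin blocks
*before* digitization, then each binned pixel receives one zero-mean
Gaussian readout draw (sd 5) plus a constant offset (10), clamped at zero.
This embodies why high binning suits solution scattering: one readout event
is spread over bin² pixel areas, so readout-noise variance per unit
detector area falls as 1/bin² — measured as a ratio of 1/16 between 8×8 and
2×2 in a Monte-Carlo over ≥10⁴ binned pixels (10% tolerance). A
conservation property (noise-free total signal invariant under binning
mode) pins down that binning sums and never discards.

The scattering scene is deliberately schematic: a dilute-particle,
sphere-like radially decaying profile `A/(1+(r/r₀)²)²` on a flat solvent
background for a loaded sample, flat backgrounds for water and the empty
cell, plus a `contamination` fraction of the previous sample's profile.
No q-calibration or absolute intensity is claimed; only relative behaviour
(normalization, subtraction, carry-over) is asserted anywhere.

**Robot and cell** — the seven pre-programmed methods move a shared-cell
state machine (contents, source well, bubble flag, contamination).
Aspiration rate is limited to 0–20 µl/s and volume to 1–20 µl (closed
ranges); loading a non-empty cell is a fault; washing zeroes contamination;
emptying a sample leaves a configurable carry-over residue (default 0.05)
unless followed by a wash. Durations are configurable; the water wash is
180 s — the screening throughput bottleneck — while the others (load 30 s,
empty 15–20 s, soap wash 240 s, bubble 15 s) are plausible invented
defaults. `LOAD_SAMPLE` introduces a bubble with probability `p_bubble`
(default 0.1) and the Bubble routine makes exactly four back-and-forth
passes, each clearing a present bubble with probability 0.7 — both
placeholders exposed in config, not calibrated claims; the four-pass count
is the only fixed part.

## The expose operation

For each requested time (1–5 per step, rejected outside that range): take
a video snapshot of the cell and score it for bubbles, start the padded
2000 Hz trace (default 50 ms on each side of the shutter window), open the
shutter, integrate the detector, close the shutter exactly `t` later on the
simulated clock, stop the trace, write image (16-bit PNG), trace (TSV:
time_s, i_mono, i_zero, i_end, shutter) and snapshot, and emit an
`ExposureRecord` carrying the per-channel integrated dose over the shutter
window. Sample membership in a dose window is decided by index arithmetic
on the 0.5 ms grid, so a 1 s window integrates exactly 2000 samples and the
windowed dose is invariant to trace padding.

The detector's effective dose is the beam intensity integrated over the
shutter-open window on the same 0.5 ms grid the trace uses. That choice
makes normalization exact in noise-free mode: a profile divided by its
I_zero windowed dose is independent of beam scale and drift to machine
precision, while unnormalized profile ratios deviate at the drift scale
(~2×10⁻³ at 1% drift). Records keep the float image and the trace in
memory; the PNG on disk is the quantized archival copy.

If a dump overlaps the upcoming exposure window (or is in progress), the
operation flips to PAUSED, polls the beam each simulated second, and
repeats that exposure after restore — a dump therefore delays but never
loses an image. Reduction helpers (`radial_average` over integer-radius
annuli `k ≤ r < k+1`, `normalize_profile`, `subtract_buffer`) provide the
minimal pipeline needed to demonstrate matched sample/blank subtraction and
the zero-carry-over wash control.

## The screening operation

`compile_plan` expands the selected rows of a ≤96-well plan, in row order,
into template steps (≤8, at least one EXPOSE) bound to each well, appending
one WASH_WATER when the row's wash flag is set — the per-row checkbox model
that lets a dilution series (buffer + three concentrations, wash every
fourth well → 24 washes saving ~3.6 h of simulated wash time) skip
redundant washes. `execute_queue` runs tasks through a cursor that only
advances on success: dumps pause/resume inside the expose step; a robot
fault leaves the queue PAUSED after exactly one SERIOUS notification, and a
later call resumes from the cursor so every task runs exactly once.
`buffer_pairing` matches each sample exposure to its nearest preceding
buffer exposure of the same index within the group, with a
`before_and_after` mode for the bracketing-blank control.
`estimate_duration` is plain bookkeeping over the compiled tasks plus a
per-exposure overhead (default 1 s, an invented readout allowance);
simulated estimates are not wall-clock claims.

## Bubble detection

The statistic is the population variance (divisor N — the histogram-based
definition) of 8-bit greyscale intensities over the beam-footprint ROI,
with Rec.601 luma (0.299/0.587/0.114, rounded) for RGB frames since the
original greyscale conversion is unspecified. Thresholds: σ² ≥ 2000 →
BUBBLE, 1500 ≤ σ² < 2000 → SUSPECT, below 1500 → CLEAN, with ~400 typical
of a clean cell. Both boundaries fall on the more alarming side so the
three intervals partition [0, ∞); values in [400, 1500) are CLEAN because
no finer boundary is defined there. The thresholds are empirical constants
of the original camera; the synthetic frame generator (flat background,
Gaussian noise, dark discs with bright rims, optional specular meniscus
edge) targets the three regimes, not that camera. ROIs are clamped to the
frame; a fully outside ROI is an error. Detection never aborts collection
— scores are flagged in the run log.

## Plan and log I/O

Plans travel as XLSX or CSV with fixed lower-case headers (`well,
selected, buffer, wash, notes`); flags accept 1/0, true/false, yes/no, x
or blank. Import collects *all* violations (duplicate wells, >96 rows,
unknown columns, malformed flags) with row numbers and raises them
together. Export appends `images, bubble_label, bubble_variance` result
columns, which import recognises and ignores so export→import is an
identity on the plan content. The sheet deliberately carries only per-well
rows; the action template, exposure times and binning are run settings, as
in the tabbed-GUI workflow the format mirrors. The run log is plain text,
one line per step — ISO-8601 timestamp rendered from the simulated clock
against a fixed epoch (2000-01-01, keeping logs seed-deterministic), step
description, file names, and the bubble label and σ² for exposures.

## What the simulators do and do not show

Passing tests demonstrate the *control* contracts: exact shutter/trace
bookkeeping, dose normalization algebra, queue completeness under faults,
determinism from a single seed, arbitration and capacity limits, and the
variance classifier's decision boundaries. They do not validate SAXS
physics (no q-space, no absolute intensities, no detector geometry), real
robot timings other than the wash, bubble occurrence rates, or wall-clock
throughput — the ~desk-scale detector (64² default) and the schematic
scene are stand-ins chosen for test speed and clarity, with sizes scaled
up only where a statistic needs pixels (the 256²-chip noise Monte-Carlo).

## Numerical choices

- Clock resolution 1 µs; all durations rounded to ticks.
- Trace windows and dose integrals use index arithmetic, not float
  comparisons, against the 0.5 ms grid.
- Detector and trace integrate beam intensity on the identical grid
  (left-endpoint rectangle rule), making normalization exact by
  construction rather than approximately.
- Radial annuli use `floor(r)`; the brute-force oracles in the tests use
  the same convention stated independently.
- Digitization clamps at zero; images are archived as 16-bit PNG and the
  float image is kept on the record for reduction.
- Run capacity: 16 run tabs (config default), 5 exposure times, 8 template
  steps, 96 plan rows; all enforced with explicit errors.
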