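# htsaxs

Desk-scale, hardware-free control framework for high-throughput
small-angle X-ray scattering (SAXS) data acquisition.

Biological SAXS beamlines screen 96-well plates of protein solutions: a
liquid-handling robot moves each 10–20 µl sample into a shared cell, the
shutter opens for 0.5–10 s while a binned CCD integrates and three ion
chambers (I_mono, I_zero, I_end) are logged at 2000 Hz, matched buffer
blanks are collected for subtraction, and the cell is washed between
unrelated samples. Getting useful data out of that pipeline is mostly a
*control* problem — exact shutter/trace timing for dose normalization,
queueing with pause/resume across beam dumps, robot fault alerts, bubble
screening of the sample cell — and this package re-creates that control
stack with deterministic device simulators so the logic can be developed,
tested and taught without a synchrotron. It is aimed at beamline software
developers and at anyone who wants an executable model of how automated
solution-scattering acquisition hangs together.

The pieces:

- **`hub`** — the central control server: many monitoring clients, at most
  one ACTIVE; operations stored hub-side so the run survives client
  disconnects; PAUSE vs SERIOUS notification tiers.
- **`devices`** — seedable simulators: shutter with an exact transition
  log, CCD with 2×2/4×4/8×8 pre-digitization binning (one readout-noise
  event per *binned* pixel), drifting/dumping beam, ion chambers, robot
  and sample-cell state machine.
- **`expose`** — the expose scripted operation: up to five exposures in
  rapid succession, each with a snapshot + bubble check, a padded 2000 Hz
  (0.5 ms) intensity trace, per-channel integrated dose over the
  shutter-open window, and the reduction helpers (radial average,
  I_zero-dose normalization, buffer subtraction).
- **`screening`** — the 96-well queue: per-row wash flags, dump
  pause/resume, one SERIOUS alert per robot fault, sample↔buffer pairing.
- **`bubbles`** — ROI intensity variance σ² on greyscale cell frames with
  the three-way decision σ² ≥ 2000 → BUBBLE, 1500 ≤ σ² < 2000 → SUSPECT,
  else CLEAN (~400 is a typical clean cell), plus a parametric frame
  generator.
- **`planio`** — XLSX/CSV screening plans with full-plan validation and
  round-trip export, deterministic file naming, and the plain-text run log.

## Worked example

Screen four wells (a buffer followed by three samples), exposure times
0.5 s / 5 s / 0.5 s, with a beam dump injected 100 s into the run:

```python
import htsaxs as hx

rows = [hx.PlanRow(w, selected=True, is_buffer=(i == 0), wash_after=(i == 3))
        for i, w in enumerate(hx.all_wells()[:4])]
plan = hx.ScreeningPlan(rows=rows, exposure_times=(0.5, 5.0, 0.5),
                        prefix="xyl", directory="demo")
cfg = hx.SimulationConfig()
cfg.beam.dump_schedule = ((100.0, 30.0),)

print("estimated duration:", hx.estimate_duration(plan, exposure_overhead=1.0), "s")
result = hx.run_screening_session(plan, config=cfg, seed=1, out_dir="demo")
print("status:", result.status.state.value)
print("records:", len(result.records), "paused intervals:", result.status.paused_intervals())
print("sample/buffer pairs:", len(hx.buffer_pairing(result.records, plan)))
r = result.records[0]
print("first record:", r.image_path.split("/")[-1], "bubble:", r.bubble.label.value,
      round(r.bubble.variance, 1), "I_zero dose:", round(r.integrated_dose["I_zero"], 2))
```

prints

```
estimated duration: 476.0 s
status: COMPLETED
records: 12 paused intervals: 1
sample/buffer pairs: 9
first record: xyl_A1_e0.png bubble: CLEAN 4.1 I_zero dose: 500.0
```

All 12 exposures (4 wells × 3 times) complete despite the 30 s dump — the
operation pauses once and resumes on its own. Each sample exposure is
paired with the buffer exposure of the same index (9 pairs), ready for
normalized subtraction. The first record's cell snapshot scored σ² ≈ 4.1,
far below the 1500 SUSPECT threshold, and its I_zero dose is 500
intensity·s (nominal intensity 1000 × 0.5 s shutter-open), the quantity a
profile is divided by during normalization. `demo/` now holds the 16-bit
PNG images, TSV traces, snapshots, the run log (`xyl.log`, one ISO-stamped
line per step with file names and bubble results), the results spreadsheet
and the hub state dump.

The same run from the shell:

```bash
htsaxs plan template --out plan.xlsx        # blank 96-well sheet
htsaxs screen run plan.xlsx --seed 1 --out demo
htsaxs bubble check demo/xyl_A1_e0.snap.png --roi 60,40,40,40
htsaxs expose --times 0.5,5,0.5 --binning 8 --prefix lys --dir out --well A1
```

`bubble check` exits 0/1/2 for CLEAN/SUSPECT/BUBBLE.

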