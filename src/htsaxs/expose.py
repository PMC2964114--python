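"""The expose scripted operation and its data reduction.

One Expose step takes up to five exposures in rapid succession.  For each
exposure the operation: snapshots the sample cell and scores it for
bubbles, starts the 2000 Hz three-channel ion-chamber trace, opens the
shutter for exactly the requested time on the simulated clock, integrates
the detector, closes the shutter, stops the trace, and writes the image,
trace and snapshot with their provenance record.  The integrated I_zero
dose over the shutter-open window is what normalizes a profile: sample and
blank share one cell, one beam and one detector, so they are measured
minutes apart while the source drifts by more than 1e-3, and dividing by
the per-exposure dose is what makes their subtraction meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from .bubbles import ROI, BubbleScore, detect, save_frame, synth_frame
from .config import CameraConfig, SimulationConfig
from .devices import Beamline, CellContents, RobotMethod, SampleCellState, scattering_scene
from .errors import ValidationError
from .planio import LogEntry, make_filename
from .wells import WellAddress

#: ion-chamber trace sampling: one row every 0.5 ms (2000 Hz)
TRACE_PERIOD = 0.0005
CHANNELS = {"I_mono": 0, "I_zero": 1, "I_end": 2}
MAX_EXPOSURES = 5


def trace_sample_count(duration: float) -> int:
    """Number of trace rows covering ``duration`` seconds at 2000 Hz."""
    if duration < 0:
        raise ValidationError("duration must be >= 0")
    return int(round(duration / TRACE_PERIOD))


@dataclass
class IntensityTrace:
    """2000 Hz record of (I_mono, I_zero, I_end) around one exposure.

    The trace spans a padded interval around the shutter window; both the
    windowed and the full integrals are therefore available.
    """

    sample_period: float
    t0: float
    samples: np.ndarray  # (n, 3)
    shutter_window: tuple[float, float]

    @property
    def span(self) -> float:
        return len(self.samples) * self.sample_period

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) * self.sample_period

    def shutter_mask(self) -> np.ndarray:
        # index arithmetic (not float comparison) so a window aligned to the
        # sampling grid selects exactly round(width / period) samples
        a, b = self.shutter_window
        i0 = int(round((a - self.t0) / self.sample_period))
        n = int(round((b - a) / self.sample_period))
        mask = np.zeros(len(self.samples), dtype=bool)
        mask[max(i0, 0) : min(i0 + n, len(self.samples))] = True
        return mask


def integrated_dose(trace: IntensityTrace, channel: str, window: tuple[float, float]) -> float:
    """Integral of one channel over ``window`` (rectangle rule, exact per sample).

    The window must lie within the trace span; sample membership is decided
    by index arithmetic so a window aligned to the sampling grid contains
    exactly round(width / period) samples.
    """
    if channel not in CHANNELS:
        raise ValidationError(f"unknown channel {channel!r}")
    w0, w1 = window
    t_end = trace.t0 + trace.span
    if w1 < w0 or w0 < trace.t0 - 1e-9 or w1 > t_end + 1e-9:
        raise ValidationError(
            f"window [{w0}, {w1}] outside trace span [{trace.t0}, {t_end}]"
        )
    i0 = int(round((w0 - trace.t0) / trace.sample_period))
    n = trace_sample_count(w1 - w0)
    col = trace.samples[i0 : i0 + n, CHANNELS[channel]]
    return float(np.sum(col) * trace.sample_period)


def normalize_profile(profile: np.ndarray, trace: IntensityTrace) -> np.ndarray:
    """Divide a radial profile by the I_zero dose over the shutter window."""
    dose = integrated_dose(trace, "I_zero", trace.shutter_window)
    if dose <= 0:
        raise ValidationError("I_zero dose over the shutter window is zero (dumped beam?)")
    return np.asarray(profile, dtype=float) / dose


def subtract_buffer(sample: np.ndarray, buffer: np.ndarray) -> np.ndarray:
    """Elementwise sample - buffer of two normalized profiles."""
    sample = np.asarray(sample, dtype=float)
    buffer = np.asarray(buffer, dtype=float)
    if sample.shape != buffer.shape:
        raise ValidationError(
            f"profile length mismatch: {sample.shape} vs {buffer.shape}"
        )
    return sample - buffer


def radial_average(image: np.ndarray, center: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Mean intensity per integer-radius annulus (annulus k: k <= r < k+1).

    ``center`` is (x, y) in pixel coordinates; defaults to the image
    centre.  Returns a 1D profile indexed by radius in (binned) pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("radial_average expects a 2D image")
    h, w = img.shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValidationError(f"center {center} outside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.floor(np.hypot(xx - cx, yy - cy)).astype(int)
    counts = np.bincount(r.ravel())
    sums = np.bincount(r.ravel(), weights=img.ravel())
    return sums / counts


@dataclass
class RunDefinition:
    """One Collect-tab run: a single sample's exposure and robot program."""

    prefix: str = "run"
    directory: str = "."
    binning: int = 8
    well: Optional[WellAddress] = None
    aspiration_rate: float = 10.0
    volume: float = 15.0
    times: Sequence[float] = (1.0,)
    steps: Sequence[RobotMethod] = (RobotMethod.EXPOSE,)


class RunBook:
    """The Collect tab's bank of run tabs (capacity from config, default 16)."""

    def __init__(self, max_tabs: Optional[int] = None):
        self.max_tabs = SimulationConfig().max_run_tabs if max_tabs is None else max_tabs
        self.runs: list[RunDefinition] = []

    def add(self, run: RunDefinition) -> int:
        if len(self.runs) >= self.max_tabs:
            raise ValidationError(f"all {self.max_tabs} run tabs are in use")
        self.runs.append(run)
        return len(self.runs)


@dataclass
class ExposureRecord:
    """Provenance of one recorded image."""

    image_path: str
    trace_path: str
    snapshot_path: str
    well: Optional[WellAddress]
    exposure_time: float
    binning: int
    integrated_dose: dict
    bubble: Optional[BubbleScore]
    start_time: float
    #: float detector image before 16-bit quantization (in-memory only)
    image: Optional[np.ndarray] = None
    #: the full intensity trace (also written to trace_path)
    trace: Optional[IntensityTrace] = None

    def key(self) -> tuple:
        """Content identity, independent of the output directory."""
        bub = None
        if self.bubble is not None:
            bub = (round(self.bubble.variance, 6), self.bubble.label.value)
        return (
            Path(self.image_path).name,
            Path(self.trace_path).name,
            Path(self.snapshot_path).name,
            str(self.well),
            self.exposure_time,
            self.binning,
            tuple(sorted((k, round(v, 9)) for k, v in self.integrated_dose.items())),
            bub,
            round(self.start_time, 9),
        )


def render_cell_frame(cell: SampleCellState, camera: CameraConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Simulated video snapshot of the cell: clean, bubbled, or empty/meniscus."""
    shape = (camera.frame_height, camera.frame_width)
    roi_cx = camera.roi_x0 + camera.roi_width / 2.0
    roi_cy = camera.roi_y0 + camera.roi_height / 2.0
    bubbles = ()
    meniscus = None
    if cell.bubble_present:
        bubbles = (((roi_cx, roi_cy), camera.bubble_radius, camera.bubble_rim_contrast),)
    elif cell.contents is CellContents.EMPTY:
        meniscus = int(roi_cy)
    return synth_frame(
        shape=shape,
        background=camera.background,
        noise_sd=camera.noise_sd,
        bubbles=bubbles,
        meniscus_row=meniscus,
        seed=rng,
    )


def camera_roi(camera: CameraConfig) -> ROI:
    return ROI(camera.roi_x0, camera.roi_y0, camera.roi_width, camera.roi_height)


def write_image(image: np.ndarray, path) -> None:
    """Write a detector image as 16-bit greyscale PNG."""
    arr = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)


def write_trace(trace: IntensityTrace, path) -> None:
    """TSV with header: time_s, i_mono, i_zero, i_end, shutter (0/1)."""
    t = trace.times()
    mask = trace.shutter_mask().astype(int)
    with open(path, "w") as fh:
        fh.write("time_s\ti_mono\ti_zero\ti_end\tshutter\n")
        for i in range(len(trace.samples)):
            s = trace.samples[i]
            fh.write(f"{t[i]:.4f}\t{s[0]:.6f}\t{s[1]:.6f}\t{s[2]:.6f}\t{mask[i]}\n")


def read_trace(path) -> IntensityTrace:
    """Read a TSV trace written by :func:`write_trace`."""
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    data = np.atleast_2d(data)
    t = data[:, 0]
    samples = data[:, 1:4]
    shutter = data[:, 4].astype(bool)
    if shutter.any():
        idx = np.nonzero(shutter)[0]
        window = (float(t[idx[0]]), float(t[idx[-1]] + TRACE_PERIOD))
    else:
        window = (float(t[0]), float(t[0]))
    period = float(t[1] - t[0]) if len(t) > 1 else TRACE_PERIOD
    return IntensityTrace(sample_period=period, t0=float(t[0]), samples=samples,
                          shutter_window=window)


def _pause_until_clear(beamline: Beamline, window: float, status=None) -> bool:
    """Advance the clock (1 s polls) until [now, now+window) is dump-free.

    Returns True if a pause actually happened.  ``status`` (an
    OperationStatus) is flipped RUNNING -> PAUSED -> RUNNING around the wait.
    """
    beam, clock = beamline.beam, beamline.clock
    paused = False

    def clear_at(t):
        return bool(beam.stored(t)) and beam.next_conflict(t, t + window) is None

    while not clear_at(clock.now):
        if not paused:
            paused = True
            if status is not None and status.state.value == "RUNNING":
                status.transition("PAUSED", "waiting for stored beam")
        clock.advance(1.0)
    if paused and status is not None and status.state.value == "PAUSED":
        status.transition("RUNNING", "beam restored; resuming")
    return paused


def run_expose(
    times: Sequence[float],
    run: RunDefinition,
    beamline: Beamline,
    status=None,
    log: Optional[list] = None,
    exposure_index_offset: int = 0,
) -> list[ExposureRecord]:
    """Execute one Expose step: up to five exposures in rapid succession.

    Before each exposure a video snapshot is taken and scored for bubbles;
    the shutter-open duration equals the requested time exactly on the
    simulated clock.  If a beam dump would overlap an exposure (or is in
    progress), the operation pauses, polls each simulated second, and
    repeats that exposure once the beam is back — every requested image is
    eventually produced.
    """
    times = list(times)
    if not (1 <= len(times) <= MAX_EXPOSURES):
        raise ValidationError(
            f"{len(times)} exposure times requested; must be 1-{MAX_EXPOSURES}"
        )
    if any(t <= 0 for t in times):
        raise ValidationError("exposure times must be positive")
    cfg = beamline.config
    det_cfg = cfg.detector
    if run.binning != det_cfg.binning:
        det_cfg = type(det_cfg)(**{**det_cfg.__dict__, "binning": run.binning})
    out_dir = Path(run.directory)
    out_dir.mkdir(parents=True, exist_ok=True)
    pad = cfg.trace_pad
    records = []
    for i, duration in enumerate(times):
        idx = exposure_index_offset + i
        _pause_until_clear(beamline, duration + 2 * pad, status)
        start_time = beamline.clock.now

        frame = render_cell_frame(beamline.cell, cfg.camera, beamline.rng)
        snap_path = out_dir / make_filename(run.prefix, run.well, idx, "snapshot")
        save_frame(frame, snap_path)
        score = detect(frame, camera_roi(cfg.camera))
        score = BubbleScore(score.variance, score.label, str(snap_path))

        # padded trace around the shutter window
        t_trace0 = beamline.clock.now
        beamline.clock.advance(pad)
        t_open = beamline.clock.now
        beamline.shutter.open(t_open)
        beamline.clock.advance(duration)
        t_close = beamline.clock.now
        beamline.shutter.close(t_close)
        beamline.clock.advance(pad)

        n = trace_sample_count(beamline.clock.now - t_trace0)
        t_samples = t_trace0 + np.arange(n) * TRACE_PERIOD
        chans = beamline.ion_chambers(t_samples)
        samples = np.stack(chans, axis=1)
        trace = IntensityTrace(
            sample_period=TRACE_PERIOD,
            t0=t_trace0,
            samples=samples,
            shutter_window=(t_open, t_close),
        )

        # detector dose: beam intensity integrated over the open window, on
        # the same sampling grid as the trace so normalization is exact
        grid = t_open + np.arange(trace_sample_count(duration)) * TRACE_PERIOD
        dose_beam = float(np.sum(beamline.beam.intensity(grid)) * TRACE_PERIOD)
        scene = scattering_scene(beamline.cell, det_cfg)
        image = type(beamline.detector)(det_cfg, beamline.rng).integrate(scene, dose_beam)

        image_path = out_dir / make_filename(run.prefix, run.well, idx, "image")
        trace_path = out_dir / make_filename(run.prefix, run.well, idx, "trace")
        write_image(image, image_path)
        write_trace(trace, trace_path)

        doses = {
            ch: integrated_dose(trace, ch, trace.shutter_window) for ch in CHANNELS
        }
        record = ExposureRecord(
            image_path=str(image_path),
            trace_path=str(trace_path),
            snapshot_path=str(snap_path),
            well=run.well,
            exposure_time=duration,
            binning=det_cfg.binning,
            integrated_dose=doses,
            bubble=score,
            start_time=start_time,
            image=image,
            trace=trace,
        )
        records.append(record)
        if log is not None:
            log.append(
                LogEntry(
                    time=beamline.clock.now,
                    step=f"EXPOSE {duration}s well={run.well}",
                    files=[image_path.name, trace_path.name, snap_path.name],
                    bubble_label=score.label.value,
                    bubble_variance=score.variance,
                    trace_file=trace_path.name,
                )
            )
        beamline.clock.advance(cfg.exposure_overhead)
    return records
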