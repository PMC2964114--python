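"""Deterministic, seedable simulators for the beamline devices.

Everything runs on a discrete-event clock: one simulated second costs no
wall-clock time, and every stochastic draw (bubble introduction, bubble
clearing, detector readout noise, camera noise) flows from a single
injected ``numpy`` generator, so a (config, seed) pair reproduces a run
bit-for-bit.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import (
    BeamConfig,
    DetectorConfig,
    IonChamberConfig,
    RobotConfig,
    SimulationConfig,
)
from .errors import DeviceFault, ValidationError
from .wells import WellAddress


class RobotMethod(enum.Enum):
    """The seven pre-programmed liquid-handling actions plus Expose.

    EXPOSE is a scheduling placeholder: it is dispatched to the expose
    operation, never to the robot simulator itself.
    """

    LOAD_SAMPLE = "LOAD_SAMPLE"
    LOAD_WATER = "LOAD_WATER"
    WASH_WATER = "WASH_WATER"
    EMPTY_TO_WELL = "EMPTY_TO_WELL"
    EMPTY_TO_GARBAGE = "EMPTY_TO_GARBAGE"
    WASH_SOAP = "WASH_SOAP"
    BUBBLE = "BUBBLE"
    EXPOSE = "EXPOSE"


class CellContents(enum.Enum):
    EMPTY = "EMPTY"
    SAMPLE = "SAMPLE"
    WATER = "WATER"


class SimClock:
    """Monotonic discrete-event clock.

    Time is held as integer microseconds so that repeated advances never
    accumulate floating-point error: an exposure commanded for 5 s is
    exactly 5 000 000 clock ticks long, which keeps shutter bookkeeping and
    trace grids exact and runs reproducible.
    """

    RESOLUTION = 1e-6  # seconds per tick

    def __init__(self, t0: float = 0.0):
        self._ticks = round(t0 / self.RESOLUTION)

    @property
    def now(self) -> float:
        return self._ticks * self.RESOLUTION

    @property
    def now_ticks(self) -> int:
        return self._ticks

    def advance(self, dt: float) -> float:
        ticks = round(dt / self.RESOLUTION)
        if ticks < 0:
            raise ValidationError("clock cannot run backwards")
        self._ticks += ticks
        return self.now


class Shutter:
    """Experimental X-ray shutter with an exact transition log."""

    def __init__(self):
        self.is_open = False
        self.transition_log: list[tuple[float, bool]] = []

    def _log(self, t: float, state: bool):
        if self.transition_log and t < self.transition_log[-1][0]:
            raise ValidationError("shutter transitions must be time-ordered")
        self.transition_log.append((t, state))

    def open(self, t: float):
        if self.is_open:
            raise DeviceFault("shutter already open")
        self.is_open = True
        self._log(t, True)

    def close(self, t: float):
        if not self.is_open:
            raise DeviceFault("shutter already closed")
        self.is_open = False
        self._log(t, False)

    def open_intervals(self) -> list[tuple[float, float]]:
        """Closed shutter-open intervals reconstructed from the log."""
        out, opened = [], None
        for t, state in self.transition_log:
            if state:
                opened = t
            elif opened is not None:
                out.append((opened, t))
                opened = None
        return out

    def total_open_time(self) -> float:
        return sum(b - a for a, b in self.open_intervals())


class Beam:
    """Storage-ring beam with sinusoidal drift and scheduled dumps."""

    def __init__(self, config: BeamConfig):
        self.config = config

    def stored(self, t) -> bool | np.ndarray:
        t = np.asarray(t, dtype=float)
        up = np.ones(t.shape, dtype=bool)
        for start, duration in self.config.dump_schedule:
            up &= ~((t >= start) & (t < start + duration))
        return bool(up) if up.ndim == 0 else up

    def drift_factor(self, t):
        t = np.asarray(t, dtype=float)
        c = self.config
        out = 1.0 + c.drift_amplitude * np.sin(2 * np.pi * t / c.drift_period)
        return float(out) if out.ndim == 0 else out

    def intensity(self, t):
        """Intensity at time(s) t: nominal x drift, zero while dumped."""
        t = np.asarray(t, dtype=float)
        out = np.asarray(
            self.config.nominal_intensity * self.drift_factor(t) * self.stored(t),
            dtype=float,
        )
        return float(out) if out.ndim == 0 else out

    def restore_time(self, t: float) -> float:
        """End of the dump covering t (t itself if the beam is stored)."""
        for start, duration in self.config.dump_schedule:
            if start <= t < start + duration:
                return start + duration
        return t

    def next_conflict(self, t0: float, t1: float) -> Optional[tuple[float, float]]:
        """Earliest dump interval overlapping [t0, t1), or None."""
        hits = [
            (s, d)
            for s, d in self.config.dump_schedule
            if s < t1 and s + d > t0
        ]
        return min(hits) if hits else None


@dataclass
class SampleCellState:
    """Shared 2 mm sample cell fed by the loading needle."""

    contents: CellContents = CellContents.EMPTY
    source_well: Optional[WellAddress] = None
    bubble_present: bool = False
    #: fraction of the previous sample's scattering still contributing
    contamination: float = 0.0


def scattering_scene(cell: SampleCellState, config: DetectorConfig) -> np.ndarray:
    """Noise-free scattering rate per unbinned pixel (dimensionless).

    A dilute particle scatters into a radially decaying, centro-symmetric
    profile; water and the empty cell give flat backgrounds.  The profile is
    a generic sharply decaying form-factor stand-in — only relative
    behaviour (normalization, buffer subtraction, carry-over) is meaningful,
    not absolute SAXS physics.
    """
    n = config.base_pixels
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(xx - c, yy - c)
    r0 = n / 8.0
    particle = config.sample_amplitude / (1.0 + (r / r0) ** 2) ** 2
    if cell.contents is CellContents.SAMPLE:
        scene = config.water_background + particle
    elif cell.contents is CellContents.WATER:
        scene = config.water_background + cell.contamination * particle
    else:
        scene = config.empty_background + cell.contamination * particle
    return np.asarray(scene, dtype=float) + np.zeros((n, n))


class Detector:
    """CCD simulator: pre-digitization hardware binning, one readout per binned pixel."""

    def __init__(self, config: DetectorConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng

    def integrate(self, scene: np.ndarray, dose: float) -> np.ndarray:
        """Accumulate ``scene`` x ``dose`` then read out binned pixels.

        ``dose`` is the integral of beam intensity over the shutter-open,
        beam-stored part of the exposure.  Binning sums bin x bin blocks of
        accumulated charge *before* digitization; the readout then adds a
        single zero-mean Gaussian draw (sd ``readout_noise_sd``) plus a
        constant offset per binned pixel, and digitization clamps at zero.
        """
        cfg = self.config
        n, b = cfg.base_pixels, cfg.binning
        if n % b != 0:
            raise ValidationError(f"base_pixels {n} not divisible by binning {b}")
        scene = np.asarray(scene, dtype=float)
        if scene.shape != (n, n):
            raise ValidationError(f"scene shape {scene.shape} != ({n}, {n})")
        charge = scene * float(dose)
        m = n // b
        binned = charge.reshape(m, b, m, b).sum(axis=(1, 3))
        if cfg.readout_noise_sd > 0:
            binned = binned + self.rng.normal(0.0, cfg.readout_noise_sd, (m, m))
        binned = binned + cfg.readout_offset
        return np.clip(binned, 0.0, None)


def detector_integrate(
    duration: float,
    config: DetectorConfig,
    shutter: Shutter,
    beam: Beam,
    cell: SampleCellState,
    rng: np.random.Generator,
    t0: float = 0.0,
    sample_period: float = 0.0005,
) -> np.ndarray:
    """Convenience single-shot integration over [t0, t0 + duration).

    The effective dose is the beam intensity integrated over the overlap of
    the shutter-open intervals and the beam-stored intervals within the
    window, evaluated at the intensity-trace resolution.
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    n = int(round(duration / sample_period))
    times = t0 + np.arange(n) * sample_period
    open_mask = np.zeros(n, dtype=bool)
    for a, b in shutter.open_intervals():
        open_mask |= (times >= a) & (times < b)
    if shutter.is_open and shutter.transition_log:
        # window may extend past the last logged open without a close yet
        last_t, last_state = shutter.transition_log[-1]
        if last_state:
            open_mask |= times >= last_t
    dose = float(np.sum(beam.intensity(times) * open_mask) * sample_period)
    return Detector(config, rng).integrate(scattering_scene(cell, config), dose)


def ion_chamber_read(t, beam: Beam, cell: SampleCellState, config: IonChamberConfig):
    """(I_mono, I_zero, I_end) at time(s) t.

    All three channels scale with the instantaneous beam intensity through
    fixed gains; I_end sits behind the sample cell and is attenuated by its
    contents.
    """
    base = beam.intensity(t)
    trans = {
        CellContents.SAMPLE: config.transmission_sample,
        CellContents.WATER: config.transmission_water,
        CellContents.EMPTY: config.transmission_empty,
    }[cell.contents]
    return (
        config.gain_mono * base,
        config.gain_zero * base,
        config.gain_end * trans * base,
    )


RATE_RANGE = (0.0, 20.0)   # aspiration rate, ul/s
VOLUME_RANGE = (1.0, 20.0)  # ul


class Robot:
    """Simulated liquid-handling robot driving the shared sample cell."""

    def __init__(self, config: RobotConfig, cell: SampleCellState, clock: SimClock,
                 rng: np.random.Generator, command_log: Optional[list] = None):
        self.config = config
        self.cell = cell
        self.clock = clock
        self.rng = rng
        self.command_log = command_log if command_log is not None else []
        self._calls = 0

    def execute(
        self,
        method: RobotMethod,
        well: Optional[WellAddress] = None,
        rate: float = 10.0,
        volume: float = 15.0,
    ) -> tuple[float, SampleCellState]:
        """Run one pre-programmed method; returns (duration s, new cell state)."""
        if method is RobotMethod.EXPOSE:
            raise ValidationError("EXPOSE is handled by the expose operation, not the robot")
        if not (RATE_RANGE[0] <= rate <= RATE_RANGE[1]):
            raise ValidationError(f"aspiration rate {rate} ul/s outside {RATE_RANGE}")
        if not (VOLUME_RANGE[0] <= volume <= VOLUME_RANGE[1]):
            raise ValidationError(f"volume {volume} ul outside {VOLUME_RANGE}")
        if method in (RobotMethod.LOAD_SAMPLE, RobotMethod.EMPTY_TO_WELL) and well is None:
            raise ValidationError(f"{method.value} requires a well address")
        if self.config.fail_on_call is not None and self._calls == self.config.fail_on_call:
            self._calls += 1
            raise DeviceFault(f"robot failed to complete {method.value}")
        self._calls += 1

        cell = self.cell
        if method is RobotMethod.LOAD_SAMPLE:
            if cell.contents is not CellContents.EMPTY:
                raise DeviceFault("cannot load: cell not empty (empty or wash first)")
            cell.contents = CellContents.SAMPLE
            cell.source_well = well
            cell.bubble_present = bool(self.rng.random() < self.config.p_bubble)
        elif method is RobotMethod.LOAD_WATER:
            if cell.contents is not CellContents.EMPTY:
                raise DeviceFault("cannot load: cell not empty (empty or wash first)")
            cell.contents = CellContents.WATER
            cell.source_well = None
        elif method in (RobotMethod.WASH_WATER, RobotMethod.WASH_SOAP):
            cell.contents = CellContents.EMPTY
            cell.source_well = None
            cell.contamination = 0.0
            cell.bubble_present = False
        elif method in (RobotMethod.EMPTY_TO_WELL, RobotMethod.EMPTY_TO_GARBAGE):
            if cell.contents is CellContents.SAMPLE:
                cell.contamination = self.config.carryover_fraction
            elif cell.contents is CellContents.WATER:
                cell.contamination *= 0.1  # water partially rinses residue
            cell.contents = CellContents.EMPTY
            cell.source_well = None
            cell.bubble_present = False
        elif method is RobotMethod.BUBBLE:
            self.bubble_routine()
            return (self.config.durations["BUBBLE"], cell)

        duration = self.config.durations[method.value]
        self.clock.advance(duration)
        self.command_log.append((self.clock.now, method.value, str(well) if well else ""))
        return (duration, cell)

    def bubble_routine(self) -> int:
        """Sweep the needle back and forth exactly four times to dislodge bubbles.

        Each pass independently clears a present bubble with probability
        ``bubble_clear_prob``; multiple/small bubbles are thus not always
        removed.  Returns the pass count (always 4).
        """
        if self.cell.contents is CellContents.EMPTY:
            raise DeviceFault("Bubble routine requires a loaded cell")
        passes = 4
        for _ in range(passes):
            if self.cell.bubble_present and self.rng.random() < self.config.bubble_clear_prob:
                self.cell.bubble_present = False
        self.clock.advance(self.config.durations["BUBBLE"])
        self.command_log.append((self.clock.now, "BUBBLE", ""))
        return passes


class Beamline:
    """One simulated bench: clock plus every device, sharing a single RNG."""

    def __init__(self, config: Optional[SimulationConfig] = None, seed: int = 0):
        self.config = config or SimulationConfig()
        self.rng = np.random.default_rng(seed)
        self.clock = SimClock()
        self.shutter = Shutter()
        self.beam = Beam(self.config.beam)
        self.cell = SampleCellState()
        self.detector = Detector(self.config.detector, self.rng)
        self.command_log: list[tuple[float, str, str]] = []
        self.robot = Robot(self.config.robot, self.cell, self.clock, self.rng,
                           self.command_log)

    def ion_chambers(self, t):
        return ion_chamber_read(t, self.beam, self.cell, self.config.chambers)

    def device_names(self) -> tuple[str, ...]:
        return ("shutter", "detector", "robot", "ionchambers", "beam")
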