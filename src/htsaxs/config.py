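"""Configuration for the simulated beamline.

Every tunable of the device simulators lives here as a plain dataclass so a
whole bench setup can be dumped to / loaded from YAML and injected into
tests.  Units are SI seconds for times, arbitrary intensity units for beam
and detector signal, and pixels for geometry.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ValidationError

#: Hard capacity of the Collect tab: number of run tabs available for
#: pre-programmed single-sample acquisitions.
DEFAULT_MAX_RUN_TABS = 16


@dataclass
class BeamConfig:
    """Storage-ring beam: nominal flux, slow multiplicative drift, dumps.

    ``drift_amplitude`` is the relative amplitude of a sinusoidal intensity
    drift with period ``drift_period`` seconds; real sources drift by more
    than 1e-3 over the minutes separating a sample from its blank, which is
    the entire reason exposures are normalized to ion-chamber dose.
    ``dump_schedule`` lists (start, duration) intervals during which no beam
    is stored and all intensities read zero.
    """

    nominal_intensity: float = 1000.0
    drift_amplitude: float = 0.0
    drift_period: float = 60.0
    dump_schedule: tuple = ()

    def __post_init__(self):
        if self.drift_amplitude < 0:
            raise ValidationError("drift_amplitude must be >= 0")
        if self.drift_period <= 0:
            raise ValidationError("drift_period must be > 0")


@dataclass
class DetectorConfig:
    """CCD with n x n hardware binning.

    Binning happens before digitization, so each *binned* pixel receives a
    single readout-noise draw (sd ``readout_noise_sd``) plus a constant
    ``readout_offset``; higher binning therefore spreads one readout event
    over a larger detector area.  ``base_pixels`` is the unbinned side
    length of the simulated chip (desk-scale default, far smaller than a
    real 165 mm CCD).
    """

    binning: int = 8
    base_pixels: int = 64
    readout_noise_sd: float = 5.0
    readout_offset: float = 10.0
    # scattering scene model (dimensionless rates, multiplied by beam dose)
    sample_amplitude: float = 0.2
    water_background: float = 0.02
    empty_background: float = 0.005

    def __post_init__(self):
        if self.binning not in (2, 4, 8):
            raise ValidationError(f"binning must be 2, 4 or 8, got {self.binning}")
        if self.base_pixels % self.binning != 0:
            raise ValidationError(
                f"base_pixels {self.base_pixels} not divisible by binning {self.binning}"
            )


@dataclass
class IonChamberConfig:
    """Fixed per-channel gains for I_mono, I_zero and I_end.

    I_mono sits just after the monochromator, I_zero immediately upbeam of
    the sample, and I_end is the PIN diode in the beam stop, so I_end is
    additionally attenuated by whatever is in the sample cell.
    """

    gain_mono: float = 1.2
    gain_zero: float = 1.0
    gain_end: float = 0.6
    transmission_sample: float = 0.80
    transmission_water: float = 0.85
    transmission_empty: float = 1.0


@dataclass
class RobotConfig:
    """Liquid-handling robot timings and stochastic sample behaviour.

    Only the wash duration (~3 min) is an established figure; the other
    durations are plausible defaults and freely overridable.  ``p_bubble``
    is the probability that loading a sample introduces a bubble;
    ``bubble_clear_prob`` the per-pass success of the mechanical Bubble
    routine (bubbles are not always successfully removed).
    ``fail_on_call`` injects a hard robot fault on the Nth execute() call
    (0-based) for fault-recovery testing; ``carryover_fraction`` is the
    residue left in the cell after emptying a sample without washing.
    """

    durations: dict = field(
        default_factory=lambda: {
            "LOAD_SAMPLE": 30.0,
            "LOAD_WATER": 20.0,
            "WASH_WATER": 180.0,
            "EMPTY_TO_WELL": 20.0,
            "EMPTY_TO_GARBAGE": 15.0,
            "WASH_SOAP": 240.0,
            "BUBBLE": 15.0,
        }
    )
    p_bubble: float = 0.1
    bubble_clear_prob: float = 0.7
    carryover_fraction: float = 0.05
    fail_on_call: Optional[int] = None


@dataclass
class CameraConfig:
    """Sample-cell video camera and the beam-footprint ROI used for bubble checks."""

    frame_height: int = 120
    frame_width: int = 160
    roi_x0: int = 60
    roi_y0: int = 40
    roi_width: int = 40
    roi_height: int = 40
    background: float = 60.0
    noise_sd: float = 2.0
    bubble_radius: float = 12.0
    bubble_rim_contrast: float = 150.0


@dataclass
class SimulationConfig:
    """Aggregate configuration for one simulated bench."""

    beam: BeamConfig = field(default_factory=BeamConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    chambers: IonChamberConfig = field(default_factory=IonChamberConfig)
    robot: RobotConfig = field(default_factory=RobotConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    #: seconds of intensity trace recorded on each side of the shutter window
    trace_pad: float = 0.05
    #: per-exposure overhead (detector readout etc.), seconds
    exposure_overhead: float = 1.0
    max_run_tabs: int = DEFAULT_MAX_RUN_TABS

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        cfg = cls()
        sections = {
            "beam": BeamConfig,
            "detector": DetectorConfig,
            "chambers": IonChamberConfig,
            "robot": RobotConfig,
            "camera": CameraConfig,
        }
        for key, klass in sections.items():
            if key in raw:
                sub = dict(raw[key])
                if key == "beam" and "dump_schedule" in sub:
                    sub["dump_schedule"] = tuple(tuple(x) for x in sub["dump_schedule"])
                setattr(cfg, key, klass(**sub))
        for key in ("trace_pad", "exposure_overhead", "max_run_tabs"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg
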