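"""Oxygen-level calibration and rate estimation for hypoxic flux assays.

Under ambient hypoxia the oxygen tension in the transient microchamber sits
close to zero, so OCR values computed against a normoxic calibration are
badly biased.  The instrument workflow adds sodium-sulfite reference wells:
sulfite chemically scavenges all dissolved oxygen and pins the sensor at
its true zero-O2 reading.  This module implements a transparent version of
that workflow:

* a two-anchor affine calibration mapping raw sensor signal to kPa, fixed
  by the ambient set point (pre-assay plateau signal) and the sulfite zero,
* a diffusion-corrected rate estimator: within each measure phase the
  microchamber obeys dC/dt = kd (C_amb - C) - r / (V alpha), so an OLS fit
  of level against time over the first half of the phase yields
  r = V alpha (kd (C_amb - C_mean) - slope),
* the percent-suppression statistic used to compare normoxic and hypoxic
  rates.

Oxygen is carried in kPa internally; percent O2 converts at a configurable
barometric pressure (101.325 kPa default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError, ValidationError
from .flux_core import (
    InjectionSchedule,
    KineticTrace,
    RateMeasurement,
)

__all__ = [
    "LevelCycle",
    "LevelTrace",
    "OxygenCalibration",
    "calibrate_zero",
    "estimate_rates_from_levels",
    "percent_suppression",
    "percent_o2_to_kpa",
    "read_level_table",
    "write_level_table",
]

BAROMETRIC_KPA = 101.325


def percent_o2_to_kpa(percent: float, barometric_kpa: float = BAROMETRIC_KPA) -> float:
    """Convert an ambient %O2 to partial pressure in kPa."""
    return percent / 100.0 * barometric_kpa


@dataclass(frozen=True)
class LevelCycle:
    """Sampled sensor levels within one measure phase.

    ``times_min`` are absolute assay times (strictly increasing);
    ``signal`` is the raw sensor reading (or kPa if already calibrated).
    """

    index: int
    times_min: np.ndarray
    signal: np.ndarray
    phase: str = "measure"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape:
            raise ValidationError("times and signal must have matching length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"cycle {self.index}: sample times not increasing")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "signal", s)


@dataclass
class LevelTrace:
    """Per-well raw level samples, the raw counterpart of a KineticTrace."""

    well_id: str
    group: str
    cycles: list[LevelCycle]

    def __post_init__(self) -> None:
        self.cycles = sorted(self.cycles, key=lambda c: c.index)
        seen = set()
        for c in self.cycles:
            if c.index in seen:
                raise ValidationError(
                    f"well {self.well_id}: duplicate level cycle {c.index}"
                )
            seen.add(c.index)


@dataclass(frozen=True)
class OxygenCalibration:
    """Affine raw-signal -> kPa mapping anchored at ambient and at zero O2."""

    ambient_o2_kpa: float
    zero_signal: float
    ambient_signal: float

    def __post_init__(self) -> None:
        if self.ambient_signal == self.zero_signal:
            raise CalibrationError("ambient anchor signal equals zero-O2 signal")

    def signal_to_kpa(self, signal):
        return (
            self.ambient_o2_kpa
            * (np.asarray(signal, dtype=float) - self.zero_signal)
            / (self.ambient_signal - self.zero_signal)
        )

    @classmethod
    def identity(cls, ambient_o2_kpa: float) -> "OxygenCalibration":
        """Calibration for data already expressed in kPa."""
        return cls(
            ambient_o2_kpa=ambient_o2_kpa,
            zero_signal=0.0,
            ambient_signal=ambient_o2_kpa,
        )


def calibrate_zero(
    sulfite_wells: Sequence[LevelTrace],
    schedule: InjectionSchedule,
    ambient_o2_kpa: float,
) -> OxygenCalibration:
    """Two-anchor calibration from sodium-sulfite zero-reference wells.

    The zero anchor is the pooled median signal over the last three
    post-sulfite measure phases of every sulfite well; the ambient anchor
    is the pooled median of the pre-sulfite plateau (sulfite wells carry no
    cells, so before the injection they sit at the ambient set point).
    """
    if not sulfite_wells:
        raise CalibrationError("need at least one sulfite well")
    try:
        sulfite_ev = next(
            e for e in schedule if e.name.upper() in ("SULFITE", "NA2SO3")
        )
    except StopIteration:
        raise ConfigurationError("schedule has no SULFITE injection")

    pre: list[np.ndarray] = []
    zero: list[np.ndarray] = []
    for tr in sulfite_wells:
        post = [c for c in tr.cycles if c.index > sulfite_ev.after_index]
        if len(post) < 3:
            raise CalibrationError(
                f"well {tr.well_id}: need >= 3 post-sulfite cycles, got {len(post)}"
            )
        pre.extend(c.signal for c in tr.cycles if c.index <= sulfite_ev.after_index)
        zero.extend(c.signal for c in post[-3:])
    if not pre:
        raise CalibrationError("no pre-sulfite plateau cycles for the ambient anchor")

    ambient_signal = float(np.median(np.concatenate(pre)))
    zero_signal = float(np.median(np.concatenate(zero)))
    if zero_signal >= ambient_signal:
        raise CalibrationError(
            f"sulfite signal ({zero_signal:.3g}) is not below the ambient plateau "
            f"({ambient_signal:.3g}); sensor polarity or injection failure?"
        )
    return OxygenCalibration(
        ambient_o2_kpa=ambient_o2_kpa,
        zero_signal=zero_signal,
        ambient_signal=ambient_signal,
    )


def estimate_rates_from_levels(
    levels: LevelTrace,
    calibration: OxygenCalibration,
    chamber: "MicrochamberModel",
) -> KineticTrace:
    """Diffusion-corrected OCR estimates, one per measure phase.

    Within a measure phase, oxygen in the microchamber follows
    ``dC/dt = kd (C_amb - C) - r / (V alpha)``; with the consumption rate
    approximately constant over the short fit window, an ordinary
    least-squares line through the calibrated levels of the first half of
    the phase gives ``r = V alpha (kd (C_amb - C_mean) - slope)``.  The
    first half keeps back-diffusion curvature negligible while retaining
    enough samples.  Phases with fewer than three fit samples yield no rate
    (with a warning).
    """
    v_alpha = chamber.volume_ul * chamber.solubility_pmol_per_ul_kpa
    kd = chamber.kd_per_min
    c_amb = calibration.ambient_o2_kpa

    measurements = []
    for cyc in levels.cycles:
        t = cyc.times_min
        half = t[0] + (t[-1] - t[0]) / 2.0
        mask = t <= half
        if mask.sum() < 3:
            warnings.warn(
                f"well {levels.well_id} cycle {cyc.index}: <3 samples in fit "
                "window, rate skipped",
                stacklevel=2,
            )
            continue
        c = calibration.signal_to_kpa(cyc.signal[mask])
        tt = t[mask]
        slope, _ = np.polyfit(tt, c, 1)
        c_mean = float(np.mean(c))
        ocr = v_alpha * (kd * (c_amb - c_mean) - slope)
        measurements.append(
            RateMeasurement(
                well_id=levels.well_id,
                group=levels.group,
                index=cyc.index,
                time_min=float(np.mean(tt)),
                ocr=float(ocr),
            )
        )
    if len(measurements) < 2:
        raise ValidationError(
            f"well {levels.well_id}: fewer than 2 estimable cycles"
        )
    return KineticTrace(
        well_id=levels.well_id, group=levels.group, measurements=measurements
    )


def percent_suppression(normoxic: float, hypoxic: float) -> float:
    """Percent reduction of a rate under hypoxia: 100 (1 - hypoxic/normoxic)."""
    if normoxic <= 0:
        raise ValidationError("normoxic rate must be positive")
    return 100.0 * (1.0 - hypoxic / normoxic)


# ---------------------------------------------------------------------------
# Level-trace I/O (long format: well, group, cycle, phase, time_min, signal)
# ---------------------------------------------------------------------------


def write_level_table(traces: Mapping[str, LevelTrace], sink, sep: str = ",") -> None:
    rows = []
    for tr in traces.values():
        for cyc in tr.cycles:
            for t, s in zip(cyc.times_min, cyc.signal):
                rows.append(
                    {
                        "well": tr.well_id,
                        "group": tr.group,
                        "cycle": cyc.index,
                        "phase": cyc.phase,
                        "time_min": t,
                        "signal": s,
                    }
                )
    df = pd.DataFrame(rows)
    if hasattr(sink, "write"):
        df.to_csv(sink, sep=sep, index=False)
    else:
        df.to_csv(sink, sep=sep, index=False)


def read_level_table(source, sep: str = ",") -> dict[str, LevelTrace]:
    df = pd.read_csv(source, sep=sep, comment="#")
    required = {"well", "group", "cycle", "time_min", "signal"}
    if not required <= set(df.columns):
        from .errors import FormatError

        raise FormatError(f"level table missing columns: {sorted(required - set(df.columns))}")
    out: dict[str, LevelTrace] = {}
    for well, sub in df.groupby("well", sort=False):
        cycles = []
        for cyc, csub in sub.groupby("cycle", sort=True):
            csub = csub.sort_values("time_min")
            cycles.append(
                LevelCycle(
                    index=int(cyc),
                    times_min=csub["time_min"].to_numpy(),
                    signal=csub["signal"].to_numpy(),
                    phase=str(csub["phase"].iloc[0]) if "phase" in csub else "measure",
                )
            )
        out[str(well)] = LevelTrace(
            well_id=str(well), group=str(sub["group"].iloc[0]), cycles=cycles
        )
    return out
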