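"""Ground-truth simulator for kinetic flux plates.

The simulator produces plates whose per-well traces follow a known
continuous-time rate model, so every downstream statistic can be checked
against truth.  Two output modes are supported:

* **rate mode** — the instrument's processed view: one ECAR/OCR value per
  measure cycle, sampled from the continuous model at the middle of each
  measure phase, with a multiplicative per-well effect and additive
  measurement noise;
* **level mode** — the raw view: oxygen tension sampled within each
  measure phase of a transient microchamber that obeys
  ``dC/dt = kd (C_amb - C) - r(t) / (V alpha)`` and is re-equilibrated to
  ambient by every mix phase.  Sodium-sulfite reference wells are driven
  to zero oxygen for calibration.

Injection kinetics are piecewise: a *step-exponential* response relaxes
the rate toward a new target with time constant tau (tau = 0 switches
instantly), a *transient* response adds a rise-and-decay excursion
``A (1 - exp(-t/tau_r)) exp(-t/tau_d)`` on top of the pre-injection rate,
and a biphasic response is the sum of two transients (the second may be
onset-delayed).  Rates scale linearly with seeded cells per well.

``preset_library`` ships named presets whose true trace levels encode the
group-mean rates printed for human eosinophil and neutrophil assays:
glycolysis stress tests at 1 and 10 mM glucose, the glucose-oxidation run
with early oligomycin, PMA and primed-agonist respiratory bursts, and
matched normoxic/hypoxic mitochondrial stress tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .flux_core import (
    InjectionEvent,
    InjectionSchedule,
    KineticTrace,
    PlateAssay,
    RateMeasurement,
)
from .hypoxia import LevelCycle, LevelTrace

__all__ = [
    "StepResponse",
    "TransientComponent",
    "TransientResponse",
    "ChannelKinetics",
    "RatePreset",
    "NoiseModel",
    "MicrochamberModel",
    "LevelPlate",
    "rate_function",
    "simulate_rate_plate",
    "simulate_level_plate",
    "preset_library",
    "preset_to_dict",
    "preset_from_dict",
]


# ---------------------------------------------------------------------------
# Kinetic building blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepResponse:
    """Relax the rate toward ``target`` with time constant ``tau_min``."""

    target: float
    tau_min: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_min < 0:
            raise ValidationError("tau_min must be >= 0")


@dataclass(frozen=True)
class TransientComponent:
    """One rise-and-decay excursion; ``delay_min`` postpones its onset."""

    amplitude: float
    tau_rise: float
    tau_decay: float
    delay_min: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValidationError("transient time constants must be > 0")
        if self.delay_min < 0:
            raise ValidationError("delay_min must be >= 0")

    def evaluate(self, dt: np.ndarray) -> np.ndarray:
        u = np.asarray(dt, dtype=float) - self.delay_min
        out = np.where(
            u > 0,
            self.amplitude
            * (1.0 - np.exp(-np.maximum(u, 0) / self.tau_rise))
            * np.exp(-np.maximum(u, 0) / self.tau_decay),
            0.0,
        )
        return out


@dataclass(frozen=True)
class TransientResponse:
    """Sum of one or more transient components (two = biphasic)."""

    components: tuple[TransientComponent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if not self.components:
            raise ValidationError("transient response needs >= 1 component")

    def scaled(self, factor: float) -> "TransientResponse":
        return TransientResponse(
            tuple(replace(c, amplitude=c.amplitude * factor) for c in self.components)
        )


Response = StepResponse | TransientResponse | None


@dataclass(frozen=True)
class ChannelKinetics:
    """Baseline rate plus one response per scheduled injection.

    ``responses`` aligns 1:1 with the schedule's events; ``None`` marks an
    injection with no effect on this channel (media control, primer).
    """

    baseline: float
    responses: tuple[Response, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", tuple(self.responses))
        if self.baseline < 0:
            raise ValidationError("baseline rate must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: lognormal per-well effect (mean 1, CV
    ``well_cv``) plus additive Gaussian noise with SD
    ``rel_sd * |value| + abs_sd`` per rate reading and ``signal_sd`` per raw
    level sample.  The same seed always reproduces the same plate."""

    well_cv: float = 0.05
    rel_sd: float = 0.02
    abs_sd: float = 0.5
    signal_sd: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.well_cv, self.rel_sd, self.abs_sd, self.signal_sd) < 0:
            raise ValidationError("noise parameters must be >= 0")

    @classmethod
    def off(cls, seed: int | None = None) -> "NoiseModel":
        return cls(well_cv=0.0, rel_sd=0.0, abs_sd=0.0, signal_sd=0.0, seed=seed)


@dataclass(frozen=True)
class MicrochamberModel:
    """Transient-microchamber physics and assay cadence.

    The effective oxygen capacity ``V alpha`` (volume_ul times
    solubility_pmol_per_ul_kpa) converts a consumption rate in pmol/min to
    a tension decline in kPa/min; ``kd_per_min`` is the back-diffusion
    constant through the chamber walls.  The sensor reading is affine in
    tension: ``signal = signal_zero + signal_gain * C``.
    """

    volume_ul: float = 2.28
    kd_per_min: float = 0.05
    ambient_o2_kpa: float = 19.1
    mix_min: float = 3.0
    measure_min: float = 3.0
    samples_per_measure: int = 10
    solubility_pmol_per_ul_kpa: float = 22.0
    signal_zero: float = 200.0
    signal_gain: float = 40.0

    def __post_init__(self) -> None:
        if min(
            self.volume_ul,
            self.mix_min,
            self.measure_min,
            self.solubility_pmol_per_ul_kpa,
        ) <= 0 or self.kd_per_min < 0 or self.samples_per_measure < 2:
            raise ValidationError("invalid microchamber parameters")

    @property
    def cycle_min(self) -> float:
        return self.mix_min + self.measure_min

    def measurement_time(self, index: int) -> float:
        """Assay time attributed to measure cycle ``index`` (1-based)."""
        return (index - 1) * self.cycle_min + self.mix_min + self.measure_min / 2.0

    def injection_time(self, after_index: int) -> float:
        """Injections fire in the gap after a completed cycle."""
        return after_index * self.cycle_min


@dataclass(frozen=True)
class RatePreset:
    """Named ground truth for a simulated plate.

    ``truth`` records the quantities the preset is built to reproduce as
    ``{name: (value, sem_or_None)}``, with values on the scale of the
    published group means and SEMs the published ones where available.
    """

    name: str
    schedule: InjectionSchedule
    n_cycles: int
    ecar: ChannelKinetics | None = None
    ocr: ChannelKinetics | None = None
    reference_cells: float = 150e3
    ambient_o2_kpa: float = 19.1
    glucose_mm: float = 10.0
    truth: Mapping[str, tuple[float, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ecar is None and self.ocr is None:
            raise ValidationError(f"preset {self.name}: no channel defined")
        for label, ch in (("ecar", self.ecar), ("ocr", self.ocr)):
            if ch is not None and len(ch.responses) != len(self.schedule):
                raise ConfigurationError(
                    f"preset {self.name}: {label} has {len(ch.responses)} responses "
                    f"for {len(self.schedule)} scheduled injections"
                )
        if self.n_cycles <= max((e.after_index for e in self.schedule), default=0):
            raise ValidationError(f"preset {self.name}: schedule exceeds n_cycles")


# ---------------------------------------------------------------------------
# Continuous-time rate model
# ---------------------------------------------------------------------------


def rate_function(
    kinetics: ChannelKinetics,
    injection_times: Sequence[float],
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized evaluator of the true rate r(t) for one channel.

    Responses compose sequentially: each step anchors at the rate reached
    at its injection time; each transient adds its excursion on top of that
    frozen pre-injection rate; a ``None`` response leaves the previous
    segment running.
    """
    if len(injection_times) != len(kinetics.responses):
        raise ConfigurationError("injection_times must align with responses")

    # Segment list: (t_start, r_at_start, response); baseline first.
    segments: list[tuple[float, float, Response]] = [(0.0, kinetics.baseline, None)]

    def _seg_eval(seg, t):
        t0, r0, resp = seg
        dt = np.asarray(t, dtype=float) - t0
        if resp is None:
            return np.full_like(dt, r0, dtype=float)
        if isinstance(resp, StepResponse):
            if resp.tau_min == 0:
                return np.full_like(dt, resp.target, dtype=float)
            return resp.target + (r0 - resp.target) * np.exp(-dt / resp.tau_min)
        total = np.full_like(dt, r0, dtype=float)
        for comp in resp.components:
            total = total + comp.evaluate(dt)
        return total

    for t_i, resp in zip(injection_times, kinetics.responses):
        if resp is None:
            continue  # injection with no effect: previous segment continues
        r_i = float(_seg_eval(segments[-1], np.array([t_i]))[0])
        segments.append((float(t_i), r_i, resp))

    starts = np.array([s[0] for s in segments])

    def r(t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.empty_like(t)
        seg_idx = np.searchsorted(starts, t, side="right") - 1
        for k in range(len(segments)):
            mask = seg_idx == k
            if mask.any():
                out[mask] = _seg_eval(segments[k], t[mask])
        return out[0] if scalar else out

    return r


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGH"
    names = [f"{r}{c}" for r in rows for c in range(1, 13)]
    if n > len(names):
        raise ValidationError("a plate holds at most 96 wells")
    return names[:n]


def _well_rng(seed: int | None, well_index: int) -> np.random.Generator:
    return np.random.default_rng([0 if seed is None else int(seed), well_index])


def _well_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


# ---------------------------------------------------------------------------
# Rate mode
# ---------------------------------------------------------------------------


def simulate_rate_plate(
    preset: RatePreset,
    n_wells: int = 6,
    noise: NoiseModel | None = None,
    cells_per_well: float | None = None,
    chamber: MicrochamberModel | None = None,
    schedule: InjectionSchedule | None = None,
) -> PlateAssay:
    """Simulate processed per-cycle rate traces for ``n_wells`` wells.

    With noise off the measured values equal the continuous model sampled
    at the measurement times exactly.  Well randomness is keyed by
    (seed, well position), so the simulated plate is independent of well
    ordering and identical under an identical seed.
    """
    noise = noise if noise is not None else NoiseModel()
    chamber = chamber or MicrochamberModel(ambient_o2_kpa=preset.ambient_o2_kpa)
    schedule = schedule or preset.schedule
    cells = cells_per_well if cells_per_well is not None else preset.reference_cells
    if cells <= 0:
        raise ValidationError("cells_per_well must be positive")
    scale = cells / preset.reference_cells

    inj_times = [chamber.injection_time(e.after_index) for e in schedule]
    t_meas = np.array(
        [chamber.measurement_time(k) for k in range(1, preset.n_cycles + 1)]
    )
    channel_fns: dict[str, Callable] = {}
    for label, ch in (("ecar", preset.ecar), ("ocr", preset.ocr)):
        if ch is not None:
            channel_fns[label] = rate_function(ch, inj_times)

    traces: dict[str, KineticTrace] = {}
    for w, well in enumerate(_well_names(n_wells)):
        rng = _well_rng(noise.seed, w)
        wf = _well_factor(rng, noise.well_cv)
        values: dict[str, np.ndarray] = {}
        for label, fn in channel_fns.items():
            true = fn(t_meas) * scale
            if wf != 1.0:
                true = true * wf
            if noise.rel_sd > 0 or noise.abs_sd > 0:
                sd = noise.rel_sd * np.abs(true) + noise.abs_sd
                true = true + rng.normal(0.0, 1.0, size=true.shape) * sd
            values[label] = true
        ms = [
            RateMeasurement(
                well_id=well,
                group=preset.name,
                index=k + 1,
                time_min=float(t_meas[k]),
                ecar=float(values["ecar"][k]) if "ecar" in values else None,
                ocr=float(values["ocr"][k]) if "ocr" in values else None,
            )
            for k in range(preset.n_cycles)
        ]
        traces[well] = KineticTrace(well_id=well, group=preset.name, measurements=ms)

    return PlateAssay(
        traces=traces,
        schedule=schedule,
        cells_per_well=cells,
        ambient_o2_percent=100.0 * preset.ambient_o2_kpa / 101.325,
        glucose_mm=preset.glucose_mm,
    )


# ---------------------------------------------------------------------------
# Level mode
# ---------------------------------------------------------------------------


@dataclass
class LevelPlate:
    """Raw level traces for sample wells plus sulfite reference wells."""

    samples: dict[str, LevelTrace]
    sulfite: dict[str, LevelTrace]
    schedule: InjectionSchedule
    sulfite_schedule: InjectionSchedule


SULFITE_TAU_MIN = 0.5  # chemical zeroing time constant after sulfite injection


def _integrate_measure_phase(
    r_fn: Callable,
    factors: np.ndarray,
    t0: float,
    chamber: MicrochamberModel,
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """RK4 integration of chamber O2 over one measure phase for all wells.

    Returns (sample_times, C) with C of shape (n_wells, n_samples).  The
    phase starts at ambient tension (the preceding mix re-equilibrates the
    chamber).  Fixed-step fourth-order integration keeps the result
    bit-reproducible.
    """
    n_samples = chamber.samples_per_measure
    sample_dt = chamber.measure_min / n_samples
    steps_per_sample = max(1, round(sample_dt / dt))
    h = sample_dt / steps_per_sample
    n_steps = n_samples * steps_per_sample  # integrate across the full phase

    # Rates on the half-step grid, shared across wells then scaled per well.
    grid = t0 + np.arange(2 * n_steps + 1) * (h / 2.0)
    r_grid = np.asarray(r_fn(grid), dtype=float)

    v_alpha = chamber.volume_ul * chamber.solubility_pmol_per_ul_kpa
    kd = chamber.kd_per_min
    c_amb = chamber.ambient_o2_kpa

    c = np.full(len(factors), c_amb, dtype=float)
    sample_times = t0 + np.arange(n_samples) * sample_dt
    out = np.empty((len(factors), n_samples))
    sample_i = 0
    for step in range(n_steps):
        if step % steps_per_sample == 0:
            out[:, sample_i] = c
            sample_i += 1
        r0 = r_grid[2 * step] * factors
        rh = r_grid[2 * step + 1] * factors
        r1 = r_grid[2 * step + 2] * factors

        def f(ci, ri):
            return kd * (c_amb - ci) - ri / v_alpha

        k1 = f(c, r0)
        k2 = f(c + 0.5 * h * k1, rh)
        k3 = f(c + 0.5 * h * k2, rh)
        k4 = f(c + h * k3, r1)
        c = c + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        c = np.maximum(c, 0.0)
    return sample_times, out


def simulate_level_plate(
    preset: RatePreset,
    n_wells: int = 6,
    noise: NoiseModel | None = None,
    chamber: MicrochamberModel | None = None,
    cells_per_well: float | None = None,
    n_sulfite_wells: int = 2,
    sulfite_after_index: int = 1,
) -> LevelPlate:
    """Simulate raw oxygen-level traces plus sulfite zero-reference wells.

    Sample wells consume oxygen according to the preset's OCR model;
    cell-free sulfite wells sit at the ambient plateau until the sulfite
    injection, after which their tension decays chemically to zero and is
    not restored by mixing.
    """
    if preset.ocr is None:
        raise ConfigurationError(f"preset {preset.name}: level mode needs an OCR model")
    noise = noise if noise is not None else NoiseModel()
    chamber = chamber or MicrochamberModel(ambient_o2_kpa=preset.ambient_o2_kpa)
    cells = cells_per_well if cells_per_well is not None else preset.reference_cells
    scale = cells / preset.reference_cells

    inj_times = [chamber.injection_time(e.after_index) for e in preset.schedule]
    r_fn = rate_function(preset.ocr, inj_times)

    names = _well_names(n_wells + n_sulfite_wells)
    sample_names = names[:n_wells]
    sulfite_names = names[n_wells:]

    factors = np.array(
        [
            _well_factor(_well_rng(noise.seed, w), noise.well_cv) * scale
            for w in range(n_wells)
        ]
    )
    rngs = [_well_rng(noise.seed, 10_000 + w) for w in range(len(names))]

    def to_signal(c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        s = chamber.signal_zero + chamber.signal_gain * c
        if noise.signal_sd > 0:
            s = s + rng.normal(0.0, noise.signal_sd, size=s.shape)
        return s

    sample_cycles: list[list[LevelCycle]] = [[] for _ in sample_names]
    for k in range(1, preset.n_cycles + 1):
        t0 = (k - 1) * chamber.cycle_min + chamber.mix_min
        times, c = _integrate_measure_phase(r_fn, factors, t0, chamber)
        for w in range(n_wells):
            sample_cycles[w].append(
                LevelCycle(index=k, times_min=times, signal=to_signal(c[w], rngs[w]))
            )

    t_sulfite = chamber.injection_time(sulfite_after_index)
    sulfite_cycles: list[list[LevelCycle]] = [[] for _ in sulfite_names]
    n_samples = chamber.samples_per_measure
    for k in range(1, preset.n_cycles + 1):
        t0 = (k - 1) * chamber.cycle_min + chamber.mix_min
        times = t0 + np.arange(n_samples) * (chamber.measure_min / n_samples)
        if k <= sulfite_after_index:
            c = np.full(n_samples, chamber.ambient_o2_kpa)
        else:
            c = chamber.ambient_o2_kpa * np.exp(
                -(times - t_sulfite) / SULFITE_TAU_MIN
            )
        for j, _ in enumerate(sulfite_names):
            sulfite_cycles[j].append(
                LevelCycle(
                    index=k,
                    times_min=times,
                    signal=to_signal(c, rngs[n_wells + j]),
                )
            )

    samples = {
        name: LevelTrace(well_id=name, group=preset.name, cycles=cycles)
        for name, cycles in zip(sample_names, sample_cycles)
    }
    sulfite = {
        name: LevelTrace(well_id=name, group="sulfite", cycles=cycles)
        for name, cycles in zip(sulfite_names, sulfite_cycles)
    }
    return LevelPlate(
        samples=samples,
        sulfite=sulfite,
        schedule=preset.schedule,
        sulfite_schedule=InjectionSchedule(
            (InjectionEvent("SULFITE", sulfite_after_index, "100 mM"),)
        ),
    )


# ---------------------------------------------------------------------------
# Preset library
# ---------------------------------------------------------------------------


def _schedule(*events: tuple[str, int, str | None]) -> InjectionSchedule:
    return InjectionSchedule(tuple(InjectionEvent(n, a, c) for n, a, c in events))


GLYCO_SCHEDULE = _schedule(
    ("GLUC", 3, None), ("OLIGO", 6, "2.5 uM"), ("2-DG", 9, "100 mM")
)
MITO_SCHEDULE = _schedule(
    ("OLIGO", 3, "2.5 uM"), ("FCCP", 6, "1.5 uM"), ("ROT/AA", 9, "1 uM")
)


def _glyco_preset(
    name: str,
    baseline: float,
    peak: float,
    sem: float,
    glucose_mm: float,
    tau: float = 1.5,
) -> RatePreset:
    """Glycolysis stress test: glucose -> oligomycin -> 2-DG on the ECAR
    channel.  Granulocytes run near glycolytic capacity after glucose, so
    the post-oligomycin target sits only slightly above the post-glucose
    target (minimal glycolytic reserve)."""
    gc_target = peak * 1.06
    return RatePreset(
        name=name,
        schedule=replace(
            GLYCO_SCHEDULE,
            events=(
                InjectionEvent("GLUC", 3, f"{glucose_mm:g} mM"),
                GLYCO_SCHEDULE.events[1],
                GLYCO_SCHEDULE.events[2],
            ),
        ),
        n_cycles=12,
        ecar=ChannelKinetics(
            baseline=baseline,
            responses=(
                StepResponse(peak, tau),
                StepResponse(gc_target, tau),
                StepResponse(baseline * 1.1, tau),
            ),
        ),
        glucose_mm=glucose_mm,
        truth={
            "post_glucose_peak_ecar": (peak, sem),
            "nga": (baseline, None),
            "glycolytic_capacity_ecar": (gc_target, None),
        },
    )


def _sampled_peak_scale(
    kinetics: ChannelKinetics,
    schedule: InjectionSchedule,
    n_cycles: int,
    stimulus_after: int,
    target_peak: float,
    chamber: MicrochamberModel,
) -> ChannelKinetics:
    """Rescale transient amplitudes so the noiseless measured peak at the
    default cadence equals ``target_peak``."""
    inj_times = [chamber.injection_time(e.after_index) for e in schedule]
    t_meas = np.array([chamber.measurement_time(k) for k in range(1, n_cycles + 1)])
    fn = rate_function(kinetics, inj_times)
    post = t_meas[t_meas > chamber.injection_time(stimulus_after)]
    raw_peak = float(np.max(fn(post)))
    factor = (target_peak - kinetics.baseline) / (raw_peak - kinetics.baseline)
    scaled = tuple(
        r.scaled(factor) if isinstance(r, TransientResponse) else r
        for r in kinetics.responses
    )
    return ChannelKinetics(baseline=kinetics.baseline, responses=scaled)


def _agonist_preset(
    name: str,
    baseline: float,
    peak: float,
    sem: float,
    components: Sequence[TransientComponent],
    stimulus: str,
    primer: str | None = None,
    n_post_cycles: int = 24,
    ambient_o2_kpa: float = 19.1,
    extra_truth: Mapping[str, tuple[float, float | None]] | None = None,
) -> RatePreset:
    """Respiratory-burst preset on the OCR channel, scaled so the sampled
    noiseless peak equals the published group-mean peak."""
    if primer is None:
        schedule = _schedule((stimulus, 3, None))
        responses: tuple[Response, ...] = (TransientResponse(tuple(components)),)
        stim_after = 3
    else:
        schedule = _schedule((primer, 3, "10 ng/ml"), (stimulus, 8, None))
        responses = (None, TransientResponse(tuple(components)))
        stim_after = 8
    n_cycles = stim_after + n_post_cycles
    chamber = MicrochamberModel(ambient_o2_kpa=ambient_o2_kpa)
    kinetics = _sampled_peak_scale(
        ChannelKinetics(baseline=baseline, responses=responses),
        schedule,
        n_cycles,
        stim_after,
        peak,
        chamber,
    )
    truth = {"peak_ocr": (peak, sem), "baseline_ocr": (baseline, None)}
    if extra_truth:
        truth.update(extra_truth)
    return RatePreset(
        name=name,
        schedule=schedule,
        n_cycles=n_cycles,
        ocr=kinetics,
        ambient_o2_kpa=ambient_o2_kpa,
        truth=truth,
    )


def _mito_preset(
    name: str,
    baseline: float,
    oligo_target: float,
    fccp_target: float,
    fccp_sem: float | None,
    rot_target: float,
    ambient_o2_kpa: float = 19.1,
    tau: float = 1.5,
) -> RatePreset:
    return RatePreset(
        name=name,
        schedule=MITO_SCHEDULE,
        n_cycles=12,
        ocr=ChannelKinetics(
            baseline=baseline,
            responses=(
                StepResponse(oligo_target, tau),
                StepResponse(fccp_target, tau),
                StepResponse(rot_target, tau),
            ),
        ),
        ambient_o2_kpa=ambient_o2_kpa,
        truth={
            "post_fccp_peak_ocr": (fccp_target, fccp_sem),
            "baseline_ocr": (baseline, None),
        },
    )


def preset_library() -> dict[str, RatePreset]:
    """Named ground-truth presets encoding published granulocyte group means.

    Glycolysis stress tests carry the post-glucose peak ECAR (eosinophils
    31.2 / 41.6 mpH/min at 1 / 10 mM glucose; neutrophils 48.4 / 73.1),
    the glucose-oxidation run the eosinophil OCR rise 22.9 -> 62.1 pmol/min
    suppressed by early oligomycin, the PMA presets the respiratory-burst
    peaks (eosinophil 24.5 -> 572.8, biphasic sustained; neutrophil
    13.9 -> 513, transient), the primed-agonist presets the IL-5/PAF,
    IL-5/fMLP and GM-CSF/fMLP peaks (150.9, 112.1, 84.3), and the
    normoxia/hypoxia pairs the post-FCCP rates (63.8 vs 9.4) and PMA peaks
    (389.7 vs 17.8).  Two noise-free tau=0 reference presets with simple
    integer truths support exact-recovery checks.
    """
    hypoxic_kpa = 0.8 / 100.0 * 101.325  # 0.8% O2 chamber atmosphere

    lib: dict[str, RatePreset] = {}

    def add(p: RatePreset) -> None:
        lib[p.name] = p

    add(_glyco_preset("eos_glyco_1mM", 12.0, 31.2, 6.4, glucose_mm=1.0))
    add(_glyco_preset("eos_glyco_10mM", 12.0, 41.6, 7.9, glucose_mm=10.0))
    add(_glyco_preset("neut_glyco_1mM", 15.0, 48.4, 2.6, glucose_mm=1.0))
    add(_glyco_preset("neut_glyco_10mM", 15.0, 73.1, 0.4, glucose_mm=10.0))

    # Glucose-oxidation run: OCR channel, glucose then *early* oligomycin
    # (18 min after glucose).  The eosinophil OCR rise collapses under
    # oligomycin; the neutrophil trace stays flat.
    add(
        RatePreset(
            name="eos_glucose_oxidation",
            schedule=GLYCO_SCHEDULE,
            n_cycles=12,
            ocr=ChannelKinetics(
                baseline=22.9,
                responses=(
                    StepResponse(62.1, 2.0),
                    StepResponse(30.0, 1.5),
                    StepResponse(26.0, 1.5),
                ),
            ),
            truth={
                "post_glucose_peak_ocr": (62.1, 3.2),
                "baseline_ocr": (22.9, 1.9),
            },
        )
    )
    add(
        RatePreset(
            name="neut_glucose_flat",
            schedule=GLYCO_SCHEDULE,
            n_cycles=12,
            ocr=ChannelKinetics(
                baseline=15.0,
                responses=(None, StepResponse(12.0, 1.5), None),
            ),
            truth={"post_glucose_peak_ocr": (15.0, None), "baseline_ocr": (15.0, None)},
        )
    )

    # PMA respiratory bursts.  The eosinophil burst is biphasic and
    # sustained: a fast NADPH-oxidase wave plus a delayed second wave.
    add(
        _agonist_preset(
            "eos_pma",
            baseline=24.5,
            peak=572.8,
            sem=15.8,
            components=(
                TransientComponent(1.0, tau_rise=3.0, tau_decay=12.0),
                TransientComponent(0.9, tau_rise=8.0, tau_decay=90.0, delay_min=45.0),
            ),
            stimulus="PMA",
        )
    )
    add(
        _agonist_preset(
            "neut_pma",
            baseline=13.9,
            peak=513.0,
            sem=28.8,
            components=(TransientComponent(1.0, tau_rise=3.0, tau_decay=22.0),),
            stimulus="PMA",
        )
    )

    # Primed agonist responses (primer injected first; no baseline shift).
    add(
        _agonist_preset(
            "eos_il5_paf",
            baseline=38.5,
            peak=150.9,
            sem=65.1,
            components=(TransientComponent(1.0, tau_rise=4.0, tau_decay=45.0),),
            stimulus="PAF",
            primer="IL-5",
        )
    )
    add(
        _agonist_preset(
            "eos_il5_fmlp",
            baseline=38.6,
            peak=112.1,
            sem=22.3,
            components=(TransientComponent(1.0, tau_rise=3.0, tau_decay=30.0),),
            stimulus="fMLP",
            primer="IL-5",
        )
    )
    add(
        _agonist_preset(
            "neut_gmcsf_fmlp",
            baseline=12.5,
            peak=84.3,
            sem=25.5,
            components=(TransientComponent(1.0, tau_rise=3.0, tau_decay=25.0),),
            stimulus="fMLP",
            primer="GM-CSF",
        )
    )

    # Normoxia/hypoxia mitochondrial stress-test pair (post-FCCP OCR).
    add(_mito_preset("eos_fccp_normoxia", 48.0, 20.0, 63.8, 0.7, 8.0))
    add(
        _mito_preset(
            "eos_fccp_hypoxia", 12.0, 6.0, 9.4, 1.6, 2.0, ambient_o2_kpa=hypoxic_kpa
        )
    )

    # Normoxia/hypoxia PMA pair (peak-height OCR).
    add(
        _agonist_preset(
            "neut_pma_normoxia",
            baseline=12.5,
            peak=389.7,
            sem=32.3,
            components=(TransientComponent(1.0, tau_rise=3.0, tau_decay=22.0),),
            stimulus="PMA",
        )
    )
    add(
        _agonist_preset(
            "neut_pma_hypoxia",
            baseline=5.0,
            peak=17.8,
            sem=0.8,
            components=(TransientComponent(1.0, tau_rise=3.0, tau_decay=22.0),),
            stimulus="PMA",
            ambient_o2_kpa=hypoxic_kpa,
        )
    )

    # tau = 0 reference presets with simple integer truths (exact recovery).
    add(
        RatePreset(
            name="glyco_reference",
            schedule=GLYCO_SCHEDULE,
            n_cycles=12,
            ecar=ChannelKinetics(
                baseline=10.0,
                responses=(
                    StepResponse(35.0, 0.0),
                    StepResponse(42.0, 0.0),
                    StepResponse(11.0, 0.0),
                ),
            ),
            truth={
                "nga": (10.0, None),
                "glycolysis": (25.0, None),
                "glycolytic_capacity": (32.0, None),
                "glycolytic_reserve": (7.0, None),
            },
        )
    )
    add(
        RatePreset(
            name="mito_reference",
            schedule=MITO_SCHEDULE,
            n_cycles=12,
            ocr=ChannelKinetics(
                baseline=50.0,
                responses=(
                    StepResponse(20.0, 0.0),
                    StepResponse(90.0, 0.0),
                    StepResponse(5.0, 0.0),
                ),
            ),
            truth={
                "non_mito": (5.0, None),
                "basal_respiration": (45.0, None),
                "proton_leak": (15.0, None),
                "atp_linked": (30.0, None),
                "max_capacity": (85.0, None),
                "spare_capacity": (40.0, None),
            },
        )
    )
    return lib


def get_preset(name: str) -> RatePreset:
    lib = preset_library()
    try:
        return lib[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(lib)}"
        ) from None


# ---------------------------------------------------------------------------
# Preset serialization
# ---------------------------------------------------------------------------


def _response_to_dict(r: Response) -> dict | None:
    if r is None:
        return None
    if isinstance(r, StepResponse):
        return {"kind": "step", "target": r.target, "tau_min": r.tau_min}
    return {
        "kind": "transient",
        "components": [
            {
                "amplitude": c.amplitude,
                "tau_rise": c.tau_rise,
                "tau_decay": c.tau_decay,
                "delay_min": c.delay_min,
            }
            for c in r.components
        ],
    }


def _response_from_dict(d: dict | None) -> Response:
    if d is None:
        return None
    if d["kind"] == "step":
        return StepResponse(target=d["target"], tau_min=d["tau_min"])
    return TransientResponse(
        tuple(TransientComponent(**c) for c in d["components"])
    )


def _channel_to_dict(ch: ChannelKinetics | None) -> dict | None:
    if ch is None:
        return None
    return {
        "baseline": ch.baseline,
        "responses": [_response_to_dict(r) for r in ch.responses],
    }


def _channel_from_dict(d: dict | None) -> ChannelKinetics | None:
    if d is None:
        return None
    return ChannelKinetics(
        baseline=d["baseline"],
        responses=tuple(_response_from_dict(r) for r in d["responses"]),
    )


def preset_to_dict(p: RatePreset) -> dict:
    return {
        "name": p.name,
        "schedule": [
            {"name": e.name, "after_index": e.after_index, "compound_conc": e.compound_conc}
            for e in p.schedule
        ],
        "n_cycles": p.n_cycles,
        "ecar": _channel_to_dict(p.ecar),
        "ocr": _channel_to_dict(p.ocr),
        "reference_cells": p.reference_cells,
        "ambient_o2_kpa": p.ambient_o2_kpa,
        "glucose_mm": p.glucose_mm,
        "truth": {k: list(v) for k, v in p.truth.items()},
    }


def preset_from_dict(d: dict) -> RatePreset:
    return RatePreset(
        name=d["name"],
        schedule=InjectionSchedule(
            tuple(InjectionEvent(**e) for e in d["schedule"])
        ),
        n_cycles=d["n_cycles"],
        ecar=_channel_from_dict(d["ecar"]),
        ocr=_channel_from_dict(d["ocr"]),
        reference_cells=d["reference_cells"],
        ambient_o2_kpa=d["ambient_o2_kpa"],
        glucose_mm=d["glucose_mm"],
        truth={k: (v[0], v[1]) for k, v in d["truth"].items()},
    )


def preset_to_json(p: RatePreset) -> str:
    return json.dumps(preset_to_dict(p), indent=2)


def preset_from_json(s: str) -> RatePreset:
    return preset_from_dict(json.loads(s))
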