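"""Agonist-stimulated oxygen-consumption responses.

Granulocytes mount a respiratory burst when stimulated with soluble
agonists (PMA, fMLP, PAF), which appears in the flux assay as a large OCR
excursion above baseline.  Cytokine priming (IL-5, GM-CSF) potentiates the
response to a subsequent agonist without itself moving the baseline, so for
a primer-then-stimulus schedule the baseline is read before the first
injection of the pair.

The headline statistic is the peak-height OCR — the absolute maximum rate
reached after the stimulus — reported alongside the baseline-subtracted
delta, trapezoidal area above baseline, time to peak, and a persistence
fraction used to classify the response kinetics as transient, sustained or
biphasic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .flux_core import InjectionSchedule, KineticTrace

__all__ = [
    "AgonistResponse",
    "KineticsConfig",
    "GlucoseOxidationIndex",
    "peak_height",
    "classify_kinetics",
    "glucose_oxidation_index",
]


@dataclass(frozen=True)
class KineticsConfig:
    """Thresholds for kinetic classification.

    These cutoffs are analysis conventions of this package, not published
    values; all are configurable.  A response whose delta is below
    ``detection_delta`` (rate units) is classed ``"none"``.  Biphasic
    requires two local maxima, each at least ``biphasic_fraction`` of the
    delta above baseline, separated by at least ``biphasic_min_separation``
    cycles.  Sustained requires the trace to extend at least
    ``sustained_at_min`` minutes past the stimulus with a persistence
    fraction of at least ``sustained_persistence``.
    """

    detection_delta: float = 1.0
    biphasic_fraction: float = 0.6
    biphasic_min_separation: int = 3
    sustained_persistence: float = 0.5
    sustained_at_min: float = 90.0


@dataclass(frozen=True)
class AgonistResponse:
    """Per-well summary of one stimulation.

    ``peak`` is the absolute maximum post-stimulus rate; ``delta`` is
    ``peak - baseline``; ``persistence`` is ``(final - baseline) / delta``
    (NaN when delta <= 0).  Rates are in the channel's native units.
    """

    baseline: float
    peak: float
    delta: float
    time_to_peak_min: float
    auc_above_baseline: float
    persistence: float
    kinetic_class: str


@dataclass(frozen=True)
class GlucoseOxidationIndex:
    """Glucose-oxidation readout from a glucose-then-oligomycin OCR run.

    ``delta_ocr_glucose`` is the glucose-stimulated OCR rise;
    ``oligo_suppression_fraction`` is the fraction of the post-glucose peak
    removed by ATP-synthase inhibition — near zero when the rise is not
    mitochondrial.
    """

    delta_ocr_glucose: float
    oligo_suppression_fraction: float


def _split_at_stimulus(
    trace: KineticTrace,
    schedule: InjectionSchedule,
    stimulus: str,
    baseline_event: str | None,
):
    try:
        stim = schedule.event(stimulus)
    except KeyError:
        raise ConfigurationError(f"schedule has no injection named {stimulus!r}")
    if stim.after_index >= trace.n_cycles:
        raise ValidationError(
            f"stimulus {stimulus!r} injected after the final measurement"
        )
    base_ev = schedule.event(baseline_event) if baseline_event else schedule.events[0]
    if base_ev.after_index > stim.after_index:
        raise ConfigurationError(
            f"baseline event {base_ev.name!r} comes after stimulus {stimulus!r}"
        )
    return stim, base_ev


def peak_height(
    trace: KineticTrace,
    schedule: InjectionSchedule,
    stimulus: str,
    channel: str = "ocr",
    baseline_event: str | None = None,
    config: KineticsConfig | None = None,
) -> AgonistResponse:
    """Peak-height response of one well to the named stimulus.

    The baseline is the last measurement before ``baseline_event`` (default:
    the first injection of the schedule, so that a primer injection does not
    reset the baseline).  The peak is taken over every measurement after the
    stimulus through the end of the assay; AUC is trapezoidal integration of
    the post-stimulus excess over baseline.
    """
    cfg = config or KineticsConfig()
    stim, base_ev = _split_at_stimulus(trace, schedule, stimulus, baseline_event)

    idx = trace.indices()
    t = trace.times()
    v = trace.values(channel)
    if np.isnan(v).any():
        raise ValidationError(f"well {trace.well_id}: missing {channel} values")

    pre = idx <= base_ev.after_index
    post = idx > stim.after_index
    if pre.sum() < 1 or post.sum() < 2:
        raise ValidationError(
            "need >= 1 pre-stimulus and >= 2 post-stimulus measurements"
        )

    baseline = float(v[pre][-1])
    t_stim = float(t[idx <= stim.after_index][-1])
    vp, tp = v[post], t[post]
    k = int(np.argmax(vp))
    peak = float(vp[k])
    delta = peak - baseline
    auc = float(np.trapezoid(vp - baseline, tp))
    persistence = (float(vp[-1]) - baseline) / delta if delta > 0 else float("nan")

    kclass = classify_kinetics(
        trace, schedule, stimulus, channel=channel,
        baseline_event=base_ev.name, config=cfg,
    )
    return AgonistResponse(
        baseline=baseline,
        peak=peak,
        delta=delta,
        time_to_peak_min=float(tp[k]) - t_stim,
        auc_above_baseline=auc,
        persistence=persistence,
        kinetic_class=kclass,
    )


def _local_maxima(v: np.ndarray) -> list[int]:
    """Indices of strict local maxima, counting the endpoints."""
    out = []
    for i in range(len(v)):
        left = v[i] > v[i - 1] if i > 0 else True
        right = v[i] > v[i + 1] if i < len(v) - 1 else True
        if left and right:
            out.append(i)
    return out


def classify_kinetics(
    trace: KineticTrace,
    schedule: InjectionSchedule,
    stimulus: str,
    channel: str = "ocr",
    baseline_event: str | None = None,
    config: KineticsConfig | None = None,
) -> str:
    """Classify the post-stimulus kinetics as biphasic, sustained, transient
    or none.

    The decision cascade: no detectable response -> ``"none"``; two
    well-separated high local maxima -> ``"biphasic"``; a response still at
    least half its delta above baseline late in the run -> ``"sustained"``;
    otherwise ``"transient"``.  Thresholds are relative to the response
    delta, so the class is invariant under uniform rescaling of rates.
    """
    cfg = config or KineticsConfig()
    stim, base_ev = _split_at_stimulus(trace, schedule, stimulus, baseline_event)

    idx = trace.indices()
    t = trace.times()
    v = trace.values(channel)
    pre = idx <= base_ev.after_index
    post = idx > stim.after_index
    if post.sum() < 2:
        warnings.warn("post-stimulus window too short to classify", stacklevel=2)
        return "none"

    baseline = float(v[pre][-1])
    t_stim = float(t[idx <= stim.after_index][-1])
    vp, tp = v[post], t[post]
    delta = float(np.max(vp)) - baseline
    if delta <= cfg.detection_delta:
        return "none"

    high = baseline + cfg.biphasic_fraction * delta
    peaks = [i for i in _local_maxima(vp) if vp[i] >= high]
    for a, b in zip(peaks, peaks[1:]):
        if b - a >= cfg.biphasic_min_separation:
            return "biphasic"

    post_duration = float(tp[-1]) - t_stim
    persistence = (float(vp[-1]) - baseline) / delta
    if post_duration >= cfg.sustained_at_min and persistence >= cfg.sustained_persistence:
        return "sustained"
    return "transient"


def glucose_oxidation_index(
    trace: KineticTrace,
    schedule: InjectionSchedule,
) -> GlucoseOxidationIndex:
    """Glucose-stimulated OCR rise and its oligomycin suppressibility.

    A rise in OCR after glucose that collapses under early oligomycin
    indicates mitochondrial oxidation of glucose-derived pyruvate; a rise
    that persists (or no rise at all) does not.
    """
    from .stress_params import EVENT_SYNONYMS, _find_window
    from .flux_core import segment_windows, window_values

    windows = segment_windows(trace, schedule)
    w_gluc = _find_window(windows, "GLUC")
    w_oligo = _find_window(windows, "OLIGO")
    gluc_pos = [w.label for w in windows].index(w_gluc.label)
    oligo_pos = [w.label for w in windows].index(w_oligo.label)
    if oligo_pos <= gluc_pos:
        raise ConfigurationError("OLIGO injection must follow GLUC")

    pre_gluc = trace.value_at_index(w_gluc.start - 1, "ocr")
    post_gluc_max = float(np.max(window_values(trace, w_gluc, "ocr")))
    post_oligo_min = float(np.min(window_values(trace, w_oligo, "ocr")))
    if post_gluc_max <= 0:
        raise ValidationError("non-positive post-glucose OCR maximum")
    return GlucoseOxidationIndex(
        delta_ocr_glucose=post_gluc_max - pre_gluc,
        oligo_suppression_fraction=(post_gluc_max - post_oligo_min) / post_gluc_max,
    )
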