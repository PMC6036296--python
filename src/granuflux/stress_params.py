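"""Glycolytic and oxidative stress-test parameters from segmented traces.

Glycolysis stress test (ECAR channel, injections glucose -> oligomycin ->
2-deoxy-D-glucose):

* non-glycolytic acidification (NGA) — ECAR before glucose addition,
* glycolysis (G) — maximal post-glucose ECAR minus NGA,
* glycolytic capacity (GC) — maximal post-oligomycin ECAR minus NGA,
* glycolytic reserve (GR) — GC minus G.

Mitochondrial stress test (OCR channel, injections oligomycin -> FCCP ->
rotenone/antimycin A):

* non-mitochondrial OCR (NON-MITO) — minimum OCR after rotenone/antimycin A,
* basal respiration (BR) — last pre-oligomycin OCR minus NON-MITO,
* proton leak (PL) — minimum post-oligomycin OCR minus NON-MITO,
* ATP-linked respiration — BR minus PL,
* maximum respiratory capacity (MAX CAP) — maximal post-FCCP OCR minus
  NON-MITO,
* spare respiratory capacity (SPA CAP) — MAX CAP minus BR.

Parameters are computed per well and are never floored at zero: a hypoxic
plate legitimately yields negative spare capacity when the uncoupled rate
falls below the basal rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .flux_core import (
    InjectionSchedule,
    KineticTrace,
    Window,
    segment_windows,
    window_values,
)

__all__ = [
    "GlycoParams",
    "MitoParams",
    "glyco_params",
    "mito_params",
    "post_glucose_peak",
    "EVENT_SYNONYMS",
]

# Canonical event name -> accepted spellings in schedules.
EVENT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "GLUC": ("GLUC", "GLUCOSE"),
    "OLIGO": ("OLIGO", "OLIGOMYCIN"),
    "2-DG": ("2-DG", "2DG", "2-DEOXYGLUCOSE"),
    "FCCP": ("FCCP",),
    "ROT/AA": ("ROT/AA", "ROT_AA", "ROTAA", "ROTENONE/ANTIMYCIN"),
}


@dataclass(frozen=True)
class GlycoParams:
    """Per-well glycolysis stress-test parameters (mpH/min)."""

    nga: float
    g: float
    gc: float
    gr: float


@dataclass(frozen=True)
class MitoParams:
    """Per-well mitochondrial stress-test parameters (pmol O2/min)."""

    non_mito: float
    br: float
    pl: float
    atp_link: float
    max_cap: float
    spa_cap: float


def _find_window(windows: list[Window], canonical: str) -> Window:
    accepted = EVENT_SYNONYMS.get(canonical, (canonical,))
    for w in windows:
        if w.label.upper() in accepted:
            return w
    raise ConfigurationError(
        f"schedule has no {canonical!r} injection (windows: "
        f"{[w.label for w in windows]})"
    )


def glyco_params(
    trace: KineticTrace,
    schedule: InjectionSchedule,
    baseline: str = "last",
) -> GlycoParams:
    """Glycolysis stress-test parameters for one well.

    ``baseline`` selects how the pre-glucose reference (NGA) is read:
    ``"last"`` (default) uses the single measurement immediately before the
    glucose injection; ``"mean"`` averages the whole baseline window.
    """
    if baseline not in ("last", "mean"):
        raise ValueError("baseline must be 'last' or 'mean'")
    windows = segment_windows(trace, schedule)
    w_gluc = _find_window(windows, "GLUC")
    w_oligo = _find_window(windows, "OLIGO")
    _find_window(windows, "2-DG")  # required for a complete test

    if baseline == "last":
        nga = trace.value_at_index(w_gluc.start - 1, "ecar")
    else:
        nga = float(np.mean(window_values(trace, windows[0], "ecar")))
    g = float(np.max(window_values(trace, w_gluc, "ecar"))) - nga
    gc = float(np.max(window_values(trace, w_oligo, "ecar"))) - nga
    return GlycoParams(nga=nga, g=g, gc=gc, gr=gc - g)


def mito_params(trace: KineticTrace, schedule: InjectionSchedule) -> MitoParams:
    """Mitochondrial stress-test parameters for one well."""
    windows = segment_windows(trace, schedule)
    w_oligo = _find_window(windows, "OLIGO")
    w_fccp = _find_window(windows, "FCCP")
    w_rot = _find_window(windows, "ROT/AA")

    non_mito = float(np.min(window_values(trace, w_rot, "ocr")))
    br = trace.value_at_index(w_oligo.start - 1, "ocr") - non_mito
    pl = float(np.min(window_values(trace, w_oligo, "ocr"))) - non_mito
    max_cap = float(np.max(window_values(trace, w_fccp, "ocr"))) - non_mito
    return MitoParams(
        non_mito=non_mito,
        br=br,
        pl=pl,
        atp_link=br - pl,
        max_cap=max_cap,
        spa_cap=max_cap - br,
    )


def post_glucose_peak(
    trace: KineticTrace,
    schedule: InjectionSchedule,
    channel: str = "ecar",
) -> float:
    """Absolute peak rate in the post-glucose window.

    The window runs from the first post-glucose cycle through the last
    cycle before the next injection (or to the end of the assay).  The
    value is the raw maximum, not baseline-subtracted.
    """
    windows = segment_windows(trace, schedule)
    w_gluc = _find_window(windows, "GLUC")
    return float(np.max(window_values(trace, w_gluc, channel)))
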