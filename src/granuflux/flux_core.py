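"""Core data model and I/O for kinetic extracellular-flux plate assays.

An extracellular-flux analyser reports, for every well of a 96-well plate
and every measurement cycle, an extracellular acidification rate (ECAR,
mpH/min) and an oxygen consumption rate (OCR, pmol O2/min).  Compounds are
injected from a sensor-cartridge port between measurement cycles, so every
injection is anchored to "after measurement cycle k" rather than to clock
time.  This module holds the in-memory containers for such assays, the
canonical long-format table dialect used to read and write them, the
segmentation of a trace into per-injection analysis windows, and well-to-
group aggregation (mean +/- SEM).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "RateMeasurement",
    "InjectionEvent",
    "InjectionSchedule",
    "KineticTrace",
    "PlateAssay",
    "GroupTrace",
    "Window",
    "OutlierRule",
    "read_rate_table",
    "write_rate_table",
    "segment_windows",
    "aggregate_group",
    "scale_to_reference_density",
]

RATE_COLUMNS = ("well", "group", "index", "time_min", "ecar", "ocr")
SCHEDULE_COLUMNS = ("name", "after_index", "compound_conc")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class RateMeasurement:
    """One measurement cycle in one well.

    Either rate may be absent (``None``) but not both; indices are the
    instrument's 1-based cycle numbers.
    """

    well_id: str
    group: str
    index: int
    time_min: float
    ecar: float | None = None
    ocr: float | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"measurement index must be >= 1, got {self.index}")
        if self.time_min < 0:
            raise ValidationError(f"time_min must be >= 0, got {self.time_min}")
        if _is_missing(self.ecar) and _is_missing(self.ocr):
            raise ValidationError(
                f"well {self.well_id} cycle {self.index}: both ECAR and OCR absent"
            )


@dataclass(frozen=True)
class InjectionEvent:
    """A port injection taking effect after measurement cycle ``after_index``.

    ``compound_conc`` is free-text metadata (e.g. ``"10 mM"``); it plays no
    role in any computation.
    """

    name: str
    after_index: int
    compound_conc: str | None = None

    def __post_init__(self) -> None:
        if self.after_index < 1:
            raise ValidationError(
                f"injection {self.name!r}: after_index must be >= 1, got {self.after_index}"
            )


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered sequence of injection events shared by all wells of a plate."""

    events: tuple[InjectionEvent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        idx = [e.after_index for e in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"injection events must be strictly ordered by after_index, got {idx}"
            )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.events)

    def event(self, name: str) -> InjectionEvent:
        for e in self.events:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass
class KineticTrace:
    """Ordered rate measurements for a single well."""

    well_id: str
    group: str
    measurements: list[RateMeasurement]

    def __post_init__(self) -> None:
        ms = sorted(self.measurements, key=lambda m: m.index)
        if len(ms) < 2:
            raise ValidationError(f"well {self.well_id}: need >= 2 measurements")
        seen = set()
        for m in ms:
            if m.index in seen:
                raise ValidationError(
                    f"well {self.well_id}: duplicate measurement index {m.index}"
                )
            seen.add(m.index)
        for a, b in zip(ms, ms[1:]):
            if b.time_min <= a.time_min:
                raise ValidationError(
                    f"well {self.well_id}: time not strictly increasing at index {b.index}"
                )
        self.measurements = ms

    @property
    def n_cycles(self) -> int:
        return self.measurements[-1].index

    def indices(self) -> np.ndarray:
        return np.array([m.index for m in self.measurements], dtype=int)

    def times(self) -> np.ndarray:
        return np.array([m.time_min for m in self.measurements], dtype=float)

    def values(self, channel: str) -> np.ndarray:
        """Per-measurement rates for ``channel`` ('ecar' or 'ocr'); missing -> NaN."""
        if channel not in ("ecar", "ocr"):
            raise ValueError(f"channel must be 'ecar' or 'ocr', got {channel!r}")
        out = np.array(
            [getattr(m, channel) for m in self.measurements], dtype=object
        )
        return np.array([np.nan if _is_missing(v) else float(v) for v in out])

    def value_at_index(self, index: int, channel: str) -> float:
        for m in self.measurements:
            if m.index == index:
                v = getattr(m, channel)
                return np.nan if _is_missing(v) else float(v)
        raise KeyError(f"well {self.well_id}: no measurement with index {index}")


@dataclass
class PlateAssay:
    """All traces of one plate run plus the shared injection schedule.

    Metadata fields record the assay conditions that matter downstream:
    seeded cells per well, ambient O2 (%) and assay-medium glucose (mM).
    """

    traces: dict[str, KineticTrace]
    schedule: InjectionSchedule
    cells_per_well: float | None = None
    ambient_o2_percent: float | None = None
    glucose_mm: float | None = None

    def __post_init__(self) -> None:
        for well, tr in self.traces.items():
            if tr.well_id != well:
                raise ValidationError(f"trace keyed {well!r} has well_id {tr.well_id!r}")
            for ev in self.schedule:
                if ev.after_index >= tr.n_cycles:
                    raise ValidationError(
                        f"injection {ev.name!r} after cycle {ev.after_index} but "
                        f"well {well} has only {tr.n_cycles} cycles"
                    )

    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for tr in self.traces.values():
            seen.setdefault(tr.group, None)
        return tuple(seen)

    def wells_in_group(self, group: str) -> list[KineticTrace]:
        out = [tr for tr in self.traces.values() if tr.group == group]
        if not out:
            raise ValidationError(f"no wells in group {group!r}")
        return out


@dataclass(frozen=True)
class Window:
    """Contiguous 1-based measurement-index range [start, end] (inclusive)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"window {self.label!r}: start {self.start} > end {self.end}"
            )

    def indices(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class OutlierRule:
    """Median-absolute-deviation outlier rule on a per-well summary.

    A well is flagged when the robust z-score of its trace mean exceeds
    ``threshold``.  Flags are always reported; wells are excluded from
    aggregation only when ``enabled`` is True.  Off by default.
    """

    enabled: bool = False
    threshold: float = 3.5


@dataclass
class GroupTrace:
    """Per-cycle mean / SEM / n for one well group.

    SEM is the sample SD over wells divided by sqrt(n) and is NaN where
    n = 1.  ``flagged_wells`` lists wells the outlier rule would exclude.
    """

    group: str
    indices: np.ndarray
    time_min: np.ndarray
    ecar_mean: np.ndarray
    ecar_sem: np.ndarray
    ecar_n: np.ndarray
    ocr_mean: np.ndarray
    ocr_sem: np.ndarray
    ocr_n: np.ndarray
    flagged_wells: tuple[str, ...] = ()
    excluded_wells: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# I/O — canonical long-format dialect
# ---------------------------------------------------------------------------

_META_KEYS = ("cells_per_well", "ambient_o2_percent", "glucose_mm")


def _as_text_handle(source, mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def read_rate_table(
    source,
    schedule_source=None,
    sep: str = ",",
) -> PlateAssay:
    """Read a long-format rate table (and companion schedule) into a PlateAssay.

    The rate table needs columns ``well, group, index, time_min`` and at
    least one of ``ecar``/``ocr``; ``#``-prefixed header lines of the form
    ``# key=value`` carry plate metadata.  The schedule table has columns
    ``name, after_index`` and optional ``compound_conc``.  Row order is
    irrelevant; a duplicated (well, index) pair is an error.
    """
    handle, close = _as_text_handle(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()

    meta: dict[str, float] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                k = k.strip()
                if k in _META_KEYS and v.strip().lower() not in ("", "none"):
                    meta[k] = float(v)
        else:
            body_lines.append(line)

    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep=sep)
    required = {"well", "group", "index", "time_min"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"rate table missing columns: {sorted(missing)}")
    if "ecar" not in df.columns and "ocr" not in df.columns:
        raise FormatError("rate table needs at least one of columns 'ecar'/'ocr'")
    for col in ("ecar", "ocr"):
        if col not in df.columns:
            df[col] = np.nan

    dup = df.duplicated(subset=["well", "index"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValidationError(
            f"duplicate (well, index) row: ({first['well']}, {int(first['index'])})"
        )

    events: list[InjectionEvent] = []
    if schedule_source is not None:
        shandle, sclose = _as_text_handle(schedule_source)
        try:
            sdf = pd.read_csv(shandle, sep=sep, comment="#")
        finally:
            if sclose:
                shandle.close()
        if not {"name", "after_index"} <= set(sdf.columns):
            raise FormatError("schedule table missing 'name'/'after_index' columns")
        if "compound_conc" not in sdf.columns:
            sdf["compound_conc"] = None
        for _, row in sdf.iterrows():
            conc = row["compound_conc"]
            events.append(
                InjectionEvent(
                    name=str(row["name"]),
                    after_index=int(row["after_index"]),
                    compound_conc=None if pd.isna(conc) else str(conc),
                )
            )

    traces: dict[str, KineticTrace] = {}
    for well, sub in df.groupby("well", sort=False):
        ms = [
            RateMeasurement(
                well_id=str(well),
                group=str(row["group"]),
                index=int(row["index"]),
                time_min=float(row["time_min"]),
                ecar=None if pd.isna(row["ecar"]) else float(row["ecar"]),
                ocr=None if pd.isna(row["ocr"]) else float(row["ocr"]),
            )
            for _, row in sub.iterrows()
        ]
        traces[str(well)] = KineticTrace(
            well_id=str(well), group=ms[0].group, measurements=ms
        )

    return PlateAssay(
        traces=traces,
        schedule=InjectionSchedule(tuple(events)),
        cells_per_well=meta.get("cells_per_well"),
        ambient_o2_percent=meta.get("ambient_o2_percent"),
        glucose_mm=meta.get("glucose_mm"),
    )


def write_rate_table(assay: PlateAssay, sink, schedule_sink=None, sep: str = ",") -> None:
    """Write ``assay`` losslessly in the canonical long-format dialect."""
    rows = []
    for tr in assay.traces.values():
        for m in tr.measurements:
            rows.append(
                {
                    "well": m.well_id,
                    "group": m.group,
                    "index": m.index,
                    "time_min": m.time_min,
                    "ecar": np.nan if _is_missing(m.ecar) else m.ecar,
                    "ocr": np.nan if _is_missing(m.ocr) else m.ocr,
                }
            )
    df = pd.DataFrame(rows, columns=list(RATE_COLUMNS))

    handle, close = _as_text_handle(sink, "w")
    try:
        for key in _META_KEYS:
            val = getattr(assay, key if key != "glucose_mm" else "glucose_mm")
            if val is not None:
                handle.write(f"# {key}={val}\n")
        df.to_csv(handle, sep=sep, index=False)
    finally:
        if close:
            handle.close()

    if schedule_sink is not None:
        sdf = pd.DataFrame(
            [
                {
                    "name": e.name,
                    "after_index": e.after_index,
                    "compound_conc": e.compound_conc,
                }
                for e in assay.schedule
            ],
            columns=list(SCHEDULE_COLUMNS),
        )
        shandle, sclose = _as_text_handle(schedule_sink, "w")
        try:
            sdf.to_csv(shandle, sep=sep, index=False)
        finally:
            if sclose:
                shandle.close()


# ---------------------------------------------------------------------------
# Window segmentation
# ---------------------------------------------------------------------------


def segment_windows(trace: KineticTrace, schedule: InjectionSchedule) -> list[Window]:
    """Partition a trace's cycle range into per-injection analysis windows.

    Window 0 is the pre-injection baseline ``[1, after_index_1]``; the
    window for event i runs from the first post-injection cycle through the
    last cycle before the next injection (the final window extends to the
    end of the assay).  Every cycle belongs to exactly one window.
    """
    n = trace.n_cycles
    if not schedule.events:
        return [Window("baseline", 1, n)]
    for ev in schedule:
        if ev.after_index >= n:
            raise ValidationError(
                f"injection {ev.name!r} after cycle {ev.after_index} beyond trace "
                f"of {n} cycles"
            )
    windows = [Window("baseline", 1, schedule.events[0].after_index)]
    for i, ev in enumerate(schedule.events):
        start = ev.after_index + 1
        end = (
            schedule.events[i + 1].after_index
            if i + 1 < len(schedule.events)
            else n
        )
        if start > end:
            raise ValidationError(
                f"empty window for injection {ev.name!r} "
                f"(after_index {ev.after_index})"
            )
        windows.append(Window(ev.name, start, end))
    return windows


def window_values(trace: KineticTrace, window: Window, channel: str) -> np.ndarray:
    """Channel values of the measurements whose cycle index falls in ``window``."""
    idx = trace.indices()
    vals = trace.values(channel)
    mask = (idx >= window.start) & (idx <= window.end)
    out = vals[mask]
    if out.size == 0:
        raise ValidationError(
            f"well {trace.well_id}: no measurements in window {window.label!r}"
        )
    if np.isnan(out).any():
        raise ValidationError(
            f"well {trace.well_id}: missing {channel} values in window {window.label!r}"
        )
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _mad_flags(wells: Sequence[KineticTrace], threshold: float) -> tuple[str, ...]:
    """Wells whose trace mean has robust z > threshold in either channel."""
    flagged: list[str] = []
    for channel in ("ecar", "ocr"):
        means = []
        for tr in wells:
            v = tr.values(channel)
            means.append(np.nan if np.isnan(v).all() else np.nanmean(v))
        means = np.asarray(means)
        ok = ~np.isnan(means)
        if ok.sum() < 3:
            continue
        med = np.median(means[ok])
        mad = np.median(np.abs(means[ok] - med))
        if mad == 0:
            continue
        rz = 0.6745 * np.abs(means - med) / mad
        for tr, z, good in zip(wells, rz, ok):
            if good and z > threshold and tr.well_id not in flagged:
                flagged.append(tr.well_id)
    return tuple(flagged)


def aggregate_group(
    assay: PlateAssay,
    group: str,
    outlier_rule: OutlierRule | None = None,
) -> GroupTrace:
    """Per-cycle mean / SEM / n of each channel over the wells of ``group``.

    The optional MAD outlier rule is evaluated and reported regardless, but
    wells are excluded only when the rule is enabled.
    """
    wells = assay.wells_in_group(group)
    rule = outlier_rule or OutlierRule()
    flagged = _mad_flags(wells, rule.threshold)
    excluded = flagged if rule.enabled else ()
    used = [tr for tr in wells if tr.well_id not in excluded]
    if not used:
        raise ValidationError(f"group {group!r}: all wells excluded by outlier rule")

    all_idx = sorted({int(i) for tr in used for i in tr.indices()})
    n_idx = len(all_idx)
    pos = {ix: k for k, ix in enumerate(all_idx)}
    stacks = {
        "ecar": np.full((len(used), n_idx), np.nan),
        "ocr": np.full((len(used), n_idx), np.nan),
    }
    tgrid = np.full((len(used), n_idx), np.nan)
    for w, tr in enumerate(used):
        idx = tr.indices()
        tgrid[w, [pos[int(i)] for i in idx]] = tr.times()
        for channel in ("ecar", "ocr"):
            stacks[channel][w, [pos[int(i)] for i in idx]] = tr.values(channel)

    out: dict[str, np.ndarray] = {}
    for channel, stack in stacks.items():
        n = (~np.isnan(stack)).sum(axis=0).astype(float)
        total = np.nansum(stack, axis=0)
        mean = np.where(n >= 1, total / np.maximum(n, 1), np.nan)
        sd = np.full(n_idx, np.nan)
        for k in range(n_idx):
            col = stack[:, k]
            col = col[~np.isnan(col)]
            if col.size >= 2:
                sd[k] = np.std(col, ddof=1)
        sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        mean = np.where(n >= 1, mean, np.nan)
        out[f"{channel}_mean"] = mean
        out[f"{channel}_sem"] = sem
        out[f"{channel}_n"] = n

    return GroupTrace(
        group=group,
        indices=np.array(all_idx, dtype=int),
        time_min=np.nanmean(tgrid, axis=0),
        ecar_mean=out["ecar_mean"],
        ecar_sem=out["ecar_sem"],
        ecar_n=out["ecar_n"],
        ocr_mean=out["ocr_mean"],
        ocr_sem=out["ocr_sem"],
        ocr_n=out["ocr_n"],
        flagged_wells=flagged,
        excluded_wells=excluded,
    )


def scale_to_reference_density(value, cells_per_well: float, reference: float):
    """Linearly rescale a rate to a reference seeding density.

    Basal and substrate-stimulated rates scale linearly with the number of
    seeded cells over the working range, so rates measured at one density
    are comparable after multiplication by ``reference / cells_per_well``.
    Accepts scalars or arrays.
    """
    if cells_per_well <= 0 or reference <= 0:
        raise ValidationError("cell counts must be positive")
    return np.multiply(value, reference / cells_per_well)
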