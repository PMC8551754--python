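"""Reading, validation, segmentation and report output for temperature traces.

Traces are timestamped core body-temperature series. Timestamps are
normalized to decimal hours since the first reading as soon as a file is
read; all downstream statistics are agnostic to absolute calendar time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tbshape.errors import TraceFormatError, ValidationError

logger = logging.getLogger(__name__)

#: Validation bounds for plausible core body temperature, °C.
TB_MIN_C = 0.0
TB_MAX_C = 50.0

#: Default column names expected in a trace CSV.
DEFAULT_COLUMNS: Mapping[str, str] = {"time": "time", "temperature": "tb_c"}

#: Segments shorter than this are flagged unusable for quantile fitting
#: (>= 3 circadian cycles so the slow smooth is identified).
DEFAULT_MIN_FIT_DURATION_H = 72.0

#: Default maximum tolerated inter-sample gap before a trace is split.
DEFAULT_MAX_GAP_H = 6.0


@dataclass
class TbTrace:
    """A validated core body-temperature time series.

    Parameters
    ----------
    time_h
        Decimal hours since the first reading; strictly increasing.
    tb_c
        Core body temperature in °C, one value per time point.
    individual_id, species
        Opaque labels carried through to reports.
    sample_interval_min
        Nominal sampling interval in minutes (metadata only).
    truth_labels
        Optional per-reading ground-truth phase labels; synthetic traces
        only. Values in {"ACTIVE", "REST", "TRANSITIONAL"}.
    fit_usable
        Set False by :func:`segment_trace` for segments too short to fit.
    """

    time_h: np.ndarray
    tb_c: np.ndarray
    individual_id: str = "unknown"
    species: str = "unknown"
    sample_interval_min: float | None = None
    truth_labels: np.ndarray | None = None
    fit_usable: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.tb_c = np.asarray(self.tb_c, dtype=float)
        if self.time_h.ndim != 1 or self.tb_c.ndim != 1:
            raise ValidationError("time_h and tb_c must be 1-D arrays")
        if self.time_h.shape != self.tb_c.shape:
            raise ValidationError(
                f"time_h has {self.time_h.size} entries but tb_c has {self.tb_c.size}"
            )
        if self.time_h.size == 0:
            raise ValidationError("trace is empty")
        if not np.all(np.isfinite(self.time_h)):
            raise ValidationError("non-finite timestamps in trace")
        if np.any(np.diff(self.time_h) <= 0):
            i = int(np.argmax(np.diff(self.time_h) <= 0))
            raise ValidationError(
                f"timestamps not strictly increasing at index {i + 1} "
                f"(t={self.time_h[i]:g} h followed by t={self.time_h[i + 1]:g} h)"
            )
        if not np.all(np.isfinite(self.tb_c)):
            raise ValidationError("non-finite temperature values in trace")
        bad = (self.tb_c < TB_MIN_C) | (self.tb_c > TB_MAX_C)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValidationError(
                f"temperature {self.tb_c[i]:g} °C at index {i} outside "
                f"[{TB_MIN_C:g}, {TB_MAX_C:g}] °C"
            )
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels)
            if self.truth_labels.shape != self.tb_c.shape:
                raise ValidationError("truth_labels length differs from tb_c")

    def __len__(self) -> int:
        return int(self.time_h.size)

    @property
    def duration_h(self) -> float:
        """Span of the trace in hours."""
        return float(self.time_h[-1] - self.time_h[0])

    def slice(self, start: int, stop: int) -> "TbTrace":
        """Positional sub-trace [start:stop); labels and metadata preserved."""
        labels = None if self.truth_labels is None else self.truth_labels[start:stop]
        return replace(
            self,
            time_h=self.time_h[start:stop],
            tb_c=self.tb_c[start:stop],
            truth_labels=labels,
        )


def _times_to_hours(raw: pd.Series, timestamp_format: str, path: str) -> np.ndarray:
    """Convert a raw timestamp column to decimal hours since the first reading."""
    if timestamp_format == "auto":
        timestamp_format = "hours" if pd.api.types.is_numeric_dtype(raw) else "iso"
    if timestamp_format == "hours":
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise TraceFormatError(
                f"{path}: unparseable decimal-hour timestamp {raw.iloc[row]!r} at row {row}"
            )
        hours = vals.to_numpy(dtype=float)
    elif timestamp_format == "iso":
        parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise TraceFormatError(
                f"{path}: unparseable timestamp {raw.iloc[row]!r} at row {row}"
            )
        hours = (parsed - parsed.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    else:
        raise ValidationError(
            f"unknown timestamp_format {timestamp_format!r}; use 'iso', 'hours' or 'auto'"
        )
    return hours - hours[0]


def read_trace(
    path: str | Path,
    column_spec: Mapping[str, str] | None = None,
    timestamp_format: str = "auto",
    individual_id: str | None = None,
    species: str = "unknown",
    time_range_h: tuple[float, float] | None = None,
) -> TbTrace:
    """Read a trace CSV and return a validated :class:`TbTrace`.

    Rows with missing temperature are dropped (and counted in the log);
    they are never interpolated, because interpolation would distort the
    marginal distribution under study.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_spec
        Maps the roles ``"time"`` and ``"temperature"`` to column names
        in the file. Defaults to ``{"time": "time", "temperature": "tb_c"}``.
    timestamp_format
        ``"iso"`` (ISO-8601 datetimes), ``"hours"`` (decimal hours), or
        ``"auto"`` (numeric column -> hours, otherwise ISO).
    time_range_h
        Optional (start, end) window in hours-since-start applied after
        normalization; readings outside are dropped.
    """
    path = Path(path)
    spec = dict(DEFAULT_COLUMNS)
    if column_spec:
        spec.update(column_spec)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise TraceFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    for role in ("time", "temperature"):
        if spec[role] not in df.columns:
            raise TraceFormatError(
                f"{path}: missing column {spec[role]!r} (for {role}); "
                f"found {list(df.columns)}"
            )
    tb = pd.to_numeric(df[spec["temperature"]], errors="coerce")
    keep = tb.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with missing temperature", path, n_dropped)
    df = df.loc[keep]
    tb = tb.loc[keep]
    if df.empty:
        raise ValidationError(f"{path}: no rows with a temperature value")
    hours = _times_to_hours(df[spec["time"]], timestamp_format, str(path))
    if time_range_h is not None:
        lo, hi = time_range_h
        sel = (hours >= lo) & (hours <= hi)
        hours, tb = hours[sel] - hours[sel][0], tb.iloc[sel]
    interval = None
    if hours.size > 1:
        interval = float(np.median(np.diff(hours)) * 60.0)
    return TbTrace(
        time_h=hours,
        tb_c=tb.to_numpy(dtype=float),
        individual_id=individual_id or path.stem,
        species=species,
        sample_interval_min=interval,
    )


def write_trace(trace: TbTrace, path: str | Path, labels: bool = False) -> None:
    """Write a trace as CSV (columns time, tb_c[, truth_label])."""
    cols = {"time": trace.time_h, "tb_c": trace.tb_c}
    if labels and trace.truth_labels is not None:
        cols["truth_label"] = trace.truth_labels
    pd.DataFrame(cols).to_csv(path, index=False)


def segment_trace(
    trace: TbTrace,
    max_gap_h: float = DEFAULT_MAX_GAP_H,
    min_fit_duration_h: float = DEFAULT_MIN_FIT_DURATION_H,
) -> list[TbTrace]:
    """Split a trace at every inter-sample gap exceeding ``max_gap_h``.

    Quantile smooths must never bridge logger gaps. Segments shorter
    than ``min_fit_duration_h`` get ``fit_usable=False``. Concatenating
    the returned segments reproduces the input readings in order.
    """
    if max_gap_h <= 0:
        raise ValidationError("max_gap_h must be positive")
    gaps = np.diff(trace.time_h)
    cuts = np.flatnonzero(gaps > max_gap_h) + 1
    bounds = [0, *cuts.tolist(), len(trace)]
    segments = []
    for start, stop in zip(bounds[:-1], bounds[1:]):
        seg = trace.slice(start, stop)
        seg.fit_usable = seg.duration_h >= min_fit_duration_h
        if not seg.fit_usable:
            logger.info(
                "segment [%g, %g] h of %s too short to fit (%.1f h < %.1f h)",
                seg.time_h[0], seg.time_h[-1], trace.individual_id,
                seg.duration_h, min_fit_duration_h,
            )
        segments.append(seg)
    return segments


def write_labels(
    path: str | Path,
    trace: TbTrace,
    q45: np.ndarray,
    q55: np.ndarray,
    phase: Sequence[str],
) -> None:
    """Write the per-reading label file (time_h, tb_c, q45, q55, phase)."""
    pd.DataFrame(
        {
            "time_h": trace.time_h,
            "tb_c": trace.tb_c,
            "q45": np.asarray(q45, dtype=float),
            "q55": np.asarray(q55, dtype=float),
            "phase": list(phase),
        }
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a label file written by :func:`write_labels`."""
    df = pd.read_csv(path)
    missing = {"time_h", "tb_c", "phase"} - set(df.columns)
    if missing:
        raise TraceFormatError(f"{path}: label file missing columns {sorted(missing)}")
    return df


def write_report(
    summaries: Iterable,
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write per-individual summaries (one row/object each) as CSV or JSON.

    Values round-trip losslessly at 4 decimal places via
    :func:`read_report`.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("write_report requires at least one summary")
    rows = [s.to_flat_dict() for s in summaries]
    path = Path(path)
    if format == "csv":
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f")
    elif format == "json":
        def _round(v):
            return round(v, 4) if isinstance(v, float) else v

        payload = [{k: _round(v) for k, v in row.items()} for row in rows]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValidationError(f"unknown report format {format!r}; use 'csv' or 'json'")


def read_report(path: str | Path, format: str = "csv") -> list:
    """Read back a report written by :func:`write_report`."""
    from tbshape.summaries import IndividualSummary  # local import: avoids cycle

    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
        rows = df.to_dict(orient="records")
    elif format == "json":
        rows = json.loads(path.read_text())
    else:
        raise ValidationError(f"unknown report format {format!r}; use 'csv' or 'json'")
    return [IndividualSummary.from_flat_dict(row) for row in rows]
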