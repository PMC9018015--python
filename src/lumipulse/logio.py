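"""Serial-monitor log and experiment-config I/O.

The device streams integer pulse counts per integration window over a serial
monitor, conventionally captured to CSV.  The firmware's exact line format is
not standardised, so two dialects are supported:

Canonical dialect (written by :func:`write_log`)::

    # lumipulse-log v1
    # device_id: SIM
    # n_wells: 2
    # integration_window_ms: 300000
    # session_start: 0
    # wells: A,B
    0,0,6,7
    1,300000,7,6

Metadata lines are prefixed ``#``; data rows are
``window_index,elapsed_ms,count_well1,...`` with LF line endings, window
indices strictly increasing from 0 and ``elapsed_ms = index * window_ms``.

Raw dialect (:func:`read_raw_log`): one line per window, comma-separated
counts only, no header -- the form a bare serial capture takes; the window
length must then be supplied by the caller.

Experiment designs are read from YAML (:func:`read_design`), schema-validated
with unknown keys rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .device import AcquisitionConfig, CountSeries, SensorSpec
from .signals import (
    ExperimentDesign,
    SignalProfile,
    TreatmentEffect,
    WellDesign,
)

__all__ = [
    "LogHeader",
    "LogParseError",
    "read_log",
    "read_raw_log",
    "write_log",
    "read_design",
]

_MAGIC = "# lumipulse-log v1"


class LogParseError(ValueError):
    """Raised when a serial log violates the dialect, naming the line."""


@dataclass(frozen=True)
class LogHeader:
    device_id: str
    n_wells: int
    integration_window_ms: int
    wells: tuple[str, ...]
    session_start: str = "0"

    def __post_init__(self) -> None:
        if len(self.wells) != self.n_wells:
            raise ValueError("header wells list must match n_wells")
        if self.integration_window_ms <= 0:
            raise ValueError("integration_window_ms must be positive")
        for w in self.wells:
            _check_label(w)


def _check_label(label: str) -> None:
    if not label or not label.isascii() or any(c in label for c in ",#\n\r \t"):
        raise ValueError(
            f"well label {label!r} invalid: labels must be non-empty ASCII "
            "without commas, whitespace or '#'"
        )


def _as_text(source) -> str:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        p = Path(source)
        if p.exists():
            return p.read_text()
    if isinstance(source, str):
        return source
    if isinstance(source, Path):
        return source.read_text()
    if hasattr(source, "read"):
        data = source.read()
        return data.decode() if isinstance(data, bytes) else data
    raise TypeError("expected path, text or file-like object")


def read_log(source) -> tuple[list[CountSeries], LogHeader]:
    """Parse a canonical serial log into one :class:`CountSeries` per well.

    ``source`` may be a path, the log text itself, or a file-like object.
    Malformed input raises :class:`LogParseError` naming the offending line.
    """
    text = _as_text(source)
    lines = text.split("\n")
    meta: dict[str, str] = {}
    data_start = 0
    if not lines or lines[0].strip() != _MAGIC:
        raise LogParseError("line 1: missing 'lumipulse-log v1' signature")
    for i, line in enumerate(lines):
        if line.startswith("#"):
            data_start = i + 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
        else:
            break

    for key in ("device_id", "n_wells", "integration_window_ms", "wells"):
        if key not in meta:
            raise LogParseError(f"header: missing '{key}' field")
    try:
        n_wells = int(meta["n_wells"])
        window_ms = int(meta["integration_window_ms"])
    except ValueError as exc:
        raise LogParseError(f"header: {exc}") from None
    wells = tuple(meta["wells"].split(","))
    header = LogHeader(
        device_id=meta["device_id"],
        n_wells=n_wells,
        integration_window_ms=window_ms,
        wells=wells,
        session_start=meta.get("session_start", "0"),
    )

    counts_rows: list[list[int]] = []
    expected_index = 0
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2 + n_wells:
            raise LogParseError(
                f"line {lineno}: expected {2 + n_wells} fields, got {len(parts)}"
            )
        try:
            values = [int(p) for p in parts]
        except ValueError:
            raise LogParseError(f"line {lineno}: non-integer field") from None
        idx, elapsed, counts = values[0], values[1], values[2:]
        if idx != expected_index:
            raise LogParseError(
                f"line {lineno}: window_index {idx}, expected {expected_index}"
            )
        if elapsed != idx * window_ms:
            raise LogParseError(
                f"line {lineno}: elapsed_ms {elapsed} != {idx * window_ms}"
            )
        if any(c < 0 for c in counts):
            raise LogParseError(f"line {lineno}: negative count")
        counts_rows.append(counts)
        expected_index += 1

    window_s = window_ms / 1000.0
    arr = np.array(counts_rows, dtype=np.int64).reshape(len(counts_rows), n_wells)
    return (
        [
            CountSeries(well_id=wells[j], window_length=window_s, counts=arr[:, j])
            for j in range(n_wells)
        ],
        header,
    )


def read_raw_log(
    source, window_s: float, well_ids: Sequence[str] | None = None
) -> list[CountSeries]:
    """Parse a headerless capture: one comma-separated count row per window."""
    text = _as_text(source)
    rows = []
    n_cols = None
    for lineno, line in enumerate(text.split("\n"), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split(",")
        if n_cols is None:
            n_cols = len(parts)
        elif len(parts) != n_cols:
            raise LogParseError(f"line {lineno}: ragged row ({len(parts)} fields)")
        try:
            vals = [int(p) for p in parts]
        except ValueError:
            raise LogParseError(f"line {lineno}: non-integer field") from None
        if any(v < 0 for v in vals):
            raise LogParseError(f"line {lineno}: negative count")
        rows.append(vals)
    if not rows:
        raise LogParseError("no data rows")
    if well_ids is None:
        well_ids = [f"W{j + 1}" for j in range(n_cols)]
    if len(well_ids) != n_cols:
        raise LogParseError("well_ids length does not match column count")
    arr = np.array(rows, dtype=np.int64)
    return [
        CountSeries(well_id=well_ids[j], window_length=window_s, counts=arr[:, j])
        for j in range(n_cols)
    ]


def write_log(series: Sequence[CountSeries], header: LogHeader | None = None) -> str:
    """Render CountSeries to the canonical dialect (LF endings, '#' header)."""
    if not series:
        if header is None:
            raise ValueError("header required when writing an empty series set")
        return _render_header(header)
    lengths = {len(s) for s in series}
    windows = {s.window_length for s in series}
    if len(lengths) != 1 or len(windows) != 1:
        raise ValueError("all series must share window_length and length")
    window_ms = int(round(series[0].window_length * 1000))
    if header is None:
        header = LogHeader(
            device_id="SIM",
            n_wells=len(series),
            integration_window_ms=window_ms,
            wells=tuple(s.well_id for s in series),
        )
    if header.n_wells != len(series):
        raise ValueError("header n_wells does not match series count")
    if header.integration_window_ms != window_ms:
        raise ValueError("header window does not match series window_length")
    out = [_render_header(header)]
    matrix = np.stack([s.counts for s in series], axis=1)
    for k in range(matrix.shape[0]):
        row = ",".join(str(int(c)) for c in matrix[k])
        out.append(f"{k},{k * window_ms},{row}\n")
    return "".join(out)


def _render_header(header: LogHeader) -> str:
    return (
        f"{_MAGIC}\n"
        f"# device_id: {header.device_id}\n"
        f"# n_wells: {header.n_wells}\n"
        f"# integration_window_ms: {header.integration_window_ms}\n"
        f"# session_start: {header.session_start}\n"
        f"# wells: {','.join(header.wells)}\n"
    )


# ---------------------------------------------------------------------------
# Experiment-design configs (YAML)
# ---------------------------------------------------------------------------

_SENSOR_KEYS = {"dark_frequency", "responsivity", "max_frequency", "spectral_range"}
_ACQ_KEYS = {"n_wells", "integration_window", "total_duration", "interrupt_dead_time", "seed"}
_WELL_KEYS = {"well_id", "profile", "treatments", "replicate_group", "basal_rate"}
_TREAT_KEYS = {"time", "kind", "concentration", "ic50", "hill_n"}
_TOP_KEYS = {"name", "sensor", "acquisition", "wells"}


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")


def read_design(source) -> ExperimentDesign:
    """Load an :class:`ExperimentDesign` from a YAML config.

    Schema (unknown keys rejected)::

        name: my-experiment          # optional label
        sensor:                      # optional; datasheet defaults
          dark_frequency: 0.1
        acquisition:
          total_duration: 43200
          integration_window: 300    # optional, default 300 s
          interrupt_dead_time: 5e-6  # optional
          seed: 0                    # optional
        wells:
          - well_id: A
            replicate_group: treated
            basal_rate: 0.04
            profile: {variant: rise_decay, latency: 3600, rise_tau: 9000,
                      peak_rate: 0.41, decay_tau: 57500}
            treatments:
              - {time: 3600, kind: activate}

    A cosine profile without a period defaults to 30 h.
    """
    text = _as_text(source)
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("design must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "design")
    if "wells" not in raw or "acquisition" not in raw:
        raise ValueError("design requires 'acquisition' and 'wells' sections")

    sensor_cfg = raw.get("sensor", {}) or {}
    _reject_unknown(sensor_cfg, _SENSOR_KEYS, "sensor")
    if "spectral_range" in sensor_cfg:
        sensor_cfg["spectral_range"] = tuple(sensor_cfg["spectral_range"])
    sensor = SensorSpec(**sensor_cfg)

    acq_cfg = dict(raw["acquisition"])
    _reject_unknown(acq_cfg, _ACQ_KEYS, "acquisition")
    wells_raw = raw["wells"]
    if not isinstance(wells_raw, list) or not wells_raw:
        raise ValueError("wells must be a non-empty list")
    acq_cfg.setdefault("n_wells", len(wells_raw))
    acquisition = AcquisitionConfig(**acq_cfg)

    wells = []
    for i, w in enumerate(wells_raw):
        where = f"wells[{i}]"
        if not isinstance(w, dict):
            raise ValueError(f"{where}: must be a mapping")
        _reject_unknown(w, _WELL_KEYS, where)
        if "profile" not in w:
            raise ValueError(f"{where}: missing profile")
        prof = dict(w["profile"])
        variant = prof.pop("variant", None)
        if variant is None:
            raise ValueError(f"{where}: profile requires a variant")
        profile = SignalProfile(variant, prof)
        treatments = tuple(
            _parse_treatment(t, f"{where}.treatments[{j}]")
            for j, t in enumerate(w.get("treatments", []) or [])
        )
        wells.append(
            WellDesign(
                well_id=str(w.get("well_id", f"W{i + 1}")),
                profile=profile,
                treatments=treatments,
                replicate_group=str(w.get("replicate_group", "default")),
                basal_rate=float(w.get("basal_rate", 0.0)),
            )
        )
    return ExperimentDesign(wells=tuple(wells), acquisition=acquisition, sensor=sensor)


def _parse_treatment(t: dict, where: str) -> TreatmentEffect:
    if not isinstance(t, dict):
        raise ValueError(f"{where}: must be a mapping")
    _reject_unknown(t, _TREAT_KEYS, where)
    if "time" not in t or "kind" not in t:
        raise ValueError(f"{where}: requires 'time' and 'kind'")
    return TreatmentEffect(
        time=float(t["time"]),
        kind=str(t["kind"]),
        concentration=float(t.get("concentration", 0.0)),
        ic50=float(t.get("ic50", 1.0)),
        hill_n=float(t.get("hill_n", 1.0)),
    )
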