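"""Trace file input/output and instrument calibration.

A *trace* is one flow-through respirometry trial: a multichannel time
series (dry excurrent O2 and CO2 fractions, excurrent relative humidity,
humidity-probe temperature, STPD mass-flow rate) recorded every 10-30 s,
bracketed by animal-free baseline segments, plus the trial metadata
(animal, population, body masses, final body temperature, target ambient
temperature, chamber geometry).

The canonical on-disk format is a single UTF-8 CSV per trial with the
metadata in ``# key=value`` comment lines before the column header.  Gas
fractions are stored dimensionless (0.2095, not 20.95); a reader-side
``percent`` declaration in the header converts on load.  Floats are
written with ``repr`` so a write->read round trip is bit exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "CANONICAL_COLUMNS",
    "STANDARD_PRESSURE_KPA",
    "TraceParseError",
    "CalibrationError",
    "TrialMeta",
    "RawTrace",
    "ChannelCalibration",
    "CalibrationModel",
    "Finding",
    "ValidationRules",
    "read_trace",
    "write_trace",
    "apply_calibration",
    "validate_trace",
]

#: Phase labels, in the order they must appear within a trial.
PHASES = ("baseline_pre", "animal", "baseline_post")

#: Canonical data columns of the trace CSV.
CANONICAL_COLUMNS = (
    "time_s",
    "o2_frac",
    "co2_frac",
    "rh_pct",
    "t_probe_C",
    "flow_stpd_ml_min",
    "phase",
)

#: Sea-level standard pressure, used when a trial does not record one.
STANDARD_PRESSURE_KPA = 101.325

_TRACE_MAGIC = "endophys-trace v1"


class TraceParseError(ValueError):
    """A trace file violates the format or a hard invariant."""


class CalibrationError(ValueError):
    """A calibration model is degenerate (e.g. zero-width span)."""


# ---------------------------------------------------------------------------
# Trial metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialMeta:
    """Per-trial metadata carried alongside the time series.

    ``barometric_pressure_kPa`` may be ``None``; :meth:`pressure_kPa`
    then falls back to standard pressure with a warning, since many
    field respirometry datasets omit it.
    """

    animal_id: str
    population_id: str
    species: str = "unspecified"
    mass_before_g: float = float("nan")
    mass_after_g: float = float("nan")
    tb_final_C: float | None = None
    ta_target_C: float = 25.0
    chamber_volume_ml: float = 8000.0
    barometric_pressure_kPa: float | None = None
    sample_interval_s: float = 15.0
    fi_o2: float = 0.2095
    fi_co2: float = 0.0004
    calibrated: bool = False

    @property
    def mean_mass_g(self) -> float:
        return 0.5 * (self.mass_before_g + self.mass_after_g)

    def pressure_kPa(self) -> float:
        """Barometric pressure, defaulting to 101.325 kPa with a warning."""
        if self.barometric_pressure_kPa is None:
            warnings.warn(
                "barometric pressure missing; assuming standard "
                f"{STANDARD_PRESSURE_KPA} kPa",
                stacklevel=2,
            )
            return STANDARD_PRESSURE_KPA
        return self.barometric_pressure_kPa


_META_FLOAT_FIELDS = {
    "mass_before_g",
    "mass_after_g",
    "tb_final_C",
    "ta_target_C",
    "chamber_volume_ml",
    "barometric_pressure_kPa",
    "sample_interval_s",
    "fi_o2",
    "fi_co2",
}
_META_BOOL_FIELDS = {"calibrated"}
_META_OPTIONAL_FIELDS = {"tb_final_C", "barometric_pressure_kPa"}


# ---------------------------------------------------------------------------
# RawTrace
# ---------------------------------------------------------------------------

@dataclass
class RawTrace:
    """One trial's calibrated or uncalibrated multichannel time series."""

    time_s: np.ndarray
    o2_frac: np.ndarray
    co2_frac: np.ndarray
    rh_pct: np.ndarray
    t_probe_C: np.ndarray
    flow_stpd_ml_min: np.ndarray
    phase: np.ndarray
    meta: TrialMeta

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in CANONICAL_COLUMNS:
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise TraceParseError(f"column {name!r} has length {arr.shape}, expected ({n},)")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.time_s)

    def phase_mask(self, name: str) -> np.ndarray:
        return self.phase == name

    def phase_duration_s(self, name: str) -> float:
        """Duration of a phase, counting each sample as one interval."""
        m = self.phase_mask(name)
        if not m.any():
            return 0.0
        t = self.time_s[m]
        if len(t) == 1:
            return float(self.meta.sample_interval_s)
        dt = float(np.median(np.diff(t)))
        return float(t[-1] - t[0] + dt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in CANONICAL_COLUMNS})


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def write_trace(trace: RawTrace, path: str | Path) -> Path:
    """Write a trace to the canonical CSV format (bit-exact round trip)."""
    path = Path(path)
    lines = [f"# {_TRACE_MAGIC}"]
    for f in fields(TrialMeta):
        v = getattr(trace.meta, f.name)
        if v is None:
            v = "none"
        elif isinstance(v, bool):
            v = "true" if v else "false"
        elif isinstance(v, float):
            v = repr(v)
        lines.append(f"# {f.name}={v}")
    lines.append(",".join(CANONICAL_COLUMNS))
    cols = [getattr(trace, c) for c in CANONICAL_COLUMNS[:-1]]
    for i in range(len(trace)):
        row = [repr(float(c[i])) for c in cols]
        row.append(str(trace.phase[i]))
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _parse_meta(header: Mapping[str, str], path: Path) -> TrialMeta:
    kwargs: dict = {}
    known = {f.name for f in fields(TrialMeta)}
    for key, raw in header.items():
        if key not in known:
            continue  # forward-compatible: ignore unknown keys
        if key in _META_FLOAT_FIELDS:
            if raw.lower() in {"none", "nan", ""}:
                kwargs[key] = None if key in _META_OPTIONAL_FIELDS else float("nan")
            else:
                try:
                    kwargs[key] = float(raw)
                except ValueError as exc:
                    raise TraceParseError(
                        f"{path}: metadata {key}={raw!r} is not a number"
                    ) from exc
        elif key in _META_BOOL_FIELDS:
            kwargs[key] = raw.lower() in {"true", "1", "yes"}
        else:
            kwargs[key] = raw
    for required in ("animal_id", "population_id"):
        if required not in kwargs:
            raise TraceParseError(f"{path}: missing metadata key {required!r}")
    return TrialMeta(**kwargs)


def read_trace(path: str | Path, schema: Mapping[str, str] | None = None) -> RawTrace:
    """Read a trace CSV.

    Parameters
    ----------
    path : path to the trace file.
    schema : optional map from canonical column names to the names used
        in the file, for foreign CSV dialects.  ``schema`` may also carry
        the key ``"units"`` with value ``"percent"`` to declare that gas
        fractions are stored as percentages and must be divided by 100.

    Raises
    ------
    TraceParseError
        Missing column, non-monotone time, or unknown phase label; the
        message names the offending column or data row.
    """
    path = Path(path)
    if not path.exists():
        raise TraceParseError(f"{path}: no such file")

    header: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                header[key.strip()] = val.strip()

    percent = False
    rename: dict[str, str] = {}
    if schema:
        percent = str(schema.get("units", "")).lower() == "percent"
        rename = {v: k for k, v in schema.items() if k in CANONICAL_COLUMNS}

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if rename:
        df = df.rename(columns=rename)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise TraceParseError(f"{path}: missing column {col!r}")

    time = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(time) <= 0)[0]
    if bad.size:
        raise TraceParseError(
            f"{path}: time_s not strictly increasing at data row {int(bad[0]) + 1}"
        )

    phase = df["phase"].astype(str).to_numpy()
    unknown = ~np.isin(phase, PHASES)
    if unknown.any():
        row = int(np.nonzero(unknown)[0][0])
        raise TraceParseError(
            f"{path}: unknown phase label {phase[row]!r} at data row {row}"
        )
    _check_phase_order(phase, path)

    scale = 0.01 if percent else 1.0
    meta = _parse_meta(header, path)
    return RawTrace(
        time_s=time,
        o2_frac=df["o2_frac"].to_numpy(dtype=float) * scale,
        co2_frac=df["co2_frac"].to_numpy(dtype=float) * scale,
        rh_pct=df["rh_pct"].to_numpy(dtype=float),
        t_probe_C=df["t_probe_C"].to_numpy(dtype=float),
        flow_stpd_ml_min=df["flow_stpd_ml_min"].to_numpy(dtype=float),
        phase=phase,
        meta=meta,
    )


def _check_phase_order(phase: np.ndarray, path: Path) -> None:
    order = {p: i for i, p in enumerate(PHASES)}
    seen: list[str] = []
    for i, p in enumerate(phase):
        if not seen or seen[-1] != p:
            if p in seen:
                raise TraceParseError(f"{path}: phase {p!r} re-appears at data row {i}")
            if seen and order[p] < order[seen[-1]]:
                raise TraceParseError(
                    f"{path}: phase {p!r} out of order at data row {i}"
                )
            seen.append(p)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelCalibration:
    """Two-point linear map: raw analyzer reading -> physical value.

    ``reading_zero`` maps to ``value_zero`` and ``reading_span`` to
    ``value_span``; intermediate readings are linearly interpolated
    (and extrapolated beyond the anchors).
    """

    reading_zero: float
    reading_span: float
    value_zero: float
    value_span: float

    def __post_init__(self) -> None:
        if not self.reading_span > self.reading_zero:
            raise CalibrationError(
                "span reading must be strictly greater than zero reading "
                f"({self.reading_span} <= {self.reading_zero})"
            )

    def apply(self, raw: np.ndarray) -> np.ndarray:
        frac = (np.asarray(raw, dtype=float) - self.reading_zero) / (
            self.reading_span - self.reading_zero
        )
        return self.value_zero + frac * (self.value_span - self.value_zero)

    @classmethod
    def identity(cls) -> "ChannelCalibration":
        return cls(0.0, 1.0, 0.0, 1.0)


@dataclass(frozen=True)
class CalibrationModel:
    """Full instrument calibration for one respirometry system.

    Gas channels use a zero gas (nitrogen, 0% O2 and CO2) and a span gas
    (room air 20.95% O2; a precision CO2 mix); the RH probe uses 1% RH
    (desiccated air) and 100% RH (saturated) anchors; the flow channel
    carries a multiplicative STPD correction traceable to a flow standard.
    """

    o2: ChannelCalibration = field(
        default_factory=lambda: ChannelCalibration(0.0, 0.2095, 0.0, 0.2095)
    )
    co2: ChannelCalibration = field(
        default_factory=lambda: ChannelCalibration(0.0, 0.0053, 0.0, 0.0053)
    )
    rh: ChannelCalibration = field(
        default_factory=lambda: ChannelCalibration(1.0, 100.0, 1.0, 100.0)
    )
    flow_stpd_factor: float = 1.0

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(
            o2=ChannelCalibration.identity(),
            co2=ChannelCalibration.identity(),
            rh=ChannelCalibration.identity(),
            flow_stpd_factor=1.0,
        )


def apply_calibration(trace: RawTrace, cal: CalibrationModel) -> RawTrace:
    """Map every channel of a raw trace through its two-point calibration.

    Identity calibration leaves the trace unchanged.  The returned trace's
    metadata is marked ``calibrated=True``.
    """
    if cal.flow_stpd_factor <= 0:
        raise CalibrationError("flow STPD factor must be positive")
    return RawTrace(
        time_s=trace.time_s.copy(),
        o2_frac=cal.o2.apply(trace.o2_frac),
        co2_frac=cal.co2.apply(trace.co2_frac),
        rh_pct=cal.rh.apply(trace.rh_pct),
        t_probe_C=trace.t_probe_C.copy(),
        flow_stpd_ml_min=trace.flow_stpd_ml_min * cal.flow_stpd_factor,
        phase=trace.phase.copy(),
        meta=replace(trace.meta, calibrated=True),
    )


# ---------------------------------------------------------------------------
# Validation (findings, not exceptions)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    channel: str
    message: str
    index: int | None = None


@dataclass(frozen=True)
class ValidationRules:
    """Physical-range and protocol checks applied by :func:`validate_trace`."""

    o2_range: tuple[float, float] = (0.0, 0.25)
    co2_range: tuple[float, float] = (0.0, 0.06)
    rh_range: tuple[float, float] = (0.0, 100.0)
    interval_range_s: tuple[float, float] = (10.0, 30.0)
    min_animal_s: float = 1200.0
    min_baseline_s: float = 1200.0
    require_all_phases: bool = True


def validate_trace(trace: RawTrace, rules: ValidationRules | None = None) -> list[Finding]:
    """Check a trace against invariants and physical-range rules.

    Returns an empty list iff everything passes.  Range violations on a
    channel are errors; protocol shortfalls (short phases, off-nominal
    sampling interval) are warnings.
    """
    rules = rules or ValidationRules()
    out: list[Finding] = []

    def _range(channel: str, arr: np.ndarray, lo: float, hi: float) -> None:
        bad = np.nonzero((arr < lo) | (arr > hi) | ~np.isfinite(arr))[0]
        if bad.size:
            out.append(
                Finding(
                    "error",
                    channel,
                    f"{bad.size} sample(s) outside [{lo}, {hi}], first at index {int(bad[0])}",
                    int(bad[0]),
                )
            )

    _range("o2_frac", trace.o2_frac, *rules.o2_range)
    _range("co2_frac", trace.co2_frac, *rules.co2_range)
    _range("rh_pct", trace.rh_pct, *rules.rh_range)
    if (trace.flow_stpd_ml_min <= 0).any():
        idx = int(np.nonzero(trace.flow_stpd_ml_min <= 0)[0][0])
        out.append(Finding("error", "flow_stpd_ml_min", "non-positive flow", idx))

    if len(trace) > 1:
        dt = np.diff(trace.time_s)
        if (dt <= 0).any():
            idx = int(np.nonzero(dt <= 0)[0][0]) + 1
            out.append(Finding("error", "time_s", "time not strictly increasing", idx))
        lo, hi = rules.interval_range_s
        med = float(np.median(dt))
        if not lo <= med <= hi:
            out.append(
                Finding(
                    "warning",
                    "time_s",
                    f"median sample interval {med:.1f} s outside [{lo}, {hi}] s",
                )
            )

    present = [p for p in PHASES if trace.phase_mask(p).any()]
    if rules.require_all_phases:
        for p in PHASES:
            if p not in present:
                out.append(Finding("error", "phase", f"phase {p!r} missing"))
    for p, minimum in (
        ("baseline_pre", rules.min_baseline_s),
        ("baseline_post", rules.min_baseline_s),
        ("animal", rules.min_animal_s),
    ):
        dur = trace.phase_duration_s(p)
        if p in present and dur < minimum:
            out.append(
                Finding(
                    "warning",
                    "phase",
                    f"phase {p!r} lasts {dur:.0f} s, below minimum {minimum:.0f} s",
                )
            )
    return out
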