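"""Single-lead iECG record type and CSV input/output.

The CSV dialect mirrors the shape of the per-recording export of a
smartwatch health app: an optional block of ``key,value`` header lines
(sampling rate, unit, record id, age), followed by one voltage sample
per line. Voltages are micro-volts internally; a ``unit,mV`` header is
converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

DEFAULT_SAMPLING_RATE_HZ = 512.0

_HEADER_KEYS = {"sample-rate-hz", "unit", "record-id", "age-years"}


class IECGParseError(ValueError):
    """A voltage row could not be parsed."""


@dataclass
class IECGRecord:
    """A single-lead voltage time series.

    Parameters
    ----------
    samples
        Voltage samples in micro-volts (µV).
    sampling_rate_hz
        Sampling rate; the watch records at 512 Hz.
    age_years
        Patient age in years, or ``None`` when unknown. The rhythm
        decision tree needs it; it therefore travels with the record.
    record_id
        Opaque identifier (defaults to the file stem on read).
    metadata
        Free-form string map (device, date, processing notes).
    """

    samples: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    age_years: float | None = None
    record_id: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def read_iecg_csv(
    path: str | Path,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    age_years: float | None = None,
) -> IECGRecord:
    """Read a single-lead iECG CSV export.

    Header ``key,value`` lines are consumed first; a ``sample-rate-hz``
    header overrides the ``sampling_rate_hz`` argument, an
    ``age-years`` header overrides ``age_years``, and ``unit,mV``
    rescales voltages to µV. The remaining lines must hold one numeric
    voltage each.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    IECGParseError
        On a non-numeric voltage row (the message names the line).
    ValueError
        If the file contains no voltage samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"iECG CSV not found: {path}")

    rate = float(sampling_rate_hz)
    age = age_years
    record_id = path.stem
    metadata: dict[str, str] = {}
    unit_scale = 1.0
    values: list[float] = []
    in_header = True

    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if in_header and "," in line:
                key, _, value = line.partition(",")
                key = key.strip().lower()
                value = value.strip()
                if key == "sample-rate-hz":
                    rate = float(value)
                elif key == "unit":
                    if value.lower() in ("mv", "millivolt", "millivolts"):
                        unit_scale = 1000.0
                    elif value.lower() not in ("uv", "µv", "microvolt", "microvolts"):
                        raise IECGParseError(
                            f"line {lineno}: unknown voltage unit {value!r}"
                        )
                elif key == "record-id":
                    record_id = value
                elif key == "age-years":
                    age = float(value)
                else:
                    metadata[key] = value
                continue
            in_header = False
            try:
                values.append(float(line))
            except ValueError as exc:
                raise IECGParseError(
                    f"line {lineno}: expected a numeric voltage, got {line!r}"
                ) from exc

    if not values:
        raise ValueError(f"{path}: file contains no voltage samples")

    samples = np.asarray(values, dtype=float) * unit_scale
    return IECGRecord(
        samples=samples,
        sampling_rate_hz=rate,
        age_years=age,
        record_id=record_id,
        metadata=metadata,
    )


def write_iecg_csv(record: IECGRecord, path: str | Path) -> None:
    """Write ``record`` in the dialect accepted by :func:`read_iecg_csv`.

    The header records the sampling rate and the unit (µV); voltages
    are written with six decimals, so a read-back agrees to 1e-6 µV.
    """
    path = Path(path)
    lines = [f"sample-rate-hz,{record.sampling_rate_hz:g}", "unit,uV"]
    if record.record_id:
        lines.append(f"record-id,{record.record_id}")
    if record.age_years is not None:
        lines.append(f"age-years,{record.age_years:g}")
    for key, value in record.metadata.items():
        lines.append(f"{key},{value}")
    body = "\n".join(f"{v:.6f}" for v in record.samples)
    path.write_text("\n".join(lines) + "\n" + body + "\n", encoding="utf-8")


def metadata_header(record: IECGRecord) -> Mapping[str, str]:
    """Header key/value pairs that :func:`write_iecg_csv` would emit."""
    out = {"sample-rate-hz": f"{record.sampling_rate_hz:g}", "unit": "uV"}
    if record.record_id:
        out["record-id"] = record.record_id
    if record.age_years is not None:
        out["age-years"] = f"{record.age_years:g}"
    out.update(record.metadata)
    return out
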