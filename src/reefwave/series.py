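"""The core in-memory container for one sensor variable at one site.

An :class:`EnvironmentalSeries` is a time-stamped, unit-labeled vector of one
environmental variable (pH, temperature, salinity, depth, or raw ISFET
voltage) with an explicit validity mask.  Missing data are always represented
through the mask, never through sentinel values, so every downstream stage can
account for gaps without guessing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError

#: Canonical variable labels and their units.
VARIABLE_UNITS = {
    "pH_total": "total-scale pH",
    "temperature_C": "degC",
    "salinity": "unitless (kg solids / kg seawater)",
    "depth_m": "m",
    "voltage_V": "V",
}


@dataclass
class EnvironmentalSeries:
    """One uniformly or irregularly sampled sensor variable at one site.

    Parameters
    ----------
    site : str
        Site label (e.g. ``"moorea-like"``).
    variable : str
        Variable label; one of the keys of :data:`VARIABLE_UNITS` or a
        caller-defined label.
    timestamps : numpy.ndarray
        Strictly increasing ``datetime64[ns]`` time points (UTC).
    values : numpy.ndarray
        Float values in the variable's units; entries where ``valid`` is
        False carry no meaning.
    valid : numpy.ndarray
        Boolean mask, True where the sample is usable.
    """

    site: str
    variable: str
    timestamps: np.ndarray
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.timestamps) == len(self.values) == len(self.valid)):
            raise ValueError(
                "timestamps, values and valid must have equal length "
                f"({len(self.timestamps)}, {len(self.values)}, {len(self.valid)})"
            )
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > np.timedelta64(0, "ns")):
            raise ValueError("timestamps must be strictly increasing")

    # ---- construction helpers -------------------------------------------------

    @classmethod
    def from_regular(
        cls,
        start: str | np.datetime64,
        dt_seconds: float,
        values: np.ndarray,
        *,
        site: str = "synthetic",
        variable: str = "value",
        valid: np.ndarray | None = None,
    ) -> "EnvironmentalSeries":
        """Build a series on a uniform grid starting at ``start``."""
        values = np.asarray(values, dtype=float)
        t0 = np.datetime64(start, "ns")
        steps = (np.arange(len(values)) * (dt_seconds * 1e9)).astype("timedelta64[ns]")
        return cls(site=site, variable=variable, timestamps=t0 + steps, values=values, valid=valid)

    # ---- basic properties -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def t_seconds(self) -> np.ndarray:
        """Elapsed time in seconds since the first sample (float64)."""
        if len(self.timestamps) == 0:
            return np.empty(0)
        return (self.timestamps - self.timestamps[0]) / np.timedelta64(1, "s")

    @property
    def dt(self) -> float | None:
        """Sampling interval in seconds if the grid is uniform, else None."""
        if len(self.timestamps) < 2:
            return None
        d = np.diff(self.timestamps) / np.timedelta64(1, "s")
        if np.allclose(d, d[0], rtol=0, atol=1e-6):
            return float(d[0])
        return None

    @property
    def is_uniform(self) -> bool:
        return self.dt is not None

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def copy(self, **changes) -> "EnvironmentalSeries":
        out = replace(
            self,
            timestamps=self.timestamps.copy(),
            values=self.values.copy(),
            valid=self.valid.copy(),
        )
        for k, v in changes.items():
            setattr(out, k, v)
        return out

    def same_grid(self, other: "EnvironmentalSeries") -> bool:
        return len(self) == len(other) and bool(np.array_equal(self.timestamps, other.timestamps))

    # ---- CSV round trip -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "value": self.values,
                "valid": self.valid.astype(int),
            }
        )

    def write_csv(self, path, *, seed: int | None = None) -> None:
        """Write the documented CSV dialect.

        Header comment lines record site, variable, units and (optionally) the
        generator seed; the body has ``timestamp`` (ISO-8601 UTC), ``value``
        and ``valid`` (0/1) columns.
        """
        units = VARIABLE_UNITS.get(self.variable, "unspecified")
        buf = io.StringIO()
        buf.write(f"# site: {self.site}\n")
        buf.write(f"# variable: {self.variable}\n")
        buf.write(f"# units: {units}\n")
        if seed is not None:
            buf.write(f"# seed: {seed}\n")
        df = self.to_frame()
        df["timestamp"] = pd.DatetimeIndex(df["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S.%f")
        df.to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def read_sensor_csv(path, *, site: str | None = None, variable: str | None = None) -> EnvironmentalSeries:
    """Read the CSV dialect written by :meth:`EnvironmentalSeries.write_csv`.

    Raises :class:`~reefwave.errors.FormatError` (with a line number where one
    can be attributed) for unparseable timestamps or non-monotone time.
    """
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in ("timestamp", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    try:
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601").dt.tz_localize(None)
    except Exception as exc:
        raise FormatError(f"{path}: unparseable timestamp(s): {exc}") from exc
    ts = np.asarray(ts, dtype="datetime64[ns]")
    bad = np.nonzero(np.diff(ts) <= np.timedelta64(0, "ns"))[0]
    if bad.size:
        # +2: 1-based line numbering plus the column-header line
        raise FormatError(f"{path}: non-monotone timestamp at data line {bad[0] + 2 + n_header}")
    valid = df["valid"].to_numpy().astype(bool) if "valid" in df.columns else None
    return EnvironmentalSeries(
        site=site or meta.get("site", "unknown"),
        variable=variable or meta.get("variable", "value"),
        timestamps=ts,
        values=df["value"].to_numpy(dtype=float),
        valid=valid,
    )
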