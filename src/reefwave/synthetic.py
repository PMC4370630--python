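"""Phenomenological generator for reef-like sensor time series.

The generator produces series with the structure autonomous reef sensors
record: a diel (24 h) cycle, a semidiurnal tidal component whose amplitude is
modulated over the ~14.77-day spring–neap cycle, episodic multi-day
depressions (typhoon/upwelling events), and AR(1) red-noise background.  All
components have known ground truth, so every downstream stage (QC, calibration,
carbonate chemistry, wavelets, site comparison) is testable end to end without
field data.

Nothing here is a process model: the forcing is purely descriptive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .calibration import BottleSample, nernst_slope
from .errors import AlignmentError, InvalidConfigError
from .series import EnvironmentalSeries

#: Component periods (hours / days).
DIEL_PERIOD_H = 24.0
#: Principal lunar semidiurnal (M2) tidal period.
SEMIDIURNAL_PERIOD_H = 12.4206012
#: Spring–neap (fortnightly) beat period of the M2/S2 constituents.
SPRING_NEAP_PERIOD_D = 14.765294

EVENT_SHAPES = ("half-cosine", "exp-recovery")

DEFAULT_START = "2012-05-24T00:00:00"


@dataclass
class EventSpec:
    """One episodic depression of a variable (e.g. typhoon-driven upwelling).

    ``half-cosine`` is a smooth Hann-shaped pulse reaching
    ``depth_of_depression`` at the window midpoint; ``exp-recovery`` drops by
    the full depth at ``start_day`` and relaxes back with an e-folding time of
    one fifth of the window (≈0.7 % residual at the window end).
    """

    start_day: float
    duration_days: float
    depth_of_depression: float
    shape: str = "half-cosine"

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise InvalidConfigError("event duration_days must be positive")
        if self.shape not in EVENT_SHAPES:
            raise InvalidConfigError(f"event shape must be one of {EVENT_SHAPES}")

    def evaluate(self, t_days: np.ndarray) -> np.ndarray:
        """Signed contribution (a depression is negative) on a day grid."""
        u = (t_days - self.start_day) / self.duration_days
        inside = (u >= 0) & (u <= 1)
        out = np.zeros_like(t_days)
        if self.shape == "half-cosine":
            out[inside] = -self.depth_of_depression * 0.5 * (1 - np.cos(2 * np.pi * u[inside]))
        else:
            out[inside] = -self.depth_of_depression * np.exp(-5.0 * u[inside])
        return out


@dataclass
class ForcingConfig:
    """Everything needed to generate one variable's series deterministically."""

    duration_days: float
    dt_minutes: float
    baseline: float
    diel_amplitude: float = 0.0
    semidiurnal_amplitude: float = 0.0
    fortnight_modulation_depth: float = 0.0
    ar1_coefficient: float = 0.0
    ar1_innovation_sd: float = 0.0
    events: list[EventSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days <= 0 or self.dt_minutes <= 0:
            raise InvalidConfigError("duration_days and dt_minutes must be positive")
        if self.n_samples < 2:
            raise InvalidConfigError("dt_minutes must divide the duration into at least 2 samples")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise InvalidConfigError("ar1_coefficient must be in [0, 1)")
        if not 0.0 <= self.fortnight_modulation_depth <= 1.0:
            raise InvalidConfigError("fortnight_modulation_depth must be in [0, 1]")
        if self.diel_amplitude < 0 or self.semidiurnal_amplitude < 0 or self.ar1_innovation_sd < 0:
            raise InvalidConfigError("amplitudes and innovation SD must be nonnegative")
        for ev in self.events:
            if ev.start_day < 0 or ev.start_day + ev.duration_days > self.duration_days:
                raise InvalidConfigError("event window must lie inside [0, duration_days]")

    @property
    def n_samples(self) -> int:
        return int(math.floor(self.duration_days * 24 * 60 / self.dt_minutes)) + 1


def _ar1_noise(alpha: float, innovation_sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) draw: x_t = alpha x_{t-1} + eps_t with x_0 ~ N(0, sd^2/(1-alpha^2))."""
    if innovation_sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, innovation_sd, size=n)
    x0 = rng.normal(0.0, innovation_sd / math.sqrt(1 - alpha * alpha))
    x, _ = lfilter([1.0], [1.0, -alpha], eps, zi=np.array([alpha * x0]))
    return x


def generate_series(
    config: ForcingConfig,
    *,
    site: str = "synthetic",
    variable: str = "value",
    start: str | np.datetime64 = DEFAULT_START,
) -> EnvironmentalSeries:
    """Generate one variable's series from its forcing configuration.

    The series is baseline + diel sinusoid + semidiurnal sinusoid whose
    amplitude is modulated on the spring–neap period + event depressions +
    stationary AR(1) noise.  Deterministic for a fixed ``config.seed``.
    """
    n = config.n_samples
    dt_s = config.dt_minutes * 60.0
    t_h = np.arange(n) * (config.dt_minutes / 60.0)
    t_d = t_h / 24.0

    x = np.full(n, config.baseline, dtype=float)
    x += config.diel_amplitude * np.sin(2 * np.pi * t_h / DIEL_PERIOD_H)
    modulation = 1.0 + config.fortnight_modulation_depth * np.sin(
        2 * np.pi * t_d / SPRING_NEAP_PERIOD_D
    )
    x += config.semidiurnal_amplitude * modulation * np.sin(2 * np.pi * t_h / SEMIDIURNAL_PERIOD_H)
    for ev in config.events:
        x += ev.evaluate(t_d)
    rng = np.random.default_rng(config.seed)
    x += _ar1_noise(config.ar1_coefficient, config.ar1_innovation_sd, n, rng)

    return EnvironmentalSeries.from_regular(start, dt_s, x, site=site, variable=variable)


def generate_voltage_series(
    ph: EnvironmentalSeries, temp: EnvironmentalSeries, e_star: float
) -> EnvironmentalSeries:
    """Synthesize the raw ISFET voltage a sensor with reference potential
    ``e_star`` would record for a known pH and temperature history.

    voltage_t = E* + slope(T_t) * pH_t, the exact inverse of the Nernstian
    calibration, so calibrated pH round-trips bit-for-bit.
    """
    if not ph.same_grid(temp):
        raise AlignmentError("pH and temperature series must share one time grid")
    slope = nernst_slope(temp.values + 273.15)
    v = e_star + slope * ph.values
    return EnvironmentalSeries(
        site=ph.site,
        variable="voltage_V",
        timestamps=ph.timestamps.copy(),
        values=v,
        valid=ph.valid & temp.valid,
    )


def inject_gap(series: EnvironmentalSeries, start, stop) -> EnvironmentalSeries:
    """Flag samples in [start, stop) as missing; the grid is unchanged.

    An empty intersection is a no-op (with a warning), mirroring how a field
    record loses a QC-failed segment without losing its time base.
    """
    start = np.datetime64(start, "ns")
    stop = np.datetime64(stop, "ns")
    if start >= stop:
        raise InvalidConfigError("gap start must precede stop")
    hit = (series.timestamps >= start) & (series.timestamps < stop)
    out = series.copy()
    if not hit.any():
        import warnings

        warnings.warn("gap window does not intersect the series; no samples flagged")
        return out
    out.valid[hit] = False
    return out


# ---------------------------------------------------------------------------
# Site scenarios
# ---------------------------------------------------------------------------


@dataclass
class SiteScenario:
    """Per-variable forcing for one synthetic site plus its calibration bottle."""

    name: str
    ph: ForcingConfig
    temperature: ForcingConfig
    salinity: ForcingConfig
    depth: ForcingConfig
    bottle: BottleSample

    def __post_init__(self) -> None:
        cfgs = [self.ph, self.temperature, self.salinity, self.depth]
        if len({c.duration_days for c in cfgs}) != 1 or len({c.dt_minutes for c in cfgs}) != 1:
            raise InvalidConfigError("all variables of a scenario must share duration and dt")

    def generate(self) -> dict[str, EnvironmentalSeries]:
        """Generate all four variables on the shared grid."""
        return {
            "pH_total": generate_series(self.ph, site=self.name, variable="pH_total"),
            "temperature_C": generate_series(
                self.temperature, site=self.name, variable="temperature_C"
            ),
            "salinity": generate_series(self.salinity, site=self.name, variable="salinity"),
            "depth_m": generate_series(self.depth, site=self.name, variable="depth_m"),
        }


def _derive_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(k)]


def moorea_like(
    seed: int = 0, *, duration_days: float = 33.3, dt_minutes: float = 6.0
) -> SiteScenario:
    """North-shore-fringing-reef-like scenario: steady diel pH/temperature
    cycles, constant salinity, small microtidal depth signal."""
    s_ph, s_t, s_d = _derive_seeds(seed, 3)
    return SiteScenario(
        name="moorea-like",
        ph=ForcingConfig(
            duration_days, dt_minutes, baseline=7.989,
            diel_amplitude=0.042, semidiurnal_amplitude=0.008,
            fortnight_modulation_depth=0.3,
            ar1_coefficient=0.9, ar1_innovation_sd=0.010, seed=s_ph,
        ),
        temperature=ForcingConfig(
            duration_days, dt_minutes, baseline=28.76,
            diel_amplitude=0.65, semidiurnal_amplitude=0.05,
            fortnight_modulation_depth=0.2,
            ar1_coefficient=0.97, ar1_innovation_sd=0.08, seed=s_t,
        ),
        salinity=ForcingConfig(duration_days, dt_minutes, baseline=35.65),
        depth=ForcingConfig(
            duration_days, dt_minutes, baseline=3.0,
            diel_amplitude=0.05, semidiurnal_amplitude=0.15,
            fortnight_modulation_depth=0.4,
            ar1_coefficient=0.8, ar1_innovation_sd=0.02, seed=s_d,
        ),
        bottle=BottleSample(
            timestamp=np.datetime64(DEFAULT_START)
            + np.timedelta64(int(0.3 * duration_days * 86400), "s"),
            ph25_total=8.026, alkalinity=2353.0, salinity=35.65,
            temperature_insitu=28.8,
        ),
    )


def taiwan_like(
    seed: int = 1, *, duration_days: float = 45.9, dt_minutes: float = 6.0
) -> SiteScenario:
    """Semi-enclosed-bay-like scenario: mixed (diurnal + semidiurnal) tides,
    spring–neap amplitude modulation, and episodic typhoon/upwelling
    depressions of temperature and salinity."""
    s_ph, s_t, s_s, s_d = _derive_seeds(seed + 10_000, 4)
    # event timing scales with the deployment length so short test scenarios
    # keep the same qualitative structure
    d = duration_days
    temp_events = [
        EventSpec(start_day=0.17 * d, duration_days=0.11 * d, depth_of_depression=3.0,
                  shape="half-cosine"),
        EventSpec(start_day=0.65 * d, duration_days=0.17 * d, depth_of_depression=6.5,
                  shape="exp-recovery"),
    ]
    sal_events = [
        EventSpec(start_day=0.17 * d, duration_days=0.11 * d, depth_of_depression=1.2,
                  shape="half-cosine"),
        EventSpec(start_day=0.65 * d, duration_days=0.17 * d, depth_of_depression=2.5,
                  shape="exp-recovery"),
    ]
    return SiteScenario(
        name="taiwan-like",
        ph=ForcingConfig(
            duration_days, dt_minutes, baseline=7.976,
            diel_amplitude=0.030, semidiurnal_amplitude=0.012,
            fortnight_modulation_depth=0.4,
            ar1_coefficient=0.92, ar1_innovation_sd=0.008, seed=s_ph,
        ),
        temperature=ForcingConfig(
            duration_days, dt_minutes, baseline=28.2,
            diel_amplitude=0.40, semidiurnal_amplitude=0.10,
            fortnight_modulation_depth=0.3,
            ar1_coefficient=0.97, ar1_innovation_sd=0.10,
            events=temp_events, seed=s_t,
        ),
        salinity=ForcingConfig(
            duration_days, dt_minutes, baseline=33.3,
            diel_amplitude=0.05, semidiurnal_amplitude=0.08,
            fortnight_modulation_depth=0.3,
            ar1_coefficient=0.95, ar1_innovation_sd=0.05,
            events=sal_events, seed=s_s,
        ),
        depth=ForcingConfig(
            duration_days, dt_minutes, baseline=4.0,
            diel_amplitude=0.30, semidiurnal_amplitude=0.60,
            fortnight_modulation_depth=0.5,
            ar1_coefficient=0.7, ar1_innovation_sd=0.02, seed=s_d,
        ),
        bottle=BottleSample(
            timestamp=np.datetime64(DEFAULT_START)
            + np.timedelta64(int(0.44 * duration_days * 86400), "s"),
            ph25_total=8.006, alkalinity=2181.0, salinity=33.43,
            temperature_insitu=27.9,
        ),
    )


SCENARIOS = {"moorea-like": moorea_like, "taiwan-like": taiwan_like}
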