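"""End-to-end orchestration of the two-site analysis.

``run_pipeline`` takes a :class:`RunConfig` (usually parsed from a YAML file)
and produces, per site: QC'd series, calibrated pH, a per-sample carbonate
chemistry table, wavelet power with red-noise significance plus global and
scale-averaged exports, and (partial) coherence maps; and across sites: a
summary-statistics table, mean/variance randomization tests, per-percentile
comparisons and a Kolmogorov–Smirnov result.  A manifest with content
checksums is written last, so a completed run is self-describing and two runs
with the same config are byte-comparable.

Every stochastic stage consumes an explicit seed derived from the run seed;
all times are UTC.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import calibration, carbonate, compare, qc, synthetic, wavelet
from .errors import InvalidConfigError, ReefwaveError
from .series import EnvironmentalSeries, read_sensor_csv

__version__ = "0.1.0"

log = logging.getLogger("reefwave.pipeline")


@dataclass
class SiteSpec:
    """One site: either a named synthetic scenario or paths to sensor CSVs."""

    name: str
    scenario: str | None = None
    scenario_duration_days: float | None = None
    scenario_dt_minutes: float | None = None
    ph_csv: str | None = None
    voltage_csv: str | None = None
    temperature_csv: str | None = None
    salinity_csv: str | None = None
    depth_csv: str | None = None
    salinity_constant: float | None = None
    alkalinity: float | None = None  # umol/kg, deployment constant
    bottle: dict | None = None

    def validate(self) -> None:
        if self.scenario is not None:
            if self.scenario not in synthetic.SCENARIOS:
                raise InvalidConfigError(
                    f"site '{self.name}': unknown scenario '{self.scenario}'"
                )
            return
        if self.ph_csv is None and self.voltage_csv is None:
            raise InvalidConfigError(f"site '{self.name}': needs scenario, ph_csv or voltage_csv")
        if self.voltage_csv is not None and self.bottle is None:
            raise InvalidConfigError(
                f"site '{self.name}': voltage input requires a calibration bottle record"
            )
        if self.temperature_csv is None:
            raise InvalidConfigError(f"site '{self.name}': temperature_csv is required")
        if self.salinity_csv is None and self.salinity_constant is None:
            raise InvalidConfigError(
                f"site '{self.name}': provide salinity_csv or salinity_constant"
            )
        for p in (self.ph_csv, self.voltage_csv, self.temperature_csv,
                  self.salinity_csv, self.depth_csv):
            if p is not None and not Path(p).exists():
                raise InvalidConfigError(f"site '{self.name}': input file not found: {p}")


@dataclass
class RunConfig:
    sites: list[SiteSpec]
    output_dir: str = "reefwave_out"
    seed: int = 0
    resample_minutes: float | None = None
    lowpass: bool = True
    spike_k: float | None = 6.0
    wavelet_dj: float = 1.0 / 12.0
    n_surrogates: int = 199
    coherence_enabled: bool = True
    n_randomizations: int = 999
    compare_variables: tuple = ("pH_total", "temperature_C")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sites = [SiteSpec(**s) for s in raw.get("sites", [])]
        qc_cfg = raw.get("qc", {})
        wav = raw.get("wavelet", {})
        cmp_cfg = raw.get("compare", {})
        return cls(
            sites=sites,
            output_dir=raw.get("output_dir", "reefwave_out"),
            seed=int(raw.get("seed", 0)),
            resample_minutes=qc_cfg.get("resample_minutes"),
            lowpass=bool(qc_cfg.get("lowpass", True)),
            spike_k=qc_cfg.get("spike_k", 6.0),
            wavelet_dj=float(wav.get("dj", 1.0 / 12.0)),
            n_surrogates=int(wav.get("n_surrogates", 199)),
            coherence_enabled=bool(wav.get("coherence", True)),
            n_randomizations=int(cmp_cfg.get("n_randomizations", 999)),
            compare_variables=tuple(cmp_cfg.get("variables", ("pH_total", "temperature_C"))),
        )

    def validate(self) -> None:
        if len(self.sites) != 2:
            raise InvalidConfigError("the pipeline compares exactly two sites")
        names = [s.name for s in self.sites]
        if len(set(names)) != 2:
            raise InvalidConfigError("site names must be distinct")
        for s in self.sites:
            s.validate()

    def config_hash(self) -> str:
        # hash the analysis configuration, not the output location
        blob = json.dumps(
            {**{k: v for k, v in self.__dict__.items() if k not in ("sites", "output_dir")},
             "sites": [s.__dict__ for s in self.sites]},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    outputs: dict = field(default_factory=dict)  # path -> sha256
    stages: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _bottle_from_dict(d: dict) -> calibration.BottleSample:
    return calibration.BottleSample(
        timestamp=np.datetime64(d["timestamp"]),
        ph25_total=float(d["ph25_total"]),
        alkalinity=float(d["alkalinity"]),
        salinity=float(d["salinity"]),
        temperature_insitu=float(d["temperature_insitu"]),
    )


def _ph_insitu_to_25(ph_insitu: float, ta: float, t_insitu: float, s: float) -> float:
    return carbonate.convert_ph_temperature(ph_insitu, ta, t_insitu, 25.0, s)


def _load_site(spec: SiteSpec, seed: int):
    """Return (series dict, bottle, alkalinity, salinity constant or None)."""
    if spec.scenario is not None:
        kwargs = {}
        if spec.scenario_duration_days is not None:
            kwargs["duration_days"] = spec.scenario_duration_days
        if spec.scenario_dt_minutes is not None:
            kwargs["dt_minutes"] = spec.scenario_dt_minutes
        scn = synthetic.SCENARIOS[spec.scenario](seed=seed, **kwargs)
        series = scn.generate()
        bottle = scn.bottle
        # Exercise the raw-voltage path: synthesize the voltage record the
        # sensor would have produced, with a bottle made exactly consistent
        # with the generated pH at the calibration instant.
        true_ph = series.pop("pH_total")
        temp = series["temperature_C"]
        e_star_true = 0.95
        voltage = synthetic.generate_voltage_series(true_ph, temp, e_star_true)
        t_cal = (bottle.timestamp - true_ph.timestamps[0]) / np.timedelta64(1, "s")
        ph_at_cal = float(np.interp(t_cal, true_ph.t_seconds, true_ph.values))
        temp_at_cal = float(np.interp(t_cal, temp.t_seconds, temp.values))
        bottle = calibration.BottleSample(
            timestamp=bottle.timestamp,
            ph25_total=_ph_insitu_to_25(ph_at_cal, bottle.alkalinity, temp_at_cal,
                                        bottle.salinity),
            alkalinity=bottle.alkalinity,
            salinity=bottle.salinity,
            temperature_insitu=temp_at_cal,
        )
        series["voltage_V"] = voltage
        sal_const = None
        if np.var(series["salinity"].values) == 0:
            sal_const = float(series["salinity"].values[0])
        return series, bottle, bottle.alkalinity, sal_const

    series = {}
    if spec.ph_csv:
        series["pH_total"] = read_sensor_csv(spec.ph_csv, variable="pH_total")
    if spec.voltage_csv:
        series["voltage_V"] = read_sensor_csv(spec.voltage_csv, variable="voltage_V")
    series["temperature_C"] = read_sensor_csv(spec.temperature_csv, variable="temperature_C")
    if spec.salinity_csv:
        series["salinity"] = read_sensor_csv(spec.salinity_csv, variable="salinity")
    if spec.depth_csv:
        series["depth_m"] = read_sensor_csv(spec.depth_csv, variable="depth_m")
    bottle = _bottle_from_dict(spec.bottle) if spec.bottle else None
    ta = spec.alkalinity if spec.alkalinity is not None else (
        bottle.alkalinity if bottle else None
    )
    if ta is None:
        raise InvalidConfigError(f"site '{spec.name}': no alkalinity available")
    return series, bottle, float(ta), spec.salinity_constant


def _qc_series(s: EnvironmentalSeries, cfg: RunConfig):
    cleaned, report = qc.clean_outliers(s, spike_k=cfg.spike_k)
    dt = cfg.resample_minutes * 60.0 if cfg.resample_minutes else (cleaned.dt or 600.0)
    uniform = qc.resample_uniform(cleaned, dt)
    if cfg.lowpass and dt <= 1800.0:
        uniform = qc.lowpass_1h(uniform)
    log.info("qc[%s/%s]: %d in, %d out-of-range, %d spikes, dt=%.0fs",
             s.site, s.variable, report.n_input, report.n_removed_out_of_range,
             report.n_removed_spike, dt)
    return uniform, report


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full two-site analysis; see the module docstring."""
    import pandas as pd

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__, seed=config.seed,
        started=str(np.datetime64("now")),
    )
    written: list[Path] = []

    def save_csv(df, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)
        return p

    def save_json(obj, name: str) -> Path:
        p = out / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=1, default=str)
        written.append(p)
        return p

    stage = "setup"
    site_seeds = [int(s) % (2**31 - 1)
                  for s in np.random.SeedSequence(config.seed).generate_state(8)]
    try:
        processed = {}
        summaries = {}
        for i, spec in enumerate(config.sites):
            stage = f"load:{spec.name}"
            series, bottle, ta, sal_const = _load_site(spec, site_seeds[i])

            stage = f"calibrate:{spec.name}"
            if "pH_total" not in series:
                fit = calibration.calibrate_from_bottles(
                    series["voltage_V"], series["temperature_C"], bottle
                )
                fit.to_json(out / f"{spec.name}_calibration.json", bottle=bottle)
                written.append(out / f"{spec.name}_calibration.json")
                series["pH_total"] = calibration.voltage_to_ph(
                    series["voltage_V"], series["temperature_C"], fit
                )

            stage = f"qc:{spec.name}"
            clean = {}
            reports = {}
            for var in ("pH_total", "temperature_C", "salinity", "depth_m"):
                if var in series:
                    clean[var], reports[var] = _qc_series(series[var], config)
                    p = out / f"{spec.name}_{var}_qc.csv"
                    clean[var].write_csv(p, seed=config.seed)
                    written.append(p)
            save_json({v: r.to_dict() for v, r in reports.items()},
                      f"{spec.name}_qc_report.json")

            stage = f"carbonate:{spec.name}"
            sal = sal_const if sal_const is not None else clean.get("salinity", sal_const)
            if sal is None:
                sal = bottle.salinity if bottle else 35.0
            if isinstance(sal, EnvironmentalSeries) and not clean["pH_total"].same_grid(sal):
                sal = float(np.nanmean(sal.values))
            carb = carbonate.solve_series(clean["pH_total"], clean["temperature_C"], sal, ta)
            save_csv(carb, f"{spec.name}_carbonate.csv")

            stage = f"wavelet:{spec.name}"
            params = wavelet.WaveletParams(dj=config.wavelet_dj)
            wave_results = {}
            for var in ("pH_total", "temperature_C"):
                spc = wavelet.cwt_morlet(clean[var], params)
                model = wavelet.ar1_fit(clean[var])
                wavelet.rednoise_significance(spc, model)
                save_csv(wavelet.spectrum_to_frame(spc), f"{spec.name}_{var}_wavelet.csv")
                save_csv(
                    pd.DataFrame({"period_hours": spc.periods,
                                  "global_power": wavelet.global_spectrum(spc)}),
                    f"{spec.name}_{var}_global_spectrum.csv",
                )
                save_csv(
                    pd.DataFrame({"timestamp": spc.times,
                                  "scale_averaged_power": wavelet.scale_averaged_power(spc)}),
                    f"{spec.name}_{var}_scale_averaged.csv",
                )
                wave_results[var] = spc

            stage = f"coherence:{spec.name}"
            if config.coherence_enabled:
                cmap = wavelet.surrogate_significance(
                    clean["pH_total"], clean["temperature_C"],
                    params=params, n_surrogates=max(19, config.n_surrogates),
                    seed=site_seeds[4 + i],
                )
                save_csv(wavelet.coherence_to_frame(cmap),
                         f"{spec.name}_coherence_pH_temperature.csv")
                if "salinity" in clean and np.var(clean["salinity"].valid_values()) > 0:
                    pmap = wavelet.surrogate_significance(
                        clean["pH_total"], clean["temperature_C"], clean["salinity"],
                        params=params, n_surrogates=max(19, config.n_surrogates),
                        seed=site_seeds[6 + i],
                    )
                    save_csv(wavelet.coherence_to_frame(pmap),
                             f"{spec.name}_partial_coherence_pH_temperature_given_salinity.csv")

            processed[spec.name] = clean
            row = {}
            for var, s in clean.items():
                row[var] = compare.summarize(s).to_dict()
            for col in ("pco2", "omega_arag", "omega_cal"):
                v = carb.loc[carb["valid"] == 1, col].to_numpy()
                row[col] = compare.summarize(v).to_dict()
            summaries[spec.name] = row

        stage = "compare"
        a_name, b_name = config.sites[0].name, config.sites[1].name
        rows = []
        for site, row in summaries.items():
            for var, st in row.items():
                rows.append({"site": site, "variable": var, **st})
        save_csv(pd.DataFrame(rows), "summary_statistics.csv")

        results = {}
        for var in config.compare_variables:
            if var not in processed[a_name] or var not in processed[b_name]:
                continue
            a, b = processed[a_name][var], processed[b_name][var]
            res_var = {}
            for k, metric in enumerate(("mean", "variance")):
                r = compare.mc_difference_test(
                    b, a, metric=metric, n_rand=config.n_randomizations,
                    seed=site_seeds[2] + 7 * k,
                )
                res_var[metric] = r.to_dict()
            pc = compare.percentile_difference_test(
                a, b, n_rand=config.n_randomizations, seed=site_seeds[3]
            )
            save_csv(pc.to_frame(), f"percentile_comparison_{var}.csv")
            d, p = compare.ks_test(a, b)
            res_var["ks"] = {"D": d, "p": p}
            results[var] = res_var
        save_json(results, "comparison_results.json")

        stage = "manifest"
        manifest.stages = ["load", "calibrate", "qc", "carbonate", "wavelet",
                           "coherence", "compare"]
        manifest.outputs = {str(p.relative_to(out)): _sha256(p) for p in written}
        manifest.finished = str(np.datetime64("now"))
        manifest.to_json(out / "manifest.json")
        return manifest
    except ReefwaveError as exc:
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise type(exc)(f"[{stage}] {exc}") from exc
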