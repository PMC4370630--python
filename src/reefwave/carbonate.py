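"""Seawater CO2-system solver for the pH + total-alkalinity input pair.

Given total-scale pH and total alkalinity (TA), the full carbonate speciation
is explicit algebra — no iteration is needed — because [H+] is known:

    [H+]   = 10^(-pH)                                 (total scale)
    CA     = TA − [B(OH)4−] − [OH−] + [H+]_F + [HSO4−] + [HF]
    [CO3=] = CA·K2 / ([H+] + 2 K2)
    [HCO3−]= CA·[H+] / ([H+] + 2 K2)
    [CO2*] = [HCO3−]·[H+] / K1
    fCO2   = [CO2*]/K0,  pCO2 = fCO2 / (fugacity factor)
    Ω      = [Ca2+][CO3=] / Ksp

Constants follow the classic CO2SYS option set used by reef carbonate
chemistry work of this era: K1/K2 of Mehrbach et al. (1973) as refit by
Dickson & Millero (1987) (measured on the seawater scale, converted to total),
KB of Dickson (1990b), KW of Millero (1995), KS of Dickson (1990a), KF of
Dickson & Riley (1979), aragonite/calcite solubility of Mucci (1983), total
boron of Uppström (1974), and the CO2 solubility and fugacity coefficient of
Weiss (1974).  All calculations are at surface pressure (deployments at 3–6 m;
no pressure correction) and vectorize over numpy arrays.

Converting a bench pH measured at 25 °C to in-situ temperature holds DIC and
TA fixed: DIC is computed at 25 °C from (pH25, TA), then the total-scale pH at
the in-situ temperature is found by root-solving the alkalinity equation.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasibleChemistryError, InvalidConfigError


@dataclass
class EquilibriumConstants:
    """Equilibrium constants (total pH scale, mol/kg-SW) and total concentrations.

    ``KS``/``KF`` are on the free scale as conventionally tabulated; they enter
    only through scale conversions and the sulfate/fluoride alkalinity terms.
    """

    K0: np.ndarray  # CO2 solubility, mol kg-1 atm-1
    K1: np.ndarray
    K2: np.ndarray
    KB: np.ndarray
    KW: np.ndarray
    KS: np.ndarray
    KF: np.ndarray
    Ksp_arag: np.ndarray
    Ksp_cal: np.ndarray
    BT: np.ndarray  # total boron, mol kg-1
    ST: np.ndarray  # total sulfate, mol kg-1
    FT: np.ndarray  # total fluoride, mol kg-1
    CaT: np.ndarray  # total calcium, mol kg-1
    fugacity_factor: np.ndarray  # fCO2 -> pCO2 divisor, dimensionless

    def __post_init__(self) -> None:
        for name in ("K0", "K1", "K2", "KB", "KW", "KS", "KF", "Ksp_arag", "Ksp_cal",
                     "BT", "ST", "FT", "CaT"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise InfeasibleChemistryError(f"{name} must be positive")
        if np.any(self.K1 <= self.K2):
            raise InfeasibleChemistryError("K1 must exceed K2")
        # aragonite is the more soluble polymorph
        if np.any(self.Ksp_arag <= self.Ksp_cal):
            raise InfeasibleChemistryError("Ksp_arag must exceed Ksp_cal")


@dataclass
class CarbonateState:
    """Derived CO2-system state; concentrations in μmol/kg, pCO2 in μatm."""

    ph_total: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray
    alkalinity: np.ndarray
    dic: np.ndarray
    pco2: np.ndarray
    co3: np.ndarray
    hco3: np.ndarray
    omega_arag: np.ndarray
    omega_cal: np.ndarray


def constants(temperature, salinity, *, total_boron: str = "uppstrom") -> EquilibriumConstants:
    """Evaluate the constant set at temperature (°C) and practical salinity.

    The Mehrbach refit is valid for roughly 0–45 °C and salinity 19–43; values
    outside that envelope produce a warning, not a failure.

    ``total_boron`` may be ``"uppstrom"`` (default, the CO2SYS-era choice) or
    ``"lee"`` (Lee et al. 2010); the difference moves derived quantities by
    well under 0.5 %.
    """
    tC = np.asarray(temperature, dtype=float)
    S = np.asarray(salinity, dtype=float)
    if np.any((tC < 0) | (tC > 45)) or np.any((S < 19) | (S > 43)):
        warn("temperature/salinity outside the K1/K2 refit validity range (0-45 degC, S 19-43)")
    T = tC + 273.15
    lnT = np.log(T)
    sqS = np.sqrt(S)
    ion_strength = 19.924 * S / (1000.0 - 1.005 * S)

    # Bisulfate: Dickson (1990a), free scale, converted mol/kg-H2O -> mol/kg-SW.
    lnKS = (
        -4276.1 / T + 141.328 - 23.093 * lnT
        + (-13856.0 / T + 324.57 - 47.986 * lnT) * np.sqrt(ion_strength)
        + (35474.0 / T - 771.54 + 114.723 * lnT) * ion_strength
        - 2698.0 / T * ion_strength**1.5
        + 1776.0 / T * ion_strength**2
    )
    KS = np.exp(lnKS) * (1 - 0.001005 * S)
    ST = 0.14 / 96.062 * S / 1.80655  # Morris & Riley (1966)
    FT = 0.000067 / 18.998 * S / 1.80655  # Riley (1965)
    KF = np.exp(1590.2 / T - 12.641 + 1.525 * np.sqrt(ion_strength)) * (1 - 0.001005 * S)

    sws_to_total = (1 + ST / KS) / (1 + ST / KS + FT / KF)

    # CO2 solubility, Weiss (1974).
    TK100 = T / 100.0
    lnK0 = (
        -60.2409 + 93.4517 / TK100 + 23.3585 * np.log(TK100)
        + S * (0.023517 - 0.023656 * TK100 + 0.0047036 * TK100**2)
    )
    K0 = np.exp(lnK0)

    # Carbonic acid: Mehrbach et al. (1973) refit by Dickson & Millero (1987),
    # seawater scale, converted to total.
    pK1 = 3670.7 / T - 62.008 + 9.7944 * lnT - 0.0118 * S + 0.000116 * S**2
    pK2 = 1394.7 / T + 4.777 - 0.0184 * S + 0.000118 * S**2
    K1 = 10.0 ** (-pK1) * sws_to_total
    K2 = 10.0 ** (-pK2) * sws_to_total

    # Boric acid: Dickson (1990b), total scale.
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2) / T
        + 148.0248 + 137.1942 * sqS + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnT
        + 0.053105 * sqS * T
    )
    KB = np.exp(lnKB)

    # Water: Millero (1995), seawater scale, converted to total.
    lnKW = (
        148.9802 - 13847.26 / T - 23.6521 * lnT
        + (-5.977 + 118.67 / T + 1.0495 * lnT) * sqS - 0.01615 * S
    )
    KW = np.exp(lnKW) * sws_to_total

    # Solubility products: Mucci (1983).
    log10T = np.log10(T)
    log10_Kspc = (
        -171.9065 - 0.077993 * T + 2839.319 / T + 71.595 * log10T
        + (-0.77712 + 0.0028426 * T + 178.34 / T) * sqS
        - 0.07711 * S + 0.0041249 * S**1.5
    )
    log10_Kspa = (
        -171.945 - 0.077993 * T + 2903.293 / T + 71.595 * log10T
        + (-0.068393 + 0.0017276 * T + 88.135 / T) * sqS
        - 0.10018 * S + 0.0059415 * S**1.5
    )

    if total_boron == "uppstrom":
        BT = 0.000232 / 10.811 * S / 1.80655
    elif total_boron == "lee":
        BT = 0.0002414 / 10.811 * S / 1.80655
    else:
        raise InvalidConfigError("total_boron must be 'uppstrom' or 'lee'")
    CaT = 0.02128 / 40.087 * S / 1.80655  # Riley & Tongudai (1967)

    # Fugacity coefficient at 1 atm total pressure, Weiss (1974).
    RT_cm3 = 83.14462618 * T  # cm3 bar mol-1 K-1 * K
    B_virial = -1636.75 + 12.0408 * T - 0.0327957 * T**2 + 3.16528e-5 * T**3
    delta = 57.7 - 0.118 * T
    fugacity_factor = np.exp((B_virial + 2 * delta) * 1.01325 / RT_cm3)

    return EquilibriumConstants(
        K0=K0, K1=K1, K2=K2, KB=KB, KW=KW, KS=KS, KF=KF,
        Ksp_arag=10.0**log10_Kspa, Ksp_cal=10.0**log10_Kspc,
        BT=BT, ST=ST, FT=FT, CaT=CaT, fugacity_factor=fugacity_factor,
    )


def _free_h(h_total, c: EquilibriumConstants):
    return h_total / (1 + c.ST / c.KS)


def _noncarbonate_alkalinity(h_total, c: EquilibriumConstants):
    """Borate + hydroxide − free H − bisulfate − fluoride terms, mol/kg."""
    h_free = _free_h(h_total, c)
    return (
        c.BT * c.KB / (c.KB + h_total)
        + c.KW / h_total
        - h_free
        - c.ST / (1 + c.KS / h_free)
        - c.FT / (1 + c.KF / h_free)
    )


def total_alkalinity_from_ph_dic(ph_total, dic, c: EquilibriumConstants):
    """TA (μmol/kg) implied by total-scale pH and DIC (μmol/kg) at constants ``c``.

    Used for the closure invariant and as the residual in the 25 °C → in-situ
    pH root solve.
    """
    h = 10.0 ** (-np.asarray(ph_total, dtype=float))
    dic_mol = np.asarray(dic, dtype=float) * 1e-6
    denom = h * h + c.K1 * h + c.K1 * c.K2
    hco3 = dic_mol * c.K1 * h / denom
    co3 = dic_mol * c.K1 * c.K2 / denom
    ta = hco3 + 2 * co3 + _noncarbonate_alkalinity(h, c)
    return ta * 1e6


def solve_from_ph_ta(ph_total, alkalinity, temperature, salinity, *,
                     consts: EquilibriumConstants | None = None) -> CarbonateState:
    """Solve the CO2 system from total-scale pH and TA (μmol/kg).

    All inputs broadcast; the returned state carries per-sample arrays (scalars
    come back as 0-d arrays).  Negative carbonate alkalinity — alkalinity too
    small to be consistent with the stated pH — raises
    :class:`~reefwave.errors.InfeasibleChemistryError`.
    """
    ph_total, alkalinity, temperature, salinity = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (ph_total, alkalinity, temperature, salinity))
    )
    c = consts if consts is not None else constants(temperature, salinity)
    h = 10.0 ** (-ph_total)
    ca = alkalinity * 1e-6 - _noncarbonate_alkalinity(h, c)
    if np.any(ca <= 0):
        raise InfeasibleChemistryError("carbonate alkalinity is non-positive for some sample(s)")
    co3 = ca * c.K2 / (h + 2 * c.K2)
    hco3 = ca * h / (h + 2 * c.K2)
    co2_star = hco3 * h / c.K1
    dic = co2_star + hco3 + co3
    fco2 = co2_star / c.K0
    pco2 = fco2 / c.fugacity_factor * 1e6
    return CarbonateState(
        ph_total=ph_total, temperature=temperature, salinity=salinity,
        alkalinity=alkalinity,
        dic=dic * 1e6, pco2=pco2, co3=co3 * 1e6, hco3=hco3 * 1e6,
        omega_arag=c.CaT * co3 / c.Ksp_arag,
        omega_cal=c.CaT * co3 / c.Ksp_cal,
    )


def convert_ph_temperature(ph_total, alkalinity, temperature_from, temperature_to,
                           salinity, *, tol: float = 1e-7):
    """Re-express a total-scale pH at a different temperature, holding DIC and
    TA fixed.

    DIC is computed at ``temperature_from`` from (pH, TA); the pH at
    ``temperature_to`` is then the root of
    TA(pH; DIC, constants at temperature_to) − TA on the bracket pH ∈ [3, 13]
    (Brent's method, tolerance ``tol`` in pH units).  Scalar inputs return a
    float; array inputs are solved elementwise.
    """

    def _scalar(ph: float, ta: float, t_from: float, t_to: float, s: float) -> float:
        c_from = constants(t_from, s)
        dic = float(solve_from_ph_ta(ph, ta, t_from, s, consts=c_from).dic)
        c_to = constants(t_to, s)

        def resid(p):
            return total_alkalinity_from_ph_dic(p, dic, c_to) - ta

        lo, hi = 3.0, 13.0
        if resid(lo) * resid(hi) > 0:
            raise InfeasibleChemistryError("no pH root in [3, 13] at the target temperature")
        return float(brentq(resid, lo, hi, xtol=tol))

    args = [np.asarray(a, dtype=float)
            for a in (ph_total, alkalinity, temperature_from, temperature_to, salinity)]
    if all(a.ndim == 0 for a in args):
        return _scalar(*(float(a) for a in args))
    b = np.broadcast_arrays(*args)
    out = np.empty(b[0].shape)
    for idx in np.ndindex(b[0].shape):
        out[idx] = _scalar(*(float(a[idx]) for a in b))
    return out


def ph25_to_insitu(ph25_total, alkalinity, temperature_insitu, salinity,
                   *, tol: float = 1e-7):
    """Convert a bench pH measured at 25 °C to pH at in-situ temperature
    (fixed DIC and TA); see :func:`convert_ph_temperature`."""
    return convert_ph_temperature(ph25_total, alkalinity, 25.0, temperature_insitu,
                                  salinity, tol=tol)


@dataclass
class RangeUncertainty:
    """Half-range sensitivity of derived quantities to one uncertain input."""

    parameter: str  # "alkalinity" | "salinity"
    half_range: float  # same units as the parameter
    d_pco2: float  # μatm
    d_omega_arag: float


def uncertainty_by_range(ph_total, alkalinity, temperature, salinity,
                         parameter: str, half_range: float) -> RangeUncertainty:
    """Propagate a ± half-range in TA or salinity into pCO2 and Ω_arag.

    The uncertainty is half the two-sided range:
    d_x = |x(p + h) − x(p − h)| / 2, everything else held fixed.  Symmetric in
    the sign of h and first-order consistent with a central finite difference.
    """
    if parameter not in ("alkalinity", "salinity"):
        raise InvalidConfigError("parameter must be 'alkalinity' or 'salinity'")
    if half_range < 0:
        raise InvalidConfigError("half_range must be nonnegative")
    h = abs(half_range)
    base = dict(ph_total=ph_total, alkalinity=alkalinity,
                temperature=temperature, salinity=salinity)
    up, dn = dict(base), dict(base)
    up[parameter] = np.asarray(base[parameter], dtype=float) + h
    dn[parameter] = np.asarray(base[parameter], dtype=float) - h
    s_up = solve_from_ph_ta(up["ph_total"], up["alkalinity"], up["temperature"], up["salinity"])
    s_dn = solve_from_ph_ta(dn["ph_total"], dn["alkalinity"], dn["temperature"], dn["salinity"])
    return RangeUncertainty(
        parameter=parameter,
        half_range=h,
        d_pco2=float(np.mean(np.abs(s_up.pco2 - s_dn.pco2) / 2.0)),
        d_omega_arag=float(np.mean(np.abs(s_up.omega_arag - s_dn.omega_arag) / 2.0)),
    )


def solve_series(ph_series, temperature_series, salinity, alkalinity):
    """Solve the CO2 system along a deployment.

    ``ph_series`` and ``temperature_series`` are aligned
    :class:`~reefwave.series.EnvironmentalSeries`; ``salinity`` is a scalar or
    a third aligned series; ``alkalinity`` is the deployment-constant TA in
    μmol/kg.  Returns a pandas DataFrame with one row per sample (invalid
    samples carry NaN in the derived columns).
    """
    import pandas as pd

    from .errors import AlignmentError
    from .series import EnvironmentalSeries

    if not ph_series.same_grid(temperature_series):
        raise AlignmentError("pH and temperature series must share one time grid")
    if isinstance(salinity, EnvironmentalSeries):
        if not ph_series.same_grid(salinity):
            raise AlignmentError("salinity series must share the pH time grid")
        sal = salinity.values
        mask = ph_series.valid & temperature_series.valid & salinity.valid
    else:
        sal = np.full(len(ph_series), float(salinity))
        mask = ph_series.valid & temperature_series.valid

    cols = ["dic", "pco2", "co3", "hco3", "omega_arag", "omega_cal"]
    out = pd.DataFrame({
        "timestamp": ph_series.timestamps,
        "ph_total": ph_series.values,
        "temperature_C": temperature_series.values,
        "salinity": sal,
        "alkalinity": float(alkalinity),
        "valid": mask.astype(int),
    })
    for col in cols:
        out[col] = np.nan
    if mask.any():
        st = solve_from_ph_ta(
            ph_series.values[mask], float(alkalinity),
            temperature_series.values[mask], sal[mask],
        )
        for col in cols:
            out.loc[mask, col] = getattr(st, col)
    return out
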