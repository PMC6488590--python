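"""Two-state analysis of thermal denaturation (CD melts and DSC).

The temperature-induced N ↔ D transition is modelled with the van't Hoff
equilibrium constant K(T) = exp[−(ΔH_vH/R)(1/T − 1/T_d)], temperatures in
kelvin. A CD melting curve is fitted as the population-weighted average of
two linear baselines; a DSC thermogram is analysed non-parametrically: the
native baseline (linear in T) is subtracted, T_d is the peak maximum, the
calorimetric enthalpy ΔdH is the integrated peak area, the van't Hoff
enthalpy follows from the peak height (ΔvH = 4·R·T_d²·Cp_max/ΔdH), and
their ratio CU = ΔdH/ΔvH is the cooperative unit — close to 1 is a
necessary condition for a two-state transition.

Temperatures are °C at every interface and kelvin inside every formula;
enthalpies are kJ/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ramastrain.errors import FitError, NoTransitionError

__all__ = ["MeltCurve", "Thermogram", "ThermalFit",
           "fit_melt_curve", "dsc_analyze", "compare_td"]

#: Gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314
C_TO_K = 273.15


@dataclass
class MeltCurve:
    """A thermal melting curve: temperature (°C, strictly increasing) vs
    signal (e.g. molar ellipticity at 222 nm, deg cm² dmol⁻¹)."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.ndim != 1 or self.temperature.size < 10:
            raise ValueError("melting curve needs >= 10 points")
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if not np.all(np.isfinite(self.temperature)) or not np.all(np.isfinite(self.signal)):
            raise ValueError("non-finite values in melting curve")

    @classmethod
    def from_csv(cls, path) -> "MeltCurve":
        data = np.loadtxt(path, delimiter=",", skiprows=_header_rows(path))
        return cls(temperature=data[:, 0], signal=data[:, 1])


@dataclass
class Thermogram:
    """A DSC thermogram: temperature (°C) vs excess molar heat capacity
    (kJ mol⁻¹ K⁻¹, buffer-subtracted but before native-baseline removal)."""

    temperature: np.ndarray
    cp_excess: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.cp_excess = np.asarray(self.cp_excess, dtype=float)
        if self.temperature.ndim != 1 or self.temperature.size < 20:
            raise ValueError("thermogram needs >= 20 points spanning the peak")
        if self.temperature.shape != self.cp_excess.shape:
            raise ValueError("temperature and cp must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "Thermogram":
        data = np.loadtxt(path, delimiter=",", skiprows=_header_rows(path))
        return cls(temperature=data[:, 0], cp_excess=data[:, 1])


def _header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    try:
        [float(x) for x in first.replace("#", "").split(",")[:2]]
        return 0
    except ValueError:
        return 1


@dataclass
class ThermalFit:
    """Recovered two-state parameters from a melt curve or thermogram.

    td: transition midpoint / peak maximum, °C.
    dh_vh: van't Hoff enthalpy, kJ/mol.
    dh_cal: calorimetric enthalpy (DSC only), kJ/mol.
    cu: cooperative unit ΔdH/ΔvH (DSC only).
    """

    td: float
    dh_vh: float
    mode: str
    dh_cal: float | None = None
    cu: float | None = None
    native_baseline: tuple[float, float] = (0.0, 0.0)
    denatured_baseline: tuple[float, float] | None = None
    fit_quality: dict = field(default_factory=dict)
    td_derivative: float | None = None

    def summary(self) -> str:
        rows = [("mode", self.mode), ("Td (degC)", f"{self.td:.2f}")]
        if self.dh_cal is not None:
            rows.append(("dH_cal (kJ/mol)", f"{self.dh_cal:.1f}"))
        rows.append(("dH_vH (kJ/mol)", f"{self.dh_vh:.1f}"))
        if self.cu is not None:
            rows.append(("CU = dH_cal/dH_vH", f"{self.cu:.2f}"))
        a, b = self.native_baseline
        rows.append(("native baseline", f"{a:.4g} + {b:.4g}*T"))
        if self.denatured_baseline is not None:
            a, b = self.denatured_baseline
            rows.append(("denatured baseline", f"{a:.4g} + {b:.4g}*T"))
        for k, v in self.fit_quality.items():
            rows.append((k, f"{v:.4g}" if isinstance(v, float) else str(v)))
        width = max(len(k) for k, _ in rows)
        lines = ["Two-state thermal analysis", "-" * 30]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "td": self.td, "dh_cal": self.dh_cal, "dh_vh": self.dh_vh,
            "cu": self.cu, "mode": self.mode,
            "native_baseline": list(self.native_baseline),
            "denatured_baseline": (None if self.denatured_baseline is None
                                   else list(self.denatured_baseline)),
            "fit_quality": self.fit_quality,
            "td_derivative": self.td_derivative,
        }


def _two_state_fraction(t_c: np.ndarray, td_c: float, dh_kj: float) -> np.ndarray:
    T = t_c + C_TO_K
    Td = td_c + C_TO_K
    K = np.exp(-(dh_kj * 1e3 / R_GAS) * (1.0 / T - 1.0 / Td))
    return K / (1.0 + K)


def _melt_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    td, dh, a_n, b_n, a_d, b_d = params
    f_d = _two_state_fraction(t, td, dh)
    return (a_n + b_n * t) * (1.0 - f_d) + (a_d + b_d * t) * f_d


def fit_melt_curve(curve: MeltCurve) -> ThermalFit:
    """Two-state fit of a melting curve with linear baselines.

    signal(T) = [θ_N(T) + θ_D(T)·K(T)]/(1 + K(T)); the fit returns T_d
    (where K = 1), the van't Hoff ΔH, and the two baselines. A curve that a
    straight line explains to within the noise raises NoTransitionError;
    optimizer failure raises FitError with diagnostics.
    """
    t, y = curve.temperature, curve.signal
    y_range = float(y.max() - y.min())
    # robust noise estimate from first differences
    noise = 1.4826 * float(np.median(np.abs(np.diff(y)))) / np.sqrt(2.0)
    coeffs = np.polyfit(t, y, 1)
    resid_lin = y - np.polyval(coeffs, t)
    if y_range < 1e-12 or float(np.max(np.abs(resid_lin))) <= max(5.0 * noise,
                                                                  1e-9 * y_range):
        raise NoTransitionError("no transition detected: signal is linear in "
                                "temperature to within the noise")
    # initial guesses: Td from the extremum of the smoothed derivative
    win = max(3, len(t) // 25) | 1
    kernel = np.ones(win) / win
    y_s = np.convolve(y, kernel, mode="same")
    dy = np.gradient(y_s, t)
    interior = slice(win, len(t) - win)
    i0 = int(np.argmax(np.abs(dy[interior]))) + win
    td0 = float(t[i0])
    n_edge = max(3, len(t) // 5)
    a_n0, b_n0 = _linfit(t[:n_edge], y[:n_edge])
    a_d0, b_d0 = _linfit(t[-n_edge:], y[-n_edge:])
    x0 = np.array([td0, 400.0, a_n0, b_n0, a_d0, b_d0])
    lo = [t[0], 10.0, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [t[-1], 10000.0, np.inf, np.inf, np.inf, np.inf]
    scale = max(y_range, 1e-9)

    def resid(p):
        return (_melt_model(p, t) - y) / scale

    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                        gtol=1e-14)
    if not sol.success:
        raise FitError(f"melt-curve fit did not converge: {sol.message}")
    td, dh, a_n, b_n, a_d, b_d = sol.x
    amp = abs((a_d + b_d * td) - (a_n + b_n * td))
    if amp <= max(5.0 * noise, 1e-6 * y_range):
        raise NoTransitionError("fitted transition amplitude is within the noise")
    rmse = float(np.sqrt(np.mean((_melt_model(sol.x, t) - y) ** 2)))
    return ThermalFit(
        td=float(td), dh_vh=float(dh), mode="cd",
        native_baseline=(float(a_n), float(b_n)),
        denatured_baseline=(float(a_d), float(b_d)),
        fit_quality={"rmse": rmse, "n_points": len(t),
                     "noise_sd_est": float(noise)},
        td_derivative=td0,
    )


def _linfit(x, y) -> tuple[float, float]:
    b, a = np.polyfit(x, y, 1)
    return float(a), float(b)


def dsc_analyze(thermogram: Thermogram,
                baseline_fraction: float = 0.2) -> ThermalFit:
    """Model-free two-state analysis of a DSC thermogram.

    The native baseline (linear in T) is fitted on the coolest
    baseline_fraction of the temperature range and subtracted; T_d is the
    temperature of the excess-Cp maximum, ΔdH its trapezoidal integral,
    ΔvH = 4·R·T_d²·Cp_max/ΔdH, CU = ΔdH/ΔvH. A thermogram whose excess Cp
    is negative over more than 20% of the range triggers a baseline
    warning; a missing or edge-located peak raises NoTransitionError.
    """
    t, cp = thermogram.temperature, thermogram.cp_excess
    n_base = max(3, int(round(baseline_fraction * len(t))))
    a0, b0 = _linfit(t[:n_base], cp[:n_base])
    excess = cp - (a0 + b0 * t)
    noise = 1.4826 * float(np.median(np.abs(np.diff(cp)))) / np.sqrt(2.0)
    imax = int(np.argmax(excess))
    cp_max = float(excess[imax])
    if cp_max <= max(5.0 * noise, 1e-12) or imax in (0, len(t) - 1):
        raise NoTransitionError("no DSC peak found above the baseline")
    if np.mean(excess < -max(3.0 * noise, 1e-6 * cp_max)) > 0.2:
        warnings.warn("excess Cp negative over more than 20% of the range; "
                      "the native-baseline window may be inappropriate",
                      stacklevel=2)
    td = float(t[imax])
    dh_cal = float(np.trapezoid(excess, t))
    if dh_cal <= 0:
        raise NoTransitionError("non-positive integrated peak area")
    td_k = td + C_TO_K
    # R [J/mol/K] · Td² [K²] · (Cp_max/ΔdH) [1/K] = J/mol → kJ/mol
    dh_vh = 4.0 * R_GAS * td_k ** 2 * (cp_max / dh_cal) / 1e3
    cu = dh_cal / dh_vh
    return ThermalFit(
        td=td, dh_cal=dh_cal, dh_vh=float(dh_vh), cu=float(cu), mode="dsc",
        native_baseline=(a0, b0),
        fit_quality={"cp_max": cp_max, "n_points": len(t),
                     "grid_step": float(np.median(np.diff(t))),
                     "noise_sd_est": noise},
    )


def compare_td(fit_a: ThermalFit | float, fit_b: ThermalFit | float) -> float:
    """Signed midpoint-temperature difference td_a − td_b, °C."""
    ta = fit_a.td if isinstance(fit_a, ThermalFit) else float(fit_a)
    tb = fit_b.td if isinstance(fit_b, ThermalFit) else float(fit_b)
    return ta - tb
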