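"""Diurnal thermal regimes and the heat-ramping protocol.

Developmental acclimation treatments are either constant or diurnally
fluctuating.  A fluctuating regime is modelled as a nocturnal baseline plus a
Gaussian daytime bump, made 24-h periodic by measuring time circularly::

    T(t) = base + amplitude * exp(-d(t)^2 / (2 * sigma^2))

where ``d(t)`` is the wrap-around distance in hours from ``t`` to the peak
hour.  The three numbers that characterise a treatment — daily mean, daily
minimum and daily maximum — determine the parameterisation uniquely: the
baseline is the daily minimum, the amplitude is the daily range, and the
Gaussian width ``sigma`` is solved numerically so that the 24-h time-average
equals the requested mean.

The heat-tolerance assay heats at a constant rate from a start temperature,
capped at an end temperature (``ramp_temperature``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "ThermalRegime",
    "RampProtocol",
    "constant_regime",
    "solve_regime",
    "temperature_at",
    "ramp_temperature",
    "regime_profile",
]

#: Hours in one diurnal cycle.
PERIOD = 24.0

#: Absolute tolerance (°C) on the 24-h mean when solving for sigma.
MEAN_TOL = 1e-6


class RegimeInfeasibleError(ValueError):
    """No Gaussian width satisfies the requested daily-mean constraint."""


@dataclass(frozen=True)
class ThermalRegime:
    """A 24-h periodic developmental temperature regime.

    Parameters
    ----------
    kind
        ``"constant"`` or ``"fluctuating"``.
    mean_temp
        Daily time-average temperature, °C.
    base_temp
        Nocturnal baseline (daily minimum), °C.
    amplitude
        Daily range (peak minus base), °C; 0 for constant regimes.
    sigma_hours
        Gaussian width of the daytime bump, hours.
    peak_hour
        Hour-of-day of the daily maximum, in [0, 24).
    """

    kind: str
    mean_temp: float
    base_temp: float
    amplitude: float = 0.0
    sigma_hours: float = 0.0
    peak_hour: float = 14.0
    light_dark_cycle: str = field(default="12:12", compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "fluctuating"):
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.kind == "constant":
            if self.amplitude != 0.0 or self.base_temp != self.mean_temp:
                raise ValueError("constant regimes require amplitude 0 and base == mean")
        else:
            if not (self.base_temp < self.mean_temp < self.base_temp + self.amplitude):
                raise ValueError("fluctuating regimes require base < mean < base + amplitude")
            if self.sigma_hours <= 0:
                raise ValueError("fluctuating regimes require sigma_hours > 0")

    def temperature(self, t):
        """Temperature (°C) at hour-of-day ``t`` (array-friendly)."""
        return temperature_at(self, t)

    def to_config(self) -> dict:
        """Plain key-value serialisation of the regime."""
        return {
            "kind": self.kind,
            "mean_temp": self.mean_temp,
            "base_temp": self.base_temp,
            "amplitude": self.amplitude,
            "sigma_hours": self.sigma_hours,
            "peak_hour": self.peak_hour,
            "light_dark_cycle": self.light_dark_cycle,
        }

    @classmethod
    def from_config(cls, config: dict) -> "ThermalRegime":
        return cls(**config)


@dataclass(frozen=True)
class RampProtocol:
    """Linear heating protocol: start at ``start_temp``, heat at ``rate``
    °C/min, hold at ``end_temp`` once reached."""

    start_temp: float = 20.0
    rate: float = 0.1
    end_temp: float = 35.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("ramp rate must be >= 0")
        if self.end_temp < self.start_temp:
            raise ValueError("end_temp must be >= start_temp")

    def temperature(self, minutes):
        return ramp_temperature(self, minutes)

    @property
    def minutes_to_end(self) -> float:
        """Minutes until the cap is reached (inf for a zero rate)."""
        if self.rate == 0:
            return float("inf")
        return (self.end_temp - self.start_temp) / self.rate


def constant_regime(mean_temp: float) -> ThermalRegime:
    """A constant regime at ``mean_temp`` °C."""
    return ThermalRegime(kind="constant", mean_temp=mean_temp, base_temp=mean_temp)


def _circular_distance(t, peak_hour):
    d = np.abs(np.asarray(t, dtype=float) % PERIOD - peak_hour)
    return np.minimum(d, PERIOD - d)


def temperature_at(regime: ThermalRegime, t):
    """Evaluate the regime at hour-of-day ``t``.

    ``t`` outside [0, 24) is reduced modulo 24 — the profile is periodic, so
    this is a convenience rather than an error.
    """
    t = np.asarray(t, dtype=float)
    if regime.kind == "constant":
        out = np.full_like(t, regime.mean_temp)
        return float(out) if out.ndim == 0 else out
    d = _circular_distance(t, regime.peak_hour)
    out = regime.base_temp + regime.amplitude * np.exp(-(d**2) / (2.0 * regime.sigma_hours**2))
    return float(out) if out.ndim == 0 else out


def _periodic_mean(base: float, amplitude: float, sigma: float) -> float:
    # Mean over one period of base + A*exp(-d^2/2s^2); by symmetry the
    # circular distance sweeps [0, 12] twice per cycle.
    bump, _ = integrate.quad(lambda u: np.exp(-(u**2) / (2.0 * sigma**2)), 0.0, PERIOD / 2)
    return base + amplitude * bump / (PERIOD / 2)


def solve_regime(
    mean_temp: float,
    range_lo: float,
    range_hi: float,
    peak_hour: float = 14.0,
) -> ThermalRegime:
    """Construct the fluctuating regime with daily range [range_lo, range_hi]
    whose 24-h time-average is ``mean_temp``.

    The baseline is ``range_lo``, the amplitude is ``range_hi - range_lo`` and
    the Gaussian width is solved by bisection on [0.1, 12] h so that the
    integrated periodic mean matches ``mean_temp`` to within 1e-6 °C.

    Raises
    ------
    RegimeInfeasibleError
        If ``mean_temp`` lies outside ``(range_lo, range_hi)`` or is so close
        to ``range_hi`` that no width <= 12 h satisfies the constraint.
    """
    if not (range_lo < mean_temp < range_hi):
        raise RegimeInfeasibleError(
            f"mean_temp={mean_temp} must lie strictly inside ({range_lo}, {range_hi})"
        )
    amplitude = range_hi - range_lo
    lo, hi = 0.1, PERIOD / 2

    def residual(sigma: float) -> float:
        return _periodic_mean(range_lo, amplitude, sigma) - mean_temp

    if residual(lo) > 0:
        raise RegimeInfeasibleError(
            "requested mean is below the narrowest representable daily bump"
        )
    if residual(hi) < -MEAN_TOL:
        raise RegimeInfeasibleError(
            "requested mean is too close to the daily maximum: no sigma <= 12 h "
            "yields the required time-average"
        )
    sigma = optimize.brentq(residual, lo, hi, xtol=1e-10)
    # brentq solves residual (°C) to machine precision in sigma; verify the
    # mean tolerance explicitly.
    if abs(residual(sigma)) > MEAN_TOL:  # pragma: no cover - defensive
        raise RegimeInfeasibleError("sigma solver failed to reach the mean tolerance")
    return ThermalRegime(
        kind="fluctuating",
        mean_temp=mean_temp,
        base_temp=range_lo,
        amplitude=amplitude,
        sigma_hours=float(sigma),
        peak_hour=peak_hour,
    )


def ramp_temperature(protocol: RampProtocol, minutes):
    """Water-bath temperature after ``minutes`` of ramping (clamped at the cap)."""
    minutes = np.asarray(minutes, dtype=float)
    if np.any(minutes < 0):
        raise ValueError("minutes must be >= 0")
    out = np.minimum(protocol.start_temp + protocol.rate * minutes, protocol.end_temp)
    return float(out) if out.ndim == 0 else out


def regime_profile(regime: ThermalRegime, step_minutes: float = 1.0):
    """Sample one 24-h cycle on a regular grid.

    Returns a :class:`pandas.DataFrame` with columns ``hour`` and ``temp_C``,
    suitable for two-column CSV export.
    """
    import pandas as pd

    hours = np.arange(0.0, PERIOD, step_minutes / 60.0)
    return pd.DataFrame({"hour": hours, "temp_C": temperature_at(regime, hours)})
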