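"""CTD-profile helpers: potential density, mixed-layer depth and averages.

The surface mixed layer is defined as the depth range over which potential
density stays within a threshold (default 0.35 kg m^-3) of its surface
value; temperature and salinity reported for a station are averaged over
that layer.  Potential density anomaly σθ is computed with the UNESCO
EOS-80 international equation of state of seawater (density polynomial and
secant bulk modulus) together with the Fofonoff–Millard adiabatic lapse
rate for referencing in-situ temperature to surface pressure.  EOS-80 uses
practical salinity and ITS-68 temperatures; for the mixed-layer threshold
criterion the difference from the modern TEOS-10 formulation is far below
the 0.35 kg m^-3 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CtdProfile",
    "MixedLayer",
    "density",
    "potential_temperature",
    "potential_density",
    "mixed_layer_depth",
    "mixed_layer_average",
]


class HydroError(ValueError):
    """Invalid hydrographic input."""


@dataclass(frozen=True)
class MixedLayer:
    """Mixed-layer depth result; ``extends_beyond_profile`` is set when the
    density criterion is never exceeded within the profile."""

    depth_m: float
    extends_beyond_profile: bool = False


@dataclass
class CtdProfile:
    """Ordered CTD records: depth (m, strictly increasing), temperature
    (°C), practical salinity, optional pressure (dbar, approximated as
    numerically equal to depth when absent — exact to <1% in the upper
    ocean)."""

    depth_m: np.ndarray
    temperature_C: np.ndarray
    salinity: np.ndarray
    pressure_db: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.salinity = np.asarray(self.salinity, dtype=float)
        if self.depth_m.size < 2:
            raise HydroError("a profile needs at least 2 records")
        if not (np.diff(self.depth_m) > 0).all():
            raise HydroError("depths must be strictly increasing")
        if (self.depth_m <= 0).any():
            raise HydroError("depths must be > 0")
        for name, arr in (("temperature", self.temperature_C), ("salinity", self.salinity)):
            if arr.shape != self.depth_m.shape:
                raise HydroError(f"{name} length does not match depth")
            if np.isnan(arr).any():
                raise HydroError(f"missing {name} values in profile")
        if self.pressure_db is None:
            self.pressure_db = self.depth_m.copy()
        else:
            self.pressure_db = np.asarray(self.pressure_db, dtype=float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CtdProfile":
        return cls(
            depth_m=df["depth_m"].to_numpy(),
            temperature_C=df["temp_C"].to_numpy(),
            salinity=df["sal_psu"].to_numpy(),
            pressure_db=df["pressure_db"].to_numpy() if "pressure_db" in df else None,
        )

    def sigma_theta(self) -> np.ndarray:
        return potential_density(self.temperature_C, self.salinity, self.pressure_db)


def _check_ranges(T, S) -> None:
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    if ((T < -2) | (T > 40)).any():
        raise HydroError("temperature outside [-2, 40] °C")
    if ((S < 0) | (S > 42)).any():
        raise HydroError("salinity outside [0, 42]")


def _density_atm(S, T):
    """EOS-80 density of seawater at atmospheric pressure, kg m^-3."""
    # pure water (Bigg 1967, as adopted by EOS-80)
    rho_w = (
        999.842594
        + 6.793952e-2 * T
        - 9.095290e-3 * T**2
        + 1.001685e-4 * T**3
        - 1.120083e-6 * T**4
        + 6.536332e-9 * T**5
    )
    A = (
        8.24493e-1
        - 4.0899e-3 * T
        + 7.6438e-5 * T**2
        - 8.2467e-7 * T**3
        + 5.3875e-9 * T**4
    )
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    return rho_w + A * S + B * S**1.5 + C * S**2


def _bulk_modulus(S, T, p_bar):
    """EOS-80 secant bulk modulus K(S, T, p), bar."""
    Kw = (
        19652.21
        + 148.4206 * T
        - 2.327105 * T**2
        + 1.360477e-2 * T**3
        - 5.155288e-5 * T**4
    )
    K0 = (
        Kw
        + S * (54.6746 - 0.603459 * T + 1.09987e-2 * T**2 - 6.1670e-5 * T**3)
        + S**1.5 * (7.944e-2 + 1.6483e-2 * T - 5.3009e-4 * T**2)
    )
    A = (
        3.239908
        + 1.43713e-3 * T
        + 1.16092e-4 * T**2
        - 5.77905e-7 * T**3
        + S * (2.2838e-3 - 1.0981e-5 * T - 1.6078e-6 * T**2)
        + 1.91075e-4 * S**1.5
    )
    B = (
        8.50935e-5
        - 6.12293e-6 * T
        + 5.2787e-8 * T**2
        + S * (-9.9348e-7 + 2.0816e-8 * T + 9.1697e-10 * T**2)
    )
    return K0 + A * p_bar + B * p_bar**2


def density(T, S, P=0.0):
    """In-situ seawater density ρ(S, T, P), kg m^-3 (EOS-80).

    T in °C, S practical salinity, P pressure in decibars.
    """
    _check_ranges(T, S)
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    p_bar = np.asarray(P, dtype=float) / 10.0
    rho0 = _density_atm(S, T)
    out = np.where(p_bar == 0, rho0, rho0 / (1.0 - p_bar / _bulk_modulus(S, T, p_bar)))
    return out if out.ndim else float(out)


def _adiabatic_lapse_rate(S, T, P):
    """Adiabatic temperature gradient, °C per decibar (Fofonoff–Millard)."""
    ds = S - 35.0
    return (
        (
            ((-2.1687e-16 * T + 1.8676e-14) * T - 4.6206e-13) * P
            + ((2.7759e-12 * T - 1.1351e-10) * ds
               + ((-5.4481e-14 * T + 8.733e-12) * T - 6.7795e-10) * T
               + 1.8741e-8)
        ) * P
        + (-4.2393e-8 * T + 1.8932e-6) * ds
        + ((6.6228e-10 * T - 6.836e-8) * T + 8.5258e-6) * T
        + 3.5803e-5
    )


def potential_temperature(T, S, P, P_ref=0.0):
    """Potential temperature θ (°C) referenced to ``P_ref`` (dbar), by the
    standard 4th-order Runge–Kutta integration of the adiabatic lapse rate."""
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    P = np.asarray(P, dtype=float)
    h = P_ref - P
    xk = h * _adiabatic_lapse_rate(S, T, P)
    t = T + 0.5 * xk
    q = xk
    p = P + 0.5 * h
    xk = h * _adiabatic_lapse_rate(S, t, p)
    t = t + 0.29289322 * (xk - q)
    q = 0.58578644 * xk + 0.121320344 * q
    xk = h * _adiabatic_lapse_rate(S, t, p)
    t = t + 1.707106781 * (xk - q)
    q = 3.414213562 * xk - 4.121320344 * q
    p = P_ref
    xk = h * _adiabatic_lapse_rate(S, t, p)
    t = t + (xk - 2.0 * q) / 6.0
    return t if t.ndim else float(t)


def potential_density(T, S, P=0.0):
    """Potential density anomaly σθ (kg m^-3) referenced to the surface.

    Density of a parcel moved adiabatically to 0 dbar, minus 1000: σθ is
    monotone increasing in salinity and decreasing in temperature over
    oceanographic ranges.
    """
    _check_ranges(T, S)
    theta = potential_temperature(T, S, P, 0.0)
    return density(theta, S, 0.0) - 1000.0


def mixed_layer_depth(
    profile: CtdProfile,
    threshold: float = 0.35,
    interpolate: bool = True,
) -> MixedLayer:
    """Mixed-layer depth: shallowest depth where σθ exceeds the surface
    value by more than ``threshold`` kg m^-3.

    The surface value is the shallowest record's σθ.  With
    ``interpolate=True`` (default) the crossing depth is found by linear
    interpolation of Δσθ between the bracketing records; otherwise the first
    record exceeding the threshold is returned.  A profile that never
    exceeds the threshold returns its deepest depth flagged as extending
    beyond the profile.
    """
    sigma = profile.sigma_theta()
    dsig = sigma - sigma[0]
    exceeds = np.flatnonzero(dsig > threshold)
    if exceeds.size == 0:
        return MixedLayer(float(profile.depth_m[-1]), extends_beyond_profile=True)
    i = exceeds[0]
    if i == 0:  # cannot happen: dsig[0] == 0 <= threshold for threshold >= 0
        return MixedLayer(float(profile.depth_m[0]))
    if not interpolate:
        return MixedLayer(float(profile.depth_m[i]))
    z0, z1 = profile.depth_m[i - 1], profile.depth_m[i]
    d0, d1 = dsig[i - 1], dsig[i]
    frac = (threshold - d0) / (d1 - d0)
    return MixedLayer(float(z0 + frac * (z1 - z0)))


def mixed_layer_average(
    profile: CtdProfile, mld: float | MixedLayer
) -> tuple[float, float]:
    """Depth-weighted (trapezoidal) mean temperature and salinity over the
    mixed layer [shallowest record, mld].

    Values at ``mld`` are linearly interpolated; the means are exact for
    piecewise-linear profiles, so refining a linear profile with interior
    points leaves them unchanged.
    """
    if isinstance(mld, MixedLayer):
        mld = mld.depth_m
    z = profile.depth_m
    if mld < z[0]:
        raise HydroError(f"mld {mld} m is above the shallowest record ({z[0]} m)")
    if mld > z[-1]:
        raise HydroError(f"mld {mld} m is below the deepest record ({z[-1]} m)")
    if mld == z[0]:
        warnings.warn("mixed layer collapses to the surface record", stacklevel=2)
        return float(profile.temperature_C[0]), float(profile.salinity[0])
    means = []
    for values in (profile.temperature_C, profile.salinity):
        inside = z <= mld
        zz = np.append(z[inside], mld)
        vv = np.append(values[inside], np.interp(mld, z, values))
        means.append(float(np.trapezoid(vv, zz) / (mld - z[0])))
    return means[0], means[1]
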