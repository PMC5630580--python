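"""Lake stratification metrics from depth-resolved temperature/oxygen profiles.

The chain of quantities, per profile:

1. water density from temperature (Thiesen–Scheel–Diesselhorst polynomial,
   pure water — salinity corrections are out of scope for a freshwater lake);
2. squared buoyancy frequency N^2 = (g/rho) drho/dz evaluated at the
   thermocline, taken as the depth of the steepest density gradient;
3. the mixing proxy 1/N^2 (large when the water column is well mixed) —
   vertical eddy diffusivity scales like 1/N^2, so this is a dimensionally
   simple stand-in for the oxygen diffusivity across the thermocline;
4. oxygen percent saturation from temperature and dissolved O2;
5. a hysteresis statistic: the signed area enclosed by the seasonal
   trajectory in the (1/N^2, O2 saturation) plane at a fixed hypolimnion
   depth. A lake that deoxygenates under stratification and stays anoxic
   through fall turnover traces an open loop (positive area under the
   time-ordering convention below); a lake that re-oxygenates retraces its
   path and encloses ~0 area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "ProfileSeries",
    "StratificationRecord",
    "HysteresisLoop",
    "GRAVITY",
    "N2_FLOOR",
    "water_density",
    "buoyancy_frequency_squared",
    "mixing_proxy",
    "oxygen_saturation_concentration",
    "oxygen_saturation",
    "stratification_records",
    "hysteresis_loop",
]

#: gravitational acceleration (m/s^2)
GRAVITY = 9.8

#: floor on N^2 (1/s^2) when forming the 1/N^2 proxy: a fully mixed profile
#: maps to a large finite proxy instead of infinity
N2_FLOOR = 1e-6

# Thiesen–Scheel–Diesselhorst pure-water density polynomial (kg/m^3),
# rho(T) = 1000 * (1 - (T + A)/(B*(T + C)) * (T - T_MAX_DENSITY)^2),
# T in degrees Celsius. Coefficients as tabulated in the limnological
# literature (CRC Handbook / Vetter's compilation); maximum density at
# T = 3.9863 C.
_TSD_A = 288.9414
_TSD_B = 508929.2
_TSD_C = 68.12963
_TSD_TMAX = 3.9863

# Benson–Krause coefficients for the equilibrium dissolved-oxygen
# concentration of air-saturated fresh water at standard pressure
# (USGS formulation; T in kelvin, result in mg/L). Swappable constant
# table: replace these to adopt a different solubility formula.
_BK_COEFF = (-139.34411, 1.575701e5, -6.642308e7, 1.2438e10, -8.621949e11)
_O2_MOLAR_MASS = 31.9988  # g/mol


@dataclass(frozen=True)
class DepthProfile:
    """One sampling date: depth-resolved temperature and oxygen.

    Depths in metres, strictly increasing downward; temperature in degrees
    Celsius; oxygen in uM. Optional sulfate/sulfide in uM.
    """

    timestamp: pd.Timestamp
    depths: np.ndarray
    temperature: np.ndarray
    oxygen: np.ndarray
    sulfate: Optional[np.ndarray] = None
    sulfide: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "timestamp", pd.Timestamp(self.timestamp))
        for name in ("depths", "temperature", "oxygen", "sulfate", "sulfide"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        z = self.depths
        if z.ndim != 1 or len(z) < 1:
            raise ValueError("depths must be a 1-D array")
        if np.any(np.diff(z) <= 0):
            raise ValueError("depths must be strictly increasing")
        for name in ("temperature", "oxygen", "sulfate", "sulfide"):
            v = getattr(self, name)
            if v is not None and v.shape != z.shape:
                raise ValueError(f"{name} must have one value per depth")

    def __len__(self) -> int:
        return len(self.depths)


@dataclass
class ProfileSeries:
    """Time-ordered sequence of :class:`DepthProfile` objects."""

    profiles: List[DepthProfile]

    def __post_init__(self):
        ts = [p.timestamp for p in self.profiles]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("profile timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, i):
        return self.profiles[i]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: date, depth_m, temp_C, oxygen_uM[, solutes]."""
        rows = []
        for p in self.profiles:
            for i, z in enumerate(p.depths):
                row = {
                    "date": p.timestamp,
                    "depth_m": z,
                    "temp_C": p.temperature[i],
                    "oxygen_uM": p.oxygen[i],
                }
                if p.sulfate is not None:
                    row["sulfate_uM"] = p.sulfate[i]
                if p.sulfide is not None:
                    row["sulfide_uM"] = p.sulfide[i]
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProfileSeries":
        required = {"date", "depth_m", "temp_C", "oxygen_uM"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"profile table is missing columns: {sorted(missing)}")
        profiles = []
        for ts, g in df.groupby("date", sort=True):
            g = g.sort_values("depth_m")
            profiles.append(
                DepthProfile(
                    timestamp=pd.Timestamp(ts),
                    depths=g["depth_m"].to_numpy(),
                    temperature=g["temp_C"].to_numpy(),
                    oxygen=g["oxygen_uM"].to_numpy(),
                    sulfate=g["sulfate_uM"].to_numpy() if "sulfate_uM" in g else None,
                    sulfide=g["sulfide_uM"].to_numpy() if "sulfide_uM" in g else None,
                )
            )
        return cls(profiles)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProfileSeries":
        return cls.from_frame(pd.read_csv(path, parse_dates=["date"]))


@dataclass(frozen=True)
class StratificationRecord:
    timestamp: pd.Timestamp
    N2: float                    # 1/s^2, at the thermocline
    inv_N2: float                # s^2, floored proxy
    proxy_capped: bool           # True when N2 was below the floor
    thermocline_depth: float     # m
    O2_below_thermocline: float  # percent saturation
    unstable_gradient: bool      # True when drho/dz < 0 at the thermocline


def water_density(T, validity=(-2.0, 40.0)):
    """Pure-water density (kg/m^3) from temperature (deg C).

    Uses the Thiesen–Scheel–Diesselhorst polynomial; outside *validity*
    a warning is emitted and the polynomial is still evaluated.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < validity[0]) or np.any(T > validity[1]):
        warnings.warn(
            f"temperature outside the density formula's validity window {validity}",
            stacklevel=2,
        )
    rho = 1000.0 * (
        1.0 - (T + _TSD_A) / (_TSD_B * (T + _TSD_C)) * (T - _TSD_TMAX) ** 2
    )
    return float(rho) if rho.ndim == 0 else rho


def _density_gradient(depths: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """drho/dz, centered in the interior and one-sided at the boundaries
    (np.gradient); z positive downward."""
    return np.gradient(rho, depths)


def buoyancy_frequency_squared(profile: DepthProfile) -> Tuple[float, float]:
    """(N^2, thermocline depth) for one profile.

    N^2 = (g/rho) drho/dz evaluated at the depth of the steepest density
    gradient. A density inversion (drho/dz < 0 at that depth) yields a
    negative N^2 — returned as-is so callers can flag it, never silently
    zeroed.
    """
    if len(profile) < 2:
        raise ValueError("need at least 2 depths to form a density gradient")
    rho = water_density(profile.temperature)
    grad = _density_gradient(profile.depths, rho)
    i = int(np.argmax(np.abs(grad)))
    n2 = GRAVITY / rho[i] * grad[i]
    return float(n2), float(profile.depths[i])


def mixing_proxy(N2: float, floor: float = N2_FLOOR) -> Tuple[float, bool]:
    """(1/N^2, capped-flag) with N^2 floored at *floor*.

    Negative N^2 (unstable density gradient) is a caller error here;
    flag and handle inversions before taking the proxy.
    """
    if N2 < 0:
        raise ValueError(f"N2 must be >= 0, got {N2}")
    if N2 < floor:
        return 1.0 / floor, True
    return 1.0 / N2, False


def oxygen_saturation_concentration(T) -> float:
    """Equilibrium O2 concentration (uM) of air-saturated fresh water at
    temperature T (deg C), Benson–Krause formulation at standard pressure."""
    T = np.asarray(T, dtype=float)
    TK = T + 273.15
    a0, a1, a2, a3, a4 = _BK_COEFF
    ln_mgL = a0 + a1 / TK + a2 / TK**2 + a3 / TK**3 + a4 / TK**4
    um = np.exp(ln_mgL) / _O2_MOLAR_MASS * 1000.0
    return float(um) if um.ndim == 0 else um


def oxygen_saturation(T, O) -> float:
    """Percent saturation, 100 * O / O_sat(T), O in uM."""
    O = np.asarray(O, dtype=float)
    if np.any(O < 0):
        raise ValueError("dissolved oxygen must be >= 0")
    sat = 100.0 * O / oxygen_saturation_concentration(T)
    return float(sat) if sat.ndim == 0 else sat


def _value_at_depth(profile: DepthProfile, values: np.ndarray, depth: float,
                    max_offset: float = 0.5) -> float:
    """Value at the sampled depth nearest the requested one; warn when the
    nearest sample is farther than *max_offset* metres."""
    i = int(np.argmin(np.abs(profile.depths - depth)))
    if abs(profile.depths[i] - depth) > max_offset:
        warnings.warn(
            f"requested depth {depth} m not sampled on {profile.timestamp.date()}; "
            f"using nearest depth {profile.depths[i]} m",
            stacklevel=3,
        )
    return float(values[i])


def stratification_records(
    series: ProfileSeries, o2_depth: Optional[float] = None
) -> List[StratificationRecord]:
    """One :class:`StratificationRecord` per profile.

    ``o2_depth`` fixes the depth at which oxygen saturation is reported;
    by default it is read just below the thermocline (1 m deeper).
    """
    records = []
    for p in series:
        n2, z_t = buoyancy_frequency_squared(p)
        unstable = n2 < 0
        inv_n2, capped = mixing_proxy(max(n2, 0.0))
        depth = (z_t + 1.0) if o2_depth is None else o2_depth
        o2 = _value_at_depth(p, p.oxygen, depth)
        temp = _value_at_depth(p, p.temperature, depth)
        records.append(
            StratificationRecord(
                timestamp=p.timestamp,
                N2=float(n2),
                inv_N2=inv_n2,
                proxy_capped=capped,
                thermocline_depth=z_t,
                O2_below_thermocline=oxygen_saturation(temp, o2),
                unstable_gradient=unstable,
            )
        )
    return records


def records_frame(records: Sequence[StratificationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class HysteresisLoop:
    """Seasonal trajectory in the (1/N^2, O2 saturation) plane.

    ``area`` is the shoelace signed area of the closed, time-ordered
    polygon. With mixing proxy on x and O2 saturation on y, a seasonal
    cycle that is oxic while stratification builds but anoxic at the same
    mixing intensity after turnover runs counter-clockwise and has
    positive area; a retracing (reversible) cycle has area ~0.
    ``phase_separation`` is the mean O2-saturation difference between the
    stratifying limb and the breakdown limb compared at matched proxy
    values (positive when the breakdown limb is the oxygen-poorer one).
    """

    timestamps: List[pd.Timestamp]
    inv_N2: np.ndarray
    O2_sat: np.ndarray
    area: float
    phase_separation: float
    depth: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.timestamps, "inv_N2": self.inv_N2, "O2_sat": self.O2_sat}
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.plot(self.inv_N2, self.O2_sat, "o-", ms=3)
        for i in range(0, len(self.inv_N2) - 1, max(1, len(self.inv_N2) // 8)):
            ax.annotate(
                "",
                xy=(self.inv_N2[i + 1], self.O2_sat[i + 1]),
                xytext=(self.inv_N2[i], self.O2_sat[i]),
                arrowprops=dict(arrowstyle="->", color="red"),
            )
        ax.set_xscale("log")
        ax.set_xlabel(r"mixing proxy $1/N^2$ (s$^2$)")
        ax.set_ylabel(r"O$_2$ saturation (%)")
        return ax


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    """Signed area of the closed polygon through the points in order."""
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def hysteresis_loop(series: ProfileSeries, depth: float = 7.0) -> HysteresisLoop:
    """Extract the (1/N^2, O2 saturation) loop at a fixed depth.

    For each profile the mixing proxy comes from the thermocline-level N^2
    and the oxygen saturation from the requested depth (nearest sampled
    depth; a warning is issued beyond 0.5 m). Requires at least 4 profiles.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 time points to measure a loop")
    ts, xs, ys, capped = [], [], [], []
    for p in series:
        n2, _ = buoyancy_frequency_squared(p)
        inv_n2, cap = mixing_proxy(max(n2, 0.0))
        o2 = _value_at_depth(p, p.oxygen, depth)
        temp = _value_at_depth(p, p.temperature, depth)
        ts.append(p.timestamp)
        xs.append(inv_n2)
        ys.append(oxygen_saturation(temp, o2))
        capped.append(cap)
    x = np.array(xs)
    y = np.array(ys)
    capped = np.array(capped)
    # loop area on a log-proxy axis: the proxy spans orders of magnitude, so
    # the polygon is formed in (log10 proxy, O2sat) coordinates; a retracing
    # path has zero area in any monotone transform of x
    area = _shoelace(np.log10(x), y)

    # phase separation: split at peak stratification (minimum proxy),
    # interpolate each limb over the shared proxy range, compare. Capped
    # (fully mixed) points all share one artificial proxy value and are
    # excluded from the limb interpolation.
    i_min = int(np.argmin(x))
    sep = float("nan")
    if 0 < i_min < len(x) - 1:
        m1 = ~capped[: i_min + 1]
        m2 = ~capped[i_min:]
        x1, y1 = x[: i_min + 1][m1], y[: i_min + 1][m1]   # stratifying limb
        x2, y2 = x[i_min:][m2], y[i_min:][m2]             # breakdown limb
        if len(x1) >= 2 and len(x2) >= 2:
            lo = max(x1.min(), x2.min())
            hi = min(x1.max(), x2.max())
            if hi > lo:
                grid = np.logspace(np.log10(lo), np.log10(hi), 25)
                o1, o2_ = np.argsort(x1), np.argsort(x2)
                y1i = np.interp(grid, x1[o1], y1[o1])
                y2i = np.interp(grid, x2[o2_], y2[o2_])
                sep = float(np.mean(y1i - y2i))
    return HysteresisLoop(
        timestamps=ts, inv_N2=x, O2_sat=y, area=area,
        phase_separation=sep, depth=depth,
    )
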