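"""Treatment-outcome metrics over a temperature history.

Three scalars summarize one treatment case:

* theta_A — apoptosis retention ratio: the time average, over the 600 s
  treatment, of the fraction of tumor volume inside the apoptosis band
  [43, 50) deg C.  1 means the whole tumor sat in the band the whole time.
* theta_H — thermal hazard retention value: the time- and volume-averaged
  sum of temperature-band weights over the shell of normal tissue extending
  1 mm outward from the tumor (50% of the tumor length).  0 when the shell
  never reaches 43 deg C.
* theta_eff — effective apoptosis retention ratio theta_A / theta_H, the
  optimization objective balancing tumor coverage against collateral
  heating.  When theta_H = 0 the case is flagged a "no-hazard optimum"
  rather than dividing by zero.

The hazard band weights are a configurable scheme; the default (0 below
43 C, 1 in the apoptosis band, 2 at necrosis temperatures) expresses that
necrosis-range collateral heating is categorically worse than
apoptosis-range heating.  Absolute theta_H / theta_eff values are only
meaningful relative to the chosen weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .bioheat import TemperatureField

__all__ = [
    "HazardWeighting",
    "MetricsResult",
    "apoptotic_fraction",
    "theta_A",
    "theta_H",
    "theta_eff",
    "compute_metrics",
]


@dataclass(frozen=True)
class HazardWeighting:
    """Ordered band edges (deg C) and weights for the len(edges)+1 bands.

    Bands are closed below / open above: with edges (43, 50), temperatures
    fall in (-inf, 43), [43, 50), [50, inf).
    """

    edges: tuple = (C.APOPTOSIS_LOW_C, C.APOPTOSIS_HIGH_C)
    weights: tuple = (0.0, 1.0, 2.0)

    def __post_init__(self):
        if len(self.weights) != len(self.edges) + 1:
            raise ValueError("need one weight per band (len(edges) + 1)")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("band edges must be strictly increasing")
        if any(w < 0 for w in self.weights):
            raise ValueError("band weights must be non-negative")
        if self.edges[0] == C.APOPTOSIS_LOW_C and self.weights[0] != 0.0:
            raise ValueError("weight below 43 C must be 0 (no thermal damage)")

    def weight_of(self, T: np.ndarray) -> np.ndarray:
        return np.asarray(self.weights)[
            np.searchsorted(self.edges, T, side="right")
        ]


@dataclass
class MetricsResult:
    """theta_A / theta_H / theta_eff plus their underlying time series."""

    theta_A: float
    theta_H: float
    theta_eff: float
    no_hazard: bool
    times: np.ndarray
    apoptotic_series: np.ndarray       # tumor in-band fraction per snapshot
    band_occupancy: np.ndarray         # (n_snap, 3) tumor fractions <43 / band / >=50
    diagnostics: dict = field(default_factory=dict)


def apoptotic_fraction(
    T: np.ndarray,
    low: float = C.APOPTOSIS_LOW_C,
    high: float = C.APOPTOSIS_HIGH_C,
) -> float:
    """Fraction of voxels with low <= T < high over one masked snapshot."""
    T = np.asarray(T)
    if T.size == 0:
        raise ValueError("empty temperature mask")
    return float(np.mean((T >= low) & (T < high)))


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two snapshots")
    if np.any(np.diff(times) <= 0):
        raise ValueError("snapshot times must be strictly increasing")
    return times


def theta_A(
    times: np.ndarray,
    tumor_temps: np.ndarray,
    low: float = C.APOPTOSIS_LOW_C,
    high: float = C.APOPTOSIS_HIGH_C,
) -> float:
    """Time-averaged (trapezoidal) apoptotic tumor-volume fraction, in [0, 1]."""
    times = _check_times(times)
    series = np.array([apoptotic_fraction(T, low, high) for T in tumor_temps])
    return float(np.trapezoid(series, times) / (times[-1] - times[0]))


def theta_H(
    times: np.ndarray,
    shell_temps: np.ndarray,
    weighting: HazardWeighting | None = None,
) -> float:
    """Time- and shell-averaged band-weight sum; 0 for an always-cool shell."""
    times = _check_times(times)
    w = weighting or HazardWeighting()
    series = np.array([np.mean(w.weight_of(T)) for T in shell_temps])
    return float(np.trapezoid(series, times) / (times[-1] - times[0]))


def theta_eff(theta_a: float, theta_h: float) -> tuple[float, bool]:
    """theta_A / theta_H; returns (value, no_hazard_flag).

    A zero hazard yields (inf for nonzero theta_A, else 0) with the flag set
    — a "no-hazard optimum" — never a division crash.
    """
    if theta_a < 0 or theta_h < 0:
        raise ValueError("metric inputs must be non-negative")
    if theta_h == 0.0:
        return (np.inf if theta_a > 0 else 0.0), True
    return theta_a / theta_h, False


def compute_metrics(
    history: TemperatureField,
    weighting: HazardWeighting | None = None,
) -> MetricsResult:
    """All three metrics from one solved temperature history."""
    w = weighting or HazardWeighting()
    times = _check_times(history.times)
    tumor = history.tumor_temps
    a_series = np.array([apoptotic_fraction(T) for T in tumor])
    occ = np.column_stack(
        [
            [np.mean(T < C.APOPTOSIS_LOW_C) for T in tumor],
            a_series,
            [np.mean(T >= C.APOPTOSIS_HIGH_C) for T in tumor],
        ]
    )
    span = times[-1] - times[0]
    t_a = float(np.trapezoid(a_series, times) / span)
    t_h = theta_H(times, history.shell_temps, w)
    t_eff, no_hazard = theta_eff(t_a, t_h)
    return MetricsResult(
        theta_A=t_a,
        theta_H=t_h,
        theta_eff=t_eff,
        no_hazard=no_hazard,
        times=times,
        apoptotic_series=a_series,
        band_occupancy=occ,
    )
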