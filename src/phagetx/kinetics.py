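"""Phage infection-kinetics metrics.

Implements the standard phage-microbiology quantities estimated from titer
and growth-curve data:

* adsorption constant  k = 2.3/(B*t) * log10(P0/Pt)  [mL/min], from
  free-phage depletion at bacterial titer B (CFU/mL) after t minutes;
* local virulence      v_MOI = 1 - A_MOI / A_NC, where A is the area under
  the OD600 infection curve and NC the uninfected control;
* virulence index      V_phi = A_virulence-curve / A_max, the area under the
  v_MOI vs log10(MOI) curve normalised by the area of v == 1 over the tested
  log-MOI range (0 = no killing, 1 = instantaneous complete lysis);
* phage score          P_s = [sum_i (A_MOI(i)/A_NC)/MOI(i)] / [sum_i 1/MOI(i)],
  the 1/MOI-weighted mean of normalised areas, implemented exactly in this
  printed form (so P_s = 1 means no killing). A virulence-weighted variant
  (numerators v_MOI instead of A_MOI/A_NC) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TiterSeries:
    """Adsorption-assay measurements: free phage over time."""

    B: float                 # bacterial titer, CFU/mL
    times: tuple             # minutes
    P0: float                # initial phage titer, PFU/mL
    P_t: tuple               # free phage titer at each time, PFU/mL

    def validate(self):
        if self.B <= 0 or self.P0 <= 0 or any(p <= 0 for p in self.P_t):
            raise ValueError("all titers must be positive")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if len(self.times) != len(self.P_t):
            raise ValueError("times and P_t must align")


@dataclass
class GrowthCurveSet:
    time_grid: np.ndarray          # minutes
    nc_curve: np.ndarray           # uninfected control OD600
    od_curves: dict                # MOI -> OD600 series

    def validate(self):
        n = len(self.time_grid)
        if len(self.nc_curve) != n or any(len(c) != n for c in self.od_curves.values()):
            raise ValueError("all curves must share the time grid")
        if np.any(self.nc_curve < 0) or any(np.any(np.asarray(c) < 0) for c in self.od_curves.values()):
            raise ValueError("OD must be non-negative")


@dataclass
class KineticsResult:
    k_per_time: dict = field(default_factory=dict)   # minute -> k (mL/min)
    A_MOI: dict = field(default_factory=dict)        # MOI -> area (OD*min)
    A_NC: float = 0.0
    v_MOI: dict = field(default_factory=dict)        # MOI -> local virulence
    V_phi: float = 0.0
    P_s: float = 0.0
    A_max: float = 0.0


def adsorption_constant(B: float, t: float, P0: float, Pt: float) -> float:
    """k = 2.3/(B*t) * log10(P0/Pt); 0 when no phage have adsorbed.

    The constant 2.3 is the conventional printed approximation of ln 10.
    """
    if B <= 0 or t <= 0 or P0 <= 0 or Pt <= 0:
        raise ValueError("all inputs must be positive")
    if Pt == P0:
        return 0.0
    return 2.3 / (B * t) * math.log10(P0 / Pt)


def adsorption_constants(series: TiterSeries) -> dict:
    series.validate()
    return {
        t: adsorption_constant(series.B, t, series.P0, p)
        for t, p in zip(series.times, series.P_t)
    }


def area_under_curve(times, values) -> float:
    """Trapezoidal area under one growth curve (OD600 * min)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have the same length")
    if len(times) < 2:
        raise ValueError("need at least 2 points")
    return float(np.trapezoid(values, times))


def local_virulence(A_MOI: float, A_NC: float) -> float:
    """v = 1 - A_MOI/A_NC; may be negative if the infected culture outgrows NC."""
    if A_NC == 0:
        raise ValueError("control area is zero")
    return 1.0 - A_MOI / A_NC


def _areas(curves: GrowthCurveSet):
    curves.validate()
    a_nc = area_under_curve(curves.time_grid, curves.nc_curve)
    a_moi = {
        moi: area_under_curve(curves.time_grid, od)
        for moi, od in curves.od_curves.items()
    }
    return a_moi, a_nc


def virulence_index(curves: GrowthCurveSet) -> float:
    """Area under v_MOI vs log10(MOI), normalised by the v == 1 area."""
    a_moi, a_nc = _areas(curves)
    if len(a_moi) < 2:
        raise ValueError("virulence index needs >= 2 MOI values")
    mois = sorted(a_moi)
    x = np.log10(mois)
    v = np.array([local_virulence(a_moi[m], a_nc) for m in mois])
    a_curve = float(np.trapezoid(v, x))
    a_max = float(x[-1] - x[0])
    if a_max == 0:
        raise ValueError("zero-width MOI range")
    return a_curve / a_max


def phage_score(curves: GrowthCurveSet, variant: str = "as_printed") -> float:
    """1/MOI-weighted mean of A_MOI/A_NC ("as_printed") or of v_MOI
    ("virulence_weighted")."""
    a_moi, a_nc = _areas(curves)
    if not a_moi:
        raise ValueError("no MOI curves")
    if a_nc == 0:
        raise ValueError("control area is zero")
    num = 0.0
    den = 0.0
    for moi, a in a_moi.items():
        ratio = a / a_nc
        if variant == "virulence_weighted":
            ratio = 1.0 - ratio
        elif variant != "as_printed":
            raise ValueError(f"unknown phage_score variant {variant!r}")
        num += ratio / moi
        den += 1.0 / moi
    return num / den


def compute_kinetics(
    curves: GrowthCurveSet,
    titers: TiterSeries | None = None,
    phage_score_variant: str = "as_printed",
) -> KineticsResult:
    """All growth-curve metrics (plus adsorption constants when titers given)."""
    a_moi, a_nc = _areas(curves)
    mois = sorted(a_moi)
    res = KineticsResult(
        A_MOI=a_moi,
        A_NC=a_nc,
        v_MOI={m: local_virulence(a_moi[m], a_nc) for m in mois},
        P_s=phage_score(curves, phage_score_variant),
    )
    if len(mois) >= 2:
        res.V_phi = virulence_index(curves)
        res.A_max = float(np.log10(mois[-1]) - np.log10(mois[0]))
    if titers is not None:
        res.k_per_time = adsorption_constants(titers)
    return res


@dataclass(frozen=True)
class GrowthSimParams:
    """Logistic growth for the uninfected control; infected cultures track the
    control until a MOI-dependent lysis onset, then decay exponentially."""

    moi_values: tuple = (1.0, 10.0)
    od0: float = 0.3
    carrying_capacity: float = 1.4
    growth_rate: float = 0.025        # 1/min
    lysis_onset_ref: float = 30.0     # min, onset at MOI 10
    onset_slope: float = 15.0         # min added per decade below MOI 10
    lysis_rate: float = 0.12          # 1/min OD decay after onset
    od_floor: float = 0.03
    noise_sd: float = 0.005           # additive OD noise on infected curves
    t_max: float = 145.0
    t_step: float = 15.0


def simulate_growth_curves(params: GrowthSimParams | None = None, seed: int = 0) -> GrowthCurveSet:
    """Deterministic-for-seed OD600 fixture generator.

    The control curve is noise-free (hence monotone until stationary phase);
    infected curves carry additive Gaussian noise clipped at the OD floor.
    """
    params = params or GrowthSimParams()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, params.t_max + 1e-9, params.t_step)
    K, n0, r = params.carrying_capacity, params.od0, params.growth_rate
    nc = K * n0 * np.exp(r * t) / (K + n0 * (np.exp(r * t) - 1.0))
    curves = {}
    for moi in params.moi_values:
        onset = params.lysis_onset_ref + params.onset_slope * (1.0 - np.log10(moi))
        od = nc.copy()
        if params.lysis_rate > 0:
            after = t > onset
            onset_od = float(np.interp(onset, t, nc))
            od[after] = params.od_floor + (onset_od - params.od_floor) * np.exp(
                -params.lysis_rate * (t[after] - onset)
            )
        if params.noise_sd > 0:
            od = od + rng.normal(0.0, params.noise_sd, size=od.shape)
        curves[moi] = np.clip(od, 0.0, None)
    return GrowthCurveSet(time_grid=t, nc_curve=nc, od_curves=curves)
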