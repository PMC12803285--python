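"""Two-fluorophore maturation kinetics and compartmental trafficking.

A tandem fluorescent timer (tFT) fuses a fast-maturing GFP-like chromophore
to a slow-maturing Cherry-like one.  Because both chromophores are produced
in equimolar amounts on the same polypeptide, the normalized slow/fast
fluorescence ratio of a protein pool depends only on the age distribution of
the pool: a newly synthesized pool has ratio near ``m_slow / m_fast`` while
an infinitely old pool has ratio 1.  This module provides

* the closed-form maturation model for a pulse of synthesis (the
  calibration experiment: 1 h induction, imaging every 15 min),
* the steady-state ratio of a constitutively synthesized pool that exits
  with first-order rate ``k`` (exponential age mixture) and its algebraic
  inverse, and
* a linear two-pool trafficking model (basolateral membrane -> apical
  degradative compartment) tracking total and matured amounts per
  chromophore.

Time is in hours throughout; amounts are arbitrary protein units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "FluorophorePair",
    "TraffickingParams",
    "PoolState",
    "PoolTrajectory",
    "CalibrationCurve",
    "KineticsError",
    "RatioOutOfRange",
    "pulse_matured_fraction",
    "pulse_ratio_curve",
    "steady_state_ratio",
    "invert_steady_state_ratio",
    "steady_state_pools",
    "simulate_trafficking",
]

LN2 = float(np.log(2.0))

#: fluorophore identifiers, fixed order used everywhere downstream
FLUOROPHORES = ("fast", "slow")


class KineticsError(ValueError):
    """Parameter-domain error in the kinetics layer."""


class RatioOutOfRange(KineticsError):
    """A slow/fast ratio outside the invertible open interval.

    ``side`` is ``"young"`` (at/below the lower bound m_slow/m_fast,
    younger than the method resolves) or ``"old"`` (at/above 1 or beyond
    the curve horizon, older than the method resolves).
    """

    def __init__(self, message: str, side: str):
        super().__init__(message)
        self.side = side


@dataclass(frozen=True)
class FluorophorePair:
    """Maturation rate constants (per hour) of the tandem pair.

    ``q_fast_acidic`` / ``q_slow_acidic`` are the fractional fluorescence
    retained in acidic compartments.  GFP-like chromophores are quenched at
    endo-lysosomal pH (default 0.0) while Cherry-like ones are not
    (default 1.0); ammonium-chloride neutralization restores both to 1.
    """

    m_fast: float
    m_slow: float
    q_fast_acidic: float = 0.0
    q_slow_acidic: float = 1.0

    def __post_init__(self) -> None:
        if not (self.m_fast > self.m_slow > 0):
            raise KineticsError(
                f"need m_fast > m_slow > 0, got m_fast={self.m_fast}, "
                f"m_slow={self.m_slow}"
            )
        for name in ("q_fast_acidic", "q_slow_acidic"):
            q = getattr(self, name)
            if not (0.0 <= q <= 1.0):
                raise KineticsError(f"{name} must lie in [0, 1], got {q}")

    @classmethod
    def from_half_times(
        cls,
        half_fast: float = 3.0,
        half_slow: float = 6.0,
        **quench: float,
    ) -> "FluorophorePair":
        """Build from maturation half-times in hours (rate = ln2 / t_half).

        Defaults are the calibrated wing-disc half-times of the GFP:Cherry
        tandem: approximately 3 h (fast) and 6 h (slow).
        """
        if not (0 < half_fast < half_slow):
            raise KineticsError(
                f"need 0 < half_fast < half_slow, got {half_fast}, {half_slow}"
            )
        return cls(m_fast=LN2 / half_fast, m_slow=LN2 / half_slow, **quench)

    @property
    def half_fast(self) -> float:
        return LN2 / self.m_fast

    @property
    def half_slow(self) -> float:
        return LN2 / self.m_slow

    @property
    def ratio_floor(self) -> float:
        """Small-age limit of the slow/fast ratio, m_slow / m_fast."""
        return self.m_slow / self.m_fast

    def rate(self, fluor: str) -> float:
        if fluor not in FLUOROPHORES:
            raise KeyError(f"unknown fluorophore {fluor!r}; expected {FLUOROPHORES}")
        return self.m_fast if fluor == "fast" else self.m_slow

    def quench(self, fluor: str, acidic: bool, nh4cl: bool = False) -> float:
        """Fluorescence scale factor for a pool (acidic unless neutralized)."""
        if not acidic or nh4cl:
            return 1.0
        return self.q_fast_acidic if fluor == "fast" else self.q_slow_acidic

    def neutralized(self) -> "FluorophorePair":
        """The pair with ammonium-chloride neutralization applied."""
        return replace(self, q_fast_acidic=1.0, q_slow_acidic=1.0)


@dataclass(frozen=True)
class TraffickingParams:
    """First-order trafficking rates of the tagged protein in one region.

    sigma   : synthesis rate delivering protein to the basolateral pool
              (units / h)
    k_exit  : basolateral -> apical transfer rate (1/h); the basolateral
              residence time is tau_B = 1 / k_exit
    k_deg   : apical degradation rate (1/h)
    """

    sigma: float
    k_exit: float
    k_deg: float
    region_label: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise KineticsError(f"sigma must be >= 0, got {self.sigma}")
        if self.k_exit <= 0:
            raise KineticsError(f"k_exit must be > 0, got {self.k_exit}")
        if self.k_deg <= 0:
            raise KineticsError(f"k_deg must be > 0, got {self.k_deg}")

    @property
    def residence_time(self) -> float:
        """Mean basolateral residence time tau_B = 1/k_exit (hours)."""
        return 1.0 / self.k_exit

    @classmethod
    def from_residence_time(
        cls,
        tau_b: float,
        sigma: float = 1.0,
        k_deg: float = 0.5,
        region_label: str = "",
    ) -> "TraffickingParams":
        if tau_b <= 0:
            raise KineticsError(f"residence time must be > 0, got {tau_b}")
        return cls(sigma=sigma, k_exit=1.0 / tau_b, k_deg=k_deg,
                   region_label=region_label)


@dataclass(frozen=True)
class PoolState:
    """Instantaneous pool amounts: totals plus matured amount per chromophore."""

    B: float = 0.0
    E: float = 0.0
    B_mat: Mapping[str, float] = field(default_factory=lambda: {"fast": 0.0, "slow": 0.0})
    E_mat: Mapping[str, float] = field(default_factory=lambda: {"fast": 0.0, "slow": 0.0})

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.B, self.B_mat["fast"], self.B_mat["slow"],
             self.E, self.E_mat["fast"], self.E_mat["slow"]]
        )

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "PoolState":
        return cls(
            B=float(v[0]),
            B_mat={"fast": float(v[1]), "slow": float(v[2])},
            E=float(v[3]),
            E_mat={"fast": float(v[4]), "slow": float(v[5])},
        )

    def ratio(self, pool: str) -> float:
        """Normalized slow/fast matured ratio of one pool ('B' or 'E')."""
        mat = self.B_mat if pool == "B" else self.E_mat
        if mat["fast"] <= 0:
            raise KineticsError(f"pool {pool!r} has no matured fast signal")
        return mat["slow"] / mat["fast"]


@dataclass
class PoolTrajectory:
    """Time course of the two-pool system on a sampling grid.

    ``totals[pool]`` is an array over times; ``matured[(pool, fluor)]``
    likewise, with pool in {"B", "E"} and fluor in {"fast", "slow"}.
    ``degraded`` is the cumulative degraded amount (for mass balance).
    """

    times: np.ndarray
    totals: dict
    matured: dict
    degraded: np.ndarray
    params: TraffickingParams
    pair: FluorophorePair

    def state_at(self, index: int) -> PoolState:
        return PoolState(
            B=float(self.totals["B"][index]),
            E=float(self.totals["E"][index]),
            B_mat={f: float(self.matured[("B", f)][index]) for f in FLUOROPHORES},
            E_mat={f: float(self.matured[("E", f)][index]) for f in FLUOROPHORES},
        )

    def to_frame(self):
        """Tidy table: columns time_h, pool, species, amount."""
        import pandas as pd

        rows = []
        for i, t in enumerate(self.times):
            for pool in ("B", "E"):
                rows.append((float(t), pool, "total", float(self.totals[pool][i])))
                for f in FLUOROPHORES:
                    rows.append(
                        (float(t), pool, f"matured_{f}",
                         float(self.matured[(pool, f)][i]))
                    )
        return pd.DataFrame(rows, columns=["time_h", "pool", "species", "amount"])


# ---------------------------------------------------------------------------
# Pulse (calibration) model
# ---------------------------------------------------------------------------

def pulse_matured_fraction(t, pulse_duration: float, m: float, lag: float = 0.0):
    """Normalized matured fluorescence after a synthesis pulse.

    Protein is synthesized at a constant rate during ``[0, pulse_duration]``
    with no degradation; a molecule of age ``a`` is fluorescent with
    probability ``1 - exp(-m a)``.  The cohort integral has the closed form

        f(t) = [t - (1 - e^{-m t}) / m] / D                 for t <= D
        f(t) = [D - e^{-m t} (e^{m D} - 1) / m] / D          for t >= D

    normalized so that f -> 1 as t -> infinity.  ``lag`` shifts expression
    onset (default 0).  Accepts scalar or array ``t``.
    """
    if pulse_duration <= 0:
        raise KineticsError(f"pulse_duration must be > 0, got {pulse_duration}")
    if m <= 0:
        raise KineticsError(f"maturation rate must be > 0, got {m}")
    t = np.asarray(t, dtype=float)
    te = np.clip(t - lag, 0.0, None)
    D = pulse_duration
    rising = np.minimum(te, D)
    # during the pulse: t - (1 - e^{-mt})/m ; afterwards the same cohort sum
    # with all cohorts aged by (t - D)
    f = np.where(
        te <= D,
        te - (-np.expm1(-m * te)) / m,
        D - np.exp(-m * te) * np.expm1(m * D) / m,
    )
    out = f / D
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone mapping from protein age to normalized slow/fast ratio.

    Built from the pulse model (``pulse_ratio_curve``) or from a fitted
    :class:`~tftimer.calibrate.CalibrationFit`.  Inversion is by bisection
    on a monotone interpolant (tolerance 1e-6 h).
    """

    ages: np.ndarray
    ratios: np.ndarray
    pair: FluorophorePair
    pulse_duration: float = 1.0

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        ratios = np.asarray(self.ratios, dtype=float)
        if ages.size == 0:
            raise KineticsError("calibration curve needs a non-empty age grid")
        if ages.size != ratios.size:
            raise KineticsError("ages and ratios must have equal length")
        if not np.all(np.diff(ages) > 0) or ages[0] <= 0:
            raise KineticsError("age grid must be strictly increasing and positive")
        if not np.all(np.diff(ratios) > 0):
            raise KineticsError("ratio values must be strictly increasing")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "ratios", ratios)

    @property
    def _interp(self) -> PchipInterpolator:
        return PchipInterpolator(self.ages, self.ratios, extrapolate=False)

    def ratio_at(self, age) -> float:
        """Ratio at an age inside the grid domain."""
        age = np.asarray(age, dtype=float)
        if np.any(age < self.ages[0]) or np.any(age > self.ages[-1]):
            raise RatioOutOfRange(
                f"age outside curve domain [{self.ages[0]}, {self.ages[-1]}] h",
                side="old",
            )
        val = self._interp(age)
        return val if val.ndim else float(val)

    def age_at(self, ratio: float, xtol: float = 1e-6) -> float:
        """Invert the curve by bisection; raises RatioOutOfRange at bounds."""
        lo, hi = float(self.ratios[0]), float(self.ratios[-1])
        if ratio <= lo:
            raise RatioOutOfRange(
                f"ratio {ratio:.4g} at/below curve minimum {lo:.4g}: "
                "younger than the curve resolves", side="young",
            )
        if ratio >= hi:
            raise RatioOutOfRange(
                f"ratio {ratio:.4g} at/above curve maximum {hi:.4g}: "
                f"older than the {self.ages[-1]:g} h curve horizon", side="old",
            )
        f = self._interp
        return float(brentq(lambda a: float(f(a)) - ratio,
                            self.ages[0], self.ages[-1], xtol=xtol))

    @property
    def domain(self) -> tuple:
        return float(self.ages[0]), float(self.ages[-1])


def pulse_ratio_curve(
    pair: FluorophorePair,
    pulse_duration: float = 1.0,
    times=None,
) -> CalibrationCurve:
    """Slow/fast ratio of the pulse-model fluorescence on an age grid.

    The ratio starts at ``m_slow / m_fast`` in the small-age limit and
    rises monotonically toward 1.  Default grid: 0.25 h to 12 h in 15-min
    steps (the imaging cadence of the calibration experiment).
    """
    if times is None:
        times = np.arange(0.25, 12.0 + 1e-9, 0.25)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise KineticsError("empty time grid")
    if times[0] <= 0 or not np.all(np.diff(times) > 0):
        raise KineticsError("time grid must be positive and strictly increasing")
    f_fast = pulse_matured_fraction(times, pulse_duration, pair.m_fast)
    f_slow = pulse_matured_fraction(times, pulse_duration, pair.m_slow)
    return CalibrationCurve(
        ages=times, ratios=f_slow / f_fast, pair=pair, pulse_duration=pulse_duration
    )


# ---------------------------------------------------------------------------
# Steady-state (exponential age mixture) model
# ---------------------------------------------------------------------------

def steady_state_ratio(k: float, pair: FluorophorePair) -> float:
    """Slow/fast ratio of a pool with exponential age distribution, rate k.

    The matured fraction of a chromophore with rate m is m / (m + k), so

        R(k) = [m_slow / (m_slow + k)] * [(m_fast + k) / m_fast]

    which decreases from 1 at k=0 to m_slow/m_fast as k -> infinity.
    """
    if k < 0:
        raise KineticsError(f"turnover rate k must be >= 0, got {k}")
    ms, mf = pair.m_slow, pair.m_fast
    return (ms / (ms + k)) * ((mf + k) / mf)


def invert_steady_state_ratio(R: float, pair: FluorophorePair) -> float:
    """Exit rate k (1/h) whose steady-state ratio equals R.

    Algebraic inverse: k = m_slow m_fast (1 - R) / (R m_fast - m_slow);
    defined only for R strictly inside (m_slow/m_fast, 1).
    """
    floor = pair.ratio_floor
    if R >= 1.0:
        raise RatioOutOfRange(
            f"ratio {R:.4g} not in open interval ({floor:.4g}, 1): "
            "a fully matured pool has k = 0", side="old",
        )
    if R <= floor:
        raise RatioOutOfRange(
            f"ratio {R:.4g} not in open interval ({floor:.4g}, 1): "
            "below the newly-synthesized floor m_slow/m_fast", side="young",
        )
    ms, mf = pair.m_slow, pair.m_fast
    return ms * mf * (1.0 - R) / (R * mf - ms)


# ---------------------------------------------------------------------------
# Two-pool trafficking model
# ---------------------------------------------------------------------------

def _rhs(t, y, sigma, k_exit, k_deg, mf, ms):
    B, Bmf, Bms, E, Emf, Ems, _deg = y
    return [
        sigma - k_exit * B,
        mf * (B - Bmf) - k_exit * Bmf,
        ms * (B - Bms) - k_exit * Bms,
        k_exit * B - k_deg * E,
        k_exit * Bmf + mf * (E - Emf) - k_deg * Emf,
        k_exit * Bms + ms * (E - Ems) - k_deg * Ems,
        k_deg * E,
    ]


def steady_state_pools(params: TraffickingParams, pair: FluorophorePair) -> PoolState:
    """Closed-form steady state of the trafficking system.

    B = sigma/k_exit, Bmat_f = m_f B / (m_f + k_exit), E = sigma/k_deg,
    Emat_f = (k_exit Bmat_f + m_f E) / (m_f + k_deg).
    """
    B = params.sigma / params.k_exit
    E = params.sigma / params.k_deg
    B_mat, E_mat = {}, {}
    for f in FLUOROPHORES:
        m = pair.rate(f)
        B_mat[f] = m * B / (m + params.k_exit)
        E_mat[f] = (params.k_exit * B_mat[f] + m * E) / (m + params.k_deg)
    return PoolState(B=B, E=E, B_mat=B_mat, E_mat=E_mat)


def simulate_trafficking(
    params: TraffickingParams,
    pair: FluorophorePair,
    times,
    initial: PoolState | None = None,
    rtol: float = 1e-8,
) -> PoolTrajectory:
    """Integrate the linear two-pool ODE system on a sampling grid.

    dB/dt    = sigma - k_exit B
    dBmat/dt = m (B - Bmat) - k_exit Bmat          (per chromophore)
    dE/dt    = k_exit B - k_deg E
    dEmat/dt = k_exit Bmat + m (E - Emat) - k_deg Emat

    Solved with LSODA (stiff-capable, adaptive).  Mass balance — cumulative
    synthesis minus cumulative degradation equals protein present — holds to
    integration tolerance and is tracked via an auxiliary degraded-mass state.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise KineticsError("empty time grid")
    if times[0] < 0 or not np.all(np.diff(times) > 0):
        raise KineticsError("time grid must be sorted, non-negative, distinct")
    y0 = np.zeros(7)
    if initial is not None:
        y0[:6] = initial.as_vector()
    sol = solve_ivp(
        _rhs,
        (times[0], times[-1]) if times.size > 1 else (0.0, times[0] + 1e-9),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=1e-10,
        args=(params.sigma, params.k_exit, params.k_deg, pair.m_fast, pair.m_slow),
    )
    if not sol.success:
        raise KineticsError(
            f"ODE solver failed near t={sol.t[-1] if sol.t.size else times[0]:.3g} h: "
            f"{sol.message}"
        )
    y = np.clip(sol.y, 0.0, None)  # clip solver-level negative round-off
    return PoolTrajectory(
        times=times,
        totals={"B": y[0], "E": y[3]},
        matured={
            ("B", "fast"): y[1], ("B", "slow"): y[2],
            ("E", "fast"): y[4], ("E", "slow"): y[5],
        },
        degraded=y[6],
        params=params,
        pair=pair,
    )
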