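"""One-compartment intravenous-infusion pharmacokinetics.

Closed-form solutions for a one-compartment model with first-order
elimination and zero-order (constant-rate) infusion input: single-dose and
multi-dose (superposition) concentration profiles, steady-state profiles by
geometric accumulation, exposure (AUC), half-life, and the fraction of a
steady-state dosing interval during which the free drug concentration
exceeds a minimal inhibitory concentration (MIC).

Units are fixed throughout the package: dose in mg, volume in L, time in h,
concentration in ug/mL (numerically identical to mg/L). No unit inference is
performed.

The model
---------
With clearance ``CL`` (L/h), volume of distribution ``V`` (L) and
elimination rate constant ``k = CL/V`` (1/h), a dose ``D`` infused at
constant rate over ``Tinf`` hours gives

    C(t) = (D / (Tinf * CL)) * (1 - exp(-k t)),              0 <= t <= Tinf
    C(t) = C(Tinf) * exp(-k (t - Tinf)),                     t > Tinf

Multiple doses superpose linearly; with interval ``tau`` the steady-state
profile over one interval follows from summing the geometric series of
trailing exponentials.

Bolus dosing (``infusion_duration == 0``) is deliberately unsupported: the
infusion closed form covers every regimen of interest and removes a
discontinuous special case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PKParams",
    "DosingRegimen",
    "PDTarget",
    "concentration",
    "steady_state_concentration",
    "steady_state_trough",
    "steady_state_peak",
    "auc24_ss",
    "half_life",
    "fraction_time_above_mic",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKParams:
    """Structural parameters of one subject.

    Parameters
    ----------
    clearance : float
        Plasma clearance CL in L/h. Must be positive.
    volume : float
        Apparent volume of distribution V in L. Must be positive.
    """

    clearance: float
    volume: float

    def __post_init__(self) -> None:
        if not (self.clearance > 0):
            raise ValueError(f"clearance must be > 0, got {self.clearance}")
        if not (self.volume > 0):
            raise ValueError(f"volume must be > 0, got {self.volume}")

    @property
    def k(self) -> float:
        """Elimination rate constant CL/V (1/h)."""
        return self.clearance / self.volume


@dataclass(frozen=True)
class DosingRegimen:
    """A repeated constant-rate infusion schedule.

    Parameters
    ----------
    dose : float
        Amount per administration (mg).
    infusion_duration : float
        Duration of each infusion (h); must satisfy
        ``0 < infusion_duration <= interval``.
    interval : float
        Inter-dose interval tau (h). May be ``math.inf`` for a single dose
        followed by washout.
    n_doses : int or None
        Number of doses for a finite schedule; ``None`` means steady state.
    """

    dose: float
    infusion_duration: float
    interval: float
    n_doses: int | None = None

    def __post_init__(self) -> None:
        if not (self.dose > 0):
            raise ValueError(f"dose must be > 0, got {self.dose}")
        if not (self.infusion_duration > 0):
            raise ValueError(
                "infusion_duration must be > 0 (bolus dosing is not supported)"
            )
        if not (self.infusion_duration <= self.interval):
            raise ValueError("infusion_duration must not exceed interval")
        if self.n_doses is not None and self.n_doses < 1:
            raise ValueError(f"n_doses must be >= 1, got {self.n_doses}")

    @property
    def rate(self) -> float:
        """Infusion rate D/Tinf (mg/h)."""
        return self.dose / self.infusion_duration

    @property
    def daily_dose(self) -> float:
        """Total daily dose (mg); requires the interval to divide 24 h."""
        n = 24.0 / self.interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"interval {self.interval} h does not divide 24 h; "
                "pass an explicit daily-dose override where supported"
            )
        return self.dose * round(n)


@dataclass(frozen=True)
class PDTarget:
    """A pharmacokinetic/pharmacodynamic attainment target.

    ``kind`` is either ``"ft_above_mic"`` (threshold = required percent of
    the dosing interval with free concentration above the MIC, e.g. 85) or
    ``"fauc_mic"`` (threshold = required ratio of free 24-h AUC to MIC,
    e.g. 80 or 100). ``fraction_unbound`` converts total to free drug;
    linezolid plasma protein binding gives 0.69.
    """

    kind: str
    threshold: float
    fraction_unbound: float = 0.69

    _KINDS = ("ft_above_mic", "fauc_mic")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if not (self.threshold > 0):
            raise ValueError("threshold must be > 0")
        if not (0 < self.fraction_unbound <= 1):
            raise ValueError("fraction_unbound must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Low-level vectorised kernels (complex-safe: used with complex CL/V by the
# estimation module's complex-step differentiation)
# ---------------------------------------------------------------------------

def _single_dose_conc(cl, v, dose, tinf, t):
    """Concentration ``t`` hours after the start of one infusion.

    All arguments may be arrays (broadcast); ``cl``/``v`` may be complex.
    Times are real. Returns 0 for ``t <= 0``.
    """
    t = np.asarray(t, dtype=float)
    k = cl / v
    plateau = dose / (tinf * cl)  # asymptotic infusion plateau R/CL
    during = plateau * -np.expm1(-k * np.minimum(t, tinf))
    after = during * np.exp(-k * np.maximum(t - tinf, 0.0))
    return np.where(t > 0, after, 0.0 * after)


def _css_at_offset(cl, v, dose, tinf, tau, u):
    """Steady-state concentration at offset ``u`` in [0, tau] of an interval.

    Geometric accumulation of the single-dose solution; ``u = 0`` and
    ``u = tau`` both give the trough. Complex-safe in ``cl``/``v``.
    """
    u = np.asarray(u, dtype=float)
    k = cl / v
    plateau = dose / (tinf * cl)
    pk_term = plateau * -np.expm1(-k * tinf)  # end-of-infusion single-dose level
    # Tails of the doses at -tau, -2tau, ... sum to a geometric series:
    # pk_term * e^{-k (u + tau - tinf)} / (1 - e^{-k tau}).
    prev = pk_term * np.exp(-k * (u + tau - tinf)) / -np.expm1(-k * tau)
    current = plateau * -np.expm1(-k * np.minimum(u, tinf))
    current = current * np.exp(-k * np.maximum(u - tinf, 0.0))
    return current + prev


def _css_trough(cl, v, dose, tinf, tau):
    """Steady-state trough (interval end); infinite ``tau`` gives 0."""
    k = cl / v
    plateau = dose / (tinf * cl)
    pk_term = plateau * -np.expm1(-k * tinf)
    with np.errstate(over="ignore"):
        out = pk_term * np.exp(-k * (tau - tinf)) / -np.expm1(-k * tau)
    return np.where(np.isfinite(tau), out, 0.0 * out)


def _css_peak(cl, v, dose, tinf, tau):
    """Steady-state peak (end of infusion)."""
    k = cl / v
    plateau = dose / (tinf * cl)
    return plateau * -np.expm1(-k * tinf) / -np.expm1(-k * tau)


def _ft_above_mic_arrays(cl, v, dose, tinf, tau, mic, fub):
    """Percent of the steady-state interval with free concentration > MIC.

    Vectorised over ``cl``/``v`` (real arrays). Solves the at-most-two
    crossings of the monotone rise (during infusion) and monotone decay
    (after the peak) analytically.
    """
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    k = cl / v
    plateau = dose / (tinf * cl)
    trough = _css_trough(cl, v, dose, tinf, tau)
    peak = _css_peak(cl, v, dose, tinf, tau)
    m = mic / fub  # equivalent threshold on the *total* concentration

    # Rising crossing: C(u) = plateau + (trough - plateau) e^{-k u} = m.
    # plateau > peak >= m > trough in the crossing case, so the log argument
    # lies in (0, 1). Clip keeps the vectorised np.where branches finite.
    arg_up = np.clip((plateau - m) / (plateau - trough), 1e-300, 1.0)
    t1 = -np.log(arg_up) / k
    # Falling crossing: peak e^{-k (u - tinf)} = m.
    arg_dn = np.clip(peak / m if m > 0 else np.inf, 1.0, None)
    t2 = np.minimum(tinf + np.log(arg_dn) / k, tau)

    frac = 100.0 * (t2 - t1) / tau
    frac = np.where(m >= peak, 0.0, frac)
    frac = np.where(m <= trough, 100.0, frac)
    if mic == 0:
        frac = np.full_like(frac, 100.0)
    return frac


# ---------------------------------------------------------------------------
# Public scalar API
# ---------------------------------------------------------------------------

def concentration(params: PKParams, regimen: DosingRegimen, t: float) -> float:
    """Total plasma concentration ``t`` hours after the first dose (ug/mL).

    For a finite schedule (``regimen.n_doses`` set) the profile is the
    superposition of single-dose solutions at dose times 0, tau, 2*tau, ...;
    for ``n_doses=None`` the periodic steady-state profile is returned,
    evaluated at offset ``t mod tau``.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    cl, v = params.clearance, params.volume
    if regimen.n_doses is None:
        if not math.isfinite(regimen.interval):
            return float(
                _single_dose_conc(cl, v, regimen.dose, regimen.infusion_duration, t)
            )
        u = t % regimen.interval
        return float(
            _css_at_offset(
                cl, v, regimen.dose, regimen.infusion_duration, regimen.interval, u
            )
        )
    starts = np.arange(regimen.n_doses) * regimen.interval
    contrib = _single_dose_conc(
        cl, v, regimen.dose, regimen.infusion_duration, t - starts
    )
    return float(np.sum(contrib))


def steady_state_concentration(
    params: PKParams, regimen: DosingRegimen, offset: float
) -> float:
    """Steady-state concentration at ``offset`` hours into a dosing interval."""
    if offset < 0 or offset > regimen.interval:
        raise ValueError("offset must lie in [0, interval]")
    if not math.isfinite(regimen.interval):
        return 0.0 if offset == 0 else float(
            _single_dose_conc(
                params.clearance, params.volume, regimen.dose,
                regimen.infusion_duration, offset,
            )
        )
    return float(
        _css_at_offset(
            params.clearance, params.volume, regimen.dose,
            regimen.infusion_duration, regimen.interval, offset,
        )
    )


def steady_state_trough(params: PKParams, regimen: DosingRegimen) -> float:
    """Concentration at the end of a dosing interval in the infinite-dose limit."""
    return float(
        _css_trough(
            params.clearance, params.volume, regimen.dose,
            regimen.infusion_duration, regimen.interval,
        )
    )


def steady_state_peak(params: PKParams, regimen: DosingRegimen) -> float:
    """Steady-state concentration at the end of the infusion."""
    return float(
        _css_peak(
            params.clearance, params.volume, regimen.dose,
            regimen.infusion_duration, regimen.interval,
        )
    )


def auc24_ss(
    params: PKParams,
    regimen: DosingRegimen,
    daily_dose_override: float | None = None,
) -> float:
    """Total steady-state exposure over 24 h (ug*h/mL).

    At steady state the AUC over 24 h equals ``daily_dose / CL`` regardless
    of the infusion shape. The daily dose is taken from the regimen, which
    requires the interval to divide 24 h; for other intervals an explicit
    ``daily_dose_override`` (mg) must be supplied.

    Multiply by the fraction unbound to obtain the free AUC.
    """
    if daily_dose_override is not None:
        if daily_dose_override <= 0:
            raise ValueError("daily_dose_override must be > 0")
        daily = daily_dose_override
    else:
        daily = regimen.daily_dose
    return daily / params.clearance


def half_life(params: PKParams) -> float:
    """Elimination half-life ln(2) * V / CL (h)."""
    return math.log(2.0) * params.volume / params.clearance


def fraction_time_above_mic(
    params: PKParams,
    regimen: DosingRegimen,
    mic: float,
    fraction_unbound: float = 0.69,
) -> float:
    """Percent of the steady-state interval with free concentration above MIC.

    Returns ``100 * |{u in [0, tau): fub * C_ss(u) > mic}| / tau``. The free
    profile rises monotonically from the trough during the infusion and
    decays monotonically after the peak, so there are at most two crossings,
    solved in closed form.
    """
    if mic < 0:
        raise ValueError(f"mic must be >= 0, got {mic}")
    if not (0 < fraction_unbound <= 1):
        raise ValueError("fraction_unbound must lie in (0, 1]")
    if not math.isfinite(regimen.interval):
        raise ValueError("steady-state interval required (finite interval)")
    return float(
        _ft_above_mic_arrays(
            params.clearance, params.volume, regimen.dose,
            regimen.infusion_duration, regimen.interval, mic, fraction_unbound,
        )
    )
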