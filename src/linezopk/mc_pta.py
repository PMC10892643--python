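"""Monte Carlo dosing simulation: PTA and CFR.

Virtual patients are drawn from the fitted population distribution
(lognormal between-subject variability on clearance and volume with the
estimated covariance), each patient's steady-state exposure is evaluated
against a PK/PD target over a grid of MIC values, and the probability of
target attainment (PTA) per MIC is weighted by a pathogen's MIC frequency
distribution to give the cumulative fraction of response,

    CFR = sum_i PTA_i * F_i,

where ``F_i`` is the fraction of isolates in MIC category *i*.

Attainment is evaluated on residual-error-free ("true") concentrations: the
PK/PD index concerns the patient's actual exposure, not the assay noise.
Free-drug quantities use the fraction unbound of the target (0.69 for
linezolid). For fAUC24/MIC targets the steady-state identity
``fAUC24 = fub * daily_dose / CL`` is used; %fT>MIC is evaluated
analytically on one steady-state dosing interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nlme import PopEstimates
from .structural import DosingRegimen, PDTarget, _css_trough, _ft_above_mic_arrays

__all__ = [
    "DEFAULT_MIC_GRID",
    "PopulationSample",
    "MICDistribution",
    "PTAResult",
    "CFRResult",
    "SafetyCounts",
    "sample_population",
    "pta_curve",
    "cfr",
    "safety_flags",
    "steady_state_troughs",
]

# two-fold dilutions 0.0625 .. 16 mg/L
DEFAULT_MIC_GRID = tuple(float(0.0625 * 2**i) for i in range(9))

PTA_DESIRABLE = 90.0  # percent, the conventional "desirable" PTA breakpoint
CFR_ACCEPTABLE = 90.0


@dataclass(frozen=True, eq=False)
class PopulationSample:
    """Simulated patients' structural parameters, reproducible from the seed."""

    n: int
    clearance: np.ndarray
    volume: np.ndarray
    seed: int
    source: PopEstimates

    def __post_init__(self) -> None:
        if np.any(self.clearance <= 0) or np.any(self.volume <= 0):
            raise ValueError("sampled clearances and volumes must be positive")


@dataclass(frozen=True, eq=False)
class MICDistribution:
    """Isolate frequency by MIC for one pathogen (fractions normalised)."""

    pathogen: str
    mics: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        mics = np.asarray(self.mics, dtype=float)
        fr = np.asarray(self.fractions, dtype=float)
        if len(mics) != len(fr) or len(mics) == 0:
            raise ValueError("mics and fractions must be equal-length, non-empty")
        if np.any(mics <= 0) or np.any(np.diff(mics) <= 0):
            raise ValueError("MIC values must be positive and strictly increasing")
        if np.any(fr < 0) or fr.sum() <= 0:
            raise ValueError("fractions must be non-negative with positive sum")
        fr = fr / fr.sum()
        assert abs(fr.sum() - 1.0) <= 1e-9
        object.__setattr__(self, "mics", mics)
        object.__setattr__(self, "fractions", fr)


@dataclass(frozen=True, eq=False)
class PTAResult:
    """PTA (percent) per grid MIC for one regimen and target."""

    regimen: DosingRegimen
    target: PDTarget
    mics: np.ndarray
    pta: np.ndarray
    n: int
    seed: int
    breakpoint_mic: float | None  # largest grid MIC with PTA >= 90%


@dataclass(frozen=True)
class CFRResult:
    pathogen: str
    regimen: DosingRegimen
    target: PDTarget
    cfr: float

    @property
    def acceptable(self) -> bool:
        """Whether the CFR reaches the conventional 90% acceptability bar."""
        return self.cfr >= CFR_ACCEPTABLE


@dataclass(frozen=True)
class SafetyCounts:
    below_window: int
    in_window: int
    above_threshold: int


def sample_population(est: PopEstimates, n: int, seed: int) -> PopulationSample:
    """Draw ``n`` virtual patients from the population distribution.

    ``(eta_V, eta_CL)`` pairs come from a bivariate normal with the
    estimates' Omega (which must already be positive semi-definite — apply
    :meth:`PopEstimates.repaired` first for published covariances that imply
    |correlation| > 1); clearance and volume are the typical values times
    ``exp(eta)``. Bit-for-bit reproducible given ``(seed, n, est)``.
    """
    if n <= 0:
        raise ValueError(f"n must be >= 1, got {n}")
    if not est.is_psd():
        raise ValueError(
            "Omega is not positive semi-definite; repair it first "
            "(PopEstimates.repaired)"
        )
    om = est.omega_matrix()
    ev, U = np.linalg.eigh(om)
    L = U @ np.diag(np.sqrt(np.clip(ev, 0.0, None)))
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal((n, 2)) @ L.T  # columns: (eta_V, eta_CL)
    cl = est.typical_clearance * np.exp(eta[:, 1])
    v = est.typical_volume * np.exp(eta[:, 0])
    return PopulationSample(n=n, clearance=cl, volume=v, seed=seed, source=est)


def pta_curve(
    sample: PopulationSample,
    regimen: DosingRegimen,
    target: PDTarget,
    mic_grid=DEFAULT_MIC_GRID,
    strict: bool = False,
) -> PTAResult:
    """Probability of target attainment per MIC over the grid.

    For ``fauc_mic`` targets a patient attains when
    ``fub * daily_dose / CL / MIC >= threshold``; for ``ft_above_mic`` when
    the percent of the steady-state interval with free concentration above
    the MIC is at least the threshold. ``strict=True`` uses ``>`` instead of
    ``>=`` in the attainment comparison.
    """
    mics = np.asarray(mic_grid, dtype=float)
    if mics.size == 0:
        raise ValueError("MIC grid must be non-empty")
    if np.any(mics <= 0) or np.any(np.diff(mics) <= 0):
        raise ValueError("MIC grid must be positive and strictly increasing")
    fub = target.fraction_unbound
    cmp = np.greater if strict else np.greater_equal
    pta = np.empty(len(mics))
    if target.kind == "fauc_mic":
        fauc = fub * regimen.daily_dose / sample.clearance
        for i, mic in enumerate(mics):
            pta[i] = 100.0 * np.mean(cmp(fauc / mic, target.threshold))
    else:
        for i, mic in enumerate(mics):
            ft = _ft_above_mic_arrays(
                sample.clearance, sample.volume, regimen.dose,
                regimen.infusion_duration, regimen.interval, float(mic), fub,
            )
            pta[i] = 100.0 * np.mean(cmp(ft, target.threshold))
    ok = mics[pta >= PTA_DESIRABLE]
    breakpoint_mic = float(ok.max()) if ok.size else None
    return PTAResult(
        regimen=regimen, target=target, mics=mics, pta=pta,
        n=sample.n, seed=sample.seed, breakpoint_mic=breakpoint_mic,
    )


def cfr(pta: PTAResult, dist: MICDistribution) -> CFRResult:
    """Cumulative fraction of response: PTA weighted by isolate fractions.

    Every MIC of the distribution must be present on the PTA grid (no
    silent interpolation); a missing MIC raises an error naming it.
    """
    total = 0.0
    for mic, frac in zip(dist.mics, dist.fractions):
        match = np.isclose(pta.mics, mic, rtol=1e-9, atol=0.0)
        if not match.any():
            raise ValueError(
                f"distribution MIC {mic} mg/L ({dist.pathogen}) is absent "
                "from the PTA grid"
            )
        total += float(pta.pta[match.argmax()]) * frac
    return CFRResult(pathogen=dist.pathogen, regimen=pta.regimen,
                     target=pta.target, cfr=total)


def safety_flags(
    troughs,
    window: tuple[float, float] = (2.0, 8.0),
    toxicity_threshold: float = 8.0,
) -> SafetyCounts:
    """Count troughs below / within the therapeutic window and above the
    toxicity threshold.

    Boundary convention: in-window means ``low <= trough <= high``;
    above-threshold means ``trough > threshold`` (strict). Defaults follow
    the commonly recommended linezolid trough range 2-8 mg/L with 8 mg/L as
    the thrombocytopenia-risk threshold.
    """
    low, high = window
    if low > high:
        raise ValueError("window low must not exceed high")
    t = np.asarray(list(troughs), dtype=float)
    if t.size and (np.any(~np.isfinite(t)) or np.any(t < 0)):
        raise ValueError("troughs must be finite and >= 0")
    return SafetyCounts(
        below_window=int(np.sum(t < low)),
        in_window=int(np.sum((t >= low) & (t <= high))),
        above_threshold=int(np.sum(t > toxicity_threshold)),
    )


def steady_state_troughs(sample: PopulationSample, regimen: DosingRegimen) -> np.ndarray:
    """Steady-state trough concentration of every simulated patient (ug/mL)."""
    return _css_trough(
        sample.clearance, sample.volume, regimen.dose,
        regimen.infusion_duration, regimen.interval,
    )
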