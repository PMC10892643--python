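"""Synthetic study cohorts with the statistical structure the analysis assumes.

The original concentration data are not publicly deposited, so everything
downstream (estimation, bootstrap, VPC, PTA) is exercised on virtual cohorts
that emulate the study design: nine subjects at steady state on 600 mg
linezolid infused over 30 min every 8 h, sampled pre-dose and 0.5, 1, 2, 4
and 6 h after the start of an infusion, with one missing 0.5 h sample,
lognormal between-subject variability on clearance and volume (negatively
correlated), proportional residual error, and an assay quantification range
of 0.75-30 ug/mL. Defaults reproduce that design exactly (53 observation
records from 9 subjects).

The generating truth defaults to the published population estimates
(``table3_estimates``). Observed concentrations are computed by
superposition over the subject's recorded dose events — with the required
six-plus preceding doses this is steady state to well under 0.1% — so a fit
to a noise-free cohort recovers the truth exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nlme import PKDataset, PopEstimates, Subject
from .structural import DosingRegimen, _single_dose_conc

__all__ = [
    "StudyDesign",
    "TruthSpec",
    "table3_estimates",
    "default_design",
    "generate_cohort",
    "table2_fixture",
    "toy_mic_distributions",
]


def table3_estimates(
    sigma_interpretation: str = "sd",
    iiv_interpretation: str = "sd",
) -> PopEstimates:
    """Published population estimates: TVCL 5.9 L/h, TVV 41.1 L,
    IIV 24.8% (CL) and 36.3% (V), eta covariance -0.0901, proportional
    residual error 0.114.

    The published table does not state whether 0.114 is the standard
    deviation or the variance of the proportional error, nor whether the
    IIV percentages are 100*omega or the exact lognormal CV; both readings
    are supported. Defaults take them as standard deviations
    (``sigma_interpretation="sd"``, ``iiv_interpretation="sd"``), the usual
    reporting convention and consistent with the described goodness of fit.
    ``sigma_interpretation="variance"`` uses sqrt(0.114);
    ``iiv_interpretation="exact_cv"`` solves CV% = 100*sqrt(exp(omega^2)-1).

    Note the printed covariance implies |correlation| slightly above 1
    (rounding); apply :meth:`PopEstimates.repaired` before sampling.
    """
    sigma = 0.114 if sigma_interpretation == "sd" else math.sqrt(0.114)
    if iiv_interpretation == "sd":
        ocl, ov = 0.248, 0.363
    elif iiv_interpretation == "exact_cv":
        ocl = math.sqrt(math.log(1.0 + 0.248**2))
        ov = math.sqrt(math.log(1.0 + 0.363**2))
    else:
        raise ValueError("iiv_interpretation must be 'sd' or 'exact_cv'")
    if sigma_interpretation not in ("sd", "variance"):
        raise ValueError("sigma_interpretation must be 'sd' or 'variance'")
    return PopEstimates(
        typical_clearance=5.9,
        typical_volume=41.1,
        omega_cl=ocl,
        omega_v=ov,
        omega_cov=-0.0901,
        sigma_prop=sigma,
    )


@dataclass(frozen=True)
class StudyDesign:
    """Dosing, sampling and missingness layout of a virtual study.

    ``sampling_offsets`` are hours into the sampled steady-state interval;
    offset 0 is the pre-dose sample, i.e. the trough of the preceding
    interval. ``missing`` lists (subject index, offset) pairs to drop,
    emulating samples not obtained. ``doses_before_sampling`` doses are
    administered before the sampled interval (>= 6 to guarantee steady
    state).
    """

    n_subjects: int = 9
    regimen: DosingRegimen = field(
        default_factory=lambda: DosingRegimen(dose=600.0, infusion_duration=0.5, interval=8.0)
    )
    doses_before_sampling: int = 6
    sampling_offsets: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0)
    missing: tuple[tuple[int, float], ...] = ((7, 0.5),)
    assay_limits: tuple[float, float] = (0.75, 30.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.doses_before_sampling < 6:
            raise ValueError("doses_before_sampling must be >= 6 (steady state)")
        for u in self.sampling_offsets:
            if not (0 <= u < self.regimen.interval):
                raise ValueError("sampling offsets must lie in [0, interval)")
        if list(self.sampling_offsets) != sorted(set(self.sampling_offsets)):
            raise ValueError("sampling offsets must be strictly increasing")
        for i, u in self.missing:
            if not (0 <= i < self.n_subjects) or u not in self.sampling_offsets:
                raise ValueError(f"missing spec ({i}, {u}) outside the design")


@dataclass(frozen=True)
class TruthSpec:
    """Generating truth: population estimates plus the cohort seed."""

    estimates: PopEstimates = field(default_factory=table3_estimates)
    seed: int = 0


def default_design() -> StudyDesign:
    """The study's sampling design (9 subjects, one missing 0.5 h sample)."""
    return StudyDesign()


def generate_cohort(design: StudyDesign, truth: TruthSpec) -> PKDataset:
    """Simulate one cohort: eta draws, steady-state sampling, proportional
    noise, assay-range flagging, specified missing samples.

    Per subject, ``(eta_V, eta_CL)`` is drawn from the (repaired) Omega,
    concentrations at the design offsets are computed by superposition over
    the recorded dose events, and multiplied by ``1 + eps`` with
    ``eps ~ N(0, sigma_prop^2)`` truncated at -0.999 so concentrations stay
    positive. Values outside the assay range are flagged, not clamped.
    Deterministic given the seed.
    """
    est, _ = truth.estimates.repaired()
    rng = np.random.default_rng(truth.seed)
    om = est.omega_matrix()
    ev, U = np.linalg.eigh(om)
    L = U @ np.diag(np.sqrt(np.clip(ev, 0.0, None)))
    n = design.n_subjects
    eta = rng.standard_normal((n, 2)) @ L.T

    tau = design.regimen.interval
    tinf = design.regimen.infusion_duration
    amt = design.regimen.dose
    dose_times = np.arange(design.doses_before_sampling + 1) * tau
    offsets = np.asarray(design.sampling_offsets, dtype=float)
    obs_times = design.doses_before_sampling * tau + offsets

    eps = rng.normal(0.0, est.sigma_prop, size=(n, len(offsets)))
    eps = np.maximum(eps, -0.999)

    missing = {(i, u) for i, u in design.missing}
    lo, hi = design.assay_limits
    subjects = []
    for i in range(n):
        cl = est.typical_clearance * math.exp(eta[i, 1])
        v = est.typical_volume * math.exp(eta[i, 0])
        sdt = obs_times[:, None] - dose_times[None, :]
        f = _single_dose_conc(cl, v, amt, tinf, sdt).sum(axis=1)
        y = f * (1.0 + eps[i])
        keep = np.array([(i, float(u)) not in missing for u in offsets])
        y, t = y[keep], obs_times[keep]
        flag = (y < lo) | (y > hi)
        subjects.append(
            Subject(
                subject_id=f"S{i + 1:02d}",
                dose_times=dose_times,
                dose_amounts=np.full(len(dose_times), amt),
                dose_durations=np.full(len(dose_times), tinf),
                obs_times=t,
                obs_conc=y,
                blloq=flag,
            )
        )
    return PKDataset(tuple(subjects), assay_limits=design.assay_limits)


_TABLE2_ROWS = [
    # patient_id, peak, trough, auc24 (ug*h/mL), half-life (h)
    ("1", 20.8, 8.5, 312.40, 5.46),
    ("2", 23.5, 10.3, 340.89, 6.23),
    ("4", 25.0, 1.4, 207.54, 1.78),
    ("6", 23.5, 11.7, 425.36, 10.83),
    ("7", 21.2, 7.2, 303.57, 4.54),
    ("8", 22.1, 2.5, 215.01, 2.19),
    ("9", 22.3, 4.0, 254.33, 3.12),
    ("10", 20.8, 9.7, 327.02, 6.14),
    ("11", 25.0, 14.8, 434.67, 11.12),
]


def table2_fixture() -> pd.DataFrame:
    """The nine published individual PK summaries (peak and trough
    concentration in ug/mL, AUC24 in ug*h/mL, half-life in h), verbatim,
    for regression tests of the reporting operations."""
    return pd.DataFrame(
        _TABLE2_ROWS,
        columns=["patient_id", "peak", "trough", "auc24", "half_life"],
    )


def toy_mic_distributions() -> list:
    """Three clearly synthetic MIC frequency distributions.

    These are hand-made toy stand-ins for the three pathogens evaluated in
    the analysis (Enterococcus faecium, Staphylococcus aureus, Streptococcus
    pneumoniae) — they are NOT surveillance (EUCAST) data and carry a
    "synthetic" label. Real analyses should load user-supplied distribution
    files instead. All MICs lie on the default two-fold PTA grid.
    """
    from importlib import resources

    from .cli_io import read_mic_distribution

    out = []
    for name in (
        "synthetic_mic_e_faecium.tsv",
        "synthetic_mic_s_aureus.tsv",
        "synthetic_mic_s_pneumoniae.tsv",
    ):
        ref = resources.files("linezopk.data").joinpath(name)
        with resources.as_file(ref) as path:
            out.append(read_mic_distribution(path))
    return out
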