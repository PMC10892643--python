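"""Nonlinear mixed-effects estimation for the population PK model.

Model
-----
Subject *i* has clearance and volume

    CL_i = TVCL * exp(eta_CL,i),   V_i = TVV * exp(eta_V,i),

with ``eta_i = (eta_V, eta_CL)`` bivariate normal with mean zero and
covariance ``Omega = [[omega_v**2, omega_cov], [omega_cov, omega_cl**2]]``.
An observation at time *t* is

    y = f(t; CL_i, V_i) * (1 + eps),   eps ~ N(0, sigma_prop**2),

where *f* is the one-compartment infusion model evaluated by superposition
over the subject's recorded dose events (proportional residual error).

The marginal likelihood integrates the random effects per subject; the
integral is approximated by the Laplace method at the per-subject posterior
mode (adaptive Gauss-Hermite quadrature is available as an alternative).
The objective function value (OFV) is -2 times the marginal log-likelihood,
additive over subjects.

Estimation works on an unconstrained scale: logs of the typical values and
of the random-effect standard deviations, with the eta correlation mapped
through arctanh, so Omega stays valid throughout optimisation. Derivatives
for the inner (per-subject) Newton steps use complex-step differentiation,
which is exact to machine precision; the Laplace curvature is a central
finite difference of that gradient.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .structural import _single_dose_conc

__all__ = [
    "PopEstimates",
    "Subject",
    "PKDataset",
    "FitConfig",
    "FitResult",
    "marginal_ofv",
    "fit_poppk",
    "empirical_bayes",
    "covariate_search",
    "bootstrap_ci",
    "vpc_bands",
    "simulate_observations",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopEstimates:
    """Population parameters: typical values, IIV covariance, residual error.

    ``omega_cl`` and ``omega_v`` are the *standard deviations* of the
    log-scale random effects (so 100*omega approximates the CV%);
    ``omega_cov`` is the covariance of the two log-scale effects (volume
    first); ``sigma_prop`` is the standard deviation of the proportional
    residual error.
    """

    typical_clearance: float
    typical_volume: float
    omega_cl: float
    omega_v: float
    omega_cov: float
    sigma_prop: float

    def __post_init__(self) -> None:
        if not (self.typical_clearance > 0 and self.typical_volume > 0):
            raise ValueError("typical values must be > 0")
        if self.omega_cl < 0 or self.omega_v < 0:
            raise ValueError("omega standard deviations must be >= 0")
        if self.sigma_prop < 0:
            # 0 is tolerated for simulation (deterministic limit); estimation
            # requires a strictly positive residual error
            raise ValueError("sigma_prop must be >= 0")

    def omega_matrix(self) -> np.ndarray:
        """2x2 IIV covariance matrix, order (volume, clearance)."""
        return np.array(
            [
                [self.omega_v**2, self.omega_cov],
                [self.omega_cov, self.omega_cl**2],
            ]
        )

    @property
    def correlation(self) -> float:
        """Correlation of the (eta_V, eta_CL) pair; nan if either omega is 0."""
        denom = self.omega_v * self.omega_cl
        return self.omega_cov / denom if denom > 0 else float("nan")

    def is_psd(self) -> bool:
        if self.omega_v == 0 or self.omega_cl == 0:
            return self.omega_cov == 0
        return abs(self.correlation) <= 1.0

    def repaired(self, max_abs_corr: float = 0.999) -> tuple["PopEstimates", bool]:
        """Clip the eta correlation into [-max_abs_corr, max_abs_corr].

        Published variance/covariance triples are rounded independently and
        can imply |correlation| > 1; clipping preserves the printed
        variances and recomputes the covariance. Returns the (possibly
        unchanged) estimates and whether a repair was applied.
        """
        denom = self.omega_v * self.omega_cl
        if denom == 0:
            if self.omega_cov != 0:
                raise ValueError("omega_cov must be 0 when an omega is 0")
            return self, False
        rho = self.omega_cov / denom
        if abs(rho) <= max_abs_corr:
            return self, False
        new_cov = math.copysign(max_abs_corr, rho) * denom
        return replace(self, omega_cov=new_cov), True


@dataclass(frozen=True, eq=False)
class Subject:
    """One subject's dose and observation events (times in h since first dose)."""

    subject_id: str
    dose_times: np.ndarray
    dose_amounts: np.ndarray
    dose_durations: np.ndarray
    obs_times: np.ndarray
    obs_conc: np.ndarray
    blloq: np.ndarray  # True where the observation is outside the assay range

    def __post_init__(self) -> None:
        for name in ("dose_times", "dose_amounts", "dose_durations", "obs_times", "obs_conc"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "blloq", np.asarray(self.blloq, dtype=bool))
        if len(self.dose_times) == 0:
            raise ValueError(f"subject {self.subject_id}: at least one dose required")
        if np.any(self.dose_times < 0) or np.any(self.obs_times < 0):
            raise ValueError(f"subject {self.subject_id}: negative event time")
        if np.any(np.diff(self.obs_times) <= 0):
            raise ValueError(
                f"subject {self.subject_id}: observation times must be strictly increasing"
            )
        if np.any(self.dose_amounts <= 0) or np.any(self.dose_durations <= 0):
            raise ValueError(f"subject {self.subject_id}: doses need positive amount and duration")

    @property
    def n_obs(self) -> int:
        return len(self.obs_times)


@dataclass(frozen=True, eq=False)
class PKDataset:
    """A collection of subjects plus the assay quantification limits (ug/mL)."""

    subjects: tuple[Subject, ...]
    assay_limits: tuple[float, float] = (0.75, 30.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        lo, hi = self.assay_limits
        if not (0 < lo < hi):
            raise ValueError("assay limits must satisfy 0 < lower < upper")
        for s in self.subjects:
            quantifiable = (s.obs_conc >= lo) & (s.obs_conc <= hi)
            if np.any(~quantifiable & ~s.blloq):
                raise ValueError(
                    f"subject {s.subject_id}: concentration outside assay range "
                    f"[{lo}, {hi}] without an out-of-range flag"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return int(sum(s.n_obs for s in self.subjects))


@dataclass
class FitConfig:
    """Optimiser and validation settings.

    ``inner_tol`` is the gradient tolerance of the per-subject MAP Newton
    iteration; ``n_starts`` the number of multi-start outer optimisations
    (start 1 at the supplied init, the rest jittered); ``eta_method``
    selects the marginal-likelihood approximation; ``agq_nodes`` the
    per-dimension node count for adaptive Gauss-Hermite quadrature.
    """

    n_starts: int = 5
    inner_tol: float = 1e-8
    outer_maxiter: int = 400
    seed: int = 0
    eta_method: str = "laplace"  # or "adaptive-quadrature"
    agq_nodes: int = 9
    bootstrap_n: int = 1000
    vpc_n: int = 1000

    def __post_init__(self) -> None:
        if self.n_starts < 1 or self.bootstrap_n < 1 or self.vpc_n < 1:
            raise ValueError("replicate and start counts must be >= 1")
        if self.inner_tol <= 0:
            raise ValueError("inner_tol must be > 0")
        if self.eta_method not in ("laplace", "adaptive-quadrature"):
            raise ValueError("eta_method must be 'laplace' or 'adaptive-quadrature'")


@dataclass
class FitResult:
    estimates: PopEstimates
    ofv: float
    converged: bool
    message: str
    start_ofvs: list[float]
    warnings: list[str]
    n_blloq_dropped: int
    covariate_effects: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Workspace: padded arrays for vectorised likelihood evaluation
# ---------------------------------------------------------------------------

class _Workspace:
    """Padded per-dataset arrays; drops out-of-range-flagged observations."""

    def __init__(self, dataset: PKDataset):
        subs = [s for s in dataset.subjects if int(np.sum(~s.blloq)) > 0]
        self.excluded_ids = [s.subject_id for s in dataset.subjects if s not in subs]
        self.n_blloq_dropped = int(sum(np.sum(s.blloq) for s in dataset.subjects))
        self.ids = [s.subject_id for s in subs]
        n = len(subs)
        self.n_sub = n
        if n == 0:
            return
        n_obs = max(int(np.sum(~s.blloq)) for s in subs)
        n_dose = max(len(s.dose_times) for s in subs)
        self.obs_t = np.zeros((n, n_obs))
        self.obs_y = np.ones((n, n_obs))
        self.mask = np.zeros((n, n_obs), dtype=bool)
        self.dose_t = np.zeros((n, n_dose))
        self.dose_a = np.zeros((n, n_dose))
        self.dose_d = np.ones((n, n_dose))
        for i, s in enumerate(subs):
            keep = ~s.blloq
            m = int(np.sum(keep))
            self.obs_t[i, :m] = s.obs_times[keep]
            self.obs_y[i, :m] = s.obs_conc[keep]
            self.mask[i, :m] = True
            d = len(s.dose_times)
            self.dose_t[i, :d] = s.dose_times
            self.dose_a[i, :d] = s.dose_amounts
            self.dose_d[i, :d] = s.dose_durations
        self.n_obs_per_sub = self.mask.sum(axis=1)
        self.total_obs = int(self.mask.sum())
        # precomputed superposition kernels: time since each dose start,
        # split into rise (within infusion) and fall (post-infusion) parts
        sdt = self.obs_t[:, :, None] - self.dose_t[:, None, :]
        dur = self.dose_d[:, None, :]
        self.pos = sdt > 0
        self.s_rise = np.clip(sdt, 0.0, dur)
        self.s_fall = np.maximum(sdt - dur, 0.0)
        self.rate = self.dose_a / self.dose_d  # (n_sub, n_dose), mg/h

    def predict(self, cl, v):
        """Model concentration at every retained observation (n_sub, n_obs).

        ``cl``/``v`` are (n_sub,) arrays, real or complex (complex-step safe).
        """
        k = (cl / v)[:, None, None]
        plateau = self.rate[:, None, :] / cl[:, None, None]
        f = plateau * -np.expm1(-k * self.s_rise) * np.exp(-k * self.s_fall)
        f = np.where(self.pos, f, 0.0 * f)
        return f.sum(axis=2)

    def predict_multi(self, cl, v):
        """Predictions for (n_sub, G) candidate parameter grids -> (n_sub, G, n_obs)."""
        k = (cl / v)[:, :, None, None]
        plateau = self.rate[:, None, None, :] / cl[:, :, None, None]
        f = plateau * -np.expm1(-k * self.s_rise[:, None]) * np.exp(
            -k * self.s_fall[:, None]
        )
        f = np.where(self.pos[:, None], f, 0.0)
        return f.sum(axis=3)

    def replicate(self, R: int) -> "_Workspace":
        """R stacked copies of the workspace (rows ordered replica-major),
        letting several population parameter vectors share one inner solve."""
        w = _Workspace.__new__(_Workspace)
        w.ids = [f"r{r}_{i}" for r in range(R) for i in self.ids]
        w.excluded_ids = list(self.excluded_ids)
        w.n_blloq_dropped = self.n_blloq_dropped
        w.n_sub = self.n_sub * R
        for name in ("obs_t", "obs_y", "mask", "dose_t", "dose_a", "dose_d",
                     "pos", "s_rise", "s_fall", "rate"):
            a = getattr(self, name)
            setattr(w, name, np.tile(a, (R,) + (1,) * (a.ndim - 1)))
        w.n_obs_per_sub = w.mask.sum(axis=1)
        w.total_obs = int(w.mask.sum())
        return w


def _neg2ll_conditional(ws: _Workspace, cl, v, sigma):
    """-2 log p(y | eta) per subject, proportional error (complex-safe).

    ``sigma`` may be a scalar or a per-subject (n,) array."""
    f = ws.predict(cl, v)
    f = np.where(ws.mask, f, 1.0 + 0.0 * f)  # padded cells: benign placeholder
    sig = np.asarray(sigma, dtype=float)
    if sig.ndim == 1:
        sig = sig[:, None]
    var = (sig * f) ** 2
    res = (ws.obs_y - f) ** 2 / var
    terms = np.where(ws.mask, _LOG2PI + np.log(var) + res, 0.0 * res)
    return terms.sum(axis=1)


# ---------------------------------------------------------------------------
# Inner problem: per-subject MAP of eta, vectorised Newton
# ---------------------------------------------------------------------------

class _EtaProblem:
    """Joint machinery for eta MAP, Laplace OFV and AGQ on one workspace.

    Population parameters are held per workspace row, so several population
    parameter vectors (e.g. a finite-difference stencil of the outer
    optimisation) can share one stacked inner solve.
    """

    def __init__(self, ws: _Workspace, est: PopEstimates,
                 mult_cl: np.ndarray | None = None,
                 mult_v: np.ndarray | None = None):
        if not (est.sigma_prop > 0):
            raise ValueError("estimation requires sigma_prop > 0")
        if not est.is_psd():
            raise ValueError(
                "Omega is not positive semi-definite (|correlation| > 1); "
                "repair it first (PopEstimates.repaired)"
            )
        # active random-effect dimensions: 0 = eta_V, 1 = eta_CL
        active = [d for d, w in enumerate((est.omega_v, est.omega_cl)) if w > 0]
        om = est.omega_matrix()
        omega_act = om[np.ix_(active, active)]
        n = ws.n_sub
        mcl = np.ones(n) if mult_cl is None else mult_cl
        mv = np.ones(n) if mult_v is None else mult_v
        self._init_rows(
            ws,
            est.typical_clearance * mcl,
            est.typical_volume * mv,
            np.full(n, est.sigma_prop),
            np.broadcast_to(omega_act, (n, len(active), len(active))),
            active,
        )

    @classmethod
    def from_rows(cls, ws: _Workspace, tvcl_row, tvv_row, sig_row,
                  omega_rows, active):
        """Row-wise constructor: one population parameter set per row."""
        self = cls.__new__(cls)
        self._init_rows(ws, tvcl_row, tvv_row, sig_row, omega_rows, active)
        return self

    def _init_rows(self, ws, tvcl_row, tvv_row, sig_row, omega_rows, active):
        self.ws = ws
        self.active = list(active)
        self.d = len(self.active)
        self.tvcl_row = np.asarray(tvcl_row, dtype=float)
        self.tvv_row = np.asarray(tvv_row, dtype=float)
        sig = np.asarray(sig_row, dtype=float)
        if not np.all(sig > 0):
            raise ValueError("estimation requires sigma_prop > 0")
        self.sig2_row = sig**2
        if self.d > 0:
            self.omega_rows = np.asarray(omega_rows, dtype=float)
            sign, logdet = np.linalg.slogdet(self.omega_rows)
            if np.any(sign <= 0):
                raise ValueError("Omega is singular on its active dimensions")
            self.omega_inv_row = np.linalg.inv(self.omega_rows)
            self.omega_logdet_row = logdet
            # representative covariance for grid-candidate placement only
            self.omega_act = self.omega_rows[0]

    def _cl_v(self, eta_full):
        cl = self.tvcl_row * np.exp(eta_full[:, 1])
        v = self.tvv_row * np.exp(eta_full[:, 0])
        return cl, v

    def _expand(self, eta_act):
        """(n, d_active) -> (n, 2) with inactive dims fixed at 0."""
        full = np.zeros((self.ws.n_sub, 2), dtype=eta_act.dtype)
        for j, dim in enumerate(self.active):
            full[:, dim] = eta_act[:, j]
        return full

    def g(self, eta_act):
        """Per-subject -log [p(y|eta) p(eta)] (complex-safe)."""
        eta_full = self._expand(eta_act)
        cl, v = self._cl_v(eta_full)
        out = 0.5 * _neg2ll_conditional(self.ws, cl, v, np.sqrt(self.sig2_row))
        if self.d > 0:
            quad = np.einsum("ni,nij,nj->n", eta_act, self.omega_inv_row, eta_act)
            out = out + 0.5 * (quad + self.d * _LOG2PI + self.omega_logdet_row)
        return out

    def _grad_multi(self, etas):
        """g values (n, S) and exact gradients (n, S, d) at S points per
        subject, from a single batched complex-step evaluation."""
        n, S, d = etas.shape
        h = 1e-20
        E = np.repeat(etas, d, axis=1).astype(complex)  # (n, S*d, d)
        for j in range(d):
            E[:, j::d, j] += 1j * h
        eta_full = np.zeros((n, S * d, 2), dtype=complex)
        for j, dim in enumerate(self.active):
            eta_full[:, :, dim] = E[:, :, j]
        cl = self.tvcl_row[:, None] * np.exp(eta_full[:, :, 1])
        v = self.tvv_row[:, None] * np.exp(eta_full[:, :, 0])
        F = self.ws.predict_multi(cl, v)  # (n, S*d, m) complex
        f = F[:, 0::d].real  # (n, S, m)
        J = np.stack([F[:, j::d].imag / h for j in range(d)], axis=-1)
        mask = self.ws.mask[:, None]
        y = self.ws.obs_y[:, None]
        sig2 = self.sig2_row[:, None, None]
        fm = np.where(mask, f, 1.0)
        r = y - fm
        gval = 0.5 * np.where(
            mask, _LOG2PI + np.log(sig2 * fm**2) + r**2 / (sig2 * fm**2), 0.0
        ).sum(axis=2)
        dgdf = np.where(
            mask, 1.0 / fm - r / (sig2 * fm**2) - r**2 / (sig2 * fm**3), 0.0
        )
        grad = np.einsum("nsm,nsmj->nsj", dgdf, J)
        quad = np.einsum("nsi,nij,nsj->ns", etas, self.omega_inv_row, etas)
        gval = gval + 0.5 * (quad + d * _LOG2PI + self.omega_logdet_row[:, None])
        grad = grad + np.einsum("nsi,nij->nsj", etas, self.omega_inv_row)
        return gval, grad

    def _g_values(self, etas):
        """g at S points per subject, (n, S), value-only batched evaluation."""
        n, S, d = etas.shape
        eta_full = np.zeros((n, S, 2))
        for j, dim in enumerate(self.active):
            eta_full[:, :, dim] = etas[:, :, j]
        cl = self.tvcl_row[:, None] * np.exp(eta_full[:, :, 1])
        v = self.tvv_row[:, None] * np.exp(eta_full[:, :, 0])
        f = self.ws.predict_multi(cl, v)
        mask = self.ws.mask[:, None]
        sig2 = self.sig2_row[:, None, None]
        fm = np.where(mask, f, 1.0)
        r = self.ws.obs_y[:, None] - fm
        gval = 0.5 * np.where(
            mask, _LOG2PI + np.log(sig2 * fm**2) + r**2 / (sig2 * fm**2), 0.0
        ).sum(axis=2)
        quad = np.einsum("nsi,nij,nsj->ns", etas, self.omega_inv_row, etas)
        return gval + 0.5 * (quad + d * _LOG2PI + self.omega_logdet_row[:, None])

    def value_and_grad(self, eta_act):
        """g and its exact gradient (no Hessian work)."""
        gval, grad = self._grad_multi(eta_act[:, None, :])
        return gval[:, 0], grad[:, 0]

    def grad(self, eta_act):
        """Exact gradient of g, (n, d)."""
        return self.value_and_grad(eta_act)[1]

    def hessian(self, eta_act, step: float = 1e-5):
        """Central FD of the exact gradient, (n, d, d), symmetrised.

        The whole 2d-point stencil is evaluated in one batched call."""
        n, d = self.ws.n_sub, self.d
        stencil = np.repeat(eta_act[:, None, :], 2 * d, axis=1)
        for k in range(d):
            stencil[:, 2 * k, k] += step
            stencil[:, 2 * k + 1, k] -= step
        _, grads = self._grad_multi(stencil)  # (n, 2d, d)
        H = np.empty((n, d, d))
        for k in range(d):
            H[:, :, k] = (grads[:, 2 * k] - grads[:, 2 * k + 1]) / (2 * step)
        return 0.5 * (H + np.transpose(H, (0, 2, 1)))

    def _grid_start(self):
        """Best eta per subject over a prior-covariance-scaled grid.

        The per-subject posterior can be multimodal (sparse sampling leaves a
        clearance/volume trade-off); refining from the grid's global minimum
        keeps the Laplace objective continuous in the population parameters
        (a min of smooth surfaces), where tracking a single Newton basin
        would jump between modes.
        """
        d = self.d
        z = np.linspace(-3.0, 3.0, 9)
        if d == 1:
            zs = z[:, None]
        else:
            za, zb = np.meshgrid(z, z, indexing="ij")
            zs = np.stack([za.ravel(), zb.ravel()], axis=1)
        L = np.linalg.cholesky(
            self.omega_act + 1e-12 * np.eye(d) * np.trace(self.omega_act)
        )
        cand = zs @ L.T  # (G, d)
        eta_full = np.zeros((self.ws.n_sub, len(cand), 2))
        for j, dim in enumerate(self.active):
            eta_full[:, :, dim] = cand[None, :, j]
        cl = self.tvcl_row[:, None] * np.exp(eta_full[:, :, 1])
        v = self.tvv_row[:, None] * np.exp(eta_full[:, :, 0])
        f = self.ws.predict_multi(cl, v)  # (n, G, m)
        mask = self.ws.mask[:, None]
        fm = np.where(mask, f, 1.0)
        sig2 = self.sig2_row[:, None, None]
        r = self.ws.obs_y[:, None] - fm
        g = 0.5 * np.where(
            mask, _LOG2PI + np.log(sig2 * fm**2) + r**2 / (sig2 * fm**2), 0.0
        ).sum(axis=2)
        quad = np.einsum("gi,nij,gj->ng", cand, self.omega_inv_row, cand)
        g = g + 0.5 * quad
        return cand[np.argmin(g, axis=1)]

    def map_eta(self, eta0=None, tol: float = 1e-8, maxiter: int = 100,
                return_curvature: bool = False, use_grid: bool = True):
        """Vectorised damped Newton to the per-subject posterior mode,
        started from the best point of a prior-scaled grid scan (or from
        ``eta0`` where that is better).

        ``use_grid=False`` (requires ``eta0``) refines from ``eta0`` alone —
        appropriate when the caller already holds the global modes of an
        infinitesimally perturbed copy of the same problem.

        With ``return_curvature=True`` also returns the exact Hessian of g
        at the mode (for the Laplace determinant)."""
        n, d = self.ws.n_sub, self.d
        if d == 0:
            eta = np.zeros((n, 0))
            return (eta, np.zeros((n, 0, 0))) if return_curvature else eta
        with np.errstate(all="ignore"):
            if not use_grid and eta0 is not None:
                eta = eta0.copy()
                bad = ~np.isfinite(eta).all(axis=1) | (np.abs(eta).max(axis=1) > 20)
                eta[bad] = 0.0
            else:
                eta = self._grid_start()
                if eta0 is not None:
                    cand = eta0.copy()
                    bad = ~np.isfinite(cand).all(axis=1) | (np.abs(cand).max(axis=1) > 20)
                    cand[bad] = 0.0
                    better = self.g(cand).real < self.g(eta).real
                    eta[better] = cand[better]
            gval, gr = self.value_and_grad(eta)
            if not np.all(np.isfinite(gval)):
                eta = np.zeros((n, d))
                gval, gr = self.value_and_grad(eta)
            ts = 2.0 ** -np.arange(15.0)  # batched backtracking grid
            curv = None
            for _ in range(maxiter):
                H_raw = self.hessian(eta)
                # make each block positive definite before solving
                ev = np.linalg.eigvalsh(H_raw)
                ridge = np.maximum(1e-6 - ev[:, 0], 0.0)
                H = H_raw + ridge[:, None, None] * np.eye(d)
                step = -np.linalg.solve(H, gr[..., None])[..., 0]
                step = np.where(np.isfinite(step), step, -np.sign(gr))
                # scale-free stop: the Newton decrement bounds the remaining
                # decrease of g (an absolute gradient test is unattainable
                # when a tiny omega makes the prior curvature enormous)
                decrement = 0.5 * np.einsum("ni,ni->n", gr, -step)
                unconverged = decrement >= tol
                if not unconverged.any():
                    curv = H_raw  # exact Hessian at the final eta
                    break
                # trust region: |eta| beyond a few prior SDs is never the mode
                norm = np.linalg.norm(step, axis=1, keepdims=True)
                step = step * np.minimum(1.0, 3.0 / np.maximum(norm, 1e-300))
                # fast path: the full Newton step is accepted almost always
                full = eta + step
                g_full, gr_full = self.value_and_grad(full)
                ok_full = np.isfinite(g_full) & (g_full < gval)
                stuck = np.zeros(n, dtype=bool)
                if np.all(ok_full | ~unconverged):
                    move = ok_full & unconverged
                    eta = np.where(move[:, None], full, eta)
                    gval = np.where(move, g_full, gval)
                    gr = np.where(move[:, None], gr_full, gr)
                else:
                    trials = eta[:, None, :] + ts[None, :, None] * step[:, None, :]
                    gt = self._g_values(trials)  # (n, T)
                    gt = np.where(np.isfinite(gt), gt, np.inf)
                    decrease = gt < gval[:, None]
                    first = np.argmax(decrease, axis=1)  # largest improving t
                    improved = decrease[np.arange(n), first] & unconverged
                    stuck = unconverged & ~improved
                    eta = np.where(
                        improved[:, None],
                        trials[np.arange(n), first],
                        eta,
                    )
                    gval, gr = self.value_and_grad(eta)
                    if stuck.any():
                        # no measurable decrease left for some subject: the
                        # objective is at its numerical floor there
                        break
            if return_curvature:
                return eta, (curv if curv is not None else self.hessian(eta))
        return eta

    def laplace_rows(self, eta_hat, H=None) -> np.ndarray:
        """Per-row -2 log marginal likelihood by Laplace approximation."""
        gv = self.g(eta_hat).real
        if self.d == 0:
            return 2.0 * gv
        if H is None:
            with np.errstate(all="ignore"):
                H = self.hessian(eta_hat)
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            # curvature not PD at the reported mode: fall back to ridge
            ev = np.linalg.eigvalsh(H)
            ridge = np.maximum(1e-8 - ev[:, 0], 0.0)
            sign, logdet = np.linalg.slogdet(H + ridge[:, None, None] * np.eye(self.d))
        ll = -gv + 0.5 * self.d * _LOG2PI - 0.5 * logdet
        return -2.0 * ll

    def laplace_ofv(self, eta_hat, H=None) -> float:
        """-2 marginal log-likelihood by Laplace approximation at the mode."""
        return float(self.laplace_rows(eta_hat, H).sum())

    def agq_ofv(self, eta_hat, n_nodes: int = 9) -> float:
        """Adaptive Gauss-Hermite quadrature centred at the Laplace mode."""
        if self.d == 0:
            return float(2.0 * self.g(eta_hat).real.sum())
        H = self.hessian(eta_hat)
        ev = np.linalg.eigvalsh(H)
        ridge = np.maximum(1e-8 - ev[:, 0], 0.0)
        H = H + ridge[:, None, None] * np.eye(self.d)
        L = np.linalg.cholesky(np.linalg.inv(H))  # (n, d, d)
        z, w = np.polynomial.hermite.hermgauss(n_nodes)
        grids = np.meshgrid(*([z] * self.d), indexing="ij")
        zs = np.stack([g.ravel() for g in grids], axis=1)          # (m, d)
        ws_ = np.prod(np.meshgrid(*([w] * self.d), indexing="ij"), axis=0).ravel()
        m = zs.shape[0]
        # eta nodes: eta_hat + sqrt(2) L z
        nodes = eta_hat[:, None, :] + math.sqrt(2.0) * np.einsum(
            "nij,mj->nmi", L, zs
        )
        gvals = np.empty((self.ws.n_sub, m))
        for q in range(m):
            gvals[:, q] = self.g(nodes[:, q, :]).real
        # log integral = log sum_q w_q exp(-g + |z|^2) + d/2 log 2 + log|L|
        z2 = np.sum(zs**2, axis=1)
        logterms = -gvals + z2[None, :] + np.log(ws_)[None, :]
        mx = logterms.max(axis=1)
        logsum = mx + np.log(np.exp(logterms - mx[:, None]).sum(axis=1))
        _, logdetL = np.linalg.slogdet(L)
        ll = logsum + 0.5 * self.d * math.log(2.0) + logdetL
        return float(-2.0 * ll.sum())


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def marginal_ofv(
    dataset: PKDataset,
    est: PopEstimates,
    method: str = "laplace",
    inner_tol: float = 1e-8,
    agq_nodes: int = 9,
    _eta0=None,
) -> float:
    """-2 x marginal log-likelihood of the population model on the dataset.

    The eta integral per subject uses the Laplace approximation at the MAP
    mode by default; ``method="adaptive-quadrature"`` switches to adaptive
    Gauss-Hermite quadrature centred at that mode. Subjects whose retained
    observation count is zero contribute exactly 0. Raises if Omega is not
    positive semi-definite (use :meth:`PopEstimates.repaired` first).
    """
    ws = _Workspace(dataset)
    if ws.n_sub == 0:
        return 0.0
    prob = _EtaProblem(ws, est)
    eta_hat = prob.map_eta(eta0=_eta0, tol=inner_tol)
    if method == "adaptive-quadrature":
        return prob.agq_ofv(eta_hat, n_nodes=agq_nodes)
    return prob.laplace_ofv(eta_hat)


def _pack(est: PopEstimates, fit_corr: bool) -> np.ndarray:
    rho = est.correlation if fit_corr else 0.0
    if not np.isfinite(rho):
        rho = 0.0
    rho = float(np.clip(rho, -0.999, 0.999))
    x = [
        math.log(est.typical_clearance),
        math.log(est.typical_volume),
        math.log(max(est.omega_cl, 1e-3)),
        math.log(max(est.omega_v, 1e-3)),
    ]
    if fit_corr:
        x.append(math.atanh(rho))
    x.append(math.log(est.sigma_prop))
    return np.array(x)


def _unpack(x: np.ndarray, fit_corr: bool) -> PopEstimates:
    tvcl, tvv = math.exp(x[0]), math.exp(x[1])
    ocl, ov = math.exp(x[2]), math.exp(x[3])
    if fit_corr:
        rho = math.tanh(x[4])
        sigma = math.exp(x[5])
    else:
        rho = 0.0
        sigma = math.exp(x[4])
    return PopEstimates(tvcl, tvv, ocl, ov, rho * ocl * ov, sigma)


def _make_objective(ws: _Workspace, fit_corr: bool, inner_tol: float,
                    candidates: list[tuple[str, np.ndarray]] | None = None):
    """OFV as a function of the unconstrained vector.

    The per-subject eta modes are re-solved from the prior mode (eta = 0) on
    every call: the inner posterior can be multimodal, and a history-dependent
    warm start would make the objective discontinuous wherever the tracked
    mode switches basins, corrupting finite-difference gradients.

    ``candidates`` appends one power/shift exponent per (parameter,
    covariate multiplier column) after the base parameters.
    """
    n_base = 6 if fit_corr else 5
    cands = candidates or []

    def objective(x: np.ndarray) -> float:
        try:
            est = _unpack(x[:n_base], fit_corr)
        except (OverflowError, ValueError):
            return 1e12
        mult_cl = np.ones(ws.n_sub)
        mult_v = np.ones(ws.n_sub)
        for (param, logmult, _key), beta in zip(cands, x[n_base:]):
            m = np.exp(beta * logmult)
            if param == "clearance":
                mult_cl = mult_cl * m
            else:
                mult_v = mult_v * m
        try:
            with np.errstate(all="ignore"):
                prob = _EtaProblem(ws, est, mult_cl, mult_v)
                eta_hat, curv = prob.map_eta(tol=inner_tol, return_curvature=True)
                val = prob.laplace_ofv(eta_hat, curv)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    return objective


_FD_STEP = 1e-5  # forward-difference step for the outer gradient


def _make_fun_and_grad(ws: _Workspace, fit_corr: bool, inner_tol: float,
                       candidates: list | None = None):
    """Batched OFV-and-gradient: the base point plus one forward-difference
    replica per parameter share a single stacked inner solve.

    The per-subject eta modes are re-solved from the prior-scaled grid on
    every call: the inner posterior can be multimodal, and a
    history-dependent warm start would make the objective discontinuous
    wherever the tracked mode switches basins, corrupting the gradient.
    """
    n_base = 6 if fit_corr else 5
    cands = candidates or []
    n = ws.n_sub
    scalar = _make_objective(ws, fit_corr, inner_tol, candidates)

    def fun_and_grad(x: np.ndarray):
        p = len(x)
        xs = np.vstack([x, x + _FD_STEP * np.eye(p)])  # (p+1, p)
        R = p + 1
        tvcl = np.empty(R * n)
        tvv = np.empty(R * n)
        sig = np.empty(R * n)
        om = np.empty((R * n, 2, 2))
        try:
            for r, xr in enumerate(xs):
                est = _unpack(xr[:n_base], fit_corr)
                mult_cl = np.ones(n)
                mult_v = np.ones(n)
                for (param, logmult, _key), beta in zip(cands, xr[n_base:]):
                    m = np.exp(beta * logmult)
                    if param == "clearance":
                        mult_cl = mult_cl * m
                    else:
                        mult_v = mult_v * m
                sl = slice(r * n, (r + 1) * n)
                tvcl[sl] = est.typical_clearance * mult_cl
                tvv[sl] = est.typical_volume * mult_v
                sig[sl] = est.sigma_prop
                om[sl] = est.omega_matrix()
        except (OverflowError, ValueError):
            return 1e12, np.zeros(p)
        try:
            with np.errstate(all="ignore"):
                # solve the base replica first (with the global-mode grid
                # scan), then refine all FD replicas from those modes: a
                # 1e-5 parameter perturbation never changes the mode basin
                # converge to the numerical floor: any independent position
                # error in the replica modes would otherwise leak into the
                # finite-difference gradient amplified by 1/step
                tol_fd = min(inner_tol, 1e-13)
                base = _EtaProblem.from_rows(
                    ws, tvcl[:n], tvv[:n], sig[:n], om[:n], (0, 1)
                )
                eta_base = base.map_eta(tol=tol_fd)
                prob = _EtaProblem.from_rows(
                    ws.replicate(R), tvcl, tvv, sig, om, (0, 1)
                )
                eta_hat, curv = prob.map_eta(
                    eta0=np.tile(eta_base, (R, 1)), use_grid=False,
                    tol=tol_fd, return_curvature=True,
                )
                rows = prob.laplace_rows(eta_hat, curv)
            ofv = rows.reshape(R, n).sum(axis=1)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return 1e12, np.zeros(p)
        if not np.all(np.isfinite(ofv)):
            # fall back to the (slower) scalar objective at the base point
            f0 = scalar(x)
            return f0, np.zeros(p)
        grad = (ofv[1:] - ofv[0]) / _FD_STEP
        return float(ofv[0]), grad

    return fun_and_grad


def _bounds(n_params: int, fit_corr: bool) -> list[tuple[float, float]]:
    """Box bounds on the unconstrained scale.

    Typical values roam widely; random-effect and residual SDs are capped at
    e^2 ~ 7.4 (an IIV beyond 740% CV only arises as a degenerate attractor)
    and floored at e^-7; covariate exponents stay in a physiological range.
    """
    b = [(-12.0, 12.0), (-12.0, 12.0), (-7.0, 2.0), (-7.0, 2.0)]
    if fit_corr:
        b.append((-7.0, 7.0))
    b.append((-7.0, 2.0))
    while len(b) < n_params:
        b.append((-10.0, 10.0))
    return b


def _naive_init(ws: _Workspace) -> PopEstimates:
    """Crude data-driven starting point: clearance from the mean steady-state
    concentration (AUC24 ~ 24 * mean concentration), volume from the
    peak-trough swing."""
    conc = ws.obs_y[ws.mask]
    cbar = float(np.mean(conc))
    dailies = []
    swings = []
    for i in range(ws.n_sub):
        times = ws.dose_t[i][ws.dose_a[i] > 0]
        amt = ws.dose_a[i][ws.dose_a[i] > 0]
        if len(times) >= 2:
            tau = float(np.median(np.diff(times)))
            if tau > 0:
                dailies.append(amt[0] * 24.0 / tau)
        ci = ws.obs_y[i][ws.mask[i]]
        if len(ci) >= 2 and ci.max() > ci.min():
            swings.append(amt[0] / (ci.max() - ci.min()))
    daily = float(np.median(dailies)) if dailies else 1800.0
    cl0 = float(np.clip(daily / (24.0 * max(cbar, 1e-6)), 0.1, 100.0))
    v0 = float(np.clip(np.median(swings) if swings else 40.0, 5.0, 500.0))
    return PopEstimates(cl0, v0, 0.3, 0.3, 0.0, 0.2)


def fit_poppk(
    dataset: PKDataset,
    init: PopEstimates,
    config: FitConfig | None = None,
    _candidates: list[tuple[str, np.ndarray]] | None = None,
    _beta_init: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the population model (Laplace objective).

    Runs ``config.n_starts`` quasi-Newton optimisations on the unconstrained
    scale (start 1 at ``init``, later starts jittered) and returns the best.
    With fewer than two informative subjects the eta correlation is fixed to
    zero (Omega diagonal) with a warning.
    """
    config = config or FitConfig()
    ws = _Workspace(dataset)
    warn: list[str] = []
    if ws.n_blloq_dropped:
        warn.append(f"dropped {ws.n_blloq_dropped} out-of-assay-range observation(s)")
    if ws.excluded_ids:
        warn.append(f"subjects with no retained observations: {ws.excluded_ids}")
    if ws.n_sub == 0:
        raise ValueError("no informative subjects in dataset")
    fit_corr = ws.n_sub >= 2
    if not fit_corr:
        warn.append("fewer subjects than random effects: Omega fixed to diagonal")

    x0 = _pack(init, fit_corr)
    x_naive = _pack(_naive_init(ws), fit_corr)
    if _candidates:
        betas = _beta_init if _beta_init is not None else np.zeros(len(_candidates))
        x0 = np.concatenate([x0, betas])
        x_naive = np.concatenate([x_naive, betas])
    rng = np.random.default_rng(config.seed)
    bounds = _bounds(len(x0), fit_corr)

    best = None
    start_ofvs: list[float] = []
    converged = False
    message = ""
    for s in range(config.n_starts):
        if s == 0:
            xs = x0
        elif s == 1:
            xs = x_naive  # data-driven start guards against a poor init
        else:
            base = x0 if s % 2 == 0 else x_naive
            xs = base + rng.uniform(-0.7, 0.7, size=len(x0))
        xs = np.clip(xs, [b[0] for b in bounds], [b[1] for b in bounds])
        fun_and_grad = _make_fun_and_grad(ws, fit_corr, config.inner_tol, _candidates)
        res = optimize.minimize(
            fun_and_grad, xs, method="L-BFGS-B", jac=True, bounds=bounds,
            # stopping rules sit above the inner-solve noise floor (~1e-6 in
            # OFV, ~0.1 in the FD gradient); tighter settings polish noise
            options={"maxiter": config.outer_maxiter, "ftol": 2e-9,
                     "gtol": 0.05},
        )
        ok = bool(res.success)
        if not ok and np.all(np.isfinite(res.jac)):
            # line searches can fail at the objective's noise floor (often at
            # an active bound with degenerate data); accept the iterate when
            # the projected gradient says it is a constrained optimum
            pg = res.jac.copy()
            for j, (lo_b, hi_b) in enumerate(bounds):
                if res.x[j] <= lo_b + 1e-9 and pg[j] > 0:
                    pg[j] = 0.0
                if res.x[j] >= hi_b - 1e-9 and pg[j] < 0:
                    pg[j] = 0.0
            ok = bool(np.max(np.abs(pg)) < 0.5)
        start_ofvs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
            converged = ok
            message = str(res.message)
    if not converged:
        warn.append(f"optimizer did not report convergence: {message}")
    n_base = 6 if fit_corr else 5
    est = _unpack(best.x[:n_base], fit_corr)
    effects: dict[tuple[str, str], float] = {}
    if _candidates:
        effects = {
            key: float(b)
            for (_, _, key), b in zip(_candidates, best.x[n_base:])
        }
    return FitResult(
        estimates=est,
        ofv=float(best.fun),
        converged=converged,
        message=message,
        start_ofvs=start_ofvs,
        warnings=warn,
        n_blloq_dropped=ws.n_blloq_dropped,
        covariate_effects=effects,
    )


def _infer_daily_dose(subject: Subject) -> float:
    """Daily dose implied by the subject's (regular) dose schedule."""
    if len(subject.dose_times) < 2:
        raise ValueError(
            f"subject {subject.subject_id}: cannot infer dosing interval from one dose"
        )
    gaps = np.diff(subject.dose_times)
    tau = gaps[0]
    if not np.allclose(gaps, tau, rtol=1e-9, atol=1e-9):
        raise ValueError(f"subject {subject.subject_id}: irregular dose schedule")
    amt = subject.dose_amounts[0]
    if not np.allclose(subject.dose_amounts, amt):
        raise ValueError(f"subject {subject.subject_id}: varying dose amounts")
    return amt * 24.0 / tau


def empirical_bayes(dataset: PKDataset, est: PopEstimates) -> pd.DataFrame:
    """Per-subject MAP (empirical Bayes) parameters and derived summaries.

    Returns a data frame with one row per subject: eta estimates, individual
    clearance and volume, AUC over 24 h at steady state
    (daily dose / CL_i), and half-life. A subject with no retained
    observations sits at the population typical values (eta = 0) with
    ``shrunk_to_prior`` set — complete shrinkage.
    """
    ws = _Workspace(dataset)
    eta_by_id: dict[str, np.ndarray] = {}
    if ws.n_sub > 0:
        prob = _EtaProblem(ws, est)
        eta_hat_act = prob.map_eta(tol=1e-10)
        eta_full = prob._expand(eta_hat_act).real
        eta_by_id = {sid: eta_full[i] for i, sid in enumerate(ws.ids)}
    rows = []
    for s in dataset.subjects:
        eta = eta_by_id.get(s.subject_id, np.zeros(2))
        cl = est.typical_clearance * math.exp(eta[1])
        v = est.typical_volume * math.exp(eta[0])
        rows.append(
            {
                "subject_id": s.subject_id,
                "eta_v": eta[0],
                "eta_cl": eta[1],
                "clearance": cl,
                "volume": v,
                "auc24": _infer_daily_dose(s) / cl,
                "half_life": math.log(2.0) * v / cl,
                "shrunk_to_prior": s.subject_id not in eta_by_id,
            }
        )
    df = pd.DataFrame(rows)
    if df["shrunk_to_prior"].any():
        _warnings.warn(
            "subject(s) without observations received population typical values "
            "(complete shrinkage)", stacklevel=2,
        )
    return df


# ---------------------------------------------------------------------------
# Covariate search
# ---------------------------------------------------------------------------

# chi-square quantiles for 1 df at p = 0.05 and p = 0.01
FORWARD_DOFV = 3.84
BACKWARD_DOFV = 6.63


@dataclass
class CovariateSearchResult:
    selected: list[tuple[str, str]]
    final_fit: FitResult
    ledger: pd.DataFrame
    warnings: list[str]


def covariate_search(
    dataset: PKDataset,
    covariates: pd.DataFrame,
    config: FitConfig | None = None,
    parameters: tuple[str, ...] = ("clearance", "volume"),
) -> CovariateSearchResult:
    """Stepwise forward-inclusion / backward-elimination covariate model build.

    Continuous covariates enter as power models centred on the median,
    ``theta * (cov / median(cov)) ** beta``; binary covariates as
    proportional shifts ``theta * exp(beta * cov)``. Forward inclusion
    requires the objective function to drop by at least 3.84 (1 df,
    p < 0.05); backward elimination removes any covariate whose removal
    raises it by less than 6.63 (1 df, p > 0.01). Every tested delta-OFV is
    recorded in the returned ledger.

    ``covariates`` must be indexed by (or carry a column) ``subject_id``
    with one numeric column per candidate covariate.
    """
    config = config or FitConfig()
    cov = covariates.copy()
    if "subject_id" in cov.columns:
        cov = cov.set_index("subject_id")
    cov.index = cov.index.astype(str)
    ws = _Workspace(dataset)
    warn: list[str] = []

    # candidate -> per-subject log-multiplier column (beta = 1 scale)
    candidates: dict[tuple[str, str], np.ndarray] = {}
    for name in cov.columns:
        vals = cov.loc[ws.ids, name].to_numpy(dtype=float)
        uniq = np.unique(vals)
        if len(uniq) < 2:
            warn.append(f"covariate {name!r} is constant; skipped")
            continue
        if len(uniq) == 2 and set(uniq) <= {0.0, 1.0}:
            logmult = vals  # proportional shift exp(beta * x)
        else:
            med = float(np.median(vals))
            if med <= 0 or np.any(vals <= 0):
                warn.append(f"covariate {name!r} non-positive; skipped")
                continue
            logmult = np.log(vals / med)  # power model (cov/median)^beta
        for p in parameters:
            candidates[(p, name)] = logmult

    def fit_with(included: list[tuple[str, str]], init: PopEstimates,
                 beta_init: np.ndarray | None) -> FitResult:
        cands = [(p, candidates[(p, n)], (p, n)) for (p, n) in included]
        return fit_poppk(
            dataset, init,
            replace_config(config, n_starts=1),
            _candidates=cands or None,
            _beta_init=beta_init,
        )

    def replace_config(c: FitConfig, **kw) -> FitConfig:
        d = {f: getattr(c, f) for f in (
            "n_starts", "inner_tol", "outer_maxiter", "seed", "eta_method",
            "agq_nodes", "bootstrap_n", "vpc_n")}
        d.update(kw)
        return FitConfig(**d)

    base_init = PopEstimates(5.0, 40.0, 0.3, 0.3, 0.0, 0.15)
    base = fit_poppk(dataset, base_init, config)
    current_fit = base
    included: list[tuple[str, str]] = []
    ledger_rows = []
    step = 0

    # forward inclusion
    remaining = list(candidates)
    while remaining:
        step += 1
        trials = []
        for cand in remaining:
            trial = fit_with(included + [cand], current_fit.estimates, None)
            dofv = current_fit.ofv - trial.ofv
            trials.append((dofv, cand, trial))
            ledger_rows.append(
                {"phase": "forward", "step": step, "parameter": cand[0],
                 "covariate": cand[1], "delta_ofv": dofv,
                 "action": "tested"}
            )
        dofv, cand, trial = max(trials, key=lambda t: t[0])
        if dofv >= FORWARD_DOFV:
            included.append(cand)
            remaining.remove(cand)
            current_fit = trial
            ledger_rows.append(
                {"phase": "forward", "step": step, "parameter": cand[0],
                 "covariate": cand[1], "delta_ofv": dofv, "action": "included"}
            )
        else:
            break

    # backward elimination
    while included:
        step += 1
        trials = []
        for cand in included:
            rest = [c for c in included if c != cand]
            trial = fit_with(rest, current_fit.estimates, None)
            incr = trial.ofv - current_fit.ofv
            trials.append((incr, cand, trial))
            ledger_rows.append(
                {"phase": "backward", "step": step, "parameter": cand[0],
                 "covariate": cand[1], "delta_ofv": incr, "action": "tested"}
            )
        incr, cand, trial = min(trials, key=lambda t: t[0])
        if incr < BACKWARD_DOFV:
            included.remove(cand)
            current_fit = trial
            ledger_rows.append(
                {"phase": "backward", "step": step, "parameter": cand[0],
                 "covariate": cand[1], "delta_ofv": incr, "action": "removed"}
            )
        else:
            break

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["phase", "step", "parameter", "covariate", "delta_ofv", "action"],
    )
    return CovariateSearchResult(included, current_fit, ledger, warn)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    intervals: pd.DataFrame  # rows: parameter; cols: estimate, ci_lower, ci_upper
    n_converged: int
    n_failed: int
    replicate_seeds: list[int]
    warnings: list[str]
    replicate_estimates: pd.DataFrame


_PARAM_NAMES = (
    "typical_clearance", "typical_volume", "omega_cl", "omega_v",
    "omega_cov", "sigma_prop",
)


def bootstrap_ci(
    dataset: PKDataset,
    config: FitConfig | None = None,
    point_fit: FitResult | None = None,
    init: PopEstimates | None = None,
    level: float = 0.95,
) -> BootstrapResult:
    """Nonparametric bootstrap percentile confidence intervals.

    Subjects are resampled with replacement (same count per replicate); each
    replicate is refitted starting from the original point estimate.
    Non-converged replicates are counted and excluded from the percentiles;
    more than 20% failures attaches a warning. The per-replicate resampling
    seeds are returned for reproducibility.
    """
    config = config or FitConfig()
    init = init or PopEstimates(5.0, 40.0, 0.3, 0.3, 0.0, 0.15)
    if point_fit is None:
        point_fit = fit_poppk(dataset, init, config)
    rng = np.random.default_rng(config.seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=config.bootstrap_n)]
    fast = FitConfig(
        n_starts=1, inner_tol=config.inner_tol, outer_maxiter=config.outer_maxiter,
        seed=config.seed, eta_method=config.eta_method, agq_nodes=config.agq_nodes,
        bootstrap_n=config.bootstrap_n, vpc_n=config.vpc_n,
    )
    rows = []
    n_failed = 0
    n = dataset.n_subjects
    for b, seed in enumerate(seeds):
        r = np.random.default_rng(seed)
        idx = r.integers(0, n, size=n)
        subs = []
        for j, i in enumerate(idx):
            s = dataset.subjects[i]
            subs.append(
                Subject(f"bs{b}_{j}", s.dose_times, s.dose_amounts,
                        s.dose_durations, s.obs_times, s.obs_conc, s.blloq)
            )
        try:
            fr = fit_poppk(
                PKDataset(tuple(subs), dataset.assay_limits),
                point_fit.estimates, fast,
            )
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not fr.converged:
            n_failed += 1
            continue
        e = fr.estimates
        rows.append([getattr(e, p) for p in _PARAM_NAMES])
    warn = list(point_fit.warnings)
    if n_failed > 0.2 * config.bootstrap_n:
        warn.append(
            f"{n_failed}/{config.bootstrap_n} bootstrap replicates failed to converge"
        )
    reps = pd.DataFrame(rows, columns=list(_PARAM_NAMES))
    alpha = (1.0 - level) / 2.0
    est_vals = [getattr(point_fit.estimates, p) for p in _PARAM_NAMES]
    if len(reps):
        lo = reps.quantile(alpha)
        hi = reps.quantile(1.0 - alpha)
        med = reps.quantile(0.5)
    else:
        lo = hi = med = pd.Series([np.nan] * len(_PARAM_NAMES), index=list(_PARAM_NAMES))
    intervals = pd.DataFrame(
        {
            "estimate": est_vals,
            "boot_median": med.to_numpy(),
            "ci_lower": lo.to_numpy(),
            "ci_upper": hi.to_numpy(),
        },
        index=list(_PARAM_NAMES),
    )
    return BootstrapResult(intervals, len(reps), n_failed, seeds, warn, reps)


# ---------------------------------------------------------------------------
# Visual predictive check
# ---------------------------------------------------------------------------

def simulate_observations(
    dataset: PKDataset, est: PopEstimates, rng: np.random.Generator
) -> list[np.ndarray]:
    """Simulate one replicate of every subject's observations from ``est``.

    Reuses each subject's dose schedule and sampling times; draws fresh
    (eta_V, eta_CL) from Omega and proportional residual error (truncated
    at -0.999 on the relative scale so concentrations stay positive).
    Returns one concentration array per subject, aligned with
    ``subject.obs_times``.
    """
    om = est.omega_matrix()
    # allow degenerate (zero) variances
    ev, U = np.linalg.eigh(om)
    if np.any(ev < -1e-12):
        raise ValueError("Omega must be positive semi-definite")
    L = U @ np.diag(np.sqrt(np.clip(ev, 0.0, None)))
    out = []
    for s in dataset.subjects:
        eta = L @ rng.standard_normal(2)
        cl = est.typical_clearance * math.exp(eta[1])
        v = est.typical_volume * math.exp(eta[0])
        sdt = s.obs_times[:, None] - s.dose_times[None, :]
        f = _single_dose_conc(
            cl, v, s.dose_amounts[None, :], s.dose_durations[None, :], sdt
        ).sum(axis=1)
        eps = np.maximum(rng.normal(0.0, est.sigma_prop, size=len(f)), -0.999)
        out.append(f * (1.0 + eps))
    return out


@dataclass
class VPCResult:
    bands: pd.DataFrame
    n_replicates: int
    suppressed_times: list[float]
    notes: list[str]


def vpc_bands(
    dataset: PKDataset,
    est: PopEstimates,
    config: FitConfig | None = None,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
) -> VPCResult:
    """Visual-predictive-check statistics: observed percentiles per nominal
    timepoint with 95% simulation intervals around each.

    Simulation replicates reuse every subject's dose schedule and sampling
    design and include residual error. Timepoints with fewer than three
    observations are suppressed (recorded in ``suppressed_times``).
    """
    config = config or FitConfig()
    times_all = np.concatenate([s.obs_times for s in dataset.subjects])
    conc_all = np.concatenate([s.obs_conc for s in dataset.subjects])
    keep = ~np.concatenate([s.blloq for s in dataset.subjects])
    times_all, conc_all = times_all[keep], conc_all[keep]
    key = np.round(times_all, 6)
    uniq = np.unique(key)
    suppressed = [float(t) for t in uniq if np.sum(key == t) < 3]
    use_t = [float(t) for t in uniq if np.sum(key == t) >= 3]

    rng = np.random.default_rng(config.seed)
    sim_pct = np.empty((config.vpc_n, len(use_t), 3))
    for r in range(config.vpc_n):
        sim = simulate_observations(dataset, est, rng)
        sim_all = np.concatenate(sim)[keep]
        for j, t in enumerate(use_t):
            sel = key == t
            sim_pct[r, j] = np.percentile(sim_all[sel], percentiles)
    rows = []
    for j, t in enumerate(use_t):
        sel = key == t
        obs_p = np.percentile(conc_all[sel], percentiles)
        row = {"time": t, "n_obs": int(sel.sum())}
        for i, p in enumerate(percentiles):
            tag = f"p{int(p)}"
            row[f"obs_{tag}"] = obs_p[i]
            row[f"sim_{tag}_lo"] = np.percentile(sim_pct[:, j, i], 2.5)
            row[f"sim_{tag}_median"] = np.percentile(sim_pct[:, j, i], 50.0)
            row[f"sim_{tag}_hi"] = np.percentile(sim_pct[:, j, i], 97.5)
        rows.append(row)
    notes = []
    if suppressed:
        notes.append(
            f"suppressed {len(suppressed)} timepoint(s) with <3 observations"
        )
    return VPCResult(pd.DataFrame(rows), config.vpc_n, suppressed, notes)
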