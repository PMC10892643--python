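"""Mixed-effects estimation: likelihood oracles, recovery, EBE, bootstrap, VPC."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import linezopk as lz
from linezopk import nlme
from linezopk.nlme import FitConfig, PKDataset, PopEstimates, Subject

Q8_DOSE_TIMES = np.arange(7) * 8.0
Q8_OBS_TIMES = 48.0 + np.array([0.0, 0.5, 1.0, 2.0, 4.0, 6.0])


WIDE_LIMITS = (0.01, 1000.0)  # keeps toy datasets free of assay flagging


def make_subject(sid, cl, v, obs_times=None, noise=None, n_doses=7,
                 limits=WIDE_LIMITS):
    """A subject whose concentrations are exact model values (optionally
    perturbed), built through the public structural API."""
    dose_times = np.arange(n_doses) * 8.0
    obs_times = Q8_OBS_TIMES if obs_times is None else np.asarray(obs_times)
    params = lz.PKParams(cl, v)
    single = lz.DosingRegimen(600, 0.5, 8, n_doses=1)
    f = np.array(
        [
            sum(
                lz.concentration(params, single, t - dt) if t >= dt else 0.0
                for dt in dose_times
            )
            for t in obs_times
        ]
    )
    y = f if noise is None else f * (1.0 + np.asarray(noise))
    flags = (y < limits[0]) | (y > limits[1])
    return Subject(
        sid, dose_times, np.full(n_doses, 600.0), np.full(n_doses, 0.5),
        obs_times, y, flags,
    )


def pooled_neg2ll(dataset, est):
    """Closed-form -2 log-likelihood at typical values (no random effects)."""
    total = 0.0
    params = lz.PKParams(est.typical_clearance, est.typical_volume)
    single = lz.DosingRegimen(600, 0.5, 8, n_doses=1)
    for s in dataset.subjects:
        for t, y in zip(s.obs_times, s.obs_conc):
            f = sum(
                lz.concentration(params, single, t - dt) if t >= dt else 0.0
                for dt in s.dose_times
            )
            var = (est.sigma_prop * f) ** 2
            total += math.log(2 * math.pi * var) + (y - f) ** 2 / var
    return total


def agq_oracle_ofv(dataset, est, n_nodes=40):
    """Independent adaptive Gauss-Hermite oracle for the marginal OFV.

    Per subject: find the joint-density mode with Nelder-Mead, take a
    numeric Hessian, and integrate exp(log p(y|eta) + log prior) on the
    mode-centred scaled Gauss-Hermite grid.
    """
    om = est.omega_matrix()
    om_inv = np.linalg.inv(om)
    _, om_logdet = np.linalg.slogdet(om)
    single = lz.DosingRegimen(600, 0.5, 8, n_doses=1)

    def neg_log_joint(eta, s):
        cl = est.typical_clearance * math.exp(eta[1])
        v = est.typical_volume * math.exp(eta[0])
        params = lz.PKParams(cl, v)
        out = 0.5 * (eta @ om_inv @ eta) + math.log(2 * math.pi) + 0.5 * om_logdet
        for t, y in zip(s.obs_times, s.obs_conc):
            f = sum(
                lz.concentration(params, single, t - dt) if t >= dt else 0.0
                for dt in s.dose_times
            )
            var = (est.sigma_prop * f) ** 2
            out += 0.5 * (math.log(2 * math.pi * var) + (y - f) ** 2 / var)
        return out

    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    ofv = 0.0
    for s in dataset.subjects:
        res = optimize.minimize(
            neg_log_joint, np.zeros(2), args=(s,), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        mode = res.x
        h = 1e-4
        H = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                ei, ej = np.eye(2)[i] * h, np.eye(2)[j] * h
                H[i, j] = (
                    neg_log_joint(mode + ei + ej, s)
                    - neg_log_joint(mode + ei - ej, s)
                    - neg_log_joint(mode - ei + ej, s)
                    + neg_log_joint(mode - ei - ej, s)
                ) / (4 * h * h)
        L = np.linalg.cholesky(np.linalg.inv(H))
        logsum_terms = []
        for zi, wi in zip(z, w):
            for zj, wj in zip(z, w):
                zz = np.array([zi, zj])
                eta = mode + math.sqrt(2.0) * L @ zz
                logsum_terms.append(
                    -neg_log_joint(eta, s) + zz @ zz + math.log(wi * wj)
                )
        m = max(logsum_terms)
        logI = m + math.log(sum(math.exp(t - m) for t in logsum_terms))
        logI += math.log(2.0) + math.log(np.linalg.det(L))
        ofv += -2.0 * logI
    return ofv


TOY_ESTIMATES = PopEstimates(5.9, 41.1, 0.25, 0.3, -0.02, 0.08)


def toy_two_subject_dataset(seed=11):
    """Two subjects, three observations each, drawn from the model itself
    (eta from the prior, proportional noise at the model sigma)."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(TOY_ESTIMATES.omega_matrix())
    subs = []
    for sid, times in (("A", [48.0, 49.0, 52.0]), ("B", [48.0, 50.0, 54.0])):
        eta = L @ rng.standard_normal(2)
        cl = 5.9 * math.exp(eta[1])
        v = 41.1 * math.exp(eta[0])
        subs.append(
            make_subject(sid, cl, v, obs_times=times,
                         noise=rng.normal(0, TOY_ESTIMATES.sigma_prop, 3))
        )
    return PKDataset(tuple(subs), assay_limits=WIDE_LIMITS)


@pytest.fixture(scope="module")
def toy_dataset():
    return toy_two_subject_dataset()


@pytest.fixture(scope="module")
def toy_estimates():
    return TOY_ESTIMATES


class TestMarginalOFV:
    def test_degenerate_omega_equals_pooled_closed_form(self, default_cohort):
        est = PopEstimates(5.9, 41.1, 0.0, 0.0, 0.0, 0.3)
        assert lz.marginal_ofv(default_cohort, est) == pytest.approx(
            pooled_neg2ll(default_cohort, est), rel=1e-9
        )

    def test_laplace_close_to_quadrature_oracle(self, toy_dataset, toy_estimates):
        laplace = lz.marginal_ofv(toy_dataset, toy_estimates)
        oracle = agq_oracle_ofv(toy_dataset, toy_estimates)
        assert laplace == pytest.approx(oracle, abs=0.05)

    def test_builtin_agq_matches_oracle(self, toy_dataset, toy_estimates):
        agq = lz.marginal_ofv(
            toy_dataset, toy_estimates, method="adaptive-quadrature",
            agq_nodes=32,
        )
        assert agq == pytest.approx(agq_oracle_ofv(toy_dataset, toy_estimates),
                                    abs=0.01)

    def test_additive_over_subjects(self, default_cohort, published):
        s0 = default_cohort.subjects[0]
        dup = Subject("dup", s0.dose_times, s0.dose_amounts, s0.dose_durations,
                      s0.obs_times, s0.obs_conc, s0.blloq)
        with_dup = PKDataset(default_cohort.subjects + (dup,),
                             default_cohort.assay_limits)
        only_dup = PKDataset((dup,), default_cohort.assay_limits)
        assert lz.marginal_ofv(with_dup, published) == pytest.approx(
            lz.marginal_ofv(default_cohort, published)
            + lz.marginal_ofv(only_dup, published),
            abs=1e-6,
        )

    def test_invariant_under_subject_reordering(self, default_cohort, published):
        rev = PKDataset(tuple(reversed(default_cohort.subjects)),
                        default_cohort.assay_limits)
        assert lz.marginal_ofv(rev, published) == pytest.approx(
            lz.marginal_ofv(default_cohort, published), abs=1e-6
        )

    def test_non_psd_omega_rejected(self, default_cohort):
        raw = lz.table3_estimates()  # printed covariance: |corr| > 1
        with pytest.raises(ValueError):
            lz.marginal_ofv(default_cohort, raw)


class TestFit:
    def test_fit_improves_on_init_and_truth(self, default_cohort, published,
                                            init_estimates, fast_fit):
        fr = lz.fit_poppk(default_cohort, init_estimates, fast_fit)
        assert fr.ofv <= lz.marginal_ofv(default_cohort, published) + 1e-6
        assert fr.ofv <= lz.marginal_ofv(default_cohort, init_estimates) + 1e-6

    def test_multistart_consistency_from_distant_init(self, default_cohort,
                                                      init_estimates):
        near = lz.fit_poppk(default_cohort, init_estimates, FitConfig(n_starts=1))
        far_init = PopEstimates(50.0, 400.0, 0.3, 0.3, 0.0, 0.15)
        far = lz.fit_poppk(default_cohort, far_init, FitConfig(n_starts=2, seed=0))
        assert far.ofv == pytest.approx(near.ofv, abs=0.01)

    def test_single_subject_fixes_omega_diagonal(self, init_estimates):
        rng = np.random.default_rng(3)
        s = make_subject("solo", 6.0, 40.0, noise=rng.normal(0, 0.1, 6))
        fr = lz.fit_poppk(PKDataset((s,), assay_limits=WIDE_LIMITS), init_estimates, FitConfig(n_starts=1))
        assert fr.estimates.omega_cov == 0.0
        assert any("diagonal" in w for w in fr.warnings)


class TestEmpiricalBayes:
    def test_zero_observation_subject_at_typical_values(self, published):
        rng = np.random.default_rng(5)
        s1 = make_subject("obs", 6.5, 45.0, noise=rng.normal(0, 0.1, 6))
        blank = Subject(
            "blank", Q8_DOSE_TIMES, np.full(7, 600.0), np.full(7, 0.5),
            np.array([48.5]), np.array([0.5]), np.array([True]),  # all BLLOQ
        )
        ds = PKDataset((s1, blank))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ebe = lz.empirical_bayes(ds, published)
        row = ebe.set_index("subject_id").loc["blank"]
        assert row["clearance"] == published.typical_clearance
        assert row["volume"] == published.typical_volume
        assert bool(row["shrunk_to_prior"])

    def test_auc24_is_daily_dose_over_individual_clearance(self, default_cohort,
                                                           published):
        ebe = lz.empirical_bayes(default_cohort, published)
        assert np.allclose(ebe["auc24"], 1800.0 / ebe["clearance"], rtol=1e-12)
        assert np.allclose(
            ebe["half_life"], math.log(2) * ebe["volume"] / ebe["clearance"],
            rtol=1e-12,
        )

    def test_data_influence_shrinks_as_sigma_grows(self, published):
        """Growing residual noise shrinks the influence of the observed
        concentrations on the EBEs. (Under proportional error the influence
        does not vanish entirely: the log f(eta) variance term keeps the
        mode data-coupled at any sigma, so complete eta -> 0 shrinkage is a
        property of additive-error models only.)"""
        import dataclasses

        design = lz.default_design()
        a = lz.generate_cohort(design, lz.TruthSpec(estimates=published, seed=1))
        b = lz.generate_cohort(design, lz.TruthSpec(estimates=published, seed=2))

        def influence(sigma):
            noisy = dataclasses.replace(published, sigma_prop=sigma)
            ea = lz.empirical_bayes(a, noisy)[["eta_v", "eta_cl"]].to_numpy()
            eb = lz.empirical_bayes(b, noisy)[["eta_v", "eta_cl"]].to_numpy()
            return float(np.max(np.abs(ea - eb)))

        diffs = [influence(s) for s in (0.114, 0.5, 2.0, 10.0)]
        assert all(d1 > d2 for d1, d2 in zip(diffs, diffs[1:]))
        assert diffs[-1] < diffs[0] / 2


class TestCovariateSearch:
    @staticmethod
    def cohort_with_covariate(n, exponent, seed, truth):
        rng = np.random.default_rng(seed)
        wt = rng.lognormal(math.log(75), 0.3, n)
        med = float(np.median(wt))
        om = truth.omega_matrix()
        ev, U = np.linalg.eigh(om)
        L = U @ np.diag(np.sqrt(np.clip(ev, 0, None)))
        eta = rng.standard_normal((n, 2)) @ L.T
        subs = []
        for i in range(n):
            cl = 5.9 * (wt[i] / med) ** exponent * math.exp(eta[i, 1])
            v = 41.1 * math.exp(eta[i, 0])
            noise = np.maximum(rng.normal(0, truth.sigma_prop, 6), -0.999)
            subs.append(make_subject(f"S{i}", cl, v, noise=noise))
        cov = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(n)], "weight": wt,
             "flat": np.ones(n)}
        )
        return PKDataset(tuple(subs), assay_limits=WIDE_LIMITS), cov

    def test_strong_effect_retained_null_rejected(self, published):
        ds, cov = self.cohort_with_covariate(40, 0.75, 42, published)
        cov["noise_cov"] = np.random.default_rng(1).uniform(50, 100, len(cov))
        res = nlme.covariate_search(
            ds, cov, FitConfig(n_starts=1), parameters=("clearance",)
        )
        assert ("clearance", "weight") in res.selected
        assert ("clearance", "noise_cov") not in res.selected
        assert any("flat" in w for w in res.warnings)  # constant -> skipped
        beta = res.final_fit.covariate_effects[("clearance", "weight")]
        assert beta == pytest.approx(0.75, abs=0.35)
        tested = res.ledger[res.ledger.action == "tested"]
        assert len(tested) >= 2  # every candidate's delta-OFV is recorded

    def test_small_improvement_not_retained(self, published):
        """A covariate buying less than 3.84 OFV units stays out."""
        ds, cov = self.cohort_with_covariate(20, 0.0, 9, published)
        res = nlme.covariate_search(
            ds, cov[["subject_id", "weight"]], FitConfig(n_starts=1),
            parameters=("clearance",),
        )
        dofv = res.ledger.query("action == 'tested'")["delta_ofv"].max()
        if dofv < nlme.FORWARD_DOFV:
            assert res.selected == []


class TestBootstrap:
    def test_single_replicate_collapses_interval(self, default_cohort,
                                                 init_estimates):
        fr = lz.fit_poppk(default_cohort, init_estimates, FitConfig(n_starts=1))
        br = nlme.bootstrap_ci(
            default_cohort, FitConfig(n_starts=1, seed=1, bootstrap_n=1),
            point_fit=fr,
        )
        iv = br.intervals
        assert np.allclose(iv["ci_lower"], iv["ci_upper"])
        assert np.allclose(iv["ci_lower"], iv["boot_median"])
        assert len(br.replicate_seeds) == 1

    def test_identical_subjects_zero_width(self, init_estimates):
        """Five byte-identical subjects leave no sampling variability, so
        every resample is the same dataset and the percentile intervals
        collapse onto the point estimate. (A fixed small residual
        perturbation keeps sigma off its boundary, where the likelihood
        becomes degenerately sharp; the invariance under resampling is the
        property of interest.)"""
        rng = np.random.default_rng(4)
        base = make_subject("c0", 6.0, 42.0, noise=rng.normal(0, 0.08, 6))
        clones = tuple(
            Subject(f"c{i}", base.dose_times, base.dose_amounts,
                    base.dose_durations, base.obs_times, base.obs_conc,
                    base.blloq)
            for i in range(5)
        )
        ds = PKDataset(clones, assay_limits=WIDE_LIMITS)
        fr = lz.fit_poppk(ds, init_estimates, FitConfig(n_starts=1))
        br = nlme.bootstrap_ci(
            ds, FitConfig(n_starts=1, seed=2, bootstrap_n=6), point_fit=fr
        )
        width = br.intervals["ci_upper"] - br.intervals["ci_lower"]
        scale = br.intervals["estimate"].abs().clip(lower=1e-6)
        assert np.all(width / scale < 1e-3)


class TestVPC:
    def test_deterministic_limit_collapses_bands(self):
        det = PopEstimates(5.9, 41.1, 0.0, 0.0, 0.0, 0.0)
        design = lz.default_design()
        ds = lz.generate_cohort(design, lz.TruthSpec(estimates=det, seed=1))
        vr = nlme.vpc_bands(ds, det, FitConfig(n_starts=1, seed=2, vpc_n=20))
        for tag in ("p5", "p50", "p95"):
            assert np.allclose(vr.bands[f"obs_{tag}"], vr.bands["obs_p50"])
            assert np.allclose(
                vr.bands[f"sim_{tag}_lo"], vr.bands[f"sim_{tag}_hi"], rtol=1e-12
            )
            assert np.allclose(
                vr.bands[f"sim_{tag}_median"], vr.bands[f"obs_{tag}"], rtol=1e-12
            )

    def test_thousand_replicates_accepted_and_recorded(self, default_cohort,
                                                       published):
        vr = nlme.vpc_bands(default_cohort, published,
                            FitConfig(n_starts=1, seed=3, vpc_n=1000))
        assert vr.n_replicates == 1000
        assert len(vr.bands) == 6  # the six nominal sampling offsets

    def test_sparse_timepoints_suppressed(self, published):
        rng = np.random.default_rng(8)
        subs = [make_subject(f"S{i}", 6.0, 42.0, noise=rng.normal(0, 0.1, 6))
                for i in range(3)]
        lone = make_subject("L", 6.0, 42.0, obs_times=[48.0, 49.7],
                            noise=rng.normal(0, 0.1, 2))
        ds = PKDataset(tuple(subs) + (lone,), assay_limits=WIDE_LIMITS)
        vr = nlme.vpc_bands(ds, published, FitConfig(n_starts=1, seed=4, vpc_n=20))
        assert 49.7 in vr.suppressed_times
        assert 49.7 not in vr.bands["time"].tolist()
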