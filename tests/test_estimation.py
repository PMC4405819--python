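"""FOCE-I objective, empirical-Bayes estimation and fitting tests."""
import math
from dataclasses import replace

import numpy as np
import pytest
from sklearn.base import clone

from efavpk.cohort import recovery_config, simulate_cohort
from efavpk.data import Dataset, Observation
from efavpk.estimation import (FoceNlme, ModelSpec, covariate_df, ebe, fit,
                               ofv_focei, rse)
from efavpk.pk import FixedEffects, RandomEffects, StructuralParams, conc_ss
from oracles import aghq_neg2ll, foce_constants, grid_ebe


def _flat_fe(cl, **kw):
    return FixedEffects(cl_18={"TT": cl, "TC": cl, "CC": cl},
                        frac_6={"GT": 0.0}, wt_center=58.0, **kw)


class TestEbe:
    def test_tiny_omega_shrinks_to_zero(self, make_subject):
        s = make_subject()
        obs = [Observation("S1", 13.5, 9.0)]
        re = RandomEffects(omega2=1e-8, sigma2_prop=0.12)
        e_hat, curv = ebe(s, obs, _flat_fe(7.01), re)
        assert abs(e_hat) < 1e-3
        assert curv > 0

    def test_exact_observation_eta_vanishes_with_shrinkage(self, make_subject):
        """An observation equal to the population prediction leaves no
        residual pull on eta; the remaining displacement of the conditional
        mode comes only from the interaction variance term and scales with
        omega^2."""
        s = make_subject()
        pop = conc_ss(13.5, 600.0, 24.0, StructuralParams(cl=7.01))
        obs = [Observation("S1", 13.5, pop)]
        e_big, _ = ebe(s, obs, _flat_fe(7.01),
                       RandomEffects(omega2=0.4, sigma2_prop=0.12))
        e_small, _ = ebe(s, obs, _flat_fe(7.01),
                         RandomEffects(omega2=0.004, sigma2_prop=0.12))
        assert abs(e_small) < 5e-3
        assert abs(e_small) < abs(e_big) / 20  # ~linear in omega^2

    @pytest.mark.parametrize("conc", [0.8, 2.0, 9.0])
    def test_matches_grid_search(self, make_subject, conc):
        """Mode from the package matches a dense grid over eta in [-5, 5]."""
        s = make_subject()
        obs = [Observation("S1", 13.5, conc)]
        fe = _flat_fe(7.01)
        re = RandomEffects(omega2=0.494, sigma2_prop=0.12)
        e_hat, _ = ebe(s, obs, fe, re)
        assert e_hat == pytest.approx(grid_ebe(s, obs, fe, re), abs=1e-4)

    def test_requires_positive_omega(self, make_subject):
        with pytest.raises(ValueError):
            ebe(make_subject(), [Observation("S1", 13.5, 2.0)], _flat_fe(7.0),
                RandomEffects(omega2=0.0, sigma2_prop=0.12))


class TestOfvFocei:
    def test_additive_over_independent_subjects(self, toy_dataset, ref_fe, ref_re):
        spec = ModelSpec(covariates=("cyp2b6_6", "sex"), wt_center=58.0)
        base = ofv_focei(toy_dataset, spec, ref_fe, ref_re)
        doubled = Dataset(
            subjects={**toy_dataset.subjects,
                      **{sid + "x": replace(s, id=sid + "x")
                         for sid, s in toy_dataset.subjects.items()}},
            observations=toy_dataset.observations + [
                replace(o, subject_id=o.subject_id + "x")
                for o in toy_dataset.observations])
        assert ofv_focei(doubled, spec, ref_fe, ref_re) == pytest.approx(
            2 * base, rel=1e-9)

    @pytest.mark.parametrize("jitter", [0.0, 0.25, -0.3])
    def test_agrees_with_gauss_hermite(self, ref_fe, ref_re, recovery_cohort,
                                       jitter):
        """FOCE-I OFV is within 1% of 64-point adaptive Gauss-Hermite
        quadrature on small instances, across a jittered parameter grid."""
        sids = list(recovery_cohort.subjects)[:8]
        subjects = {sid: recovery_cohort.subjects[sid] for sid in sids}
        obs = [o for o in recovery_cohort.observations if o.subject_id in subjects]
        ds = Dataset(subjects=subjects, observations=obs)
        fe = replace(ref_fe,
                     cl_18={k: v * math.exp(jitter) for k, v in ref_fe.cl_18.items()})
        re = RandomEffects(omega2=ref_re.omega2 * math.exp(jitter),
                           sigma2_prop=ref_re.sigma2_prop)
        spec = ModelSpec(wt_center=58.0)
        pkg = ofv_focei(ds, spec, fe, re) + foce_constants(
            [(subjects[sid], [o for o in obs if o.subject_id == sid])
             for sid in sids])
        ref = aghq_neg2ll(
            [(subjects[sid], [o for o in obs if o.subject_id == sid])
             for sid in sids], fe, re)
        assert pkg == pytest.approx(ref, rel=0.01)

    def test_truth_near_minimum_on_large_sample(self, ref_fe, ref_re):
        """Perturbing a parameter away from the generating value increases
        the objective on a large synthetic dataset."""
        ds = simulate_cohort(recovery_config(400), ref_fe, ref_re, seed=9)
        spec = ModelSpec(wt_center=58.0)
        at_truth = ofv_focei(ds, spec, ref_fe, ref_re)
        for factor in (0.7, 1.4):
            fe_p = replace(ref_fe, cl_18={k: v * factor
                                          for k, v in ref_fe.cl_18.items()})
            assert ofv_focei(ds, spec, fe_p, ref_re) > at_truth


class TestFit:
    def test_noiseless_identifiable(self, ref_fe, make_subject):
        """With near-zero noise the clearance parameters are recovered to
        optimizer tolerance."""
        subs, obs = {}, []
        rng = np.random.default_rng(0)
        for i in range(30):
            s = make_subject(id=f"S{i}", weight=float(rng.uniform(45, 75)),
                             sex="female" if i % 2 else "male",
                             g_cyp2b6_18=["TT", "TC"][i % 2],
                             g_cyp2b6_6=["GG", "GT", "TT"][i % 3])
            subs[s.id] = s
            from efavpk.pk import predict
            for t in (2.0, 13.5, 24.0):
                obs.append(Observation(s.id, t, predict(s, t, ref_fe)))
        ds = Dataset(subjects=subs, observations=obs)
        spec = ModelSpec(covariates=("cyp2b6_18", "cyp2b6_6", "weight", "sex"),
                         wt_center=58.0)
        res = fit(ds, spec, compute_rse=False)
        assert res.fe.cl_18["TT"] == pytest.approx(7.01, rel=1e-3)
        assert res.fe.frac_6["TT"] == pytest.approx(-0.634, abs=5e-3)
        assert res.re.sigma2_prop < 1e-4

    def test_ofv_not_worse_than_init(self, recovery_cohort, ref_fe, ref_re):
        spec = ModelSpec(wt_center=58.0)
        res = fit(recovery_cohort, spec, init=(ref_fe, ref_re),
                  compute_rse=False)
        assert res.ofv <= ofv_focei(recovery_cohort, spec, ref_fe, ref_re) + 1e-6
        assert res.converged
        assert len(res.ebes) == recovery_cohort.n_subjects

    def test_refit_on_self_simulated_data(self, recovery_cohort, ref_re):
        """Refitting data simulated from a fit's own parameters lands within
        sampling noise of the generating optimum: the refit OFV is no worse
        than the OFV at the generating values, and the gap is of the order
        of the parameter count, not larger."""
        spec = ModelSpec(wt_center=58.0)
        first = fit(recovery_cohort, spec, compute_rse=False)
        ds2 = simulate_cohort(recovery_config(120), first.fe, first.re, seed=5)
        second = fit(ds2, spec, compute_rse=False)
        at_generating = ofv_focei(ds2, spec, first.fe, first.re)
        assert second.ofv <= at_generating + 1e-6
        assert at_generating - second.ofv < 40.0


class TestRse:
    def test_scales_with_sample_size(self, ref_fe, ref_re):
        """RSE shrinks by about 1/sqrt(2) when the dataset doubles."""
        spec = ModelSpec(covariates=("cyp2b6_18",), wt_center=58.0)
        rses = []
        for n, seed in ((80, 11), (160, 11)):
            ds = simulate_cohort(recovery_config(n), ref_fe, ref_re, seed=seed)
            res = fit(ds, spec, compute_rse=True)
            rses.append(res.rse["CL_TT"])
        ratio = rses[1] / rses[0]
        assert 0.4 < ratio < 1.0

    def test_same_order_as_reported_precision(self, ref_fe, ref_re):
        """Recovery-design RSE for the TT base clearance lands in the same
        order of magnitude as the ~10% reported for the cohort."""
        ds = simulate_cohort(recovery_config(200), ref_fe, ref_re, seed=21)
        res = fit(ds, ModelSpec(wt_center=58.0), compute_rse=True)
        assert 2.0 < res.rse["CL_TT"] < 40.0

    def test_flat_direction_flagged_not_crash(self, ref_fe, ref_re):
        """A covariate with zero observed variation leaves its parameter at
        a flat direction; RSE is flagged unavailable, not a crash."""
        cfg = recovery_config(40)
        ds = simulate_cohort(cfg, ref_fe, ref_re, seed=4)
        for s in ds.subjects.values():
            s.age = 38.0  # constant age -> frac_age unidentified
        spec = ModelSpec(covariates=("cyp2b6_18", "age"), wt_center=58.0)
        res = fit(ds, spec, compute_rse=True)
        assert res.hessian_pd is False or math.isnan(res.rse["FRAC_AGE_PER_YR"])

    def test_requires_converged_fit(self, recovery_cohort):
        from efavpk.estimation import EstimationError, FitResult
        res = fit(recovery_cohort, ModelSpec(wt_center=58.0), compute_rse=False)
        bad = replace(res, converged=False)
        with pytest.raises(EstimationError):
            rse(bad, recovery_cohort)


class TestFoceNlmeEstimator:
    def test_sklearn_protocol(self):
        est = FoceNlme(covariates=("cyp2b6_18",), compute_rse=False)
        params = est.get_params()
        assert params["covariates"] == ("cyp2b6_18",)
        est2 = clone(est).set_params(max_iter=50)
        assert est2.max_iter == 50

    def test_fit_predict_on_frame(self, recovery_cohort):
        df = recovery_cohort.to_frame()
        y = df.pop("DV").to_numpy()
        est = FoceNlme(compute_rse=False, wt_center=58.0).fit(df, y)
        assert est.converged_
        pred = est.predict(recovery_cohort)
        ipred = est.predict(recovery_cohort, individual=True)
        assert pred.shape == (recovery_cohort.n_observations,)
        # individual predictions track the data more closely than population
        obs = np.array([o.conc for o in recovery_cohort.observations])
        assert np.mean(np.abs(np.log(ipred) - np.log(obs))) < \
            np.mean(np.abs(np.log(pred) - np.log(obs)))


def test_allometric_weight_variant(ref_fe, ref_re, recovery_cohort):
    """The optional power-law weight model fits and reports an exponent;
    the default linear parameterisation is unchanged."""
    spec = ModelSpec(covariates=("cyp2b6_18", "weight"), wt_center=58.0,
                     weight_model="allometric")
    res = fit(recovery_cohort, spec, compute_rse=False)
    assert "WT_ALLOMETRIC_EXP" in res.estimates
    assert res.fe.wt_allometric_exp is not None
    # a positive exponent: heavier subjects clear faster in these data
    assert res.fe.wt_allometric_exp > 0
    with pytest.raises(ValueError):
        ModelSpec(weight_model="quadratic")


def test_covariate_df_counts_observed_levels():
    from efavpk.data import Observation, Subject
    subs = {f"S{i}": Subject(id=f"S{i}", sex="male", weight=60.0,
                             g_cyp2a6_9=["GG", "TT"][i % 2])
            for i in range(4)}
    ds = Dataset(subjects=subs,
                 observations=[Observation(f"S{i}", 13.5, 2.0) for i in range(4)])
    assert covariate_df(ds, "cyp2a6_9") == 1  # only GG/TT observed
    assert covariate_df(ds, "weight") == 1
    assert covariate_df(ds, "cyp2b6_18") == 0  # constant
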