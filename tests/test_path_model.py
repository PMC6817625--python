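import inspect

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from voxpath.path_model import (
    PathModelSpec,
    build_path_spec,
    fit_path_model,
    implied_covariance,
    invariance_test,
    jackknife_stability,
    ml_chisquare,
    permutation_pvalues,
)


def _chain_spec():
    return PathModelSpec(
        variables=("x", "m", "y"),
        roles={"x": "exogenous", "m": "mediator", "y": "outcome"},
        regressions=(("x", "m"), ("m", "y")),
        covariances=(),
    )


def _simulate(spec, params, n, rng):
    """Draw from the model-implied covariance (independent data route)."""
    sigma = implied_covariance(params, spec)
    X = rng.multivariate_normal(np.zeros(len(spec.variables)), sigma, size=n)
    return pd.DataFrame(X, columns=list(spec.variables))


class TestBuildPathSpec:
    def test_default_counts(self, default_spec):
        assert len(default_spec.regressions) == 38
        assert len(default_spec.covariances) == 6

    def test_variable_roles(self, default_spec):
        roles = default_spec.roles
        assert sum(r == "exogenous" for r in roles.values()) == 4
        assert sum(r == "mediator" for r in roles.values()) == 4
        assert sum(r == "outcome" for r in roles.values()) == 2
        assert sum(r == "final" for r in roles.values()) == 1

    def test_vtl_basis_swaps_mediators(self):
        spec = build_path_spec("vtl")
        assert "speech_vtl_cm" in spec.variables
        assert "speech_f0_st" not in spec.variables
        assert len(spec.regressions) == 38

    def test_acyclic_by_construction(self, default_spec):
        # constructing the spec runs the cycle check; a cyclic graph raises
        with pytest.raises(ValueError, match="acyclic"):
            PathModelSpec(
                variables=("a", "b"),
                roles={"a": "exogenous", "b": "outcome"},
                regressions=(("a", "b"), ("b", "a")),
                covariances=(),
            )

    def test_rejects_bad_basis(self):
        with pytest.raises(ValueError):
            build_path_spec("formant")


class TestFitPathModel:
    def test_estimates_match_lstsq_oracle(self, cohort, default_spec):
        grp = cohort[cohort["sex"] == "M"]
        fit = fit_path_model(grp, default_spec)
        X = grp[list(default_spec.variables)].dropna().to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        cols = {v: i for i, v in enumerate(default_spec.variables)}
        by_resp: dict[str, list[str]] = {}
        for pred, resp in default_spec.regressions:
            by_resp.setdefault(resp, []).append(pred)
        for resp, preds in by_resp.items():
            b = np.linalg.lstsq(Z[:, [cols[p] for p in preds]], Z[:, cols[resp]], rcond=None)[0]
            for pred, coef in zip(preds, b):
                assert fit.estimates[f"{resp}~{pred}"] == pytest.approx(coef, abs=1e-8)
        for a, bb in default_spec.covariances:
            assert fit.estimates[f"{a}~~{bb}"] == pytest.approx(
                float(np.corrcoef(Z[:, cols[a]], Z[:, cols[bb]])[0, 1]), abs=1e-8
            )

    def test_chain_recovery(self, rng):
        spec = _chain_spec()
        params = {"m~x": 0.5, "y~m": 0.5, "m~~m": 0.75, "y~~y": 0.75}
        data = _simulate(spec, params, 5000, rng)
        fit = fit_path_model(data, spec)
        assert fit.estimates["m~x"] == pytest.approx(0.5, abs=0.05)
        assert fit.estimates["y~m"] == pytest.approx(0.5, abs=0.05)

    def test_null_data_small_estimates(self, rng, default_spec):
        data = pd.DataFrame(
            rng.normal(size=(2000, 11)), columns=list(default_spec.variables)
        )
        fit = fit_path_model(data, default_spec)
        assert max(abs(v) for v in fit.estimates.values()) < 0.12
        sig = sum(p < 0.05 for p in fit.analytic_p.values())
        assert sig <= 8  # ~5% of 44 under the null, generous bound

    def test_saturated_model_chi2_zero(self, rng):
        vars4 = ("a", "b", "c", "d")
        spec = PathModelSpec(
            variables=vars4,
            roles={"a": "exogenous", "b": "mediator", "c": "mediator", "d": "outcome"},
            regressions=tuple((p, r) for i, r in enumerate(vars4) for p in vars4[:i]),
            covariances=(),
        )
        data = pd.DataFrame(rng.normal(size=(60, 4)), columns=vars4)
        fit = fit_path_model(data, spec)
        assert fit.df == 0
        assert fit.chi_square == pytest.approx(0.0, abs=1e-8)

    def test_default_spec_df(self, cohort, default_spec):
        fit = fit_path_model(cohort[cohort["sex"] == "F"], default_spec)
        # 66 moments - (44 structural + 11 variances)
        assert fit.df == 11
        assert fit.chi_square >= 0

    def test_rejects_rank_deficiency(self, rng):
        spec = _chain_spec()
        x = rng.normal(size=50)
        data = pd.DataFrame({"x": x, "m": x, "y": rng.normal(size=50)})
        with pytest.raises(ValueError):
            fit_path_model(data, spec)

    def test_rejects_tiny_n(self, rng, default_spec):
        data = pd.DataFrame(rng.normal(size=(8, 11)), columns=list(default_spec.variables))
        with pytest.raises(ValueError, match="too small"):
            fit_path_model(data, default_spec)


class TestImpliedCovariance:
    def test_identity_when_no_effects(self):
        spec = _chain_spec()
        np.testing.assert_allclose(implied_covariance({}, spec), np.eye(3))

    def test_single_path_tracing(self):
        spec = PathModelSpec(
            variables=("x", "y"),
            roles={"x": "exogenous", "y": "outcome"},
            regressions=(("x", "y"),),
            covariances=(),
        )
        sigma = implied_covariance({"y~x": 0.6, "y~~y": 1 - 0.36}, spec)
        np.testing.assert_allclose(sigma, [[1.0, 0.6], [0.6, 1.0]], atol=1e-12)

    def test_matches_structural_simulation_oracle(self, rng):
        spec = PathModelSpec(
            variables=("u", "v", "m", "y"),
            roles={"u": "exogenous", "v": "exogenous", "m": "mediator", "y": "outcome"},
            regressions=(("u", "m"), ("v", "m"), ("m", "y"), ("u", "y")),
            covariances=(("u", "v"),),
        )
        params = {"m~u": 0.4, "m~v": -0.3, "y~m": 0.5, "y~u": 0.2,
                  "u~~v": 0.3, "m~~m": 0.8, "y~~y": 0.6}
        sigma = implied_covariance(params, spec)
        # independent oracle: simulate the equations sequentially
        n = 400_000
        L = np.linalg.cholesky(np.array([[1.0, 0.3], [0.3, 1.0]]))
        uv = rng.normal(size=(n, 2)) @ L.T
        m = 0.4 * uv[:, 0] - 0.3 * uv[:, 1] + rng.normal(0, np.sqrt(0.8), n)
        y = 0.5 * m + 0.2 * uv[:, 0] + rng.normal(0, np.sqrt(0.6), n)
        emp = np.cov(np.column_stack([uv, m, y]), rowvar=False)
        np.testing.assert_allclose(sigma, emp, atol=0.02)

    def test_rejects_unknown_parameter(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            implied_covariance({"y~z": 0.2}, _chain_spec())


class TestMlChisquare:
    def test_zero_at_equality(self, rng):
        A = rng.normal(size=(4, 4))
        S = A @ A.T + 4 * np.eye(4)
        assert ml_chisquare(S, S, 100) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_bivariate(self):
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        got = ml_chisquare(S, np.eye(2), 101)
        assert got == pytest.approx(-100 * np.log(1 - 0.36), rel=1e-12)
        assert got == pytest.approx(44.6287, abs=1e-3)

    def test_nonnegative(self, rng):
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            B = rng.normal(size=(3, 3))
            S = A @ A.T + 3 * np.eye(3)
            Sig = B @ B.T + 3 * np.eye(3)
            assert ml_chisquare(S, Sig, 50) >= 0

    def test_rejects_non_positive_definite(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            ml_chisquare(bad, np.eye(2), 50)


class TestPermutationPvalues:
    def test_add_one_lower_bound(self, rng):
        spec = _chain_spec()
        x = rng.normal(size=120)
        m = 0.95 * x + 0.1 * rng.normal(size=120)
        y = 0.95 * m + 0.1 * rng.normal(size=120)
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        B = 199
        p = permutation_pvalues(data, spec, B=B, seed=0)
        assert p["m~x"] == pytest.approx(1 / (B + 1))
        assert all(v >= 1 / (B + 1) for v in p.values())

    def test_default_B_is_ten_thousand(self):
        sig = inspect.signature(permutation_pvalues)
        assert sig.parameters["B"].default == 10_000

    def test_seed_reproducibility(self, rng, default_spec):
        data = pd.DataFrame(rng.normal(size=(60, 11)), columns=list(default_spec.variables))
        p1 = permutation_pvalues(data, default_spec, B=200, seed=7)
        p2 = permutation_pvalues(data, default_spec, B=200, seed=7)
        assert p1 == p2

    def test_joint_scheme_preserves_endogenous_block(self, rng):
        # under joint row permutation the m~x link is broken but y~m survives
        spec = _chain_spec()
        x = rng.normal(size=200)
        m = 0.8 * x + 0.6 * rng.normal(size=200)
        y = 0.8 * m + 0.6 * rng.normal(size=200)
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        p = permutation_pvalues(data, spec, B=199, seed=1, scheme="joint")
        assert p["m~x"] <= 0.05
        assert p["y~m"] > 0.2  # y~m not nullified by the joint scheme

    def test_rejects_bad_scheme(self, rng):
        data = pd.DataFrame(rng.normal(size=(50, 3)), columns=["x", "m", "y"])
        with pytest.raises(ValueError):
            permutation_pvalues(data, _chain_spec(), B=10, scheme="rows")


class TestJackknife:
    def test_strong_signal_stable(self, rng):
        spec = _chain_spec()
        x = rng.normal(size=200)
        m = 0.8 * x + 0.6 * rng.normal(size=200)
        y = 0.8 * m + 0.6 * rng.normal(size=200)
        stable = jackknife_stability(pd.DataFrame({"x": x, "m": m, "y": y}), spec)
        assert stable["m~x"] and stable["y~m"]

    def test_outlier_driven_association_unstable(self, rng):
        spec = _chain_spec()
        n = 60
        x = np.append(0.1 * rng.normal(size=n - 1), 10.0)
        m = np.append(0.1 * rng.normal(size=n - 1), 10.0)
        y = 0.1 * rng.normal(size=n)
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        full = fit_path_model(data, spec)
        assert full.analytic_p["m~x"] < 0.05  # driven by the inserted point
        assert not jackknife_stability(data, spec)["m~x"]

    def test_nonsignificant_is_unstable_by_definition(self, rng):
        spec = _chain_spec()
        data = pd.DataFrame(rng.normal(size=(80, 3)), columns=["x", "m", "y"])
        fit = fit_path_model(data, spec)
        stable = jackknife_stability(data, spec)
        for name, p in fit.analytic_p.items():
            if p >= 0.05:
                assert not stable[name]

    def test_rejects_tiny_sample(self, rng):
        data = pd.DataFrame(rng.normal(size=(9, 3)), columns=["x", "m", "y"])
        with pytest.raises(ValueError, match="n >= 10"):
            jackknife_stability(data, _chain_spec())


class TestInvariance:
    def test_default_spec_df_44(self, cohort, default_spec):
        res = invariance_test(cohort, "sex", default_spec)
        assert res.df_diff == 44
        assert res.chi2_invariant >= res.chi2_configural
        assert 0 < res.p <= 1

    def test_null_invariance(self, rng):
        spec = _chain_spec()
        params = {"m~x": 0.4, "y~m": 0.4, "m~~m": 0.84, "y~~y": 0.84}
        frames = []
        for g in ("a", "b"):
            d = _simulate(spec, params, 800, rng)
            d["grp"] = g
            frames.append(d)
        res = invariance_test(pd.concat(frames), "grp", spec)
        assert res.p > 0.05
        assert res.chi2_diff < 10

    def test_nesting_on_random_datasets(self, rng):
        spec = _chain_spec()
        for _ in range(5):
            d = pd.DataFrame(rng.normal(size=(120, 3)), columns=["x", "m", "y"])
            d["grp"] = rng.choice(["a", "b"], size=120)
            res = invariance_test(d, "grp", spec)
            assert res.chi2_invariant >= res.chi2_configural
            assert res.df_diff == 2

    def test_power_against_a_differing_coefficient(self, rng):
        # groups differ by 0.6 in one path; scaled-down version of the
        # full-size power property
        spec = _chain_spec()
        hits = 0
        reps = 40
        for _ in range(reps):
            da = _simulate(spec, {"m~x": 0.6, "y~m": 0.3, "m~~m": 0.64, "y~~y": 0.91}, 300, rng)
            db = _simulate(spec, {"m~x": 0.0, "y~m": 0.3, "m~~m": 1.0, "y~~y": 0.91}, 300, rng)
            da["grp"], db["grp"] = "a", "b"
            res = invariance_test(pd.concat([da, db]), "grp", spec)
            hits += res.p < 0.001
        assert hits >= 0.9 * reps

    def test_requires_two_groups(self, rng):
        d = pd.DataFrame(rng.normal(size=(50, 3)), columns=["x", "m", "y"])
        d["grp"] = "only"
        with pytest.raises(ValueError, match="2 groups"):
            invariance_test(d, "grp", _chain_spec())


class TestAnalyticCalibration:
    def test_analytic_p_uniform_under_null(self, rng):
        # pooled analytic p-values over independent null datasets are ~uniform
        spec = _chain_spec()
        pvals = []
        for _ in range(200):
            d = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "m", "y"])
            pvals.extend(fit_path_model(d, spec).analytic_p.values())
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.03 < rate < 0.07
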