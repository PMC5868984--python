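"""Design assembly, serial covariance and the marginal-covariance engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spcurve as sp
from spcurve.design import MarginalCovariance, VarianceComponents

from conftest import make_spec


def _dense_V(design, vc):
    """Dense oracle: V = Zb D Zb' + blockdiag(sigma_u^2 J + Sigma_i)."""
    n = design.n_obs
    d = np.empty(design.n_spline)
    for var, cols in zip(vc.sigma2_b, design.spline_block_map):
        d[list(cols)] = var
    V = design.Zb @ np.diag(d) @ design.Zb.T
    for sl in design.subject_slices.values():
        t_i = design.times[sl]
        m = sl.stop - sl.start
        block = vc.sigma2_u * np.ones((m, m)) + vc.sigma2_noise * np.eye(m)
        if vc.serial != "none" and vc.sigma2_serial > 0:
            lag = np.abs(t_i[:, None] - t_i[None, :])
            corr = np.exp(-lag / vc.tau) if vc.serial == "exponential" else np.exp(-((lag / vc.tau) ** 2))
            block += vc.sigma2_serial * corr
        V[sl, sl] += block
    return V


class TestColumnLayout:
    @pytest.mark.parametrize(
        "structure,n_fixed,n_spline,n_blocks",
        [("1.1", 7, 9, 1), ("1.2", 8, 9, 1), ("1.3", 10, 9, 1),
         ("1.4", 10, 18, 1), ("1.5", 10, 18, 2)],
    )
    def test_counts_with_nine_knots_four_covariates(
        self, small_dataset, structure, n_fixed, n_spline, n_blocks
    ):
        dataset, _ = small_dataset
        spec = make_spec(dataset, structure=structure, n_knots=9)
        d = sp.build_design(dataset, spec)
        assert (d.n_fixed, d.n_spline) == (n_fixed, n_spline)
        assert len(d.spline_block_map) == n_blocks
        assert sorted(c for blk in d.spline_block_map for c in blk) == list(range(n_spline))

    def test_reference_level_coded_zero(self, small_dataset):
        dataset, _ = small_dataset
        d = sp.build_design(dataset, make_spec(dataset, structure="1.2"))
        # CTR is the reference: its rows have 0 in the group column
        gcol = d.x_names.index("group[OSA]")
        groups = dataset.frame["group"].to_numpy()
        assert np.all(d.X[groups == "CTR", gcol] == 0.0)
        assert np.all(d.X[groups == "OSA", gcol] == 1.0)

    def test_structure_aliases(self, small_dataset):
        dataset, _ = small_dataset
        a = sp.build_design(dataset, make_spec(dataset, structure="quadratic_by_group"))
        b = sp.build_design(dataset, make_spec(dataset, structure="1.3"))
        assert a.x_names == b.x_names
        np.testing.assert_array_equal(a.X, b.X)

    def test_split_splines_require_two_groups(self, small_dataset):
        dataset, _ = small_dataset
        frame = dataset.frame.copy()
        frame.loc[frame["subject"] == "OSA001", "group"] = "THIRD"
        ds3 = sp.LongitudinalDataset(frame, covariates=dataset.covariates)
        knots = sp.select_knots_quantile(ds3.times(), 5)
        spec = sp.ModelSpec(structure="1.4", basis=sp.BasisSpec(degree=2, knots=knots))
        with pytest.raises(sp.UnsupportedStructureError, match="two groups"):
            sp.build_design(ds3, spec)

    def test_nesting_column_spaces(self, small_dataset):
        """Each stepwise fixed design spans the previous one (1.1 ⊂ 1.2 ⊂ 1.3)."""
        dataset, _ = small_dataset
        Xs = [sp.build_design(dataset, make_spec(dataset, structure=s)).X
              for s in ("1.1", "1.2", "1.3")]
        for X_small, X_big in zip(Xs, Xs[1:]):
            proj, *_ = np.linalg.lstsq(X_big, X_small, rcond=None)
            assert np.abs(X_big @ proj - X_small).max() < 1e-8

    def test_split_spline_block_masks(self, small_dataset):
        dataset, _ = small_dataset
        d = sp.build_design(dataset, make_spec(dataset, structure="1.5", n_knots=5))
        groups = dataset.frame["group"].to_numpy()
        K = 5
        # first block = indicator (OSA) columns, second = reference (CTR)
        assert np.all(d.Zb[groups == "CTR", :K] == 0.0)
        assert np.all(d.Zb[groups == "OSA", K:] == 0.0)


class TestCurveDesign:
    def test_row_matches_observation_row(self, small_dataset):
        """Curve rows at an observed time reproduce the observation design row."""
        dataset, _ = small_dataset
        d = sp.build_design(dataset, make_spec(dataset, structure="1.3"))
        frame = dataset.frame.reset_index(drop=True)
        i = 17
        g, t = frame.loc[i, "group"], frame.loc[i, "time"]
        covs = {c: frame.loc[i, c] for c in dataset.covariates}
        Xg, Zg = sp.build_curve_design(d, np.array([t]), g, covariate_values=covs)
        assert np.abs(Xg[0] - d.X[i]).max() < 1e-12
        assert np.abs(Zg[0] - d.Zb[i]).max() < 1e-12

    def test_unknown_group_rejected(self, small_dataset):
        dataset, _ = small_dataset
        d = sp.build_design(dataset, make_spec(dataset))
        with pytest.raises(ValueError, match="unknown group"):
            sp.build_curve_design(d, np.array([1.0]), "XXX")

    def test_derivative_rows_zero_intercepts(self, small_dataset):
        dataset, _ = small_dataset
        d = sp.build_design(dataset, make_spec(dataset, structure="1.3"))
        Xg, _ = sp.build_curve_design(d, np.array([3.0]), "OSA", derivative=True)
        for name in ("intercept", "group[OSA]"):
            assert Xg[0, d.x_names.index(name)] == 0.0
        for c in dataset.covariates:
            assert Xg[0, d.x_names.index(c)] == 0.0


class TestSerialCovariance:
    def test_exponential_entries(self):
        spec = sp.CovarianceSpec(serial="exponential", sigma2_serial=0.3,
                                 tau=2.0, sigma2_noise=0.1)
        S = sp.serial_covariance(np.array([0.0, 1.0, 3.0]), spec)
        assert S[0, 0] == pytest.approx(0.4)  # sigma2_serial + sigma2_noise
        assert S[0, 1] == pytest.approx(0.3 * np.exp(-0.5))
        assert S[0, 2] == pytest.approx(0.3 * np.exp(-1.5))

    def test_gaussian_decays_faster_than_exponential_at_long_lags(self):
        t = np.array([0.0, 4.0])
        e = sp.serial_covariance(t, sp.CovarianceSpec(serial="exponential",
                                                      sigma2_serial=1.0, tau=1.0,
                                                      sigma2_noise=0.0))
        g = sp.serial_covariance(t, sp.CovarianceSpec(serial="gaussian",
                                                      sigma2_serial=1.0, tau=1.0,
                                                      sigma2_noise=0.0))
        assert g[0, 1] < e[0, 1]

    def test_none_is_white_noise(self):
        S = sp.serial_covariance(np.arange(4.0), sp.CovarianceSpec(sigma2_noise=0.7))
        np.testing.assert_allclose(S, 0.7 * np.eye(4))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_positive_definite(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 24, 6))
        serial = ["exponential", "gaussian"][seed % 2]
        spec = sp.CovarianceSpec(serial=serial, sigma2_serial=rng.uniform(0.1, 2),
                                 tau=rng.uniform(0.5, 5), sigma2_noise=rng.uniform(0.05, 1))
        S = sp.serial_covariance(t, spec)
        assert np.linalg.eigvalsh(S).min() > 0

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            sp.CovarianceSpec(serial="spherical")
        with pytest.raises(ValueError, match="tau"):
            sp.CovarianceSpec(serial="exponential", tau=0.0)


def _vc(serial="none", blocks=1):
    return VarianceComponents(
        sigma2_u=0.4, sigma2_b=tuple([0.6] * blocks), sigma2_noise=0.25,
        sigma2_serial=0.2 if serial != "none" else 0.0, tau=1.7, serial=serial,
    )


class TestMarginalCovariance:
    @pytest.mark.parametrize("serial", ["none", "exponential", "gaussian"])
    def test_dense_oracle_solve_and_logdet(self, tiny_dataset, serial):
        d = sp.build_design(tiny_dataset, make_spec(tiny_dataset, structure="1.3",
                                                    n_knots=3, reference="A"))
        vc = _vc(serial)
        engine = MarginalCovariance(d, serial=serial)
        V = _dense_V(d, vc)
        rng = np.random.default_rng(7)
        v = rng.normal(size=d.n_obs)
        np.testing.assert_allclose(engine.solve_V(v, vc), np.linalg.solve(V, v),
                                   atol=1e-8)
        assert engine.logdet_V(vc) == pytest.approx(np.linalg.slogdet(V)[1], abs=1e-8)

    @pytest.mark.parametrize("serial", ["none", "exponential"])
    def test_whitened_products_match_dense(self, tiny_dataset, serial):
        d = sp.build_design(tiny_dataset, make_spec(tiny_dataset, structure="1.3",
                                                    n_knots=3, reference="A"))
        vc = _vc(serial)
        engine = MarginalCovariance(d, serial=serial)
        y = tiny_dataset.response()
        C = d.C()
        # dense R (V without the spline low-rank part)
        Rd = _dense_V(d, VarianceComponents(vc.sigma2_u, (0.0,) * len(vc.sigma2_b),
                                            vc.sigma2_noise, vc.sigma2_serial,
                                            vc.tau, vc.serial))
        Rin = np.linalg.inv(Rd)
        A, b, s, logdetR = engine.whitened_products(vc, y)
        np.testing.assert_allclose(A, C.T @ Rin @ C, atol=1e-8)
        np.testing.assert_allclose(b, C.T @ Rin @ y, atol=1e-8)
        assert s == pytest.approx(y @ Rin @ y, abs=1e-8)
        assert logdetR == pytest.approx(np.linalg.slogdet(Rd)[1], abs=1e-8)

    def test_fast_path_agrees_with_generic_path(self, tiny_dataset):
        """Sherman-Morrison shortcut equals the per-block Cholesky route."""
        d = sp.build_design(tiny_dataset, make_spec(tiny_dataset, structure="1.1",
                                                    n_knots=3, reference="A"))
        y = tiny_dataset.response()
        vc_fast = _vc("none")
        fast = MarginalCovariance(d, serial="none").whitened_products(vc_fast, y)
        # generic path: serial family set but zero serial variance => same R
        vc_slow = VarianceComponents(vc_fast.sigma2_u, vc_fast.sigma2_b,
                                     vc_fast.sigma2_noise, 0.0, 1.0, "exponential")
        slow = MarginalCovariance(d, serial="exponential").whitened_products(vc_slow, y)
        for a, b in zip(fast, slow):
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_zero_serial_and_intercept_reduces_to_scaled_identity(self, tiny_dataset):
        d = sp.build_design(tiny_dataset, make_spec(tiny_dataset, structure="1.1",
                                                    n_knots=3, reference="A"))
        vc = VarianceComponents(sigma2_u=0.0, sigma2_b=(0.0,), sigma2_noise=0.5)
        engine = MarginalCovariance(d)
        v = np.arange(float(d.n_obs))
        np.testing.assert_allclose(engine.solve_V(v, vc), v / 0.5, atol=1e-10)
        assert engine.logdet_V(vc) == pytest.approx(d.n_obs * np.log(0.5))

    def test_subject_order_invariance(self):
        """Shuffling subject rows leaves the whitened cross-products unchanged."""
        rng = np.random.default_rng(11)
        rows = []
        for s, g in [("a", "A"), ("b", "B"), ("c", "A")]:
            for t in np.linspace(0, 8, 5):
                rows.append({"subject": s, "group": g, "time": t,
                             "response": rng.normal()})
        frame = pd.DataFrame(rows)
        shuffled = frame.sample(frac=1.0, random_state=3)
        results = []
        for fr in (frame, shuffled):
            ds = sp.LongitudinalDataset(fr, group_levels=("A", "B"))
            d = sp.build_design(ds, make_spec(ds, structure="1.2", n_knots=2,
                                              reference="A"))
            engine = MarginalCovariance(d)
            results.append(engine.whitened_products(_vc(), ds.response()))
        for a, b in zip(results[0], results[1]):
            np.testing.assert_allclose(a, b, atol=1e-10)
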