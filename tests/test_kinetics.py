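"""Unit and property tests for the saturating-exponential kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sascakit as sk
from sascakit import published
from sascakit.kinetics import FitError, derived_metrics, simulate_grid

RNG = np.random.default_rng


class TestEvaluation:
    def test_zero_at_origin(self):
        assert sk.eval_one_exp(2.8010, 0.0008, np.array([0.0]))[0] == 0.0
        assert sk.eval_two_exp(0.4378, 0.0556, 0.4905, 0.0046, np.array([0.0]))[0] == 0.0

    def test_one_exp_plateau_is_P(self):
        # Asymptotic accumulation of the representative sensitive cell.
        f = sk.eval_one_exp(2.8010, 0.0008, np.array([1e9]))
        assert f[0] == pytest.approx(2.8010, abs=1e-12)

    def test_one_exp_half_plateau_identity(self):
        t_half = math.log(2) / 0.0008
        f = sk.eval_one_exp(2.8010, 0.0008, np.array([t_half]))
        assert f[0] == pytest.approx(1.4005, abs=1e-10)

    def test_two_exp_plateau_is_A_plus_C(self):
        # Cell 58: A + C = 0.9283.
        f = sk.eval_two_exp(0.4378, 0.0556, 0.4905, 0.0046, np.array([1e9]))
        assert f[0] == pytest.approx(0.9283, abs=1e-12)

    def test_two_exp_nests_one_exp(self, grid_1s):
        one = sk.eval_one_exp(0.7, 0.003, grid_1s)
        two = sk.eval_two_exp(0.7, 0.003, 0.0, 0.5, grid_1s)
        np.testing.assert_allclose(two, one, atol=1e-14)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sk.eval_one_exp(1.0, 0.01, np.array([-1.0]))
        with pytest.raises(ValueError):
            sk.eval_two_exp(1.0, 0.01, 1.0, 0.001, np.array([-1.0]))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            sk.eval_one_exp(1.0, 0.0, np.array([1.0]))
        with pytest.raises(ValueError):
            sk.eval_two_exp(1.0, 0.01, 1.0, -0.2, np.array([1.0]))

    @given(
        P=st.floats(0.1, 5.0),
        Q=st.floats(1e-4, 0.5),
        t=st.floats(0.0, 5000.0),
    )
    def test_one_exp_monotone_and_bounded(self, P, Q, t):
        f = sk.eval_one_exp(P, Q, np.array([t, t + 1.0]))
        assert f[1] >= f[0] - 1e-12
        assert 0.0 <= f[0] <= P + 1e-12


def _one_exp_rows():
    return [
        pytest.param(float(r.P), float(r.Q), id=f"wt-{r.cell_id}")
        for r in published.WT_FITS.itertuples()
    ]


def _two_exp_rows():
    rows = []
    for r in published.WT_FITS.itertuples():
        rows.append(pytest.param(float(r.A), float(r.B), float(r.C), float(r.D),
                                 id=f"wt2-{r.cell_id}"))
    for table, tag in ((published.VLB_FITS, "vlb"), (published.VLB_CSA_FITS, "csa")):
        for r in table.itertuples():
            rows.append(pytest.param(float(r.A), float(r.B), float(r.C), float(r.D),
                                     id=f"{tag}-{r.cell_id}"))
    for r in published.SASCA_FITS.itertuples():
        rows.append(pytest.param(float(r.A), float(r.B), float(r.C), float(r.D),
                                 id=f"sasca-{r.cell_id}-{r.phase}"))
    return rows


def _canonical(params):
    A, B, C, D = params
    return (A, B, C, D) if B >= D else (C, D, A, B)


class TestParameterRecovery:
    """Noiseless curves generated from every published parameter row must
    be recovered by the matching fitter to relative error < 1e-4."""

    @pytest.mark.parametrize("P,Q", _one_exp_rows())
    def test_one_exp_rows(self, grid_1s, P, Q):
        fit = sk.fit_one_exp(grid_1s, sk.eval_one_exp(P, Q, grid_1s))
        assert fit.converged
        np.testing.assert_allclose(fit.params, (P, Q), rtol=1e-4)

    @pytest.mark.parametrize("A,B,C,D", _two_exp_rows())
    def test_two_exp_rows(self, grid_1s, A, B, C, D):
        fit = sk.fit_two_exp(grid_1s, sk.eval_two_exp(A, B, C, D, grid_1s))
        assert fit.converged
        assert fit.model_kind == "two_exp"
        np.testing.assert_allclose(fit.params, _canonical((A, B, C, D)), rtol=1e-4)

    def test_canonical_ordering(self, grid_1s, vlb58_truth):
        fit = sk.fit_two_exp(grid_1s, vlb58_truth.evaluate(grid_1s))
        assert fit.params[1] >= fit.params[3]

    def test_noisy_one_exp_median_P(self, grid_1s):
        """Median recovered P over seeded noisy replicates within 1% of truth."""
        P, Q = 2.8010, 0.0008
        y = sk.eval_one_exp(P, Q, grid_1s)
        rng = RNG(11)
        t = grid_1s[::5]
        ps = []
        for _ in range(30):
            yy = y[::5] + rng.normal(0, 0.01, t.size)
            ps.append(sk.fit_one_exp(t, yy).params[0])
        assert abs(np.median(ps) / P - 1) < 0.01

    def test_all_zero_trace_flagged(self, grid_1s):
        fit = sk.fit_one_exp(grid_1s, np.zeros_like(grid_1s))
        assert fit.params[0] == 0.0
        assert "amplitude-degenerate" in fit.flags

    def test_two_exp_on_one_exp_input_minimal_second_component(self, grid_1s, wt148_truth):
        """A drug-sensitive-like curve needs no second uptake component."""
        fit = sk.fit_two_exp(grid_1s, wt148_truth.evaluate(grid_1s))
        if fit.model_kind == "one_exp":
            assert "rate-collapse" in fit.flags
        else:
            A, _, C, _ = fit.params
            assert min(A, C) < 0.05 * max(A, C)

    def test_too_few_observations(self):
        t = np.arange(5.0)
        with pytest.raises(FitError):
            sk.fit_one_exp(t, t)


class TestFitProperties:
    def test_nesting_rss(self, grid_1s):
        """The richer model never fits the same data worse."""
        rng = RNG(3)
        y = sk.eval_one_exp(2.8, 0.0008, grid_1s) + rng.normal(0, 0.05, grid_1s.size)
        t = grid_1s[::5]
        f1 = sk.fit_one_exp(t, y[::5])
        f2 = sk.fit_two_exp(t, y[::5])
        assert f2.rss <= f1.rss * (1 + 1e-9)

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_scale_equivariance(self, grid_1s, vlb58_truth, c):
        """Scaling the trace scales amplitudes, leaves rates and R alone."""
        rng = RNG(5)
        t = grid_1s[::5]
        y = vlb58_truth.evaluate(t) + rng.normal(0, 0.02, t.size)
        base = sk.fit_two_exp(t, y)
        scaled = sk.fit_two_exp(t, c * y)
        np.testing.assert_allclose(scaled.params[0::2], np.multiply(base.params[0::2], c), rtol=1e-5)
        np.testing.assert_allclose(scaled.params[1::2], base.params[1::2], rtol=1e-5)
        assert scaled.R == pytest.approx(base.R, abs=1e-9)

    def test_fitted_curve_monotone(self, grid_1s, vlb58_truth):
        rng = RNG(8)
        t = grid_1s[::5]
        y = vlb58_truth.evaluate(t) + rng.normal(0, 0.02, t.size)
        fit = sk.fit_two_exp(t, y)
        assert np.all(np.diff(fit.predict(grid_1s)) >= -1e-12)


class TestCorrelationR:
    def test_perfect_agreement(self):
        y = np.linspace(0, 1, 50)
        assert sk.correlation_R(y, y) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        y = np.linspace(0, 1, 50)
        assert sk.correlation_R(y, -y) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = RNG(2)
        truth = sk.eval_one_exp(2.0, 0.002, np.arange(200.0))
        obs = truth + rng.normal(0, 0.1, truth.size)
        # Brute-force Pearson formula.
        ox, fx = obs - obs.mean(), truth - truth.mean()
        expected = float((ox @ fx) / np.sqrt((ox @ ox) * (fx @ fx)))
        assert sk.correlation_R(obs, truth) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(FitError):
            sk.correlation_R(np.ones(10), np.linspace(0, 1, 10))


class TestDerivedMetrics:
    def test_plateau_cell24(self, grid_1s):
        """Largest published resistant-cell plateau: A + C = 1.4980."""
        fit = sk.fit_two_exp(grid_1s, sk.eval_two_exp(0.7980, 0.0100, 0.7000, 0.0051, grid_1s))
        assert derived_metrics(fit)["plateau"] == pytest.approx(1.4980, abs=1e-4)

    def test_one_exp_half_time_closed_form(self, grid_1s):
        fit = sk.fit_one_exp(grid_1s, sk.eval_one_exp(1.0, 0.001, grid_1s))
        assert derived_metrics(fit)["half_time_s"] == pytest.approx(math.log(2) / 0.001, rel=1e-6)

    def test_two_exp_half_time_matches_grid_search(self, grid_1s, vlb58_truth):
        """Root-bracketed half-time equals a brute-force 0.1 s grid search."""
        fit = sk.fit_two_exp(grid_1s, vlb58_truth.evaluate(grid_1s))
        metrics = derived_metrics(fit)
        tg = np.arange(0.0, 3000.0, 0.1)
        fg = vlb58_truth.evaluate(tg)
        brute = tg[np.argmin(np.abs(fg - vlb58_truth.plateau / 2))]
        assert metrics["half_time_s"] == pytest.approx(brute, abs=0.1)
        assert metrics["share_fast"] + metrics["share_slow"] == pytest.approx(1.0)


class TestSimulateGrid:
    def test_representative_curve(self, grid_1s, wt148_truth):
        fam = simulate_grid({"a": wt148_truth}, grid_1s)
        np.testing.assert_allclose(fam["a"].to_numpy(), wt148_truth.evaluate(grid_1s))

    def test_doubling_P_doubles_curve(self, grid_1s):
        fam = simulate_grid(
            {"base": ("one_exp", (1.0, 0.001)), "double": ("one_exp", (2.0, 0.001))},
            grid_1s,
        )
        np.testing.assert_allclose(fam["double"], 2 * fam["base"], rtol=1e-12)

    def test_doubling_Q_same_plateau_half_half_time(self):
        t = np.array([math.log(2) / 0.002])
        fam = simulate_grid(
            {"base": ("one_exp", (1.0, 0.001)), "fast": ("one_exp", (1.0, 0.002))},
            t,
        )
        # At the fast curve's half-time (half the slow one's) it reads P/2.
        assert fam["fast"].iloc[0] == pytest.approx(0.5, abs=1e-12)
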