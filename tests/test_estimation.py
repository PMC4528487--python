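import numpy as np
import pytest

from ctlsim import (ExtinctionCurve, SimulationConfig, adaptive_cstar_search,
                    classify_outcome, extinction_probability, fit_sigmoid,
                    sigmoid)
from ctlsim.world import TimeCourse


def _timecourse(t_min, infected):
    n = len(t_min)
    z = np.zeros(n)
    return TimeCourse.from_arrays(
        time_min=np.asarray(t_min, float), susceptible=z, infected=infected,
        dead=z, ctl_free=z, ctl_conjugated=z, virions=z)


class TestClassifyOutcome:
    def test_trailing_zero_is_extinct(self):
        t = np.arange(0, 3000, 60.0)
        counts = np.maximum(100 - t / 20, 0.0)
        assert classify_outcome(_timecourse(t, counts)) == "extinct"

    def test_rising_tail_is_established(self):
        t = np.arange(0, 3000, 60.0)
        assert classify_outcome(_timecourse(t, 50 + t / 30)) == "established"

    def test_declining_tail_without_reaching_zero_is_extinct(self):
        """100 -> 80 over the final 12 h: negative gradient implies eventual
        extinction even though the count never hits zero."""
        t = np.arange(0, 48 * 60 + 1, 60.0)
        counts = np.full(len(t), 100.0)
        in_window = t > t[-1] - 720
        counts[in_window] = np.linspace(100, 80, in_window.sum())
        assert classify_outcome(_timecourse(t, counts)) == "extinct"

    def test_short_course_classified_with_warning(self):
        t = np.arange(0, 300, 60.0)
        with pytest.warns(UserWarning, match="shorter"):
            out = classify_outcome(_timecourse(t, 50 + t / 30))
        assert out == "established"


class TestSigmoid:
    def test_anchor_points(self):
        assert sigmoid(0.03, 0.03, 8.0) == pytest.approx(0.5)
        assert sigmoid(0.0, 0.03, 8.0) == 0.0
        assert sigmoid(3.0, 0.03, 8.0) > 0.999

    def test_strictly_increasing(self):
        c = np.linspace(1e-4, 0.2, 200)
        p = sigmoid(c, 0.03, 8.0)
        assert np.all(np.diff(p) > 0)

    def test_large_alpha_approaches_step(self):
        assert sigmoid(0.029, 0.03, 5000.0) < 1e-3
        assert sigmoid(0.031, 0.03, 5000.0) > 1 - 1e-3

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sigmoid(0.1, -0.03, 8.0)
        with pytest.raises(ValueError):
            sigmoid(0.1, 0.03, 0.0)


class TestExtinctionCurve:
    def test_validation_and_ordering(self):
        curve = ExtinctionCurve(C=[0.3, 0.1, 0.2], n_reps=[10, 10, 10],
                                n_extinct=[9, 1, 5])
        assert list(curve.C) == [0.1, 0.2, 0.3]
        assert list(curve.n_extinct) == [1, 5, 9]
        with pytest.raises(ValueError):
            ExtinctionCurve(C=[0.1], n_reps=[10], n_extinct=[11])

    def test_from_points_merges_duplicates(self):
        curve = ExtinctionCurve.from_points(
            [(0.1, 10, 2), (0.1, 10, 4), (0.2, 10, 9)])
        assert list(curve.n_reps) == [20, 10]
        assert list(curve.n_extinct) == [6, 9]

    def test_csv_roundtrip(self, tmp_path):
        curve = ExtinctionCurve(C=[0.1, 0.2], n_reps=[10, 10],
                                n_extinct=[2, 8])
        curve.to_csv(tmp_path / "c.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "c.csv")
        assert list(df.columns) == ["C", "n_reps", "n_extinct", "proportion",
                                    "ci_lo", "ci_hi"]


class TestFitSigmoid:
    C = np.array([0.01, 0.02, 0.025, 0.03, 0.035, 0.04, 0.06])

    def test_noiseless_recovery_to_1e4(self):
        p = sigmoid(self.C, 0.03, 8.0)
        big = 10**9  # effectively exact proportions
        curve = ExtinctionCurve(C=self.C, n_reps=np.full(7, big),
                                n_extinct=np.round(p * big).astype(int))
        fit = fit_sigmoid(curve)
        assert fit.C_star == pytest.approx(0.03, rel=1e-4)
        assert fit.alpha == pytest.approx(8.0, rel=1e-4)
        assert fit.converged

    def test_binomial_noise_recovery(self):
        """200 replicates per point: C* recovered within 5% (and alpha within
        25%) across 100 simulated estimation rounds."""
        rng = np.random.default_rng(0)
        p = sigmoid(self.C, 0.03, 8.0)
        c_err, a_err = [], []
        for _ in range(100):
            x = rng.binomial(200, p)
            fit = fit_sigmoid(ExtinctionCurve(
                C=self.C, n_reps=np.full(7, 200), n_extinct=x))
            c_err.append(abs(fit.C_star / 0.03 - 1))
            a_err.append(abs(fit.alpha / 8.0 - 1))
        assert max(c_err) < 0.05
        assert np.mean(a_err) < 0.25

    def test_point_order_invariance(self):
        rng = np.random.default_rng(3)
        p = sigmoid(self.C, 0.03, 8.0)
        x = rng.binomial(200, p)
        f1 = fit_sigmoid(ExtinctionCurve(C=self.C, n_reps=np.full(7, 200),
                                         n_extinct=x))
        perm = rng.permutation(7)
        f2 = fit_sigmoid(ExtinctionCurve(C=self.C[perm],
                                         n_reps=np.full(7, 200),
                                         n_extinct=x[perm]))
        assert f1.C_star == pytest.approx(f2.C_star, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid(ExtinctionCurve(C=[0.1, 0.2], n_reps=[10, 10],
                                        n_extinct=[1, 9]))


class TestAdaptiveSearch:
    def test_step_oracle_converges_to_half(self):
        def oracle(C):
            return 1000, 1000 if C > 0.5 else 0

        curve = adaptive_cstar_search(initial_guesses=[0.1, 0.9],
                                      prob_fn=oracle, tolerance=0.01)
        below = curve.C[curve.proportion < 0.5].max()
        above = curve.C[curve.proportion >= 0.5].min()
        assert below <= 0.5 <= above
        assert above - below < 0.01 * 0.5 * (above + below) + 1e-12

    def test_hill_oracle_bracket_contains_truth(self):
        rng = np.random.default_rng(1)

        def oracle(C):
            return 200, int(rng.binomial(200, sigmoid(C, 0.03, 8.0)))

        curve = adaptive_cstar_search(initial_guesses=[0.005, 0.2],
                                      prob_fn=oracle, tolerance=0.05)
        fit = fit_sigmoid(curve)
        assert fit.C_star == pytest.approx(0.03, rel=0.15)

    def test_all_evaluations_retained(self):
        calls = []

        def oracle(C):
            calls.append(C)
            return 100, 100 if C > 0.4 else 0

        curve = adaptive_cstar_search(initial_guesses=[0.1, 0.8],
                                      prob_fn=oracle, tolerance=0.02)
        assert int(curve.n_reps.sum()) == 100 * len(calls)

    def test_unbracketable_raises(self):
        def always_extinct(C):
            return 10, 10

        with pytest.raises(RuntimeError):
            adaptive_cstar_search(initial_guesses=[0.5],
                                  prob_fn=always_extinct)


class TestExtinctionProbability:
    def test_no_ctl_never_extinct(self):
        cfg = SimulationConfig(n_rows=32, n_cols=32, timestep=10.0, i_c=20,
                               t_max=1.0)
        p, ci = extinction_probability(cfg, 0.0, 4, seed=0)
        assert p == 0.0
        assert 0.0 <= ci[0] <= ci[1] <= 1.0

    def test_saturating_density_always_extinct(self):
        cfg = SimulationConfig(n_rows=24, n_cols=24, timestep=5.0, i_c=10,
                               t_max=3.0, ctl_velocity=7.5)
        p, _ = extinction_probability(cfg, 1.0, 4, seed=1)
        assert p == 1.0
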