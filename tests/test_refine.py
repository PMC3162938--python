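"""Stage II tests: interpolation, sigmoid, ML fit, AIC pruning."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from lightgrn.dataset import ExpressionDataset, TimeSeriesExpression
from lightgrn.errors import AlignmentError, GridError, IdentifiabilityError, SingularityError
from lightgrn.refine import (
    AICRegulatorPruner,
    RegressionSystem,
    SigmoidParams,
    aic_score,
    build_regression_system,
    interpolate_profile,
    ml_fit,
    prune_regulators,
    refine_network,
    sigmoid_activity,
)
from lightgrn.rough import CandidateEdge, RoughNetwork
from lightgrn.synthetic import DESIGN_TIMES, generate_tf_profiles

GRID = 0.5 * np.arange(97)  # uniform inference grid over [0, 48] h


def design_profile(gene, values):
    return TimeSeriesExpression(gene, np.asarray(DESIGN_TIMES), np.asarray(values, float))


def uniform_profile(gene, values):
    return TimeSeriesExpression(gene, GRID, np.asarray(values, float))


def simulate_discrete(expressions, params, b, beta, k, step, y0, n=97):
    """Roll the midpoint-discretised recursion forward exactly.

    Activities are the sigmoid of the midpoint TF expression — the same
    convention the regression uses — so the produced target trajectory is
    exactly consistent with the midpoint regression model and least squares
    must recover (b, beta, k) to machine precision.
    """
    acts = {
        tf: sigmoid_activity((z[:-1] + z[1:]) / 2, params, tf)
        for tf, z in expressions.items()
        if tf in b
    }
    y = np.empty(n)
    y[0] = y0
    for j in range(n - 1):
        drive = sum(b[tf] * a[j] for tf, a in acts.items())
        y[j + 1] = (y[j] * (1 - step * beta / 2) + step * (drive + k)) / (1 + step * beta / 2)
    return y


@pytest.fixture(scope="module")
def tf_bank():
    """Four diverse TF trajectories sampled on the uniform grid."""
    profs = generate_tf_profiles(4, GRID, seed=21)
    return {name: p.mean_profile() for name, p in profs.items()}


class TestInterpolation:
    def test_grid_size(self):
        p = design_profile("G", [1, 2, 3, 2, 1])
        out = interpolate_profile(p, 0.5)
        assert out.n_times == 97
        assert out.times[0] == 0.0 and out.times[-1] == 48.0

    def test_constant_profile_stays_constant(self):
        p = design_profile("G", [2.0] * 5)
        for kind in ("log-cubic", "cubic", "pchip", "linear"):
            out = interpolate_profile(p, 0.5, kind)
            assert np.allclose(out.mean_profile(), 2.0)

    def test_design_values_reproduced(self):
        p = design_profile("G", [1.0, 1.5, 2.5, 4.0, 3.0])
        out = interpolate_profile(p, 0.5)
        for t, v in zip(p.times, p.mean_profile()):
            j = int(round(t / 0.5))
            assert out.mean_profile()[j] == pytest.approx(v, abs=1e-9)

    def test_step_larger_than_span_rejected(self):
        with pytest.raises(GridError):
            interpolate_profile(design_profile("G", [1, 2, 3, 2, 1]), 50.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            interpolate_profile(design_profile("G", [1, 2, 3, 2, 1]), 0.5, "quintic")

    def test_two_points_fall_back_to_linear(self):
        p = TimeSeriesExpression("G", np.array([0.0, 48.0]), np.array([1.0, 3.0]))
        out = interpolate_profile(p, 0.5)
        assert np.allclose(out.mean_profile(), 1.0 + 2.0 * out.times / 48.0)


class TestSigmoid:
    PARAMS = SigmoidParams(r=1.0, means={"A": 2.0}, scales={"A": 0.5})

    def test_midpoint_is_half(self):
        assert sigmoid_activity(2.0, self.PARAMS, "A") == pytest.approx(0.5)

    def test_antisymmetry(self):
        for d in (0.1, 1.0, 7.3):
            total = sigmoid_activity(2.0 + d, self.PARAMS, "A") + sigmoid_activity(
                2.0 - d, self.PARAMS, "A"
            )
            assert total == pytest.approx(1.0)

    def test_saturation(self):
        assert sigmoid_activity(2.0 + 20 * 0.5, self.PARAMS, "A") == pytest.approx(1.0, abs=1e-8)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            SigmoidParams(r=0.0, means={}, scales={})

    def test_calibration_from_profiles(self, tf_bank):
        params = SigmoidParams.from_profiles(tf_bank)
        for name, z in tf_bank.items():
            assert params.means[name] == pytest.approx(z.mean())
            assert params.scales[name] == pytest.approx(z.std())


class TestRegressionSystem:
    def test_row_count(self, tf_bank):
        name, z = next(iter(tf_bank.items()))
        params = SigmoidParams.from_profiles({name: z})
        sys_ = build_regression_system(
            uniform_profile("G", np.linspace(1, 2, 97)),
            {name: uniform_profile(name, z)},
            params, 0.5,
        )
        assert sys_.n_obs == 96
        assert sys_.design.shape == (96, 3)

    def test_zero_regulators_two_columns(self):
        params = SigmoidParams.from_profiles({})
        sys_ = build_regression_system(
            uniform_profile("G", np.linspace(1, 2, 97)), {}, params, 0.5
        )
        assert sys_.labels == ("-y", "const")
        assert sys_.design.shape == (96, 2)

    def test_constant_target_degenerate(self):
        """y == c with no regulators: response is 0 and the steady-state
        relation k = beta * c leaves (beta, k) unidentifiable — the -y and
        constant columns are collinear and the fit reports them."""
        params = SigmoidParams.from_profiles({})
        sys_ = build_regression_system(
            uniform_profile("G", np.full(97, 3.0)), {}, params, 0.5
        )
        assert np.allclose(sys_.response, 0.0)
        with pytest.raises(SingularityError) as err:
            ml_fit(sys_)
        assert set(err.value.columns) <= {"-y", "const"}

    def test_grid_mismatch_rejected(self, tf_bank):
        name, z = next(iter(tf_bank.items()))
        params = SigmoidParams.from_profiles({name: z})
        other = TimeSeriesExpression(name, 0.5 * np.arange(10), z[:10])
        with pytest.raises(AlignmentError):
            build_regression_system(
                uniform_profile("G", np.linspace(1, 2, 97)), {name: other}, params, 0.5
            )


class TestMLFit:
    def test_noise_free_recovery_exact(self, tf_bank):
        """Data from the exactly consistent discrete system: parameters back
        to within 1e-6 relative error."""
        params = SigmoidParams.from_profiles(tf_bank)
        b = {"TF001": 1.4, "TF002": -0.8, "TF003": 0.5, "TF004": 2.0}
        y = simulate_discrete(tf_bank, params, b, beta=0.3, k=1.1, step=0.5, y0=2.0)
        sys_ = build_regression_system(
            uniform_profile("G", y),
            {n: uniform_profile(n, z) for n, z in tf_bank.items()},
            params, 0.5,
        )
        fit = ml_fit(sys_)
        assert fit.beta == pytest.approx(0.3, rel=1e-6)
        assert fit.k == pytest.approx(1.1, rel=1e-6)
        for tf, val in b.items():
            assert fit.b[tf] == pytest.approx(val, rel=1e-6)

    def test_matches_normal_equations_oracle(self):
        """lstsq solution equals (A'A)^-1 A'y to 1e-8 on random systems."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n, p = int(rng.integers(10, 60)), int(rng.integers(2, 8))
            A = rng.normal(size=(n, p))
            yv = rng.normal(size=n)
            labels = tuple(f"C{i}" for i in range(p - 2)) + ("-y", "const")
            sys_ = RegressionSystem("G", np.arange(n + 1.0), yv, A, labels)
            fit = ml_fit(sys_)
            oracle = np.linalg.solve(A.T @ A, A.T @ yv)
            got = np.array([fit.b[l] for l in labels[:-2]] + [fit.beta, fit.k])
            assert np.max(np.abs(got - oracle)) < 1e-8

    def test_loglik_and_sigma2_definition(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(30, 3))
        yv = rng.normal(size=30)
        sys_ = RegressionSystem("G", np.arange(31.0), yv, A, ("C0", "-y", "const"))
        fit = ml_fit(sys_)
        resid = yv - A @ np.linalg.solve(A.T @ A, A.T @ yv)
        sigma2 = resid @ resid / 30
        assert fit.sigma2 == pytest.approx(sigma2)
        assert fit.loglik == pytest.approx(-0.5 * 30 * (np.log(2 * np.pi * sigma2) + 1))

    def test_zero_variance_response_floored_not_crashed(self):
        sys_ = RegressionSystem(
            "G", np.arange(11.0), np.zeros(10),
            np.column_stack([np.arange(10.0), np.ones(10)]), ("-y", "const"),
        )
        fit = ml_fit(sys_)
        assert fit.sigma2 == 0.0
        assert "sigma2_floored" in fit.flags
        assert np.isfinite(fit.aic)

    def test_rank_deficient_names_columns(self):
        x = np.linspace(0, 1, 20)
        A = np.column_stack([x, 2 * x, np.ones(20)])
        sys_ = RegressionSystem("G", np.arange(21.0), x, A, ("TFA", "TFB", "const"))
        with pytest.raises(SingularityError) as err:
            ml_fit(sys_)
        assert set(err.value.columns) & {"TFA", "TFB"}

    def test_more_params_than_rows_rejected(self):
        A = np.ones((2, 3))
        sys_ = RegressionSystem("G", np.arange(3.0), np.ones(2), A, ("A", "-y", "const"))
        with pytest.raises(IdentifiabilityError):
            ml_fit(sys_)


class TestAICScore:
    def test_penalty_arithmetic(self):
        assert aic_score(2.0, 50, 3) - aic_score(2.0, 50, 5) == pytest.approx(-4.0)

    def test_formula_value(self):
        assert aic_score(1.0, 96, 4) == pytest.approx(8.0)

    def test_floor_guards_log_zero(self):
        assert np.isfinite(aic_score(0.0, 96, 4))
        assert aic_score(0.0, 96, 4) == pytest.approx(96 * np.log(1e-12) + 8)


def _pruning_dataset(tf_bank, true_b, beta=0.3, k=1.1):
    """Uniform-grid dataset whose target follows the discrete model driven
    by a subset of the TF bank, sampled noise-free."""
    params = SigmoidParams.from_profiles(tf_bank)
    y = simulate_discrete(tf_bank, params, true_b, beta=beta, k=k, step=0.5, y0=2.0)
    target = uniform_profile("G001", y)
    profiles = [target] + [uniform_profile(n, z) for n, z in tf_bank.items()]
    return ExpressionDataset("cond", profiles)


class TestPruning:
    def test_noise_free_recovery_both_modes(self, tf_bank):
        """True regulators {TF001, TF002} among four candidates survive and
        both decoys are eliminated, by greedy and exhaustive search."""
        true_b = {"TF001": 1.4, "TF002": -0.9}
        ds = _pruning_dataset(tf_bank, true_b)
        for mode in ("greedy_backward", "exhaustive"):
            fit = prune_regulators(
                ds["G001"], sorted(tf_bank), ds, mode=mode, interp_kind="linear"
            )
            assert set(fit.regulators) == set(true_b), mode
            assert fit.b["TF001"] > 0 and fit.b["TF002"] < 0

    def test_single_true_candidate_retained(self, tf_bank):
        true_b = {"TF003": 1.2}
        ds = _pruning_dataset(tf_bank, true_b)
        fit = prune_regulators(ds["G001"], ["TF003"], ds, interp_kind="linear")
        assert fit.regulators == ("TF003",)

    def test_empty_candidates_regulator_free_fit(self, tf_bank):
        ds = _pruning_dataset(tf_bank, {"TF001": 1.0})
        fit = prune_regulators(ds["G001"], [], ds)
        assert fit.regulators == ()
        assert np.isfinite(fit.aic)

    def test_trace_strictly_decreasing(self, tf_bank):
        true_b = {"TF001": 1.4, "TF002": -0.9}
        ds = _pruning_dataset(tf_bank, true_b)
        fit = prune_regulators(ds["G001"], sorted(tf_bank), ds, interp_kind="linear")
        aics = [a for _, a in fit.trace]
        assert all(a2 < a1 for a1, a2 in zip(aics, aics[1:]))

    def test_greedy_never_beats_exhaustive(self, small_study):
        ds = small_study.datasets["PSI-to-PSII"]
        truth = small_study.truths["PSI-to-PSII"]
        for target in list(truth.regulators)[:4]:
            cands = sorted(truth.tf_means)[:6]
            fg = prune_regulators(ds[target], cands, ds, mode="greedy_backward")
            fe = prune_regulators(ds[target], cands, ds, mode="exhaustive")
            assert fg.aic >= fe.aic - 1e-9

    def test_exhaustive_cap_falls_back_to_greedy(self, tf_bank):
        ds = _pruning_dataset(tf_bank, {"TF001": 1.0})
        with pytest.warns(RuntimeWarning):
            fit = prune_regulators(
                ds["G001"], sorted(tf_bank), ds, mode="exhaustive", exhaustive_cap=2
            )
        assert np.isfinite(fit.aic)


class TestEstimator:
    def _xy(self, tf_bank):
        import pandas as pd

        params = SigmoidParams.from_profiles(tf_bank)
        true_b = {"TF001": 1.3, "TF004": -1.0}
        y = simulate_discrete(tf_bank, params, true_b, beta=0.25, k=0.9, step=0.5, y0=1.5)
        X = pd.DataFrame({n: tf_bank[n] for n in sorted(tf_bank)})
        return X, y

    def test_selects_true_regulators(self, tf_bank):
        X, y = self._xy(tf_bank)
        sel = AICRegulatorPruner(step=0.5).fit(X, y)
        chosen = set(np.asarray(X.columns)[sel.support_])
        assert chosen == {"TF001", "TF004"}
        assert sel.transform(X).shape == (97, 2)

    def test_sklearn_protocol(self, tf_bank):
        X, y = self._xy(tf_bank)
        sel = AICRegulatorPruner(step=0.5, mode="exhaustive")
        cloned = clone(sel)
        assert cloned.get_params()["mode"] == "exhaustive"
        pipe = Pipeline([("select", AICRegulatorPruner(step=0.5))])
        pipe.fit(X, y)
        assert pipe.named_steps["select"].b_.shape == (4,)

    def test_fitted_attributes(self, tf_bank):
        X, y = self._xy(tf_bank)
        sel = AICRegulatorPruner(step=0.5).fit(X, y)
        assert sel.n_features_in_ == 4
        assert np.isfinite(sel.aic_) and np.isfinite(sel.loglik_)
        assert sel.beta_ == pytest.approx(0.25, rel=1e-4)
        assert sel.k_ == pytest.approx(0.9, rel=1e-4)


class TestRefineNetwork:
    @staticmethod
    def _rough_from(study, label):
        from lightgrn.rough import build_rough_network

        return build_rough_network(
            study.seed_genes, study.candidates, study.datasets[label]
        )

    def test_refined_edges_subset_of_rough(self, small_study):
        label = "PSI-to-PSII"
        rough = self._rough_from(small_study, label)
        refined = refine_network(rough, small_study.datasets[label])
        assert refined.edge_set() <= {e.pair for e in rough.edges}
        assert refined.n_edges <= rough.n_edges

    def test_zero_edge_rough_network(self, small_study):
        label = "PSI-to-PSII"
        ds = small_study.datasets[label]
        rough = RoughNetwork(label, (), frozenset(ds.genes))
        refined = refine_network(rough, ds)
        assert refined.n_edges == 0
        assert len(refined.fits) == len(ds.genes)

    def test_target_order_invariance(self, small_study):
        """Per-target independence: reversing edge order leaves the result
        unchanged."""
        label = "PSII-to-PSI"
        rough = self._rough_from(small_study, label)
        ds = small_study.datasets[label]
        a = refine_network(rough, ds)
        reversed_net = RoughNetwork(rough.condition, tuple(reversed(rough.edges)), rough.genes)
        b = refine_network(reversed_net, ds)
        assert a.edge_set() == b.edge_set()
        for (u, v) in a.edge_set():
            assert a.graph.edges[u, v]["weight"] == pytest.approx(
                b.graph.edges[u, v]["weight"]
            )

    def test_edge_signs_follow_b(self, small_study):
        label = "PSI-to-PSII"
        rough = self._rough_from(small_study, label)
        refined = refine_network(rough, small_study.datasets[label])
        for u, v, d in refined.graph.edges(data=True):
            assert d["sign"] == ("activates" if d["weight"] > 0 else "represses")
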