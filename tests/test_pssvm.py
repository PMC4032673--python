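import numpy as np
import pytest
from scipy.optimize import minimize

from palmgeo import (
    InvalidHyperparameterError,
    InvalidInputError,
    LabeledDataset,
    PssvmHyperparams,
    PssvmModel,
    SolverConfig,
    SplitError,
    fit_classifier,
    gradient_hessian,
    objective,
    predict,
    smooth_plus,
    smooth_plus_d1,
    smooth_plus_d2,
    split_train_test,
    train,
)


def random_problem(rng, m=20, n=2):
    X = rng.normal(size=(m, n))
    y = np.where(rng.random(m) < 0.5, 1, -1)
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    return LabeledDataset(X=X, y=y)


def theta_of(model: PssvmModel) -> np.ndarray:
    return np.concatenate([model.omega, [model.gamma]])


class TestSmoothPlus:
    @pytest.mark.parametrize(
        "x, k, expected",
        [
            (2.0, 1.0, 2.0),  # linear branch
            (-2.0, 1.0, 0.0),  # zero branch
            (0.0, 1.0, 0.1875),  # cubic at 0: 3/16
            (1.0, 1.0, 1.0),  # breakpoint joins linear branch
            (-1.0, 1.0, 0.0),  # breakpoint joins zero branch
        ],
    )
    def test_branch_values(self, x, k, expected):
        assert smooth_plus(x, k) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("k", [1.0, 10.0, 100.0])
    def test_continuity_at_breakpoints(self, k):
        # the cubic branch evaluated at +-1/k must match the outer branches,
        # for both h and h' (one-sided limits agree)
        for x0, h_ref, d1_ref in ((1 / k, 1 / k, 1.0), (-1 / k, 0.0, 0.0)):
            assert smooth_plus(x0, k) == pytest.approx(h_ref, abs=1e-12)
            assert smooth_plus_d1(x0, k) == pytest.approx(d1_ref, abs=1e-12)
            eps = 1e-9 / k
            for x in (x0 - eps, x0 + eps):
                assert abs(smooth_plus(x, k) - h_ref) <= 2 * eps + 1e-12
                assert abs(smooth_plus_d1(x, k) - d1_ref) <= 10 * k * eps + 1e-12

    @pytest.mark.parametrize("k", [1.0, 10.0, 100.0])
    def test_max_deviation_from_plus_function(self, k):
        """sup_x |h(x,k) - max(x,0)| = 3/(16k), attained at x = 0."""
        x = np.linspace(-2 / k, 2 / k, 200_001)
        dev = np.abs(smooth_plus(x, k) - np.maximum(x, 0.0))
        assert dev.max() == pytest.approx(3 / (16 * k), abs=1e-12)
        assert abs(x[dev.argmax()]) <= 2 / k / 200_000 + 1e-15

    def test_exact_outside_band(self, rng):
        k = 7.0
        x = rng.uniform(1 / k + 1e-9, 50, size=100)
        assert (smooth_plus(x, k) == x).all()
        assert (smooth_plus(-x, k) == 0.0).all()

    def test_convex_second_derivative_nonnegative(self):
        k = 3.0
        x = np.linspace(-1 / k, 1 / k, 1001)
        assert (smooth_plus_d2(x, k) >= 0).all()

    def test_invalid_k_rejected(self):
        with pytest.raises(InvalidHyperparameterError):
            smooth_plus(1.0, 0.0)
        with pytest.raises(InvalidHyperparameterError):
            PssvmHyperparams(nu=1.0, k=-2.0)


class TestObjective:
    def test_value_at_origin(self, rng):
        # r_i = 1 > 1/k for k = 2, so h = 1 and F(0) = nu * m / 2
        data = random_problem(rng, m=13, n=3)
        hp = PssvmHyperparams(nu=5.0, k=2.0)
        omega = np.zeros(3)
        assert objective(omega, 0.0, data, hp) == pytest.approx(5.0 * 13 / 2)

    def test_separated_data_loses_only_regularizer(self):
        # margins >= 1 + 1/k make every h term vanish
        X = np.array([[-10.0], [10.0]])
        data = LabeledDataset(X=X, y=np.array([-1, 1]))
        hp = PssvmHyperparams(nu=100.0, k=10.0)
        omega = np.array([1.0])
        assert objective(omega, 0.0, data, hp) == pytest.approx(0.5)

    def test_regularizer_lower_bound(self, rng):
        data = random_problem(rng)
        hp = PssvmHyperparams()
        for _ in range(20):
            omega = rng.normal(size=2)
            gamma = rng.normal()
            assert objective(omega, gamma, data, hp) >= 0.5 * (
                omega @ omega + gamma**2
            ) - 1e-12

    def test_convexity_along_segments(self, rng):
        data = random_problem(rng, m=15)
        hp = PssvmHyperparams(nu=3.0, k=4.0)
        for _ in range(30):
            p, q = rng.normal(size=(2, 3)) * 3
            t = rng.random()
            mid = t * p + (1 - t) * q
            f = lambda v: objective(v[:2], v[2], data, hp)
            assert f(mid) <= t * f(p) + (1 - t) * f(q) + 1e-12

    def test_dimension_mismatch_rejected(self, rng):
        data = random_problem(rng)
        with pytest.raises(InvalidInputError):
            objective(np.zeros(5), 0.0, data, PssvmHyperparams())


class TestDerivatives:
    def test_gradient_matches_finite_differences(self, rng):
        data = random_problem(rng, m=20, n=3)
        hp = PssvmHyperparams(nu=7.0, k=5.0)
        eps = 1e-6
        for _ in range(20):
            theta = rng.normal(size=4)
            grad, _ = gradient_hessian(theta[:3], theta[3], data, hp)
            fd = np.empty(4)
            for j in range(4):
                e = np.zeros(4)
                e[j] = eps
                fp = objective((theta + e)[:3], (theta + e)[3], data, hp)
                fm = objective((theta - e)[:3], (theta - e)[3], data, hp)
                fd[j] = (fp - fm) / (2 * eps)
            assert np.linalg.norm(fd - grad) / max(np.linalg.norm(grad), 1.0) <= 1e-5

    def test_hessian_spd_and_symmetric(self, rng):
        data = random_problem(rng, m=25, n=3)
        hp = PssvmHyperparams(nu=50.0, k=8.0)
        for _ in range(25):
            theta = rng.normal(size=4) * 2
            _, hess = gradient_hessian(theta[:3], theta[3], data, hp)
            assert np.allclose(hess, hess.T)
            assert np.linalg.eigvalsh(hess).min() >= 1 - 1e-9


class TestTrain:
    def test_two_point_problem(self):
        data = LabeledDataset(X=np.array([[-1.0], [1.0]]), y=np.array([-1, 1]))
        hp = PssvmHyperparams(nu=100.0, k=10.0)
        model = train(data, hp)
        assert model.converged
        assert model.final_gradient_norm <= 1e-8
        assert predict(model, data.X).tolist() == [-1, 1]
        res = minimize(
            lambda th: objective(th[:1], th[1], data, hp),
            np.zeros(2),
            method="Nelder-Mead",
            options=dict(xatol=1e-12, fatol=1e-14, maxfev=50_000),
        )
        assert objective(model.omega, model.gamma, data, hp) <= res.fun + 1e-8

    def test_matches_derivative_free_oracle(self, rng):
        hp = PssvmHyperparams(nu=10.0, k=5.0)
        for _ in range(10):
            data = random_problem(rng, m=20, n=2)
            model = train(data, hp)
            fun = lambda th: objective(th[:2], th[2], data, hp)
            res = minimize(
                fun, np.zeros(3), method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-12, maxiter=20_000, maxfev=20_000),
            )
            assert np.linalg.norm(theta_of(model) - res.x) <= 1e-4
            assert abs(fun(theta_of(model)) - res.fun) <= 1e-8

    def test_start_point_invariance(self, rng):
        data = random_problem(rng, m=30, n=3)
        hp = PssvmHyperparams(nu=20.0, k=10.0)
        ref = theta_of(train(data, hp))
        for _ in range(5):
            model = train(data, hp, x0=rng.normal(size=4) * 10)
            assert np.linalg.norm(theta_of(model) - ref) <= 1e-6

    def test_duplicating_samples_equals_halving_nu(self, rng):
        data = random_problem(rng, m=15, n=2)
        doubled = LabeledDataset(
            X=np.vstack([data.X, data.X]), y=np.concatenate([data.y, data.y])
        )
        m1 = train(data, PssvmHyperparams(nu=50.0, k=10.0))
        m2 = train(doubled, PssvmHyperparams(nu=25.0, k=10.0))
        assert np.linalg.norm(theta_of(m1) - theta_of(m2)) <= 1e-7

    def test_solution_converges_as_k_grows(self):
        rng = np.random.default_rng(2)
        X = np.vstack(
            [rng.normal(-1.0, 0.8, size=(20, 2)), rng.normal(1.0, 0.8, size=(20, 2))]
        )
        data = LabeledDataset(X=X, y=np.r_[[-1] * 20, [1] * 20])
        sols = {
            k: theta_of(train(data, PssvmHyperparams(nu=1.0, k=k)))
            for k in (10, 20, 40, 80, 160)
        }
        diffs = [np.linalg.norm(sols[k] - sols[2 * k]) for k in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(diffs, diffs[1:]))

    def test_single_class_rejected(self, rng):
        data = LabeledDataset(X=rng.normal(size=(5, 2)), y=np.ones(5, dtype=int))
        with pytest.raises(InvalidInputError):
            train(data)

    def test_nonconvergence_flagged_not_raised(self, rng):
        data = random_problem(rng)
        with pytest.warns(RuntimeWarning):
            model = train(data, config=SolverConfig(tol=1e-16, max_iter=1))
        assert not model.converged


class TestPredict:
    def test_sign_rule_with_tie(self):
        model = PssvmModel(
            omega=np.array([1.0, 0.0]), gamma=1.0,
            hyperparams=PssvmHyperparams(), converged=True,
            final_gradient_norm=0.0,
        )
        assert predict(model, np.array([2.0, 0.0])) == 1
        assert predict(model, np.array([0.0, 0.0])) == -1
        assert predict(model, np.array([1.0, 5.0])) == 1  # on the plane -> +1

    def test_standardization_round_trips_through_dict(self, rng):
        data = random_problem(rng, m=30, n=3)
        model = fit_classifier(data, PssvmHyperparams(nu=10.0, k=10.0))
        clone = PssvmModel.from_dict(model.to_dict())
        x = rng.normal(size=(8, 3)) * 5
        assert (predict(model, x) == predict(clone, x)).all()

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_classifier(random_problem(rng, n=3))
        with pytest.raises(InvalidInputError):
            predict(model, np.zeros(2))


class TestSplit:
    def test_database_shaped_split(self, rng):
        data = random_problem(rng, m=180, n=3)
        train_set, test_set = split_train_test(data, 0.2, seed=4)
        assert (train_set.m, test_set.m) == (36, 144)

    def test_small_even_split(self, rng):
        data = LabeledDataset(X=rng.normal(size=(4, 2)), y=np.array([1, 1, -1, -1]))
        for seed in range(20):
            try:
                tr, te = split_train_test(data, 0.5, seed=seed)
            except SplitError:
                continue  # single-class draw: legitimately refused
            assert (tr.m, te.m) == (2, 2)

    def test_deterministic_given_seed(self, rng):
        data = random_problem(rng, m=50)
        a = split_train_test(data, 0.3, seed=9)
        b = split_train_test(data, 0.3, seed=9)
        assert (a[0].X == b[0].X).all()
        assert (a[1].y == b[1].y).all()

    def test_disjoint_and_exhaustive(self, rng):
        data = LabeledDataset(
            X=np.arange(40, dtype=float).reshape(20, 2),
            y=np.where(np.arange(20) % 2 == 0, 1, -1),
        )
        tr, te = split_train_test(data, 0.25, seed=0)
        seen = np.sort(np.concatenate([tr.X[:, 0], te.X[:, 0]]))
        assert (seen == data.X[:, 0]).all()

    def test_bad_fraction_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            split_train_test(random_problem(rng), 1.5, seed=0)
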