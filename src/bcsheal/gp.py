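"""Gaussian-process surrogates for healing and cosmetic outcomes.

Implements standard GP regression with a squared-exponential (SE) ARD
kernel, maximum-marginal-likelihood hyperparameter fitting (multi-restart
L-BFGS-B with analytic gradients), and the two-level nonlinear
autoregressive multi-fidelity GP (NARGP): the second level is a standard
GP over the augmented input ``(x, f1*(x))`` with the composite kernel
``k_rho(x, x') * k_f(f, f') + k_delta(x, x')``, every factor SE.  The
multi-fidelity posterior at a new point is obtained by Monte Carlo
propagation of the level-1 posterior through the level-2 predictive law.

All kernels operate on pre-scaled inputs (see :class:`InputScaler`);
outputs are z-scored internally per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .cohort import TABLE_RANGES, TABLE_MEDIANS

__all__ = [
    "SEKernel",
    "ProductKernel",
    "SumKernel",
    "GPModel",
    "MFGPModel",
    "InputScaler",
    "ValidationReport",
    "validate",
    "fit_visibility_classifier",
    "prediction_maps",
]

JITTER_LADDER = (0.0, 1e-10, 1e-8, 1e-6)


# ---------------------------------------------------------------------------
# kernels


class SEKernel:
    """Squared-exponential ARD kernel over a subset of input columns.

    Parameters (log scale): ``[log signal variance, log lengthscale_1..d]``.
    """

    def __init__(self, dims):
        self.dims = np.atleast_1d(np.asarray(dims, dtype=int))
        self.n_params = 1 + len(self.dims)

    def init_params(self):
        return np.zeros(self.n_params)

    def lengthscale_mask(self):
        m = np.zeros(self.n_params, dtype=bool)
        m[1:] = True
        return m

    def _sq(self, theta, X, Z):
        ls = np.exp(theta[1:])
        Xs = X[:, self.dims] / ls
        Zs = Z[:, self.dims] / ls
        d2 = (
            np.sum(Xs**2, axis=1)[:, None]
            + np.sum(Zs**2, axis=1)[None, :]
            - 2.0 * Xs @ Zs.T
        )
        return np.maximum(d2, 0.0)

    def cross(self, theta, X, Z):
        return np.exp(theta[0]) * np.exp(-0.5 * self._sq(theta, X, Z))

    def diag(self, theta, X):
        return np.full(len(X), np.exp(theta[0]))

    def forward(self, theta, X):
        """Symmetric kernel matrix and per-parameter gradients."""
        K = self.cross(theta, X, X)
        grads = [K.copy()]  # d/d log variance
        ls = np.exp(theta[1:])
        for j, d in enumerate(self.dims):
            diff = (X[:, d][:, None] - X[:, d][None, :]) / ls[j]
            grads.append(K * diff**2)  # d/d log lengthscale_j
        return K, grads


class ProductKernel:
    def __init__(self, k1, k2):
        self.k1, self.k2 = k1, k2
        self.n_params = k1.n_params + k2.n_params

    def init_params(self):
        return np.concatenate([self.k1.init_params(), self.k2.init_params()])

    def lengthscale_mask(self):
        return np.concatenate([self.k1.lengthscale_mask(), self.k2.lengthscale_mask()])

    def _split(self, theta):
        return theta[: self.k1.n_params], theta[self.k1.n_params :]

    def cross(self, theta, X, Z):
        t1, t2 = self._split(theta)
        return self.k1.cross(t1, X, Z) * self.k2.cross(t2, X, Z)

    def diag(self, theta, X):
        t1, t2 = self._split(theta)
        return self.k1.diag(t1, X) * self.k2.diag(t2, X)

    def forward(self, theta, X):
        t1, t2 = self._split(theta)
        K1, g1 = self.k1.forward(t1, X)
        K2, g2 = self.k2.forward(t2, X)
        return K1 * K2, [g * K2 for g in g1] + [K1 * g for g in g2]


class SumKernel:
    def __init__(self, k1, k2):
        self.k1, self.k2 = k1, k2
        self.n_params = k1.n_params + k2.n_params

    def init_params(self):
        return np.concatenate([self.k1.init_params(), self.k2.init_params()])

    def lengthscale_mask(self):
        return np.concatenate([self.k1.lengthscale_mask(), self.k2.lengthscale_mask()])

    def _split(self, theta):
        return theta[: self.k1.n_params], theta[self.k1.n_params :]

    def cross(self, theta, X, Z):
        t1, t2 = self._split(theta)
        return self.k1.cross(t1, X, Z) + self.k2.cross(t2, X, Z)

    def diag(self, theta, X):
        t1, t2 = self._split(theta)
        return self.k1.diag(t1, X) + self.k2.diag(t2, X)

    def forward(self, theta, X):
        t1, t2 = self._split(theta)
        K1, g1 = self.k1.forward(t1, X)
        K2, g2 = self.k2.forward(t2, X)
        return K1 + K2, g1 + g2


def nargp_kernel(d: int):
    """Level-2 NARGP kernel on ``(x_1..x_d, f)``:
    ``k_rho(x) * k_f(f) + k_delta(x)``."""
    return SumKernel(
        ProductKernel(SEKernel(range(d)), SEKernel([d])),
        SEKernel(range(d)),
    )


# ---------------------------------------------------------------------------
# GP regression


@dataclass
class GPModel:
    """GP regression with SE-type kernel and learned Gaussian noise.

    The last entry of ``params`` is the log noise variance; outputs are
    z-scored internally.  ``fit`` maximizes the marginal log-likelihood
    ``-1/2 y^T (K + s2 I)^-1 y - 1/2 log |K + s2 I| - n/2 log 2 pi`` by
    multi-restart quasi-Newton ascent with analytic gradients.
    """

    kernel: object
    params: np.ndarray | None = None
    X: np.ndarray | None = None
    y_mean: float = 0.0
    y_std: float = 1.0
    noise_floor: float = 1e-12
    _alpha: np.ndarray = field(default=None, repr=False)
    _chol: tuple = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)

    # -- likelihood --------------------------------------------------------

    def _gram(self, theta, X):
        K, grads = self.kernel.forward(theta[:-1], X)
        s2 = np.exp(theta[-1]) + self.noise_floor
        Ky = K + s2 * np.eye(len(X))
        return Ky, grads, s2

    def _chol_with_jitter(self, Ky):
        scale = float(np.trace(Ky)) / len(Ky)
        for j in JITTER_LADDER:
            try:
                return cho_factor(Ky + j * scale * np.eye(len(Ky)), lower=True)
            except np.linalg.LinAlgError:
                continue
        raise np.linalg.LinAlgError("covariance not positive definite after max jitter")

    def log_marginal_likelihood(self, theta, X, y, with_grad=False):
        Ky, grads, s2 = self._gram(theta, X)
        c = self._chol_with_jitter(Ky)
        alpha = cho_solve(c, y)
        n = len(y)
        mll = -0.5 * y @ alpha - np.log(np.diag(c[0])).sum() - 0.5 * n * np.log(2 * np.pi)
        if not with_grad:
            return mll
        Kinv = cho_solve(c, np.eye(n))
        W = np.outer(alpha, alpha) - Kinv
        g = np.array([0.5 * np.sum(W * dK) for dK in grads] + [0.5 * np.sum(np.diag(W)) * s2])
        return mll, g

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, restarts: int = 6, seed: int = 0, init_noise: float = 1e-4,
            fix_noise: float | None = None, prior_scale: float | None = None):
        """Fit hyperparameters by maximum marginal likelihood.

        ``fix_noise`` pins the noise variance (excluded from optimization);
        used for noise-free interpolation of deterministic simulator output.
        ``prior_scale`` adds a weak log-normal prior (sd in log space) on the
        kernel hyperparameters about unit variance / unit lengthscale — a MAP
        fit that keeps small-data fits from collapsing onto degenerate
        lengthscales.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) < 2:
            raise ValueError("need at least 2 training points")
        self.y_mean = float(y.mean())
        self.y_std = float(y.std()) or 1.0
        ys = (y - self.y_mean) / self.y_std
        rng = np.random.default_rng(seed)

        if prior_scale is not None:
            lam = 0.5 / prior_scale**2
        if fix_noise is not None:
            log_fix = np.log(fix_noise) if fix_noise > 0 else -50.0

            def neg(theta_k):
                theta = np.concatenate([theta_k, [log_fix]])
                mll, g = self.log_marginal_likelihood(theta, X, ys, with_grad=True)
                f, gr = -mll, -g[:-1]
                if prior_scale is not None:
                    f += lam * np.sum(theta_k**2)
                    gr = gr + 2 * lam * theta_k
                return f, gr
        else:
            def neg(theta):
                mll, g = self.log_marginal_likelihood(theta, X, ys, with_grad=True)
                f, gr = -mll, -g
                if prior_scale is not None:
                    f += lam * np.sum(theta[:-1]**2)
                    gr = gr + 2 * lam * np.concatenate([theta[:-1], [0.0]])
                return f, gr

        # deterministic initial points spanning plausible lengthscales and
        # noise levels (guards against the all-noise local optimum), then
        # seeded random perturbations
        kp = self.kernel.init_params()
        if fix_noise is not None:
            ls_mask = self.kernel.lengthscale_mask()
            starts = [kp + log_ls * ls_mask for log_ls in (np.log(0.3), 0.0, np.log(3.0))]
        else:
            ls_mask = np.concatenate([self.kernel.lengthscale_mask(), [False]])
            starts = [
                np.concatenate([kp, [np.log(nz)]]) + log_ls * ls_mask
                for log_ls in (np.log(0.3), 0.0)
                for nz in (init_noise, 1e-2)
            ]
        base = starts[0]
        for r in range(max(restarts - len(starts), 0)):
            starts.append(base + rng.normal(0.0, 1.0, size=base.shape))
        best, best_val = None, np.inf
        for t0 in starts[: max(restarts, len(starts))]:
            try:
                res = minimize(neg, t0, jac=True, method="L-BFGS-B",
                               bounds=[(-12.0, 10.0)] * len(base),
                               options={"maxiter": 200})
            except np.linalg.LinAlgError:
                continue
            if res.fun < best_val:
                best, best_val = res.x, res.fun
        if best is None:
            raise RuntimeError("all hyperparameter restarts failed")
        if fix_noise is not None:
            log_fix = np.log(fix_noise) if fix_noise > 0 else -50.0
            best = np.concatenate([best, [log_fix]])
        self.params = best
        self.X = X
        self._y = ys
        Ky, _, _ = self._gram(best, X)
        self._chol = self._chol_with_jitter(Ky)
        self._alpha = cho_solve(self._chol, ys)
        return self

    @property
    def noise_variance(self) -> float:
        return float(np.exp(self.params[-1]) + self.noise_floor)

    # -- prediction --------------------------------------------------------

    def predict(self, Xs, include_noise: bool = False):
        """Posterior mean and variance (original output units)."""
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        ks = self.kernel.cross(self.params[:-1], Xs, self.X)
        mean = ks @ self._alpha
        v = solve_triangular(self._chol[0], ks.T, lower=True)
        var = self.kernel.diag(self.params[:-1], Xs) - np.sum(v**2, axis=0)
        if include_noise:
            var = var + self.noise_variance
        var = np.clip(var, 0.0, None)
        return mean * self.y_std + self.y_mean, var * self.y_std**2


# ---------------------------------------------------------------------------
# multi-fidelity (NARGP)


@dataclass
class MFGPModel:
    """Two-level nonlinear autoregressive multi-fidelity GP.

    Level 1 is a standard GP on the low-fidelity data; level 2 is a GP on
    ``(x, mu_1(x))`` with the composite kernel ``k_rho * k_f + k_delta``.
    Prediction propagates level-1 posterior samples through level 2 and
    moment-matches (law of total variance).
    """

    gp1: GPModel = None
    gp2: GPModel = None
    n_dims: int = 0
    f_scale: float = 1.0  # scaling applied to the augmented column

    def fit(self, X1, y1, X2, y2, restarts: int = 6, seed: int = 0):
        X1 = np.asarray(X1, dtype=float)
        X2 = np.asarray(X2, dtype=float)
        self.n_dims = X1.shape[1]
        self.gp1 = GPModel(SEKernel(range(self.n_dims))).fit(
            X1, y1, restarts=restarts, seed=seed
        )
        f1, _ = self.gp1.predict(X2)
        sd = float(np.std(f1))
        self.f_scale = sd if sd > 0 else 1.0
        X2aug = np.column_stack([X2, f1 / self.f_scale])
        self.gp2 = GPModel(nargp_kernel(self.n_dims)).fit(
            X2aug, y2, restarts=restarts, seed=seed + 1
        )
        return self

    def predict(self, Xs, n_mc: int = 500, seed: int = 0):
        """Monte Carlo posterior mean and variance at ``Xs``."""
        if n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        mu1, var1 = self.gp1.predict(Xs)
        if np.all(var1 < 1e-14):
            Xaug = np.column_stack([Xs, mu1 / self.f_scale])
            return self.gp2.predict(Xaug)
        rng = np.random.default_rng(seed)
        draws = mu1[None, :] + np.sqrt(var1)[None, :] * rng.standard_normal((n_mc, len(Xs)))
        flat = np.column_stack([
            np.tile(Xs, (n_mc, 1)),
            (draws / self.f_scale).reshape(-1, 1),
        ])
        m2 = np.empty(len(flat))
        v2 = np.empty(len(flat))
        for i in range(0, len(flat), 20000):  # chunked: O(batch x train) memory
            m2[i:i + 20000], v2[i:i + 20000] = self.gp2.predict(flat[i:i + 20000])
        m2 = m2.reshape(n_mc, len(Xs))
        v2 = v2.reshape(n_mc, len(Xs))
        mean = m2.mean(axis=0)
        var = v2.mean(axis=0) + m2.var(axis=0)
        return mean, var


# ---------------------------------------------------------------------------
# input scaling for the patient-characteristic space


class InputScaler:
    """Scales the four patient characteristics to [0, 1] by the cohort
    ranges (plus normalized time in [0, 1] as an optional 5th column)."""

    def __init__(self, with_time: bool = False, horizon: float = 28.0):
        self.keys = list(TABLE_RANGES)
        self.lo = np.array([TABLE_RANGES[k][0] for k in self.keys])
        self.hi = np.array([TABLE_RANGES[k][1] for k in self.keys])
        self.with_time = with_time
        self.horizon = horizon

    @property
    def n_dims(self):
        return 4 + int(self.with_time)

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = (X[:, :4] - self.lo) / (self.hi - self.lo)
        if self.with_time:
            out = np.column_stack([out, X[:, 4] / self.horizon])
        return out

    def median_point(self):
        return np.array([TABLE_MEDIANS[k] for k in self.keys])


# ---------------------------------------------------------------------------
# datasets from simulation outcomes


def bsd_dataset(outcomes):
    """(X raw 4-col, y %BSD in percent) from outcome records."""
    X = np.vstack([o.characteristics.as_array() for o in outcomes])
    y = np.array([o.pbsd for o in outcomes])
    return X, y


def contraction_dataset(outcomes):
    """(X raw 5-col incl. day, y contraction fraction of excised volume)."""
    rows, ys = [], []
    for o in outcomes:
        c4 = o.characteristics.as_array()
        for d, v in zip(o.days, o.contraction):
            rows.append(np.concatenate([c4, [d]]))
            ys.append(v / 100.0)
    return np.vstack(rows), np.array(ys)


# ---------------------------------------------------------------------------
# validation protocol


@dataclass
class ValidationReport:
    n_repeats: int
    n_test: int
    rmse_contraction: list
    mae_bsd: list
    n_predictions: int
    seed: int

    @property
    def mean_rmse(self):
        return float(np.mean(self.rmse_contraction))

    @property
    def mean_mae(self):
        return float(np.mean(self.mae_bsd))


def _split_sizes(n_high: int, train_ref: int = 150, test_ref: int = 13):
    """Scale the reference 150:13 split preserving the ratio."""
    n_test = max(1, int(round(n_high * test_ref / (train_ref + test_ref))))
    return n_high - n_test, n_test


def validate(low_outcomes, high_outcomes, n_repeats: int = 20, seed: int = 0,
             restarts: int = 3, n_mc: int = 100,
             surrogates: tuple = ("bsd", "contraction")):
    """Repeated random-split validation of both multi-fidelity surrogates.

    Each repeat splits the high-fidelity set train/test in the reference
    150:13 proportion, trains the %BSD and contraction-trajectory MF
    surrogates on all low-fidelity outcomes plus the training highs, and
    scores held-out predictions: MAE for %BSD (percent points), RMSE for
    contraction (fraction of excised volume).
    """
    n_high = len(high_outcomes)
    n_train, n_test = _split_sizes(n_high)
    if n_train < 2:
        raise ValueError("not enough high-fidelity outcomes to validate")
    sc4 = InputScaler()
    sc5 = InputScaler(with_time=True)
    Xb_lo, yb_lo = bsd_dataset(low_outcomes)
    Xc_lo, yc_lo = contraction_dataset(low_outcomes)
    rng = np.random.default_rng(seed)
    rmses, maes = [], []
    n_pred = 0
    for rep in range(n_repeats):
        perm = rng.permutation(n_high)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        tr = [high_outcomes[i] for i in train_idx]
        te = [high_outcomes[i] for i in test_idx]

        if "bsd" in surrogates:
            Xb_tr, yb_tr = bsd_dataset(tr)
            Xb_te, yb_te = bsd_dataset(te)
            mf_b = MFGPModel().fit(sc4.transform(Xb_lo), yb_lo, sc4.transform(Xb_tr), yb_tr,
                                   restarts=restarts, seed=seed + 7 * rep)
            pb, _ = mf_b.predict(sc4.transform(Xb_te), n_mc=n_mc, seed=seed + rep)
            maes.append(float(np.mean(np.abs(pb - yb_te))))

        if "contraction" in surrogates:
            Xc_tr, yc_tr = contraction_dataset(tr)
            Xc_te, yc_te = contraction_dataset(te)
            mf_c = MFGPModel().fit(sc5.transform(Xc_lo), yc_lo, sc5.transform(Xc_tr), yc_tr,
                                   restarts=restarts, seed=seed + 7 * rep + 3)
            pc, _ = mf_c.predict(sc5.transform(Xc_te), n_mc=n_mc, seed=seed + rep + 1)
            rmses.append(float(np.sqrt(np.mean((pc - yc_te) ** 2))))
        n_pred += len(te)
    return ValidationReport(
        n_repeats=n_repeats, n_test=n_test, rmse_contraction=rmses,
        mae_bsd=maes, n_predictions=n_pred, seed=seed,
    )


def fit_visibility_classifier(X_raw, scores, restarts: int = 4, seed: int = 0):
    """GP regression on reviewer-consensus scores over the 4 characteristics.

    Returns ``(model, scaler)``; use :func:`predict_visibility` for clamped
    [0, 1] likelihood predictions.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("consensus scores must lie in [0, 1]")
    sc = InputScaler()
    gp = GPModel(SEKernel(range(4))).fit(sc.transform(X_raw), scores,
                                         restarts=restarts, seed=seed)
    return gp, sc


def predict_visibility(model: GPModel, scaler: InputScaler, X_raw):
    mean, var = model.predict(scaler.transform(X_raw))
    return np.clip(mean, 0.0, 1.0), var


def prediction_maps(predict_fn, vary: tuple, grid_n: int = 50, medians=None,
                    extra: dict | None = None):
    """2-D outcome maps over a pair of characteristics.

    ``predict_fn(X_raw) -> (mean, var)`` is evaluated on a ``grid_n x
    grid_n`` grid spanning the cohort ranges of the two varied
    characteristics, with the remaining characteristics held at the cohort
    medians (``grid_n = 50`` gives the 2,500-point maps).  Returns a dict
    with the grid axes and the mean / sd surfaces.
    """
    keys = list(TABLE_RANGES)
    for v in vary:
        if v not in keys:
            raise KeyError(f"unknown characteristic {v!r}")
    med = dict(TABLE_MEDIANS if medians is None else medians)
    if extra:
        med.update(extra)
    ax = {v: np.linspace(*TABLE_RANGES[v], grid_n) for v in vary}
    G1, G2 = np.meshgrid(ax[vary[0]], ax[vary[1]], indexing="ij")
    X = np.empty((grid_n * grid_n, 4))
    for j, k in enumerate(keys):
        if k == vary[0]:
            X[:, j] = G1.ravel()
        elif k == vary[1]:
            X[:, j] = G2.ravel()
        else:
            X[:, j] = med[k]
    mean, var = predict_fn(X)
    return {
        "vary": vary,
        "axis_1": ax[vary[0]],
        "axis_2": ax[vary[1]],
        "mean": np.asarray(mean).reshape(grid_n, grid_n),
        "sd": np.sqrt(np.asarray(var)).reshape(grid_n, grid_n),
    }
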