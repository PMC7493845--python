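"""Gaussian-process Bayesian optimization of the filter parameters (s, tau).

The filter response is an expensive black box of two parameters, so the
loss ``1 / max_x Bp(x; s, tau)`` is minimized with a GP surrogate and the
expected-improvement (EI) acquisition.  The surrogate is a constant-mean GP
with an ARD Matern 5/2 kernel on inputs rescaled to the unit box; amplitude,
length scales and noise are refit by marginal-likelihood maximization each
iteration.  Posterior mean and variance at a query z are the standard
conditionals

    mu(z)     = u + k(z)^T (K + sigma_n^2 I)^-1 (y - u)
    sigma2(z) = k(z, z) - k(z)^T (K + sigma_n^2 I)^-1 k(z)

with the variance clamped at zero.

An overexploitation safeguard keeps the search out of local minima: when the
posterior standard deviation at the proposed point falls below ``t_sigma``
times the fitted noise standard deviation, the kernel amplitude is inflated
(first by the current iteration index, then by successive factors of 10) and
a new point proposed, up to five retries, after which the last candidate is
accepted with a logged flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.stats import qmc

from .blob_filter import FilterParams, filter_response, lam3_reference
from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "GPModel",
    "AcquisitionState",
    "OptTrace",
    "TraceEntry",
    "gp_posterior",
    "expected_improvement",
    "overexploit_adjust",
    "bayes_optimize",
    "reciprocal_loss",
]

_JITTER = 1e-10  # floor on sigma_n^2
_MAX_RETRIES = 5


def _matern52(X1: np.ndarray, X2: np.ndarray, amplitude: float,
              length_scales: np.ndarray) -> np.ndarray:
    """ARD Matern 5/2 covariance between two point sets."""
    d = (X1[:, None, :] - X2[None, :, :]) / length_scales
    r = np.sqrt(np.sum(d * d, axis=-1))
    sr = np.sqrt(5.0) * r
    return amplitude ** 2 * (1.0 + sr + sr * sr / 3.0) * np.exp(-sr)


@dataclass
class GPModel:
    """GP surrogate over observed (s, tau) -> loss pairs.

    Inputs ``X`` live in the original parameter box; they are rescaled to
    the unit box internally via ``bounds``.  ``prior_mean`` defaults to the
    mean of the observed losses.
    """

    X: np.ndarray
    y: np.ndarray
    bounds: np.ndarray  # (2, 2): rows (low, high) per dimension
    amplitude: float = 1.0
    length_scales: np.ndarray = field(default_factory=lambda: np.array([0.3, 0.3]))
    noise_var: float = 1e-6
    prior_mean: float | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.bounds = np.asarray(self.bounds, dtype=float)
        self.length_scales = np.asarray(self.length_scales, dtype=float)
        if len(self.X) != len(self.y) or len(self.y) == 0:
            raise ValueError("need matching, non-empty X and y")
        if self.prior_mean is None:
            self.prior_mean = float(np.mean(self.y))

    # -- geometry ---------------------------------------------------------
    def _unit(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return (np.atleast_2d(X) - lo) / (hi - lo)

    def kernel_matrix(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Covariance between raw-coordinate point sets (public for oracles)."""
        return _matern52(self._unit(A), self._unit(B),
                         self.amplitude, self.length_scales)

    def _chol(self):
        K = self.kernel_matrix(self.X, self.X)
        K[np.diag_indices_from(K)] += max(self.noise_var, _JITTER)
        for boost in (0.0, 1e-8, 1e-6):
            try:
                return cho_factor(K + boost * np.eye(len(K)), lower=True)
            except np.linalg.LinAlgError:
                continue
        raise np.linalg.LinAlgError("covariance matrix singular after jitter escalation")

    # -- hyperparameters --------------------------------------------------
    def log_marginal_likelihood(self, log_params: np.ndarray) -> float:
        return self._lml_and_grad(log_params)[0]

    def _lml_and_grad(self, log_params: np.ndarray) -> tuple[float, np.ndarray]:
        """Log marginal likelihood and its analytic gradient in log space.

        Gradient: dL/dt_j = 0.5 tr((a a^T - K^-1) dK/dt_j) with
        a = K^-1 (y - u); the Matern 5/2 length-scale derivative uses
        dk/dr = -(5/3) amp^2 r (1 + sqrt(5) r) exp(-sqrt(5) r).
        """
        amp, l1, l2, noise = np.exp(log_params)
        ls = np.array([l1, l2])
        Xu = self._unit(self.X)
        diff = Xu[:, None, :] - Xu[None, :, :]
        d2 = (diff / ls) ** 2
        r = np.sqrt(np.sum(d2, axis=-1))
        sr = np.sqrt(5.0) * r
        expsr = np.exp(-sr)
        Kf = amp ** 2 * (1.0 + sr + sr * sr / 3.0) * expsr
        noise2 = max(noise ** 2, _JITTER)
        K = Kf + noise2 * np.eye(len(Kf))
        try:
            c = cholesky(K + 1e-10 * np.eye(len(K)), lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(4)
        resid = self.y - self.prior_mean
        alpha = cho_solve((c, True), resid)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        lml = float(-0.5 * resid @ alpha - 0.5 * logdet
                    - 0.5 * len(self.y) * np.log(2 * np.pi))

        Kinv = cho_solve((c, True), np.eye(len(K)))
        W = np.outer(alpha, alpha) - Kinv  # dL/dK = W / 2
        grads = np.empty(4)
        grads[0] = 0.5 * np.sum(W * (2.0 * Kf))          # d/d log amp
        dk_dr_over = -(5.0 / 3.0) * amp ** 2 * (1.0 + sr) * expsr  # dk/dr / r
        for j in range(2):
            # dK/d log l_j = (dk/dr) * dr/d log l_j = -(dk/dr / r) * d2_j
            dK = -dk_dr_over * d2[..., j]
            grads[1 + j] = 0.5 * np.sum(W * dK)
        grads[3] = 0.5 * np.trace(W) * 2.0 * noise2      # d/d log noise
        return lml, grads

    def fit_hyperparameters(self) -> "GPModel":
        """Refit amplitude, length scales and noise by maximum marginal likelihood."""
        y_std = float(np.std(self.y)) or 1.0
        starts = [
            np.log([y_std, 0.3, 0.3, 1e-3 * y_std]),
            np.log([y_std, 1.0, 1.0, 1e-2 * y_std]),
        ]
        bounds = [(np.log(1e-3 * y_std), np.log(1e3 * y_std)),
                  (np.log(0.03), np.log(10.0)),
                  (np.log(0.03), np.log(10.0)),
                  (np.log(1e-6 * y_std), np.log(1.0 * y_std))]

        def neg(lp):
            val, grad = self._lml_and_grad(lp)
            if not np.isfinite(val):
                return 1e12, np.zeros(4)
            return -val, -grad

        best, best_val = None, -np.inf
        for x0 in starts:
            res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B",
                                    bounds=bounds, options={"maxiter": 60})
            if -res.fun > best_val:
                best, best_val = res.x, -res.fun
        amp, l1, l2, noise = np.exp(best)
        return replace(self, amplitude=float(amp),
                       length_scales=np.array([l1, l2]),
                       noise_var=float(noise ** 2))

    def with_amplitude(self, amplitude: float) -> "GPModel":
        """Same data and length scales, inflated kernel amplitude."""
        return replace(self, amplitude=float(amplitude))

    @property
    def noise_std(self) -> float:
        return float(np.sqrt(max(self.noise_var, 0.0)))


def _params_to_array(p: FilterParams | Sequence[float]) -> np.ndarray:
    if isinstance(p, FilterParams):
        return np.array([p.s, p.tau], dtype=float)
    return np.asarray(p, dtype=float)


def gp_posterior(model: GPModel, query: FilterParams | Sequence[float]
                 ) -> tuple[float, float]:
    """Posterior mean and variance at a query point (variance clamped >= 0)."""
    z = _params_to_array(query)[None, :]
    c, lower = model._chol()
    resid = model.y - model.prior_mean
    alpha = cho_solve((c, lower), resid)
    kz = model.kernel_matrix(model.X, z)[:, 0]
    mean = model.prior_mean + float(kz @ alpha)
    v = cho_solve((c, lower), kz)
    var = float(model.amplitude ** 2 - kz @ v)
    return mean, max(var, 0.0)


def expected_improvement(mean: float, variance: float, f_best: float) -> float:
    """Closed-form EI for minimization; zero when nothing can improve.

    With sigma = sqrt(variance) and d = f_best - mean:
    EI = d * Phi(d / sigma) + sigma * phi(d / sigma); at sigma = 0 it
    degenerates to max(d, 0).
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    d = f_best - mean
    sigma = np.sqrt(variance)
    if sigma == 0.0:
        return max(d, 0.0)
    u = d / sigma
    return float(d * stats.norm.cdf(u) + sigma * stats.norm.pdf(u))


@dataclass
class AcquisitionState:
    """Bookkeeping for the overexploitation safeguard at one iteration."""

    f_best: float
    iteration: int
    t_sigma: float = 0.5
    retries: int = 0
    overexploited: bool = False


def _propose_ei(model: GPModel, f_best: float, rng: np.random.Generator,
                n_scan: int = 2048) -> np.ndarray:
    """Maximize EI over a Sobol scan of the box plus a local polish."""
    sob = qmc.Sobol(d=2, scramble=True,
                    seed=int(rng.integers(0, 2 ** 31 - 1)))
    unit = sob.random(n_scan)
    lo, hi = model.bounds[:, 0], model.bounds[:, 1]
    cand = lo + unit * (hi - lo)

    c, lower = model._chol()
    resid = model.y - model.prior_mean
    alpha = cho_solve((c, lower), resid)

    def ei_batch(Z: np.ndarray) -> np.ndarray:
        Kz = model.kernel_matrix(model.X, Z)
        means = model.prior_mean + Kz.T @ alpha
        V = cho_solve((c, lower), Kz)
        vars_ = np.maximum(model.amplitude ** 2 - np.sum(Kz * V, axis=0), 0.0)
        sig = np.sqrt(vars_)
        d = f_best - means
        u = np.divide(d, sig, out=np.zeros_like(d), where=sig > 0)
        return np.where(sig > 0,
                        d * stats.norm.cdf(u) + sig * stats.norm.pdf(u),
                        np.maximum(d, 0.0))

    vals = ei_batch(cand)
    x0 = cand[int(np.argmax(vals))]
    res = optimize.minimize(
        lambda z: -ei_batch(np.clip(z, lo, hi)[None, :])[0], x0,
        method="Nelder-Mead", options={"maxiter": 80, "xatol": 1e-4, "fatol": 1e-10})
    best = np.clip(res.x, lo, hi)
    if ei_batch(best[None, :])[0] < vals.max():
        best = x0
    return best


def overexploit_adjust(model: GPModel, state: AcquisitionState,
                       candidate: np.ndarray | FilterParams,
                       rng: np.random.Generator | None = None
                       ) -> np.ndarray:
    """Re-propose candidates that sit in an overexploited region.

    A candidate is overexploited when its posterior standard deviation is
    below ``t_sigma`` times the model's noise standard deviation.  The kernel
    amplitude is then inflated — first by the current iteration index, then
    by successive factors of 10 — and EI re-maximized, up to five retries.
    """
    rng = rng or np.random.default_rng(0)
    cand = _params_to_array(candidate)
    sigma_noise = model.noise_std
    work = model
    while True:
        _, var = gp_posterior(work, cand)
        if np.sqrt(var) >= sigma_noise * state.t_sigma:
            return cand
        if state.retries >= _MAX_RETRIES:
            state.overexploited = True
            logger.info("overexploitation persists after %d retries; accepting candidate",
                        _MAX_RETRIES)
            return cand
        factor = max(state.iteration, 1) if state.retries == 0 else 10.0
        work = work.with_amplitude(work.amplitude * factor)
        state.retries += 1
        cand = _propose_ei(work, state.f_best, rng)


@dataclass
class TraceEntry:
    iteration: int
    params: FilterParams
    loss: float
    best_loss: float
    overexploit: bool


@dataclass
class OptTrace:
    """Full evaluation history of one optimization run."""

    entries: list[TraceEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def best_losses(self) -> np.ndarray:
        return np.array([e.best_loss for e in self.entries])

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "s", "tau", "loss", "best_loss", "overexploit"])
            for e in self.entries:
                w.writerow([e.iteration, e.params.s, e.params.tau,
                            e.loss, e.best_loss, int(e.overexploit)])

    def plot(self, path) -> None:
        """Convergence plot: per-iteration losses and the best-so-far curve."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        it = [e.iteration for e in self.entries]
        fig, ax = plt.subplots()
        ax.plot(it, [e.loss for e in self.entries], "o", ms=4,
                label="evaluated")
        ax.plot(it, self.best_losses, "-", label="best so far")
        ax.set_xlabel("iteration")
        ax.set_ylabel("loss 1/max Bp")
        ax.legend()
        fig.savefig(path, dpi=100)
        plt.close(fig)


def bayes_optimize(objective: Callable[[FilterParams], float],
                   bounds: Sequence[Sequence[float]] = ((0.5, 20.0), (0.7, 1.0)),
                   budget: int = 50,
                   seed: int = 0,
                   n_initial: int = 4,
                   t_sigma: float = 0.5,
                   ) -> tuple[FilterParams, OptTrace]:
    """Minimize ``objective`` over the (s, tau) box with GP-EI.

    Evaluates the objective exactly ``budget`` times (a Sobol initial design
    of ``n_initial`` points, then EI proposals) and returns the argmin over
    all evaluations with the full trace.  Deterministic given ``seed``.
    Non-finite objective values are recorded as a large penalty and logged.
    """
    bounds = np.asarray(bounds, dtype=float)
    if budget < n_initial:
        raise ValueError(f"budget {budget} below initial design size {n_initial}")
    rng = np.random.default_rng(seed)
    lo, hi = bounds[:, 0], bounds[:, 1]

    sob = qmc.Sobol(d=2, scramble=True, seed=int(rng.integers(0, 2 ** 31 - 1)))
    X = list(lo + sob.random(n_initial) * (hi - lo))
    trace = OptTrace()
    ys: list[float] = []

    def record(i: int, z: np.ndarray, flag: bool) -> None:
        p = FilterParams(float(np.clip(z[0], lo[0], hi[0])),
                         float(np.clip(z[1], lo[1], hi[1])))
        val = objective(p)
        if not np.isfinite(val):
            penalty = (max(ys) * 10 if ys and np.isfinite(max(ys)) else 1e12)
            logger.warning("objective returned non-finite value at %s; recording %g",
                           p, penalty)
            val = penalty
        ys.append(float(val))
        trace.entries.append(TraceEntry(i, p, float(val), float(min(ys)), flag))

    for i, z in enumerate(X):
        record(i, np.asarray(z), False)

    for i in range(n_initial, budget):
        model = GPModel(np.array([[e.params.s, e.params.tau] for e in trace]),
                        np.array(ys), bounds)
        model = model.fit_hyperparameters()
        f_best = float(min(ys))
        cand = _propose_ei(model, f_best, rng)
        state = AcquisitionState(f_best=f_best, iteration=i, t_sigma=t_sigma)
        cand = overexploit_adjust(model, state, cand, rng)
        record(i, cand, state.overexploited)

    best = min(trace, key=lambda e: e.loss)
    return best.params, trace


def reciprocal_loss(volume: Volume, jerman_compat: bool = False,
                    lam3_ref: float | None = None,
                    exclude: np.ndarray | None = None,
                    ) -> Callable[[FilterParams], float]:
    """Loss closure ``1 / (eps + max_x Bp)`` over a preprocessed volume.

    The detection stage seeds at the global response maximum, so the maximum
    is the scalar being optimized; ``eps = 1e-12`` keeps the loss finite on
    volumes with zero response.  The cross-scale eigenvalue reference is
    precomputed once (or supplied) so every (s, tau) query shares the same
    cutoff normalization — this is what gives the loss its scale
    selectivity.
    """
    eps = 1e-12
    if lam3_ref is None:
        lam3_ref = lam3_reference(volume, exclude=exclude)

    def loss(params: FilterParams) -> float:
        resp = filter_response(volume, params, lam3_ref=lam3_ref,
                               jerman_compat=jerman_compat, exclude=exclude)
        return 1.0 / (eps + float(resp.values.max()))

    return loss
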