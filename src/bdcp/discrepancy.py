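"""Kullback-Leibler discrepancy machinery for Gaussian linear candidates.

The Kullback-Leibler discrepancy (KLD) of a candidate density f(.|theta)
against the truth g is d(g, theta) = E_g[-2 l(theta | y)], the variable part
of twice the KL information.  For a Gaussian linear candidate fitted by MLE
to data generated as y = X beta0 + eps with mean-zero errors of variance
sigma0^2, the discrepancy conditional on the design X has the closed form

    d(g, theta_hat) = n log(2 pi sigma2_hat)
                      + n sigma0^2 / sigma2_hat
                      + || X beta0 - X beta_hat ||^2 / sigma2_hat.

Only the first two moments of the error law enter, because the candidate is
Gaussian: the formula is exact for normal, Student-t and normal-mixture
errors alike, with sigma0^2 = Var(eps).

The bootstrap plug-in estimate of the discrepancy replaces g by the empirical
distribution and theta_hat by the MLE on a bootstrap resample:
d(g_hat, theta_star) = -2 l(theta_star | y) evaluated on the ORIGINAL data.
This estimator is negatively biased; two additive corrections are provided:

* ``k`` -- the number of functionally independent parameters (AIC-style),
  justified when the candidate subsumes the truth;
* ``kb`` -- a bootstrap-based correction, mean of the plug-in replicates
  minus -2 l(theta_hat | y), requiring no correct-specification assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import DataSet, FittedLinearModel, neg2_loglik

__all__ = [
    "NormalError",
    "StudentTError",
    "NormalMixtureError",
    "GeneratingModel",
    "BootstrapDiscrepancySet",
    "error_variance",
    "kld_gaussian_linear",
    "plug_in_bd",
    "kb_correction",
    "bd_point_estimates",
]

#: per-covariate design variance used by every simulation scenario
DESIGN_VARIANCE = 100.0


@dataclass(frozen=True)
class NormalError:
    """Mean-zero normal errors with variance ``sigma2``."""

    sigma2: float

    def variance(self) -> float:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        return float(self.sigma2)

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(self.sigma2), size=size)


@dataclass(frozen=True)
class StudentTError:
    """Student-t errors with ``df`` degrees of freedom (df > 2 for finite variance)."""

    df: float

    def variance(self) -> float:
        if self.df <= 2:
            raise ValueError(f"t errors need df > 2 for finite variance, got {self.df}")
        return float(self.df / (self.df - 2.0))

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_t(self.df, size=size)


@dataclass(frozen=True)
class NormalMixtureError:
    """Two-component scale mixture: N(0, sigma2_a) w.p. ``pi``, else N(0, sigma2_b)."""

    pi: float
    sigma2_a: float
    sigma2_b: float

    def variance(self) -> float:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")
        if self.sigma2_a <= 0 or self.sigma2_b <= 0:
            raise ValueError("component variances must be positive")
        return float(self.pi * self.sigma2_a + (1.0 - self.pi) * self.sigma2_b)

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        z = rng.random(size) < self.pi
        sd = np.where(z, np.sqrt(self.sigma2_a), np.sqrt(self.sigma2_b))
        return rng.normal(0.0, 1.0, size=size) * sd


ErrorSpec = NormalError | StudentTError | NormalMixtureError


def error_variance(error_spec: ErrorSpec) -> float:
    """Var(eps) of an error specification; the sigma0^2 of the closed-form KLD."""
    return error_spec.variance()


@dataclass(frozen=True)
class GeneratingModel:
    """The true data-generating mechanism g of a simulation scenario.

    ``y_i = x_i' beta0 + eps_i`` where the covariates (all columns named in
    ``columns``, intercept excluded) are independent normals with means
    ``mu`` and common variance ``DESIGN_VARIANCE``.  ``beta0`` is aligned to
    ``("intercept", *columns)``; covariates generated only for
    over-specified candidates carry a true coefficient of zero.
    """

    beta0: np.ndarray
    error: ErrorSpec
    mu: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        beta0 = np.asarray(self.beta0, dtype=float).ravel()
        mu = np.asarray(self.mu, dtype=float).ravel()
        if beta0.shape[0] != mu.shape[0] + 1:
            raise ValueError("beta0 must have one more entry (intercept) than mu")
        if len(self.columns) != mu.shape[0]:
            raise ValueError("columns must name each generated covariate")
        self.error.variance()  # validates finiteness
        object.__setattr__(self, "beta0", beta0)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "columns", tuple(self.columns))

    @property
    def sigma0_sq(self) -> float:
        return error_variance(self.error)

    def sample(self, n: int, rng: np.random.Generator) -> tuple[DataSet, np.ndarray]:
        """Draw one dataset of size ``n``: fresh design, fresh errors.

        Returns the dataset (holding every generated covariate column) and
        the true conditional mean vector X beta0.
        """
        p = self.mu.shape[0]
        Z = rng.normal(self.mu, np.sqrt(DESIGN_VARIANCE), size=(n, p))
        X = np.column_stack([np.ones(n), Z])
        true_mean = X @ self.beta0
        y = true_mean + self.error.sample(n, rng)
        data = DataSet(y=y, X=X, columns=("intercept", *self.columns))
        return data, true_mean


def kld_gaussian_linear(
    fitted: FittedLinearModel,
    X: np.ndarray,
    true_mean: np.ndarray,
    sigma0_sq: float,
) -> float:
    """Closed-form KLD of a fitted Gaussian linear candidate against the truth.

    ``X`` is the candidate's design on the fitting data (so ``X @ beta_hat``
    is the fitted mean), ``true_mean`` the true conditional mean vector on
    the same rows, and ``sigma0_sq`` the error variance of the truth.
    """
    if fitted.sigma2_hat <= 0:
        raise ValueError("fitted sigma2 must be positive")
    X = np.asarray(X, dtype=float)
    true_mean = np.asarray(true_mean, dtype=float).ravel()
    if X.shape[0] != true_mean.shape[0]:
        raise ValueError("design and true mean have different lengths")
    if X.shape[1] != fitted.beta_hat.shape[0]:
        raise ValueError("design width does not match fitted coefficients")
    n = true_mean.shape[0]
    diff = true_mean - X @ fitted.beta_hat
    return float(
        n * np.log(2.0 * np.pi * fitted.sigma2_hat)
        + n * sigma0_sq / fitted.sigma2_hat
        + (diff @ diff) / fitted.sigma2_hat
    )


def plug_in_bd(
    theta_star: tuple[np.ndarray, float],
    original: DataSet,
) -> float:
    """Plug-in bootstrap discrepancy: -2 l(theta_star | y) on the ORIGINAL data.

    ``theta_star = (beta, sigma2)`` is the MLE from a bootstrap resample;
    plugging it into the original-data log-likelihood realises the empirical
    (plug-in) version of the discrepancy.
    """
    beta, sigma2 = theta_star
    return neg2_loglik(beta, sigma2, original)


@dataclass(frozen=True)
class BootstrapDiscrepancySet:
    """J plug-in discrepancies of one candidate plus the kb ingredients."""

    bd_replicates: np.ndarray
    neg2ll_at_mle: float
    k: int

    def __post_init__(self) -> None:
        reps = np.asarray(self.bd_replicates, dtype=float).ravel()
        if reps.shape[0] < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if not np.isfinite(reps).all():
            raise ValueError("bootstrap replicates must be finite")
        object.__setattr__(self, "bd_replicates", reps)

    @property
    def J(self) -> int:
        return self.bd_replicates.shape[0]


def kb_correction(s: BootstrapDiscrepancySet) -> float:
    """Bootstrap bias correction: mean plug-in discrepancy minus -2 l(theta_hat | y)."""
    return float(np.mean(s.bd_replicates) - s.neg2ll_at_mle)


def bd_point_estimates(s: BootstrapDiscrepancySet) -> tuple[float, float, float]:
    """Point estimates (BD, BDk, BDb) of the discrepancy of one candidate.

    BD is the raw mean of the plug-in replicates, BDk adds the parameter
    count k, and BDb adds the bootstrap correction kb (equivalently
    ``2 BD - (-2 l(theta_hat | y))``).
    """
    bd = float(np.mean(s.bd_replicates))
    return bd, bd + s.k, bd + kb_correction(s)
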