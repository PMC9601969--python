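"""Gaussian linear candidate models: data container, MLE fit, -2 log-likelihood.

A candidate model here is an ordinary linear regression with an intercept and
i.i.d. Gaussian errors, fitted by maximum likelihood.  The error-variance MLE
uses denominator ``n`` (not ``n - p``): the closed-form Kullback-Leibler
discrepancy for Gaussian linear candidates is derived under the MLE, so the
unbiased variant is deliberately not offered.

The parameter count ``k`` reported on a fit counts the error variance as a
free parameter (``k = n_coefficients + 1``), following the AIC convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DataSet",
    "ModelSpec",
    "FittedLinearModel",
    "SingularDesignError",
    "DegenerateFitError",
    "fit_mle",
    "neg2_loglik",
]

INTERCEPT = "intercept"

#: relative floor below which the residual variance is treated as zero
_DEGENERATE_REL_TOL = 1e-12


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank deficient on the original data."""


class DegenerateFitError(ValueError):
    """Raised when the MLE residual variance is (numerically) zero.

    The Gaussian log-likelihood is unbounded as sigma^2 -> 0, so a perfect
    fit leaves the discrepancy machinery undefined.
    """


@dataclass(frozen=True)
class DataSet:
    """Response vector plus design matrix, the unit every fit consumes.

    ``X`` always carries the intercept as its first column; ``columns`` names
    the design columns, with ``"intercept"`` first.
    """

    y: np.ndarray
    X: np.ndarray
    columns: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"y has {y.shape[0]} rows but X has {X.shape[0]}"
            )
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError("missing or non-finite values are not accepted")
        cols = tuple(self.columns) or (INTERCEPT,) + tuple(
            f"x{i}" for i in range(2, X.shape[1] + 1)
        )
        if len(cols) != X.shape[1]:
            raise ValueError("column names do not match design width")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "columns", cols)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def k_beta(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        response: str,
        covariates: list[str] | tuple[str, ...] | None = None,
    ) -> "DataSet":
        """Build a dataset from a rectangular table.

        Adds the intercept column; ``covariates=None`` takes every column
        except the response.  Rows with missing values are rejected.
        """
        if response not in frame.columns:
            raise KeyError(f"response column {response!r} not in table")
        if covariates is None:
            covariates = [c for c in frame.columns if c != response]
        missing = [c for c in covariates if c not in frame.columns]
        if missing:
            raise KeyError(f"covariate columns not in table: {missing}")
        sub = frame[[response, *covariates]]
        if sub.isna().any().any():
            raise ValueError("input table contains missing values")
        y = sub[response].to_numpy(dtype=float)
        Z = sub[list(covariates)].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(y)), Z])
        return cls(y=y, X=X, columns=(INTERCEPT, *covariates))

    def select(self, spec: "ModelSpec") -> "DataSet":
        """Column-subset dataset for one candidate (intercept always kept)."""
        idx = [0] + [self._col_index(c) for c in spec.covariate_names]
        return DataSet(
            y=self.y,
            X=self.X[:, idx],
            columns=tuple(self.columns[i] for i in idx),
        )

    def _col_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise KeyError(f"column {name!r} not in dataset {self.columns}") from None


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: an ordered list of covariate names (intercept implicit)."""

    covariate_names: tuple[str, ...]
    family: str = "gaussian-linear"

    def __post_init__(self) -> None:
        names = tuple(self.covariate_names)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate covariates in spec: {names}")
        if INTERCEPT in names:
            raise ValueError("the intercept is implicit; do not list it")
        if self.family != "gaussian-linear":
            raise NotImplementedError(f"unsupported family {self.family!r}")
        object.__setattr__(self, "covariate_names", names)

    @property
    def k(self) -> int:
        """Number of free parameters: coefficients (incl. intercept) + sigma^2."""
        return len(self.covariate_names) + 2


@dataclass(frozen=True)
class FittedLinearModel:
    """MLE fit of a Gaussian linear model.

    ``k`` counts the intercept, the slopes and the error variance;
    ``neg2ll_at_fit`` equals ``n*log(2*pi*sigma2_hat) + n`` at the MLE.
    """

    beta_hat: np.ndarray
    sigma2_hat: float
    n: int
    k: int
    neg2ll_at_fit: float


def _degenerate_floor(y: np.ndarray) -> float:
    return _DEGENERATE_REL_TOL * max(1.0, float(np.mean(y * y)))


def fit_mle(data: DataSet) -> FittedLinearModel:
    """Maximum-likelihood fit: beta by least squares, sigma^2 = RSS / n.

    Raises :class:`SingularDesignError` on a rank-deficient design and
    :class:`DegenerateFitError` when the fit is perfect (sigma^2 -> 0).
    """
    y, X = data.y, data.X
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need n >= k_beta + 2 (n={n}, k_beta={p})")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {p})"
        )
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= _degenerate_floor(y):
        raise DegenerateFitError(
            "residual variance is numerically zero; log-likelihood undefined"
        )
    neg2ll = n * np.log(2.0 * np.pi * sigma2) + n
    return FittedLinearModel(
        beta_hat=beta,
        sigma2_hat=sigma2,
        n=n,
        k=p + 1,
        neg2ll_at_fit=float(neg2ll),
    )


def neg2_loglik(beta: np.ndarray, sigma2: float, data: DataSet) -> float:
    """-2 log-likelihood of a Gaussian linear model at arbitrary parameters.

    ``n*log(2*pi*sigma2) + RSS(beta)/sigma2`` on ``data``; the quantity whose
    expectation under the truth is the Kullback-Leibler discrepancy.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != data.k_beta:
        raise ValueError(
            f"beta has length {beta.shape[0]}, design has {data.k_beta} columns"
        )
    resid = data.y - data.X @ beta
    return float(data.n * np.log(2.0 * np.pi * sigma2) + (resid @ resid) / sigma2)
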