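"""Paired bootstrap engine and the discrepancy comparison probability estimators.

Two candidate models (a "null" and an "alternative", which need not be
nested) are refit on the SAME nonparametric bootstrap resamples of the data:
rows (y_i, x_i) are drawn jointly with replacement, both candidates are
fitted by MLE on the resample, and each bootstrap MLE is plugged into the
original-data log-likelihood.  The resulting index-aligned pairs of plug-in
discrepancies estimate the joint bootstrap distribution of the two
candidates' Kullback-Leibler discrepancies, and three comparison
probabilities are read off them:

* ``bdcp``   -- proportion of resamples where the null's plug-in discrepancy
  is strictly smaller (uncorrected; approximates the LRT p-value for nested
  candidates under a true null);
* ``bdcp_k`` -- the same proportion after shifting each candidate's
  replicates by its parameter count k (AIC-style correction);
* ``bdcp_b`` -- the same with the bootstrap corrections kb, which need no
  correct-specification assumption.

Degenerate resamples (rank-deficient design or zero residual variance) would
send the plug-in discrepancy to -infinity, so they are rejected and redrawn;
the rejection count is surfaced for audit.  Each replicate owns a
deterministic child stream of the root seed, so increasing J extends the
replicate set without perturbing earlier replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .discrepancy import BootstrapDiscrepancySet
from .model_core import DataSet, ModelSpec, _degenerate_floor, fit_mle

__all__ = [
    "PairedBootstrapReplicates",
    "ComparisonResult",
    "BootstrapConvergenceError",
    "paired_bootstrap",
    "bootstrap_discrepancy_set",
    "bdcp",
    "bdcp_k",
    "bdcp_b",
    "compare",
]

#: total resample draws allowed before the engine gives up, as a multiple of J
_MAX_ATTEMPT_FACTOR = 10

#: condition-number threshold above which a resample fit is flagged (not fatal)
CONDITION_WARN = 1e10


class BootstrapConvergenceError(RuntimeError):
    """Raised when too many resamples are degenerate for some candidate."""


@dataclass(frozen=True)
class PairedBootstrapReplicates:
    """Index-aligned plug-in discrepancies of both candidates on shared resamples.

    Entry ``j`` of ``d1_star`` and ``d2_star`` comes from the same resample,
    whose row indices are ``indices[j]`` (stored so any replicate can be
    replayed).  ``k1b``/``k2b`` are the bootstrap bias corrections computed
    from these replicates and the original-data -2 log-likelihoods.
    """

    d1_star: np.ndarray
    d2_star: np.ndarray
    k1: int
    k2: int
    k1b: float
    k2b: float
    neg2ll_1: float
    neg2ll_2: float
    indices: np.ndarray = field(repr=False)
    n_rejected: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        d1 = np.asarray(self.d1_star, dtype=float).ravel()
        d2 = np.asarray(self.d2_star, dtype=float).ravel()
        if d1.shape != d2.shape:
            raise ValueError("null and alternative replicate vectors differ in length")
        if d1.shape[0] < 2:
            raise ValueError("need J >= 2 paired replicates")
        if not (np.isfinite(d1).all() and np.isfinite(d2).all()):
            raise ValueError("replicates must be finite")
        object.__setattr__(self, "d1_star", d1)
        object.__setattr__(self, "d2_star", d2)

    @property
    def J(self) -> int:
        return self.d1_star.shape[0]

    def swapped(self) -> "PairedBootstrapReplicates":
        """The same replicates with null and alternative labels exchanged."""
        return PairedBootstrapReplicates(
            d1_star=self.d2_star,
            d2_star=self.d1_star,
            k1=self.k2,
            k2=self.k1,
            k1b=self.k2b,
            k2b=self.k1b,
            neg2ll_1=self.neg2ll_2,
            neg2ll_2=self.neg2ll_1,
            indices=self.indices,
            n_rejected=self.n_rejected,
            seed=self.seed,
        )


@dataclass(frozen=True)
class ComparisonResult:
    """Bundle of the three comparison probabilities and both candidates' point estimates."""

    bdcp: float
    bdcp_k: float
    bdcp_b: float
    bd1: float
    bd1_k: float
    bd1_b: float
    bd2: float
    bd2_k: float
    bd2_b: float
    J: int
    seed: int
    n_rejected: int
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "bdcp": self.bdcp,
            "bdcp_k": self.bdcp_k,
            "bdcp_b": self.bdcp_b,
            "bd1": self.bd1,
            "bd1_k": self.bd1_k,
            "bd1_b": self.bd1_b,
            "bd2": self.bd2,
            "bd2_k": self.bd2_k,
            "bd2_b": self.bd2_b,
            "J": self.J,
            "seed": self.seed,
            "n_rejected": self.n_rejected,
            "version": self.version,
        }


def _batched_ols(y: np.ndarray, X: np.ndarray, idx: np.ndarray, floor: float):
    """OLS on each resample in ``idx`` (m, n); returns (beta, sigma2, ok)."""
    Xb = X[idx]  # (m, n, p)
    yb = y[idx]  # (m, n)
    G = np.einsum("mnp,mnq->mpq", Xb, Xb, optimize=True)
    c = np.einsum("mnp,mn->mp", Xb, yb, optimize=True)
    try:
        beta = np.linalg.solve(G, c[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        # isolate the singular resamples; the rest proceed normally
        beta = np.full((idx.shape[0], X.shape[1]), np.nan)
        for i in range(idx.shape[0]):
            try:
                beta[i] = np.linalg.solve(G[i], c[i])
            except np.linalg.LinAlgError:
                pass
    fit_resid = yb - np.einsum("mnp,mp->mn", Xb, beta, optimize=True)
    sigma2 = np.mean(fit_resid * fit_resid, axis=1)
    ok = np.isfinite(beta).all(axis=1) & np.isfinite(sigma2) & (sigma2 > floor)
    return beta, sigma2, ok


def _plug_in_batch(y: np.ndarray, X: np.ndarray, beta: np.ndarray, sigma2: np.ndarray):
    """Plug-in discrepancies -2 l(theta*_j | y) on the original data, vectorized."""
    n = y.shape[0]
    resid = y[None, :] - beta @ X.T
    return n * np.log(2.0 * np.pi * sigma2) + np.sum(resid * resid, axis=1) / sigma2


def _resample_engine(
    y: np.ndarray,
    designs: list[np.ndarray],
    J: int,
    seed: int,
):
    """Draw J shared case resamples, fit every design on each, plug into the original data.

    Rejects resamples degenerate for ANY design and redraws them from the
    replicate's own substream; returns (list of plug-in vectors, indices,
    n_rejected).
    """
    n = y.shape[0]
    floor = _degenerate_floor(y)
    children = np.random.SeedSequence(seed).spawn(J)
    rngs = [np.random.default_rng(c) for c in children]

    idx = np.empty((J, n), dtype=np.intp)
    d = [np.empty(J) for _ in designs]
    pending = np.arange(J)
    n_rejected = 0
    attempts = 0
    fail_counts = [0] * len(designs)

    while pending.size:
        attempts += pending.size
        if attempts > _MAX_ATTEMPT_FACTOR * J:
            worst = int(np.argmax(fail_counts))
            raise BootstrapConvergenceError(
                f"exceeded {_MAX_ATTEMPT_FACTOR * J} resample attempts; "
                f"model {worst + 1} produced {fail_counts[worst]} degenerate fits"
            )
        for j in pending:
            idx[j] = rngs[j].integers(0, n, size=n)
        block = idx[pending]
        ok_all = np.ones(pending.size, dtype=bool)
        fits = []
        for m, X in enumerate(designs):
            beta, sigma2, ok = _batched_ols(y, X, block, floor)
            fits.append((beta, sigma2))
            fail_counts[m] += int(np.sum(~ok))
            ok_all &= ok
        good = pending[ok_all]
        for m, X in enumerate(designs):
            beta, sigma2 = fits[m]
            d[m][good] = _plug_in_batch(y, X, beta[ok_all], sigma2[ok_all])
        n_rejected += int(np.sum(~ok_all))
        pending = pending[~ok_all]

    return d, idx, n_rejected


def _require_seed(seed) -> int:
    if seed is None or isinstance(seed, bool) or not isinstance(seed, (int, np.integer)):
        raise ValueError("an integer seed is required; resampling must be reproducible")
    return int(seed)


def paired_bootstrap(
    data: DataSet,
    null_spec: ModelSpec,
    alt_spec: ModelSpec,
    J: int,
    seed: int,
) -> PairedBootstrapReplicates:
    """J paired case-bootstrap plug-in discrepancies for two candidates.

    Both candidates are refit on the same resample (rows drawn jointly with
    replacement) and each bootstrap MLE is evaluated in the original-data
    log-likelihood.  Degenerate resamples are rejected and redrawn.
    """
    seed = _require_seed(seed)
    if J < 2:
        raise ValueError("need J >= 2 bootstrap replicates")
    d_null = data.select(null_spec)
    d_alt = data.select(alt_spec)
    fit1 = fit_mle(d_null)  # also validates rank / non-degeneracy on the original data
    fit2 = fit_mle(d_alt)

    d, idx, n_rejected = _resample_engine(data.y, [d_null.X, d_alt.X], J, seed)
    d1, d2 = d
    return PairedBootstrapReplicates(
        d1_star=d1,
        d2_star=d2,
        k1=fit1.k,
        k2=fit2.k,
        k1b=float(np.mean(d1) - fit1.neg2ll_at_fit),
        k2b=float(np.mean(d2) - fit2.neg2ll_at_fit),
        neg2ll_1=fit1.neg2ll_at_fit,
        neg2ll_2=fit2.neg2ll_at_fit,
        indices=idx,
        n_rejected=n_rejected,
        seed=seed,
    )


def bootstrap_discrepancy_set(data: DataSet, J: int, seed: int) -> BootstrapDiscrepancySet:
    """Single-candidate bootstrap: J plug-in discrepancies of ``data``'s own model."""
    seed = _require_seed(seed)
    if J < 2:
        raise ValueError("need J >= 2 bootstrap replicates")
    fit = fit_mle(data)
    d, _, _ = _resample_engine(data.y, [data.X], J, seed)
    return BootstrapDiscrepancySet(
        bd_replicates=d[0], neg2ll_at_mle=fit.neg2ll_at_fit, k=fit.k
    )


def bdcp(r: PairedBootstrapReplicates) -> float:
    """Uncorrected comparison probability: share of resamples favouring the null.

    Strict inequality; exact ties count against the null (probability-zero
    events for continuous data).
    """
    return float(np.mean(r.d1_star < r.d2_star))


def bdcp_k(r: PairedBootstrapReplicates) -> float:
    """Comparison probability with each candidate's replicates shifted by its k."""
    return float(np.mean(r.d1_star + r.k1 < r.d2_star + r.k2))


def bdcp_b(r: PairedBootstrapReplicates) -> float:
    """Comparison probability with each candidate shifted by its bootstrap correction kb."""
    return float(np.mean(r.d1_star + r.k1b < r.d2_star + r.k2b))


def compare(
    data: DataSet,
    null_spec: ModelSpec,
    alt_spec: ModelSpec,
    J: int,
    seed: int,
) -> ComparisonResult:
    """Full pairwise comparison: paired bootstrap, all three probabilities, point estimates."""
    r = paired_bootstrap(data, null_spec, alt_spec, J, seed)
    bd1 = float(np.mean(r.d1_star))
    bd2 = float(np.mean(r.d2_star))
    return ComparisonResult(
        bdcp=bdcp(r),
        bdcp_k=bdcp_k(r),
        bdcp_b=bdcp_b(r),
        bd1=bd1,
        bd1_k=bd1 + r.k1,
        bd1_b=bd1 + r.k1b,
        bd2=bd2,
        bd2_k=bd2 + r.k2,
        bd2_b=bd2 + r.k2b,
        J=r.J,
        seed=r.seed,
        n_rejected=r.n_rejected,
    )
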