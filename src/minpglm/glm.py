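"""Exponential-family GLM machinery for coding-selection inference.

Provides the null-model fit (adjustment covariates only, by iteratively
reweighted least squares), Rao efficient-score tests for adding a coded
block of the variable of interest, and the joint null correlation of the
1-df score statistics across codings.  The score test uses the expected
information, so the vector of 1-df statistics is asymptotically multivariate
normal with a correlation matrix computable in closed form from the null
fit — exactly what the exact (maxT) correction integrates over.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special
from scipy import stats as sps

__all__ = [
    "FamilyLink",
    "NullFit",
    "ScoreTestResult",
    "Dataset",
    "GlmError",
    "RankDeficientError",
    "ConvergenceError",
    "SingularScoreError",
    "fit_null",
    "score_test",
    "score_correlation",
]


class GlmError(Exception):
    """Base class for model-fitting and score-test failures."""


class RankDeficientError(GlmError):
    """Adjustment design is not full column rank."""

    def __init__(self, columns: Sequence[int]):
        self.columns = tuple(int(c) for c in columns)
        super().__init__(
            "adjustment design is rank deficient; collinear column(s) "
            f"at index {self.columns} (0-based, intercept = 0)"
        )


class ConvergenceError(GlmError):
    """IRLS did not converge; carries the deviance trace."""

    def __init__(self, message: str, trace: Sequence[float]):
        self.trace = list(trace)
        super().__init__(f"{message} (deviance trace: {self.trace})")


class SingularScoreError(GlmError):
    """Score-test null variance is singular for a coding."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(
            f"singular score variance for coding {label!r}: the coded "
            "column(s) are constant or collinear with the adjustment design"
        )


# --------------------------------------------------------------------------
# Family / link
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyLink:
    """One of the four supported family/link pairs.

    ``mu`` maps the linear predictor eta to the mean, ``dmu_deta`` is its
    derivative, ``variance`` is V(mu), and ``link`` maps a mean back to eta
    (used to initialise IRLS).  The dispersion phi is fixed at 1 for
    binomial and poisson and estimated by maximum likelihood for gaussian.
    """

    family: str
    link: str
    mu: Callable[[np.ndarray], np.ndarray]
    dmu_deta: Callable[[np.ndarray], np.ndarray]
    variance: Callable[[np.ndarray], np.ndarray]
    linkfun: Callable[[np.ndarray], np.ndarray]
    fixed_dispersion: bool

    @staticmethod
    def from_names(family: str, link: str) -> "FamilyLink":
        key = (family.lower(), link.lower())
        try:
            return _FAMILY_LINKS[key]
        except KeyError:
            supported = ", ".join("-".join(k) for k in _FAMILY_LINKS)
            raise ValueError(
                f"unsupported family/link {family}-{link}; "
                f"supported: {supported}"
            ) from None

    def __repr__(self) -> str:  # compact, stable (used in reports)
        return f"FamilyLink({self.family}-{self.link})"


def _clip_prob(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 1e-10, 1 - 1e-10)


_FAMILY_LINKS = {
    ("gaussian", "identity"): FamilyLink(
        "gaussian", "identity",
        mu=lambda eta: eta,
        dmu_deta=lambda eta: np.ones_like(eta),
        variance=lambda mu: np.ones_like(mu),
        linkfun=lambda mu: mu,
        fixed_dispersion=False,
    ),
    ("binomial", "logit"): FamilyLink(
        "binomial", "logit",
        mu=special.expit,
        dmu_deta=lambda eta: (p := special.expit(eta)) * (1.0 - p),
        variance=lambda mu: mu * (1.0 - mu),
        linkfun=lambda mu: special.logit(_clip_prob(mu)),
        fixed_dispersion=True,
    ),
    ("binomial", "probit"): FamilyLink(
        "binomial", "probit",
        mu=special.ndtr,
        dmu_deta=lambda eta: np.exp(-0.5 * eta * eta) / np.sqrt(2 * np.pi),
        variance=lambda mu: mu * (1.0 - mu),
        linkfun=lambda mu: special.ndtri(_clip_prob(mu)),
        fixed_dispersion=True,
    ),
    ("poisson", "log"): FamilyLink(
        "poisson", "log",
        mu=np.exp,
        dmu_deta=np.exp,
        variance=lambda mu: mu,
        linkfun=lambda mu: np.log(np.maximum(mu, 1e-10)),
        fixed_dispersion=True,
    ),
}


# --------------------------------------------------------------------------
# Data container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Dataset:
    """Outcome y, continuous variable of interest x, adjustment design Z.

    Z always contains the intercept as its first column; with no adjustment
    covariates it is the n-by-1 column of ones.
    """

    y: np.ndarray
    x: np.ndarray
    Z: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if Z.shape[0] == 1 and Z.shape[1] == self.y.shape[0] != 1:
            Z = Z.T
        object.__setattr__(self, "Z", Z)
        n = self.y.shape[0]
        if self.x.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("y, x and Z must have the same number of rows")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @classmethod
    def from_arrays(cls, y, x, adjust=None) -> "Dataset":
        """Build a Dataset, prepending the intercept to the adjustment block."""
        y = np.asarray(y, dtype=float)
        n = y.shape[0]
        cols = [np.ones(n)]
        if adjust is not None:
            A = np.asarray(adjust, dtype=float)
            if A.ndim == 1:
                A = A[:, None]
            cols.append(A)
        return cls(y=y, x=np.asarray(x, dtype=float), Z=np.column_stack(cols))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, outcome: str, interest: str,
                   adjust: Sequence[str] = ()) -> "Dataset":
        adjust = list(adjust)
        block = df[adjust].to_numpy(dtype=float) if adjust else None
        return cls.from_arrays(df[outcome].to_numpy(dtype=float),
                               df[interest].to_numpy(dtype=float), block)


# --------------------------------------------------------------------------
# Null fit (IRLS)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NullFit:
    """GLM fitted under H0: the model contains only the adjustment design Z.

    ``weights`` are the working weights w_i = (dmu/deta)_i^2 / (V(mu_i) phi),
    ``score_residual`` is (dmu/deta)_i (y_i - mu_i) / (V(mu_i) phi) — the
    per-observation ingredient of every efficient score — and ``zwz_inv`` is
    (Z' W Z)^{-1}, cached so that projecting codings out of the adjustment
    space costs one small matrix product per test.
    """

    gamma: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    weights: np.ndarray
    dispersion: float
    converged: bool
    n_iter: int
    loglik: float
    deviance: float
    y: np.ndarray
    Z: np.ndarray
    family_link: FamilyLink
    score_residual: np.ndarray
    zwz_inv: np.ndarray

    @property
    def n(self) -> int:
        return self.y.shape[0]


def _check_support(y: np.ndarray, fl: FamilyLink) -> None:
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")
    if fl.family == "binomial":
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("binomial outcome must be binary 0/1")
    elif fl.family == "poisson":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson outcome must be non-negative integers")


def _check_rank(Z: np.ndarray) -> None:
    n, q = Z.shape
    _, R, piv = linalg.qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, q) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < q:
        raise RankDeficientError(sorted(piv[rank:]))


def _deviance(y: np.ndarray, mu: np.ndarray, fl: FamilyLink) -> float:
    if fl.family == "gaussian":
        return float(np.sum((y - mu) ** 2))
    if fl.family == "binomial":
        mu = _clip_prob(mu)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        return float(2.0 * np.sum(t1 + t2))
    # poisson
    mu = np.maximum(mu, 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(t - (y - mu)))


def _loglik(y: np.ndarray, mu: np.ndarray, phi: float, fl: FamilyLink) -> float:
    n = y.shape[0]
    if fl.family == "gaussian":
        rss = np.sum((y - mu) ** 2)
        return float(-0.5 * (n * np.log(2 * np.pi * phi) + rss / phi))
    if fl.family == "binomial":
        mu = _clip_prob(mu)
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    mu = np.maximum(mu, 1e-10)
    return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))


def _irls(y: np.ndarray, Z: np.ndarray, fl: FamilyLink,
          tol: float, max_iter: int):
    """Core IRLS loop; returns (gamma, eta, mu, trace, converged, n_iter).

    Step-halving keeps the deviance non-increasing.
    """
    n, q = Z.shape
    # standard mean initialisation
    if fl.family == "binomial":
        mu = (y + 0.5) / 2.0
    elif fl.family == "poisson":
        mu = y + 0.5
    else:
        mu = np.full(n, y.mean()) if np.ptp(y) == 0 else y.astype(float)
    eta = fl.linkfun(mu)
    mu = fl.mu(eta)
    gamma = np.zeros(q)
    dev = None                  # deviance of the previous model iterate
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = fl.dmu_deta(eta)
        v = fl.variance(mu)
        w = d * d / v
        z = eta + (y - mu) / d
        WZ = w[:, None] * Z
        A = Z.T @ WZ
        b = WZ.T @ z
        try:
            gamma_new = linalg.solve(A, b, assume_a="pos")
        except (linalg.LinAlgError, ValueError) as exc:
            raise ConvergenceError(f"weighted normal equations singular: {exc}",
                                   trace) from None
        step = gamma_new - gamma
        # step-halving keeps the deviance non-increasing across iterates;
        # the first step (from the data-initialised mean, not a model fit)
        # is accepted as is
        frac = 1.0
        for _ in range(25):
            cand = gamma + frac * step
            eta_c = Z @ cand
            mu_c = fl.mu(eta_c)
            dev_c = _deviance(y, mu_c, fl)
            if np.isfinite(dev_c) and (
                    dev is None or dev_c <= dev * (1 + 1e-12) + 1e-12):
                break
            frac *= 0.5
        gamma, eta, mu, dev = cand, eta_c, mu_c, dev_c
        trace.append(dev)
        rel = np.max(np.abs(frac * step)) / (np.max(np.abs(gamma)) + 1e-12)
        if it > 1 and rel < tol:
            converged = True
            break
    return gamma, eta, mu, trace, converged, it


def fit_null(y, Z, fl: FamilyLink, tol: float = 1e-9,
             max_iter: int = 100, dispersion: str = "ml") -> NullFit:
    """Fit the GLM under H0 (adjustment design Z only) by IRLS.

    Parameters
    ----------
    y : outcome vector (binary 0/1 for binomial, counts for poisson).
    Z : n-by-q adjustment design, intercept included, full column rank.
    fl : family/link pair.
    tol : relative coefficient-change convergence tolerance.
    max_iter : IRLS iteration cap.
    dispersion : for gaussian, ``"ml"`` uses RSS/n (the MLE, consistent with
        the parametric bootstrap) or ``"unbiased"`` uses RSS/(n-q).

    Raises
    ------
    RankDeficientError, ConvergenceError, ValueError
    """
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != y.shape[0]:
        Z = Z.T
    n, q = Z.shape
    if n <= q:
        raise ValueError(f"need n > q ({n} rows, {q} adjustment columns)")
    _check_support(y, fl)
    _check_rank(Z)
    if dispersion not in ("ml", "unbiased"):
        raise ValueError("dispersion must be 'ml' or 'unbiased'")

    gamma, eta, mu, trace, converged, n_iter = _irls(y, Z, fl, tol, max_iter)
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations",
                               trace)
    if fl.family == "gaussian":
        rss = float(np.sum((y - mu) ** 2))
        if rss <= 0:
            raise ConvergenceError(
                "zero residual variance: the adjustment design fits the "
                "outcome exactly, so no score test is defined", trace)
        phi = rss / n if dispersion == "ml" else rss / (n - q)
    else:
        phi = 1.0
    d = fl.dmu_deta(eta)
    v = fl.variance(mu)
    w = d * d / (v * phi)
    if np.any(w <= 0):
        raise ConvergenceError("non-positive working weights at convergence",
                               trace)
    zwz = Z.T @ (w[:, None] * Z)
    zwz_inv = linalg.inv(zwz)
    return NullFit(
        gamma=gamma, eta=eta, mu=mu, weights=w, dispersion=phi,
        converged=converged, n_iter=n_iter,
        loglik=_loglik(y, mu, phi, fl), deviance=trace[-1],
        y=y, Z=Z, family_link=fl,
        score_residual=d * (y - mu) / (v * phi),
        zwz_inv=zwz_inv,
    )


# --------------------------------------------------------------------------
# Score tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreTestResult:
    """Efficient-score test of H0k: beta_k = 0 for one coding.

    For 1-df codings ``statistic`` is the signed standard-normal score
    T_k = U_k / sqrt(V_k); for m-df codings it is the chi-square quadratic
    form Q_k = U_k' V_k^{-1} U_k on ``df`` degrees of freedom.
    """

    label: str
    statistic: float
    df: int
    p_value: float


def _score_blocks(nf: NullFit, C: np.ndarray):
    """Efficient score U and its null covariance V for a coded block C."""
    r = nf.score_residual
    w = nf.weights
    U = C.T @ r
    WC = w[:, None] * C
    ZtWC = nf.Z.T @ WC
    V = C.T @ WC - ZtWC.T @ nf.zwz_inv @ ZtWC
    return U, V


def two_sided_p(t: float) -> float:
    """Two-sided standard-normal p-value for a 1-df score statistic."""
    return float(2.0 * sps.norm.sf(abs(t)))


def score_test(nf: NullFit, design, fl: FamilyLink | None = None) -> ScoreTestResult:
    """Rao score test for adding the coded block ``design`` to the null model.

    The efficient score is U_k = X(k)' diag((dmu/deta)_i / (V_i phi)) (y - mu)
    and its null covariance V_k = Xt' W Xt with Xt the coded block with the
    adjustment directions projected out under the W inner product.
    """
    if fl is not None and fl is not nf.family_link:
        raise ValueError("family/link differs from the null fit's")
    C = np.atleast_2d(np.asarray(design.matrix, dtype=float))
    if C.shape[0] != nf.n:
        raise ValueError("coded design and null fit have different row counts")
    U, V = _score_blocks(nf, C)
    m = C.shape[1]
    scale = float(np.max(np.abs(V))) if V.size else 0.0
    if m == 1:
        v = float(V[0, 0])
        if v <= max(scale, 1.0) * 1e-12 or v <= 0:
            raise SingularScoreError(design.label)
        t = float(U[0] / np.sqrt(v))
        return ScoreTestResult(design.label, t, 1, two_sided_p(t))
    try:
        cf = linalg.cho_factor(V)
    except linalg.LinAlgError:
        raise SingularScoreError(design.label) from None
    q = float(U @ linalg.cho_solve(cf, U))
    return ScoreTestResult(design.label, q, m, float(sps.chi2.sf(q, m)))


def score_correlation(nf: NullFit, designs: Sequence) -> np.ndarray:
    """Joint null correlation matrix of the 1-df score statistics.

    R[k,l] = Xt_k' W Xt_l / sqrt((Xt_k' W Xt_k)(Xt_l' W Xt_l)) where Xt_k is
    the coded column with the adjustment space projected out under W.  The
    result is symmetrised and, if rounding produced eigenvalues below
    -1e-10, clipped back to positive semi-definite with a unit diagonal.
    """
    for d in designs:
        if np.atleast_2d(np.asarray(d.matrix)).shape[1] != 1:
            raise ValueError(
                f"coding {d.label!r} has {d.df} df; the exact method applies "
                "only to 1-df codings (binary, Box-Cox, degree-1 fractional "
                "polynomial)"
            )
    X = np.column_stack([np.asarray(d.matrix, dtype=float).reshape(-1)
                         for d in designs])
    _, V = _score_blocks(nf, X)
    diag = np.diag(V).copy()
    for k, d in enumerate(designs):
        if diag[k] <= 0:
            raise SingularScoreError(d.label)
    s = np.sqrt(diag)
    R = V / np.outer(s, s)
    R = 0.5 * (R + R.T)
    evals, evecs = linalg.eigh(R)
    if evals.min() < -1e-10:
        evals = np.clip(evals, 0.0, None)
        R = (evecs * evals) @ evecs.T
        d2 = np.sqrt(np.diag(R))
        R = R / np.outer(d2, d2)
        R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R
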