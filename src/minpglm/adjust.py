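"""Multiplicity corrections over a menu of K codings.

Trying several codings of one covariate and keeping the most significant
one is a union-intersection test: the global null (no effect under any
coding) is rejected when the minimum of the K individual p-values is small
enough.  The minimum p-value itself is not a valid p-value — its null
distribution depends on K and on the correlation between the score
statistics — so four corrections are provided:

* **Bonferroni**: min(1, K * p_min);
* **exact (maxT)**: the adjusted p-value 1 - P(max_k |Z_k| < t_max) under
  the joint asymptotic N(0, R) law of the 1-df score statistics, with R the
  closed-form score correlation and the rectangle probability computed by
  Genz-Bretz quasi-Monte-Carlo integration;
* **permutation (minP)**: the variable of interest is permuted across
  subjects (exchangeability under the null), codings re-derived, and the
  minimum p-value recomputed B times;
* **parametric bootstrap (minP)**: new outcomes are simulated from the
  null fit (adjustment covariates only), the null re-fitted and the
  minimum p-value recomputed B times.

Both resampling estimates use the plain Monte-Carlo estimator
p_hat = (1/B) sum_b 1{p*_min^b < p_min} with strict inequality; an opt-in
add-one variant (sum + 1)/(B + 1) is available since the plain estimator
can return exactly zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy import stats as sps
from scipy.stats import multivariate_normal

from .codings import CodedDesign, CodingSpec, realize_menu
from .glm import (
    Dataset,
    FamilyLink,
    ScoreTestResult,
    fit_null,
    score_correlation,
    score_test,
    two_sided_p,
)

__all__ = [
    "MinPState",
    "ExactResult",
    "AdjustedReport",
    "DataQualityError",
    "bonferroni_adjust",
    "exact_adjust",
    "permutation_adjust",
    "bootstrap_adjust",
    "best_coding",
    "run_all",
]

# Fixed internal seed for the QMC rectangle-probability integrator: the
# exact method is deterministic and must not depend on the resampling seed.
_MVN_SEEDS = (20190416, 20190417, 20190418)
# Fixed offsets deriving independent permutation/bootstrap streams from the
# user seed.
_PERM_STREAM, _BOOT_STREAM = 1, 2


class DataQualityError(Exception):
    """Too many resampling replicates failed to produce a valid test."""


# --------------------------------------------------------------------------
# Bonferroni
# --------------------------------------------------------------------------

def bonferroni_adjust(p_min: float, K: int) -> float:
    """Bonferroni-adjusted minimum p-value: min(1, K * p_min)."""
    if not 0 <= p_min <= 1:
        raise ValueError("p_min must lie in [0, 1]")
    if K < 1:
        raise ValueError("K must be >= 1")
    return min(1.0, K * p_min)


# --------------------------------------------------------------------------
# Exact (maxT) correction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExactResult:
    """maxT-adjusted p-value from the joint normal law of the scores."""

    p_value: float
    t_max: float
    error_estimate: float
    abseps: float


def exact_adjust(t_obs, R, abseps: float = 1e-5) -> ExactResult:
    """maxT adjusted p-value 1 - P(-t_max < Z_k < t_max for all k), Z~N(0,R).

    ``t_obs`` are the observed signed 1-df score statistics; the rectangle
    is symmetric because the individual tests are two-sided.  K = 1 reduces
    to the naive two-sided normal p-value.  The QMC integration error is
    estimated from three fixed-seed evaluations, and the result is
    projected into its exact analytic envelope [p1, min(1, K p1)] — the
    single-test p-value at t_max and the Bonferroni bound — which the true
    rectangle probability always satisfies.
    """
    t_obs = np.atleast_1d(np.asarray(t_obs, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    K = t_obs.shape[0]
    if R.shape != (K, K):
        raise ValueError("correlation matrix shape does not match t_obs")
    t_max = float(np.max(np.abs(t_obs)))
    if K == 1:
        return ExactResult(two_sided_p(t_max), t_max, 0.0, abseps)
    lower = np.full(K, -t_max)
    upper = np.full(K, t_max)
    vals = []
    for seed in _MVN_SEEDS:
        d = multivariate_normal(mean=np.zeros(K), cov=R,
                                allow_singular=True, seed=seed)
        vals.append(float(d.cdf(upper, lower_limit=lower)))
    rect = float(np.mean(vals))
    err = float((max(vals) - min(vals)) / 2.0 + abseps)
    p1 = two_sided_p(t_max)
    p = min(max(1.0 - rect, p1), min(1.0, K * p1))
    return ExactResult(p, t_max, err, abseps)


# --------------------------------------------------------------------------
# Resampling (minP) machinery
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MinPState:
    """State of one resampling run of the minimum p-value procedure."""

    method: str                     # "permutation" | "bootstrap"
    p_min: float                    # observed minimum p-value
    p_obs: tuple                    # per-coding observed p-values
    B: int
    minima: np.ndarray              # resampled minima, length B
    seed: int
    n_redrawn: int = 0              # replicates rejected and redrawn
    add_one: bool = False

    def __post_init__(self):
        if abs(self.p_min - min(self.p_obs)) > 1e-15:
            raise ValueError("p_min must equal min(p_obs)")
        if len(self.minima) != self.B:
            raise ValueError("need exactly B resampled minima")

    @property
    def estimate(self) -> float:
        """Estimated adjusted p-value P(p*_min < p_min)."""
        count = int(np.sum(self.minima < self.p_min))
        if self.add_one:
            return (count + 1) / (self.B + 1)
        return count / self.B

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error sqrt(p(1-p)/B)."""
        p = self.estimate
        return float(np.sqrt(p * (1 - p) / self.B))


def _blocks(designs: Sequence[CodedDesign]):
    """Stack the coded columns and remember each coding's column slice."""
    C = np.column_stack([d.matrix for d in designs])
    slices, start = [], 0
    for d in designs:
        slices.append(slice(start, start + d.df))
        start += d.df
    return C, slices


def _batch_min_p(U, V, slices) -> np.ndarray:
    """Minimum p-value per replicate from batched scores.

    ``U`` is (m, D) efficient scores and ``V`` (m, D, D) their null
    covariances for m replicates; replicates with a degenerate block come
    back as NaN (the callers redraw them).
    """
    m = U.shape[0]
    p_min = np.ones(m)
    for sl in slices:
        Ub = U[:, sl]
        Vb = V[:, sl, sl]
        d = Ub.shape[1]
        if d == 1:
            v = Vb[:, 0, 0]
            with np.errstate(invalid="ignore", divide="ignore"):
                t = np.where(v > 0, Ub[:, 0] / np.sqrt(np.maximum(v, 1e-300)),
                             np.nan)
                p = 2.0 * sps.norm.sf(np.abs(t))
        else:
            p = np.full(m, np.nan)
            ok = np.all(np.isfinite(Vb.reshape(m, -1)), axis=1)
            for i in np.nonzero(ok)[0]:
                try:
                    cf = linalg.cho_factor(Vb[i])
                except linalg.LinAlgError:
                    continue
                q = float(Ub[i] @ linalg.cho_solve(cf, Ub[i]))
                p[i] = float(sps.chi2.sf(q, d))
        p_min = np.fmin(p_min, p)
        p_min[~np.isfinite(p)] = np.nan
    return p_min


def _batch_scores_shared_fit(Cp: np.ndarray, r, w, Z, G):
    """Scores for m row-permuted designs under one shared null fit.

    ``Cp`` is (m, n, D); returns U (m, D) and V (m, D, D).
    """
    U = np.einsum("mnd,n->md", Cp, r)
    ZtWC = np.einsum("nq,n,mnd->mqd", Z, w, Cp)
    V = np.einsum("mnd,n,mne->mde", Cp, w, Cp) \
        - np.einsum("mqd,qs,mse->mde", ZtWC, G, ZtWC)
    return U, V


def _batch_scores_shared_design(C: np.ndarray, r, w, Zt_w, G):
    """Scores for one shared design under m refitted nulls.

    ``r`` and ``w`` are (n, m) per-replicate score residuals and weights,
    ``Zt_w`` the adjustment design transposed, ``G`` (m, q, q) the
    per-replicate (Z'WZ)^{-1}; returns U (m, D) and V (m, D, D).
    """
    U = (C.T @ r).T                                   # (m, D)
    ZtWC = np.einsum("qn,nm,nd->mqd", Zt_w, w, C)
    V = np.einsum("nd,nm,ne->mde", C, w, C) \
        - np.einsum("mqd,mqs,mse->mde", ZtWC, G, ZtWC)
    return U, V


def _observed(ds: Dataset, menu: Sequence[CodingSpec], fl: FamilyLink):
    nf = fit_null(ds.y, ds.Z, fl)
    designs = realize_menu(menu, ds.x)
    results = [score_test(nf, d) for d in designs]
    return nf, designs, results


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


_CHUNK = 256


def permutation_adjust(ds: Dataset, menu: Sequence[CodingSpec],
                       fl: FamilyLink, B: int, seed: int,
                       add_one: bool = False) -> MinPState:
    """Permutation minP procedure.

    Validity rests on exchangeability of the variable of interest under the
    null given the adjustment covariates.  Each replicate permutes the
    variable-of-interest column only (outcome and adjustment rows fixed) and
    recomputes every coding and score test.  The null fit is reused: H0
    does not involve X, so permuting X cannot change it.  Because every
    coding's thresholds depend only on the marginal sample of X — which a
    permutation leaves unchanged — re-deriving the codings on permuted X
    yields exactly the row-permuted original design; quantile and raw-cut
    codings therefore cannot degenerate and the redraw counter stays 0.
    Replicates are processed in vectorised chunks.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not menu:
        raise ValueError("empty coding menu")
    nf, designs, results = _observed(ds, menu, fl)
    p_obs = tuple(res.p_value for res in results)
    p_min = min(p_obs)
    C, slices = _blocks(designs)
    r, w, Z, G = nf.score_residual, nf.weights, nf.Z, nf.zwz_inv
    rng = _rng(seed, _PERM_STREAM)
    base = np.arange(ds.n)
    minima = np.empty(B)
    filled = 0
    n_redrawn = 0
    while filled < B:
        m = min(_CHUNK, B - filled)
        perms = rng.permuted(np.tile(base, (m, 1)), axis=1)
        U, V = _batch_scores_shared_fit(C[perms], r, w, Z, G)
        pm = _batch_min_p(U, V, slices)
        good = np.isfinite(pm)
        n_redrawn += int(m - good.sum())
        if n_redrawn > max(10, B):
            raise DataQualityError(
                "permutation replicates keep producing singular score "
                "variances; the data are too degenerate to resample")
        k = int(good.sum())
        minima[filled:filled + k] = pm[good]
        filled += k
    return MinPState("permutation", p_min, p_obs, B, minima, seed,
                     n_redrawn, add_one)


def _simulate_outcomes(rng: np.random.Generator, mu: np.ndarray,
                       phi: float, fl: FamilyLink, m: int) -> np.ndarray:
    """m simulated outcome columns (n, m) from the fitted null."""
    n = mu.shape[0]
    if fl.family == "binomial":
        return (rng.random((n, m)) < mu[:, None]).astype(float)
    if fl.family == "poisson":
        return rng.poisson(np.broadcast_to(mu[:, None], (n, m))).astype(float)
    return rng.normal(np.broadcast_to(mu[:, None], (n, m)), np.sqrt(phi))


def _batch_irls(Y: np.ndarray, Z: np.ndarray, fl: FamilyLink,
                tol: float = 1e-9, max_iter: int = 50):
    """Plain IRLS run column-wise over an (n, m) outcome matrix.

    Returns (eta, mu, converged_mask); columns that fail to converge (or
    whose normal equations blow up) come back with ``converged = False``
    and are redrawn by the caller.  No step-halving: bootstrap outcomes are
    drawn from the fitted null, where plain IRLS is reliable, and rare
    pathological draws are simply rejected.
    """
    n, m = Y.shape
    q = Z.shape[1]
    if fl.family == "binomial":
        mu = (Y + 0.5) / 2.0
    elif fl.family == "poisson":
        mu = Y + 0.5
    else:
        mu = Y.copy()
    eta = fl.linkfun(mu)
    mu = fl.mu(eta)
    gamma = np.zeros((m, q))
    converged = np.zeros(m, dtype=bool)
    alive = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        act = alive & ~converged
        if not act.any():
            break
        ea, mua, Ya = eta[:, act], mu[:, act], Y[:, act]
        d = fl.dmu_deta(ea)
        v = fl.variance(mua)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = d * d / v
            z = ea + (Ya - mua) / d
        A = np.einsum("nm,nq,ns->mqs", w, Z, Z)
        b = np.einsum("nm,nq->mq", w * z, Z)
        try:
            gnew = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # isolate offending columns and drop them
            gnew = np.empty_like(b)
            okcols = np.ones(b.shape[0], dtype=bool)
            for i in range(b.shape[0]):
                try:
                    gnew[i] = np.linalg.solve(A[i], b[i])
                except np.linalg.LinAlgError:
                    okcols[i] = False
            idx = np.nonzero(act)[0]
            alive[idx[~okcols]] = False
            act = alive & ~converged
            if not act.any():
                break
            sub = okcols
            gnew = gnew[sub]
            ea, Ya = eta[:, act], Y[:, act]
        bad = ~np.all(np.isfinite(gnew), axis=1)
        idx = np.nonzero(act)[0]
        if bad.any():
            alive[idx[bad]] = False
            keep = ~bad
            idx = idx[keep]
            gnew = gnew[keep]
            if idx.size == 0:
                continue
        gold = gamma[idx]
        gamma[idx] = gnew
        eta[:, idx] = Z @ gnew.T
        mu[:, idx] = fl.mu(eta[:, idx])
        rel = np.max(np.abs(gnew - gold), axis=1) / \
            (np.max(np.abs(gnew), axis=1) + 1e-12)
        converged[idx[rel < tol]] = True
    converged &= alive
    return eta, mu, converged


def bootstrap_adjust(ds: Dataset, menu: Sequence[CodingSpec],
                     fl: FamilyLink, B: int, seed: int,
                     add_one: bool = False,
                     max_fail_frac: float = 0.01) -> MinPState:
    """Parametric-bootstrap minP procedure.

    The null model (adjustment covariates only) is fitted by maximum
    likelihood; each replicate simulates a new outcome per subject from the
    fitted family (Bernoulli(mu_i), Poisson(mu_i) or Normal(mu_i, phi)),
    keeping X and Z fixed so the codings are realised once, then re-fits
    the null on the simulated outcome and recomputes all K score tests.
    Replicates are processed in vectorised chunks.  Replicates whose null
    re-fit fails (or whose score variance degenerates) are redrawn and
    counted; more than ``max_fail_frac`` of B failures aborts.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not menu:
        raise ValueError("empty coding menu")
    nf, designs, results = _observed(ds, menu, fl)
    p_obs = tuple(res.p_value for res in results)
    p_min = min(p_obs)
    C, slices = _blocks(designs)
    Z = nf.Z
    Zt = Z.T.copy()
    mu0, phi0 = nf.mu, nf.dispersion
    rng = _rng(seed, _BOOT_STREAM)
    n = ds.n
    minima = np.empty(B)
    filled = 0
    n_redrawn = 0
    max_fail = max(1.0, max_fail_frac * B)
    while filled < B:
        m = min(_CHUNK, B - filled)
        Ystar = _simulate_outcomes(rng, mu0, phi0, fl, m)
        eta, mu, ok = _batch_irls(Ystar, Z, fl)
        pm = np.full(m, np.nan)
        if ok.any():
            eo, muo, Yo = eta[:, ok], mu[:, ok], Ystar[:, ok]
            d = fl.dmu_deta(eo)
            v = fl.variance(muo)
            if fl.family == "gaussian":
                phi = np.sum((Yo - muo) ** 2, axis=0) / n
            else:
                phi = np.ones(int(ok.sum()))
            with np.errstate(divide="ignore", invalid="ignore"):
                w = d * d / (v * phi[None, :])
                r = d * (Yo - muo) / (v * phi[None, :])
            A = np.einsum("nm,nq,ns->mqs", w, Z, Z)
            try:
                G = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                G = np.linalg.pinv(A)
            U, V = _batch_scores_shared_design(C, r, w, Zt, G)
            pm[ok] = _batch_min_p(U, V, slices)
        good = np.isfinite(pm)
        n_redrawn += int(m - good.sum())
        if n_redrawn > max_fail:
            raise DataQualityError(
                f"more than {max_fail_frac:.0%} of bootstrap replicates "
                "failed to re-fit the null model; the fitted null is too "
                "unstable to bootstrap")
        k = int(good.sum())
        minima[filled:filled + k] = pm[good]
        filled += k
    return MinPState("bootstrap", p_min, p_obs, B, minima, seed,
                     n_redrawn, add_one)


# --------------------------------------------------------------------------
# Best coding and full report
# --------------------------------------------------------------------------

def best_coding(results: Sequence[ScoreTestResult]) -> tuple[str, bool]:
    """Label of the coding with the smallest p-value (equivalently the
    largest |T| among 1-df codings).  Exact ties resolve to the first in
    menu order; the second element flags whether a tie occurred."""
    if not results:
        raise ValueError("no score-test results")
    p = [res.p_value for res in results]
    i = int(np.argmin(p))
    tie = p.count(p[i]) > 1
    return results[i].label, tie


@dataclass(frozen=True)
class AdjustedReport:
    """Everything the analysis produced: per-coding tests, the best coding,
    and every requested correction (exact carries a not-applicable reason
    when the menu contains multi-df codings)."""

    family: str
    link: str
    n: int
    K: int
    results: tuple                      # ScoreTestResult per coding
    designs: tuple                      # CodedDesign per coding
    best: str
    best_tie: bool
    p_min: float
    methods: tuple
    bonferroni: float | None = None
    exact: ExactResult | None = None
    exact_na_reason: str | None = None
    permutation: MinPState | None = None
    bootstrap: MinPState | None = None
    correlation: np.ndarray | None = None
    B: int | None = None
    seed: int | None = None

    # ---- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        codings = []
        for res, des in zip(self.results, self.designs):
            codings.append({
                "label": res.label,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "thresholds": list(des.thresholds),
                "zeta": des.zeta,
            })
        out = {
            "model": {"family": self.family, "link": self.link, "n": self.n},
            "K": self.K,
            "codings": codings,
            "best_coding": {"label": self.best, "tie": self.best_tie},
            "p_min_naive": self.p_min,
            "methods": list(self.methods),
            "B": self.B,
            "seed": self.seed,
            "adjusted": {},
        }
        adj = out["adjusted"]
        if "bonferroni" in self.methods:
            adj["bonferroni"] = {"p_value": self.bonferroni}
        if "exact" in self.methods:
            if self.exact is not None:
                adj["exact"] = {
                    "applicable": True,
                    "p_value": self.exact.p_value,
                    "t_max": self.exact.t_max,
                    "integration_error": self.exact.error_estimate,
                }
            else:
                adj["exact"] = {"applicable": False,
                                "reason": self.exact_na_reason}
        for name in ("permutation", "bootstrap"):
            if name in self.methods:
                st: MinPState = getattr(self, name)
                adj[name] = {
                    "p_value": st.estimate,
                    "mc_se": st.mc_se,
                    "B": st.B,
                    "seed": st.seed,
                    "n_redrawn": st.n_redrawn,
                    "add_one": st.add_one,
                }
        if self.correlation is not None:
            out["score_correlation"] = [
                [float(v) for v in row] for row in self.correlation
            ]
        return out

    def to_text(self) -> str:
        lines = [
            f"model: {self.family}-{self.link}, n = {self.n}, "
            f"K = {self.K} codings",
            "",
            f"{'coding':<28}{'statistic':>12}{'df':>4}{'p-value':>12}",
        ]
        for res in self.results:
            lines.append(f"{res.label:<28}{res.statistic:>12.4f}"
                         f"{res.df:>4}{res.p_value:>12.4g}")
        lines.append("")
        lines.append(f"{'method':<16}{'adjusted p':>12}{'+/-':>12}"
                     f"{'applicable':>12}")
        lines.append(f"{'naive min-p':<16}{self.p_min:>12.4g}{'':>12}"
                     f"{'yes':>12}")
        if "bonferroni" in self.methods:
            lines.append(f"{'bonferroni':<16}{self.bonferroni:>12.4g}{'':>12}"
                         f"{'yes':>12}")
        if "exact" in self.methods:
            if self.exact is not None:
                lines.append(f"{'exact (maxT)':<16}"
                             f"{self.exact.p_value:>12.4g}"
                             f"{self.exact.error_estimate:>12.2g}{'yes':>12}")
            else:
                lines.append(f"{'exact (maxT)':<16}{'--':>12}{'':>12}{'no':>12}")
        for name, title in (("permutation", "permutation"),
                            ("bootstrap", "bootstrap")):
            if name in self.methods:
                st: MinPState = getattr(self, name)
                lines.append(f"{title:<16}{st.estimate:>12.4g}"
                             f"{st.mc_se:>12.2g}{'yes':>12}")
        lines.append("")
        tie = " (tie: first in menu order)" if self.best_tie else ""
        lines.append(f"best coding: {self.best}{tie}")
        return "\n".join(lines)


_EXACT_OK_DF = 1


def run_all(ds: Dataset, menu: Sequence[CodingSpec], fl: FamilyLink,
            methods: Sequence[str] = ("bonferroni", "exact",
                                      "permutation", "bootstrap"),
            B: int = 1000, seed: int | None = None,
            add_one: bool = False, abseps: float = 1e-5) -> AdjustedReport:
    """Run the requested corrections over one menu and assemble the report.

    The exact method is silently marked not-applicable (rather than
    raising) when the menu contains a multi-df coding — a categorical
    transformation with more than two classes or a fractional polynomial of
    degree above one.
    """
    methods = tuple(methods)
    allowed = {"bonferroni", "exact", "permutation", "bootstrap"}
    bad = set(methods) - allowed
    if bad:
        raise ValueError(f"unknown method(s): {sorted(bad)}")
    if not menu:
        raise ValueError("empty coding menu")
    resampling = [m for m in methods if m in ("permutation", "bootstrap")]
    if resampling and seed is None:
        raise ValueError(
            f"methods {resampling} need an explicit seed for reproducibility")

    nf, designs, results = _observed(ds, menu, fl)
    p_obs = [res.p_value for res in results]
    p_min = min(p_obs)
    best, tie = best_coding(results)
    K = len(menu)

    bonf = bonferroni_adjust(p_min, K) if "bonferroni" in methods else None

    exact = exact_na = corr = None
    if "exact" in methods:
        multi = [d.label for d in designs if d.df != _EXACT_OK_DF]
        if multi:
            exact_na = ("exact correction requires 1-df codings (binary, "
                        "Box-Cox, degree-1 fractional polynomial); "
                        f"multi-df coding(s) present: {multi}")
        else:
            corr = score_correlation(nf, designs)
            t = [res.statistic for res in results]
            exact = exact_adjust(t, corr, abseps=abseps)

    perm = permutation_adjust(ds, menu, fl, B, seed, add_one) \
        if "permutation" in methods else None
    boot = bootstrap_adjust(ds, menu, fl, B, seed, add_one) \
        if "bootstrap" in methods else None

    return AdjustedReport(
        family=fl.family, link=fl.link, n=ds.n, K=K,
        results=tuple(results), designs=tuple(designs),
        best=best, best_tie=tie, p_min=p_min, methods=methods,
        bonferroni=bonf, exact=exact, exact_na_reason=exact_na,
        permutation=perm, bootstrap=boot, correlation=corr,
        B=B if resampling else None, seed=seed if resampling else None,
    )
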