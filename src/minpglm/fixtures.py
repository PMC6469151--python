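"""Synthetic-data scenarios for testing and calibration studies.

Generates reproducible (Y, X, Z) datasets for each supported family: null
scenarios (X independent of Y given Z), threshold alternatives (a log-odds
or mean shift above a quantile of X), and smooth alternatives driven by a
named Box-Cox or fractional-polynomial transform.  The variable of interest
defaults to a lognormal law so that power transforms apply without
shifting; a normal-X option exercises the shift path.  A low-prevalence
binomial scenario mirrors a nested case-control design (a few dozen cases
among ~300 subjects).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special

from .codings import CodingSpec, empirical_quantile, realize
from .glm import Dataset, FamilyLink

__all__ = [
    "ScenarioSpec",
    "generate",
    "generate_dataset",
    "binomial_intercept",
    "write_csv",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one synthetic scenario.

    effect is ``"none"`` (Y independent of X given Z by construction),
    ``"threshold"`` (shift ``delta`` on the linear predictor when X is at
    or above its ``tau``-quantile) or ``"smooth"`` (``delta`` times the
    column(s) of ``effect_coding`` realised on X).  ``gamma`` holds the
    true adjustment coefficients, intercept first, length n_adjust + 1.
    """

    n: int
    family: str = "binomial"
    link: str = "logit"
    n_adjust: int = 1
    gamma: tuple = (0.0, 0.3)
    effect: str = "none"
    tau: float = 0.5
    delta: float = 0.0
    effect_coding: CodingSpec | None = None
    x_dist: str = "lognormal"       # lognormal | normal | uniform
    dispersion: float = 1.0         # gaussian residual variance
    seed: int = 0

    def __post_init__(self):
        if len(self.gamma) != self.n_adjust + 1:
            raise ValueError("gamma must have length n_adjust + 1 "
                             "(intercept first)")
        if self.effect not in ("none", "threshold", "smooth"):
            raise ValueError(f"unknown effect type {self.effect!r}")
        if self.effect == "smooth" and self.effect_coding is None:
            raise ValueError("smooth effect needs an effect_coding")
        if self.x_dist not in ("lognormal", "normal", "uniform"):
            raise ValueError(f"unknown x distribution {self.x_dist!r}")

    def to_json(self) -> str:
        d = asdict(self)
        if self.effect_coding is not None:
            d["effect_coding"] = self.effect_coding.label
        return json.dumps(d, indent=2)


def _draw_x(rng: np.random.Generator, spec: ScenarioSpec) -> np.ndarray:
    if spec.x_dist == "lognormal":
        return rng.lognormal(mean=0.0, sigma=0.5, size=spec.n)
    if spec.x_dist == "normal":
        return rng.normal(0.0, 1.0, size=spec.n)
    return rng.uniform(0.0, 1.0, size=spec.n)


def generate(spec: ScenarioSpec) -> pd.DataFrame:
    """Generate one dataset as a DataFrame (columns y, x, z1..zk).

    Adjustment covariates are independent standard normals.  The same spec
    and seed always produce the identical frame; with ``delta = 0`` the
    threshold and smooth alternatives coincide with the null generator
    draw-for-draw (the effect term is exactly zero).
    """
    rng = np.random.default_rng(spec.seed)
    fl = FamilyLink.from_names(spec.family, spec.link)
    Zadj = rng.normal(size=(spec.n, spec.n_adjust)) if spec.n_adjust else \
        np.empty((spec.n, 0))
    x = _draw_x(rng, spec)
    eta = spec.gamma[0] + Zadj @ np.asarray(spec.gamma[1:], dtype=float)
    if spec.effect == "threshold":
        cut = empirical_quantile(x, spec.tau)
        eta = eta + spec.delta * (x >= cut)
    elif spec.effect == "smooth":
        M = realize(spec.effect_coding, x).matrix
        eta = eta + spec.delta * M.sum(axis=1)
    mu = fl.mu(eta)
    if spec.family == "binomial":
        y = (rng.random(spec.n) < mu).astype(float)
    elif spec.family == "poisson":
        y = rng.poisson(mu).astype(float)
    else:
        y = rng.normal(mu, np.sqrt(spec.dispersion))
    cols = {"y": y, "x": x}
    for j in range(spec.n_adjust):
        cols[f"z{j + 1}"] = Zadj[:, j]
    return pd.DataFrame(cols)


def generate_dataset(spec: ScenarioSpec) -> Dataset:
    """Generate and package as a Dataset (intercept prepended to Z)."""
    df = generate(spec)
    adjust = [f"z{j + 1}" for j in range(spec.n_adjust)]
    return Dataset.from_frame(df, "y", "x", adjust)


def binomial_intercept(target_prevalence: float, gamma_adjust: Sequence[float],
                       link: str = "logit") -> float:
    """Intercept giving a target marginal prevalence with N(0,1) adjusters.

    With independent standard-normal adjustment covariates the linear
    combination gamma.Z is N(0, s^2), s^2 = sum gamma_j^2, so the marginal
    prevalence is the Gaussian average of the inverse link, solved for the
    intercept by root finding.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target prevalence must lie in (0, 1)")
    fl = FamilyLink.from_names("binomial", link)
    s = float(np.sqrt(np.sum(np.square(gamma_adjust)))) if len(gamma_adjust) \
        else 0.0
    if s == 0.0:
        return float(fl.linkfun(np.asarray(target_prevalence)))

    def prevalence(g0: float) -> float:
        f = lambda u: fl.mu(np.asarray(g0 + s * u)) * \
            np.exp(-0.5 * u * u) / np.sqrt(2 * np.pi)
        val, _ = integrate.quad(f, -8.5, 8.5)
        return val

    lo, hi = -30.0, 30.0
    return float(optimize.brentq(
        lambda g0: prevalence(g0) - target_prevalence, lo, hi, xtol=1e-10))


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a generated dataset as a plain CSV with header."""
    df.to_csv(path, index=False)
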