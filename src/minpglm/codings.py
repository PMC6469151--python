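"""Coding menu: transformations of the continuous variable of interest.

A *coding* is a deterministic transform g_k mapping the variable of
interest X to one or more derived regressors: a binary indicator at a
quantile or raw cutoff, a dummy block for a multi-class categorisation, a
Box-Cox power transform, or a fractional polynomial.  ``CodingSpec``
describes the transform before seeing data; ``realize`` turns it into a
``CodedDesign`` — the realised column block on a concrete sample, with its
degrees of freedom and any realised thresholds.

Conventions fixed here and relied on throughout:

* quantiles are linear-interpolation ("type 7") sample quantiles;
* a value exactly equal to a threshold goes to the UPPER class (X >= c);
* degenerate codings (constant column, empty class) are hard errors —
  silently dropping one would change K and hence every correction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CodingSpec",
    "CodedDesign",
    "CodingError",
    "DegenerateCodingError",
    "MenuConfigError",
    "empirical_quantile",
    "make_dichotomous",
    "make_categorical",
    "make_boxcox",
    "make_fracpoly",
    "auto_dichotomies",
    "auto_categoricals",
    "build_menu",
    "realize",
    "realize_menu",
]


class CodingError(Exception):
    """Base class for coding construction failures."""


class DegenerateCodingError(CodingError):
    """A coding produced a constant column or an empty class."""


class MenuConfigError(CodingError):
    """Invalid or conflicting coding-menu configuration."""


def _fmt(v: float) -> str:
    return f"{v:g}"


@dataclass(frozen=True)
class CodingSpec:
    """Declarative description of one transformation, before seeing data.

    kind is one of ``dichotomous`` (one quantile level), ``categorical``
    (ordered quantile levels), ``rawcut`` (ordered raw thresholds, 1 for a
    dichotomy), ``boxcox`` (exponent lambda), ``fracpoly`` (sorted power
    vector from the Royston-Altman set, optional shift zeta).
    """

    kind: str
    levels: tuple = ()
    thresholds: tuple = ()
    lam: float | None = None
    powers: tuple = ()
    zeta: float | None = None
    label: str = field(default="", compare=False)

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        object.__setattr__(self, "thresholds",
                           tuple(float(v) for v in self.thresholds))
        object.__setattr__(self, "powers", tuple(float(v) for v in self.powers))
        if not self.label:
            object.__setattr__(self, "label", self._default_label())
        self._validate()

    def _default_label(self) -> str:
        if self.kind == "dichotomous":
            return f"dicho(q={_fmt(self.levels[0])})"
        if self.kind == "categorical":
            return "categ(q=" + ",".join(map(_fmt, self.levels)) + ")"
        if self.kind == "rawcut":
            return "cutpoint(" + ",".join(map(_fmt, self.thresholds)) + ")"
        if self.kind == "boxcox":
            return f"boxcox(lambda={_fmt(self.lam)})"
        if self.kind == "fracpoly":
            return "fp(" + ",".join(map(_fmt, self.powers)) + ")"
        raise MenuConfigError(f"unknown coding kind {self.kind!r}")

    def _validate(self):
        if self.kind == "dichotomous":
            if len(self.levels) != 1 or not 0 < self.levels[0] < 1:
                raise MenuConfigError(
                    f"{self.label}: dichotomous coding needs one quantile "
                    "level strictly inside (0, 1)")
        elif self.kind == "categorical":
            if len(self.levels) < 2:
                raise MenuConfigError(
                    f"{self.label}: categorical coding needs >= 2 cutoff "
                    "levels (use a dichotomous coding for one)")
            if any(not 0 < v < 1 for v in self.levels):
                raise MenuConfigError(
                    f"{self.label}: quantile levels must lie in (0, 1)")
            if any(a >= b for a, b in zip(self.levels, self.levels[1:])):
                raise MenuConfigError(
                    f"{self.label}: quantile levels must be strictly increasing")
        elif self.kind == "rawcut":
            if not self.thresholds:
                raise MenuConfigError(f"{self.label}: no thresholds given")
            if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
                raise MenuConfigError(
                    f"{self.label}: raw thresholds must be strictly increasing")
        elif self.kind == "boxcox":
            if self.lam is None:
                raise MenuConfigError(f"{self.label}: lambda missing")
        elif self.kind == "fracpoly":
            if not self.powers:
                raise MenuConfigError(f"{self.label}: empty power vector")
            if any(a > b for a, b in zip(self.powers, self.powers[1:])):
                raise MenuConfigError(
                    f"{self.label}: powers must be sorted non-decreasing")
            allowed = _fp_power_set(len(self.powers))
            bad = [p for p in self.powers if p not in allowed]
            if bad:
                raise MenuConfigError(
                    f"{self.label}: powers {bad} outside the admissible set "
                    f"{sorted(allowed)}")
        else:
            raise MenuConfigError(f"unknown coding kind {self.kind!r}")

    # convenience constructors -------------------------------------------
    @staticmethod
    def dichotomous(level: float) -> "CodingSpec":
        return CodingSpec("dichotomous", levels=(level,))

    @staticmethod
    def categorical(levels: Sequence[float]) -> "CodingSpec":
        return CodingSpec("categorical", levels=tuple(levels))

    @staticmethod
    def rawcut(thresholds: Sequence[float]) -> "CodingSpec":
        return CodingSpec("rawcut", thresholds=tuple(thresholds))

    @staticmethod
    def boxcox(lam: float) -> "CodingSpec":
        return CodingSpec("boxcox", lam=float(lam))

    @staticmethod
    def fracpoly(powers: Sequence[float], zeta: float | None = None) -> "CodingSpec":
        return CodingSpec("fracpoly", powers=tuple(sorted(powers)), zeta=zeta)


def _fp_power_set(m: int) -> set:
    """Royston-Altman admissible powers: integers -max(3,m)..max(3,m) plus ±0.5."""
    top = max(3, m)
    s = {float(k) for k in range(-top, top + 1)}
    s.update({-0.5, 0.5})
    return s


@dataclass(frozen=True)
class CodedDesign:
    """The realised column block of one coding on a concrete sample."""

    label: str
    matrix: np.ndarray          # n rows, df columns
    df: int
    spec: CodingSpec
    thresholds: tuple = ()      # realised raw cutoffs (quantile codings)
    zeta: float | None = None   # realised shift (fractional polynomials)

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        object.__setattr__(self, "matrix", M)
        object.__setattr__(self, "df", int(M.shape[1]))


def _check_nonconstant(M: np.ndarray, spec: CodingSpec) -> None:
    for j in range(M.shape[1]):
        if np.ptp(M[:, j]) == 0:
            raise DegenerateCodingError(
                f"coding {spec.label!r} produced a constant column "
                f"(column {j}); its threshold or transform is degenerate "
                "on this sample")


# --------------------------------------------------------------------------
# Primitive realisations
# --------------------------------------------------------------------------

def empirical_quantile(x, p: float) -> float:
    """Linear-interpolation ("type 7") sample quantile at level p in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if not 0 < p < 1:
        raise ValueError("quantile level must lie strictly inside (0, 1)")
    return float(np.quantile(x, p))


def make_dichotomous(x, spec: CodingSpec) -> CodedDesign:
    """Binary indicator 1{X >= c}; c is the sample quantile at the spec's
    level, or the raw value for a single-threshold rawcut spec."""
    x = np.asarray(x, dtype=float)
    if spec.kind == "dichotomous":
        c = empirical_quantile(x, spec.levels[0])
    elif spec.kind == "rawcut" and len(spec.thresholds) == 1:
        c = spec.thresholds[0]
    else:
        raise MenuConfigError(
            f"{spec.label}: not a dichotomous/single-cutpoint spec")
    col = (x >= c).astype(float)
    design = CodedDesign(spec.label, col, 1, spec, thresholds=(float(c),))
    _check_nonconstant(design.matrix, spec)
    return design


def make_categorical(x, spec: CodingSpec) -> CodedDesign:
    """Dummy block for an ordered categorisation with m-1 cutoffs.

    Class j (1 <= j <= m-1) holds c_{j-1} <= X < c_j with the last class
    unbounded above; class 0 (X < c_0) is the reference.  Boundaries are
    closed on the left, matching the dichotomous convention.
    """
    x = np.asarray(x, dtype=float)
    if spec.kind == "categorical":
        cuts = [empirical_quantile(x, p) for p in spec.levels]
    elif spec.kind == "rawcut" and len(spec.thresholds) >= 2:
        cuts = list(spec.thresholds)
    else:
        raise MenuConfigError(f"{spec.label}: not a categorical spec")
    cuts_arr = np.asarray(cuts)
    cls = (x[:, None] >= cuts_arr[None, :]).sum(axis=1)
    m = len(cuts) + 1
    counts = np.bincount(cls, minlength=m)
    if np.any(counts == 0):
        raise DegenerateCodingError(
            f"coding {spec.label!r} leaves empty class(es) on this sample; "
            f"class counts {counts.tolist()} for realised cutoffs "
            f"{[float(c) for c in cuts]}")
    M = np.zeros((x.shape[0], m - 1))
    for j in range(1, m):
        M[:, j - 1] = (cls == j).astype(float)
    return CodedDesign(spec.label, M, m - 1, spec,
                       thresholds=tuple(float(c) for c in cuts))


def make_boxcox(x, spec: CodingSpec) -> CodedDesign:
    """Box-Cox power transform: (X^lambda - 1)/lambda, or ln X at lambda=0.

    Requires strictly positive X; the power form is used for every
    lambda != 0 (the negative exponents listed in the classical lambda
    table are monotone-equivalent to their reciprocal transforms).
    """
    x = np.asarray(x, dtype=float)
    if spec.kind != "boxcox":
        raise MenuConfigError(f"{spec.label}: not a boxcox spec")
    if np.any(x <= 0):
        raise CodingError(
            f"coding {spec.label!r} requires strictly positive X; shift the "
            "variable before applying a Box-Cox transform")
    lam = spec.lam
    col = np.log(x) if lam == 0 else (np.power(x, lam) - 1.0) / lam
    design = CodedDesign(spec.label, col, 1, spec)
    _check_nonconstant(design.matrix, spec)
    return design


def default_zeta(x) -> float:
    """Shift origin for non-positive samples: min(X) minus the smallest
    positive gap between distinct sorted values (the lower limit of the
    sample's rounding interval)."""
    x = np.asarray(x, dtype=float)
    u = np.unique(x)
    if u.size < 2:
        raise DegenerateCodingError("variable of interest is constant")
    delta = float(np.min(np.diff(u)))
    return float(u[0] - delta)


def make_fracpoly(x, spec: CodingSpec) -> CodedDesign:
    """Fractional-polynomial block H_1..H_m for sorted powers a_1..a_m.

    H_j = X^(a_j) when a_j != a_{j-1} (with X^(0) = ln X and a_0 = 0) and
    H_j = H_{j-1} ln X for a repeated power.  When min(X) <= 0 the sample is
    shifted by zeta (spec override, else ``default_zeta``) so all values are
    strictly positive; the realised shift is recorded.
    """
    x = np.asarray(x, dtype=float)
    if spec.kind != "fracpoly":
        raise MenuConfigError(f"{spec.label}: not a fracpoly spec")
    zeta = spec.zeta
    if zeta is None and np.min(x) <= 0:
        zeta = default_zeta(x)
    xs = x - zeta if zeta is not None else x
    if np.any(xs <= 0):
        raise CodingError(
            f"coding {spec.label!r}: shifted values are not strictly "
            f"positive (zeta={zeta}); choose a smaller zeta")
    lx = np.log(xs)
    cols = []
    H = np.ones_like(xs)        # H_0
    prev_a = 0.0                # a_0 = 0
    for j, a in enumerate(spec.powers):
        if j > 0 and a == prev_a:
            H = H * lx
        else:
            H = lx.copy() if a == 0 else np.power(xs, a)
        cols.append(H)
        prev_a = a
    M = np.column_stack(cols)
    design = CodedDesign(spec.label, M, M.shape[1], spec,
                         zeta=None if zeta is None else float(zeta))
    _check_nonconstant(design.matrix, spec)
    return design


_REALIZERS = {
    "dichotomous": make_dichotomous,
    "categorical": make_categorical,
    "boxcox": make_boxcox,
    "fracpoly": make_fracpoly,
}


def realize(spec: CodingSpec, x) -> CodedDesign:
    """Realise one CodingSpec on a sample."""
    if spec.kind == "rawcut":
        fn = make_dichotomous if len(spec.thresholds) == 1 else make_categorical
    else:
        fn = _REALIZERS[spec.kind]
    return fn(x, spec)


def realize_menu(menu: Sequence[CodingSpec], x) -> list[CodedDesign]:
    return [realize(spec, x) for spec in menu]


# --------------------------------------------------------------------------
# Quantile-based auto menus
# --------------------------------------------------------------------------

def auto_dichotomies(nb: int) -> list[CodingSpec]:
    """nb dichotomies at the interior quantiles of order nb+1.

    One transformation uses the median, two the terciles, three the
    quartiles, and so on: levels j/(nb+1) for j = 1..nb.
    """
    if nb < 1:
        raise MenuConfigError("nb_dicho must be >= 1")
    return [CodingSpec.dichotomous(j / (nb + 1)) for j in range(1, nb + 1)]


def auto_categoricals(nb: int) -> list[CodingSpec]:
    """nb categorisations of increasing resolution.

    Transformation j (j = 1..nb) cuts at the full interior quantile set of
    order j+2 — terciles, then quartiles, then quintiles, ... — giving j+2
    classes.
    """
    if nb < 1:
        raise MenuConfigError("nb_categ must be >= 1")
    out = []
    for j in range(1, nb + 1):
        order = j + 2
        out.append(CodingSpec.categorical([i / order for i in range(1, order)]))
    return out


# --------------------------------------------------------------------------
# Menu configuration block
# --------------------------------------------------------------------------

def _clean_row(row) -> list[float]:
    """Drop NA/None padding from a categ/cutpoint matrix row."""
    vals = []
    for v in row:
        if v is None:
            continue
        v = float(v)
        if math.isnan(v):
            continue
        vals.append(v)
    return vals


def build_menu(config: dict) -> list[CodingSpec]:
    """Turn a menu-configuration mapping into a list of CodingSpecs.

    Recognised keys: ``dicho`` (list of quantile levels), ``nb_dicho``
    (int), ``categ`` (list of quantile-level rows, NA padding allowed),
    ``nb_categ`` (int), ``cutpoint`` (list of raw-threshold rows), ``boxcox``
    (list of lambdas), ``fp`` (list of power rows), ``zeta`` (optional shift
    for fractional polynomials).  ``dicho``/``nb_dicho`` are mutually
    exclusive, as are ``categ``/``nb_categ``.
    """
    known = {"dicho", "nb_dicho", "categ", "nb_categ", "cutpoint",
             "boxcox", "fp", "zeta"}
    unknown = set(config) - known
    if unknown:
        raise MenuConfigError(f"unknown menu key(s): {sorted(unknown)}")
    if config.get("dicho") is not None and config.get("nb_dicho") is not None:
        raise MenuConfigError("only one of 'dicho' and 'nb_dicho' may be used")
    if config.get("categ") is not None and config.get("nb_categ") is not None:
        raise MenuConfigError("only one of 'categ' and 'nb_categ' may be used")

    zeta = config.get("zeta")
    menu: list[CodingSpec] = []
    if config.get("dicho") is not None:
        menu += [CodingSpec.dichotomous(v) for v in config["dicho"]]
    if config.get("nb_dicho") is not None:
        menu += auto_dichotomies(int(config["nb_dicho"]))
    if config.get("categ") is not None:
        for row in config["categ"]:
            vals = _clean_row(row)
            if len(vals) == 1:
                raise MenuConfigError(
                    "categ rows need >= 2 cutoffs; use dicho for a binary "
                    "transformation")
            menu.append(CodingSpec.categorical(vals))
    if config.get("nb_categ") is not None:
        menu += auto_categoricals(int(config["nb_categ"]))
    if config.get("cutpoint") is not None:
        for row in config["cutpoint"]:
            menu.append(CodingSpec.rawcut(_clean_row(row)))
    if config.get("boxcox") is not None:
        menu += [CodingSpec.boxcox(v) for v in config["boxcox"]]
    if config.get("fp") is not None:
        for row in config["fp"]:
            menu.append(CodingSpec.fracpoly(_clean_row(row), zeta=zeta))
    if not menu:
        raise MenuConfigError("empty coding menu")
    labels = [s.label for s in menu]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise MenuConfigError(f"duplicate coding label(s): {sorted(dupes)}")
    return menu
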