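"""Equilibrium binding models and dissociation-constant fitting.

A dansylated peptide at fixed total concentration ``n`` is titrated with
increasing total protein concentration ``a`` ([A]_0, the varied species).
For a 1:1 complex the bound concentration follows the standard quadratic
solution of the mass-action equilibrium, and the observed fluorescence is

    F(a) = C + k*a + B * [PA](a) / n

with [PA] the complex concentration, B the total fluorescence change at
saturation, C the signal at a = 0 and k a linear drift term describing the
slope at high protein concentration.  Under pseudo-first-order conditions
(peptide negligible against protein) the quadratic collapses to the
hyperbola F(a) = C + k*a + B*a/(K_D + a).

Fitting is nonlinear least squares over (K_D, B, C, k), with K_D
log-parameterised to keep it positive, optionally augmented with a free
stoichiometry multiplier m applied to the varied-species concentration
(a_eff = m*a).  Replicates are fitted independently and summarised as
mean +/- s.d. of the recovered K_D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingParams",
    "TitrationCurve",
    "FitResult",
    "bound_complex",
    "quadratic_model",
    "hyperbolic_model",
    "fit_titration",
    "fold_change",
    "FoldChange",
]


@dataclass(frozen=True)
class BindingParams:
    """Parameters of the quadratic/hyperbolic titration model for one complex.

    kd : dissociation constant (uM)
    n  : total concentration of the non-varied species, i.e. the peptide (uM)
    b  : total fluorescence change at saturation (arbitrary units)
    c  : fluorescence at zero protein (arbitrary units)
    k  : linear slope at high protein concentration (units per uM)
    """

    kd: float
    n: float = 5.0
    b: float = 1.0
    c: float = 0.0
    k: float = 0.001

    def __post_init__(self) -> None:
        if not (self.kd > 0):
            raise ValueError(f"kd must be positive, got {self.kd}")
        if not (self.n > 0):
            raise ValueError(f"n must be positive, got {self.n}")
        for name in ("b", "c", "k"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")


@dataclass
class TitrationCurve:
    """A titration: protein concentrations vs fluorescence, per replicate.

    ``f`` has shape (n_replicates, n_points); a single-replicate 1-D array is
    accepted and promoted.
    """

    a: np.ndarray
    f: np.ndarray
    n_fixed: float = 5.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.f = np.atleast_2d(np.asarray(self.f, dtype=float))
        if self.a.ndim != 1:
            raise ValueError("a must be one-dimensional")
        if np.any(self.a < 0):
            raise ValueError("protein concentrations must be non-negative")
        if self.f.shape[1] != self.a.shape[0]:
            raise ValueError(
                f"f has {self.f.shape[1]} points per replicate, "
                f"but a has {self.a.shape[0]}"
            )
        if not (self.n_fixed > 0):
            raise ValueError("n_fixed must be positive")

    @property
    def n_replicates(self) -> int:
        return self.f.shape[0]


def bound_complex(a, n, kd):
    """Concentration of the 1:1 complex at total concentrations a, n.

    Closed form from mass action: the smaller root of
    x**2 - (n + a + kd) x + n a = 0, guarded against tiny negative
    discriminants from floating-point cancellation.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("a must be non-negative")
    if not (n > 0 and kd > 0):
        raise ValueError("n and kd must be positive")
    s = n + a + kd
    disc = np.clip(s * s - 4.0 * n * a, 0.0, None)
    out = 0.5 * (s - np.sqrt(disc))
    # the root is mathematically within [0, min(n, a)]; clip rounding spill
    return np.clip(out, 0.0, np.minimum(n, a))


def quadratic_model(a, params: BindingParams):
    """Observed fluorescence under the full quadratic binding model."""
    a = np.asarray(a, dtype=float)
    frac = bound_complex(a, params.n, params.kd) / params.n
    return params.c + params.k * a + params.b * frac


def hyperbolic_model(a, params: BindingParams):
    """Pseudo-first-order simplification: F = C + k*a + B*a/(K_D + a)."""
    a = np.asarray(a, dtype=float)
    return params.c + params.k * a + params.b * a / (params.kd + a)


@dataclass
class FitResult:
    """Outcome of fitting one titration (possibly several replicates)."""

    model: str
    kd: float = math.nan
    kd_sd: float = 0.0
    b: float = math.nan
    c: float = math.nan
    k: float = math.nan
    m: float = math.nan          # stoichiometry multiplier (nan if not fitted)
    m_sd: float = 0.0
    kd_replicates: list = field(default_factory=list)
    stderr: dict = field(default_factory=dict)
    rss: float = math.nan
    converged: bool = False
    no_interaction: bool = False


def _predict(a, n_fixed, model, kd, b, c, k, m=1.0):
    a_eff = m * a
    if model == "quadratic":
        frac = bound_complex(a_eff, n_fixed, kd) / n_fixed
    elif model == "hyperbolic":
        frac = a_eff / (kd + a_eff)
    else:
        raise ValueError(f"unknown model {model!r}")
    return c + k * a + b * frac


def _initial_guess(a, f):
    c0 = float(f[np.argmin(a)])
    span = float(np.ptp(f))
    b0 = span if span > 0 else 1.0
    # concentration at half the observed rise
    half = c0 + 0.5 * (float(f[np.argmax(a)]) - c0)
    idx = int(np.argmin(np.abs(f - half)))
    kd0 = max(float(a[idx]), 1e-3 * max(float(a.max()), 1.0))
    # terminal slope over the top third of the concentration range
    hi = a >= (2.0 / 3.0) * a.max()
    if hi.sum() >= 2:
        k0 = float(np.polyfit(a[hi], f[hi], 1)[0])
    else:
        k0 = 0.0
    return kd0, b0, c0, k0


def _model_jacobian(a, n_fixed, model, kd, b, c, k, m, free_stoichiometry):
    """Analytic Jacobian of the prediction wrt (log kd, b, c, k[, log m])."""
    a_eff = m * a
    if model == "quadratic":
        s = n_fixed + a_eff + kd
        disc = np.sqrt(np.clip(s * s - 4.0 * n_fixed * a_eff, 1e-30, None))
        x = 0.5 * (s - disc)
        dx_dkd = 0.5 * (1.0 - s / disc)
        dx_da = 0.5 * (1.0 - (s - 2.0 * n_fixed) / disc)
        frac = x / n_fixed
        dfrac_dkd = dx_dkd / n_fixed
        dfrac_da = dx_da / n_fixed
    else:
        denom = kd + a_eff
        frac = a_eff / denom
        dfrac_dkd = -a_eff / (denom * denom)
        dfrac_da = kd / (denom * denom)
    cols = [b * dfrac_dkd * kd,            # d/d(log kd)
            frac,                          # d/db
            np.ones_like(a),               # d/dc
            a]                             # d/dk
    if free_stoichiometry:
        cols.append(b * dfrac_da * a_eff)  # d/d(log m)
    return np.column_stack(cols)


def _fit_single(a, f, n_fixed, model, free_stoichiometry):
    kd0, b0, c0, k0 = _initial_guess(a, f)

    def unpack(theta):
        # clip the log-parameters so extreme trial steps stay finite
        kd = math.exp(min(max(theta[0], -30.0), 30.0))
        m = (math.exp(min(max(theta[4], -15.0), 15.0))
             if free_stoichiometry else 1.0)
        return kd, theta[1], theta[2], theta[3], m

    def residuals(theta):
        kd, b, c, k, m = unpack(theta)
        return _predict(a, n_fixed, model, kd, b, c, k, m) - f

    def jacobian(theta):
        kd, b, c, k, m = unpack(theta)
        return _model_jacobian(a, n_fixed, model, kd, b, c, k, m,
                               free_stoichiometry)

    def run(kd_init):
        x0 = [math.log(kd_init), b0, c0, k0]
        if free_stoichiometry:
            x0.append(0.0)  # log m = 0 -> m = 1
        return least_squares(
            residuals, x0, jac=jacobian, method="lm",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=8000,
        )

    sol = run(kd0)
    scale = max(float(np.ptp(f)) ** 2, 1e-30)
    if not sol.success or not np.isfinite(sol.cost):
        sol = None
    # multistart over log-spaced kd when the first attempt failed or is poor
    if sol is None or sol.cost > 1e-4 * scale:
        for mult in (0.01, 0.1, 1.0, 10.0, 100.0):
            cand = run(kd0 * mult)
            if cand.success and (sol is None or cand.cost < sol.cost):
                sol = cand
    if sol is None:
        return None
    kd = math.exp(min(max(sol.x[0], -30.0), 30.0))
    b, c, k = sol.x[1], sol.x[2], sol.x[3]
    m = (math.exp(min(max(sol.x[4], -15.0), 15.0))
         if free_stoichiometry else math.nan)
    # asymptotic standard errors from the Jacobian at the solution
    stderr = {}
    try:
        jac = sol.jac
        dof = max(len(f) - len(sol.x), 1)
        s2 = 2.0 * sol.cost / dof
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        stderr = {"kd": kd * se[0], "b": se[1], "c": se[2], "k": se[3]}
        if free_stoichiometry:
            stderr["m"] = m * se[4]
    except np.linalg.LinAlgError:
        pass
    return {
        "kd": kd, "b": b, "c": c, "k": k, "m": m,
        "rss": 2.0 * sol.cost, "stderr": stderr, "success": bool(sol.success),
    }


def fit_titration(
    curve: TitrationCurve,
    model: str = "quadratic",
    free_stoichiometry: bool = False,
) -> FitResult:
    """Fit a titration curve, one replicate at a time.

    Returns a :class:`FitResult` with mean +/- s.d. of K_D across replicates.
    A flat curve (no fluorescence change anywhere) is reported as
    ``no_interaction`` rather than raising; non-convergence sets
    ``converged = False`` on the result instead of raising.
    """
    if model not in ("quadratic", "hyperbolic"):
        raise ValueError(f"unknown model {model!r}")
    a = curve.a
    if len(np.unique(a)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if not np.any(a > 0):
        raise ValueError("need at least one nonzero concentration")

    res = FitResult(model=model)
    span = float(np.ptp(curve.f))
    fscale = max(np.max(np.abs(curve.f)), 1.0)
    if span <= 1e-12 * fscale:
        res.no_interaction = True
        return res

    fits = []
    for rep in range(curve.n_replicates):
        out = _fit_single(a, curve.f[rep], curve.n_fixed, model,
                          free_stoichiometry)
        if out is not None:
            fits.append(out)
    if not fits:
        return res  # converged stays False

    kds = np.array([ft["kd"] for ft in fits])
    res.kd = float(np.mean(kds))
    res.kd_sd = float(np.std(kds, ddof=1)) if len(kds) > 1 else 0.0
    res.b = float(np.mean([ft["b"] for ft in fits]))
    res.c = float(np.mean([ft["c"] for ft in fits]))
    res.k = float(np.mean([ft["k"] for ft in fits]))
    res.kd_replicates = [float(x) for x in kds]
    res.rss = float(np.sum([ft["rss"] for ft in fits]))
    res.stderr = fits[0]["stderr"] if len(fits) == 1 else {}
    res.converged = all(ft["success"] for ft in fits) and len(fits) == curve.n_replicates
    if free_stoichiometry:
        ms = np.array([ft["m"] for ft in fits])
        res.m = float(np.mean(ms))
        res.m_sd = float(np.std(ms, ddof=1)) if len(ms) > 1 else 0.0
    # saturation amplitude indistinguishable from zero -> no interaction
    if abs(res.b) <= 1e-9 * fscale:
        res.no_interaction = True
    return res


def _round_1sig(x: float) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    one_sig_fig: float


def fold_change(mutant: FitResult, wt: FitResult) -> FoldChange:
    """K_D(mutant) / K_D(wild type), with a one-significant-figure rounding."""
    for which, fit in (("mutant", mutant), ("wild-type", wt)):
        if not fit.converged:
            raise ValueError(f"{which} fit did not converge")
    if wt.kd <= 0:
        raise ValueError("wild-type kd must be positive")
    ratio = mutant.kd / wt.kd
    return FoldChange(ratio=ratio, one_sig_fig=_round_1sig(ratio))
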