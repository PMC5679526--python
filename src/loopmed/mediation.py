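"""Causal mediation analysis for regulatory triads.

The treatment X (miRNA), mediator M (transcription factor) and outcome Y
(gene) are linked by the structural equations

    Y = beta1 + c  X           + e1      (total effect)
    M = beta2 + a  X           + e2      (mediator model)
    Y = beta3 + c' X  + b M    + e3      (outcome model)

For ordinary least squares these satisfy the identity c = a*b + c'. The
average causal mediation effect (ACME) is the part of X's effect routed
through M, the average direct effect (ADE) the remainder:

    ACME = c - c' = a*b,   ADE = c',   TE = ACME + ADE = a*b + c'.

Point identification rests on sequential ignorability (treatment and
mediator as-if random). Nonlinear edges are modelled with cubic
regression splines and the effects computed by counterfactual prediction
(swap the mediator values fitted under treated/control treatment levels,
average the outcome differences). Uncertainty comes from a nonparametric
bootstrap over samples with percentile intervals; the Sobel delta-method
standard error of a*b is reported alongside for the linear case. A
sensitivity analysis traces ACME as a function of the correlation rho
between the mediator- and outcome-model errors, the key quantity violated
when an unobserved confounder drives both M and Y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .loops import CandidateLoop

ORIENTATIONS = ("miRNA_treats_TF_mediates", "TF_treats_miRNA_mediates")

P_EPS = 1e-12


# ---------------------------------------------------------------------------
# model fitting


def _vec(v) -> np.ndarray:
    return np.asarray(v, dtype=float).ravel()


def fit_total_effect(x, y) -> tuple[float, float]:
    """OLS of Y on X; returns (intercept beta1, slope c)."""
    x, y = _vec(x), _vec(y)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant treatment vector")
    xc = x - x.mean()
    c = float((xc * y).sum() / (xc * xc).sum())
    beta1 = float(y.mean() - c * x.mean())
    return beta1, c


def spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cubic regression-spline design: [1, x, x^2, x^3, (x-k)^3_+ ...].

    The truncated-power basis nests the straight line, so noiseless linear
    data is fitted exactly under the spline kind.
    """
    cols = [np.ones_like(x), x, x**2, x**3]
    cols += [np.clip(x - k, 0.0, None) ** 3 for k in knots]
    return np.column_stack(cols)


def interior_knots(x: np.ndarray, n_knots: int = 3) -> np.ndarray:
    """Knots at evenly spaced interior quantiles of the covariate."""
    qs = np.arange(1, n_knots + 1) / (n_knots + 1)
    return np.quantile(x, qs)


@dataclass
class FittedModel:
    """One fitted mediator or outcome model with enough state to predict."""

    kind: str  # linear | spline
    coef: np.ndarray
    residuals: np.ndarray
    knots_x: np.ndarray | None = None
    knots_m: np.ndarray | None = None
    has_mediator: bool = False
    coef_se: np.ndarray | None = None

    def design(self, x: np.ndarray, m: np.ndarray | None = None) -> np.ndarray:
        if self.kind == "linear":
            cols = [np.ones_like(x), x]
            if self.has_mediator:
                cols.append(m)
            return np.column_stack(cols)
        parts = [spline_basis(x, self.knots_x)]
        if self.has_mediator:
            parts.append(spline_basis(m, self.knots_m)[:, 1:])  # drop 2nd intercept
        return np.hstack(parts)

    def predict(self, x, m=None) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        m = None if m is None else np.atleast_1d(np.asarray(m, dtype=float))
        if m is not None and m.size != x.size:
            x, m = np.broadcast_arrays(x, m)
        return self.design(x, m) @ self.coef


def _ols(design: np.ndarray, y: np.ndarray, want_se: bool = False) -> FittedModel:
    n, p = design.shape
    if n <= p:
        raise ValueError(f"n={n} does not exceed parameter count {p}")
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design (degenerate basis)")
    resid = y - design @ coef
    se = None
    if want_se:
        sigma2 = float(resid @ resid) / (n - p)
        xtx_inv = np.linalg.inv(design.T @ design)
        se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    return coef, resid, se


def fit_mediator_model(x, m, kind: str = "linear", n_knots: int = 3) -> FittedModel:
    """Fit M ~ X. Linear kind exposes (beta2, a); spline uses cubic splines."""
    x, m = _vec(x), _vec(m)
    if kind == "linear":
        design = np.column_stack([np.ones_like(x), x])
        coef, resid, se = _ols(design, m, want_se=True)
        return FittedModel("linear", coef, resid, coef_se=se)
    if kind != "spline":
        raise ValueError(f"unknown model kind {kind!r}")
    knots = interior_knots(x, n_knots)
    coef, resid, se = _ols(spline_basis(x, knots), m, want_se=False)
    return FittedModel("spline", coef, resid, knots_x=knots)


def fit_outcome_model(x, m, y, kind: str = "linear", n_knots: int = 3) -> FittedModel:
    """Fit Y ~ X + M (additive; no treatment-mediator interaction).

    Linear kind exposes (beta3, c_prime, b); spline kind uses additive
    cubic-spline terms in X and M.
    """
    x, m, y = _vec(x), _vec(m), _vec(y)
    if kind == "linear":
        design = np.column_stack([np.ones_like(x), x, m])
        coef, resid, se = _ols(design, y, want_se=True)
        return FittedModel("linear", coef, resid, has_mediator=True, coef_se=se)
    if kind != "spline":
        raise ValueError(f"unknown model kind {kind!r}")
    kx, km = interior_knots(x, n_knots), interior_knots(m, n_knots)
    fm = FittedModel("spline", None, None, knots_x=kx, knots_m=km, has_mediator=True)
    coef, resid, se = _ols(fm.design(x, m), y, want_se=False)
    fm.coef, fm.residuals = coef, resid
    return fm


# ---------------------------------------------------------------------------
# effects


def sobel_se(a: float, b: float, se_a: float, se_b: float) -> float:
    """Delta-method standard error of the product a*b."""
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    return float(np.sqrt(se_a**2 * b**2 + se_b**2 * a**2))


def sobel_ci(acme: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory interval acme +/- z_{1-w/2} * se, w = 1 - level."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (acme - z * se, acme + z * se)


def _counterfactual_effects(
    x: np.ndarray,
    model_m: FittedModel,
    model_y: FittedModel,
    treat_quantiles: tuple[float, float] = (0.25, 0.75),
) -> tuple[float, float, float]:
    """(acme, ade, te) by counterfactual prediction, per unit of treatment.

    Control/treated treatment levels are quantiles of X (Q1/Q3 by
    default). Counterfactual mediator values are the fitted means under
    each level plus the empirical mediator-model residuals, so nonlinear
    outcome models are averaged over the mediator's error distribution.
    Effects are divided by the treated-control contrast to match the
    per-unit linear definitions; averaging both treatment arms makes
    TE = ACME + ADE an exact identity.
    """
    x0, x1 = np.quantile(x, treat_quantiles)
    scale = x1 - x0
    if scale == 0:
        raise ValueError("degenerate treatment contrast (Q1 == Q3)")
    e = model_m.residuals
    m0 = model_m.predict(np.full_like(e, x0)) + e
    m1 = model_m.predict(np.full_like(e, x1)) + e

    def ybar(level: float, m: np.ndarray) -> float:
        return float(model_y.predict(np.full_like(m, level), m).mean())

    acme = 0.5 * ((ybar(x1, m1) - ybar(x1, m0)) + (ybar(x0, m1) - ybar(x0, m0)))
    ade = 0.5 * ((ybar(x1, m0) - ybar(x0, m0)) + (ybar(x1, m1) - ybar(x0, m1)))
    return acme / scale, ade / scale, (acme + ade) / scale


def _point_effects(x, m, y, kind_m, kind_y, n_knots=3):
    """Effects + fitted coefficient metadata for one dataset."""
    model_m = fit_mediator_model(x, m, kind_m, n_knots)
    model_y = fit_outcome_model(x, m, y, kind_y, n_knots)
    if kind_m == "linear" and kind_y == "linear":
        a = float(model_m.coef[1])
        c_prime, b = float(model_y.coef[1]), float(model_y.coef[2])
        acme, ade = a * b, c_prime
        te = acme + ade
    else:
        acme, ade, te = _counterfactual_effects(x, model_m, model_y)
    return acme, ade, te, model_m, model_y


def _boot_p(draws: np.ndarray, n_boot: int) -> float:
    """Two-sided sign-based bootstrap p with a 2/(n_boot+1) floor."""
    lo = np.mean(draws <= 0)
    hi = np.mean(draws >= 0)
    return float(max(2.0 * min(lo, hi), 2.0 / (n_boot + 1)))


def _linear_boot(x, m, y, idx):
    """Vectorised closed-form OLS over bootstrap index matrix idx (B, n)."""
    X, M, Y = x[idx], m[idx], y[idx]
    Xc = X - X.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    smm = np.einsum("ij,ij->i", Mc, Mc)
    sxm = np.einsum("ij,ij->i", Xc, Mc)
    sxy = np.einsum("ij,ij->i", Xc, Yc)
    smy = np.einsum("ij,ij->i", Mc, Yc)
    det = sxx * smm - sxm**2
    ok = (sxx > 0) & (np.abs(det) > P_EPS * np.maximum(sxx * smm, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
        c_prime = (smm * sxy - sxm * smy) / det
        b = (sxx * smy - sxm * sxy) / det
    return a * b, c_prime, ok


@dataclass
class MediationResult:
    """Fitted mediation effects and uncertainty for one triad."""

    acme: float
    ade: float
    te: float
    a: float
    b: float
    c: float
    c_prime: float
    beta1: float
    beta2: float
    beta3: float
    sobel_se: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    acme_p: float
    ade_p: float
    te_p: float
    model_m_kind: str
    model_y_kind: str
    n_boot: int
    seed: int
    orientation: str = "miRNA_treats_TF_mediates"
    loop: CandidateLoop | None = None
    n_degenerate_redraws: int = 0


def mediate(
    x,
    m,
    y,
    kind_m: str = "linear",
    kind_y: str = "linear",
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    orientation: str = "miRNA_treats_TF_mediates",
    loop: CandidateLoop | None = None,
    n_knots: int = 3,
) -> MediationResult:
    """Estimate ACME/ADE/TE for one triad with bootstrap uncertainty.

    Point estimates: for linear mediator and outcome models,
    ACME = a*b, ADE = c', TE = a*b + c'; with any spline model the
    counterfactual-prediction algorithm is used (sequential ignorability
    assumed for identification). Uncertainty: nonparametric bootstrap over
    sample rows, percentile intervals at ``ci_level``, two-sided p =
    2 * min(fraction of draws <= 0, >= 0) floored at 2/(n_boot+1).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    x, m, y = _vec(x), _vec(m), _vec(y)
    if not (x.size == m.size == y.size):
        raise ValueError("vectors must be aligned")
    n = x.size

    acme, ade, te, model_m, model_y = _point_effects(x, m, y, kind_m, kind_y, n_knots)
    beta1, c = fit_total_effect(x, y)

    # linear coefficient metadata (reported even when a spline routes the
    # effect computation, as the best linear summary of each path)
    lin_m = model_m if kind_m == "linear" else fit_mediator_model(x, m, "linear")
    lin_y = model_y if kind_y == "linear" else fit_outcome_model(x, m, y, "linear")
    beta2, a = float(lin_m.coef[0]), float(lin_m.coef[1])
    beta3, c_prime, b = (float(lin_y.coef[i]) for i in range(3))
    se = sobel_se(a, b, float(lin_m.coef_se[1]), float(lin_y.coef_se[2]))

    rng = np.random.default_rng(seed)
    linear_path = kind_m == "linear" and kind_y == "linear"
    redraws = 0
    if linear_path:
        acme_d = np.empty(n_boot)
        ade_d = np.empty(n_boot)
        need = np.arange(n_boot)
        while need.size:
            idx = rng.integers(0, n, size=(need.size, n))
            ab, cp, ok = _linear_boot(x, m, y, idx)
            acme_d[need[ok]] = ab[ok]
            ade_d[need[ok]] = cp[ok]
            redraws += int((~ok).sum())
            need = need[~ok]
    else:
        acme_d = np.empty(n_boot)
        ade_d = np.empty(n_boot)
        i = 0
        while i < n_boot:
            idx = rng.integers(0, n, size=n)
            try:
                bi_acme, bi_ade, _, _, _ = _point_effects(
                    x[idx], m[idx], y[idx], kind_m, kind_y, n_knots
                )
            except (ValueError, np.linalg.LinAlgError):
                redraws += 1
                continue
            acme_d[i], ade_d[i] = bi_acme, bi_ade
            i += 1
    if redraws > 0.01 * n_boot:
        warnings.warn(
            f"{redraws} degenerate bootstrap resamples redrawn (> 1% of {n_boot})"
        )

    lo, hi = (1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100
    te_d = acme_d + ade_d
    return MediationResult(
        acme=float(acme),
        ade=float(ade),
        te=float(te),
        a=a,
        b=b,
        c=float(c),
        c_prime=c_prime,
        beta1=float(beta1),
        beta2=beta2,
        beta3=beta3,
        sobel_se=se,
        acme_ci=tuple(np.percentile(acme_d, [lo, hi])),
        ade_ci=tuple(np.percentile(ade_d, [lo, hi])),
        acme_p=_boot_p(acme_d, n_boot),
        ade_p=_boot_p(ade_d, n_boot),
        te_p=_boot_p(te_d, n_boot),
        model_m_kind=kind_m,
        model_y_kind=kind_y,
        n_boot=n_boot,
        seed=seed,
        orientation=orientation,
        loop=loop,
        n_degenerate_redraws=redraws,
    )


# ---------------------------------------------------------------------------
# sensitivity analysis


@dataclass
class SensitivityCurve:
    """ACME as a function of the error correlation rho.

    rho is the correlation between the mediator-model and outcome-model
    errors; rho = 0 is sequential ignorability. ``rho_zero`` is the value
    at which the ACME estimate would vanish — how much hidden confounding
    the conclusion tolerates. ``r2m_tilde``/``r2y_tilde`` give the
    symmetric variance-explained parameterisation (their product is
    rho^2).
    """

    rho_grid: np.ndarray
    acme_at_rho: np.ndarray
    rho_zero: float | None
    r2m_tilde: np.ndarray
    r2y_tilde: np.ndarray


def sensitivity(x, m, y, rho_grid=None) -> SensitivityCurve:
    """Linear-SEM sensitivity analysis of the ACME.

    Implements the closed-form adjustment for correlated errors in the
    linear structural-equation case:

        ACME(rho) = a * (s1/s2) * [rt - rho * sqrt((1-rt^2)/(1-rho^2))]

    with s1, s2 the residual s.d. of the total-effect and mediator models
    and rt the correlation of those residuals. ACME(0) equals the OLS
    point estimate a*b.
    """
    x, m, y = _vec(x), _vec(m), _vec(y)
    if rho_grid is None:
        rho_grid = np.linspace(-0.95, 0.95, 39)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(np.abs(rho_grid) >= 1):
        raise ValueError("rho grid must lie in (-1, 1)")

    beta1, c = fit_total_effect(x, y)
    model_m = fit_mediator_model(x, m, "linear")
    a = float(model_m.coef[1])
    e1 = y - (beta1 + c * x)
    e2 = model_m.residuals
    s1, s2 = e1.std(), e2.std()
    rt = float(np.corrcoef(e1, e2)[0, 1])

    def acme_of(rho):
        return a * (s1 / s2) * (rt - rho * np.sqrt((1 - rt**2) / (1 - rho**2)))

    acme_vals = acme_of(rho_grid)
    rho_zero = None
    sign = np.sign(acme_vals)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if sign.min() == 0:
        rho_zero = float(rho_grid[np.argmin(np.abs(acme_vals))])
    elif crossings.size:
        i = crossings[0]
        from scipy.optimize import brentq

        rho_zero = float(brentq(acme_of, rho_grid[i], rho_grid[i + 1]))
    return SensitivityCurve(
        rho_grid=rho_grid,
        acme_at_rho=acme_vals,
        rho_zero=rho_zero,
        r2m_tilde=np.abs(rho_grid),
        r2y_tilde=np.abs(rho_grid),
    )


def sensitivity_frame(curve: SensitivityCurve):
    """Long-format TSV-ready table of the sensitivity curve."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rho": curve.rho_grid,
            "acme": curve.acme_at_rho,
            "r2m_tilde": curve.r2m_tilde,
            "r2y_tilde": curve.r2y_tilde,
        }
    )
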