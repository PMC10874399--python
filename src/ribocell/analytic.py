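"""Closed-form growth-rate maximization for the base model.

At maximum growth rate all constraints of the base model are active, so the
homogenized 12x12 constraint matrix B is singular.  Expanding det B = 0 and
rescaling time by the autocatalytic ceiling kel_bar_R*omega_AA/omega_R
yields a quadratic in the rescaled growth rate mu_hat:

    (alpha + beta*(1 - x_rP)) * mu_hat^2 + (gamma + x_rP) * mu_hat - 1 = 0

with dimensionless coefficients

    alpha = kel_bar_R * (n_AF/kcat_AF) * (omega_AA/omega_R)^2
    beta  = kel_bar_R * [ (n_IC/kcat_IC)*(omega_AA/omega_C)
            + (n_EAA/kcat_EAA + n_ENT/kcat_ENT + n_RNAP/kel_bar_RNAP)
              * (omega_AA/omega_NT) ] * (omega_AA/omega_R)
    gamma = kel_bar_R * [ (n_IC/kcat_IC)*(omega_AA/omega_C)
            + n_EAA/kcat_EAA ] * (omega_AA/omega_R)

(the carbon-source mass in these expressions is taken to be omega_C).
The positive root mu_hat(x_rP) is strictly monotone in the protein fraction:
decreasing if epsilon = (alpha+beta)/beta^2 + gamma/beta - 1 > 0, increasing
if epsilon < 0, constant if epsilon = 0 -- so the base-model optimum always
sits at an exclusive composition (x_rP = 0 or 1).  For realistic parameters
alpha << beta, epsilon > 0, and the RNA-only ribosome wins.

The module also evaluates the two autocatalytic-loop upper bounds of
Kostinski & Reuveni (fixed ribosome allocations to rP and RNAP synthesis)
and their intersection, which the full model dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_builder import build_constraints, derive_composition
from .parameters import ParameterSet


def _require_base(params: ParameterSet, what: str) -> None:
    if params.rp_import_fraction != 0.0:
        raise ValueError(
            f"{what} applies to the base model only "
            "(rp_import_fraction must be 0)"
        )


@dataclass(frozen=True)
class QuadraticCoefficients:
    """Dimensionless coefficients of the closed-form quadratic."""

    alpha: float
    beta: float
    gamma: float
    epsilon: float
    mu_hat_scale: float  # kel_bar_R*omega_AA/omega_R, converts mu_hat to 1/h
    notes: tuple = ("carbon-source mass taken as omega_C",)


def quadratic_coefficients(params: ParameterSet) -> QuadraticCoefficients:
    """alpha, beta, gamma and the monotonicity quantity epsilon."""
    _require_base(params, "the closed form")
    w = params
    aa_over_R = w.omega_AA / w.omega_R
    alpha = w.kel_bar_R * (w.n_AF / w.kcat_AF) * aa_over_R ** 2
    ic_term = (w.n_IC / w.kcat_IC) * (w.omega_AA / w.omega_C)
    beta = w.kel_bar_R * (
        ic_term
        + (w.n_EAA / w.kcat_EAA + w.n_ENT / w.kcat_ENT
           + w.n_RNAP / w.kel_bar_RNAP) * (w.omega_AA / w.omega_NT)
    ) * aa_over_R
    gamma = w.kel_bar_R * (ic_term + w.n_EAA / w.kcat_EAA) * aa_over_R
    epsilon = (alpha + beta) / beta ** 2 + gamma / beta - 1.0
    return QuadraticCoefficients(alpha=alpha, beta=beta, gamma=gamma,
                                 epsilon=epsilon, mu_hat_scale=w.mu_ceiling)


def mu_hat_root(coef: QuadraticCoefficients | tuple, x_rP: float) -> float:
    """Unique positive root of (a+b(1-x))u^2 + (g+x)u - 1 = 0.

    Uses the cancellation-free branch 2/(B + sqrt(B^2+4A)), which stays
    stable when the quadratic coefficient A is tiny (x_rP near 1 with small
    alpha).
    """
    if isinstance(coef, QuadraticCoefficients):
        a, b, g = coef.alpha, coef.beta, coef.gamma
    else:
        a, b, g = coef
    A = a + b * (1.0 - x_rP)
    B = g + x_rP
    if A <= 0:
        # degenerate linear case: B*u = 1
        return 1.0 / B
    return 2.0 / (B + math.sqrt(B * B + 4.0 * A))


def analytic_mu_max(params: ParameterSet, x_rP: float) -> float:
    """Closed-form maximum growth rate (1/h) of the base model at x_rP."""
    if not (0.0 <= x_rP <= 1.0):
        raise ValueError(f"x_rP must lie in [0, 1], got {x_rP}")
    coef = quadratic_coefficients(params)
    return mu_hat_root(coef, x_rP) * coef.mu_hat_scale


def monotonicity_class(params: ParameterSet,
                       dead_band: float = 1e-12) -> str:
    """'decreasing', 'constant' or 'increasing' mu_hat(x_rP), from epsilon."""
    eps = quadratic_coefficients(params).epsilon
    if abs(eps) < dead_band:
        return "constant"
    return "decreasing" if eps > 0 else "increasing"


# ---------------------------------------------------------------------------
# determinant method

def homogenized_matrix(params: ParameterSet, x_rP: float,
                       mu: float) -> np.ndarray:
    """The square homogenized base-model matrix B = [A | -b] at (x_rP, mu).

    All 12 constraints (equalities and inequalities treated as active) on the
    11 fluxes plus the homogenization coordinate; at the optimal growth rate
    B is singular.
    """
    _require_base(params, "the determinant method")
    comp = derive_composition(params, x_rP)
    sys = build_constraints(params, comp, mu, variant="base")
    B = np.hstack([sys.A, -sys.rhs[:, None]])
    if B.shape[0] != B.shape[1]:
        raise ValueError(f"homogenized matrix is not square: {B.shape}")
    return B


def determinant_residual(params: ParameterSet, x_rP: float,
                         mu: float) -> float:
    """Scale-free singularity residual of the homogenized matrix.

    The determinant of the row-normalized matrix, divided by the product of
    its eleven largest singular values -- i.e. the signed smallest singular
    value.  This removes the arbitrary overall determinant scale: the
    residual vanishes exactly at the optimal growth rate and grows linearly
    away from it in well-conditioned units.
    """
    B = homogenized_matrix(params, x_rP, mu)
    scale = np.max(np.abs(B), axis=1)
    scale[scale == 0] = 1.0
    Bn = B / scale[:, None]
    sigma = np.linalg.svd(Bn, compute_uv=False)
    sign = np.sign(np.linalg.det(Bn))
    return float(sign * sigma[-1])


def determinant_polynomial_roots(params: ParameterSet, x_rP: float,
                                 degree: int = 10) -> np.ndarray:
    """Positive real roots of det B(mu), expanded as a polynomial in mu.

    det B is polynomial in mu (each capacity row and the homogenization
    column are linear in mu); it is recovered exactly by interpolation on a
    Chebyshev-like grid and its positive real roots are returned, sorted.
    The closed-form optimum is one of them.
    """
    scale = params.mu_ceiling
    mus = scale * (0.2 + 2.3 * (1 - np.cos(np.linspace(0, np.pi,
                                                       degree + 1))) / 2)
    # constant row normalization (mu-independent) keeps det polynomial in mu
    B0 = homogenized_matrix(params, x_rP, scale)
    norm = np.max(np.abs(B0), axis=1)
    norm[norm == 0] = 1.0
    vals = []
    for m in mus:
        B = homogenized_matrix(params, x_rP, float(m))
        vals.append(np.linalg.det(B / norm[:, None]))
    coeffs = np.polynomial.polynomial.polyfit(mus / scale, vals, degree)
    roots = np.polynomial.polynomial.polyroots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9 * (1 + np.abs(roots))].real
    return np.sort(real[real > 0]) * scale


# ---------------------------------------------------------------------------
# Kostinski-Reuveni autocatalytic-loop bounds

@dataclass(frozen=True)
class KRBounds:
    """The two fixed-allocation growth-rate bounds at one composition."""

    phi_rP: float
    phi_RNAP: float
    gamma_rP: float
    gamma_RNAP: float
    x_rP: float
    bound_rP: float     # 1/h; inf at x_rP = 0
    bound_RNAP: float   # 1/h; inf at x_rP = 1


def _kr_gammas(params: ParameterSet):
    gamma_rP = params.kel_bar_R * params.omega_AA / params.omega_R
    gamma_RNAP = math.sqrt(
        params.kel_bar_R * params.kel_bar_RNAP * params.omega_NT
        / (params.omega_R * params.n_RNAP)
    )
    return gamma_rP, gamma_RNAP


def kr_bounds(params: ParameterSet, x_rP: float, phi_rP: float,
              phi_RNAP: float) -> KRBounds:
    """Evaluate both autocatalytic-loop bounds at fixed allocations.

    The rP loop gives mu <= kel_bar_R*phi_rP/n_rP = gamma_rP*phi_rP/x_rP
    (decreasing in x_rP); the rRNA/RNAP loop gives
    mu <= gamma_RNAP*sqrt(phi_RNAP/(1-x_rP)) (increasing).  At the
    endpoints the respective bound is infinite, not an error.
    """
    if not (0.0 < phi_rP <= 1.0 and 0.0 < phi_RNAP <= 1.0):
        raise ValueError("allocations must lie in (0, 1]")
    if not (0.0 <= x_rP <= 1.0):
        raise ValueError(f"x_rP must lie in [0, 1], got {x_rP}")
    gamma_rP, gamma_RNAP = _kr_gammas(params)
    bound_rP = math.inf if x_rP == 0 else gamma_rP * phi_rP / x_rP
    bound_RNAP = (math.inf if x_rP == 1
                  else gamma_RNAP * math.sqrt(phi_RNAP / (1.0 - x_rP)))
    return KRBounds(phi_rP=phi_rP, phi_RNAP=phi_RNAP, gamma_rP=gamma_rP,
                    gamma_RNAP=gamma_RNAP, x_rP=x_rP,
                    bound_rP=bound_rP, bound_RNAP=bound_RNAP)


def kr_optimal_composition(params: ParameterSet, phi_rP: float,
                           phi_RNAP: float):
    """Intersection of the two bounds: (x_star, mu at x_star).

    The rP bound falls from +inf and the RNAP bound rises to +inf, so for
    positive allocations the curves cross exactly once in (0, 1); the
    crossing is the fixed-allocation optimum.
    """
    gamma_rP, gamma_RNAP = _kr_gammas(params)

    def log_gap(x):
        return (math.log(gamma_rP * phi_rP / x)
                - math.log(gamma_RNAP) - 0.5 * math.log(phi_RNAP / (1 - x)))

    lo, hi = 1e-12, 1.0 - 1e-12
    assert log_gap(lo) > 0 > log_gap(hi), "bounds must cross in (0, 1)"
    x_star = brentq(log_gap, lo, hi, xtol=1e-14)
    return x_star, gamma_rP * phi_rP / x_star
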