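"""Two-compartment kinetics of cancer stem cells and differentiated cells.

The model describes a sphere culture containing cancer stem cells (CSCs,
population ``S``) and differentiated cancer cells (population ``D``) growing
in a nutrient-rich, non-adherent environment.  Each compartment grows
exponentially at its intrinsic per-capita rate and cells interconvert by
mass action::

    dS/dt = k1*S - a*S + b*D
    dD/dt = k2*D + a*S - b*D

with per-day rates ``k1`` (CSC intrinsic growth), ``k2`` (differentiated-cell
intrinsic growth), ``a`` (CSC -> differentiated conversion; asymmetric
division modelled as symmetric division followed by conversion) and ``b``
(differentiated -> CSC conversion, e.g. via EMT).  The symbols ``k1, k2, a,
b`` are conventions of this package.

Because the system is linear, ``S(t)`` and ``D(t)`` are sums of two real
exponentials whose rates are the eigenvalues of the system matrix
``[[k1-a, b], [a, k2-b]]``.  The observable of interest is the ratio
``r(t) = D(t)/S(t)``, which obeys the scalar Riccati equation

    dr/dt = a + (k2 - b - k1 + a)*r - b*r**2

and converges to a limiting ratio ``r_inf`` (the positive Riccati fixed
point, equivalently ``(lambda1 - (k1 - a))/b``).  The CSC percentage printed
by flow cytometry is ``p = 100/(1 + r)`` on the 0-100 scale.

The ratio depends on the rates only through ``(a, b, k2 - k1)``: adding a
constant to both intrinsic growth rates rescales ``S`` and ``D`` equally and
leaves ``r(t)`` unchanged.  This identifiability reduction matters for
fitting ratio-only data (see :mod:`cscdrift.inference`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateParams",
    "State",
    "ClosedForm",
    "RatioTrajectory",
    "ode_rhs",
    "eigenvalues",
    "closed_form",
    "ratio_trajectory",
    "limiting_ratio",
    "limiting_ratio_algebraic",
    "percent_to_ratio",
    "ratio_to_percent",
]

# relative eigenvalue gap below which the confluent (repeated-root) solution
# is used; exact degeneracy requires a*b == 0 and k1 - a == k2 - b
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class RateParams:
    """The four non-negative per-day rate constants of the model.

    Parameters
    ----------
    k1 : float
        Intrinsic (net birth) growth rate of CSCs, per day.
    k2 : float
        Intrinsic growth rate of differentiated cancer cells, per day.
    a : float
        Conversion rate CSC -> differentiated cell, per day.
    b : float
        Conversion rate differentiated cell -> CSC, per day.
    """

    k1: float
    k2: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "a", "b"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"rate {name!r} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"rate {name!r} must be >= 0, got {value!r}")

    @property
    def delta(self) -> float:
        """Growth-rate difference k2 - k1; the only combination of the
        intrinsic rates that the ratio trajectory depends on."""
        return self.k2 - self.k1

    def system_matrix(self) -> np.ndarray:
        """The 2x2 matrix of the linear system, [[k1-a, b], [a, k2-b]]."""
        return np.array(
            [[self.k1 - self.a, self.b], [self.a, self.k2 - self.b]], float
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.a, self.b], float)

    @classmethod
    def from_array(cls, values) -> "RateParams":
        k1, k2, a, b = (float(v) for v in values)
        return cls(k1=k1, k2=k2, a=a, b=b)


@dataclass(frozen=True)
class State:
    """Population state (t in days, S = CSC count, D = differentiated count).

    Population sizes may be on any common dimensionless scale; only S > 0 and
    D >= 0 are required so that the ratio D/S is defined.
    """

    t: float
    S: float
    D: float

    def __post_init__(self) -> None:
        if not (self.t >= 0):
            raise ValueError(f"time must be >= 0, got {self.t!r}")
        if not (self.S > 0):
            raise ValueError(f"S must be > 0, got {self.S!r}")
        if not (self.D >= 0):
            raise ValueError(f"D must be >= 0, got {self.D!r}")

    @property
    def ratio(self) -> float:
        return self.D / self.S


def ode_rhs(params: RateParams, state: State) -> tuple[float, float]:
    """Instantaneous rates (dS/dt, dD/dt) of the two-compartment system."""
    S, D = state.S, state.D
    dS = params.k1 * S - params.a * S + params.b * D
    dD = params.k2 * D + params.a * S - params.b * D
    return dS, dD


def eigenvalues(params: RateParams) -> tuple[float, float]:
    """Eigenvalues (lambda1 >= lambda2) of the system matrix.

    They are the roots of ``x**2 - T*x + Det = 0`` with trace
    ``T = (k1-a) + (k2-b)`` and determinant ``Det = (k1-a)(k2-b) - a*b``.
    The discriminant ``((k1-a)-(k2-b))**2 + 4ab`` is non-negative whenever
    a, b >= 0, so both roots are real.
    """
    alpha = params.k1 - params.a
    beta = params.k2 - params.b
    if params.a == 0 or params.b == 0:
        # triangular system: the diagonal entries are exact eigenvalues,
        # and using them exactly keeps the closed-form coefficients of the
        # decoupled eigendirection exactly zero (no cancellation noise)
        return (alpha, beta) if alpha >= beta else (beta, alpha)
    disc = (alpha - beta) ** 2 + 4.0 * params.a * params.b
    if disc < 0:  # impossible for non-negative a, b; guards misuse
        raise ArithmeticError(
            f"complex eigenvalues (discriminant {disc}); rates must be >= 0"
        )
    half_gap = 0.5 * math.sqrt(disc)
    half_trace = 0.5 * (alpha + beta)
    return half_trace + half_gap, half_trace - half_gap


def _eigen_decomp(params: RateParams) -> tuple[float, float, float, float]:
    """Eigenvalues plus the cancellation-free shifts A = lambda1 - alpha and
    B = lambda1 - beta (alpha = k1 - a, beta = k2 - b).

    Naive subtraction of lambda1 - alpha loses all precision when a*b is
    tiny compared with (alpha - beta)^2 (near-triangular systems); the
    rationalized forms a*b/(s -+ h) stay exact there.  Note lambda2 - alpha
    = -B and lambda2 - beta = -A.
    """
    alpha = params.k1 - params.a
    beta = params.k2 - params.b
    ab = params.a * params.b
    h = 0.5 * (beta - alpha)
    s = abs(h) if ab == 0 else math.sqrt(h * h + ab)
    mid = 0.5 * (alpha + beta)
    lam1, lam2 = mid + s, mid - s
    if h >= 0:
        A = h + s
        B = ab / (s + h) if s + h > 0 else 0.0
    else:
        A = ab / (s - h)  # s - h > 0 since h < 0
        B = s - h
    return lam1, lam2, A, B


@dataclass(frozen=True)
class ClosedForm:
    """Closed-form solution S(t), D(t) of the linear system.

    In the generic case each compartment is ``c1*exp(lambda1*t) +
    c2*exp(lambda2*t)``.  When the eigenvalues coincide (possible only for
    ``a*b == 0`` with ``k1 - a == k2 - b``) the confluent form
    ``(c + u*t)*exp(lambda*t)`` is used and ``degenerate`` is True.
    """

    lambda1: float
    lambda2: float
    S0: float
    D0: float
    cs: tuple[float, float]  # coefficients of S(t) on (e^{l1 t}, e^{l2 t})
    cd: tuple[float, float]  # coefficients of D(t)
    degenerate: bool = False
    # linear-in-t slopes of the confluent solution (used iff degenerate)
    us: float = 0.0
    ud: float = 0.0

    def evaluate(self, t) -> tuple[np.ndarray, np.ndarray]:
        """S(t), D(t) for scalar or array t (days)."""
        t = np.asarray(t, float)
        if self.degenerate:
            e = np.exp(self.lambda1 * t)
            return (self.S0 + self.us * t) * e, (self.D0 + self.ud * t) * e
        e1 = np.exp(self.lambda1 * t)
        e2 = np.exp(self.lambda2 * t)
        S = self.cs[0] * e1 + self.cs[1] * e2
        D = self.cd[0] * e1 + self.cd[1] * e2
        return S, D

    def S(self, t) -> np.ndarray:
        return self.evaluate(t)[0]

    def D(self, t) -> np.ndarray:
        return self.evaluate(t)[1]

    def ratio(self, t) -> np.ndarray:
        S, D = self.evaluate(t)
        return D / S


def closed_form(params: RateParams, S0: float, D0: float) -> ClosedForm:
    """Exact solution of the system for the initial state (S0, D0) at t=0."""
    if not (S0 > 0):
        raise ValueError(f"S0 must be > 0, got {S0!r}")
    if not (D0 >= 0):
        raise ValueError(f"D0 must be >= 0, got {D0!r}")
    lam1, lam2, A, B = _eigen_decomp(params)
    gap = A + B  # == lam1 - lam2, computed without cancellation
    if gap <= _DEGENERATE_TOL * max(1.0, abs(lam1)):
        # repeated eigenvalue: S(t) = (S0 + us*t) e^{lam t}, likewise D
        us = -A * S0 + params.b * D0
        ud = params.a * S0 - B * D0
        return ClosedForm(
            lambda1=lam1, lambda2=lam1, S0=S0, D0=D0,
            cs=(S0, 0.0), cd=(D0, 0.0), degenerate=True, us=us, ud=ud,
        )
    cs1 = (S0 * B + params.b * D0) / gap
    cs2 = (S0 * A - params.b * D0) / gap
    cd1 = (D0 * A + params.a * S0) / gap
    cd2 = (D0 * B - params.a * S0) / gap
    return ClosedForm(
        lambda1=lam1, lambda2=lam2, S0=S0, D0=D0,
        cs=(cs1, cs2), cd=(cd1, cd2),
    )


class RatioTrajectory:
    """Ratio r(t) = D(t)/S(t) as a callable, plus its limit r_inf.

    Depends on the rates only through (a, b, delta = k2 - k1); internally the
    reduced system with k1 = 0, k2 = delta is solved with S0 = 1, D0 = r0.
    Evaluation factors out exp(lambda1*t) so that only the decaying
    exponential exp(-(lambda1-lambda2)*t) is ever formed; naive evaluation of
    exp(lambda*t) overflows for culture horizons of hundreds of days.
    """

    def __init__(self, params: RateParams, r0: float):
        if not (r0 >= 0):
            raise ValueError(f"r0 must be >= 0, got {r0!r}")
        self.r0 = float(r0)
        self.a = params.a
        self.b = params.b
        self.delta = params.delta
        self._cf = closed_form(_reduced_params(params), 1.0, self.r0)
        self.r_inf = limiting_ratio(params)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        cf = self._cf
        if cf.degenerate:
            num = cf.D0 + cf.ud * t
            den = cf.S0 + cf.us * t
            return num / den
        decay = np.exp((cf.lambda2 - cf.lambda1) * t)  # in (0, 1] for t >= 0
        num = cf.cd[0] + cf.cd[1] * decay
        den = cf.cs[0] + cf.cs[1] * decay
        return num / den


def _reduced_params(params: RateParams) -> RateParams:
    """Shift both intrinsic rates so that k1 = 0 (ratio is invariant)."""
    delta = params.delta
    if delta >= 0:
        return RateParams(k1=0.0, k2=delta, a=params.a, b=params.b)
    # rates must stay non-negative: shift so that k2 = 0 instead
    return RateParams(k1=-delta, k2=0.0, a=params.a, b=params.b)


def ratio_trajectory(params: RateParams, r0: float) -> RatioTrajectory:
    """The ratio trajectory r(t) starting from r(0) = r0."""
    return RatioTrajectory(params, r0)


def limiting_ratio(params: RateParams) -> float:
    """Limit of r(t) as t -> infinity, via the dominant eigenvalue.

    For b > 0 the limit is ``(lambda1 - (k1 - a)) / b``, the slope of the
    dominant eigenvector.  For b == 0 the system is triangular: with a > 0
    the limit is finite, ``a / (k1 - a - k2)``, when the CSC eigenvalue
    ``k1 - a`` dominates, and +inf otherwise; with a == 0 the compartments
    are decoupled and the limit is 0 or +inf according to the sign of
    ``k2 - k1`` (NaN when k1 == k2, where r(t) == r0 for every r0).

    The a == 0, r0 == 0 caveat: r(t) stays identically 0 regardless of the
    value returned here, because the CSC-only culture never seeds the
    differentiated compartment.
    """
    alpha = params.k1 - params.a
    if params.b > 0:
        _, _, A, _ = _eigen_decomp(params)
        return A / params.b
    if params.a > 0:
        if alpha > params.k2:
            return params.a / (alpha - params.k2)
        return math.inf
    # a == b == 0: decoupled exponentials
    if params.k2 > params.k1:
        return math.inf
    if params.k2 < params.k1:
        return 0.0
    return math.nan


def limiting_ratio_algebraic(params: RateParams) -> float:
    """Limit of r(t), via the Riccati fixed point.

    The steady state solves ``b*r**2 - (k2 - b - k1 + a)*r - a = 0``; the
    non-negative root is returned, using the form of the quadratic formula
    that avoids cancellation.  Agrees with :func:`limiting_ratio` to
    floating-point accuracy.
    """
    a, b = params.a, params.b
    m = params.k2 - b - params.k1 + a  # beta - alpha
    if b > 0:
        disc = math.sqrt(m * m + 4.0 * a * b)
        if m > 0:
            return (m + disc) / (2.0 * b)
        if disc - m > 0:
            return 2.0 * a / (disc - m)
        return 0.0  # a == 0 and m <= 0
    # b == 0: linear equation m*r + a = 0
    if a > 0:
        if m < 0:
            return -a / m
        return math.inf
    if m > 0:
        return math.inf
    if m < 0:
        return 0.0
    return math.nan


def percent_to_ratio(p):
    """Convert CSC percentage p in (0, 100] to the ratio r = (100 - p)/p."""
    p = np.asarray(p, float)
    if np.any(p <= 0) or np.any(p > 100):
        raise ValueError("CSC percentage must lie in (0, 100]")
    out = (100.0 - p) / p
    return float(out) if out.ndim == 0 else out


def ratio_to_percent(r):
    """Convert the ratio r = D/S >= 0 to the CSC percentage 100/(1 + r)."""
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("ratio must be >= 0")
    out = 100.0 / (1.0 + r)
    return float(out) if out.ndim == 0 else out
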