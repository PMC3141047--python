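"""Natural cubic smoothing splines with equivalent-degrees-of-freedom control.

The ridge smoother used by the projection pursuit engine.  The smoothness
knob is not a raw penalty λ but the *equivalent degrees of freedom*: the
trace of the linear smoother matrix S(λ) mapping observations to fitted
values.  ``smooth_ridge`` calibrates λ by root finding until
``trace(S(λ))`` matches the requested df, so df=2 is a straight line and
df→n approaches interpolation.

Implementation is the classic Reinsch scheme.  With sorted distinct knots
x, weights w (counts of duplicated abscissae) and values y, the penalised
criterion  Σ wᵢ(yᵢ−fᵢ)² + λ∫f″²  is solved through the banded system

    (R + λ QᵀW⁻¹Q) γ = Qᵀ y,      f = y − λ W⁻¹ Q γ,

where Q holds scaled second differences and R the spline Gram matrix; γ
are the second derivatives at interior knots (natural boundary: zero at
the ends).  The fitted spline is recovered exactly as the natural cubic
interpolant through (x, f), which is unique.  Outside the knot range the
smoother continues linearly with the boundary slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg as sla
from scipy.interpolate import CubicSpline

from .errors import FitError, ValidationError

_LOGLAM_LO, _LOGLAM_HI = -16.0, 16.0


def _reinsch_matrices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (Q, R): n x (n-2) second-difference and (n-2) x (n-2) Gram."""
    n = len(x)
    h = np.diff(x)
    k = np.arange(n - 2)
    Q = np.zeros((n, n - 2))
    Q[k, k] = 1.0 / h[k]
    Q[k + 1, k] = -1.0 / h[k] - 1.0 / h[k + 1]
    Q[k + 2, k] = 1.0 / h[k + 1]
    R = np.zeros((n - 2, n - 2))
    R[k, k] = (h[k] + h[k + 1]) / 3.0
    kk = np.arange(n - 3)
    R[kk, kk + 1] = R[kk + 1, kk] = h[kk + 1] / 6.0
    return Q, R


class _ReinschSystem:
    """Caches the λ-independent pieces for one knot configuration."""

    def __init__(self, x: np.ndarray, y: np.ndarray, w: np.ndarray):
        self.x, self.y, self.w = x, y, w
        self.n = len(x)
        self.Q, self.R = _reinsch_matrices(x)
        self.QtWinvQ = self.Q.T @ (self.Q / w[:, None])
        self.Qty = self.Q.T @ y

    def _factor(self, lam: float):
        A = self.R + lam * self.QtWinvQ
        try:
            return sla.cho_factor(A, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            # near-coincident knots can destroy positive definiteness in
            # floating point; a relative jitter restores it
            jitter = 1e-10 * np.abs(np.diag(A)).max()
            return sla.cho_factor(
                A + jitter * np.eye(A.shape[0]), lower=True, check_finite=False
            )

    def solve(self, lam: float) -> tuple[np.ndarray, np.ndarray]:
        """Fitted values f and interior second derivatives γ at penalty λ."""
        cf = self._factor(lam)
        gamma = sla.cho_solve(cf, self.Qty, check_finite=False)
        f = self.y - lam * (self.Q @ gamma) / self.w
        return f, gamma

    def trace(self, lam: float) -> float:
        """trace of S(λ) = I − λ W⁻¹Q (R + λ QᵀW⁻¹Q)⁻¹ Qᵀ."""
        cf = self._factor(lam)
        M = sla.cho_solve(cf, self.Q.T, check_finite=False)  # (n-2) x n
        diag_corr = np.einsum("ik,ki->i", self.Q, M) / self.w
        return float(self.n - lam * diag_corr.sum())


def _calibrate_lambda(
    system: _ReinschSystem,
    df: float,
    tol: float,
    warm_loglam: Optional[float],
) -> float:
    """Find λ with trace(S(λ)) = df by bisection on log10 λ.

    trace is strictly decreasing in λ, from n (λ→0) to 2 (λ→∞).
    """
    lo, hi = _LOGLAM_LO, _LOGLAM_HI
    if warm_loglam is not None:
        # cheap local bracket around the warm start before the full range
        c = float(np.clip(warm_loglam, lo + 1, hi - 1))
        tc = system.trace(10.0**c)
        if abs(tc - df) <= tol:
            return 10.0**c
        step = 1.0
        if tc > df:  # need larger λ
            a, fa = c, tc
            b = c + step
            while b < hi and system.trace(10.0**b) > df:
                a = b
                b = min(b + 2 * step, hi)
                step *= 2
            lo, hi = a, b
        else:
            b, fb = c, tc
            a = c - step
            while a > _LOGLAM_LO and system.trace(10.0**a) < df:
                b = a
                a = max(a - 2 * step, _LOGLAM_LO)
                step *= 2
            lo, hi = a, b
    t_lo = system.trace(10.0**lo)
    t_hi = system.trace(10.0**hi)
    if t_lo <= df:  # even the tiniest penalty is too smooth -> near-interpolation
        return 10.0**lo
    if t_hi >= df:  # heaviest penalty still rougher than requested df
        return 10.0**hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        tm = system.trace(10.0**mid)
        if abs(tm - df) <= tol:
            return 10.0**mid
        if tm > df:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 10.0 ** (0.5 * (lo + hi))


@dataclass
class RidgeSmoother:
    """A fitted one-dimensional smoother: natural cubic spline + linear tails.

    ``knots``/``values`` fully determine the curve (the natural cubic
    interpolant through them), so the object serialises to plain lists.
    """

    knots: np.ndarray
    values: np.ndarray
    df_requested: float = np.nan
    df_actual: float = np.nan
    lam: float = np.nan
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.knots.ndim != 1 or self.knots.shape != self.values.shape:
            raise ValidationError("knots and values must be equal-length 1-D arrays")
        if len(self.knots) < 2:
            raise ValidationError("a smoother needs at least 2 knots")
        if np.any(np.diff(self.knots) <= 0):
            raise ValidationError("knots must be strictly increasing")

    def _ensure_spline(self) -> None:
        if self._spline is None and len(self.knots) > 2:
            self._spline = CubicSpline(self.knots, self.values, bc_type="natural")

    @property
    def _boundary_slopes(self) -> tuple[float, float]:
        if len(self.knots) == 2:
            s = (self.values[1] - self.values[0]) / (self.knots[1] - self.knots[0])
            return float(s), float(s)
        self._ensure_spline()
        d = self._spline.derivative()
        return float(d(self.knots[0])), float(d(self.knots[-1]))

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        lo, hi = self.knots[0], self.knots[-1]
        if len(self.knots) == 2:
            s = (self.values[1] - self.values[0]) / (hi - lo)
            out = self.values[0] + s * (t - lo)
        else:
            self._ensure_spline()
            out = np.asarray(self._spline(np.clip(t, lo, hi)), dtype=float)
            sl, sr = self._boundary_slopes
            below, above = t < lo, t > hi
            out[below] = self.values[0] + sl * (t[below] - lo)
            out[above] = self.values[-1] + sr * (t[above] - hi)
        return float(out[0]) if scalar else out

    def derivative(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        lo, hi = self.knots[0], self.knots[-1]
        sl, sr = self._boundary_slopes
        if len(self.knots) == 2:
            out = np.full(t.shape, sl)
        else:
            self._ensure_spline()
            out = np.asarray(self._spline.derivative()(np.clip(t, lo, hi)), dtype=float)
            out[t < lo] = sl
            out[t > hi] = sr
        return float(out[0]) if scalar else out

    def extrapolation_mask(self, t: np.ndarray) -> np.ndarray:
        """True where evaluation falls outside the training knot range."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return (t < self.knots[0]) | (t > self.knots[-1])

    def to_dict(self) -> dict:
        return {
            "knots": [float(v) for v in self.knots],
            "values": [float(v) for v in self.values],
            "df_requested": float(self.df_requested),
            "df_actual": float(self.df_actual),
            "lam": float(self.lam),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeSmoother":
        return cls(
            knots=np.asarray(d["knots"], dtype=float),
            values=np.asarray(d["values"], dtype=float),
            df_requested=float(d.get("df_requested", np.nan)),
            df_actual=float(d.get("df_actual", np.nan)),
            lam=float(d.get("lam", np.nan)),
        )


def smoother_matrix(t: np.ndarray, df: float, df_tol: float = 0.02) -> np.ndarray:
    """The explicit n x n smoother matrix S(λ) at the df-calibrated λ.

    Only meaningful for distinct ``t``; used for diagnostics and testing.
    """
    t = np.asarray(t, dtype=float)
    order = np.argsort(t)
    x = t[order]
    if len(np.unique(x)) != len(x):
        raise ValidationError("smoother_matrix requires distinct abscissae")
    system = _ReinschSystem(x, np.zeros_like(x), np.ones_like(x))
    lam = _calibrate_lambda(system, df, df_tol, None)
    A = system.R + lam * system.QtWinvQ
    cf = sla.cho_factor(A, lower=True, check_finite=False)
    M = sla.cho_solve(cf, system.Q.T, check_finite=False)
    S_sorted = np.eye(len(x)) - lam * (system.Q @ M)
    # undo the sort on both axes
    S = np.empty_like(S_sorted)
    S[np.ix_(order, order)] = S_sorted
    return S


def smooth_ridge(
    t: np.ndarray,
    r: np.ndarray,
    df: float,
    weights: np.ndarray | None = None,
    df_tol: float = 0.02,
    warm_loglam: float | None = None,
) -> RidgeSmoother:
    """Fit a df-calibrated smoothing spline of ``r`` on ``t``.

    Duplicated abscissae are merged by weighted averaging (their weights
    accumulate), which leaves the penalised criterion unchanged.  Raises if
    all ``t`` coincide (degenerate projection) or df is infeasible.
    """
    t = np.asarray(t, dtype=float).ravel()
    r = np.asarray(r, dtype=float).ravel()
    if t.shape != r.shape:
        raise ValidationError("t and r must have equal length")
    if len(t) < 5:
        raise ValidationError("smoothing needs at least 5 observations")
    if not np.isfinite(df) or df < 2:
        raise ValidationError("df must be a finite real >= 2")
    if df >= len(t):
        raise ValidationError(f"df={df} must be < number of observations {len(t)}")
    w_in = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)

    xu, inverse = np.unique(t, return_inverse=True)
    if len(xu) < 2 or not np.isfinite(xu[-1] - xu[0]) or xu[-1] - xu[0] <= 0:
        raise FitError("degenerate projection: all projected values identical")
    # merge near-coincident abscissae: tiny gaps make the penalised system
    # numerically indefinite without adding any resolvable structure
    gap_tol = 1e-7 * (xu[-1] - xu[0])
    group = np.concatenate([[0], np.cumsum(np.diff(xu) > gap_tol)])[inverse]
    w = np.bincount(group, weights=w_in)
    x = np.bincount(group, weights=w_in * t) / w
    y = np.bincount(group, weights=w_in * r) / w
    if len(x) < 2:
        raise FitError("degenerate projection: all projected values identical")

    if len(x) == 2:
        # only a straight line is identifiable; weighted LS line
        sm = RidgeSmoother(knots=x, values=y, df_requested=df, df_actual=2.0, lam=np.inf)
        return sm

    df_eff = float(np.clip(df, 2.0, len(x) - 1e-9))
    system = _ReinschSystem(x, y, w)
    lam = _calibrate_lambda(system, df_eff, df_tol, warm_loglam)
    f, _ = system.solve(lam)
    return RidgeSmoother(
        knots=x,
        values=f,
        df_requested=df,
        df_actual=system.trace(lam),
        lam=lam,
    )
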