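"""Projection pursuit regression (PPR), implemented from scratch.

The model approximates the response as a finite sum of ridge functions,

    y ≈ ȳ + Σ_i  β_i · g_i(α_i · x),

where each α_i is a unit projection direction over the standardised
descriptors, g_i a smooth one-dimensional function (a df-calibrated
natural smoothing spline, see :mod:`gsppr.smoothing`) and β_i a scale.

Fitting follows the classic forward/backward scheme:

* **Forward**: terms are added greedily on the current residuals up to
  ``max_terms``.  Each term alternates (a) smoothing the residuals against
  the current projection and (b) a Gauss–Newton update of the direction
  using the smoother's derivative, renormalised to unit length, until the
  relative residual-sum-of-squares change drops below ``tol``.  Updates are
  accepted only when they reduce the RSS (with step halving on the unit
  sphere), so forward RSS is non-increasing by construction.
* **Backward**: terms are pruned one at a time (lowest share of explained
  variance first) back to ``nterms``.  ``optlevel`` sets how much is
  refitted after each drop: 0 nothing, 1 the ridge functions and scales
  with directions frozen, 2/3 everything including directions (3 is an
  alias of 2 for a single response).

Direction initialisation is deterministic: the OLS coefficient direction
of the residuals, plus the leading eigenvector of the residual-weighted
second-moment matrix Σ_j r_j x_j x_jᵀ (which recovers even/symmetric ridge
shapes whose linear signal vanishes), plus seeded random restarts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import DescriptorTable
from .errors import FitError, ValidationError
from .smoothing import RidgeSmoother, smooth_ridge

logger = logging.getLogger(__name__)

SERIALIZATION_VERSION = 1
_EPS = 1e-12


@dataclass
class PPRHyperparams:
    """The four tunable PPR controls."""

    nterms: int
    max_terms: int | None = None
    df: float = 4.0
    optlevel: int = 1

    def __post_init__(self) -> None:
        if self.max_terms is None:
            self.max_terms = self.nterms
        if self.nterms < 1:
            raise ValidationError("nterms must be >= 1")
        if self.nterms > self.max_terms:
            raise ValidationError("nterms must not exceed max_terms")
        if self.optlevel not in (0, 1, 2, 3):
            raise ValidationError("optlevel must be 0, 1, 2 or 3")
        if not np.isfinite(self.df) or self.df < 2:
            raise ValidationError("df must be a finite real >= 2")

    def to_dict(self) -> dict:
        return {
            "nterms": int(self.nterms),
            "max_terms": int(self.max_terms),
            "df": float(self.df),
            "optlevel": int(self.optlevel),
        }


@dataclass
class RidgeTerm:
    """One fitted ridge: unit direction, smoother, scale, importance share."""

    direction: np.ndarray
    smoother: RidgeSmoother
    scale: float
    importance: float = np.nan
    ss_contribution: float = np.nan
    iterations: int = 0

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float).ravel()
        norm = np.linalg.norm(self.direction)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            raise ValidationError("ridge direction must be unit-norm")

    def project(self, Xs: np.ndarray) -> np.ndarray:
        return Xs @ self.direction

    def evaluate(self, Xs: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(self.smoother(self.project(Xs)))

    def to_dict(self) -> dict:
        return {
            "direction": [float(v) for v in self.direction],
            "smoother": self.smoother.to_dict(),
            "scale": float(self.scale),
            "importance": float(self.importance),
            "ss_contribution": float(self.ss_contribution),
            "iterations": int(self.iterations),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeTerm":
        return cls(
            direction=np.asarray(d["direction"], dtype=float),
            smoother=RidgeSmoother.from_dict(d["smoother"]),
            scale=float(d["scale"]),
            importance=float(d.get("importance", np.nan)),
            ss_contribution=float(d.get("ss_contribution", np.nan)),
            iterations=int(d.get("iterations", 0)),
        )


@dataclass
class PPRModel:
    """A fitted projection pursuit regression model."""

    terms: list[RidgeTerm]
    descriptor_names: tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    response_center: float
    hyperparams: PPRHyperparams
    converged: bool = True
    final_rel_change: float = np.nan
    fitted_values: np.ndarray | None = None

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_sd

    def _matrix(self, table_or_matrix: DescriptorTable | np.ndarray) -> np.ndarray:
        if isinstance(table_or_matrix, DescriptorTable):
            X = table_or_matrix.matrix(list(self.descriptor_names))
        else:
            X = np.asarray(table_or_matrix, dtype=float)
            if X.ndim != 2 or X.shape[1] != len(self.descriptor_names):
                raise ValidationError(
                    f"expected a matrix with {len(self.descriptor_names)} columns"
                )
        return X

    def predict(
        self,
        table_or_matrix: DescriptorTable | np.ndarray,
        return_extrapolated: bool = False,
    ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
        """Predicted activities; optionally a per-row extrapolation flag.

        A row is flagged when any term's projection falls outside the range
        seen in training; there the smoother continues linearly.
        """
        Xs = self.standardize(self._matrix(table_or_matrix))
        yhat = np.full(Xs.shape[0], self.response_center, dtype=float)
        extrapolated = np.zeros(Xs.shape[0], dtype=bool)
        for term in self.terms:
            t = term.project(Xs)
            yhat += term.scale * np.asarray(term.smoother(t))
            extrapolated |= term.smoother.extrapolation_mask(t)
        if return_extrapolated:
            return yhat, extrapolated
        return yhat

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": SERIALIZATION_VERSION,
            "descriptor_names": list(self.descriptor_names),
            "x_mean": [float(v) for v in self.x_mean],
            "x_sd": [float(v) for v in self.x_sd],
            "response_center": float(self.response_center),
            "hyperparams": self.hyperparams.to_dict(),
            "converged": bool(self.converged),
            "final_rel_change": float(self.final_rel_change),
            "terms": [t.to_dict() for t in self.terms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PPRModel":
        if d.get("format_version") != SERIALIZATION_VERSION:
            raise ValidationError(
                f"unsupported model format version {d.get('format_version')!r}"
            )
        hp = d["hyperparams"]
        return cls(
            terms=[RidgeTerm.from_dict(t) for t in d["terms"]],
            descriptor_names=tuple(d["descriptor_names"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            response_center=float(d["response_center"]),
            hyperparams=PPRHyperparams(**hp),
            converged=bool(d.get("converged", True)),
            final_rel_change=float(d.get("final_rel_change", np.nan)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PPRModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def term_importance(model: PPRModel) -> np.ndarray:
    """Share of regression sum of squares per term; sums to 1."""
    ss = np.array([t.ss_contribution for t in model.terms], dtype=float)
    total = ss.sum()
    if not np.isfinite(total) or total <= 0:
        raise FitError("total regression sum of squares is zero")
    return ss / total


# ---------------------------------------------------------------------------
# fitting internals


def _initial_directions(
    Xs: np.ndarray, resid: np.ndarray, rng: np.random.Generator, n_restarts: int
) -> list[np.ndarray]:
    p = Xs.shape[1]
    inits: list[np.ndarray] = []
    coef, *_ = np.linalg.lstsq(Xs, resid, rcond=None)
    if np.linalg.norm(coef) > _EPS:
        inits.append(coef / np.linalg.norm(coef))
    # second-moment init: leading eigenvector of sum_j r_j x_j x_j^T catches
    # even ridge shapes whose linear correlation with x vanishes
    M = (Xs * resid[:, None]).T @ Xs / len(resid)
    M = 0.5 * (M + M.T)
    if np.all(np.isfinite(M)) and np.abs(M).max() > _EPS:
        vals, vecs = np.linalg.eigh(M)
        v = vecs[:, int(np.argmax(np.abs(vals)))]
        inits.append(v / np.linalg.norm(v))
    while len(inits) < n_restarts:
        v = rng.standard_normal(p)
        inits.append(v / np.linalg.norm(v))
    return inits[:max(n_restarts, 1)]


def _scale_for(gt: np.ndarray, resid: np.ndarray) -> float:
    denom = float(gt @ gt)
    return float(gt @ resid) / denom if denom > _EPS else 0.0


def _fit_single_term(
    Xs: np.ndarray,
    resid: np.ndarray,
    df: float,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    n_restarts: int,
    init_direction: np.ndarray | None = None,
) -> tuple[RidgeTerm, bool, float]:
    """Fit one ridge term on residuals; returns (term, converged, rel_change)."""
    n, p = Xs.shape
    if init_direction is not None:
        inits = [np.asarray(init_direction, dtype=float)]
    else:
        inits = _initial_directions(Xs, resid, rng, n_restarts)

    best: tuple[float, np.ndarray, RidgeSmoother, float, int, bool, float] | None = None
    for alpha0 in inits:
        alpha = alpha0.copy()
        t = Xs @ alpha
        try:
            g = smooth_ridge(t, resid, df, df_tol=0.1)
        except FitError:
            continue
        gt = np.asarray(g(t))
        beta = _scale_for(gt, resid)
        rss = float(((resid - beta * gt) ** 2).sum())
        converged = False
        rel = np.nan
        n_iter = 0
        warm = np.log10(g.lam) if np.isfinite(g.lam) and g.lam > 0 else None
        for it in range(max_iter):
            n_iter = it + 1
            gp = np.asarray(g.derivative(t))
            slope = beta * gp
            w = slope**2
            wmax = w.max()
            if wmax <= _EPS:
                converged = True
                rel = 0.0
                break
            active = w > 1e-10 * wmax
            z = t.copy()
            z[active] += (resid[active] - beta * gt[active]) / slope[active]
            sw = np.sqrt(w[active])
            try:
                coef, *_ = np.linalg.lstsq(Xs[active] * sw[:, None], z[active] * sw, rcond=None)
            except np.linalg.LinAlgError:
                break
            norm = np.linalg.norm(coef)
            if norm <= _EPS:
                converged = True
                rel = 0.0
                break
            alpha_prop = coef / norm
            # accept only improvements; halve the step on the sphere otherwise
            improved = False
            for _halving in range(4):
                t_prop = Xs @ alpha_prop
                try:
                    g_prop = smooth_ridge(t_prop, resid, df, df_tol=0.1, warm_loglam=warm)
                except FitError:
                    break
                gt_prop = np.asarray(g_prop(t_prop))
                beta_prop = _scale_for(gt_prop, resid)
                rss_prop = float(((resid - beta_prop * gt_prop) ** 2).sum())
                if rss_prop < rss:
                    rel = (rss - rss_prop) / max(rss, _EPS)
                    alpha, t, g, gt, beta, rss = (
                        alpha_prop, t_prop, g_prop, gt_prop, beta_prop, rss_prop,
                    )
                    warm = np.log10(g.lam) if np.isfinite(g.lam) and g.lam > 0 else warm
                    improved = True
                    break
                mix = alpha + alpha_prop
                nm = np.linalg.norm(mix)
                if nm <= _EPS:
                    break
                alpha_prop = mix / nm
            if not improved:
                converged = True
                rel = 0.0
                break
            if rel < tol:
                converged = True
                break
        if best is None or rss < best[0]:
            best = (rss, alpha, g, beta, n_iter, converged, rel)

    if best is None:
        raise FitError("could not fit a ridge term: degenerate projections")
    rss, alpha, g, beta, n_iter, converged, rel = best
    # honour the df contract tightly on the final smoother
    t = Xs @ alpha
    g = smooth_ridge(t, resid, df, df_tol=0.02,
                     warm_loglam=np.log10(g.lam) if np.isfinite(g.lam) and g.lam > 0 else None)
    gt = np.asarray(g(t))
    beta = _scale_for(gt, resid)
    term = RidgeTerm(direction=alpha, smoother=g, scale=beta, iterations=n_iter)
    return term, converged, float(rel) if np.isfinite(rel) else 0.0


def _term_outputs(terms: Sequence[RidgeTerm], Xs: np.ndarray) -> np.ndarray:
    return np.column_stack([np.asarray(t.smoother(t.project(Xs))) for t in terms])


def _refit_scales(terms: list[RidgeTerm], Xs: np.ndarray, yc: np.ndarray) -> float:
    """Least-squares scales (with intercept) on the term outputs.

    Returns the intercept adjustment; sets ``scale``, ``ss_contribution``
    and ``importance`` on the terms in place.
    """
    G = _term_outputs(terms, Xs)
    design = np.column_stack([np.ones(len(yc)), G])
    coef, *_ = np.linalg.lstsq(design, yc, rcond=None)
    for k, term in enumerate(terms):
        term.scale = float(coef[k + 1])
        contrib = coef[k + 1] * (G[:, k] - G[:, k].mean())
        term.ss_contribution = float(contrib @ contrib)
    total = sum(t.ss_contribution for t in terms)
    for term in terms:
        term.importance = term.ss_contribution / total if total > 0 else np.nan
    return float(coef[0])


def _current_rss(terms: Sequence[RidgeTerm], Xs: np.ndarray, yc: np.ndarray) -> float:
    pred = np.zeros_like(yc)
    for t in terms:
        pred += t.evaluate(Xs)
    # allow an intercept correction, as the final model does
    c = float((yc - pred).mean())
    return float(((yc - pred - c) ** 2).sum())


def _backfit(
    terms: list[RidgeTerm],
    Xs: np.ndarray,
    yc: np.ndarray,
    df: float,
    refit_directions: bool,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    sweeps: int = 5,
) -> None:
    """Cyclic refit of terms on their partial residuals (optlevel >= 1).

    Each proposed update is kept only when it lowers the training RSS, so
    backfitting can never degrade the fit.
    """
    rss = _current_rss(terms, Xs, yc)
    for _sweep in range(sweeps):
        improved = False
        for i, term in enumerate(terms):
            partial = yc.copy()
            for j, other in enumerate(terms):
                if j != i:
                    partial -= other.evaluate(Xs)
            if refit_directions:
                try:
                    new_term, _, _ = _fit_single_term(
                        Xs, partial, df, rng, tol, max_iter,
                        n_restarts=1, init_direction=term.direction,
                    )
                except FitError:
                    continue
            else:
                t = term.project(Xs)
                try:
                    g = smooth_ridge(t, partial, df, df_tol=0.02)
                except FitError:
                    continue
                gt = np.asarray(g(t))
                new_term = RidgeTerm(
                    direction=term.direction.copy(),
                    smoother=g,
                    scale=_scale_for(gt, partial),
                    iterations=term.iterations,
                )
            candidate = terms[:i] + [new_term] + terms[i + 1:]
            rss_new = _current_rss(candidate, Xs, yc)
            if rss_new < rss - _EPS:
                terms[i] = new_term
                rss = rss_new
                improved = True
        if not improved:
            break


def fit_ppr(
    table: DescriptorTable,
    nterms: int,
    max_terms: int | None = None,
    df: float = 4.0,
    optlevel: int = 1,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 50,
    n_restarts: int = 4,
) -> PPRModel:
    """Fit a PPR model on the training rows of ``table``.

    ``nterms`` ridge terms remain in the final model after growing to
    ``max_terms`` and pruning back by importance; see the module docstring
    for the full algorithm.  The fit is deterministic given (data,
    hyperparameters, seed).
    """
    hp = PPRHyperparams(nterms=nterms, max_terms=max_terms, df=df, optlevel=optlevel)
    train = table.training()
    X = train.values
    y = train.activity
    n, p = X.shape
    if n <= hp.df + 2:
        raise ValidationError(f"need n > df + 2 (= {hp.df + 2}), got n = {n}")
    if n < 5:
        raise ValidationError("PPR needs at least 5 training compounds")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    degenerate = x_sd <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant descriptor(s) in PPR input",
            stacklevel=2,
        )
        x_sd = np.where(degenerate, 1.0, x_sd)
    Xs = (X - x_mean) / x_sd
    y_mean = float(y.mean())
    yc = y - y_mean

    rng = np.random.default_rng(seed)
    terms: list[RidgeTerm] = []
    resid = yc.copy()
    all_converged = True
    last_rel = 0.0
    for m in range(hp.max_terms):
        term, converged, rel = _fit_single_term(
            Xs, resid, hp.df, rng, tol, max_iter, n_restarts
        )
        all_converged &= converged
        last_rel = rel
        terms.append(term)
        resid = resid - term.evaluate(Xs)
        logger.debug("forward term %d: rss=%.6g", m + 1, float(resid @ resid))
    if not all_converged:
        warnings.warn("PPR forward pass hit max_iter without converging", stacklevel=2)

    # backward pruning to nterms
    if len(terms) > hp.nterms:
        _refit_scales(terms, Xs, yc)
        while len(terms) > hp.nterms:
            drop = int(np.argmin([t.ss_contribution for t in terms]))
            logger.debug("pruning term %d (importance %.3f)", drop, terms[drop].importance)
            del terms[drop]
            if hp.optlevel >= 1 and terms:
                _backfit(
                    terms, Xs, yc, hp.df,
                    refit_directions=hp.optlevel >= 2,
                    rng=rng, tol=tol, max_iter=max_iter,
                )
            _refit_scales(terms, Xs, yc)

    intercept_adj = _refit_scales(terms, Xs, yc)
    fitted = y_mean + intercept_adj + sum(t.evaluate(Xs) for t in terms)
    return PPRModel(
        terms=terms,
        descriptor_names=tuple(train.descriptor_names),
        x_mean=x_mean,
        x_sd=x_sd,
        response_center=y_mean + intercept_adj,
        hyperparams=hp,
        converged=all_converged,
        final_rel_change=last_rel,
        fitted_values=np.asarray(fitted, dtype=float),
    )
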