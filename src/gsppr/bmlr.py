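"""Best multi-linear regression (BMLR).

A heuristic best-subset search over molecular descriptors in the CODESSA
style: rank single descriptors, seed a beam with all sufficiently
non-collinear descriptor pairs, then grow each retained model one
descriptor at a time, keeping the ``beam_width`` best models (by Fisher F)
at every size.  Growth stops when the best model's R² improves by less
than the ``breakpoint`` (default 0.02) from one size to the next — the
over-parameterisation guard — or when ``max_size`` is reached.

Every fitted model carries the four standard QSAR statistics: R² (squared
Pearson correlation of fitted vs observed), leave-one-out cross-validated
R², the squared standard error of estimate s², and the Fisher F statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .dataset import DescriptorTable
from .errors import FitError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class LinearModel:
    """An OLS model on a descriptor subset with its fit statistics."""

    descriptor_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    n: int
    r2: float
    r2_cv: float
    s2: float
    f_stat: float

    def predict(self, table_or_matrix: DescriptorTable | np.ndarray) -> np.ndarray:
        if isinstance(table_or_matrix, DescriptorTable):
            X = table_or_matrix.matrix(list(self.descriptor_names))
        else:
            X = np.asarray(table_or_matrix, dtype=float)
            if X.shape[1] != len(self.descriptor_names):
                raise ValidationError(
                    f"expected {len(self.descriptor_names)} columns, got {X.shape[1]}"
                )
        return self.intercept + X @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "n": int(self.n),
            "r2": float(self.r2),
            "r2_cv": float(self.r2_cv),
            "s2": float(self.s2),
            "f_stat": float(self.f_stat),
        }


def _design(table: DescriptorTable, subset: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    if len(subset) == 0:
        raise ValidationError("descriptor subset is empty")
    X = table.matrix(list(subset))
    design = np.column_stack([np.ones(X.shape[0]), X])
    return design, table.activity


def _ols_core(design: np.ndarray, y: np.ndarray, subset: Sequence[str]):
    """QR-based OLS; returns coefficients, fitted, residuals, leverages."""
    n, pp1 = design.shape
    if n <= pp1:
        raise ValidationError(
            f"need n > {pp1} rows for {pp1 - 1} descriptors + intercept, got {n}"
        )
    Q, R = np.linalg.qr(design)
    diag = np.abs(np.diag(R))
    tol = max(n, pp1) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if np.any(diag < tol):
        bad = [subset[k - 1] for k in np.flatnonzero(diag < tol) if k > 0]
        raise FitError(f"rank-deficient design; collinear descriptor(s): {bad}")
    coef = sla.solve_triangular(R, Q.T @ y)
    fitted = design @ coef
    resid = y - fitted
    leverage = (Q**2).sum(axis=1)
    return coef, fitted, resid, leverage


def _squared_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    c = float(np.corrcoef(a, b)[0, 1])
    return c * c


def fit_ols(table: DescriptorTable, subset: Sequence[str]) -> LinearModel:
    """Ordinary least squares on ``subset`` with full QSAR statistics.

    ``r2_cv`` is the closed-form leave-one-out R² (PRESS via the hat-matrix
    diagonal); it is NaN when some observation is exactly determined
    (leverage 1).
    """
    design, y = _design(table, subset)
    coef, fitted, resid, leverage = _ols_core(design, y, list(subset))
    n = len(y)
    p = len(subset)
    dof = n - p - 1
    rss = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = _squared_pearson(fitted, y) if sst > 0 else 0.0
    s2 = rss / dof
    f_stat = ((sst - rss) / p) / (rss / dof) if rss > 0 else np.inf
    if np.any(leverage >= 1 - 1e-10) or sst == 0:
        r2_cv = np.nan
    else:
        press = float(((resid / (1 - leverage)) ** 2).sum())
        r2_cv = 1 - press / sst
    return LinearModel(
        descriptor_names=tuple(subset),
        coefficients=coef[1:],
        intercept=float(coef[0]),
        n=n,
        r2=r2,
        r2_cv=float(r2_cv),
        s2=float(s2),
        f_stat=float(f_stat),
    )


def loo_r2(table: DescriptorTable, subset: Sequence[str]) -> float:
    """Leave-one-out cross-validated R² = 1 − PRESS/SST, closed form.

    LOO residuals are ``e_i / (1 − h_ii)`` with ``h_ii`` the hat-matrix
    diagonal, so no refitting is needed.
    """
    design, y = _design(table, subset)
    if len(y) <= len(subset) + 2:
        raise ValidationError("LOO needs n > p + 2")
    _, _, resid, leverage = _ols_core(design, y, list(subset))
    if np.any(leverage >= 1 - 1e-10):
        raise FitError("a leverage equals 1: some point is exactly determined")
    press = float(((resid / (1 - leverage)) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise FitError("constant response: SST is zero")
    return 1 - press / sst


@dataclass
class BMLRResult:
    """Per-size champion models and the breakpoint-selected model."""

    champions: dict[int, LinearModel]
    selected_size: int
    breakpoint_fired: bool

    @property
    def selected(self) -> LinearModel:
        return self.champions[self.selected_size]

    def report_frame(self) -> pd.DataFrame:
        rows = [
            {
                "size": k,
                "descriptors": "+".join(m.descriptor_names),
                "r2": m.r2,
                "r2_cv": m.r2_cv,
                "s2": m.s2,
                "f_stat": m.f_stat,
            }
            for k, m in sorted(self.champions.items())
        ]
        return pd.DataFrame(rows)

    def write_report(self, path: str | Path) -> None:
        self.report_frame().to_csv(path, sep="\t", index=False)


def bmlr_search(
    table: DescriptorTable,
    max_size: int,
    breakpoint: float = 0.02,
    pair_corr_max: float = 0.8,
    beam_width: int = 400,
) -> BMLRResult:
    """Beam search for the best descriptor subset at each size.

    Operates on the training rows of ``table`` (or all rows when no split
    labels are assigned).  Deterministic: no randomness enters the search.
    """
    train = table.training()
    n = train.n_compounds
    if max_size < 1:
        raise ValidationError("max_size must be >= 1")
    if max_size >= n / 3:
        warnings.warn(
            f"max_size={max_size} exceeds the n/3 rule of thumb for n={n}",
            stacklevel=2,
        )
    names = train.descriptor_names
    p = len(names)
    sds = train.values.std(axis=0, ddof=1)
    usable = [j for j in range(p) if sds[j] > 0]
    if not usable:
        raise FitError("no non-constant descriptors available")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        abs_corr = np.nan_to_num(
            np.abs(np.corrcoef(train.values, rowvar=False)), nan=1.0
        )

    def safe_fit(subset: tuple[int, ...]) -> LinearModel | None:
        try:
            return fit_ols(train, [names[j] for j in subset])
        except (FitError, ValidationError):
            return None

    champions: dict[int, LinearModel] = {}

    # stage 1: rank singles by r2
    singles = [(j, safe_fit((j,))) for j in usable]
    singles = [(j, m) for j, m in singles if m is not None]
    if not singles:
        raise FitError("no single-descriptor model could be fitted")
    singles.sort(key=lambda jm: jm[1].r2, reverse=True)
    champions[1] = singles[0][1]
    logger.info("size 1: best r2=%.4f (%s)", champions[1].r2, champions[1].descriptor_names)

    def finish(selected: int, fired: bool) -> BMLRResult:
        if not fired:
            warnings.warn(
                "breakpoint criterion never fired; selected max_size model",
                stacklevel=2,
            )
        return BMLRResult(champions=champions, selected_size=selected, breakpoint_fired=fired)

    if max_size == 1:
        return finish(1, False)

    # stage 2: all admissible (non-collinear) pairs
    beam: list[tuple[tuple[int, ...], LinearModel]] = []
    for i, j in combinations(usable, 2):
        if abs_corr[i, j] >= pair_corr_max:
            continue
        m = safe_fit((i, j))
        if m is not None:
            beam.append(((i, j), m))
    if not beam:
        raise FitError("no admissible descriptor pair: all pairs are collinear")
    beam.sort(key=lambda sm: sm[1].f_stat, reverse=True)
    beam = beam[:beam_width]
    champions[2] = max(beam, key=lambda sm: sm[1].r2)[1]
    logger.info("size 2: best r2=%.4f", champions[2].r2)
    if champions[2].r2 - champions[1].r2 < breakpoint:
        return finish(1, True)

    size = 2
    while size < max_size:
        candidates: dict[tuple[int, ...], LinearModel] = {}
        for subset, _ in beam:
            members = set(subset)
            for d in usable:
                if d in members:
                    continue
                if any(abs_corr[d, mjdx] >= pair_corr_max for mjdx in subset):
                    continue
                key = tuple(sorted(members | {d}))
                if key in candidates:
                    continue
                m = safe_fit(key)
                if m is not None:
                    candidates[key] = m
        if not candidates:
            logger.info("no admissible extension at size %d; stopping", size + 1)
            return finish(size, False)
        ranked = sorted(candidates.items(), key=lambda km: km[1].f_stat, reverse=True)
        beam = ranked[:beam_width]
        size += 1
        champions[size] = max(candidates.values(), key=lambda m: m.r2)
        logger.info("size %d: best r2=%.4f", size, champions[size].r2)
        if champions[size].r2 - champions[size - 1].r2 < breakpoint:
            return finish(size - 1, True)
    return finish(max_size, False)
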