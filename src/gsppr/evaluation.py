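"""Model evaluation: RMSE/R² metrics, k-fold CV, grid search, PCA diagnostic.

The grid search tunes the four PPR controls (nterms, max.terms, df,
optlevel) by k-fold cross-validation **on the training rows only**; the
held-out test set is scored once, after selection, to avoid selection
leakage.  All cells share one fold assignment so their scores are
comparable, and the winner is the cell with the smallest mean CV RMSE
(ties broken toward parsimony: smaller nterms, then max_terms, then df).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bmlr import fit_ols
from .dataset import DescriptorTable
from .errors import FitError, ValidationError
from .ppr import PPRHyperparams, fit_ppr

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics


def rmse(y_exp: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error sqrt(mean((y_exp - y_pred)^2))."""
    y_exp = np.asarray(y_exp, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_exp.shape != y_pred.shape or y_exp.size == 0:
        raise ValidationError("rmse needs two equal-length nonempty vectors")
    return float(np.sqrt(np.mean((y_exp - y_pred) ** 2)))


def r2(y_exp: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation between experimental and predicted values."""
    y_exp = np.asarray(y_exp, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_exp.shape != y_pred.shape or y_exp.size < 2:
        raise ValidationError("r2 needs two equal-length vectors (n >= 2)")
    if y_exp.std() == 0 or y_pred.std() == 0:
        raise ValidationError("r2 undefined: a vector has zero variance")
    c = float(np.corrcoef(y_exp, y_pred)[0, 1])
    return c * c


# ---------------------------------------------------------------------------
# cross-validation


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded, size-balanced partition of range(n) into k folds."""
    if not 2 <= k <= n:
        raise ValidationError(f"k must be in [2, n={n}], got {k}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


@dataclass
class CVResult:
    """Pooled out-of-fold scores plus per-fold detail."""

    r2_cv: float
    rmse_cv: float
    per_fold: pd.DataFrame
    predictions: np.ndarray  # out-of-fold prediction for every row, in order


ModelSpec = "Sequence[str] | PPRHyperparams"


def _fit_and_predict(
    spec, train_table: DescriptorTable, predict_table: DescriptorTable,
    ppr_options: dict,
) -> np.ndarray:
    if isinstance(spec, PPRHyperparams):
        model = fit_ppr(
            train_table,
            nterms=spec.nterms,
            max_terms=spec.max_terms,
            df=spec.df,
            optlevel=spec.optlevel,
            **ppr_options,
        )
        return np.asarray(model.predict(predict_table))
    names = list(spec)
    return fit_ols(train_table, names).predict(predict_table)


def kfold_cv(
    table: DescriptorTable,
    model_spec,
    k: int = 5,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
    ppr_options: dict | None = None,
) -> CVResult:
    """k-fold cross-validation on the training rows.

    ``model_spec`` is either a sequence of descriptor names (a linear
    model) or a :class:`PPRHyperparams`.  Out-of-fold predictions are
    assembled over all rows and scored as one pooled vector; per-fold
    statistics are also reported.  ``k = n`` reduces to leave-one-out.
    """
    train = table.training()
    n = train.n_compounds
    if folds is None:
        folds = make_folds(n, k, seed)
    ppr_options = dict(ppr_options or {})
    ppr_options.setdefault("seed", seed)

    min_rows = (
        len(model_spec) + 2
        if not isinstance(model_spec, PPRHyperparams)
        else int(model_spec.df) + 3
    )
    preds = np.full(n, np.nan)
    rows = []
    for fi, hold in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        if mask.sum() < min_rows:
            raise ValidationError(
                f"fold {fi}: only {int(mask.sum())} rows to fit a model needing {min_rows}"
            )
        sub_train = train.select_rows(mask)
        sub_hold = train.select_rows(~mask)
        preds[hold] = _fit_and_predict(model_spec, sub_train, sub_hold, ppr_options)
        fold_rmse = rmse(train.activity[hold], preds[hold])
        fold_r2 = (
            r2(train.activity[hold], preds[hold])
            if len(hold) >= 2
            and train.activity[hold].std() > 0
            and preds[hold].std() > 0
            else np.nan
        )
        rows.append({"fold": fi, "n_held_out": len(hold), "rmse": fold_rmse, "r2": fold_r2})
    assert not np.isnan(preds).any()
    return CVResult(
        r2_cv=r2(train.activity, preds),
        rmse_cv=rmse(train.activity, preds),
        per_fold=pd.DataFrame(rows),
        predictions=preds,
    )


# ---------------------------------------------------------------------------
# grid search


@dataclass
class GridSpec:
    """Candidate lists for the four PPR controls."""

    nterms: Sequence[int] = (1, 2, 3)
    max_terms: Sequence[int] = (3, 5, 7)
    df: Sequence[float] = (4.0,)
    optlevel: Sequence[int] = (1,)

    def cells(self) -> list[PPRHyperparams]:
        out = []
        for nt, mt, d, ol in itertools.product(
            self.nterms, self.max_terms, self.df, self.optlevel
        ):
            if nt > mt:
                continue  # infeasible: cannot keep more terms than were grown
            out.append(PPRHyperparams(nterms=nt, max_terms=mt, df=d, optlevel=ol))
        if not out:
            raise ValidationError("grid is empty after the nterms <= max_terms constraint")
        return out

    def to_dict(self) -> dict:
        return {
            "nterms": [int(v) for v in self.nterms],
            "max_terms": [int(v) for v in self.max_terms],
            "df": [float(v) for v in self.df],
            "optlevel": [int(v) for v in self.optlevel],
        }


@dataclass
class GridResult:
    """Per-cell cross-validation scores and the selected cell."""

    records: list[dict]
    best_cell: PPRHyperparams
    tie_break_note: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: v for k, v in rec.items() if not isinstance(v, list)} for rec in self.records]
        )

    def write_surface(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def grid_search(
    table: DescriptorTable,
    grid: GridSpec,
    k: int = 5,
    seed: int = 0,
    ppr_options: dict | None = None,
) -> GridResult:
    """Evaluate every admissible grid cell by shared-fold k-fold CV.

    Also records training-set R²/RMSE per cell (the full-training refit),
    mirroring the usual optimisation-surface plots, but selection uses only
    the CV RMSE.
    """
    train = table.training()
    cells = grid.cells()
    folds = make_folds(train.n_compounds, k, seed)
    records: list[dict] = []
    failures: list[str] = []
    for cell in cells:
        try:
            cv = kfold_cv(train, cell, k=k, seed=seed, folds=folds, ppr_options=ppr_options)
            full = fit_ppr(
                train, nterms=cell.nterms, max_terms=cell.max_terms,
                df=cell.df, optlevel=cell.optlevel,
                **{"seed": seed, **(ppr_options or {})},
            )
            train_pred = full.predict(train)
            cell_train_r2 = r2(train.activity, train_pred)
            cell_train_rmse = rmse(train.activity, train_pred)
        except (FitError, ValidationError) as exc:
            failures.append(f"{cell.to_dict()}: {exc}")
            logger.warning("grid cell %s failed: %s", cell.to_dict(), exc)
            continue
        records.append(
            {
                **cell.to_dict(),
                "cv_r2": cv.r2_cv,
                "cv_rmse": cv.rmse_cv,
                "train_r2": cell_train_r2,
                "train_rmse": cell_train_rmse,
                "fold_rmse": cv.per_fold["rmse"].tolist(),
                "fold_r2": cv.per_fold["r2"].tolist(),
            }
        )
        logger.info(
            "grid cell %s: cv_rmse=%.4f cv_r2=%.4f",
            cell.to_dict(), cv.rmse_cv, cv.r2_cv,
        )
    if not records:
        raise FitError("every grid cell failed to fit: " + "; ".join(failures))

    def sort_key(rec: dict):
        return (rec["cv_rmse"], rec["nterms"], rec["max_terms"], rec["df"])

    ranked = sorted(records, key=sort_key)
    best = ranked[0]
    tie = [
        rec for rec in records
        if rec is not best and np.isclose(rec["cv_rmse"], best["cv_rmse"], rtol=0, atol=1e-12)
    ]
    note = (
        f"{len(tie)} cell(s) tied on CV RMSE; broke toward smaller (nterms, max_terms, df)"
        if tie
        else ""
    )
    best_cell = PPRHyperparams(
        nterms=best["nterms"], max_terms=best["max_terms"],
        df=best["df"], optlevel=best["optlevel"],
    )
    return GridResult(records=records, best_cell=best_cell, tie_break_note=note)


# ---------------------------------------------------------------------------
# PCA split diagnostic


@dataclass
class PCAResult:
    explained_pct: np.ndarray  # percent of total variance per component
    scores: pd.DataFrame  # columns: compound_id, PC1, PC2, split


def pca_diagnostic(table: DescriptorTable, subset: Sequence[str]) -> PCAResult:
    """PCA of the correlation matrix of ``subset``; 2-D scores per compound.

    Used to check that the train/test split covers the descriptor space
    evenly.  The correlation (not covariance) matrix is used because
    descriptors live on heterogeneous scales.
    """
    names = list(subset)
    if len(names) < 2:
        raise ValidationError("pca_diagnostic needs at least 2 descriptors")
    X = table.matrix(names)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[j] for j in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant descriptor(s) in PCA subset: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, j]))
        if vecs[lead, j] < 0:
            vecs[:, j] = -vecs[:, j]
    explained = 100.0 * vals / vals.sum()
    scores2 = Z @ vecs[:, :2]
    frame = pd.DataFrame(
        {
            "compound_id": table.compound_ids,
            "PC1": scores2[:, 0],
            "PC2": scores2[:, 1],
            "split": table.split,
        }
    )
    return PCAResult(explained_pct=explained, scores=frame)
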