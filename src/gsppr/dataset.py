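"""Descriptor tables: reading, validation, pruning, train/test splitting.

A QSAR study starts from a rectangular table — one row per compound, one
column per numeric molecular descriptor, plus the measured activity
(pIC50 = −log10 IC50, IC50 in nM).  This module owns that container and the
bookkeeping that keeps it honest: unique identifiers, finite values,
removal of constant and highly collinear descriptors, and a reproducible
random train/test split.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

SPLIT_LABELS = ("train", "test", "unassigned")


@dataclass
class DescriptorTable:
    """Compounds x descriptors matrix with activities and split labels.

    Parameters
    ----------
    compound_ids
        Unique compound identifiers, one per row.
    descriptor_names
        Unique descriptor (column) names.
    values
        Numeric matrix of shape ``(n_compounds, n_descriptors)``.
    activity
        pIC50 vector, length ``n_compounds``.
    split
        Per-compound label in ``{"train", "test", "unassigned"}``.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    activity: np.ndarray
    split: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("descriptor values must be a 2-D matrix")
        self.activity = np.asarray(self.activity, dtype=float).ravel()
        n, p = self.values.shape
        if len(self.compound_ids) != n:
            raise ValidationError(
                f"{len(self.compound_ids)} compound ids for {n} matrix rows"
            )
        if len(self.activity) != n:
            raise ValidationError(
                f"activity length {len(self.activity)} does not match {n} rows"
            )
        if len(self.descriptor_names) != p:
            raise ValidationError(
                f"{len(self.descriptor_names)} descriptor names for {p} columns"
            )
        dup = _duplicates(self.compound_ids)
        if dup:
            raise ValidationError(f"duplicated compound id(s): {sorted(dup)}")
        dup = _duplicates(self.descriptor_names)
        if dup:
            raise ValidationError(f"duplicated descriptor name(s): {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("descriptor matrix contains non-finite values")
        if not np.all(np.isfinite(self.activity)):
            raise ValidationError("activity vector contains non-finite values")
        if self.split is None:
            self.split = np.full(n, "unassigned", dtype=object)
        else:
            self.split = np.asarray(self.split, dtype=object).ravel()
            if len(self.split) != n:
                raise ValidationError("split label length does not match rows")
            bad = set(self.split) - set(SPLIT_LABELS)
            if bad:
                raise ValidationError(f"unknown split label(s): {sorted(bad)}")

    # -- basic shape -------------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def descriptor_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {d: j for j, d in enumerate(self.descriptor_names)}
        missing = [d for d in names if d not in lookup]
        if missing:
            raise ValidationError(f"unknown descriptor(s): {missing}")
        return np.asarray([lookup[d] for d in names], dtype=int)

    def matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Return the value matrix restricted to ``names`` (all by default)."""
        if names is None:
            return self.values
        return self.values[:, self.descriptor_index(names)]

    # -- derived views -----------------------------------------------------
    def select_descriptors(self, names: Sequence[str]) -> "DescriptorTable":
        idx = self.descriptor_index(names)
        return DescriptorTable(
            compound_ids=list(self.compound_ids),
            descriptor_names=[self.descriptor_names[j] for j in idx],
            values=self.values[:, idx].copy(),
            activity=self.activity.copy(),
            split=self.split.copy(),
        )

    def select_rows(self, mask: np.ndarray) -> "DescriptorTable":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            sel = np.zeros(self.n_compounds, dtype=bool)
            sel[mask] = True
            mask = sel
        return DescriptorTable(
            compound_ids=[c for c, m in zip(self.compound_ids, mask) if m],
            descriptor_names=list(self.descriptor_names),
            values=self.values[mask].copy(),
            activity=self.activity[mask].copy(),
            split=self.split[mask].copy(),
        )

    def training(self) -> "DescriptorTable":
        """Rows labelled ``train``; the whole table if nothing is labelled."""
        if not np.any(self.split != "unassigned"):
            return self
        return self.select_rows(self.split == "train")

    def testing(self) -> "DescriptorTable":
        return self.select_rows(self.split == "test")

    # -- I/O ---------------------------------------------------------------
    def to_frame(
        self, id_column: str = "id", activity_column: str = "pIC50"
    ) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, activity_column, self.activity)
        df.insert(0, id_column, self.compound_ids)
        if np.any(self.split != "unassigned"):
            df["split"] = self.split
        return df

    def write(
        self,
        path: str | Path,
        id_column: str = "id",
        activity_column: str = "pIC50",
        sep: str = ",",
    ) -> None:
        self.to_frame(id_column, activity_column).to_csv(path, sep=sep, index=False)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


# ---------------------------------------------------------------------------
# reading


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_table(
    path: str | Path,
    activity_column: str = "pIC50",
    id_column: str | None = None,
    sep: str | None = None,
    on_invalid: str = "reject",
) -> DescriptorTable:
    """Read a delimited descriptor table.

    The file must have a header row.  The first column is taken as the
    compound id unless ``id_column`` names another one; ``activity_column``
    holds the pIC50 values; an optional ``split`` column carries
    train/test labels; every remaining column is a numeric descriptor.

    ``on_invalid`` controls rows with missing or non-numeric descriptor or
    activity entries: ``"reject"`` (default) raises, ``"drop"`` removes the
    offending rows and logs which ones were lost.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if on_invalid not in ("reject", "drop"):
        raise ValidationError("on_invalid must be 'reject' or 'drop'")
    if sep is None:
        sep = _sniff_sep(path)

    with open(path, "r", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if not header:
        raise ValidationError(f"empty file: {path}")
    dup = _duplicates(header)
    if dup:
        raise ValidationError(f"duplicated column name(s) in header: {sorted(dup)}")

    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0:
        raise ValidationError(f"table has no data rows: {path}")
    if id_column is None:
        id_column = df.columns[0]
    for col in (id_column, activity_column):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")

    ids = df[id_column].astype(str).tolist()
    dup = _duplicates(ids)
    if dup:
        raise ValidationError(f"duplicated compound id(s): {sorted(dup)}")

    split = None
    desc_cols = [c for c in df.columns if c not in (id_column, activity_column, "split")]
    if "split" in df.columns:
        split = df["split"].astype(str).str.strip().str.lower().to_numpy(dtype=object)
    if not desc_cols:
        raise ValidationError("table contains no descriptor columns")

    numeric = df[[activity_column] + desc_cols].apply(pd.to_numeric, errors="coerce")
    bad_rows = ~np.isfinite(numeric.to_numpy(dtype=float)).all(axis=1)
    if bad_rows.any():
        offenders = [ids[i] for i in np.flatnonzero(bad_rows)]
        if on_invalid == "reject":
            raise ValidationError(
                f"non-numeric or missing entries in row(s): {offenders}"
            )
        logger.warning(
            "dropped %d row(s) with non-numeric or missing entries: %s",
            len(offenders),
            offenders,
        )
        keep = ~bad_rows
        ids = [c for c, k in zip(ids, keep) if k]
        numeric = numeric.loc[keep]
        if split is not None:
            split = split[keep]
        if numeric.shape[0] == 0:
            raise ValidationError("all rows dropped as invalid")

    return DescriptorTable(
        compound_ids=ids,
        descriptor_names=desc_cols,
        values=numeric[desc_cols].to_numpy(dtype=float),
        activity=numeric[activity_column].to_numpy(dtype=float),
        split=split,
    )


# ---------------------------------------------------------------------------
# pruning


@dataclass
class PruneRecord:
    """One removed descriptor and why it was removed."""

    name: str
    reason: str  # "constant" or "collinear"
    detail: str = ""

    def __str__(self) -> str:  # used for the plain-text removal log
        return f"{self.name}\t{self.reason}\t{self.detail}"


def prune_descriptors(
    table: DescriptorTable,
    var_eps: float = 1e-12,
    corr_threshold: float = 0.99,
) -> tuple[DescriptorTable, list[PruneRecord]]:
    """Remove constant and highly collinear descriptors.

    First every descriptor with sample variance ``<= var_eps`` is removed.
    Then descriptor pairs are scanned in column order; whenever a pair with
    ``|Pearson r| >= corr_threshold`` is found, the member with the larger
    mean absolute correlation to all other surviving descriptors is dropped
    (ties drop the later column) and the scan restarts.  The procedure is
    deterministic and idempotent.
    """
    if table.n_compounds < 2:
        raise ValidationError("pruning needs at least 2 compounds")
    if not 0 < corr_threshold <= 1:
        raise ValidationError("corr_threshold must be in (0, 1]")
    if var_eps < 0:
        raise ValidationError("var_eps must be nonnegative")

    log: list[PruneRecord] = []
    variances = table.values.var(axis=0, ddof=1)
    keep = [j for j in range(table.n_descriptors) if variances[j] > var_eps]
    for j in range(table.n_descriptors):
        if variances[j] <= var_eps:
            log.append(
                PruneRecord(
                    table.descriptor_names[j],
                    "constant",
                    f"variance={variances[j]:.3g}",
                )
            )
    if not keep:
        raise ValidationError("all descriptors removed as constant")

    while len(keep) > 1:
        X = table.values[:, keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-constant survivors
            corr = np.corrcoef(X, rowvar=False)
        corr = np.nan_to_num(np.abs(corr), nan=0.0)
        np.fill_diagonal(corr, 0.0)
        m = len(keep)
        offender: tuple[int, int] | None = None
        for i in range(m):
            hits = np.flatnonzero(corr[i, i + 1 :] >= corr_threshold)
            if hits.size:
                offender = (i, i + 1 + int(hits[0]))
                break
        if offender is None:
            break
        i, j = offender
        mean_i = corr[i].sum() / (m - 1)
        mean_j = corr[j].sum() / (m - 1)
        drop_local = j if mean_j >= mean_i else i  # tie -> later column
        other_local = i if drop_local == j else j
        name = table.descriptor_names[keep[drop_local]]
        partner = table.descriptor_names[keep[other_local]]
        log.append(
            PruneRecord(
                name,
                "collinear",
                f"|r|={corr[i, j]:.4f} with {partner}",
            )
        )
        del keep[drop_local]

    pruned = table.select_descriptors([table.descriptor_names[j] for j in keep])
    logger.info(
        "pruned %d of %d descriptors (%d constant, %d collinear)",
        len(log),
        table.n_descriptors,
        sum(r.reason == "constant" for r in log),
        sum(r.reason == "collinear" for r in log),
    )
    return pruned, log


def write_prune_log(log: Sequence[PruneRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("descriptor\treason\tdetail\n")
        for rec in log:
            fh.write(str(rec) + "\n")


# ---------------------------------------------------------------------------
# splitting


def split_train_test(
    table: DescriptorTable,
    test_fraction: float | None = None,
    test_ids: Sequence[str] | None = None,
    seed: int = 0,
) -> DescriptorTable:
    """Assign train/test labels, randomly or from an explicit id list.

    With ``test_fraction`` the number of test compounds is
    ``round(test_fraction * n)`` and membership is drawn with a seeded RNG,
    so the same seed reproduces the same split.  An explicit ``test_ids``
    list overrides randomness entirely.
    """
    n = table.n_compounds
    labels = np.full(n, "train", dtype=object)
    if test_ids is not None:
        unknown = set(map(str, test_ids)) - set(table.compound_ids)
        if unknown:
            raise ValidationError(f"unknown compound id(s) in test list: {sorted(unknown)}")
        test_set = set(map(str, test_ids))
        for i, cid in enumerate(table.compound_ids):
            if cid in test_set:
                labels[i] = "test"
        if np.all(labels == "test"):
            warnings.warn("every compound assigned to the test set", stacklevel=2)
    else:
        if test_fraction is None or not 0 < test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")
        n_test = int(round(test_fraction * n))
        n_test = min(max(n_test, 1), n - 1)
        rng = np.random.default_rng(seed)
        test_idx = rng.choice(n, size=n_test, replace=False)
        labels[test_idx] = "test"
    return replace(table, split=labels)
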