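"""End-to-end QSAR run: prune → split → BMLR → grid-searched PPR → scoring.

``run_pipeline`` executes the whole modelling workflow from a single
:class:`RunConfig` and writes every intermediate artifact (pruned table,
descriptor-selection report, grid surface, serialised models, per-compound
predictions) plus a ``summary.json`` holding train/test R² and RMSE for
both the linear (BMLR) and nonlinear (GS-PPR) models.  Runs are fully
reproducible: all randomness flows from the seeds recorded in the config.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .bmlr import bmlr_search
from .dataset import read_table, prune_descriptors, split_train_test, write_prune_log
from .errors import ConfigError, GspprError, PipelineError
from .evaluation import GridSpec, grid_search, pca_diagnostic, r2, rmse
from .ppr import fit_ppr

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML/JSON."""

    input_table: str
    output_dir: str
    activity_column: str = "pIC50"
    id_column: str | None = None
    on_invalid: str = "reject"
    # pruning
    var_eps: float = 1e-12
    corr_threshold: float = 0.99
    # split
    test_fraction: float = 25 / 128
    split_seed: int = 0
    use_existing_split: bool = False
    # BMLR
    bmlr_max_size: int = 9
    bmlr_breakpoint: float = 0.02
    bmlr_pair_corr_max: float = 0.8
    bmlr_beam_width: int = 400
    # grid search
    grid_nterms: Sequence[int] = (1, 2, 3)
    grid_max_terms: Sequence[int] = (3, 5, 7)
    grid_df: Sequence[float] = (4.0, 8.0)
    grid_optlevel: Sequence[int] = (1,)
    cv_k: int = 5
    cv_seed: int = 0
    # PPR engine
    ppr_seed: int = 0
    ppr_tol: float = 1e-4
    ppr_max_iter: int = 50
    ppr_restarts: int = 4
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.input_table:
            raise ConfigError("input_table is required")
        if not self.output_dir:
            raise ConfigError("output_dir is required")
        if not self.activity_column:
            raise ConfigError("activity_column is required")
        if self.on_invalid not in ("reject", "drop"):
            raise ConfigError("on_invalid must be 'reject' or 'drop'")
        if not self.use_existing_split and not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.bmlr_max_size < 1:
            raise ConfigError("bmlr_max_size must be >= 1")
        if self.cv_k < 2:
            raise ConfigError("cv_k must be >= 2")

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            nterms=list(self.grid_nterms),
            max_terms=list(self.grid_max_terms),
            df=list(self.grid_df),
            optlevel=list(self.grid_optlevel),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("grid_nterms", "grid_max_terms", "grid_df", "grid_optlevel"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        text = path.read_text(encoding="utf-8")
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )


def _score(y_exp: np.ndarray, y_pred: np.ndarray) -> dict:
    return {"r2": r2(y_exp, y_pred), "rmse": rmse(y_exp, y_pred)}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the summary dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("gsppr")
    root.addHandler(handler)
    prev_level = root.level
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s: start", name)
        try:
            result = fn(*args, **kwargs)
        except GspprError as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        logger.info("stage %s: done", name)
        return result

    try:
        logger.info(
            "gsppr %s on python %s / numpy %s",
            __version__, platform.python_version(), np.__version__,
        )
        config.write(out / "config.yaml")

        table = stage(
            "read", read_table, config.input_table,
            activity_column=config.activity_column,
            id_column=config.id_column,
            on_invalid=config.on_invalid,
        )

        pruned, prune_log = stage(
            "prune", prune_descriptors, table,
            var_eps=config.var_eps, corr_threshold=config.corr_threshold,
        )
        write_prune_log(prune_log, out / "prune_log.txt")

        if config.use_existing_split and np.any(pruned.split != "unassigned"):
            split_table = pruned
        else:
            split_table = stage(
                "split", split_train_test, pruned,
                test_fraction=config.test_fraction, seed=config.split_seed,
            )
        split_table.write(out / "pruned_table.csv", activity_column=config.activity_column)
        train = split_table.training()
        test = split_table.testing()

        bmlr_result = stage(
            "bmlr", bmlr_search, split_table,
            max_size=config.bmlr_max_size,
            breakpoint=config.bmlr_breakpoint,
            pair_corr_max=config.bmlr_pair_corr_max,
            beam_width=config.bmlr_beam_width,
        )
        bmlr_result.write_report(out / "bmlr_report.tsv")
        bmlr_model = bmlr_result.selected
        selected = list(bmlr_model.descriptor_names)
        (out / "bmlr_model.json").write_text(
            json.dumps(bmlr_model.to_dict(), indent=1), encoding="utf-8"
        )

        pca = stage("pca", pca_diagnostic, split_table, selected)
        pca.scores.to_csv(out / "pca_scores.csv", index=False)

        subset_table = split_table.select_descriptors(selected)
        ppr_options = {
            "seed": config.ppr_seed,
            "tol": config.ppr_tol,
            "max_iter": config.ppr_max_iter,
            "n_restarts": config.ppr_restarts,
        }
        grid = stage(
            "grid_search", grid_search, subset_table, config.grid_spec(),
            k=config.cv_k, seed=config.cv_seed, ppr_options=ppr_options,
        )
        grid.write_surface(out / "grid_surface.tsv")
        best = grid.best_cell
        best_rec = next(
            rec for rec in grid.records
            if all(rec[k] == v for k, v in best.to_dict().items())
        )

        ppr_model = stage(
            "final_ppr", fit_ppr, subset_table,
            nterms=best.nterms, max_terms=best.max_terms,
            df=best.df, optlevel=best.optlevel, **ppr_options,
        )
        ppr_model.save(out / "ppr_model.json")

        preds = split_table.to_frame(activity_column=config.activity_column)[
            ["id", config.activity_column]
        ].rename(columns={"id": "compound_id", config.activity_column: "y_exp"})
        preds["split"] = split_table.split
        preds["y_pred_bmlr"] = bmlr_model.predict(split_table)
        preds["y_pred_gsppr"] = ppr_model.predict(split_table)
        preds = preds[["compound_id", "split", "y_exp", "y_pred_bmlr", "y_pred_gsppr"]]
        preds.to_csv(out / "predictions.csv", index=False)

        summary = {
            "n_compounds": split_table.n_compounds,
            "n_train": train.n_compounds,
            "n_test": test.n_compounds,
            "n_descriptors_input": table.n_descriptors,
            "n_descriptors_pruned": split_table.n_descriptors,
            "selected_descriptors": selected,
            "bmlr": {
                "selected_size": bmlr_result.selected_size,
                "breakpoint_fired": bmlr_result.breakpoint_fired,
                "train": _score(train.activity, bmlr_model.predict(train)),
                "test": _score(test.activity, bmlr_model.predict(test)),
            },
            "gsppr": {
                "best_cell": best.to_dict(),
                "cv": {"r2": best_rec["cv_r2"], "rmse": best_rec["cv_rmse"]},
                "train": _score(train.activity, ppr_model.predict(train)),
                "test": _score(test.activity, ppr_model.predict(test)),
            },
            "pca": {
                "pc1_explained_pct": float(pca.explained_pct[0]),
                "pc1_pc2_explained_pct": float(pca.explained_pct[:2].sum()),
            },
            "seeds": {
                "split": config.split_seed,
                "cv": config.cv_seed,
                "ppr": config.ppr_seed,
            },
            "artifacts": sorted(
                p.name for p in out.iterdir() if p.name not in ("run.log", "summary.json")
            ),
        }
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8"
        )
        logger.info("pipeline complete: %s", out / "summary.json")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(prev_level)
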