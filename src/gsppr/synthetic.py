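"""Synthetic descriptor tables with planted, known structure.

Real QSAR tables in this problem class look like ~10²–10³ numeric
descriptors over ~10² compounds (here the template is 128 quinazoline
EGFR inhibitors, split 103 train / 25 test), of which only a handful carry
signal, many are mutually collinear, and the activity is pIC50 on a scale
of roughly 4–10.  The generator emulates exactly that shape so that every
pipeline stage can be tested against ground truth: a few *informative*
standard-normal descriptors, optional near-duplicate *collinear* copies of
each, a large block of pure-noise descriptors, and an activity built from
either a linear form or a sum of nonlinear ridge functions of the
informative block, plus Gaussian noise.

What it deliberately does not emulate: real chemistry (scaffold effects,
activity cliffs, heterogeneous descriptor marginals).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .dataset import DescriptorTable
from .errors import ValidationError

RIDGE_SHAPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "square": lambda t: t**2,
    "sine": lambda t: np.sin(1.5 * t),
    "sigmoid": lambda t: np.tanh(1.5 * t),
}


@dataclass
class PlantedRidge:
    """One planted ridge: unit direction over the informative block."""

    direction: np.ndarray
    shape: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float).ravel()
        norm = np.linalg.norm(self.direction)
        if norm <= 0:
            raise ValidationError("ridge direction must be nonzero")
        self.direction = self.direction / norm
        if self.shape not in RIDGE_SHAPES:
            raise ValidationError(f"unknown ridge shape {self.shape!r}; choose from {sorted(RIDGE_SHAPES)}")

    def evaluate(self, X_inf: np.ndarray) -> np.ndarray:
        return self.weight * RIDGE_SHAPES[self.shape](X_inf @ self.direction)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic descriptor table.

    Defaults mirror the template study's shape: 128 compounds with a small
    informative core, collinear shadows, plenty of noise columns, and
    activity on the pIC50 scale (offset 7).
    """

    n_compounds: int = 128
    n_informative: int = 3
    n_noise: int = 100
    n_collinear_per_informative: int = 1
    form: str = "linear"  # "linear" | "ridge"
    coefficients: Sequence[float] | None = None  # linear form; default 1.5, 1.0, 0.5, ...
    ridges: Sequence[PlantedRidge] | None = None  # ridge form
    noise_sd: float = 0.3
    copy_noise_sd: float = 0.1
    activity_offset: float = 7.0
    heavy_tail: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= self.n_informative + 2:
            raise ValidationError("need n_compounds > n_informative + 2")
        if self.n_informative < 1:
            raise ValidationError("need at least one informative descriptor")
        if self.form not in ("linear", "ridge"):
            raise ValidationError("form must be 'linear' or 'ridge'")
        if self.noise_sd < 0 or self.copy_noise_sd < 0:
            raise ValidationError("noise standard deviations must be nonnegative")
        if self.form == "linear":
            if self.coefficients is None:
                self.coefficients = [
                    1.5 - 0.5 * (k % 3) for k in range(self.n_informative)
                ]
            if len(self.coefficients) != self.n_informative:
                raise ValidationError("one coefficient per informative descriptor")
        else:
            if self.ridges is None:
                # two default ridges: a monotone sigmoid and a pure even bump
                d1 = np.zeros(self.n_informative)
                d1[0] = 1.0
                d2 = np.zeros(self.n_informative)
                d2[min(1, self.n_informative - 1)] = 1.0
                self.ridges = [
                    PlantedRidge(d1, "sigmoid", 1.0),
                    PlantedRidge(d2, "square", 0.6),
                ]
            for rid in self.ridges:
                if len(rid.direction) != self.n_informative:
                    raise ValidationError(
                        "ridge directions must span the informative block"
                    )


@dataclass
class GroundTruth:
    """Everything needed to verify recovery on a generated table."""

    informative_names: list[str]
    collinear_map: dict[str, str]  # copy name -> informative source name
    noise_names: list[str]
    noiseless_activity: np.ndarray
    form: str
    coefficients: list[float] | None
    ridges: list[dict] | None
    noise_sd: float

    def to_dict(self) -> dict:
        return {
            "informative_names": self.informative_names,
            "collinear_map": self.collinear_map,
            "noise_names": self.noise_names,
            "noiseless_activity": [float(v) for v in self.noiseless_activity],
            "form": self.form,
            "coefficients": self.coefficients,
            "ridges": self.ridges,
            "noise_sd": float(self.noise_sd),
        }


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Draw one table from ``spec``; same seed, same table."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds

    def draw(size):
        if spec.heavy_tail:
            return rng.standard_t(df=4, size=size)
        return rng.standard_normal(size)

    X_inf = draw((n, spec.n_informative))
    inf_names = [f"X{k + 1:03d}" for k in range(spec.n_informative)]

    copies, copy_names, collinear_map = [], [], {}
    for k, src in enumerate(inf_names):
        for c in range(spec.n_collinear_per_informative):
            col = X_inf[:, k] + spec.copy_noise_sd * rng.standard_normal(n)
            name = f"{src}_cp{c + 1}"
            copies.append(col)
            copy_names.append(name)
            collinear_map[name] = src
    noise = draw((n, spec.n_noise))
    noise_names = [f"N{k + 1:03d}" for k in range(spec.n_noise)]

    blocks = [X_inf]
    names = list(inf_names)
    if copies:
        blocks.append(np.column_stack(copies))
        names += copy_names
    if spec.n_noise:
        blocks.append(noise)
        names += noise_names
    values = np.column_stack(blocks)

    if spec.form == "linear":
        signal = X_inf @ np.asarray(spec.coefficients, dtype=float)
        ridges_rec = None
    else:
        signal = np.zeros(n)
        for rid in spec.ridges:
            signal = signal + rid.evaluate(X_inf)
        ridges_rec = [
            {
                "direction": [float(v) for v in rid.direction],
                "shape": rid.shape,
                "weight": float(rid.weight),
            }
            for rid in spec.ridges
        ]
    noiseless = spec.activity_offset + signal
    activity = noiseless + spec.noise_sd * rng.standard_normal(n)

    table = DescriptorTable(
        compound_ids=[f"cmpd{str(i + 1).zfill(len(str(n)))}" for i in range(n)],
        descriptor_names=names,
        values=values,
        activity=activity,
    )
    truth = GroundTruth(
        informative_names=inf_names,
        collinear_map=collinear_map,
        noise_names=noise_names,
        noiseless_activity=noiseless,
        form=spec.form,
        coefficients=(
            [float(c) for c in spec.coefficients] if spec.form == "linear" else None
        ),
        ridges=ridges_rec,
        noise_sd=spec.noise_sd,
    )
    return table, truth


def write_fixture(
    table: DescriptorTable, truth: GroundTruth, directory: str | Path
) -> tuple[Path, Path]:
    """Write ``table.csv`` and its ``truth.json`` sidecar; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table_path = directory / "table.csv"
    truth_path = directory / "truth.json"
    table.write(table_path)
    truth_path.write_text(json.dumps(truth.to_dict(), indent=1), encoding="utf-8")
    return table_path, truth_path
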