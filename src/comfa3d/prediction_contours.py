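"""External-set prediction, validation statistics, contour thresholds and
grid/report export.

Residuals follow one normative sign convention throughout: residual =
observed - predicted. (The source tables this pipeline is compared against
flip the sign for the external set; any comparison harness applies the
appropriate sign per table.)

Contour thresholds are nearest-rank percentiles of the per-field
coefficient-times-standard-deviation map evaluated on the raw energy
scale; lattice points whose value exceeds the favored threshold form the
favored (green/blue) set, points below the disfavored threshold the
disfavored (yellow/red) set.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .field_engine import ELECTROSTATIC, STERIC, FieldTable, GridSpec
from .qsar_pls import PLSError, PLSModel

__all__ = [
    "PredictionRecord",
    "ContourSpec",
    "ContourError",
    "predict",
    "external_validation_stats",
    "point_values",
    "contour_thresholds",
    "export_grid",
    "read_grid",
    "write_report",
]

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


class ContourError(ValueError):
    pass


@dataclass(frozen=True)
class PredictionRecord:
    id: str
    observed: float | None
    predicted: float

    @property
    def residual(self) -> float | None:
        return None if self.observed is None else self.observed - self.predicted


@dataclass(frozen=True)
class ContourSpec:
    """Favored/disfavored threshold levels for one field's coef*sd map."""

    field: str
    favored_level: float
    disfavored_level: float
    favored_threshold: float
    disfavored_threshold: float
    favored_points: tuple[int, ...]
    disfavored_points: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 < self.disfavored_level < self.favored_level < 100:
            raise ContourError(
                "levels must satisfy 0 < disfavored < favored < 100, got "
                f"({self.favored_level}, {self.disfavored_level})"
            )


def predict(
    model: PLSModel,
    rows: np.ndarray,
    ids: list[str],
    observed: np.ndarray | None = None,
) -> list[PredictionRecord]:
    """Predict activities for rows sharing the model's column layout."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] != len(ids):
        raise PLSError("row count does not match id count")
    yhat = model.predict(rows)
    out = []
    for i, cid in enumerate(ids):
        obs = None if observed is None else float(observed[i])
        out.append(PredictionRecord(id=cid, observed=obs, predicted=float(yhat[i])))
    return out


def external_validation_stats(
    predictions: list[PredictionRecord], n_components: int
) -> tuple[float, float]:
    """Squared Pearson correlation and SEE of observed vs predicted."""
    pairs = [(p.observed, p.predicted) for p in predictions if p.observed is not None]
    if len(pairs) < 3:
        raise ContourError("need at least 3 records with observed values")
    obs = np.array([p[0] for p in pairs])
    pred = np.array([p[1] for p in pairs])
    if np.var(obs) == 0:
        raise ContourError("zero variance in observed values")
    if np.var(pred) == 0:
        raise ContourError("undefined correlation: constant predictions")
    r = np.corrcoef(obs, pred)[0, 1]
    n = len(pairs)
    rss = float(np.sum((obs - pred) ** 2))
    dof = n - n_components - 1
    if dof <= 0:
        raise ContourError("not enough records for the SEE degrees of freedom")
    return float(r * r), float(np.sqrt(rss / dof))


def _nearest_rank(values: np.ndarray, level: float) -> float:
    """Nearest-rank percentile: the ceil(level/100 * n)-th smallest value."""
    ordered = np.sort(values)
    rank = max(1, math.ceil(level / 100.0 * len(ordered)))
    return float(ordered[rank - 1])


def point_values(model: PLSModel, table: FieldTable) -> dict[str, np.ndarray]:
    """Per-lattice-point coef*sd values for each field (masked points -> 0)."""
    labels = table.field_labels[table.mask]
    if model.coefficients.shape[0] != labels.shape[0]:
        raise PLSError("model was not fitted on this table's unmasked columns")
    sd = (
        table.masked_scaled().std(axis=0, ddof=1)
        if table.scaled is not None
        else table.masked_data().std(axis=0, ddof=1)
    )
    value = model.coefficients * sd
    full = np.zeros(table.data.shape[1])
    full[table.mask] = value
    p = table.n_points
    return {STERIC: full[:p], ELECTROSTATIC: full[p:]}


def contour_thresholds(
    model: PLSModel,
    table: FieldTable,
    levels: tuple[float, float] = (80.0, 20.0),
) -> dict[str, ContourSpec]:
    """Favored/disfavored thresholds of the coef*sd map, per field."""
    favored_level, disfavored_level = levels
    if not favored_level > disfavored_level:
        raise ContourError(
            f"favored level must exceed disfavored level, got {levels}"
        )
    values = point_values(model, table)
    mask = table.mask
    p = table.n_points
    out: dict[str, ContourSpec] = {}
    for name, block_mask in ((STERIC, mask[:p]), (ELECTROSTATIC, mask[p:])):
        v = values[name][block_mask]
        if v.size == 0:
            continue
        if np.ptp(v) == 0:
            raise ContourError(f"degenerate {name} value distribution (all identical)")
        fav = _nearest_rank(v, favored_level)
        dis = _nearest_rank(v, disfavored_level)
        idx = np.flatnonzero(block_mask)
        full = values[name]
        out[name] = ContourSpec(
            field=name,
            favored_level=favored_level,
            disfavored_level=disfavored_level,
            favored_threshold=fav,
            disfavored_threshold=dis,
            favored_points=tuple(int(i) for i in idx if full[i] >= fav),
            disfavored_points=tuple(int(i) for i in idx if full[i] <= dis),
        )
    return out


def export_grid(values: np.ndarray, grid: GridSpec, fmt: str, path) -> Path:
    """Write one scalar value per lattice point as Gaussian cube or OpenDX."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size != grid.n_points:
        raise ContourError(
            f"value count {values.size} does not match grid point count {grid.n_points}"
        )
    path = Path(path)
    nx, ny, nz = grid.counts
    if fmt == "cube":
        lines = ["scalar field", "lattice values, z fastest"]
        ox, oy, oz = (v * BOHR_PER_ANGSTROM for v in grid.origin)
        step = grid.spacing * BOHR_PER_ANGSTROM
        lines.append(f"{1:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}")
        lines.append(f"{nx:5d}{step:12.6f}{0.0:12.6f}{0.0:12.6f}")
        lines.append(f"{ny:5d}{0.0:12.6f}{step:12.6f}{0.0:12.6f}")
        lines.append(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{step:12.6f}")
        lines.append(f"{1:5d}{0.0:12.6f}{ox:12.6f}{oy:12.6f}{oz:12.6f}")
        for start in range(0, values.size, 6):
            lines.append("".join(f"{v:13.5E}" for v in values[start : start + 6]))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "dx":
        lines = [
            f"object 1 class gridpositions counts {nx} {ny} {nz}",
            "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
            f"delta {grid.spacing:.6f} 0.000000 0.000000",
            f"delta 0.000000 {grid.spacing:.6f} 0.000000",
            f"delta 0.000000 0.000000 {grid.spacing:.6f}",
            f"object 2 class gridconnections counts {nx} {ny} {nz}",
            f"object 3 class array type double rank 0 items {values.size} data follows",
        ]
        for start in range(0, values.size, 3):
            lines.append(" ".join(f"{v:.5E}" for v in values[start : start + 3]))
        lines.append('attribute "dep" string "positions"')
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ContourError(f"unknown grid format {fmt!r}")
    return path


def read_grid(path) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Read values back from a file written by :func:`export_grid`."""
    text = Path(path).read_text().splitlines()
    if text[0].startswith("object 1"):
        counts = tuple(int(v) for v in text[0].split()[-3:])
        n = counts[0] * counts[1] * counts[2]
        raw: list[float] = []
        for line in text[7:]:
            if line.startswith("attribute"):
                break
            raw.extend(float(v) for v in line.split())
        return np.array(raw[:n]), counts
    natoms = int(text[2].split()[0])
    counts = tuple(int(text[3 + a].split()[0]) for a in range(3))
    n = counts[0] * counts[1] * counts[2]
    raw = []
    for line in text[6 + natoms :]:
        raw.extend(float(v) for v in line.split())
    return np.array(raw[:n]), counts


def write_report(
    model_summary: dict | None,
    training_predictions: list[PredictionRecord] | None,
    test_predictions: list[PredictionRecord] | None,
    contours: dict[str, ContourSpec] | None,
    outdir,
    point_value_grids: dict[str, np.ndarray] | None = None,
    grid: GridSpec | None = None,
) -> dict[str, Path]:
    """Write the JSON + CSV report bundle; every stage must be present."""
    missing = [
        name
        for name, stage in (
            ("model", model_summary),
            ("training_predictions", training_predictions),
            ("test_predictions", test_predictions),
            ("contours", contours),
        )
        if stage is None
    ]
    if missing:
        raise ContourError(f"incomplete pipeline, missing stages: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def frame(records: list[PredictionRecord]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in records],
                "observed": [r.observed for r in records],
                "predicted": [r.predicted for r in records],
                "residual": [r.residual for r in records],
            }
        )

    paths["training_predictions"] = outdir / "training_predictions.csv"
    frame(training_predictions).to_csv(paths["training_predictions"], index=False)
    paths["test_predictions"] = outdir / "test_predictions.csv"
    frame(test_predictions).to_csv(paths["test_predictions"], index=False)

    report = dict(model_summary)
    report["contours"] = {name: asdict(spec) for name, spec in contours.items()}
    paths["report"] = outdir / "report.json"
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    if point_value_grids is not None and grid is not None:
        for name, values in point_value_grids.items():
            paths[f"contours_{name}"] = export_grid(
                values, grid, "cube", outdir / f"contours_{name}.cube"
            )
    return paths
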