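"""Sample tables, GSLIB/GeoEAS grid files and run configuration.

Samples are delimited text with header ``x,y,butts_per_m2,sharp_per_m2``.
Grids use the GeoEAS convention: a title line, the number of variables, one
variable name per line, then whitespace-separated values in x-fastest scan
order.  Grid geometry is embedded in the title line so files round-trip
without a side channel.  Values are written with 17 significant digits, so a
write/read cycle is bit-identical for float64 data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cosimulation import DEFAULT_VAR_COLS
from .exceptions import SampleFileError
from .grids import GridSpec

__all__ = [
    "read_samples",
    "write_samples",
    "write_grid",
    "read_grid",
    "GridData",
    "RunConfig",
]


def read_samples(
    path, grid: GridSpec | None = None, var_cols=DEFAULT_VAR_COLS
) -> pd.DataFrame:
    """Read and validate a sample table.

    Rejects missing columns, non-numeric entries, negative densities and
    (when ``grid`` is given) out-of-grid coordinates, naming the offending
    data rows (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SampleFileError(f"{path}: file is empty") from None
    if df.empty:
        raise SampleFileError(f"{path}: no data rows")
    required = ["x", "y", *var_cols]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SampleFileError(f"{path}: missing columns {missing}")
    df = df[required]
    bad_rows: list[int] = []
    msgs: list[str] = []
    numeric = df.apply(pd.to_numeric, errors="coerce")
    non_num = numeric.isna().any(axis=1)
    if non_num.any():
        rows = list(np.flatnonzero(non_num) + 1)
        bad_rows += rows
        msgs.append(f"non-numeric values in rows {rows}")
    neg = (numeric[list(var_cols)] < 0).any(axis=1) & ~non_num
    if neg.any():
        rows = list(np.flatnonzero(neg) + 1)
        bad_rows += rows
        msgs.append(f"negative densities in rows {rows}")
    if grid is not None:
        xy = numeric[["x", "y"]].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            outside = ~grid.contains(np.nan_to_num(xy, nan=-1e30)) & ~non_num
        if outside.any():
            rows = list(np.flatnonzero(outside) + 1)
            bad_rows += rows
            msgs.append(f"coordinates outside the grid in rows {rows}")
    if bad_rows:
        raise SampleFileError(f"{path}: " + "; ".join(msgs), rows=sorted(set(bad_rows)))
    return numeric.astype(float)


def write_samples(samples: pd.DataFrame, path) -> Path:
    path = Path(path)
    samples.to_csv(path, index=False, float_format="%.17g")
    return path


@dataclass(frozen=True)
class GridData:
    values: np.ndarray  # (n_nodes, n_vars)
    names: tuple[str, ...]
    title: str
    grid: GridSpec | None


def _grid_title(title: str, grid: GridSpec) -> str:
    return (
        f"{title} | grid nx={grid.nx} ny={grid.ny} cell={grid.cell:g} "
        f"origin=({grid.origin[0]:g},{grid.origin[1]:g})"
    )


def _parse_grid_title(title: str) -> GridSpec | None:
    import re

    m = re.search(
        r"grid nx=(\d+) ny=(\d+) cell=([0-9.eE+-]+) "
        r"origin=\(([0-9.eE+-]+),([0-9.eE+-]+)\)",
        title,
    )
    if not m:
        return None
    return GridSpec(
        nx=int(m.group(1)),
        ny=int(m.group(2)),
        cell=float(m.group(3)),
        origin=(float(m.group(4)), float(m.group(5))),
    )


def write_grid(values, path, grid: GridSpec, names=None, title="littersim grid") -> Path:
    """Write node values (one or more variables) as a GeoEAS/GSLIB grid file."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] != grid.n_nodes:
        raise ValueError(
            f"surface has {values.shape[0]} values but the grid has "
            f"{grid.n_nodes} nodes"
        )
    if names is None:
        names = [f"var{i}" for i in range(values.shape[1])]
    if len(names) != values.shape[1]:
        raise ValueError("one name per variable column required")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_grid_title(title, grid) + "\n")
        fh.write(f"{values.shape[1]}\n")
        for name in names:
            fh.write(f"{name}\n")
        np.savetxt(fh, values, fmt="%.17g")
    return path


def read_grid(path) -> GridData:
    """Read a GeoEAS/GSLIB grid file written by :func:`write_grid`."""
    path = Path(path)
    with path.open() as fh:
        title = fh.readline().rstrip("\n")
        nvar = int(fh.readline())
        names = tuple(fh.readline().strip() for _ in range(nvar))
        values = np.loadtxt(fh, ndmin=2)
    if values.shape[1] != nvar:
        raise ValueError(f"{path}: expected {nvar} columns, found {values.shape[1]}")
    grid = _parse_grid_title(title)
    if grid is not None and values.shape[0] != grid.n_nodes:
        raise ValueError(
            f"{path}: {values.shape[0]} rows but title declares "
            f"{grid.n_nodes} nodes"
        )
    return GridData(values=values, names=names, title=title, grid=grid)


@dataclass
class RunConfig:
    """Configuration of the end-to-end pipeline.

    Defaults reproduce the study conditions: the 50 m x 150 m strip at 1 m
    resolution, marginals and correlation calibrated to the published survey
    statistics, the published coregionalization model, a 530-point survey
    and 100 conditional realizations, K = 20 indices and a 3 items/m^2
    injury threshold.
    """

    # grid
    nx: int = 50
    ny: int = 150
    cell: float = 1.0
    # synthetic calibration
    means: tuple[float, float] = (3.57, 2.39)
    sds: tuple[float, float] = (4.0, 2.4)
    raw_correlation: float = 0.87
    correlation_mode: str = "match_raw"  # or "model"
    trend: float = 0.0
    n_samples: int = 530
    survey_mode: str = "uniform"
    # spatial model for conditioning: published reference model or refit
    model_source: str = "reference"  # or "fit"
    # simulation
    n_real: int = 100
    n_lines: int = 1000
    seed: int = 0
    # risk
    K: float = 20.0
    sharp_threshold: float = 3.0
    hii_variant: str = "hazard_over_log_total"
    # validation
    n_train: int = 200
    validate: bool = True
    # outputs
    outdir: str = "littersim_output"
    write_stack: bool = False
    make_plots: bool = False

    def __post_init__(self):
        self.means = tuple(float(v) for v in self.means)
        self.sds = tuple(float(v) for v in self.sds)
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(nx=self.nx, ny=self.ny, cell=self.cell)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["means"] = list(self.means)
        d["sds"] = list(self.sds)
        return d

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
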