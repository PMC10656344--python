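"""Dataset and configuration serialization.

Datasets travel as CSV with columns ``x,z,y,sx,sy``; missing ``x``/``y``
cells are written as empty strings (the reader additionally accepts "NA"
and "NaN").  A three-column ``x,z,y`` file is accepted on input, with the
selection indicators inferred from cell emptiness.  Round-trips are
lossless: values, masks and indicators survive write-then-read exactly.

Parameters, missingness specifications and study configurations are flat
JSON objects.  Every CLI invocation attaches a run record (command, config
hash, seed, library versions, timestamp, warnings) to its JSON output.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SemParams
from .simulate import IncompleteDataset, MissingnessSpec

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_params",
    "write_params",
    "read_spec",
    "DatasetValidationError",
    "run_record",
]

_NA_STRINGS = ("", "NA", "NaN", "nan")


class DatasetValidationError(ValueError):
    """Raised when a dataset file is inconsistent with its indicators."""


def write_dataset(ds: IncompleteDataset, path) -> None:
    """Write a dataset as CSV (header ``x,z,y,sx,sy``; missing cells empty)."""
    x = np.ma.getdata(ds.xstar).astype(object)
    y = np.ma.getdata(ds.ystar).astype(object)
    x[ds.sx == 0] = None
    y[ds.sy == 0] = None
    df = pd.DataFrame({"x": x, "z": ds.z, "y": y, "sx": ds.sx, "sy": ds.sy})
    df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> IncompleteDataset:
    """Read a dataset CSV, enforcing the mask/indicator invariants.

    Accepts either ``x,z,y,sx,sy`` or ``x,z,y`` (indicators inferred from
    emptiness).  Rows where an indicator says observed but the cell is
    empty — or vice versa — raise :class:`DatasetValidationError` listing
    the offending rows.
    """
    df = pd.read_csv(
        path, na_values=list(_NA_STRINGS), keep_default_na=False, skip_blank_lines=True
    )
    cols = list(df.columns)
    if cols[:3] != ["x", "z", "y"]:
        raise DatasetValidationError(
            f"expected header starting x,z,y (got {cols}); header row is mandatory"
        )
    x = df["x"].to_numpy(dtype=float)
    z = df["z"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    if np.isnan(z).any():
        bad = np.flatnonzero(np.isnan(z)).tolist()
        raise DatasetValidationError(f"z must be fully observed; missing at rows {bad}")
    if "sx" in cols and "sy" in cols:
        sx = df["sx"].to_numpy(dtype=int)
        sy = df["sy"].to_numpy(dtype=int)
        bad_rows = sorted(
            set(np.flatnonzero((sx == 1) & np.isnan(x)).tolist())
            | set(np.flatnonzero((sy == 1) & np.isnan(y)).tolist())
            | set(np.flatnonzero((sx == 0) & ~np.isnan(x)).tolist())
            | set(np.flatnonzero((sy == 0) & ~np.isnan(y)).tolist())
        )
        if bad_rows:
            raise DatasetValidationError(
                f"indicator/value mismatch at rows {bad_rows[:20]}"
                + (" ..." if len(bad_rows) > 20 else "")
            )
    else:
        sx = (~np.isnan(x)).astype(int)
        sy = (~np.isnan(y)).astype(int)
    x = np.where(np.isnan(x), 0.0, x)
    y = np.where(np.isnan(y), 0.0, y)
    return IncompleteDataset(
        z=z,
        xstar=np.ma.masked_array(x, mask=sx == 0),
        ystar=np.ma.masked_array(y, mask=sy == 0),
        sx=sx,
        sy=sy,
    )


def read_params(path) -> SemParams:
    return SemParams.from_json(Path(path).read_text())


def write_params(params: SemParams, path) -> None:
    Path(path).write_text(params.to_json())


def read_spec(path) -> MissingnessSpec:
    return MissingnessSpec.from_dict(json.loads(Path(path).read_text()))


def run_record(command: str, config: dict, seed, warnings: list | None = None) -> dict:
    """Provenance record attached to every CLI JSON output."""
    import click
    import scipy
    import statsmodels

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "command": command,
        "configHash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "click": click.__version__,
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "warnings": warnings or [],
    }
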