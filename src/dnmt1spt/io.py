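"""Reading and writing the pipeline's table and image formats.

Trajectory tables are CSV with required columns (trajectory_id, frame,
x_um, y_um, cell_id); coordinates are µm, frames are 0-based integers,
strictly increasing within a trajectory. Extra columns (e.g. the
simulator's true_state) round-trip untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

REQUIRED_COLUMNS = ["trajectory_id", "frame", "x_um", "y_um", "cell_id"]

__all__ = ["REQUIRED_COLUMNS", "validate_trajectory_table",
           "read_trajectory_table", "write_trajectory_table",
           "read_movie", "write_movie", "write_json", "read_json"]


def validate_trajectory_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        return df
    if not np.issubdtype(np.asarray(df["frame"]).dtype, np.integer):
        frames = df["frame"].to_numpy()
        if not np.allclose(frames, np.round(frames)):
            raise ValueError("frame column must be integer-valued")
        df = df.assign(frame=frames.astype(int))
    bad_rows = []
    for tid, g in df.groupby(["cell_id", "trajectory_id"]):
        fr = g["frame"].to_numpy()
        nonmono = np.flatnonzero(np.diff(fr) <= 0)
        if len(nonmono):
            bad_rows.extend(g.index[nonmono + 1].tolist())
    if bad_rows:
        raise ValueError(
            "frames must be strictly increasing within a trajectory; "
            f"offending row index(es): {bad_rows[:10]}"
            + (" ..." if len(bad_rows) > 10 else ""))
    return df


def read_trajectory_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_trajectory_table(df)


def write_trajectory_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_trajectory_table(df)
    df.to_csv(path, index=False)


def read_movie(path: str | Path) -> np.ndarray:
    movie = tifffile.imread(path)
    if movie.ndim == 2:
        movie = movie[None]
    return movie


def write_movie(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, np.uint16))


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
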