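"""End-to-end driver: simulate/localize -> track -> fit -> summarize -> compare.

Coordinates: image origin at top-left, x rightward, y downward, 0-based
frames; physical units (µm, s) everywhere except at the image boundary.
Every results bundle embeds the configuration, the seeds and a config hash
so runs are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cellstats import compare_groups, summarize_cells
from .config import PipelineConfig, _asdict_clean
from .io import (read_movie, read_trajectory_table, validate_trajectory_table,
                 write_json, write_trajectory_table)
from .kinetics import KineticFit, compile_jump_histograms, fit_kinetic_model
from .localize import localize_movie
from .track import link_localizations, trajectory_stats

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "fit_per_cell",
           "subsample_final_window"]


@dataclass
class PipelineResult:
    """Full results bundle of one pipeline run."""

    trajectories: pd.DataFrame
    fits: dict[str, KineticFit]
    cell_stats: dict[str, dict]
    summaries: pd.DataFrame
    excluded_cells: list[str]
    comparisons: list[dict]
    provenance: dict

    def to_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trajectory_table(self.trajectories, out / "trajectories.csv")
        for cell, fit in self.fits.items():
            d = fit.to_dict()
            d["provenance"] = self.provenance
            write_json(d, out / f"fit_{cell}.json")
        self.summaries.to_csv(out / "cell_summaries.csv", index=False)
        write_json({"comparisons": self.comparisons,
                    "excluded_cells": self.excluded_cells,
                    "provenance": self.provenance}, out / "statistics.json")


def fit_per_cell(trajs: pd.DataFrame, cfg: PipelineConfig
                 ) -> tuple[dict[str, KineticFit], dict[str, dict]]:
    """Compile histograms and fit the kinetic model for each cell_id."""
    fits: dict[str, KineticFit] = {}
    stats: dict[str, dict] = {}
    for cell, g in trajs.groupby("cell_id"):
        st = trajectory_stats(g, cfg.fit.n_timepoints)
        hist = compile_jump_histograms(g, cfg.fit)
        fits[cell] = fit_kinetic_model(hist, cfg.fit)
        st["n_jumps_histogram"] = hist.total_jumps
        stats[cell] = st
    return fits, stats


def _provenance(cfg: PipelineConfig) -> dict:
    cfg_json = cfg.to_json()
    return {
        "package_version": __version__,
        "config": _asdict_clean(cfg),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
    }


def run_pipeline(cfg: PipelineConfig, *, movie=None, trajectories=None,
                 conditions: dict[str, str] | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the analysis end to end.

    Exactly one of ``movie`` (array or TIFF path; localization + tracking
    run first) or ``trajectories`` (DataFrame or CSV path; those stages are
    skipped) must be given. ``conditions`` optionally maps cell_id ->
    condition label; pairwise group comparisons of F_bound / D_free1 /
    D_free2 are run per condition pair. Any stage refusal (e.g. too few
    jumps for a stable fit) propagates as the stage's exception.
    """
    if (movie is None) == (trajectories is None):
        raise ValueError("provide exactly one of movie or trajectories")
    if movie is not None:
        stack = read_movie(movie) if isinstance(movie, (str, Path)) else np.asarray(movie)
        locs = localize_movie(stack, cfg.detection, cfg.acquisition.pixel_size)
        log.info("localized %d spots in %d frames", len(locs), stack.shape[0])
        trajs = link_localizations(locs, cfg.linking)
    else:
        if isinstance(trajectories, (str, Path)):
            trajs = read_trajectory_table(trajectories)
        else:
            trajs = validate_trajectory_table(trajectories.copy())
    if len(trajs) == 0:
        raise ValueError("no trajectories to fit: empty input")

    fits, cell_stats = fit_per_cell(trajs, cfg)
    records = [{
        "cell_id": cell, "fit": fit,
        "n_trajectories": cell_stats[cell]["n_trajectories"],
        "condition": (conditions or {}).get(cell, "default"),
    } for cell, fit in fits.items()]
    summaries, excluded = summarize_cells(records, cfg.stats.min_trajectories)

    comparisons = []
    if len(summaries) and summaries["condition"].nunique() > 1:
        conds = sorted(summaries["condition"].unique())
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a = summaries[summaries["condition"] == conds[i]]
                b = summaries[summaries["condition"] == conds[j]]
                if len(a) < 2 or len(b) < 2:
                    continue
                for param in ("F_bound", "D_free1", "D_free2"):
                    c = compare_groups(a[param], b[param], cfg.stats.test_mode,
                                       labels=(conds[i], conds[j]))
                    comparisons.append({"parameter": param, **dataclasses.asdict(c)})

    result = PipelineResult(trajs, fits, cell_stats, summaries, excluded,
                            comparisons, _provenance(cfg))
    if out_dir is not None:
        result.to_dir(out_dir)
    return result


def subsample_final_window(trajs: pd.DataFrame, frame_interval: float,
                           window_s: float = 4.5, keep_every: int = 2) -> pd.DataFrame:
    """Keep every ``keep_every``-th frame of the final ``window_s`` seconds.

    A visualization aid (halving ~97 fps to ~45 fps over the last 4.5 s of
    a movie); never used for fitting.
    """
    if len(trajs) == 0:
        return trajs.copy()
    last = int(trajs["frame"].max())
    first = last - int(round(window_s / frame_interval)) + 1
    sel = trajs[(trajs["frame"] >= first) &
                ((trajs["frame"] - first) % keep_every == 0)]
    return sel.reset_index(drop=True)
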