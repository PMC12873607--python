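"""Per-cell aggregation, group comparisons and bimodality assessment.

Each cell contributes one kinetic fit; the per-cell values (D_free1,
D_free2, F_bound) are the units of the violin-plot statistics and of the
two-sample comparisons (pooled-variance Student t by default, two-tailed,
Welch optional). Bimodality of a per-cell parameter — e.g. D_free1 after a
drug that acts only on S-phase cells — is assessed with 1- vs 2-component
Gaussian mixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .kinetics import KineticFit

__all__ = ["CellSummary", "GroupComparison", "BimodalityResult",
           "summarize_cells", "compare_groups", "detect_bimodality",
           "holm_adjust"]

log = logging.getLogger(__name__)


@dataclass
class CellSummary:
    """Per-cell values entering group statistics."""

    cell_id: str
    condition: str
    D_bound: float
    D_free1: float
    D_free2: float
    F_bound: float
    n_trajectories: int
    n_jumps: int
    replicate: str = "rep_1"


def summarize_cells(fits, min_trajectories: int = 500) -> tuple[pd.DataFrame, list[str]]:
    """Map per-cell fits to a summary table, applying the minimum-data filter.

    ``fits`` is an iterable of records with keys/attributes cell_id,
    condition, fit (KineticFit), n_trajectories and optionally replicate.
    Cells with fewer than ``min_trajectories`` trajectories are excluded and
    returned in the exclusion list. Duplicate cell ids are rejected.
    """
    rows, excluded, seen = [], [], set()
    for rec in fits:
        get = rec.get if isinstance(rec, dict) else lambda k, d=None: getattr(rec, k, d)
        cell_id = get("cell_id")
        if cell_id in seen:
            raise ValueError(f"duplicate cell_id: {cell_id!r}")
        seen.add(cell_id)
        n_traj = int(get("n_trajectories"))
        if n_traj < min_trajectories:
            excluded.append(cell_id)
            log.info("cell %s excluded: %d < %d trajectories",
                     cell_id, n_traj, min_trajectories)
            continue
        fit: KineticFit = get("fit")
        rows.append(CellSummary(
            cell_id=cell_id, condition=get("condition", "default"),
            D_bound=fit.D_bound, D_free1=fit.D_free1, D_free2=fit.D_free2,
            F_bound=fit.F_bound, n_trajectories=n_traj,
            n_jumps=fit.n_jumps_used, replicate=get("replicate", "rep_1"),
        ))
    df = pd.DataFrame([vars(r) for r in rows],
                      columns=list(CellSummary.__dataclass_fields__))
    return df, excluded


@dataclass
class GroupComparison:
    """Two-sample comparison of per-cell values."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    t: float
    df: float
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float
    mode: str
    underflow: bool = False   # zero variance with unequal means


def compare_groups(a, b, mode: str = "student",
                   labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-tailed two-sample t-test on per-cell values.

    ``mode='student'`` uses the pooled-variance statistic with df =
    n_a + n_b - 2; ``mode='welch'`` the unequal-variance statistic with
    Welch-Satterthwaite df. Degenerate zero-variance inputs: equal means
    give t=0, p=1; unequal means give p below the smallest normal float
    with ``underflow=True``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    if mode not in ("student", "welch"):
        raise ValueError("mode must be 'student' or 'welch'")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb
    if va == 0 and vb == 0:
        if diff == 0:
            return GroupComparison(*labels, na, nb, 0.0, float(na + nb - 2), 1.0,
                                   0.0, 0.0, 0.0, mode)
        return GroupComparison(*labels, na, nb, np.sign(diff) * np.inf,
                               float(na + nb - 2), np.nextafter(0.0, 1.0),
                               diff, diff, diff, mode, underflow=True)
    if mode == "student":
        dof = na + nb - 2.0
        sp2 = ((na - 1) * va + (nb - 1) * vb) / dof
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        dof = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    tcrit = stats.t.ppf(0.975, dof)
    return GroupComparison(*labels, na, nb, float(t), float(dof), float(p),
                           float(diff), float(diff - tcrit * se),
                           float(diff + tcrit * se), mode)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (optional multiplicity control)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


@dataclass
class BimodalityResult:
    """1- vs 2-component Gaussian mixture assessment of per-cell values."""

    bimodal: bool
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic1: float
    bic2: float
    separation: float   # |mu1 - mu2| / pooled sd


def detect_bimodality(values, seed: int = 0, min_n: int = 10,
                      separation_threshold: float = 2.0) -> BimodalityResult:
    """Declare a per-cell distribution bimodal when a 2-component Gaussian
    mixture wins by BIC *and* the component means are separated by more
    than ``separation_threshold`` pooled standard deviations."""
    x = np.asarray(values, float).reshape(-1, 1)
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} values, got {len(x)}")
    gm1 = GaussianMixture(1, random_state=seed, n_init=1).fit(x)
    gm2 = GaussianMixture(2, random_state=seed, n_init=5).fit(x)
    bic1, bic2 = gm1.bic(x), gm2.bic(x)
    w = gm2.weights_.ravel()
    mu = gm2.means_.ravel()
    sd = np.sqrt(gm2.covariances_.ravel())
    pooled = np.sqrt(np.sum(w * sd ** 2))
    separation = abs(mu[0] - mu[1]) / pooled if pooled > 0 else np.inf
    bimodal = (bic2 < bic1) and (separation > separation_threshold)
    order = np.argsort(mu)
    return BimodalityResult(bool(bimodal), w[order], mu[order], sd[order],
                            float(bic1), float(bic2), float(separation))
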