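"""Ground-truth trajectory and movie simulation.

The generator emulates the statistical structure that the downstream
jump-length analysis assumes: a static mixture of three diffusive states
(chromatin-bound, slow-diffusing, fast-diffusing), isotropic Gaussian
localization error, geometric photobleaching-limited lifetimes, and an
axial detection slice of thickness dz that preferentially censors fast
molecules. Defaults are the asynchronous-cell conditions of the experiment
being modelled: ~10% bound / ~18% slow / ~72% fast with diffusion
coefficients ~0.005 / 0.35 / 2.3 µm²/s and 35 nm localization error.

Molecules move in 3D; only x, y are observed. The axial coordinate lives in
an extended domain (a multiple of dz, reflecting walls standing in for the
rest of the nucleus) and a molecule is observable only while inside the
detection slice [-dz/2, +dz/2]. An observed trajectory is a maximal run of
frames over which the molecule stayed inside the slice *continuously*;
within-frame boundary crossings are resolved with the exact Brownian-bridge
first-passage probability, and a molecule that leaves and re-enters starts
a new trajectory id. This makes the censoring statistics match the
continuous absorbing-boundary defocalization correction used by the
kinetic fit, and mirrors how real trackers fragment tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import AcquisitionConfig

STATE_NAMES = ("bound", "free1", "free2")

TRAJECTORY_COLUMNS = [
    "trajectory_id", "frame", "x_um", "y_um", "cell_id", "true_state",
    "molecule_id", "x_true_um", "y_true_um", "z_um",
]


@dataclass
class GroundTruthModel:
    """True mixture model that trajectories are drawn from.

    ``state_fractions`` and ``diffusion_coeffs`` are ordered (bound, free1,
    free2). ``switching_rates`` is an optional 3x3 matrix of per-pair
    transition rates (1/s); by default states are fixed per molecule, which
    is the regime the static-mixture fit assumes. ``track_length_mean`` is
    the mean of the geometric photobleaching lifetime in frames; ``density``
    is the particle density for movie rendering (1/µm²).
    ``z_domain_factor`` sets the extended axial domain (multiple of dz) in
    which out-of-focus molecules keep diffusing before re-entry.
    """

    state_fractions: tuple[float, float, float] = (0.10, 0.18, 0.72)
    diffusion_coeffs: tuple[float, float, float] = (0.005, 0.35, 2.3)
    sigma_loc: float = 0.035
    switching_rates: np.ndarray | None = None
    track_length_mean: float = 6.0
    density: float = 0.1
    z_domain_factor: float = 2.0

    def __post_init__(self) -> None:
        f = np.asarray(self.state_fractions, float)
        if f.shape != (3,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("state_fractions must be 3 probabilities summing to 1")
        d = np.asarray(self.diffusion_coeffs, float)
        if np.any(d < 0):
            raise ValueError("diffusion coefficients must be >= 0")
        if not (d[0] <= d[1] <= d[2]):
            raise ValueError("require D_bound <= D_free1 <= D_free2")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.track_length_mean < 1:
            raise ValueError("track_length_mean must be >= 1 frame")
        if self.z_domain_factor < 1:
            raise ValueError("z_domain_factor must be >= 1")


@dataclass
class SimulatedDataset:
    """Trajectory table plus the ground truth that generated it.

    ``trajectories`` has columns trajectory_id, frame, x_um, y_um, cell_id,
    true_state plus simulation-only truth columns (molecule_id, x_true_um,
    y_true_um, z_um). Bit-reproducible for a given seed.
    """

    trajectories: pd.DataFrame
    ground_truth: GroundTruthModel
    acquisition: AcquisitionConfig
    seed: int
    movie: np.ndarray | None = None

    @property
    def n_trajectories(self) -> int:
        if len(self.trajectories) == 0:
            return 0
        return self.trajectories["trajectory_id"].nunique()

    @property
    def n_molecules(self) -> int:
        if len(self.trajectories) == 0:
            return 0
        return self.trajectories["molecule_id"].nunique()


def _bridge_crossed(z0: np.ndarray, z1: np.ndarray, half: float, var: float,
                    u: np.ndarray) -> np.ndarray:
    """Whether a Brownian bridge between interior endpoints crossed ±half.

    For endpoints inside the slab the first-passage probability across one
    boundary b is exp(-2 (b - z0)(b - z1) / var) with var = 2 D dt; the two
    boundaries are combined additively (double crossings within one frame
    are negligible at the step sizes used here). ``u`` are uniform draws.
    """
    if var <= 0:
        return np.zeros(np.shape(z0), bool)
    p_up = np.exp(-2.0 * (half - z0) * (half - z1) / var)
    p_lo = np.exp(-2.0 * (half + z0) * (half + z1) / var)
    return u < np.clip(p_up + p_lo, 0.0, 1.0)


def _fold_reflect(x: np.ndarray, half_domain: float) -> np.ndarray:
    """Map an unreflected Brownian path into [-h, h] (reflection principle)."""
    period = 4.0 * half_domain
    y = np.mod(x + half_domain, period)
    return np.minimum(y, period - y) - half_domain


def _simulate_state_batch(rng: np.random.Generator, D: float, n: int,
                          model: GroundTruthModel, acq: AcquisitionConfig,
                          n_frames: int) -> dict[str, np.ndarray]:
    """Simulate n fixed-state molecules; return flat arrays of the observed
    rows (one per in-slice frame) with a per-molecule fragment index."""
    empty = dict(mol=np.empty(0, int), frag=np.empty(0, int), frame=np.empty(0, int),
                 x=np.empty(0), y=np.empty(0), z=np.empty(0))
    if n == 0:
        return empty
    dt = acq.frame_interval
    half = acq.dz / 2.0
    finite_dz = np.isfinite(half)
    half_dom = model.z_domain_factor * half if finite_dz else 0.0

    p_geo = 1.0 / model.track_length_mean
    starts = rng.integers(0, n_frames, size=n)
    lifetimes = np.minimum(rng.geometric(p_geo, size=n), n_frames - starts)
    lmax = int(lifetimes.max())

    fy, fx = acq.fov_um
    sd = np.sqrt(2.0 * D * dt)
    x = np.empty((n, lmax))
    y = np.empty((n, lmax))
    x[:, 0] = rng.uniform(0, fx, size=n)
    y[:, 0] = rng.uniform(0, fy, size=n)
    if lmax > 1:
        x[:, 1:] = x[:, :1] + np.cumsum(rng.normal(0.0, sd, size=(n, lmax - 1)), axis=1)
        y[:, 1:] = y[:, :1] + np.cumsum(rng.normal(0.0, sd, size=(n, lmax - 1)), axis=1)

    alive = np.arange(lmax)[None, :] < lifetimes[:, None]
    if finite_dz:
        z = np.empty((n, lmax))
        z[:, 0] = rng.uniform(-half_dom, half_dom, size=n)
        if lmax > 1:
            raw = z[:, :1] + np.cumsum(rng.normal(0.0, sd, size=(n, lmax - 1)), axis=1)
            z[:, 1:] = _fold_reflect(raw, half_dom)
        in_slab = np.abs(z) <= half
        observable = in_slab & alive
        if lmax > 1:
            u = rng.uniform(size=(n, lmax - 1))
            crossed = _bridge_crossed(z[:, :-1], z[:, 1:], half, 2.0 * D * dt, u)
            connected = in_slab[:, :-1] & in_slab[:, 1:] & ~crossed \
                & alive[:, :-1] & alive[:, 1:]
        else:
            connected = np.zeros((n, 0), bool)
    else:
        z = np.zeros((n, lmax))
        observable = alive
        connected = alive[:, :-1] & alive[:, 1:]

    # fragment labelling, vectorized over the flattened (molecule, frame) grid
    prev_connected = np.concatenate([np.zeros((n, 1), bool), connected], axis=1)
    frag_start = observable & ~prev_connected
    frag_of_frame = np.cumsum(frag_start, axis=1) - 1   # valid where observable
    keep = observable.ravel()
    mol_idx, frame_idx = np.divmod(np.flatnonzero(keep), lmax)
    return dict(
        mol=mol_idx,
        frag=frag_of_frame.ravel()[keep],
        frame=starts[mol_idx] + frame_idx,
        x=x.ravel()[keep], y=y.ravel()[keep], z=z.ravel()[keep],
    )


def _simulate_switching(rng: np.random.Generator, n: int, model: GroundTruthModel,
                        acq: AcquisitionConfig, n_frames: int) -> pd.DataFrame:
    """Markov-switching stress-test mode (per-frame transition probability
    rate * dt; no re-entry: a molecule's record ends at its first axial
    exit)."""
    dt = acq.frame_interval
    half = acq.dz / 2.0
    Q = np.asarray(model.switching_rates, float)
    D = np.asarray(model.diffusion_coeffs, float)
    p_geo = 1.0 / model.track_length_mean
    fy, fx = acq.fov_um
    rows = []
    for mol in range(n):
        s = int(rng.choice(3, p=model.state_fractions))
        start = int(rng.integers(0, n_frames))
        life = min(int(rng.geometric(p_geo)), n_frames - start)
        pos = np.array([rng.uniform(0, fx), rng.uniform(0, fy),
                        rng.uniform(-half, half) if np.isfinite(half) else 0.0])
        rows.append((mol, mol, start, pos[0], pos[1], pos[2], s))
        for j in range(1, life):
            jump_p = np.clip(Q[s] * dt, 0, None)
            jump_p[s] = 0.0
            probs = np.where(np.arange(3) == s, 1.0 - jump_p.sum(), jump_p)
            s = int(rng.choice(3, p=probs))
            step = rng.normal(0, np.sqrt(2 * D[s] * dt), size=3)
            new = pos + step
            if np.isfinite(half):
                if abs(new[2]) > half or _bridge_crossed(
                        np.array([pos[2]]), np.array([new[2]]), half,
                        2 * D[s] * dt, rng.uniform(size=1))[0]:
                    break
            pos = new
            rows.append((mol, mol, start + j, pos[0], pos[1], pos[2], s))
    df = pd.DataFrame(rows, columns=["trajectory_id", "molecule_id", "frame",
                                     "x_true_um", "y_true_um", "z_um", "state_idx"])
    df["true_state"] = [STATE_NAMES[k] for k in df.pop("state_idx")]
    return df


def simulate_trajectories(model: GroundTruthModel, acq: AcquisitionConfig,
                          n_trajectories: int, seed: int, *,
                          n_frames: int = 1000, cell_id: str = "cell_0") -> SimulatedDataset:
    """Simulate ``n_trajectories`` molecules and return their observed records.

    Observed positions are the true x, y plus isotropic Gaussian noise of
    standard deviation ``model.sigma_loc``. A molecule is observed while it
    is inside the axial slice and unbleached; leaving the slice ends the
    current trajectory id and re-entry starts a new one, so the number of
    emitted trajectory ids can exceed the number of molecules (the
    ``molecule_id`` column ties fragments back together).
    """
    if n_trajectories < 0:
        raise ValueError("n_trajectories must be >= 0")
    rng = np.random.default_rng(seed)
    if n_trajectories == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=float) for c in TRAJECTORY_COLUMNS})
        return SimulatedDataset(empty, model, acq, seed)

    if model.switching_rates is not None:
        df = _simulate_switching(rng, n_trajectories, model, acq, n_frames)
    else:
        states = rng.choice(3, size=n_trajectories, p=model.state_fractions)
        parts = []
        for s in range(3):
            idx = np.flatnonzero(states == s)
            batch = _simulate_state_batch(rng, model.diffusion_coeffs[s], len(idx),
                                          model, acq, n_frames)
            if len(batch["mol"]) == 0:
                continue
            parts.append(pd.DataFrame({
                "molecule_id": idx[batch["mol"]],
                "frag": batch["frag"],
                "frame": batch["frame"],
                "x_true_um": batch["x"], "y_true_um": batch["y"], "z_um": batch["z"],
                "true_state": STATE_NAMES[s],
            }))
        df = pd.concat(parts, ignore_index=True)
        df = df.sort_values(["molecule_id", "frame"], kind="stable").reset_index(drop=True)
        key = df["molecule_id"].to_numpy() * (df["frag"].max() + 1) + df["frag"].to_numpy()
        _, inv = np.unique(key, return_inverse=True)
        df["trajectory_id"] = inv
        df = df.drop(columns="frag")

    noise = rng.normal(0.0, model.sigma_loc, size=(len(df), 2)) if model.sigma_loc > 0 \
        else np.zeros((len(df), 2))
    df["x_um"] = df["x_true_um"] + noise[:, 0]
    df["y_um"] = df["y_true_um"] + noise[:, 1]
    df["cell_id"] = cell_id
    df = df[TRAJECTORY_COLUMNS].sort_values(["trajectory_id", "frame"]).reset_index(drop=True)
    return SimulatedDataset(df, model, acq, seed)


def render_movie(dataset: SimulatedDataset, acq: AcquisitionConfig, seed: int,
                 n_frames: int | None = None) -> np.ndarray:
    """Render the dataset's true positions as a 16-bit TIFF-ready stack.

    Each in-focus molecule becomes a 2D Gaussian of width ``psf_sigma``
    (pixels) with integrated intensity ``photon_budget`` on a constant
    background; Poisson shot noise is applied to the whole frame.
    """
    rng = np.random.default_rng(seed)
    ny, nx = acq.fov
    df = dataset.trajectories
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1 if len(df) else 1
    s = acq.psf_sigma
    amp = acq.photon_budget / (2.0 * np.pi * s * s)
    w = max(4, int(np.ceil(4 * s)))
    stack = np.full((n_frames, ny, nx), float(acq.background))

    xs = df["x_true_um"].to_numpy() / acq.pixel_size
    ys = df["y_true_um"].to_numpy() / acq.pixel_size
    frames = df["frame"].to_numpy(int)
    clipped = 0
    for xpx, ypx, fr in zip(xs, ys, frames):
        if fr >= n_frames:
            continue
        cx, cy = int(round(xpx)), int(round(ypx))
        if not (0 <= cx < nx and 0 <= cy < ny):
            clipped += 1
            continue
        x0, x1 = max(cx - w, 0), min(cx + w + 1, nx)
        y0, y1 = max(cy - w, 0), min(cy + w + 1, ny)
        gx = np.arange(x0, x1)
        gy = np.arange(y0, y1)
        g = np.exp(-((gy[:, None] - ypx) ** 2 + (gx[None, :] - xpx) ** 2) / (2 * s * s))
        stack[fr, y0:y1, x0:x1] += amp * g
    if clipped:
        import warnings
        warnings.warn(f"{clipped} particle positions fell outside the field of view "
                      "and were clipped", stacklevel=2)
    return rng.poisson(stack).astype(np.uint16)


class MCSurvival(NamedTuple):
    probability: float
    stderr: float
    n_walkers: int


def mc_axial_survival(D: float, t: float, dz: float, n_walkers: int,
                      n_substeps: int, seed: int, *, bridge: bool = True) -> MCSurvival:
    """Monte-Carlo fraction of molecules that never leave the axial slice.

    1D Brownian walkers start uniform in [-dz/2, dz/2] and are propagated in
    ``n_substeps`` increments over [0, t]; a walker is lost when a position
    check finds it outside the slice or (``bridge=True``, default) when the
    exact Brownian-bridge first-passage draw says it crossed between checks.
    With the bridge draw the estimate is unbiased for the continuous
    first-passage problem; without it, crossings between checks are missed
    and survival is overestimated by O(sqrt(D t / n_substeps) / dz).
    """
    if n_walkers <= 0:
        raise ValueError("n_walkers must be > 0")
    if D < 0 or t <= 0 or dz <= 0:
        raise ValueError("require D >= 0, t > 0, dz > 0")
    if D == 0:
        return MCSurvival(1.0, 0.0, n_walkers)
    rng = np.random.default_rng(seed)
    half = dz / 2.0
    dt = t / n_substeps
    var = 2.0 * D * dt
    sd = np.sqrt(var)
    n_alive_total = 0
    chunk = min(n_walkers, 200_000)
    done = 0
    while done < n_walkers:
        n = min(chunk, n_walkers - done)
        z = rng.uniform(-half, half, size=n)
        for _ in range(n_substeps):
            if z.size == 0:
                break
            znew = z + rng.normal(0.0, sd, size=z.size)
            out = np.abs(znew) > half
            if bridge:
                u = rng.uniform(size=z.size)
                dead = _bridge_crossed(z, znew, half, var, u) | out
            else:
                dead = out
            z = znew[~dead]     # lost walkers are dropped from propagation
        n_alive_total += int(z.size)
        done += n
    p = n_alive_total / n_walkers
    se = np.sqrt(max(p * (1 - p), 1e-12) / n_walkers)
    return MCSurvival(p, se, n_walkers)
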