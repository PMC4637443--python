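"""Cellular-automaton excitation spread as first-arrival shortest paths.

Activation times on the 26-neighbor voxel graph are computed with Dijkstra's
algorithm; the edge travel time is the Euclidean edge length divided by the
harmonic mean of the two voxels' conduction velocities, which composes travel
times consistently across an interface. This is equivalent to an event-driven
automaton at 0.1 ms clock resolution, to which results are rounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .anatomy import VoxelHeart
from .ap import BEAT_DURATION_MS, FRAME_INTERVAL_MS, params_at, tmv_course

CLOCK_MS = 0.1

_OFFSETS = np.array([(dx, dy, dz)
                     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                     if (dx, dy, dz) != (0, 0, 0)])


@dataclass
class ActivationMap:
    t_act: np.ndarray      # ms per myocardial voxel (flat, heart ordering); inf if unreached
    voxel_index: np.ndarray  # (n_vox, 3) grid indices, row order of t_act


@dataclass
class TMVMovie:
    tmv: np.ndarray              # (n_vox, n_frames) mV
    frame_interval: float = FRAME_INTERVAL_MS
    duration: float = BEAT_DURATION_MS

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.tmv.shape[1]) * self.frame_interval

    @property
    def n_frames(self) -> int:
        return self.tmv.shape[1]


def compute_activation(heart: VoxelHeart, cv_field: np.ndarray,
                       stimuli: list[tuple[tuple[int, int, int], float]] | None = None
                       ) -> ActivationMap:
    """First-arrival activation times (ms) under a per-voxel CV field (m/s).

    ``cv_field`` is flat over the myocardial voxels in ``np.argwhere``
    ordering. ``stimuli`` defaults to the heart's stimulus sites; each entry
    is (grid index, delay ms). Multi-source Dijkstra is realized with a
    virtual source node connected to the stimulus voxels by their delays.
    """
    idx = np.argwhere(heart.occupancy)
    n = idx.shape[0]
    cv = np.asarray(cv_field, float)
    if cv.shape != (n,):
        raise ValueError("cv_field must be flat over myocardial voxels")
    if np.any(cv <= 0):
        raise ValueError("cv_field must be positive")
    if stimuli is None:
        stimuli = heart.stimulus_sites
    if not stimuli:
        raise ValueError("at least one stimulus is required")

    flat_of = -np.ones(heart.shape, np.int64)
    flat_of[tuple(idx.T)] = np.arange(n)

    h = heart.voxel_size
    src, dst, w = [], [], []
    for off in _OFFSETS:
        nb = idx + off
        ok = np.all((nb >= 0) & (nb < np.array(heart.shape)), axis=1)
        j = np.full(n, -1, np.int64)
        j[ok] = flat_of[tuple(nb[ok].T)]
        ok &= j >= 0
        i = np.nonzero(ok)[0]
        jj = j[i]
        length = h * np.linalg.norm(off)
        hmean = 2.0 * cv[i] * cv[jj] / (cv[i] + cv[jj])
        src.append(i)
        dst.append(jj)
        w.append(length / hmean)

    # virtual source (node n) -> stimulus voxels with their delays
    stim_nodes = np.array([flat_of[s] for s, _ in stimuli], np.int64)
    if np.any(stim_nodes < 0):
        raise ValueError("stimulus site outside myocardium")
    delays = np.array([d for _, d in stimuli], float)
    src.append(np.full(len(stimuli), n, np.int64))
    dst.append(stim_nodes)
    w.append(delays)

    graph = coo_matrix((np.concatenate(w),
                        (np.concatenate(src), np.concatenate(dst))),
                       shape=(n + 1, n + 1)).tocsr()
    t = dijkstra(graph, directed=True, indices=n)[:n]
    t = np.round(t / CLOCK_MS) * CLOCK_MS
    return ActivationMap(t_act=t, voxel_index=idx)


def healthy_cv_field(heart: VoxelHeart, endpoints) -> np.ndarray:
    zf0 = np.zeros(heart.occupancy.sum())
    depth = heart.transmural_depth[heart.occupancy]
    return params_at(zf0, depth, endpoints)["cv"]


def ischemic_cv_field(heart: VoxelHeart, zf_grid: np.ndarray, endpoints) -> np.ndarray:
    zf = zf_grid[heart.occupancy]
    depth = heart.transmural_depth[heart.occupancy]
    return params_at(zf, depth, endpoints)["cv"]


def build_tmv_movie(act: ActivationMap, zf_grid: np.ndarray | None,
                    endpoints, heart: VoxelHeart,
                    duration: float = BEAT_DURATION_MS,
                    frame_interval: float = FRAME_INTERVAL_MS) -> TMVMovie:
    """Sample every voxel's AP template onto the 2 ms frame grid."""
    if not np.all(np.isfinite(act.t_act)):
        raise ValueError("activation must be finite on all myocardial voxels")
    depth = heart.transmural_depth[heart.occupancy]
    zf = np.zeros_like(depth) if zf_grid is None else zf_grid[heart.occupancy]
    p = params_at(zf, depth, endpoints)
    t = np.arange(0.0, duration + frame_interval / 2, frame_interval)
    params_cols = {k: v[:, None] for k, v in p.items()}
    tmv = tmv_course(params_cols, act.t_act[:, None], t[None, :])
    return TMVMovie(tmv=tmv, frame_interval=frame_interval, duration=duration)
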