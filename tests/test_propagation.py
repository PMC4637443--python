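"""Activation spread: shortest-path first arrival and the TMV movie."""

import heapq

import numpy as np
import pytest

from ischemia_ecg.anatomy import VoxelHeart
from ischemia_ecg.ap import default_endpoints, params_at, tmv_course
from ischemia_ecg.propagation import (CLOCK_MS, build_tmv_movie, compute_activation,
                                      healthy_cv_field)


def make_block_heart(occupancy: np.ndarray, voxel_size: float = 1.0) -> VoxelHeart:
    shape = occupancy.shape
    return VoxelHeart(voxel_size=voxel_size, origin=np.zeros(3),
                      occupancy=occupancy,
                      chamber_label=occupancy.astype(np.uint8),
                      aha_segment=np.zeros(shape, np.uint8),
                      transmural_depth=np.full(shape, 0.5) * occupancy,
                      endo_surface=np.zeros(shape, bool),
                      epi_surface=np.zeros(shape, bool),
                      lv_cavity=np.zeros(shape, bool))


def dijkstra_oracle(heart: VoxelHeart, cv: np.ndarray, stimuli) -> np.ndarray:
    """Plain heapq Dijkstra over the 26-neighbor voxel graph."""
    idx = np.argwhere(heart.occupancy)
    flat = {tuple(v): i for i, v in enumerate(idx)}
    n = idx.shape[0]
    dist = np.full(n, np.inf)
    heap = []
    for site, delay in stimuli:
        i = flat[tuple(site)]
        if delay < dist[i]:
            dist[i] = delay
            heapq.heappush(heap, (delay, i))
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    while heap:
        d, i = heapq.heappop(heap)
        if d > dist[i]:
            continue
        vi = idx[i]
        for off in offsets:
            key = (vi[0] + off[0], vi[1] + off[1], vi[2] + off[2])
            j = flat.get(key)
            if j is None:
                continue
            length = heart.voxel_size * np.sqrt(off[0] ** 2 + off[1] ** 2 + off[2] ** 2)
            hm = 2 * cv[i] * cv[j] / (cv[i] + cv[j])
            nd = d + length / hm
            if nd < dist[j]:
                dist[j] = nd
                heapq.heappush(heap, (nd, j))
    return np.round(dist / CLOCK_MS) * CLOCK_MS


def test_strip_travel_time():
    """60 mm strip at 0.6 m/s: far end activates ~100 ms after the stimulus."""
    occ = np.zeros((60, 1, 1), bool)
    occ[:, 0, 0] = True
    heart = make_block_heart(occ)
    cv = np.full(60, 0.6)
    act = compute_activation(heart, cv, [((0, 0, 0), 0.0)])
    crossing = heart.voxel_size / 0.6
    assert act.t_act[-1] == pytest.approx((60 - 1) / 0.6, abs=crossing)


def test_random_grids_match_dijkstra_oracle():
    rng = np.random.default_rng(42)
    for _ in range(5):
        shape = tuple(rng.integers(4, 11, 3))
        occ = rng.random(shape) < 0.85
        occ[tuple(np.argwhere(occ)[0])] = True
        # keep one connected component so every voxel is reachable
        from scipy import ndimage
        lab, n = ndimage.label(occ, structure=np.ones((3, 3, 3), bool))
        counts = np.bincount(lab.ravel()); counts[0] = 0
        occ = lab == np.argmax(counts)
        heart = make_block_heart(occ)
        nvox = occ.sum()
        cv = rng.uniform(0.2, 1.0, nvox)
        sites = np.argwhere(occ)[rng.choice(nvox, 2, replace=False)]
        stimuli = [(tuple(int(x) for x in s), float(d))
                   for s, d in zip(sites, rng.uniform(0, 5, 2))]
        act = compute_activation(heart, cv, stimuli)
        oracle = dijkstra_oracle(heart, cv, stimuli)
        assert np.max(np.abs(act.t_act - oracle)) <= CLOCK_MS + 1e-9


def test_two_stimuli_are_first_arrival_superposition():
    occ = np.ones((10, 4, 4), bool)
    heart = make_block_heart(occ)
    cv = np.full(occ.sum(), 0.5)
    s1, s2 = ((0, 0, 0), 0.0), ((9, 3, 3), 5.0)
    both = compute_activation(heart, cv, [s1, s2]).t_act
    only1 = compute_activation(heart, cv, [s1]).t_act
    only2 = compute_activation(heart, cv, [s2]).t_act
    assert np.allclose(both, np.minimum(only1, only2), atol=CLOCK_MS)


def test_slower_conduction_never_speeds_activation():
    rng = np.random.default_rng(3)
    occ = np.ones((8, 8, 4), bool)
    heart = make_block_heart(occ)
    cv = rng.uniform(0.3, 0.9, occ.sum())
    slow = cv.copy()
    slow[rng.random(occ.sum()) < 0.4] *= 0.5
    base = compute_activation(heart, cv, [((0, 0, 0), 0.0)]).t_act
    slowed = compute_activation(heart, slow, [((0, 0, 0), 0.0)]).t_act
    assert np.all(slowed >= base - 1e-9)


def test_no_stimuli_rejected():
    heart = make_block_heart(np.ones((3, 3, 3), bool))
    with pytest.raises(ValueError):
        compute_activation(heart, np.full(27, 0.6), [])


def test_qrs_duration_physiological(default_heart, endpoints):
    """Healthy default heart fully activates well within a normal QRS."""
    cv = healthy_cv_field(default_heart, endpoints)
    act = compute_activation(default_heart, cv)
    delays = [d for _, d in default_heart.stimulus_sites]
    assert np.isfinite(act.t_act).all()
    assert act.t_act.max() - min(delays) < 120.0


def test_movie_matches_pointwise_template(endpoints):
    occ = np.zeros((6, 5, 4), bool)
    occ[1:5, 1:4, 1:3] = True
    heart = make_block_heart(occ)
    heart.transmural_depth = np.random.default_rng(1).random(occ.shape) * occ
    n = occ.sum()
    cv = np.full(n, 0.6)
    act = compute_activation(heart, cv, [((1, 1, 1), 0.0)])
    zf = np.zeros(occ.shape)
    zf[3, 2, 1] = 0.7
    movie = build_tmv_movie(act, zf, endpoints, heart)
    t = movie.times
    depth = heart.transmural_depth[heart.occupancy]
    zf_flat = zf[heart.occupancy]
    for v in range(n):
        p = params_at(float(zf_flat[v]), float(depth[v]), endpoints)
        expected = tmv_course(p, float(act.t_act[v]), t)
        assert np.allclose(movie.tmv[v], expected, atol=1e-9)


def test_movie_rest_and_upstroke_bands(default_heart, endpoints):
    cv = healthy_cv_field(default_heart, endpoints)
    act = compute_activation(default_heart, cv)
    movie = build_tmv_movie(act, None, endpoints, default_heart)
    # frames before the earliest stimulus: whole heart at rest
    assert np.all(movie.tmv[:, :5] == -85.0)
    # first frame at least one upstroke past activation: depolarized band
    cols = np.clip(np.ceil(act.t_act / movie.frame_interval).astype(int) + 1, 0,
                   movie.n_frames - 1)
    vals = movie.tmv[np.arange(movie.tmv.shape[0]), cols]
    assert np.all(vals >= -85.0 + 0.9 * 125.0 - 1e-9)
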