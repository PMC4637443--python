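"""Phenomenological action-potential templates and their ischemic modulation.

Each voxel's transmembrane voltage follows a fixed template parameterized by
resting membrane voltage (RMV), AP amplitude, duration at 90% repolarization
(APD90) and conduction velocity (CV). Acute ischemia ten minutes after onset
(hyperkalemia, acidosis, hypoxia) depolarizes the resting membrane, reduces
amplitude and APD90 and slows conduction; the zone factor ZF interpolates
each parameter between the healthy and fully ischemic endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

BEAT_DURATION_MS = 500.0
FRAME_INTERVAL_MS = 2.0
UPSTROKE_MS = 2.0
PLATEAU_FRACTION = 0.5           # plateau ends at t_act + 0.5 * apd90
# half-cosine repolarization reaches 10% of amplitude at apd90:
# 0.5*(1+cos(pi*x)) = 0.1  =>  x = arccos(-0.8)/pi
_X90 = float(np.arccos(-0.8) / np.pi)
REPOL_SPAN_FRACTION = (1.0 - PLATEAU_FRACTION) / _X90


@dataclass(frozen=True)
class APParams:
    rmv: float        # mV
    amplitude: float  # mV
    apd90: float      # ms
    cv: float         # m/s == mm/ms

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.apd90 <= 0 or self.cv <= 0:
            raise ValueError("amplitude, apd90 and cv must be positive")


LAYERS = ("endo", "mid", "epi")


@dataclass(frozen=True)
class IschemiaEndpoints:
    """Healthy and central-ischemic-zone AP parameters per transmural layer."""

    healthy: dict[str, APParams]
    ciz: dict[str, APParams]

    def __post_init__(self) -> None:
        for layer in LAYERS:
            h, c = self.healthy[layer], self.ciz[layer]
            if not (c.rmv > h.rmv and c.amplitude < h.amplitude
                    and c.apd90 < h.apd90 and c.cv < h.cv):
                raise ValueError(
                    f"{layer}: ischemic endpoint must depolarize rest and reduce "
                    "amplitude, apd90 and cv")


def default_endpoints() -> IschemiaEndpoints:
    """Representative endpoints for acute ischemia ~10 min after onset.

    Healthy: RMV -85 mV, amplitude 125 mV, APD90 endo/mid/epi 320/340/300 ms
    (epicardial APD shorter than endocardial -> concordant T wave), CV 0.6 m/s.
    Full ischemia: RMV -70 mV, amplitude 95 mV, APD90 -25%, CV -40%.
    """
    healthy = {
        "endo": APParams(-85.0, 125.0, 320.0, 0.6),
        "mid": APParams(-85.0, 125.0, 340.0, 0.6),
        "epi": APParams(-85.0, 125.0, 300.0, 0.6),
    }
    ciz = {layer: APParams(-70.0, 95.0, p.apd90 * 0.75, p.cv * 0.6)
           for layer, p in healthy.items()}
    return IschemiaEndpoints(healthy=healthy, ciz=ciz)


def layer_of(depth: float | np.ndarray):
    """Transmural layer from wall depth: endo < 1/3 <= mid < 2/3 <= epi."""
    d = np.asarray(depth)
    out = np.where(d < 1.0 / 3.0, 0, np.where(d < 2.0 / 3.0, 1, 2))
    return out if out.ndim else LAYERS[int(out)]


def params_at(zf, depth, endpoints: IschemiaEndpoints):
    """Interpolate AP parameters at zone factor ``zf`` and wall ``depth``.

    Scalar arguments return an :class:`APParams`; array arguments return a
    dict of parameter arrays (rmv, amplitude, apd90, cv). Each parameter is
    linear in zf between the healthy (zf=0) and CIZ (zf=1) endpoint of the
    voxel's transmural layer.
    """
    zf_a = np.asarray(zf, float)
    depth_a = np.asarray(depth, float)
    if np.any(zf_a < 0) or np.any(zf_a > 1) or np.any(depth_a < 0) or np.any(depth_a > 1):
        raise ValueError("zf and depth must lie in [0, 1]")
    layer_idx = np.where(depth_a < 1.0 / 3.0, 0, np.where(depth_a < 2.0 / 3.0, 1, 2))

    def table(src, attr):
        return np.array([getattr(src[layer], attr) for layer in LAYERS])

    out = {}
    for attr in ("rmv", "amplitude", "apd90", "cv"):
        h = table(endpoints.healthy, attr)[layer_idx]
        c = table(endpoints.ciz, attr)[layer_idx]
        out[attr] = h + zf_a * (c - h)
    if zf_a.ndim == 0 and depth_a.ndim == 0:
        return APParams(float(out["rmv"]), float(out["amplitude"]),
                        float(out["apd90"]), float(out["cv"]))
    return out


def tmv_course(p, t_activation, t):
    """Transmembrane voltage template (mV) at time(s) ``t`` (ms).

    Resting at ``rmv`` before activation, a 2 ms linear upstroke to
    ``rmv + amplitude``, a plateau until ``t_act + 0.5*apd90``, then a
    half-cosine repolarization anchored so the value at ``t_act + apd90``
    equals ``rmv + 0.1*amplitude``, returning to rest afterwards.

    ``p`` may be an :class:`APParams` or a dict of arrays (vectorized over
    voxels, broadcast against ``t``).
    """
    if isinstance(p, APParams):
        rmv, amp, apd = p.rmv, p.amplitude, p.apd90
    else:
        rmv, amp, apd = p["rmv"], p["amplitude"], p["apd90"]
    rel = np.asarray(t, float) - t_activation
    plateau_end = PLATEAU_FRACTION * apd
    repol_span = REPOL_SPAN_FRACTION * apd
    frac_rep = np.clip((rel - plateau_end) / repol_span, 0.0, 1.0)
    f = np.where(rel < 0, 0.0,
                 np.where(rel < UPSTROKE_MS, rel / UPSTROKE_MS,
                          np.where(rel < plateau_end, 1.0,
                                   0.5 * (1.0 + np.cos(np.pi * frac_rep)))))
    out = rmv + amp * f
    return out if np.ndim(out) else float(out)


def with_transmural_heterogeneity(endpoints: IschemiaEndpoints,
                                  enabled: bool) -> IschemiaEndpoints:
    """Optionally flatten the transmural APD90 gradient (mid layer everywhere)."""
    if enabled:
        return endpoints
    mid_h, mid_c = endpoints.healthy["mid"], endpoints.ciz["mid"]
    return IschemiaEndpoints(healthy={layer: replace(mid_h) for layer in LAYERS},
                             ciz={layer: replace(mid_c) for layer in LAYERS})
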