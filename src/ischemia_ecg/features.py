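"""ST-deviation features: STSD, the K point and K point deviation (KPD).

STSD is the maximum over leads of the absolute mean of the 25 samples
between 110 ms and 158 ms. The K point replaces the hard-to-detect J point:
within the R-peak-to-T-peak window (40-320 ms) the across-lead envelope of
absolute signal values is formed, and the K point is the time at which this
envelope is minimal; the KPD is the envelope value there. Because the
envelope never cancels, alternating ST deviation (elevation followed by
depression) that averages to zero in the STSD window is still detected.
The elevation variant clips negative samples before forming the envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ECGRecord

ST_WINDOW_MS = (110.0, 158.0)     # inclusive, 25 samples at 2 ms
K_WINDOW_MS = (40.0, 320.0)       # R peak to T peak


@dataclass
class FeatureResult:
    stsd: float
    kpd: float
    k_elevation: float
    k_point_time: float
    lead_argmax_stsd: str
    scenario_tag: str


def _window_columns(record: ECGRecord, lo: float, hi: float) -> np.ndarray:
    t = record.times
    cols = np.nonzero((t >= lo - 1e-9) & (t <= hi + 1e-9))[0]
    if cols.size == 0 or t[cols[0]] > lo + 1e-9 or t[cols[-1]] < hi - 1e-9:
        raise ValueError(f"record does not cover the {lo}-{hi} ms window")
    return cols


def stsd(record: ECGRecord) -> tuple[float, str]:
    """ST segment deviation (uV) and the lead attaining it.

    Per lead: |mean of the samples at t = 110, 112, ..., 158 ms|; the maximum
    over leads is returned.
    """
    if not record.baseline_corrected:
        raise ValueError("record must be baseline-corrected")
    cols = _window_columns(record, *ST_WINDOW_MS)
    means = np.abs(record.signals[:, cols].mean(axis=1))
    best = int(np.argmax(means))
    return float(means[best]), record.lead_names[best]


def k_point(record: ECGRecord, mode: str = "deviation") -> tuple[float, float]:
    """K point time (ms) and envelope value (uV) in the 40-320 ms window.

    deviation mode: envelope(t) = max over leads of |b|; elevation mode:
    negative samples are clipped to zero before the envelope. The earliest
    frame wins ties.
    """
    if record.signals.shape[0] == 0:
        raise ValueError("record has no leads")
    cols = _window_columns(record, *K_WINDOW_MS)
    win = record.signals[:, cols]
    if mode == "deviation":
        env = np.abs(win).max(axis=0)
    elif mode == "elevation":
        env = np.maximum(win, 0.0).max(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    j = int(np.argmin(env))   # first occurrence = earliest-t tie break
    return float(record.times[cols[j]]), float(env[j])


def kpd(record: ECGRecord) -> float:
    """K point deviation: the envelope value at the K point (uV)."""
    return k_point(record, "deviation")[1]


def k_elevation(record: ECGRecord) -> float:
    """Elevation-only variant of the KPD (uV)."""
    return k_point(record, "elevation")[1]


def per_lead_feature(record: ECGRecord, lead: str, k_point_time: float,
                     mode: str = "deviation") -> float:
    """Single-lead deviation at a K point shared across the full lead set.

    The K point time is determined on the complete scenario lead set; this
    returns |b| (or the clipped positive part) of one lead at that time.
    """
    if lead not in record.lead_names:
        raise ValueError(f"unknown lead {lead!r}")
    col = int(round(k_point_time / record.frame_interval))
    val = record.signals[record.lead_names.index(lead), col]
    return float(abs(val)) if mode == "deviation" else float(max(val, 0.0))


def evaluate(record: ECGRecord) -> FeatureResult:
    """All ST-deviation features of one record."""
    s, lead = stsd(record)
    t_k, dev = k_point(record, "deviation")
    _, elev = k_point(record, "elevation")
    return FeatureResult(stsd=s, kpd=dev, k_elevation=elev, k_point_time=t_k,
                         lead_argmax_stsd=lead, scenario_tag=record.scenario_tag)


def signed_st_mean(record: ECGRecord, lead: str) -> float:
    """Signed mean ST-window deviation of one lead (uV).

    Positive values indicate ST elevation, negative values depression, in the
    clinical sense after diastolic baseline correction.
    """
    cols = _window_columns(record, *ST_WINDOW_MS)
    return float(record.signals[record.lead_names.index(lead), cols].mean())
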