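"""Ca2+ sparklet detection and activity scoring.

A sparklet is a local [Ca2+]i elevation produced by the opening of one or a
few channels at a fixed membrane site; amplitudes come in integer multiples
of a quantal unit q (~38-40 nM per open channel). This module detects
events, scores site activity as nPs (the optical analog of NPo, computed
here as time-averaged quantal occupancy), fits event-amplitude histograms
with the multicomponent Gaussian quantal function, and converts raw
fluorescence to nM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coupling import _round_half_away
from .singlechannel import AllPointsHistogram, QuantalFit, fit_quantal_gaussians
from .traces import CalciumTrace

__all__ = [
    "SparkletEvent",
    "SparkletSite",
    "detect_events",
    "site_nps",
    "amplitude_quantal_fit",
    "sparklet_density",
    "convert_f_to_nm",
    "estimate_baseline",
]


@dataclass
class SparkletEvent:
    """One contiguous supra-threshold event."""

    start_frame: int
    end_frame: int  # inclusive
    level: int  # maximal quantal level during the event
    mean_amplitude: float  # nM above baseline, averaged over event frames
    frame_amplitudes: np.ndarray | None = None  # nM above baseline, per frame

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class SparkletSite:
    """Per-site activity summary."""

    events: list
    nps: float  # time-averaged occupancy (optical NPo analog)
    n_levels: int  # max quantal level observed
    active_fraction: float  # Ps: fraction of frames with k >= 1
    site_id: str = ""


def estimate_baseline(values: np.ndarray, bin_width: float = 1.0) -> float:
    """Baseline as the histogram mode with 1-nM bins.

    The mode is robust at active sites where the mean sits above baseline.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi - lo < bin_width:
        return float(np.median(values))
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def detect_events(
    trace: CalciumTrace,
    q: float = 38.0,
    baseline: float | str = "auto",
    min_duration_frames: int = 2,
) -> list[SparkletEvent]:
    """Detect sparklet events as supra-threshold runs.

    An event is a maximal run of frames with value >= baseline + q/2 lasting
    at least ``min_duration_frames``. The per-frame quantal level is
    round((x - baseline)/q); the event level is the maximum frame level.
    """
    if q <= 0:
        raise ValueError("q must be positive for [Ca2+] traces")
    if len(trace) < 10:
        raise ValueError("trace too short for event detection (need >= 10 frames)")
    x = trace.values
    b = estimate_baseline(x) if baseline == "auto" else float(baseline)
    above = x >= b + q / 2.0
    events: list[SparkletEvent] = []
    # run-length scan over the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_duration_frames:
            continue
        seg = x[start:stop]
        levels = _round_half_away((seg - b) / q).astype(int)
        events.append(
            SparkletEvent(
                start_frame=int(start),
                end_frame=int(stop - 1),
                level=int(levels.max()),
                mean_amplitude=float(seg.mean() - b),
                frame_amplitudes=seg - b,
            )
        )
    return events


def site_nps(
    trace: CalciumTrace,
    q: float = 38.0,
    baseline: float | str = "auto",
) -> SparkletSite:
    """Score one site: nPs, active fraction, and number of quantal levels.

    nPs is the time-averaged quantal occupancy sum_t k_t / T (equivalently
    sum over levels of level x fractional time at that level), with k_t the
    per-frame quantized level floored at 0. Ps is the fraction of frames
    with k >= 1.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    x = trace.values
    b = estimate_baseline(x) if baseline == "auto" else float(baseline)
    k = np.clip(_round_half_away((x - b) / q).astype(int), 0, None)
    events = detect_events(trace, q=q, baseline=b)
    return SparkletSite(
        events=events,
        nps=float(k.mean()),
        n_levels=int(k.max(initial=0)),
        active_fraction=float(np.mean(k >= 1)),
        site_id=trace.site_id,
    )


def amplitude_quantal_fit(
    events: list,
    n_components: int = 3,
    bin_width: float = 4.0,
    q_init: float | str = "auto",
) -> QuantalFit:
    """Fit the event-amplitude histogram with the quantal Gaussian sum.

    ``events`` may be SparkletEvent objects or raw amplitudes in nM. For
    detected events the histogram pools the per-frame [Ca2+] amplitudes of
    every event frame: a multi-level event contributes each of its frames
    at that frame's level, which keeps the histogram quantal (the mean of a
    mixed 1q/2q event is not a multiple of q). The closed peak is absent by
    construction (only supra-threshold frames enter), so no baseline
    Gaussian is fitted. Requires >= 30 events.
    """
    n_events = len(events)
    if n_events < 30:
        raise ValueError(f"need >= 30 events for a stable quantal fit, have {n_events}")
    parts = []
    for e in events:
        if isinstance(e, SparkletEvent):
            if e.frame_amplitudes is not None:
                parts.append(np.asarray(e.frame_amplitudes, dtype=float))
            else:
                parts.append(np.array([e.mean_amplitude]))
        else:
            parts.append(np.array([float(e)]))
    amps = np.concatenate(parts)
    idx = _round_half_away(amps / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    hist = AllPointsHistogram(
        bin_centers=np.arange(lo, hi + 1) * bin_width, counts=counts, bin_width=bin_width
    )
    return fit_quantal_gaussians(hist, n_components=n_components, q_init=q_init, fit_closed_peak=False)


def sparklet_density(sites: list, footprint_area: float) -> float:
    """Active sparklet sites per um^2 of imaged footprint."""
    if footprint_area <= 0:
        raise ValueError("footprint_area must be positive")
    active = sum(1 for s in sites if len(s.events) > 0)
    return active / footprint_area


def convert_f_to_nm(
    f_trace: np.ndarray | CalciumTrace,
    calibration: dict,
    dt: float | None = None,
) -> CalciumTrace:
    """Convert a fluorescence trace (AU) to [Ca2+]i in nM.

    ``calibration['mode']`` selects:

    * ``linear``: [Ca] = scale * (F - f_rest) + rest_nm
    * ``saturating``: [Ca] = K_d (F - f_min) / (f_max - F), the standard
      single-wavelength indicator equation; F >= f_max is out of the
      indicator's range and raises.
    """
    if isinstance(f_trace, CalciumTrace):
        f, dt = f_trace.values, f_trace.dt
    else:
        f = np.asarray(f_trace, dtype=float)
        if dt is None:
            raise ValueError("dt required when passing a bare array")
    mode = calibration.get("mode")
    if mode == "linear":
        missing = {"scale", "f_rest", "rest_nm"} - set(calibration)
        if missing:
            raise ValueError(f"linear calibration missing parameters: {sorted(missing)}")
        ca = calibration["scale"] * (f - calibration["f_rest"]) + calibration["rest_nm"]
    elif mode == "saturating":
        missing = {"kd", "f_min", "f_max"} - set(calibration)
        if missing:
            raise ValueError(f"saturating calibration missing parameters: {sorted(missing)}")
        f_min, f_max, kd = calibration["f_min"], calibration["f_max"], calibration["kd"]
        if np.any(f >= f_max):
            raise ValueError("fluorescence at or above f_max; indicator saturated")
        ca = kd * (f - f_min) / (f_max - f)
    else:
        raise ValueError(f"calibration mode must be 'linear' or 'saturating', got {mode!r}")
    return CalciumTrace(values=ca, dt=dt)
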