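"""Macroscopic (whole-cell) current metrics.

Conductance transform and Boltzmann activation fits, calcium-dependent
inactivation metrics (r300, f300, percent inactivation), single-exponential
activation time constants, and voltage dependence of reconstituted-
fluorophore fluorescence (F/F0 versus voltage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .traces import CurrentTrace

__all__ = [
    "GVCurve",
    "BoltzmannFit",
    "CDIMetrics",
    "FVCurve",
    "conductance_curve",
    "fit_boltzmann",
    "cdi_metrics",
    "fit_activation_tau",
    "fluorescence_voltage_relation",
]


class FitError(RuntimeError):
    def __init__(self, message: str, residual: float = float("nan")):
        super().__init__(message)
        self.residual = residual


@dataclass
class GVCurve:
    """Normalized conductance versus test potential."""

    v: np.ndarray  # mV
    g_norm: np.ndarray  # G / G_max

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.g_norm = np.asarray(self.g_norm, dtype=float)


@dataclass
class BoltzmannFit:
    v_half: float  # mV
    slope_k: float  # mV
    g_max: float = 1.0

    def model(self, v: np.ndarray) -> np.ndarray:
        return self.g_max / (1.0 + np.exp((self.v_half - np.asarray(v)) / self.slope_k))


@dataclass
class CDIMetrics:
    """Calcium-dependent inactivation summary of paired Ca/Ba traces.

    ``r300`` is the fraction of peak current remaining at the evaluation
    time; ``f300 = r300(Ba) - r300(Ca)`` so that stronger CDI gives a more
    positive f300. Percent-inactivation values refer to the Ca2+ trace.
    """

    r300_ca: float
    r300_ba: float
    f300: float
    pct_inact_25: float
    pct_inact_300: float


@dataclass
class FVCurve:
    """Fluorescence (relative to the holding-potential value) vs voltage."""

    v: np.ndarray
    f_over_f0: np.ndarray


def conductance_curve(iv, e_rev: float) -> GVCurve:
    """G = I / (V - E_rev), normalized to its maximum magnitude.

    ``iv`` is a sequence of (v_mV, i_pA) pairs. Points at V = E_rev have no
    driving force and are excluded with a warning.
    """
    iv = np.asarray(iv, dtype=float)
    if iv.ndim != 2 or iv.shape[1] != 2:
        raise ValueError("iv must be a sequence of (v, i) pairs")
    v, i = iv[:, 0], iv[:, 1]
    keep = v != e_rev
    if not np.all(keep):
        warnings.warn("excluding I-V point(s) at the reversal potential")
    v, i = v[keep], i[keep]
    if v.size == 0:
        raise ValueError("no usable I-V points")
    g = i / (v - e_rev)
    gmax = np.max(np.abs(g))
    if gmax == 0:
        raise ValueError("all conductances are zero")
    return GVCurve(v=v, g_norm=g / gmax)


def fit_boltzmann(gv: GVCurve) -> BoltzmannFit:
    """Least-squares Boltzmann fit g = 1 / (1 + exp((v_half - v)/k)).

    Seeds v_half at the voltage whose g is closest to 0.5 and k at 8 mV.
    Saturated curves (no point below g = 0.8) do not constrain the
    transition and raise :class:`FitError`.
    """
    v, g = gv.v, gv.g_norm
    if v.size < 4:
        raise ValueError("need >= 4 points to fit a Boltzmann")
    if g.min() > 0.8:
        raise FitError("curve is saturated (all g close to 1); transition not sampled")
    v0 = float(v[np.argmin(np.abs(g - 0.5))])

    def model(v, vh, k):
        return 1.0 / (1.0 + np.exp((vh - v) / k))

    try:
        popt, _ = optimize.curve_fit(model, v, g, p0=[v0, 8.0], maxfev=10000)
    except RuntimeError as e:
        raise FitError(f"Boltzmann fit did not converge: {e}") from e
    resid = float(np.sum((model(v, *popt) - g) ** 2))
    if popt[1] <= 0:
        raise FitError("fitted slope factor is nonpositive", resid)
    return BoltzmannFit(v_half=float(popt[0]), slope_k=float(popt[1]))


def _peak_and_value_at(trace: CurrentTrace, t_ms: float) -> tuple[float, float]:
    """(|peak|, |I(t_ms)|) using a 5-sample moving mean against noise spikes."""
    sm = ndimage.uniform_filter1d(trace.values, size=5)
    peak = float(np.max(np.abs(sm)))
    if peak == 0:
        raise ValueError("trace peak is zero")
    idx = int(round(t_ms * 1e-3 / trace.dt))
    if idx >= len(trace):
        raise ValueError(f"trace shorter than {t_ms} ms")
    return peak, float(abs(sm[idx]))


def cdi_metrics(trace_ca: CurrentTrace, trace_ba: CurrentTrace, t_eval: float = 300.0) -> CDIMetrics:
    """r300, f300 and percent inactivation from paired Ca2+/Ba2+ traces.

    Depolarization onset is assumed at t = 0. Ratios use absolute currents.
    """
    peak_ca, at_ca = _peak_and_value_at(trace_ca, t_eval)
    peak_ba, at_ba = _peak_and_value_at(trace_ba, t_eval)
    r_ca = at_ca / peak_ca
    r_ba = at_ba / peak_ba
    _, at25 = _peak_and_value_at(trace_ca, 25.0)
    return CDIMetrics(
        r300_ca=r_ca,
        r300_ba=r_ba,
        f300=r_ba - r_ca,
        pct_inact_25=100.0 * (1.0 - at25 / peak_ca),
        pct_inact_300=100.0 * (1.0 - r_ca),
    )


def fit_activation_tau(trace: CurrentTrace) -> float:
    """Activation time constant (ms) from a single-exponential fit.

    Fits ``I(t) = I_max (1 - exp(-t/tau))`` from the depolarization onset
    (t = 0) to the smoothed current peak. A monotone-decaying trace has no
    activation phase and raises :class:`FitError`.
    """
    sm = ndimage.uniform_filter1d(trace.values, size=5)
    peak_idx = int(np.argmax(np.abs(sm)))
    if peak_idx < 3:
        raise FitError("no resolvable activation phase (trace peaks at onset)")
    t = trace.time[: peak_idx + 1] * 1e3  # ms
    y = trace.values[: peak_idx + 1]

    i_max0 = trace.values[peak_idx]
    # seed tau at the time to reach 63% of peak
    reach = np.nonzero(np.abs(y) >= 0.632 * abs(i_max0))[0]
    tau0 = float(t[reach[0]]) if reach.size else float(t[-1] / 3.0)
    tau0 = max(tau0, t[1] if t.size > 1 else 0.01)

    def model(t, i_max, tau):
        return i_max * (1.0 - np.exp(-t / tau))

    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=[i_max0, tau0], maxfev=10000)
    except RuntimeError as e:
        raise FitError(f"activation fit did not converge: {e}") from e
    tau = float(popt[1])
    if tau <= 0:
        raise FitError("fitted tau is nonpositive")
    return tau


def fluorescence_voltage_relation(
    stacks,
    baseline_voltage: float = -80.0,
    mask: np.ndarray | None = None,
    n_last: int = 10,
) -> FVCurve:
    """F/F0 versus voltage from per-voltage image stacks.

    ``stacks`` maps voltage (mV) to an image stack (frames, h, w). For each
    voltage the last ``n_last`` frames are averaged and summed over the cell
    mask (whole frame if no mask); values are divided by the
    baseline-voltage value, so F/F0 at the baseline voltage is 1.
    """
    stacks = dict(stacks)
    if baseline_voltage not in stacks:
        raise ValueError(f"missing baseline stack at {baseline_voltage} mV")
    totals = {}
    for v, stack in stacks.items():
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 3 or stack.shape[0] < n_last:
            raise ValueError(f"stack at {v} mV must have >= {n_last} frames")
        img = stack[-n_last:].mean(axis=0)
        totals[v] = float(img[mask].sum()) if mask is not None else float(img.sum())
    f0 = totals[baseline_voltage]
    if f0 == 0:
        raise ValueError("baseline fluorescence is zero")
    volts = np.array(sorted(totals))
    return FVCurve(v=volts, f_over_f0=np.array([totals[v] / f0 for v in volts]))
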