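"""Quantal analysis of single-channel current records.

All-points amplitude histograms pooled over sweeps are fitted with a
multi-Gaussian quantal function

    N(i) = sum_{j=1..n} a_j * exp( -(i - j q)^2 / (2 j b) )

where q is the quantal (elementary) current and the variance of the j-th
open level is j*b — level-proportional broadening, as expected when open
levels superpose independent noise. The closed (j = 0) peak is excluded from
the quantal sum and fitted separately as a baseline Gaussian that is part of
the least-squares model but not of the reported quantal parameters.

Sign convention: inward currents are negative everywhere, so q is reported
negative for inward unitary currents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize as lm_minimize
from scipy import ndimage, signal

from .coupling import OccupancyTrace, _round_half_away
from .traces import CurrentTrace, SweepSet

__all__ = [
    "AllPointsHistogram",
    "QuantalFit",
    "NpoEstimate",
    "all_points_histogram",
    "fit_quantal_gaussians",
    "idealize_sweeps",
    "ensemble_average",
    "estimate_npo",
    "fold_change_npo",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, residual: float = float("nan")):
        super().__init__(message)
        self.residual = residual


@dataclass
class AllPointsHistogram:
    """Histogram of every sample of every sweep; one bin centered at 0 pA."""

    bin_centers: np.ndarray
    counts: np.ndarray
    bin_width: float

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_centers.shape != self.counts.shape:
            raise ValueError("bin_centers and counts must have the same shape")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class QuantalFit:
    """Parameters of the multi-Gaussian quantal fit."""

    q: float  # quantal unit, signed (pA or nM)
    b: float  # width parameter; level-j variance is j*b
    a: np.ndarray  # component amplitudes a_1..a_n
    n_components: int
    residual: float  # sum of squared residuals
    closed_amplitude: float = 0.0
    closed_sigma: float = float("nan")

    def model(self, x: np.ndarray, include_closed: bool = True) -> np.ndarray:
        """Evaluate the fitted curve at amplitudes ``x``."""
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x)
        for j in range(1, self.n_components + 1):
            y += self.a[j - 1] * np.exp(-((x - j * self.q) ** 2) / (2.0 * j * self.b))
        if include_closed and self.closed_amplitude > 0:
            y += self.closed_amplitude * np.exp(-(x**2) / (2.0 * self.closed_sigma**2))
        return y


@dataclass
class NpoEstimate:
    """NPo inferred from macroscopic over unitary current."""

    npo: float
    i_unitary: float
    i_macroscopic: float


def all_points_histogram(sweeps: SweepSet | np.ndarray, bin_width: float = 0.02) -> AllPointsHistogram:
    """Pool every sample of every sweep into amplitude bins.

    Bins are aligned so that one bin center sits exactly at 0 pA; total
    counts equal the total number of samples.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    data = sweeps.sweeps if isinstance(sweeps, SweepSet) else np.asarray(sweeps, dtype=float)
    x = np.ravel(data)
    if x.size == 0:
        raise ValueError("empty sweep set")
    idx = _round_half_away(x / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    centers = np.arange(lo, hi + 1) * bin_width
    return AllPointsHistogram(bin_centers=centers, counts=counts, bin_width=bin_width)


def _auto_q_init(hist: AllPointsHistogram) -> float:
    """Location of the largest histogram peak away from the closed (0) peak."""
    c = np.asarray(hist.counts, dtype=float)
    smooth = ndimage.uniform_filter1d(c, size=3)
    peaks, _ = signal.find_peaks(smooth)
    exclude = np.abs(hist.bin_centers) < 4 * hist.bin_width
    peaks = [p for p in peaks if not exclude[p]]
    if not peaks:
        # fall back to the center of mass of the off-zero mass
        mass = np.where(exclude, 0.0, c)
        if mass.sum() == 0:
            raise FitError("histogram has no mass away from zero; cannot seed q")
        return float(np.sum(hist.bin_centers * mass) / mass.sum())
    best = max(peaks, key=lambda p: smooth[p])
    return float(hist.bin_centers[best])


def _quantal_residual(params, x, y, n_components, fit_closed):
    q = params["q"].value
    b = params["b"].value
    model = np.zeros_like(x)
    for j in range(1, n_components + 1):
        model += params[f"a{j}"].value * np.exp(-((x - j * q) ** 2) / (2.0 * j * b))
    if fit_closed:
        model += params["a0"].value * np.exp(-(x**2) / (2.0 * params["c0"].value))
    return model - y


def fit_quantal_gaussians(
    hist: AllPointsHistogram,
    n_components: int = 2,
    q_init: float | str = "auto",
    fit_closed_peak: bool = True,
) -> QuantalFit:
    """Least-squares fit of the multi-Gaussian quantal function.

    ``q_init='auto'`` seeds q at the largest non-zero-centered histogram
    peak. Three starts (q_init scaled by 0.5, 1, 2) are tried and the best
    solution kept; failure of all starts raises :class:`FitError` carrying
    the best residual seen. Component amplitudes are constrained >= 0.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x = hist.bin_centers
    y = np.asarray(hist.counts, dtype=float)
    occupied = int(np.count_nonzero(y))
    if occupied < 5 * n_components:
        raise ValueError(
            f"need >= {5 * n_components} occupied bins for {n_components} components, have {occupied}"
        )
    q0 = _auto_q_init(hist) if q_init == "auto" else float(q_init)
    if q0 == 0:
        raise ValueError("q_init must be nonzero")

    candidates = []
    best_resid = np.inf
    for scale in (1.0, 0.5, 2.0):
        qs = q0 * scale
        params = Parameters()
        params.add("q", value=qs, min=min(0.0, 3 * qs), max=max(0.0, 3 * qs))
        params.add("b", value=(qs / 3.0) ** 2, min=1e-12)
        near = np.abs(x[None, :] - qs * np.arange(1, n_components + 1)[:, None]) < abs(qs) / 2
        for j in range(1, n_components + 1):
            a0j = float(y[near[j - 1]].max()) if near[j - 1].any() else float(y.max()) / (10 * j)
            params.add(f"a{j}", value=max(a0j, 1e-3), min=0.0)
        if fit_closed_peak:
            params.add("a0", value=float(y[np.abs(x) < abs(qs) / 2].max(initial=y.max())), min=0.0)
            params.add("c0", value=(qs / 3.0) ** 2, min=1e-12)
        try:
            out = lm_minimize(
                _quantal_residual, params, args=(x, y, n_components, fit_closed_peak),
                method="least_squares",
            )
        except Exception:
            continue
        resid = float(np.sum(out.residual**2))
        if out.success:
            candidates.append((resid, out))
            best_resid = min(best_resid, resid)
    if not candidates:
        raise FitError("quantal fit failed to converge from all starts", best_resid)
    # A quantal sum is degenerate under q -> q/m (the true peak moves to
    # component m and component 1 empties), so near-ties in residual are
    # broken toward the largest |q|: the solution that uses component 1.
    close = [c for c in candidates if c[0] <= best_resid * 1.05 + 1e-12]
    best = max(close, key=lambda c: abs(c[1].params["q"].value))[1]
    best_resid = float(np.sum(best.residual**2))

    p = best.params
    return QuantalFit(
        q=float(p["q"].value),
        b=float(p["b"].value),
        a=np.array([p[f"a{j}"].value for j in range(1, n_components + 1)]),
        n_components=n_components,
        residual=best_resid,
        closed_amplitude=float(p["a0"].value) if fit_closed_peak else 0.0,
        closed_sigma=float(np.sqrt(p["c0"].value)) if fit_closed_peak else float("nan"),
    )


def idealize_sweeps(
    sweeps: SweepSet,
    q: float,
    k_max: int | None = None,
    median_prefilter: bool = False,
) -> list[OccupancyTrace]:
    """Half-amplitude idealization: k_t = clamp(round(x_t / q), 0, k_max)."""
    if q == 0:
        raise ValueError("q must be nonzero")
    out = []
    for row in sweeps.sweeps:
        x = signal.medfilt(row, kernel_size=3) if median_prefilter else row
        k = _round_half_away(x / q).astype(int)
        hi = k_max if k_max is not None else max(int(k.max(initial=0)), 0)
        k = np.clip(k, 0, hi)
        out.append(OccupancyTrace(k=k, dt=sweeps.dt, n_channels=hi if hi > 0 else None))
    return out


def ensemble_average(sweeps: SweepSet) -> CurrentTrace:
    """Pointwise mean current across sweeps."""
    return CurrentTrace(values=sweeps.sweeps.mean(axis=0), dt=sweeps.dt)


def estimate_npo(i_macroscopic: float, i_unitary: float) -> NpoEstimate:
    """NPo = |I| / |i| from whole-cell and unitary current amplitudes."""
    if i_unitary == 0:
        raise ValueError("unitary current must be nonzero")
    if i_macroscopic * i_unitary < 0:
        warnings.warn("macroscopic and unitary currents have opposite signs")
    return NpoEstimate(
        npo=abs(i_macroscopic) / abs(i_unitary),
        i_unitary=i_unitary,
        i_macroscopic=i_macroscopic,
    )


def fold_change_npo(
    i_ca_macro: float,
    i_ba_macro: float,
    i_unit_ca: float = -0.16,
    i_unit_ba: float = -0.24,
) -> float:
    """Ratio of NPo with Ca2+ over NPo with Ba2+ as charge carrier.

    Defaults use unitary L-type currents of -0.16 pA (2 mM Ca2+) and
    -0.24 pA (2 mM Ba2+) at -10 mV.
    """
    npo_ca = estimate_npo(i_ca_macro, i_unit_ca).npo
    npo_ba = estimate_npo(i_ba_macro, i_unit_ba).npo
    if npo_ba == 0:
        raise ValueError("Ba2+ NPo is zero; fold change undefined")
    return npo_ca / npo_ba
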