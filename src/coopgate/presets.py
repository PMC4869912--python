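"""Named presets anchoring the synthetic generators to measured constants.

The preset registry pins the generators to the experimental operating points
of the system they emulate: CaV1.3 short (S) and long (L) splice-variant
channels recorded in tsA-201 cells and hippocampal neurons.

* Single-channel unitary currents at -30 mV: -0.49 pA (S) / -0.48 pA (L)
  with 20 mM Ca2+, -1.10 pA (S) / -1.14 pA (L) with 20 mM Ba2+.
* Sparklet quantal amplitude: 38 nM [Ca2+]i per open channel, imaged at
  100 Hz.
* Coupling coefficients: kappa = 0.21 for CaV1.3S sparklet sites, 0.08 for
  CaV1.3L, 0 for the explicit independent-gating control.
* Whole-cell activation time constants at -10 mV: 1.17 ms (S), 1.60 ms (L);
  reversal potentials +54 mV (2 mM Ca2+) / +65 mV (2 mM Ba2+) for CaV1.3S.

Gating rates that no measurement pins down (per-frame open/close
probabilities) are package choices documented in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "GatingPreset",
    "SignalPreset",
    "BleachPreset",
    "EmitterCloudPreset",
    "WholeCellPreset",
    "GATING_PRESETS",
    "SIGNAL_PRESETS",
    "WHOLECELL_PRESETS",
    "get_gating_preset",
    "get_signal_preset",
    "get_wholecell_preset",
]


class PresetError(ValueError):
    """A preset field is out of its valid range."""


@dataclass(frozen=True)
class GatingPreset:
    """Coupled-Markov gating parameters for one site."""

    name: str
    n_channels: int
    p_open: float
    p_close: float
    kappa: float

    def __post_init__(self):
        if self.n_channels < 1:
            raise PresetError(f"n_channels must be >= 1, got {self.n_channels}")
        for f in ("p_open", "p_close"):
            p = getattr(self, f)
            if not 0.0 < p < 1.0:
                raise PresetError(f"{f} must be strictly inside (0, 1), got {p}")
        object.__setattr__(self, "kappa", float(min(1.0, max(0.0, self.kappa))))


@dataclass(frozen=True)
class SignalPreset:
    """How occupancy maps to an observed signal."""

    name: str
    quantal_amplitude: float  # signal units per open channel (nM or pA)
    baseline: float  # signal units
    noise_sd: float  # signal units
    dt: float  # seconds per frame

    def __post_init__(self):
        if self.quantal_amplitude == 0:
            raise PresetError("quantal_amplitude must be nonzero")
        if self.noise_sd < 0:
            raise PresetError("noise_sd must be >= 0")
        if self.dt <= 0:
            raise PresetError("dt must be positive")


@dataclass(frozen=True)
class BleachPreset:
    """Photobleaching staircase parameters for one spot population."""

    name: str
    n_fluorophores: int | tuple  # count, or discrete distribution {count: prob}
    step_amplitude: float  # AU lost per bleach
    bleach_rate: float  # per-frame bleach hazard
    noise_sd: float  # AU
    n_frames: int

    def __post_init__(self):
        if isinstance(self.n_fluorophores, int) and self.n_fluorophores < 0:
            raise PresetError("n_fluorophores must be >= 0")
        if not 0.0 < self.bleach_rate <= 1.0:
            raise PresetError("bleach_rate hazard must lie in (0, 1]")
        if self.noise_sd < 0:
            raise PresetError("noise_sd must be >= 0")
        if self.n_frames < 1:
            raise PresetError("n_frames must be >= 1")


@dataclass(frozen=True)
class EmitterCloudPreset:
    """Clustered 2-D emitter field for localization-microscopy synthesis."""

    name: str
    n_clusters: int
    channels_per_cluster: dict  # {"kind": "poisson"|"fixed", ...}
    cluster_radius: float  # nm
    localizations_per_fluorophore: dict
    photons_per_localization: dict  # {"kind": "lognormal"|"fixed", ...}
    dlr: float  # diffraction-limited resolution, nm
    field_size: tuple[float, float]  # nm x nm

    def __post_init__(self):
        if self.n_clusters < 0:
            raise PresetError("n_clusters must be >= 0")
        if self.dlr <= 0:
            raise PresetError("dlr must be positive")
        if self.cluster_radius < 0:
            raise PresetError("cluster_radius must be >= 0")


@dataclass(frozen=True)
class WholeCellPreset:
    """Macroscopic current waveform parameters."""

    name: str
    g_max: float  # nS
    v: float  # mV
    e_rev: float  # mV
    tau_act: float  # ms
    tau_inact: float  # ms (math.inf = non-inactivating)

    def __post_init__(self):
        if self.tau_act <= 0 or self.tau_inact <= 0:
            raise PresetError("time constants must be positive")


# Per-frame gating probabilities below are chosen so that sparklet sites are
# quiet most of the time with openings lasting a few frames (tens of ms at
# 100 Hz), and single-channel sweeps have a stationary open probability of
# 0.3 as under dihydropyridine-agonist recording conditions.
GATING_PRESETS: dict[str, GatingPreset] = {
    p.name: p
    for p in [
        GatingPreset("cav13s_sparklet", n_channels=2, p_open=0.05, p_close=0.30, kappa=0.21),
        GatingPreset("cav13l_sparklet", n_channels=2, p_open=0.03, p_close=0.35, kappa=0.08),
        GatingPreset("uncoupled_sparklet", n_channels=2, p_open=0.05, p_close=0.30, kappa=0.0),
        GatingPreset("neuron_rest", n_channels=3, p_open=0.02, p_close=0.35, kappa=0.15),
        GatingPreset("neuron_depolarized", n_channels=3, p_open=0.06, p_close=0.35, kappa=0.43),
        GatingPreset("single_channel_po30", n_channels=1, p_open=0.06, p_close=0.14, kappa=0.0),
    ]
}

SIGNAL_PRESETS: dict[str, SignalPreset] = {
    p.name: p
    for p in [
        # Sparklet fluorescence, 100 Hz imaging, 38 nM per open channel.
        SignalPreset("sparklet_default", quantal_amplitude=38.0, baseline=100.0, noise_sd=8.0, dt=0.01),
        # Cell-attached single-channel currents at -30 mV, 10 kHz sampling.
        SignalPreset("cav13s_ca_m30", quantal_amplitude=-0.49, baseline=0.0, noise_sd=0.15, dt=1e-4),
        SignalPreset("cav13l_ca_m30", quantal_amplitude=-0.48, baseline=0.0, noise_sd=0.15, dt=1e-4),
        SignalPreset("cav13s_ba_m30", quantal_amplitude=-1.10, baseline=0.0, noise_sd=0.20, dt=1e-4),
        SignalPreset("cav13l_ba_m30", quantal_amplitude=-1.14, baseline=0.0, noise_sd=0.20, dt=1e-4),
    ]
}

WHOLECELL_PRESETS: dict[str, WholeCellPreset] = {
    p.name: p
    for p in [
        # Activation calibration presets: non-inactivating so the rising
        # phase is a pure saturating exponential.
        WholeCellPreset("cav13s_act", g_max=5.0, v=-10.0, e_rev=54.0, tau_act=1.17, tau_inact=math.inf),
        WholeCellPreset("cav13l_act", g_max=5.0, v=-10.0, e_rev=51.0, tau_act=1.60, tau_inact=math.inf),
        # CDI-style waveforms (Ca2+ inactivates much faster than Ba2+).
        WholeCellPreset("cav13s_cdi_ca", g_max=5.0, v=-10.0, e_rev=54.0, tau_act=1.17, tau_inact=60.0),
        WholeCellPreset("cav13s_cdi_ba", g_max=5.0, v=-10.0, e_rev=65.0, tau_act=1.17, tau_inact=600.0),
    ]
}


def _lookup(table: dict, name: str, kind: str):
    try:
        return table[name]
    except KeyError:
        known = ", ".join(sorted(table))
        raise PresetError(f"unknown {kind} preset {name!r}; known presets: {known}") from None


def get_gating_preset(name: str, **overrides) -> GatingPreset:
    p = _lookup(GATING_PRESETS, name, "gating")
    return replace(p, **overrides) if overrides else p


def get_signal_preset(name: str, **overrides) -> SignalPreset:
    p = _lookup(SIGNAL_PRESETS, name, "signal")
    return replace(p, **overrides) if overrides else p


def get_wholecell_preset(name: str, **overrides) -> WholeCellPreset:
    p = _lookup(WHOLECELL_PRESETS, name, "whole-cell")
    return replace(p, **overrides) if overrides else p
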