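"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator returns both the observable (trace, sweep set, image stack,
localization table) and the ground truth needed to score downstream
recovery: hidden occupancy paths, bleach-step counts and frames, true
emitter positions. All randomness flows from one integer seed through named
substreams (see :mod:`coopgate._rng`), so results are bit-reproducible and
adding one generator call to a script does not perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .coupling import CoupledGatingModel, OccupancyTrace, simulate_occupancy
from .presets import (
    BleachPreset,
    EmitterCloudPreset,
    GatingPreset,
    SignalPreset,
    WholeCellPreset,
)
from .traces import CalciumTrace, CurrentTrace, SweepSet

__all__ = [
    "make_sparklet_trace",
    "make_single_channel_sweeps",
    "make_whole_cell_trace",
    "make_bleach_stack",
    "make_localizations",
    "LocalizationSet",
    "BleachGroundTruth",
]


def _gating_model(gating: GatingPreset) -> CoupledGatingModel:
    return CoupledGatingModel(gating.n_channels, gating.p_open, gating.p_close, gating.kappa)


def make_sparklet_trace(
    gating: GatingPreset,
    signal: SignalPreset,
    n_frames: int,
    seed: int,
    init: int | str = "stationary",
) -> tuple[CalciumTrace, OccupancyTrace]:
    """Simulate one sparklet site: [Ca2+]i trace plus hidden occupancy.

    Frame t reads ``baseline + quantal_amplitude * k_t + N(0, noise_sd)``
    where k_t follows the coupled Markov chain of the gating preset.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng_gate = substream(seed, f"sparklet-gating/{gating.name}")
    rng_noise = substream(seed, f"sparklet-noise/{signal.name}")
    occ = simulate_occupancy(_gating_model(gating), n_frames, rng_gate, init=init)
    occ.dt = signal.dt
    values = signal.baseline + signal.quantal_amplitude * occ.k.astype(float)
    if signal.noise_sd > 0:
        values = values + rng_noise.normal(0.0, signal.noise_sd, size=n_frames)
    trace = CalciumTrace(values=values, dt=signal.dt, site_id=f"{gating.name}:{seed}")
    return trace, occ


def make_single_channel_sweeps(
    gating: GatingPreset,
    signal: SignalPreset,
    n_sweeps: int,
    sweep_frames: int,
    seed: int,
) -> tuple[SweepSet, list[OccupancyTrace]]:
    """Simulate repeated cell-attached sweeps from one patch.

    Each sweep is ``baseline + i_unitary * k_t + noise`` with its own
    occupancy path; the unitary current is the signal preset's quantal
    amplitude. Ground-truth occupancy is returned per sweep.
    """
    if sweep_frames < 2:
        raise ValueError("sweep_frames must be >= 2")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    model = _gating_model(gating)
    rng_gate = substream(seed, f"sweep-gating/{gating.name}")
    rng_noise = substream(seed, f"sweep-noise/{signal.name}")
    sweeps = np.empty((n_sweeps, sweep_frames))
    occs = []
    for s in range(n_sweeps):
        occ = simulate_occupancy(model, sweep_frames, rng_gate, init="stationary")
        occ.dt = signal.dt
        occs.append(occ)
        sweeps[s] = signal.baseline + signal.quantal_amplitude * occ.k
    if signal.noise_sd > 0:
        sweeps += rng_noise.normal(0.0, signal.noise_sd, size=sweeps.shape)
    return SweepSet(sweeps=sweeps, dt=signal.dt, voltage=-30.0), occs


def make_whole_cell_trace(
    g_max: float,
    v: float,
    e_rev: float,
    tau_act: float,
    tau_inact: float,
    duration: float = 300.0,
    dt: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CurrentTrace:
    """Macroscopic current for a step depolarization, in pA.

    ``I(t) = g_max (v - e_rev) (1 - exp(-t/tau_act)) exp(-t/tau_inact)``
    with conductance in nS, voltages in mV, times in ms. ``tau_inact`` may be
    ``math.inf`` for a non-inactivating current. The trace dt is stored in
    seconds.
    """
    if tau_act <= 0 or tau_inact <= 0:
        raise ValueError("time constants must be positive")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    act = 1.0 - np.exp(-t / tau_act)
    inact = np.exp(-t / tau_inact) if math.isfinite(tau_inact) else 1.0
    i = g_max * (v - e_rev) * act * inact
    if noise_sd > 0:
        i = i + substream(seed, "wholecell-noise").normal(0.0, noise_sd, size=t.size)
    return CurrentTrace(values=i, dt=dt * 1e-3)


def make_whole_cell_from_preset(
    preset: WholeCellPreset, duration: float = 300.0, dt: float = 0.05, noise_sd: float = 0.0, seed: int = 0
) -> CurrentTrace:
    return make_whole_cell_trace(
        preset.g_max, preset.v, preset.e_rev, preset.tau_act, preset.tau_inact,
        duration=duration, dt=dt, noise_sd=noise_sd, seed=seed,
    )


@dataclass
class BleachGroundTruth:
    """Planted truth for one photobleaching stack."""

    centers: np.ndarray  # (n_spots, 2) row, col
    n_steps: np.ndarray  # (n_spots,) fluorophores per spot
    bleach_frames: list  # per spot, sorted frames at which a fluorophore died


def _draw_count(rng: np.random.Generator, spec) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    if isinstance(spec, dict):
        kind = spec.get("kind", "categorical")
        if kind == "fixed":
            return int(spec["value"])
        if kind == "poisson":
            return int(rng.poisson(spec["mean"]))
        if kind == "categorical":
            values = np.asarray(spec["values"], dtype=int)
            probs = np.asarray(spec["probs"], dtype=float)
            return int(rng.choice(values, p=probs / probs.sum()))
    raise ValueError(f"unrecognized count distribution spec: {spec!r}")


def make_bleach_stack(
    preset: BleachPreset,
    n_spots: int,
    image_size: int = 64,
    seed: int = 0,
    spot_sigma: float = 1.2,
    background: float = 100.0,
    forced_bleach_frames: list | None = None,
    count_spec=None,
) -> tuple[np.ndarray, BleachGroundTruth]:
    """Render a TIRF photobleaching movie of Gaussian spots.

    Each spot's amplitude is ``step_amplitude`` times the number of its
    surviving fluorophores; bleach times are geometric per frame with the
    preset hazard (memoryless discrete analog of exponential survival).
    ``forced_bleach_frames`` overrides the random bleach times of every spot
    for deterministic tests. ``count_spec`` optionally draws per-spot
    fluorophore counts from a distribution spec instead of the preset's
    fixed count. Spots are placed on a jittered grid at least 8 px apart.
    """
    rng = substream(seed, f"bleach/{preset.name}")
    # grid placement, >= 8 px separation, 4 px margin
    pitch = 8
    margin = 4
    per_side = max((image_size - 2 * margin) // pitch, 1)
    if n_spots > per_side**2:
        raise ValueError(
            f"cannot place {n_spots} spots >= {pitch} px apart in a {image_size} px field"
        )
    slots = [
        (margin + pitch // 2 + i * pitch, margin + pitch // 2 + j * pitch)
        for i in range(per_side)
        for j in range(per_side)
    ]
    centers = np.array([slots[i] for i in rng.permutation(len(slots))[:n_spots]])

    n_steps = np.empty(n_spots, dtype=int)
    bleach_frames = []
    amp = np.zeros((n_spots, preset.n_frames))
    for s in range(n_spots):
        if forced_bleach_frames is not None:
            frames = sorted(int(f) for f in forced_bleach_frames)
            count = len(frames)
        else:
            count = _draw_count(rng, count_spec if count_spec is not None else preset.n_fluorophores)
            frames = sorted(rng.geometric(preset.bleach_rate, size=count).tolist()) if count else []
        n_steps[s] = count
        bleach_frames.append(frames)
        alive = np.full(preset.n_frames, count, dtype=float)
        for f in frames:
            if f < preset.n_frames:
                alive[f:] -= 1.0
        amp[s] = preset.step_amplitude * alive

    yy, xx = np.mgrid[0:image_size, 0:image_size]
    stack = np.full((preset.n_frames, image_size, image_size), background)
    # Gaussian footprint of each spot, rendered once and scaled per frame.
    for s in range(n_spots):
        r0, c0 = centers[s]
        g = np.exp(-(((yy - r0) ** 2 + (xx - c0) ** 2) / (2.0 * spot_sigma**2)))
        stack += amp[s][:, None, None] * g[None, :, :]
    if preset.noise_sd > 0:
        stack += rng.normal(0.0, preset.noise_sd, size=stack.shape)
    return stack, BleachGroundTruth(centers=centers, n_steps=n_steps, bleach_frames=bleach_frames)


@dataclass
class LocalizationSet:
    """Single-molecule localization table (positions in nm)."""

    x: np.ndarray
    y: np.ndarray
    photons: np.ndarray
    frame: np.ndarray

    def __len__(self) -> int:
        return self.x.size


def _draw_photons(rng: np.random.Generator, spec, size: int) -> np.ndarray:
    kind = spec.get("kind", "lognormal")
    if kind == "fixed":
        return np.full(size, float(spec["value"]))
    if kind == "lognormal":
        # parameterized by the mean photon count and sigma of log-photons
        mean = float(spec.get("mean", 1900.0))
        sigma = float(spec.get("sigma", 0.4))
        mu = np.log(mean) - 0.5 * sigma**2
        return rng.lognormal(mu, sigma, size=size)
    raise ValueError(f"unrecognized photon distribution spec: {spec!r}")


def make_localizations(
    preset: EmitterCloudPreset, seed: int = 0
) -> tuple[LocalizationSet, np.ndarray]:
    """Simulate a clustered 2-D localization field.

    Cluster centers are uniform over the field (with a margin of one cluster
    radius); fluorophores scatter isotropically (Gaussian, SD =
    cluster_radius) around their center; each fluorophore yields a number of
    localizations, each displaced from the true position by an isotropic
    Gaussian error of SD ``dlr / sqrt(photons)`` with photons drawn per
    localization. Returns the table and the true cluster centers.
    """
    rng = substream(seed, f"localizations/{preset.name}")
    w, h = preset.field_size
    margin = max(preset.cluster_radius, 1.0)
    centers = np.column_stack([
        rng.uniform(margin, w - margin, size=preset.n_clusters),
        rng.uniform(margin, h - margin, size=preset.n_clusters),
    ])
    if preset.n_clusters >= 2:
        from scipy.spatial.distance import pdist

        if preset.n_clusters and pdist(centers).min() < 4 * preset.cluster_radius:
            import warnings

            warnings.warn("cluster centers closer than 4x cluster radius; clusters may merge")

    xs, ys, ph, fr = [], [], [], []
    frame_counter = 0
    for cx, cy in centers:
        n_fluor = _draw_count(rng, preset.channels_per_cluster)
        for _ in range(n_fluor):
            fx = cx + rng.normal(0.0, preset.cluster_radius)
            fy = cy + rng.normal(0.0, preset.cluster_radius)
            n_loc = _draw_count(rng, preset.localizations_per_fluorophore)
            if n_loc == 0:
                continue
            photons = _draw_photons(rng, preset.photons_per_localization, n_loc)
            sigma = preset.dlr / np.sqrt(photons)
            xs.append(fx + rng.normal(0.0, 1.0, n_loc) * sigma)
            ys.append(fy + rng.normal(0.0, 1.0, n_loc) * sigma)
            ph.append(photons)
            fr.append(np.arange(frame_counter, frame_counter + n_loc))
            frame_counter += n_loc
    if xs:
        locs = LocalizationSet(
            x=np.concatenate(xs), y=np.concatenate(ys),
            photons=np.concatenate(ph), frame=np.concatenate(fr),
        )
    else:
        empty = np.empty(0)
        locs = LocalizationSet(x=empty, y=empty.copy(), photons=empty.copy(), frame=np.empty(0, dtype=int))
    return locs, centers
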