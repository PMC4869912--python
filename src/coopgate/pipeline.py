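"""Pipeline orchestration: validated JSON configs, staged runs, summaries.

A run config is a JSON object with a top-level ``seed``, an ``outdir``, and
a ``stages`` list; each stage has a ``kind`` and stage-specific parameters.
Unknown top-level or stage keys are rejected before any computation so a
typo cannot silently change an analysis. Given the same config and seed the
result files are byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import stats as sstats

from . import coupling, io, sparklets, synthetic, wholecell
from .presets import get_gating_preset, get_signal_preset, get_wholecell_preset

__all__ = ["validate_config", "run_pipeline", "summarize", "ConfigError"]


class ConfigError(ValueError):
    """The run config failed schema validation; nothing was executed."""


_TOP_KEYS = {"seed", "outdir", "stages"}
_STAGE_SCHEMAS = {
    "simulate_sparklets": {"gating_preset", "signal_preset", "n_sites", "n_frames"},
    "kappa": {"n_channels", "q", "baseline", "noise_sd", "threshold"},
    "sparklet_activity": {"q", "baseline"},
    "cdi": {"ca_preset", "ba_preset", "duration_ms", "dt_ms", "t_eval_ms"},
}


def validate_config(config: dict) -> dict:
    """Check the config against the stage schemas; reject unknown keys."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a JSON object")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    for key in ("seed", "stages"):
        if key not in config:
            raise ConfigError(f"config missing required key {key!r}")
    if not isinstance(config["seed"], int):
        raise ConfigError("seed must be an integer")
    if not isinstance(config["stages"], list) or not config["stages"]:
        raise ConfigError("stages must be a non-empty list")
    for i, stage in enumerate(config["stages"]):
        if not isinstance(stage, dict) or "kind" not in stage:
            raise ConfigError(f"stage {i} must be an object with a 'kind'")
        kind = stage["kind"]
        if kind not in _STAGE_SCHEMAS:
            raise ConfigError(f"stage {i}: unknown kind {kind!r}")
        extra = set(stage) - _STAGE_SCHEMAS[kind] - {"kind"}
        if extra:
            raise ConfigError(f"stage {i} ({kind}): unknown keys {sorted(extra)}")
    return config


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute the configured stages in order; write deterministic outputs.

    Stages share state through the returned results dict: ``kappa`` and
    ``sparklet_activity`` operate on the traces produced by the most recent
    ``simulate_sparklets`` stage. Results are written to
    ``<outdir>/results.json``; a stage failure aborts with the stage name,
    preserving outputs of completed stages.
    """
    config = validate_config(config)
    seed = config["seed"]
    outdir = Path(outdir or config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)

    results: dict = {"seed": seed, "stages": []}
    traces: list = []
    for i, stage in enumerate(config["stages"]):
        kind = stage["kind"]
        try:
            if kind == "simulate_sparklets":
                gating = get_gating_preset(stage.get("gating_preset", "cav13s_sparklet"))
                sig = get_signal_preset(stage.get("signal_preset", "sparklet_default"))
                n_sites = stage.get("n_sites", 5)
                n_frames = stage.get("n_frames", 2000)
                traces = [
                    synthetic.make_sparklet_trace(gating, sig, n_frames, seed=seed + s)
                    for s in range(n_sites)
                ]
                out = {
                    "kind": kind,
                    "n_sites": n_sites,
                    "n_frames": n_frames,
                    "gating_preset": gating.name,
                    "signal_preset": sig.name,
                }
            elif kind == "kappa":
                if not traces:
                    raise RuntimeError("no simulated traces; add a simulate_sparklets stage first")
                sig_baseline = stage.get("baseline", 100.0)
                fits = [
                    coupling.estimate_kappa(
                        tr,
                        n_channels=stage.get("n_channels", 2),
                        q=stage.get("q", 38.0),
                        baseline=sig_baseline,
                        noise_sd=stage.get("noise_sd", 8.0),
                        threshold=stage.get("threshold", 0.1),
                    )
                    for tr, _ in traces
                ]
                out = {
                    "kind": kind,
                    "kappa_hat": [f.kappa_hat for f in fits],
                    "mean_kappa": float(np.mean([f.kappa_hat for f in fits])),
                    "n_coupled": int(sum(f.coupled for f in fits)),
                }
            elif kind == "sparklet_activity":
                if not traces:
                    raise RuntimeError("no simulated traces; add a simulate_sparklets stage first")
                sites = [
                    sparklets.site_nps(tr, q=stage.get("q", 38.0), baseline=stage.get("baseline", "auto"))
                    for tr, _ in traces
                ]
                out = {
                    "kind": kind,
                    "nps": [s.nps for s in sites],
                    "mean_nps": float(np.mean([s.nps for s in sites])),
                }
            elif kind == "cdi":
                ca = synthetic.make_whole_cell_from_preset(
                    get_wholecell_preset(stage.get("ca_preset", "cav13s_cdi_ca")),
                    duration=stage.get("duration_ms", 310.0),
                    dt=stage.get("dt_ms", 0.1),
                )
                ba = synthetic.make_whole_cell_from_preset(
                    get_wholecell_preset(stage.get("ba_preset", "cav13s_cdi_ba")),
                    duration=stage.get("duration_ms", 310.0),
                    dt=stage.get("dt_ms", 0.1),
                )
                m = wholecell.cdi_metrics(ca, ba, t_eval=stage.get("t_eval_ms", 300.0))
                out = {"kind": kind, **dataclasses.asdict(m)}
            results["stages"].append(out)
        except Exception as e:
            io.write_json(outdir / "results.json", results)
            raise RuntimeError(f"stage {i} ({kind}) failed: {e}") from e

    io.write_json(outdir / "results.json", results)
    return results


def summarize(groups: dict, paired: bool = False) -> dict:
    """Mean, SEM and n per group, plus a t-test when exactly two groups.

    Welch's t by default; ``paired=True`` uses the paired t-test and
    requires equal group lengths.
    """
    out = {}
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        out[name] = {
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(v.size)),
            "n": int(v.size),
        }
    if len(groups) == 2:
        (a_name, a), (b_name, b) = [(k, np.asarray(v, float)) for k, v in groups.items()]
        if paired:
            if a.size != b.size:
                raise ValueError("paired groups must have equal lengths")
            t, p = sstats.ttest_rel(a, b)
        else:
            t, p = sstats.ttest_ind(a, b, equal_var=False)
        out["comparison"] = {
            "groups": [a_name, b_name],
            "t": float(t),
            "p": float(p),
            "paired": paired,
        }
    return out
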