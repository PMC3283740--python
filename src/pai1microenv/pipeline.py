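"""Pipeline runner: validated configuration, staged execution, run manifest.

The configuration is a YAML/TOML-style mapping with sections ``grid``,
``rates``, ``switch``, ``ca``, ``abm``, ``synth``, ``stats`` and ``run``.
Unknown sections or keys are errors (silent typos in rate names would corrupt
simulation science), reported with their field path before anything runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .abm import ABMRates, run_abm
from .ca import CARates, run_ca
from .errors import ConfigurationError
from .io import save_field_tiff, save_field_txt, save_json, save_mask_png
from .lattice import Grid, ScalarField
from .spatial import (
    boundary_curvature,
    detect_spots,
    extract_periphery,
    heterogeneity_metrics,
    invagination_association,
)
from .switch import SwitchParams, bistable_window, sweep_hysteresis
from .synth import ShapeSpec, make_tumor_mask

SCHEMA_VERSION = 1

_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "run": {"stages": list, "seed": int, "schema_version": int},
    "grid": {"width": int, "height": int, "spacing": (int, float)},
    "rates": {
        "sigma": (int, float),
        "D": (int, float),
        "k_on": (int, float),
        "k_lat": (int, float),
        "p_div": (int, float),
        "k_int": (int, float),
        "k_prot": (int, float),
        "p_div_mes": (int, float),
        "integrity_threshold": (int, float),
        "speed_amoeboid": (int, float),
    },
    "switch": {
        "alpha_I": (int, float),
        "alpha_P": (int, float),
        "K": (int, float),
        "h": (int, float),
        "mu": (int, float),
        "noise_sd": (int, float),
    },
    "ca": {"checkpoints": list, "ticks": int, "step_cap": int},
    "abm": {
        "ticks": int,
        "snapshot_every": int,
        "initial_cells": int,
        "escape_distance": (int, float),
    },
    "synth": {
        "kind": str,
        "radius": int,
        "n_lobes": int,
        "lobe_depth": (int, float),
    },
    "stats": {"threshold": (int, float), "window": int},
    "hysteresis": {"c_max": (int, float), "rate": (int, float)},
}

_PROBABILITY_KEYS = {
    ("rates", "p_div"),
    ("rates", "p_div_mes"),
    ("rates", "integrity_threshold"),
}

_STAGES = ("synth", "ca", "abm", "hysteresis", "stats")


def validate_config(config: dict) -> dict:
    """Validate a configuration mapping against the schema.

    Raises :class:`ConfigurationError` naming the offending field path
    (e.g. ``[rates].p_div``). Returns the config unchanged.
    """
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping")
    for section, content in config.items():
        if section not in _SCHEMA:
            raise ConfigurationError(f"unknown config section [{section}]")
        if not isinstance(content, dict):
            raise ConfigurationError(f"section [{section}] must be a mapping")
        for key, value in content.items():
            if key not in _SCHEMA[section]:
                raise ConfigurationError(f"unknown key [{section}].{key}")
            expected = _SCHEMA[section][key]
            if not isinstance(value, expected) or isinstance(value, bool):
                raise ConfigurationError(
                    f"[{section}].{key} must be of type {expected}, got {value!r}"
                )
            if (section, key) in _PROBABILITY_KEYS and not 0 <= value <= 1:
                raise ConfigurationError(
                    f"[{section}].{key} must lie in [0, 1], got {value}"
                )
    stages = config.get("run", {}).get("stages", [])
    for s in stages:
        if s not in _STAGES:
            raise ConfigurationError(f"unknown stage {s!r} in [run].stages")
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def _grid_from(config: dict) -> Grid:
    g = config.get("grid", {})
    return Grid(g.get("width", 72), g.get("height", 72), g.get("spacing", 1.0))


def _ca_rates_from(config: dict) -> CARates:
    r = {k: v for k, v in config.get("rates", {}).items() if k in CARates.__dataclass_fields__}
    return CARates(**r)


def _abm_rates_from(config: dict) -> ABMRates:
    return ABMRates(**config.get("rates", {}))


def _switch_from(config: dict) -> SwitchParams:
    return SwitchParams(**config.get("switch", {}))


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    version: str
    stages: list[str]
    outputs: dict = field(default_factory=dict)
    status: str = "running"
    started: float = 0.0
    finished: float | None = None

    def to_dict(self) -> dict:
        return {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "outputs": self.outputs,
            "status": self.status,
            "started": self.started,
            "finished": self.finished,
        }


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> RunManifest:
    """Execute the configured stages in dependency order under ``out_dir``.

    The manifest is written before execution (status ``running``) and
    finalized after (status ``complete`` or ``failed``); any stage failure
    leaves a partial manifest and re-raises.
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else config.get("run", {}).get("seed", 0)
    stages = config.get("run", {}).get("stages", ["ca", "stats"])
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(digest, seed, __version__, list(stages), started=time.time())
    manifest_path = out / "manifest.json"
    save_json(manifest.to_dict(), manifest_path)

    state: dict = {}
    try:
        for stage in stages:
            stage_out = out / stage
            stage_out.mkdir(exist_ok=True)
            fn = _STAGE_FUNCS[stage]
            manifest.outputs[stage] = fn(config, state, stage_out, seed)
            save_json(manifest.to_dict(), manifest_path)
        manifest.status = "complete"
    except Exception:
        manifest.status = "failed"
        raise
    finally:
        manifest.finished = time.time()
        save_json(manifest.to_dict(), manifest_path)
    return manifest


def _stage_synth(config: dict, state: dict, out: Path, seed: int) -> dict:
    s = config.get("synth", {})
    spec = ShapeSpec(
        kind=s.get("kind", "disk"),
        radius=s.get("radius", 12),
        n_lobes=s.get("n_lobes", 0),
        lobe_depth=s.get("lobe_depth", 0.0),
        seed=seed,
    )
    mask, rec = make_tumor_mask(spec)
    save_mask_png(mask, out / "mask.png")
    save_json(rec.to_dict(), out / "mask.genrecord.json")
    state["mask"] = mask
    return {"mask": str(out / "mask.png"), "genrecord": str(out / "mask.genrecord.json")}


def _stage_ca(config: dict, state: dict, out: Path, seed: int) -> dict:
    rates = _ca_rates_from(config)
    ca_cfg = config.get("ca", {})
    kwargs: dict = {"step_cap": ca_cfg.get("step_cap", 20_000)}
    if "mask" in state:
        kwargs["initial_mask"] = state["mask"]
        kwargs["growth"] = "static"
        kwargs["ticks"] = ca_cfg.get("ticks", 200)
        kwargs["checkpoints"] = None
    else:
        kwargs["grid"] = _grid_from(config)
        kwargs["checkpoints"] = tuple(ca_cfg.get("checkpoints", [10, 100, 500]))
    res = run_ca(rates, seed=seed, **kwargs)
    paths = {}
    for cp in res.checkpoints:
        stem = out / f"bound_{cp.size:05d}"
        save_field_txt(cp.bound, stem.with_suffix(".tsv"))
        save_field_tiff(cp.bound, stem.with_suffix(".tif"))
        save_mask_png(cp.mask, out / f"mask_{cp.size:05d}.png")
        paths[f"checkpoint_{cp.size}"] = str(stem.with_suffix(".tsv"))
    final_bound = ScalarField(res.mask.grid, res.matrix.bound_active + res.matrix.bound_latent)
    save_field_txt(final_bound, out / "bound_final.tsv")
    save_mask_png(res.mask, out / "mask_final.png")
    save_json(res.summary, out / "summary.json")
    if res.log:
        import pandas as pd

        pd.DataFrame(res.log).to_csv(out / "steps.tsv", sep="\t", index=False)
    state["mask"], state["bound"] = res.mask, final_bound
    paths.update({"summary": str(out / "summary.json"), "bound_final": str(out / "bound_final.tsv")})
    return paths


def _stage_abm(config: dict, state: dict, out: Path, seed: int) -> dict:
    rates = _abm_rates_from(config)
    sparams = _switch_from(config)
    a = config.get("abm", {})
    res = run_abm(
        rates=rates,
        sparams=sparams,
        grid=_grid_from(config),
        initial_mask=state.get("mask"),
        ticks=a.get("ticks", 250),
        seed=seed,
        snapshot_every=a.get("snapshot_every"),
        initial_cells=a.get("initial_cells", 1),
        escape_distance=a.get("escape_distance", 3.0),
    )
    w = res.world
    bound = ScalarField(w.grid, w.matrix.bound_active + w.matrix.bound_latent)
    save_field_txt(bound, out / "bound_final.tsv")
    save_field_tiff(bound, out / "bound_final.tif")
    save_mask_png(w.mask, out / "mask_final.png")
    res.log.to_dataframe().to_csv(out / "events.tsv", sep="\t", index=False)
    save_json(res.summary, out / "summary.json")
    state["mask"], state["bound"] = w.mask, ScalarField(w.grid, w.matrix.bound_active)
    return {
        "summary": str(out / "summary.json"),
        "events": str(out / "events.tsv"),
        "bound_final": str(out / "bound_final.tsv"),
    }


def _stage_hysteresis(config: dict, state: dict, out: Path, seed: int) -> dict:
    sparams = _switch_from(config)
    h = config.get("hysteresis", {})
    loop = sweep_hysteresis(sparams, c_max=h.get("c_max", 4.0 * sparams.K), rate=h.get("rate"))
    lo, hi = bistable_window(sparams)
    np.savetxt(
        out / "loop.tsv",
        [(c, i, p, 1.0 if lab == "amoeboid" else 0.0) for c, i, p, lab in loop.loop_points],
        fmt="%.8g",
        delimiter="\t",
        header="C\tI\tP\tamoeboid",
    )
    summary = {
        "theta_up": loop.theta_up,
        "theta_down": loop.theta_down,
        "width": loop.width,
        "quasi_static": loop.quasi_static,
        "window_low": lo,
        "window_high": hi,
    }
    save_json(summary, out / "loop_summary.json")
    _plot_loop(loop, out / "loop.png")
    return {"loop": str(out / "loop.tsv"), "summary": str(out / "loop_summary.json")}


def _plot_loop(loop, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cs = [p[0] for p in loop.loop_points]
    labels = [1.0 if p[3] == "amoeboid" else 0.0 for p in loop.loop_points]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    half = len(cs) // 2
    ax.plot(cs[:half], labels[:half], "-", color="tab:red", label="up-sweep")
    ax.plot(cs[half:], labels[half:], "-", color="tab:blue", label="down-sweep")
    for x, name in ((loop.theta_up, r"$\theta_{up}$"), (loop.theta_down, r"$\theta_{down}$")):
        ax.axvline(x, ls=":", color="gray")
        ax.text(x, 0.5, name, rotation=90, va="center")
    ax.set_xlabel("matrix-bound active PAI-1 (a.u.)")
    ax.set_ylabel("state (0=mes, 1=amoe)")
    ax.legend(loc="center right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage_stats(config: dict, state: dict, out: Path, seed: int) -> dict:
    if "mask" not in state or "bound" not in state:
        raise ConfigurationError("stats stage requires a prior ca/abm (or synth+ca) stage")
    s = config.get("stats", {})
    prof = extract_periphery(state["mask"], state["bound"])
    boundary_curvature(prof, window=s.get("window", 5))
    spots = detect_spots(prof, s.get("threshold"))
    metrics = heterogeneity_metrics(prof, s.get("threshold"))
    assoc = invagination_association(prof, seed=seed)
    np.savetxt(
        out / "periphery.tsv",
        np.column_stack(
            [
                [p[0] for p in prof.boundary_sites],
                [p[1] for p in prof.boundary_sites],
                prof.concentration,
                prof.curvature,
            ]
        ),
        fmt="%.8g",
        delimiter="\t",
        header="row\tcol\tconcentration\tcurvature",
    )
    save_json(
        {
            "metrics": metrics,
            "association": assoc,
            "n_spots": len(spots.spots),
            "spot_fraction": spots.spot_fraction,
            "threshold": spots.threshold,
        },
        out / "stats.json",
    )
    return {"periphery": str(out / "periphery.tsv"), "stats": str(out / "stats.json")}


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "ca": _stage_ca,
    "abm": _stage_abm,
    "hysteresis": _stage_hysteresis,
    "stats": _stage_stats,
}
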