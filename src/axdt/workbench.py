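"""Reproducible experiment orchestration.

``run_experiment`` ties the library modules into a seeded, manifest-tracked
pipeline: scheme construction, the measurable-fraction sweep, phantom
generation, dark-field simulation, CGLS reconstruction, null-space probing
and scheme metrics.  Every run writes a ``manifest.json`` with the resolved
configuration, package versions and per-stage status, sufficient to
reproduce it exactly; numeric outputs are CSV/HDF5, plots are advisory
side products.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .forward_model import (
    Geometry,
    WeightModel,
    forward_darkfield,
    save_field,
    save_projections,
)
from .metrics import coverage_surrogate, experimental_metric, extract_orientations
from .phantom import add_noise, build_phantom, weldline_phantom
from .reconstruction import SolverConfig, cgls_solve, nullspace_component, probe_field
from .schemes import (
    SetupLimits,
    base_scheme,
    design_Z,
    legacy_W,
    measurable_fraction_sweep,
    sensitivity_from_alpha,
    truncate_scheme,
    write_scheme,
)
from .sphere import hemisphere, load_tdesign_56

__all__ = ["ExperimentConfig", "run_experiment", "GRATING_ALPHAS"]

log = logging.getLogger(__name__)

GRATING_ALPHAS = {"vertical": 0.0, "diagonal": 45.0, "horizontal": 90.0}

ALL_STAGES = ("scheme", "sweep", "phantom", "simulate", "reconstruct",
              "nullspace", "metrics")


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serializable description of one experiment run."""

    outdir: str = "axdt_run"
    seed: int = 0
    stages: tuple = ("scheme", "phantom", "simulate", "reconstruct", "metrics")
    design: str = "Z"              # Z | W | A
    grating: str = "diagonal"      # named alignment or numeric alpha (deg)
    N: int = 20
    psi_max: float = 40.0
    sweep_N: int = 20
    sweep_step_deg: float = 1.0
    phantom_preset: str = "weldline"
    vol_shape: tuple = (32, 32, 32)
    det_shape: tuple = (48, 48)
    noise_sigma: float = 0.0
    solver_iterations: int = 50
    nullspace_iterations: int = 1
    extraction_mode: str = "structure"

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @property
    def alpha(self) -> float:
        if self.grating in GRATING_ALPHAS:
            return GRATING_ALPHAS[self.grating]
        return float(self.grating)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("stages", "vol_shape", "det_shape"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _build_scheme(config: ExperimentConfig):
    S = sensitivity_from_alpha(config.alpha)
    if config.design == "Z":
        scheme = design_Z(hemisphere(load_tdesign_56()), S, config.N,
                          label=f"Z_{config.grating}")
    elif config.design == "W":
        scheme = legacy_W(config.N)
    elif config.design == "A":
        scheme = base_scheme(0.0, 0.0, config.N, S=S)
    else:
        raise ValueError(f"unknown design {config.design!r}")
    return truncate_scheme(scheme, SetupLimits(config.psi_max))


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Stage failures are recorded (status ``failed`` plus the error) without
    aborting independent later stages; stages whose inputs are missing
    report ``skipped`` with the missing stage named.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "axdt",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    state: dict = {}

    def run_stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.time()
        try:
            info = fn() or {}
            status = {"status": "ok", **info}
        except _MissingInput as exc:
            status = {"status": "skipped", "reason": str(exc)}
            log.warning("stage %s skipped: %s", name, exc)
        except Exception as exc:  # pragma: no cover - defensive reporting
            status = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            log.exception("stage %s failed", name)
        status["seconds"] = round(time.time() - t0, 3)
        manifest["stages"][name] = status
        log.info("stage %s: %s (%.2fs)", name, status["status"], status["seconds"])

    geometry = Geometry(tuple(config.vol_shape), 1.0, tuple(config.det_shape), 1.0)
    model = WeightModel()

    def stage_scheme():
        scheme = _build_scheme(config)
        state["scheme"] = scheme
        write_scheme(scheme, out / "scheme.csv")
        _plot_scheme(scheme, out / "scheme_sphere.png")
        return {"n_poses": len(scheme), "label": scheme.label}

    def stage_sweep():
        step = config.sweep_step_deg
        alphas = np.arange(0.0, 90.0 + step / 2, step)
        psi_maxes = np.arange(0.0, 90.0 + step / 2, step)
        fr = measurable_fraction_sweep(
            hemisphere(load_tdesign_56()), config.sweep_N, alphas, psi_maxes)
        header = ",".join(f"psi{p:g}" for p in psi_maxes)
        np.savetxt(out / "sweep.csv", fr, delimiter=",", header=header, comments="")
        _plot_sweep(alphas, psi_maxes, fr, out / "sweep.png")
        return {"shape": list(fr.shape)}

    def stage_phantom():
        if config.phantom_preset != "weldline":
            raise ValueError(f"unknown phantom preset {config.phantom_preset!r}")
        spec = weldline_phantom(seed=config.seed, shape=tuple(config.vol_shape))
        field, truth = build_phantom(spec)
        state["phantom"] = (field, truth)
        save_field(out / "phantom.h5", field)
        return {"shape": list(field.vol_shape)}

    def stage_simulate():
        _require(state, "scheme"), _require(state, "phantom")
        field, _ = state["phantom"]
        stack = forward_darkfield(field, state["scheme"], model, geometry)
        if config.noise_sigma > 0:
            stack = add_noise(stack, config.noise_sigma, config.seed)
        state["stack"] = stack
        save_projections(out / "projections.h5", stack)
        return {"n_projections": len(stack.p),
                "d_min": float(stack.d.min()), "d_max": float(stack.d.max())}

    def stage_reconstruct():
        _require(state, "stack")
        cfg = SolverConfig(max_iterations=config.solver_iterations,
                           seed=config.seed)
        rec = cgls_solve(state["scheme"], model, state["stack"], cfg)
        state["reconstruction"] = rec
        save_field(out / "reconstruction.h5", rec)
        return {"iterations": config.solver_iterations}

    def stage_nullspace():
        _require(state, "scheme")
        probe = nullspace_component(state["scheme"], model, geometry,
                                    n_iter=config.nullspace_iterations)
        dirs = hemisphere(load_tdesign_56())
        _, maps = probe_field(probe.first_iteration, dirs)
        import h5py
        with h5py.File(out / "nullspace.h5", "w") as f:
            f.create_dataset("first_iteration", data=probe.first_iteration.coeffs)
            f.create_dataset("maps", data=maps)
            f.create_dataset("residuals", data=probe.residuals)
        _plot_nullspace_maps(maps, out / "nullspace_maps.png")
        return {"residual_start": float(probe.residuals[0]),
                "residual_end": float(probe.residuals[-1])}

    def stage_metrics():
        _require(state, "scheme")
        rows = {"coverage_surrogate": coverage_surrogate(state["scheme"])}
        if "reconstruction" in state and "phantom" in state:
            _, truth = state["phantom"]
            ori = extract_orientations(state["reconstruction"],
                                       mode=config.extraction_mode)
            rows["em_vs_ground_truth"] = experimental_metric(ori, truth)
        with open(out / "metrics.csv", "w") as f:
            f.write("metric,value\n")
            for k, v in rows.items():
                f.write(f"{k},{v:.6f}\n")
        return {k: round(v, 6) for k, v in rows.items()}

    for name, fn in [("scheme", stage_scheme), ("sweep", stage_sweep),
                     ("phantom", stage_phantom), ("simulate", stage_simulate),
                     ("reconstruct", stage_reconstruct),
                     ("nullspace", stage_nullspace), ("metrics", stage_metrics)]:
        run_stage(name, fn)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


class _MissingInput(RuntimeError):
    pass


def _require(state, key):
    if key not in state:
        raise _MissingInput(f"requires output of the '{key}' stage")


# -- advisory plots ----------------------------------------------------------

def _agg():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def _plot_scheme(scheme, path):
    plt = _agg()
    t = scheme.tomographic_vectors()
    s = scheme.sensitivity_vectors()
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="3d")
    for v, color, lab in [(t, "tab:blue", "±t(x)"), (s, "tab:red", "±s(x)")]:
        both = np.vstack([v, -v])
        ax.scatter(*both.T, s=3, color=color, label=lab)
    ax.set_box_aspect((1, 1, 1))
    ax.legend()
    ax.set_title(scheme.label)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_sweep(alphas, psi_maxes, fractions, path):
    plt = _agg()
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(fractions.T, origin="lower", aspect="auto",
                   extent=(alphas[0], alphas[-1], psi_maxes[0], psi_maxes[-1]),
                   vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel("grating angle alpha (deg)")
    ax.set_ylabel("max reachable |psi| (deg)")
    fig.colorbar(im, ax=ax, label="measurable fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_nullspace_maps(maps, path):
    plt = _agg()
    n = maps.shape[-1]
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    fig, axes = plt.subplots(rows, cols, figsize=(2 * cols, 2 * rows))
    for i, ax in enumerate(np.ravel(axes)):
        ax.axis("off")
        if i < n:
            ax.imshow(maps[..., i].T, origin="lower", cmap="RdBu_r")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
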