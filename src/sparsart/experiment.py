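"""Few-view reconstruction study harness.

Runs a grid of (view count, scheme) reconstructions of the modified
Shepp-Logan phantom under the reference fan-beam geometry (57 cm source
radius, 20 cm / 128-element flat detector, 20 cm field of view), collects
per-run stopping iteration and final relative error into a table, and
optionally writes convergence curves and windowed image mosaics.

Noisy variants (conventionally suffixed "N": AN/BN/CN) are the same
schemes run on projections carrying additive Gaussian noise with standard
deviation ``noise_level * max(g)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import FanBeamGeometry, add_noise, build_system_matrix, forward_project
from .phantom import Image, generate_phantom
from .solver import SolverConfig, run_scheme
from .sparsify import HaarTransform

__all__ = ["ExperimentPlan", "run_experiment", "render_image"]


@dataclass(frozen=True)
class ExperimentPlan:
    """Study design: which view counts and schemes to run, at what scale."""

    view_counts: tuple[int, ...] = (25, 35, 45, 55)
    schemes: tuple[str, ...] = ("A", "B", "C")
    noise_level: float = 0.0
    grid_n: int = 128
    n_detectors: int = 128
    source_radius: float = 57.0
    detector_length: float = 20.0
    fov: float = 20.0
    p: float = 1.0
    alpha0: float = 2.0
    max_iter: int = 20000
    rre_stop: float = 0.1
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.view_counts):
            raise ValueError("view counts must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be nonnegative")


def run_experiment(plan: ExperimentPlan, log_every: int = 10):
    """Execute the plan; returns ``(table, logs)``.

    ``table`` is a DataFrame with one row per (views, scheme) combination:
    columns views, scheme, stop_iteration, final_rre_percent.  ``logs``
    maps ``(views, scheme)`` to the full ConvergenceLog.  When
    ``plan.out_dir`` is set, the table, per-run convergence CSVs, and
    windowed PNG mosaics are written there; partial results are preserved
    if a run fails.
    """
    phantom = generate_phantom(plan.grid_n, plan.fov)
    transform = HaarTransform(plan.grid_n)
    out = Path(plan.out_dir) if plan.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    rows = []
    logs: dict[tuple[int, str], object] = {}
    try:
        for views in plan.view_counts:
            geom = FanBeamGeometry(
                source_radius=plan.source_radius,
                detector_length=plan.detector_length,
                n_detectors=plan.n_detectors,
                n_views=views,
            )
            A = build_system_matrix(geom, plan.grid_n, plan.fov)
            g = forward_project(A, phantom)
            if plan.noise_level > 0:
                g = add_noise(g, plan.noise_level, plan.seed)
            for scheme in plan.schemes:
                config = SolverConfig(
                    scheme=scheme,
                    p=plan.p,
                    alpha0=plan.alpha0,
                    max_iter=plan.max_iter,
                    rre_stop=plan.rre_stop,
                )
                log = run_scheme(config, A, g, phantom, transform, log_every=log_every)
                logs[(views, scheme)] = log
                rows.append(
                    {
                        "views": views,
                        "scheme": scheme,
                        "stop_iteration": log.stop_iteration,
                        "final_rre_percent": log.final_rre,
                    }
                )
                if out:
                    _write_run(out, views, scheme, log)
    finally:
        table = pd.DataFrame(rows, columns=["views", "scheme", "stop_iteration", "final_rre_percent"])
        if out:
            table.to_csv(out / "results.csv", index=False)
            _write_config(out, plan)
            if logs:
                _write_curves(out, logs)
    return table, logs


def _write_run(out: Path, views: int, scheme: str, log) -> None:
    import imageio.v3 as iio

    tag = f"views{views}_scheme{scheme}"
    pd.DataFrame(
        {
            "k": log.iterations,
            "rre_percent": log.rre_percent,
            "beta": log.beta,
            "mu": log.mu,
            "discrepancy": log.discrepancy,
        }
    ).to_csv(out / f"convergence_{tag}.csv", index=False)
    img = log.final_image.values
    np.save(out / f"image_{tag}.npy", img)
    iio.imwrite(out / f"image_{tag}.png", render_image(img, (0.0, 0.5)))


def _write_curves(out: Path, logs) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    views_list = sorted({v for v, _ in logs})
    fig, axes = plt.subplots(1, len(views_list), figsize=(4 * len(views_list), 3.2), squeeze=False)
    for ax, views in zip(axes[0], views_list):
        for (v, scheme), log in sorted(logs.items()):
            if v == views:
                ax.semilogy(log.iterations, log.rre_percent, label=f"Scheme-{scheme}")
        ax.set_title(f"{views} views")
        ax.set_xlabel("iteration k")
        ax.set_ylabel("RRE (%)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out / "convergence_curves.png", dpi=120)
    plt.close(fig)


def _write_config(out: Path, plan: ExperimentPlan) -> None:
    lines = [f"{f.name} = {getattr(plan, f.name)!r}" for f in dataclasses.fields(plan)]
    (out / "plan.txt").write_text("\n".join(lines) + "\n")


def render_image(f: Image | np.ndarray, window: tuple[float, float] = (0.0, 0.5)) -> np.ndarray:
    """Clamp-and-scale an image to 8-bit grayscale for display.

    Values at or below ``window[0]`` map to 0 (black), at or above
    ``window[1]`` to 255 (white), linearly in between.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must satisfy hi > lo")
    arr = f.values if isinstance(f, Image) else np.asarray(f, dtype=float)
    scaled = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    return np.round(scaled * 255).astype(np.uint8)
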