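"""Experiment orchestration: scenario grids, simulation, scoring, synthesis.

Two factorial experiments are defined. The first crosses 7 resistance
surfaces x 7 movement-mechanism combinations x 4 focal scales x 3 focal
functions x 3 autocorrelation levels (1,764 scenarios, no destination bias).
The second fixes scale and autocorrelation and crosses the 7 surfaces x 7
mechanisms x 3 destination-bias levels (147 scenarios). Every scenario's
simulated density surface is scored against the three connectivity-model
predictions, yielding a long-format scenario table for the multivariate
synthesis.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
import yaml

from landconn.metrics import compare
from landconn.models import circuit_current, factorial_lcp, resistant_kernels
from landconn.surfaces import generate_surface_suite, sample_sources
from landconn.walker import (
    MovementConfig,
    default_energy_threshold,
    default_risk_beta,
    focal_scale,
    simulate_density,
)

#: All non-empty subsets of the three movement mechanisms, in a fixed order.
MECHANISM_COMBOS: tuple[tuple[str, ...], ...] = (
    ("energy",),
    ("attraction",),
    ("risk",),
    ("energy", "attraction"),
    ("energy", "risk"),
    ("attraction", "risk"),
    ("energy", "attraction", "risk"),
)

_MECH_ABBREV = {"energy": "E", "attraction": "A", "risk": "R"}


def mechanism_label(mechanisms: tuple[str, ...]) -> str:
    return "".join(_MECH_ABBREV[m] for m in mechanisms)


MODELS = ("flcp", "kernels", "circuit")


@dataclass
class ExperimentConfig:
    """Full parameterisation of one experiment run."""

    analysis_id: str = "first"
    nrows: int = 256
    ncols: int = 256
    n_surfaces: int = 7
    n_sources: int = 100
    paths_per_source: int = 100
    surface_seed: int = 42
    source_seed: int | None = None
    master_seed: int = 0
    mechanisms: tuple[tuple[str, ...], ...] = MECHANISM_COMBOS
    scale_ns: tuple[int, ...] | None = None
    scale_fns: tuple[str, ...] | None = None
    C_values: tuple[float, ...] | None = None
    D_values: tuple[float, ...] | None = None
    models: tuple[str, ...] = MODELS
    max_steps: int = 500
    top_fraction: float = 0.1
    output_dir: str | None = None

    def __post_init__(self):
        if self.analysis_id not in ("first", "second"):
            raise ValueError(f"unknown analysis_id {self.analysis_id!r}")
        if self.source_seed is None:
            self.source_seed = self.surface_seed + 1
        first = self.analysis_id == "first"
        if self.scale_ns is None:
            self.scale_ns = (1, 3, 5, 7) if first else (1,)
        if self.scale_fns is None:
            self.scale_fns = ("mean", "max", "min") if first else ("mean",)
        if self.C_values is None:
            self.C_values = (0.0, 0.35, 0.75) if first else (0.2,)
        if self.D_values is None:
            self.D_values = (0.0,) if first else (0.1, 0.3, 0.6)
        self.mechanisms = tuple(tuple(m) for m in self.mechanisms)

    @classmethod
    def preset(cls, name: str, analysis_id: str = "first", **overrides) -> "ExperimentConfig":
        """Named profiles: ``full`` is the published-scale experiment
        (256x256, 100 sources x 100 paths); ``desk`` is a reduced profile
        (64x64, 25 sources x 10 paths) that preserves the full factor grid.
        """
        if name == "full":
            base = dict()
        elif name == "desk":
            base = dict(nrows=64, ncols=64, n_sources=25, paths_per_source=10)
        else:
            raise ValueError(f"unknown preset {name!r}")
        base.update(overrides)
        return cls(analysis_id=analysis_id, **base)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("mechanisms",):
            if key in raw:
                raw[key] = tuple(tuple(m) for m in raw[key])
        for key in ("scale_ns", "scale_fns", "C_values", "D_values", "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        data["mechanisms"] = [list(m) for m in self.mechanisms]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class Scenario:
    scenario_id: str
    surface_id: int
    movement: MovementConfig


def enumerate_scenarios(config: ExperimentConfig) -> list[Scenario]:
    """Deterministic Cartesian scenario grid with stable identifiers."""
    scenarios = []
    for surface_id, mech, n, fn, C, D in itertools.product(
        range(config.n_surfaces),
        config.mechanisms,
        config.scale_ns,
        config.scale_fns,
        config.C_values,
        config.D_values,
    ):
        sid = (
            f"{config.analysis_id}_s{surface_id}_m{mechanism_label(mech)}"
            f"_n{n}_{fn}_C{C:g}_D{D:g}"
        )
        movement = MovementConfig(
            mechanisms=frozenset(mech),
            scale_n=n,
            scale_fn=fn,
            autocorrelation_C=C,
            dest_bias_D=D,
            max_steps=config.max_steps,
        )
        scenarios.append(Scenario(scenario_id=sid, surface_id=surface_id, movement=movement))
    return scenarios


#: mean squared length of a Moore step (4 cardinal + 4 diagonal, uniform).
_MEAN_SQ_STEP = 1.5
#: mean per-pixel-distance cost multiplier of a Moore step.
_MEAN_STEP_LENGTH = (4 * 1.0 + 4 * math.sqrt(2.0)) / 8.0


def expected_path_steps(movement: MovementConfig, scaled: np.ndarray) -> float:
    """Expected number of moves before the walk terminates, from the active
    mechanisms evaluated on median terrain."""
    n = float(movement.max_steps)
    med = float(np.median(scaled))
    if "energy" in movement.mechanisms:
        E = movement.energy_threshold_E
        if E is None:
            E = default_energy_threshold(scaled, movement.max_steps)
        n = min(n, E / (_MEAN_STEP_LENGTH * med))
    if "risk" in movement.mechanisms:
        rho = scaled / scaled.max()
        beta = movement.risk_beta
        if beta is None:
            beta = default_risk_beta(rho, movement.max_steps)
        p_med = 1.0 - math.exp(-beta * float(np.median(rho)))
        if p_med > 0:
            n = min(n, 1.0 / p_med)
    return max(n, 1.0)


#: median displacement (pixels, per sqrt(step)) of a location visited at a
#: uniformly random time by an unbiased Moore walk: |X_t| ~ Rayleigh(sigma
#: sqrt(t)) with sigma^2 = E[step^2]/2 mixed over t ~ U(0, N) has median
#: sqrt(2 sigma^2 z N) with z = 0.26742 solving int_0^1 exp(-z/u) du = 1/2.
_MEDIAN_VISIT_DISP = math.sqrt(_MEAN_SQ_STEP * 0.2674181180187172)


def kernel_threshold(surface: np.ndarray, movement: MovementConfig) -> float:
    """Dispersal threshold matched to the simulated walker's occupancy.

    The kernel footprint is sized to the median displacement of a pixel
    visit: for an expected walk lifetime of N steps the median distance of a
    uniformly chosen visited location from the source is about
    ``0.633 sqrt(N)`` pixels, which is then priced at the median resistance.
    The walker's straight-line energetic reach (budget / per-step cost) would
    be far larger than the region it actually occupies — a diffusing walker
    covers sqrt(N), not N — and a kernel thresholded on it degenerates to a
    near-flat surface.
    """
    scaled = focal_scale(surface, movement.scale_n, movement.scale_fn)
    n_steps = expected_path_steps(movement, scaled)
    reach_px = _MEDIAN_VISIT_DISP * math.sqrt(n_steps)
    return float(np.median(scaled)) * reach_px


class _PredictionCache:
    """Per-surface model predictions; kernels are re-thresholded per scenario."""

    def __init__(self, surfaces, sources):
        self.surfaces = surfaces
        self.sources = sources
        self._cache: dict[tuple, np.ndarray] = {}

    def get(self, model: str, surface_id: int, threshold: float | None = None) -> np.ndarray:
        if model == "kernels":
            key = (model, surface_id, round(float(threshold), 9))
        else:
            key = (model, surface_id)
        if key not in self._cache:
            surf = self.surfaces[surface_id]
            if model == "flcp":
                self._cache[key] = factorial_lcp(surf, self.sources)
            elif model == "kernels":
                self._cache[key] = resistant_kernels(surf, self.sources, threshold)
            elif model == "circuit":
                self._cache[key] = circuit_current(surf, self.sources)
            else:
                raise ValueError(f"unknown model {model!r}")
        return self._cache[key]


TABLE_COLUMNS = [
    "analysis", "scenario_id", "surface_id", "mechanism", "scale_n",
    "scale_fn", "C", "D", "model", "rmse", "pearson", "overlap", "seed",
]


def _scenario_seed(master_seed: int, index: int) -> int:
    """Stable per-scenario seed below 2^31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def run_experiment(
    config: ExperimentConfig,
    table_path: str | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run (or resume) an experiment and return the long scenario table.

    One row per scenario x model. When ``table_path`` is given, rows are
    appended incrementally and scenarios already present are skipped, so an
    interrupted run resumes to the same final table.
    """
    surfaces = generate_surface_suite(
        config.nrows, config.ncols, config.n_surfaces, config.surface_seed
    )
    sources = sample_sources(
        config.n_sources, config.nrows, config.ncols, config.source_seed
    )
    scenarios = enumerate_scenarios(config)
    cache = _PredictionCache(surfaces, sources)

    done: set[str] = set()
    existing = None
    fh = None
    if table_path is not None:
        path = FsPath(table_path)
        if path.exists():
            existing = pd.read_csv(path)
            done = set(existing["scenario_id"].astype(str))
        path.parent.mkdir(parents=True, exist_ok=True)
        fh = open(path, "a")
        if existing is None:
            fh.write(",".join(TABLE_COLUMNS) + "\n")

    rows = []
    try:
        for index, sc in enumerate(scenarios):
            if sc.scenario_id in done:
                continue
            tic = time.perf_counter()
            seed = _scenario_seed(config.master_seed, index)
            surf = surfaces[sc.surface_id]
            truth = simulate_density(
                surf, sources, sc.movement,
                paths_per_source=config.paths_per_source, rng_seed=seed,
            )
            T = kernel_threshold(surf, sc.movement)
            for model in config.models:
                pred = cache.get(model, sc.surface_id, threshold=T)
                st = compare(truth, pred, q=config.top_fraction)
                row = [
                    config.analysis_id, sc.scenario_id, sc.surface_id,
                    mechanism_label(tuple(sorted(sc.movement.mechanisms, key=["energy", "attraction", "risk"].index))),
                    sc.movement.scale_n, sc.movement.scale_fn,
                    sc.movement.autocorrelation_C, sc.movement.dest_bias_D,
                    model, st.rmse, st.pearson, st.overlap, seed,
                ]
                rows.append(row)
                if fh is not None:
                    fh.write(",".join(str(v) for v in row) + "\n")
            if fh is not None:
                fh.flush()
            if progress:
                print(
                    f"[{index + 1}/{len(scenarios)}] {sc.scenario_id} "
                    f"({time.perf_counter() - tic:.2f}s)"
                )
    finally:
        if fh is not None:
            fh.close()

    new = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if existing is not None and len(existing):
        table = pd.concat([existing, new], ignore_index=True)
    else:
        table = new
    order = {sc.scenario_id: i for i, sc in enumerate(scenarios)}
    table["_ord"] = table["scenario_id"].map(order)
    table = table.sort_values(["_ord", "model"], kind="stable").drop(columns="_ord")
    return table.reset_index(drop=True)


def summarize_by_model(table: pd.DataFrame) -> pd.DataFrame:
    """Pooled mean accuracy statistics per connectivity model."""
    return (
        table.groupby("model")[["rmse", "pearson", "overlap"]]
        .mean()
        .reindex([m for m in MODELS if m in set(table["model"])])
    )


def partition_groups(table: pd.DataFrame, analysis_id: str) -> dict[str, pd.DataFrame]:
    """Factor groups for variance partitioning.

    X1 = movement mechanism, X2 = surface (spatial complexity), X3 = the
    remaining movement parameters (autocorrelation, scale, focal function),
    X4 = connectivity model; the destination-bias analysis replaces X3 with
    X5 = destination bias.
    """
    t = table
    if analysis_id == "first":
        return {
            "X1_mechanism": t[["mechanism"]],
            "X2_surface": t[["surface_id"]],
            "X3_movement": t[["C", "scale_n", "scale_fn"]],
            "X4_model": t[["model"]],
        }
    return {
        "X1_mechanism": t[["mechanism"]],
        "X2_surface": t[["surface_id"]],
        "X5_destbias": t[["D"]],
        "X4_model": t[["model"]],
    }


def response_matrix(table: pd.DataFrame) -> np.ndarray:
    return table[["rmse", "pearson", "overlap"]].to_numpy(dtype=float)
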