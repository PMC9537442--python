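"""Individual-based stochastic movement on a resistance surface.

A walker starts at a source pixel and repeatedly moves to one of its Moore
(8-adjacent) neighbours. Three mechanisms shape the walk:

* ``energy`` — the walk carries a finite energetic budget ``E``; each move
  costs ``dist * (r_i + r_j) / 2`` (``dist`` = 1 cardinal, sqrt(2) diagonal)
  and the walk ends when the next sampled move would reach the budget.
* ``attraction`` — the neighbour choice is biased towards low resistance,
  with weights proportional to ``1 / r_j``; without it the choice is uniform.
* ``risk`` — after each move the walker dies with probability
  ``1 - exp(-beta * risk / risk_max)`` evaluated at the new pixel.

Two directionality parameters modulate the neighbour distribution: the
autocorrelation ``C`` (probability-like weight on continuing in the previous
direction) and the destination bias ``D`` (weight on the neighbour closest to
a fixed target pixel).  The combined step distribution is the convex mixture

    P = (1 - C' - D) * P_mech + C' * P_persist + D * P_dest,   C' = C (1 - D)

where ``P_persist`` collapses into ``P_mech`` when there is no previous
direction or its continuation leaves the grid.  All surfaces (resistance and
risk) may first be focal-scaled with an ``n x n`` mean/max/min window,
modelling a multi-scale perceptual response to the landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: Fixed Moore-neighbourhood ordering: row-major scan of the 3x3 window.
NEIGHBOURS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)
_SQRT2 = math.sqrt(2.0)
_STEP_LENGTH = tuple(_SQRT2 if dr and dc else 1.0 for dr, dc in NEIGHBOURS)

MECHANISMS = frozenset({"energy", "attraction", "risk"})
TERMINATION_REASONS = (
    "step_cap",
    "energy_exhausted",
    "mortality",
    "destination_reached",
)


@dataclass(frozen=True)
class MovementConfig:
    """Full behavioural parameterisation of one movement scenario.

    Parameters
    ----------
    mechanisms
        Any subset of {"energy", "attraction", "risk"}.
    scale_n
        Odd focal-window edge in pixels; 1 means no scaling.
    scale_fn
        Focal statistic: "mean", "max" or "min".
    autocorrelation_C
        Weight in [0, 1] on persisting in the previous direction.
    dest_bias_D
        Weight in [0, 1] on stepping towards ``destination``.
    destination
        (row, col) target pixel; required when ``dest_bias_D > 0``.
    energy_threshold_E
        Energetic budget in accumulated-cost units; ``None`` selects the
        default ``max_steps/2 * median(scaled resistance)``.
    risk_beta
        Per-step hazard scaling; ``None`` selects the default calibrated so a
        ``max_steps/2``-step walk on median-risk terrain survives with
        probability one half.
    max_steps
        Hard cap on the number of moves.
    risk_surface
        Optional separate hazard raster; defaults to the resistance surface.
    """

    mechanisms: frozenset[str] = frozenset()
    scale_n: int = 1
    scale_fn: str = "mean"
    autocorrelation_C: float = 0.0
    dest_bias_D: float = 0.0
    destination: tuple[int, int] | None = None
    energy_threshold_E: float | None = None
    risk_beta: float | None = None
    max_steps: int = 500
    risk_surface: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "mechanisms", frozenset(self.mechanisms))
        unknown = self.mechanisms - MECHANISMS
        if unknown:
            raise ValueError(f"unknown mechanisms: {sorted(unknown)}")
        if self.scale_n < 1 or self.scale_n % 2 == 0:
            raise ValueError(f"scale_n must be odd and >= 1, got {self.scale_n}")
        if self.scale_fn not in ("mean", "max", "min"):
            raise ValueError(f"unknown scale_fn {self.scale_fn!r}")
        if not 0.0 <= self.autocorrelation_C <= 1.0:
            raise ValueError("autocorrelation_C must lie in [0, 1]")
        if not 0.0 <= self.dest_bias_D <= 1.0:
            raise ValueError("dest_bias_D must lie in [0, 1]")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.energy_threshold_E is not None and self.energy_threshold_E <= 0:
            raise ValueError("energy_threshold_E must be positive")
        if self.risk_beta is not None and self.risk_beta < 0:
            raise ValueError("risk_beta must be non-negative")


@dataclass
class Path:
    """One realised walk: ordered pixel coordinates and why it stopped."""

    coords: list[tuple[int, int]]
    termination_reason: str


def focal_scale(surface: np.ndarray, n: int, fn: str = "mean") -> np.ndarray:
    """Replace each pixel by the mean/max/min of its n x n focal window.

    Windows are truncated at grid edges (only in-bounds pixels contribute).
    ``n = 1`` returns the input unchanged.
    """
    if n < 1 or n % 2 == 0:
        raise ValueError(f"focal window size must be odd and >= 1, got {n}")
    surface = np.asarray(surface, dtype=float)
    if n == 1:
        return surface.copy()
    if fn == "mean":
        total = ndimage.uniform_filter(surface, size=n, mode="constant", cval=0.0)
        count = ndimage.uniform_filter(
            np.ones_like(surface), size=n, mode="constant", cval=0.0
        )
        return total / count
    if fn == "max":
        return ndimage.maximum_filter(surface, size=n, mode="constant", cval=-np.inf)
    if fn == "min":
        return ndimage.minimum_filter(surface, size=n, mode="constant", cval=np.inf)
    raise ValueError(f"unknown focal function {fn!r}")


def _dir_index(prev_dir) -> int | None:
    if prev_dir is None:
        return None
    if isinstance(prev_dir, (int, np.integer)):
        if not 0 <= prev_dir < 8:
            raise ValueError(f"direction index out of range: {prev_dir}")
        return int(prev_dir)
    return NEIGHBOURS.index(tuple(prev_dir))


def step_distribution(
    current: tuple[int, int],
    prev_dir,
    config: MovementConfig,
    scaled_surface: np.ndarray,
) -> np.ndarray:
    """Probability vector over the admissible Moore neighbours of ``current``.

    The vector is aligned with :func:`admissible_neighbours`, i.e. the
    in-bounds neighbours taken in the fixed ``NEIGHBOURS`` order.
    """
    scaled_surface = np.asarray(scaled_surface, dtype=float)
    nrows, ncols = scaled_surface.shape
    r0, c0 = current
    if not (0 <= r0 < nrows and 0 <= c0 < ncols):
        raise ValueError(f"current pixel {current} out of bounds")
    d_prev = _dir_index(prev_dir)

    nbrs: list[tuple[int, int]] = []
    dirs: list[int] = []
    for d, (dr, dc) in enumerate(NEIGHBOURS):
        r, c = r0 + dr, c0 + dc
        if 0 <= r < nrows and 0 <= c < ncols:
            nbrs.append((r, c))
            dirs.append(d)
    if not nbrs:
        raise RuntimeError(f"pixel {current} has no admissible neighbours")

    attraction = "attraction" in config.mechanisms
    if attraction:
        w = np.array([1.0 / scaled_surface[r, c] for r, c in nbrs])
    else:
        w = np.ones(len(nbrs))
    p_mech = w / w.sum()

    D = config.dest_bias_D
    c_prime = config.autocorrelation_C * (1.0 - D)
    k_persist = dirs.index(d_prev) if (d_prev is not None and d_prev in dirs) else None

    if k_persist is None:
        probs = (1.0 - D) * p_mech
    else:
        probs = (1.0 - c_prime - D) * p_mech
        probs[k_persist] += c_prime
    if D > 0.0:
        if config.destination is None:
            raise ValueError("dest_bias_D > 0 requires a destination")
        tr, tc = config.destination
        d2 = [(r - tr) ** 2 + (c - tc) ** 2 for r, c in nbrs]
        probs[int(np.argmin(d2))] += D
    return probs


def admissible_neighbours(
    current: tuple[int, int], shape: tuple[int, int]
) -> list[tuple[int, int]]:
    """In-bounds Moore neighbours of ``current`` in the fixed ordering."""
    nrows, ncols = shape
    r0, c0 = current
    return [
        (r0 + dr, c0 + dc)
        for dr, dc in NEIGHBOURS
        if 0 <= r0 + dr < nrows and 0 <= c0 + dc < ncols
    ]


def default_energy_threshold(scaled_surface: np.ndarray, max_steps: int = 500) -> float:
    """Budget covering roughly half the step cap on median terrain."""
    return 0.5 * max_steps * float(np.median(scaled_surface))


def default_risk_beta(normalised_risk: np.ndarray, max_steps: int = 500) -> float:
    """Hazard scaling giving ~50% survival over half the step cap at median risk."""
    rho_med = float(np.median(normalised_risk))
    if rho_med <= 0:
        return 0.0
    return math.log(2.0) / (0.5 * max_steps * rho_med)


class _WalkSpace:
    """Precomputed per-scenario state shared by all walks on one surface."""

    __slots__ = (
        "shape", "config", "scaled", "nbr_js", "nbr_dirs", "nbr_costs",
        "nbr_cum", "nbr_rows", "nbr_cols", "energy_E", "p_death",
        "energy_active", "risk_active",
    )

    def __init__(self, surface: np.ndarray, config: MovementConfig):
        surface = np.asarray(surface, dtype=float)
        if not np.all(np.isfinite(surface)) or np.any(surface <= 0):
            raise ValueError("resistance surface must be finite and positive")
        self.config = config
        scaled = focal_scale(surface, config.scale_n, config.scale_fn)
        self.scaled = scaled
        nrows, ncols = scaled.shape
        self.shape = (nrows, ncols)
        flat = scaled.ravel()
        attraction = "attraction" in config.mechanisms

        self.energy_active = "energy" in config.mechanisms
        if self.energy_active:
            E = config.energy_threshold_E
            if E is None:
                E = default_energy_threshold(scaled, config.max_steps)
            self.energy_E = float(E)
        else:
            self.energy_E = math.inf

        self.risk_active = "risk" in config.mechanisms
        if self.risk_active:
            risk = config.risk_surface if config.risk_surface is not None else surface
            risk_scaled = focal_scale(np.asarray(risk, float), config.scale_n, config.scale_fn)
            rho = risk_scaled / risk_scaled.max()
            beta = config.risk_beta
            if beta is None:
                beta = default_risk_beta(rho, config.max_steps)
            self.p_death = (1.0 - np.exp(-beta * rho)).ravel()
        else:
            self.p_death = None

        # Per-pixel admissible-neighbour tables in the fixed ordering.
        nbr_js, nbr_dirs, nbr_costs, nbr_cum = [], [], [], []
        nbr_rows, nbr_cols = [], []
        for r0 in range(nrows):
            base = r0 * ncols
            for c0 in range(ncols):
                i = base + c0
                js, dirs, costs, ws, rr, cc = [], [], [], [], [], []
                for d, (dr, dc) in enumerate(NEIGHBOURS):
                    r, c = r0 + dr, c0 + dc
                    if 0 <= r < nrows and 0 <= c < ncols:
                        j = r * ncols + c
                        js.append(j)
                        dirs.append(d)
                        costs.append(_STEP_LENGTH[d] * (flat[i] + flat[j]) / 2.0)
                        ws.append(1.0 / flat[j] if attraction else 1.0)
                        rr.append(r)
                        cc.append(c)
                total = sum(ws)
                acc, cum = 0.0, []
                for w in ws:
                    acc += w / total
                    cum.append(acc)
                cum[-1] = 1.0
                nbr_js.append(tuple(js))
                nbr_dirs.append(tuple(dirs))
                nbr_costs.append(tuple(costs))
                nbr_cum.append(tuple(cum))
                nbr_rows.append(tuple(rr))
                nbr_cols.append(tuple(cc))
        self.nbr_js = nbr_js
        self.nbr_dirs = nbr_dirs
        self.nbr_costs = nbr_costs
        self.nbr_cum = nbr_cum
        self.nbr_rows = nbr_rows
        self.nbr_cols = nbr_cols


def _walk(
    space: _WalkSpace,
    source: int,
    rng: np.random.Generator,
    destination: tuple[int, int] | None,
) -> tuple[list[int], str]:
    """Run one walk from a flat source index; returns (flat coords, reason).

    Sampling composes the mixture hierarchically: a single uniform first
    selects the destination branch (mass D), then the persistence branch
    (mass C' when a continuation exists), and otherwise falls through to the
    mechanism distribution via its precomputed cumulative weights — an exact
    draw from the convex mixture in :func:`step_distribution`.
    """
    cfg = space.config
    max_steps = cfg.max_steps
    D = cfg.dest_bias_D
    c_prime = cfg.autocorrelation_C * (1.0 - D)
    dest_active = D > 0.0
    if dest_active:
        dest_r, dest_c = destination
        ncols = space.shape[1]
        dest_flat = dest_r * ncols + dest_c
    energy_active = space.energy_active
    risk_active = space.risk_active
    E = space.energy_E
    p_death = space.p_death

    u_move = rng.random(max_steps)
    u_risk = rng.random(max_steps) if risk_active else None

    nbr_js = space.nbr_js
    nbr_dirs = space.nbr_dirs
    nbr_costs = space.nbr_costs
    nbr_cum = space.nbr_cum
    nbr_rows = space.nbr_rows
    nbr_cols = space.nbr_cols

    i = source
    coords = [i]
    acc = 0.0
    prev_dir = -1
    for step in range(max_steps):
        js = nbr_js[i]
        dirs = nbr_dirs[i]
        u = u_move[step]

        k = -1
        if dest_active and u < D:
            rows_i, cols_i = nbr_rows[i], nbr_cols[i]
            best, k = None, 0
            for m in range(len(js)):
                d2 = (rows_i[m] - dest_r) ** 2 + (cols_i[m] - dest_c) ** 2
                if best is None or d2 < best:
                    best, k = d2, m
        else:
            if dest_active:
                u = (u - D) / (1.0 - D)
            if c_prime > 0.0 and prev_dir >= 0 and prev_dir in dirs:
                if u < c_prime:
                    k = dirs.index(prev_dir)
                else:
                    u = (u - c_prime) / (1.0 - c_prime)
            if k < 0:
                cum = nbr_cum[i]
                k = 0
                while cum[k] < u:
                    k += 1

        if energy_active and acc + nbr_costs[i][k] >= E:
            return coords, "energy_exhausted"
        acc += nbr_costs[i][k]
        prev_dir = dirs[k]
        i = js[k]
        coords.append(i)
        if dest_active and i == dest_flat:
            return coords, "destination_reached"
        if risk_active and u_risk[step] < p_death[i]:
            return coords, "mortality"
    return coords, "step_cap"


def _require_destination(config: MovementConfig) -> None:
    if config.dest_bias_D > 0.0 and config.destination is None:
        raise ValueError("dest_bias_D > 0 requires a destination pixel")


def simulate_path(
    surface: np.ndarray,
    source: tuple[int, int],
    config: MovementConfig,
    rng_seed: int | np.random.SeedSequence = 0,
) -> Path:
    """Simulate a single walk from ``source`` and return its Path."""
    surface = np.asarray(surface, dtype=float)
    nrows, ncols = surface.shape
    r, c = source
    if not (0 <= r < nrows and 0 <= c < ncols):
        raise ValueError(f"source {source} out of bounds for {nrows}x{ncols} grid")
    _require_destination(config)
    space = _WalkSpace(surface, config)
    rng = np.random.default_rng(rng_seed)
    flat_coords, reason = _walk(space, r * ncols + c, rng, config.destination)
    coords = [(j // ncols, j % ncols) for j in flat_coords]
    return Path(coords=coords, termination_reason=reason)


def simulate_density(
    surface: np.ndarray,
    sources: np.ndarray,
    config: MovementConfig,
    paths_per_source: int = 100,
    rng_seed: int = 0,
) -> np.ndarray:
    """Aggregate many walks into a density-of-movement ("true") surface.

    ``paths_per_source`` walks start from every source; every pixel visit of
    every path (revisits included) increments the corresponding count.  Each
    path has its own RNG stream derived from ``(rng_seed, source index,
    replicate)``, so any individual path can be reproduced in isolation and
    the aggregate is independent of iteration order.

    When ``config.dest_bias_D > 0`` and no fixed destination is set, each
    path is assigned a destination drawn uniformly from the other sources
    (from the path's own stream).
    """
    sources = np.asarray(sources)
    if sources.ndim != 2 or sources.shape[0] == 0:
        raise ValueError("sources must be a non-empty (n, 2) array")
    if paths_per_source < 1:
        raise ValueError("paths_per_source must be >= 1")
    surface = np.asarray(surface, dtype=float)
    nrows, ncols = surface.shape
    space = _WalkSpace(surface, config)
    counts = np.zeros(nrows * ncols, dtype=np.int64)
    n_sources = sources.shape[0]
    sample_dest = config.dest_bias_D > 0.0 and config.destination is None
    if config.dest_bias_D > 0.0 and not sample_dest:
        _require_destination(config)

    for si in range(n_sources):
        r, c = int(sources[si, 0]), int(sources[si, 1])
        if not (0 <= r < nrows and 0 <= c < ncols):
            raise ValueError(f"source {(r, c)} out of bounds")
        src_flat = r * ncols + c
        for rep in range(paths_per_source):
            ss = np.random.SeedSequence(entropy=rng_seed, spawn_key=(si, rep))
            rng = np.random.default_rng(ss)
            if sample_dest:
                if n_sources < 2:
                    raise ValueError(
                        "destination sampling needs at least two sources"
                    )
                other = int(rng.integers(n_sources - 1))
                if other >= si:
                    other += 1
                dest = (int(sources[other, 0]), int(sources[other, 1]))
            else:
                dest = config.destination
            flat_coords, _ = _walk(space, src_flat, rng, dest)
            for j in flat_coords:
                counts[j] += 1
    return counts.reshape(nrows, ncols)
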