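"""Synthetic resistance surfaces and source-point sampling.

A resistance surface is a strictly positive 2-D array whose pixel values
encode the cost of moving through the corresponding landscape cell.  The
experiment uses a suite of surfaces of graded spatial complexity: the first is
a uniform landscape crossed by three high-resistance linear barriers (each
with a traversable gap), and the rest are spatially autocorrelated Gaussian
random fields whose correlation range shrinks — and whose number of distinct
resistance levels grows — along the suite, so that both the value entropy and
the local heterogeneity increase monotonically.
"""

from __future__ import annotations

import numpy as np

RESISTANCE_MIN = 1.0
RESISTANCE_MAX = 100.0

#: Spectral exponents of the power-law random fields, most to least smooth.
_DEFAULT_EXPONENTS = (3.0, 2.5, 2.0, 1.5, 1.0, 0.5)
#: Number of equal-mass resistance levels per random-field surface.
_DEFAULT_LEVELS = (4, 8, 16, 32, 64, 256)


def _barrier_surface(nrows: int, ncols: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform background with three vertical barriers, each with a 3-pixel gap."""
    surf = np.full((nrows, ncols), RESISTANCE_MIN)
    cols = [ncols // 4, ncols // 2, (3 * ncols) // 4]
    gap = 3
    for c in cols:
        surf[:, c] = RESISTANCE_MAX
        start = int(rng.integers(0, max(nrows - gap, 1)))
        surf[start : start + gap, c] = RESISTANCE_MIN
    return surf


def _power_law_field(
    nrows: int, ncols: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian random field synthesised with an isotropic power-law spectrum.

    Amplitude ~ k^(-exponent/2); larger exponents concentrate power at low
    frequencies and give smoother, longer-range fields.
    """
    noise = rng.standard_normal((nrows, ncols))
    spec = np.fft.fft2(noise)
    ky = np.fft.fftfreq(nrows)[:, None]
    kx = np.fft.fftfreq(ncols)[None, :]
    k = np.sqrt(ky**2 + kx**2)
    k[0, 0] = np.inf  # zero the mean component
    spec *= k ** (-exponent / 2.0)
    field = np.fft.ifft2(spec).real
    return field


def _rank_quantize(field: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-mass quantisation of a field onto n_levels values in [1, 100].

    Ranks are split into n_levels equally populated classes, so the value
    histogram is uniform over the levels regardless of the field's marginal
    distribution.  Levels map onto the centres of n_levels equal sub-intervals
    of [1, 100], which keeps any power-of-two level ladder evenly spread over
    a fixed binning of that range.
    """
    flat = field.ravel()
    order = np.argsort(flat, kind="stable")
    levels = np.empty(flat.size, dtype=np.int64)
    levels[order] = (np.arange(flat.size) * n_levels) // flat.size
    span = RESISTANCE_MAX - RESISTANCE_MIN
    values = RESISTANCE_MIN + span * (levels + 0.5) / n_levels
    return values.reshape(field.shape)


def generate_surface_suite(
    nrows: int, ncols: int, n_surfaces: int = 7, seed: int = 0
) -> list[np.ndarray]:
    """Generate a suite of resistance surfaces of increasing spatial complexity.

    Parameters
    ----------
    nrows, ncols
        Grid dimensions (both >= 8).
    n_surfaces
        Number of surfaces. Surface 0 is always the uniform-with-barriers
        landscape; surfaces ``1..n-1`` are power-law random fields with
        decreasing spectral exponent and an increasing number of equal-mass
        resistance levels.
    seed
        Seed for the generator; identical arguments give bit-identical suites.

    Returns
    -------
    list of 2-D float arrays with values in [1, 100].
    """
    if nrows < 8 or ncols < 8:
        raise ValueError(f"grid must be at least 8x8, got {nrows}x{ncols}")
    if n_surfaces < 1:
        raise ValueError("n_surfaces must be >= 1")
    rng = np.random.default_rng(seed)
    suite = [_barrier_surface(nrows, ncols, rng)]
    n_fields = n_surfaces - 1
    if n_fields > 0:
        if n_fields == len(_DEFAULT_EXPONENTS):
            exponents = np.array(_DEFAULT_EXPONENTS)
            levels = np.array(_DEFAULT_LEVELS)
        else:
            exponents = np.linspace(
                _DEFAULT_EXPONENTS[0], _DEFAULT_EXPONENTS[-1], n_fields
            )
            levels = np.unique(
                np.geomspace(_DEFAULT_LEVELS[0], _DEFAULT_LEVELS[-1], n_fields)
                .round()
                .astype(int)
            )
            levels = np.sort(levels)
            if levels.size < n_fields:  # pad by repeating the largest
                levels = np.concatenate(
                    [levels, np.full(n_fields - levels.size, levels[-1])]
                )
        for expo, n_lev in zip(exponents, levels):
            field = _power_law_field(nrows, ncols, float(expo), rng)
            suite.append(_rank_quantize(field, int(n_lev)))
    return suite


def sample_sources(n: int, nrows: int, ncols: int, seed: int = 0) -> np.ndarray:
    """Sample n unique pixel coordinates uniformly without replacement.

    Returns an (n, 2) integer array of (row, col) pairs, 0-based, row 0 at the
    top of the raster.
    """
    n_cells = nrows * ncols
    if not 1 <= n <= n_cells:
        raise ValueError(f"need 1 <= n <= {n_cells}, got {n}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n, replace=False)
    return np.column_stack(np.unravel_index(flat, (nrows, ncols))).astype(np.int64)


def histogram_entropy(surface: np.ndarray, bins: int = 32) -> float:
    """Shannon entropy (nats) of the surface's value histogram."""
    counts, _ = np.histogram(surface, bins=bins, range=(RESISTANCE_MIN, RESISTANCE_MAX))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mean_neighbour_difference(surface: np.ndarray) -> float:
    """Mean absolute difference between cardinally adjacent pixels."""
    dv = np.abs(np.diff(surface, axis=0))
    dh = np.abs(np.diff(surface, axis=1))
    return float((dv.sum() + dh.sum()) / (dv.size + dh.size))
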