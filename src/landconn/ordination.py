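"""Constrained ordination, variance partitioning and factorial ANOVA.

These syntheses operate on the scenario table: a multivariate response
(rmse, pearson, overlap) against categorical experiment factors. Everything
here is implemented directly on the linear algebra:

* ``rda`` — redundancy analysis: principal axes of the fitted values of a
  multivariate least-squares regression of the (standardised) responses on a
  dummy-coded factor design.
* ``cca`` — canonical correspondence analysis: the same construction applied
  to the chi-square-standardised response table with row-mass weighting.
* ``variance_partition`` — unique and shared (adjusted) R-squared components
  of groups of factors, obtained from RDA fits of every subset of groups by
  solving the inclusion–exclusion system exactly.
* ``anova_factorial`` — main effects and two-way interactions for a balanced
  factorial design, with sequential sums of squares as a fallback for
  unbalanced inputs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# design-matrix helpers

def factor_design(df: pd.DataFrame, columns: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Treatment-contrast dummy coding (first level dropped) of factor columns.

    Every column is treated as categorical; returns the design matrix without
    an intercept and the coded column names.
    """
    if columns is None:
        columns = list(df.columns)
    cat = df[columns].astype(str).astype("category")
    dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
    return dummies.to_numpy(), list(dummies.columns)


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        if all(np.issubdtype(t, np.number) for t in X.dtypes):
            return X.to_numpy(dtype=float), list(X.columns)
        return factor_design(X)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep a maximal linearly independent subset of columns (QR pivoting)."""
    if X.shape[1] == 0:
        return X, names
    # greedy left-to-right selection keeps the first column of each dependent set
    keep, basis = [], np.zeros((X.shape[0], 0))
    for j in range(X.shape[1]):
        candidate = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(candidate) > basis.shape[1]:
            keep.append(j)
            basis = candidate
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear design columns: {dropped}")
    return X[:, keep], [names[j] for j in keep]


# ---------------------------------------------------------------------------
# results containers

@dataclass
class OrdinationResult:
    eigenvalues_constrained: np.ndarray
    eigenvalues_unconstrained: np.ndarray
    proportion_constrained: float
    r_squared: float
    adjusted_r_squared: float
    total_inertia: float
    site_scores: np.ndarray
    response_scores: np.ndarray
    centroid_scores: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    rank: int = 0


@dataclass
class PartitionResult:
    """Inclusion–exclusion decomposition of explained variance.

    ``components`` maps a sorted tuple of group names to the variance
    fraction shared by exactly those groups (singletons are the unique
    fractions); ``subset_r2`` holds the (adjusted) R-squared of every fitted
    subset of groups; components plus ``residual`` sum to 1.
    """

    components: dict[tuple[str, ...], float]
    residual: float
    subset_r2: dict[tuple[str, ...], float]

    def unique(self, group: str) -> float:
        return self.components[(group,)]


def ezekiel_adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjustment, the standard bias correction for R-squared."""
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _centroids(
    site_scores: np.ndarray, factors: pd.DataFrame | None, weights: np.ndarray | None = None
) -> dict[str, dict[str, np.ndarray]]:
    if factors is None:
        return {}
    out: dict[str, dict[str, np.ndarray]] = {}
    w = np.ones(len(site_scores)) if weights is None else weights
    for col in factors.columns:
        levels = {}
        vals = factors[col].astype(str).to_numpy()
        for lev in pd.unique(vals):
            mask = vals == lev
            levels[lev] = np.average(site_scores[mask], axis=0, weights=w[mask])
        out[col] = levels
    return out


# ---------------------------------------------------------------------------
# ordinations

def rda(Y, X, standardize: bool = True) -> OrdinationResult:
    """Redundancy analysis of responses Y constrained by design X.

    Y columns are centred (and by default standardised, as the accuracy
    statistics have unlike units). X may be a numeric design matrix or a
    DataFrame of factors (dummy-coded automatically).
    """
    factors = X if isinstance(X, pd.DataFrame) else None
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    Xm, names = _as_design(X)
    if Xm.shape[0] != n:
        raise ValueError("Y and X must have the same number of rows")
    Xc = Xm - Xm.mean(axis=0)
    Xc, names = _drop_collinear(Xc, names)
    p = Xc.shape[1]

    Yc = Y - Y.mean(axis=0)
    if standardize:
        sd = Yc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Yc = Yc / sd

    if p == 0:
        fitted = np.zeros_like(Yc)
    else:
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        fitted = Xc @ beta
    resid = Yc - fitted

    denom = max(n - 1, 1)
    total = float((Yc**2).sum()) / denom
    uf, sf, vtf = np.linalg.svd(fitted, full_matrices=False)
    ur, sr, vtr = np.linalg.svd(resid, full_matrices=False)
    eig_c = (sf**2) / denom
    eig_u = (sr**2) / denom
    eig_c = eig_c[eig_c > 1e-12 * max(total, 1.0)]
    eig_u = eig_u[eig_u > 1e-12 * max(total, 1.0)]
    r2 = float(eig_c.sum() / total) if total > 0 else 0.0
    site = fitted @ vtf.T[:, : max(eig_c.size, 1)]
    result = OrdinationResult(
        eigenvalues_constrained=eig_c,
        eigenvalues_unconstrained=eig_u,
        proportion_constrained=r2,
        r_squared=r2,
        adjusted_r_squared=ezekiel_adjusted_r2(r2, n, p),
        total_inertia=total,
        site_scores=site,
        response_scores=vtf.T[:, : max(eig_c.size, 1)],
        rank=p,
    )
    result.centroid_scores = _centroids(site, factors)
    return result


def cca(Y, X) -> OrdinationResult:
    """Canonical correspondence analysis of non-negative responses Y on X.

    Y is chi-square standardised (correspondence-analysis residuals from the
    independence model) and regressed on X with row-mass weights; the
    constrained axes are the singular axes of the weighted fitted values.
    """
    factors = X if isinstance(X, pd.DataFrame) else None
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.any(Y < 0):
        raise ValueError("cca requires non-negative responses")
    n = Y.shape[0]
    grand = Y.sum()
    if grand <= 0:
        raise ValueError("cca requires a positive response total")
    P = Y / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r <= 0):
        raise ValueError("cca requires positive row sums")
    expected = np.outer(r, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = (P - expected) / np.sqrt(expected)
    Q[~np.isfinite(Q)] = 0.0
    total = float((Q**2).sum())

    Xm, names = _as_design(X)
    if Xm.shape[0] != n:
        raise ValueError("Y and X must have the same number of rows")
    # weighted centring and sqrt-mass scaling put the weighted LS problem in
    # ordinary LS form
    xbar = np.average(Xm, axis=0, weights=r)
    Xw = np.sqrt(r)[:, None] * (Xm - xbar)
    Xw, names = _drop_collinear(Xw, names)
    p = Xw.shape[1]

    if p == 0 or total == 0.0:
        fitted = np.zeros_like(Q)
    else:
        beta, *_ = np.linalg.lstsq(Xw, Q, rcond=None)
        fitted = Xw @ beta
    resid = Q - fitted

    uf, sf, vtf = np.linalg.svd(fitted, full_matrices=False)
    ur, sr, vtr = np.linalg.svd(resid, full_matrices=False)
    eig_c = sf**2
    eig_u = sr**2
    eig_c = eig_c[eig_c > 1e-12 * max(total, 1.0)]
    eig_u = eig_u[eig_u > 1e-12 * max(total, 1.0)]
    r2 = float(eig_c.sum() / total) if total > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        site_w = fitted @ vtf.T[:, : max(eig_c.size, 1)] / np.sqrt(r)[:, None]
    site_w[~np.isfinite(site_w)] = 0.0
    result = OrdinationResult(
        eigenvalues_constrained=eig_c,
        eigenvalues_unconstrained=eig_u,
        proportion_constrained=r2,
        r_squared=r2,
        adjusted_r_squared=ezekiel_adjusted_r2(r2, n, p),
        total_inertia=total,
        site_scores=site_w,
        response_scores=vtf.T[:, : max(eig_c.size, 1)],
        rank=p,
    )
    result.centroid_scores = _centroids(site_w, factors, weights=r)
    return result


# ---------------------------------------------------------------------------
# variance partitioning

def variance_partition(
    Y, groups: dict[str, pd.DataFrame | np.ndarray], adjusted: bool = True
) -> PartitionResult:
    """Partition explained variance among groups of predictors.

    Fits an RDA for every non-empty subset of groups and solves the
    inclusion–exclusion system for the unique and shared components. With
    ``adjusted`` (default) the subsets' R-squared values carry Ezekiel's
    correction, the convention for variance partitioning on factors of
    unequal rank.
    """
    if not 2 <= len(groups) <= 4:
        raise ValueError("variance_partition expects 2 to 4 groups")
    designs: dict[str, tuple[np.ndarray, list[str]]] = {}
    seen: dict[str, str] = {}
    for g, X in groups.items():
        Xm, names = _as_design(X)
        for nm in names:
            if nm in seen:
                raise ValueError(
                    f"groups overlap: column {nm!r} appears in {seen[nm]!r} and {g!r}"
                )
            seen[nm] = g
        designs[g] = (Xm, names)

    names_sorted = sorted(groups)
    subsets = []
    for k in range(1, len(names_sorted) + 1):
        subsets.extend(itertools.combinations(names_sorted, k))

    subset_r2: dict[tuple[str, ...], float] = {}
    for S in subsets:
        Xm = np.column_stack([designs[g][0] for g in S])
        res = rda(Y, Xm)
        subset_r2[S] = res.adjusted_r_squared if adjusted else res.r_squared

    # solve f(S) = sum over components T intersecting S
    atoms = subsets
    A = np.zeros((len(subsets), len(atoms)))
    b = np.zeros(len(subsets))
    for i, S in enumerate(subsets):
        b[i] = subset_r2[S]
        for j, T in enumerate(atoms):
            if set(T) & set(S):
                A[i, j] = 1.0
    x = np.linalg.solve(A, b)
    components = {T: float(v) for T, v in zip(atoms, x)}
    residual = 1.0 - subset_r2[tuple(names_sorted)]
    return PartitionResult(components=components, residual=float(residual), subset_r2=subset_r2)


# ---------------------------------------------------------------------------
# factorial ANOVA

def _interaction_dummies(d1: pd.DataFrame, d2: pd.DataFrame) -> np.ndarray:
    cols = []
    for i in range(d1.shape[1]):
        for j in range(d2.shape[1]):
            cols.append(d1.iloc[:, i].to_numpy() * d2.iloc[:, j].to_numpy())
    return np.column_stack(cols) if cols else np.empty((len(d1), 0))


def anova_factorial(y, factors: pd.DataFrame, max_order: int = 2) -> pd.DataFrame:
    """ANOVA table (main effects + two-way interactions) for a factorial design.

    For balanced designs the sums of squares are orthogonal and the
    decomposition is unique; unbalanced inputs fall back to sequential
    (Type I) sums of squares in column order, with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if len(factors) != n:
        raise ValueError("y and factors must have the same length")
    cols = list(factors.columns)
    cell_sizes = factors.groupby(cols, observed=True).size()
    balanced = cell_sizes.nunique() == 1
    if not balanced:
        warnings.warn("unbalanced design: using sequential (Type I) sums of squares")

    dummies = {
        c: pd.get_dummies(factors[c].astype(str).astype("category"), drop_first=True, dtype=float)
        for c in cols
    }
    terms: list[tuple[str, np.ndarray]] = [(c, dummies[c].to_numpy()) for c in cols]
    if max_order >= 2:
        for c1, c2 in itertools.combinations(cols, 2):
            terms.append((f"{c1}:{c2}", _interaction_dummies(dummies[c1], dummies[c2])))

    yc = y - y.mean()
    ss_total = float(yc @ yc)
    rows = []
    X = np.empty((n, 0))
    rss_prev = ss_total
    used_rank = 0
    for name, block in terms:
        X = np.column_stack([X, block])
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        rss = float(((yc - Xc @ beta) ** 2).sum())
        rank = np.linalg.matrix_rank(Xc) if Xc.size else 0
        df_term = rank - used_rank
        rows.append([name, rss_prev - rss, df_term])
        rss_prev = rss
        used_rank = rank

    df_resid = n - 1 - used_rank
    ms_resid = rss_prev / df_resid if df_resid > 0 else np.nan
    table = []
    for name, ss, df_term in rows:
        ms = ss / df_term if df_term > 0 else np.nan
        F = ms / ms_resid if df_resid > 0 and ms_resid > 0 else np.nan
        pval = float(stats.f.sf(F, df_term, df_resid)) if np.isfinite(F) else np.nan
        table.append([name, ss, df_term, F, pval])
    table.append(["Residual", rss_prev, df_resid, np.nan, np.nan])
    return pd.DataFrame(
        table, columns=["term", "sum_sq", "df", "F", "PR(>F)"]
    ).set_index("term")
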