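"""Attribution of genetic diversity to climatic, topographic and anthropogenic factors.

Workflow, applied at the grid cells of the combined diversity landscape:

1. assemble a cell-level table of the response (interpolated haplotype
   diversity) and category-tagged explanatory variables;
2. drop one variable of every within-category pair with |r| above a
   collinearity threshold (0.7 by default);
3. keep the two most important variables per category, ranked by
   permutation importance in a random-forest regression (the drop in
   explained variance when a predictor is permuted);
4. fit a univariate penalized-spline GAM per selected variable (automatic
   smoothness selection) for trend shape and significance;
5. partition the variance explained by the three category sets into unique
   and shared fractions of adjusted R² (the varpart construction: with a
   univariate response, redundancy analysis reduces to OLS regression, so
   each of the seven set-union models is an OLS fit whose R² is Ezekiel-
   adjusted and combined by inclusion-exclusion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from statsmodels.gam.api import BSplines, GLMGam

from .landscape import Surface

__all__ = [
    "VariableTable",
    "GAMResult",
    "PartitionResult",
    "extract_variable_table",
    "collinearity_filter",
    "importance_select",
    "fit_gam",
    "adjusted_r2",
    "variation_partition",
    "CATEGORIES",
]

CATEGORIES = ("climatic", "topographic", "anthropogenic")


@dataclass
class VariableTable:
    """Cell-level response + explanatory variables with category tags."""

    data: pd.DataFrame  # columns: cell_id, row, col, response, <variables...>
    categories: dict[str, str]  # variable name -> category
    n_dropped: int = 0  # rows removed for missing values

    def variables(self, category: str | None = None) -> list[str]:
        names = [c for c in self.data.columns if c in self.categories]
        if category is None:
            return names
        return [c for c in names if self.categories[c] == category]


@dataclass
class GAMResult:
    variable: str
    smooth: object  # callable x -> fitted values
    r2_adj: float
    p_value: float
    trend: str  # 'increasing' | 'decreasing' | 'nonmonotone'
    edf: float = field(default=float("nan"))


@dataclass
class PartitionResult:
    """Unique/shared adjusted-R² fractions for sets C (climatic),
    T (topographic), A (anthropogenic)."""

    adj_r2: dict[str, float]  # keys C,T,A,CT,CA,TA,CTA
    fractions: dict[str, float]  # keys C,T,A,C&T,T&A,C&A,C&T&A
    residual: float

    def closure_error(self) -> float:
        return abs(sum(self.fractions.values()) - self.adj_r2["CTA"])


def extract_variable_table(rasters, surface: Surface) -> VariableTable:
    """Sample response and variable rasters at the combined surface's cells.

    ``rasters`` is a list of ``(name, category, Surface)``; rasters on a
    different grid are sampled nearest-neighbour at this grid's cell
    centers.  Rows with any missing variable are dropped and counted.
    """
    grid = surface.grid
    rows, cols = np.nonzero(grid.boundary_mask)
    lon_c = grid.lon_centers()[cols]
    lat_c = grid.lat_centers()[rows]
    table = pd.DataFrame(
        {
            "cell_id": rows * grid.n_cols + cols,
            "row": rows,
            "col": cols,
            "response": surface.values[rows, cols],
        }
    )
    categories: dict[str, str] = {}
    for name, category, raster in rasters:
        if category not in CATEGORIES:
            raise ValueError(f"variable {name!r}: unknown category {category!r}")
        if raster.grid.same_geometry(grid):
            vals = raster.values[rows, cols]
        else:
            vals = raster.sample(lon_c, lat_c)
        if not np.isfinite(vals).any():
            raise ValueError(f"raster {name!r} has no overlap with the analysis grid")
        table[name] = vals
        categories[name] = category

    ok = np.isfinite(table["response"])
    for name in categories:
        ok &= np.isfinite(table[name])
    n_dropped = int((~ok).sum())
    return VariableTable(table[ok].reset_index(drop=True), categories, n_dropped)


def collinearity_filter(table: VariableTable, threshold: float = 0.7) -> list[str]:
    """Drop one variable of every within-category pair with |r| > threshold.

    Iteratively: find the within-category pair with the highest |r|; drop
    the member with the larger mean |r| against all other remaining
    variables of its category (ties drop the lexicographically later name).
    The result has no within-category pair exceeding the threshold.
    """
    retained: list[str] = []
    for category in CATEGORIES:
        names = table.variables(category)
        if not names:
            continue
        sub = table.data[names]
        keep = list(names)
        while len(keep) > 1:
            corr = sub[keep].corr().abs().to_numpy()
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            if corr[i, j] <= threshold:
                break
            mean_i = corr[i].sum() / (len(keep) - 1)
            mean_j = corr[j].sum() / (len(keep) - 1)
            if mean_i > mean_j:
                drop = keep[i]
            elif mean_j > mean_i:
                drop = keep[j]
            else:
                drop = max(keep[i], keep[j])
            keep.remove(drop)
        retained.extend(keep)
    return retained


def importance_select(
    table: VariableTable,
    category: str,
    k: int = 2,
    seed: int = 0,
    n_rep: int = 10,
    n_trees: int = 500,
    max_cells: int = 10_000,
) -> list[str]:
    """Top-k variables of one category by random-forest permutation importance.

    Importance is the mean drop in model fit when a predictor's values are
    permuted, averaged over ``n_rep`` repeats.  Categories with exactly k
    variables are returned as-is without fitting.  Fitting uses a seeded
    subsample of at most ``max_cells`` cells; identical seeds give
    identical selections.
    """
    names = table.variables(category)
    if len(names) < k:
        raise ValueError(f"category {category!r} has {len(names)} variables; need >= {k}")
    if len(names) == k:
        return list(names)

    rng = np.random.default_rng(seed)
    df = table.data
    if len(df) > max_cells:
        idx = rng.choice(len(df), size=max_cells, replace=False)
        df = df.iloc[np.sort(idx)]
    X = df[names].to_numpy()
    y = df["response"].to_numpy()
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1
    )
    forest.fit(X, y)
    imp = permutation_importance(
        forest, X, y, n_repeats=n_rep, random_state=int(rng.integers(2**31)), n_jobs=1
    )
    order = np.lexsort((names, -imp.importances_mean))
    return [names[i] for i in order[:k]]


def fit_gam(x, y, basis_dim: int = 10, variable: str = "x") -> GAMResult:
    """Univariate penalized B-spline GAM with automatic smoothness selection.

    The penalty weight is chosen by the fitter's integrated criterion;
    adjusted R² uses the smooth's effective degrees of freedom,
    ``1 - (1-R²)(n-1)/(n-edf-1)``.  The trend label summarizes the sign of
    the fitted smooth over the central 90% of the predictor range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n <= basis_dim:
        raise ValueError(f"need n > basis_dim ({n} <= {basis_dim})")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError(f"constant predictor {variable!r}: design is rank deficient")
    if np.ptp(y) == 0:
        # degenerate null model: nothing to explain
        const = float(y[0])
        return GAMResult(
            variable=variable, smooth=lambda x_new: np.full(np.atleast_1d(x_new).shape, const),
            r2_adj=0.0, p_value=1.0, trend="increasing", edf=0.0,
        )

    bs = BSplines(x[:, None], df=[basis_dim], degree=[3])
    intercept = np.ones((n, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GLMGam(y, exog=intercept, smoother=bs)
        model.fit()
        # deterministic scalar optimizer (the default stochastic basin-hopping
        # search breaks bit-reproducibility across runs)
        alpha = model.select_penweight(method="minimize")[0]
        res = GLMGam(y, exog=intercept, smoother=bs, alpha=alpha).fit()

        fitted = res.predict(intercept, exog_smooth=x[:, None])
        ssr = float(np.sum((y - fitted) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ssr / sst if sst > 0 else 0.0
        edf = float(np.sum(res.edf)) - 1.0  # exclude the intercept column
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - edf - 1)
        try:
            test = res.test_significance(0)
            p_value = float(np.squeeze(test.pvalue))
        except Exception:
            p_value = float("nan")

    lo, hi = np.quantile(x, [0.05, 0.95])
    xx = np.linspace(lo, hi, 200)
    yy = res.predict(np.ones((200, 1)), exog_smooth=xx[:, None])
    dy = np.diff(yy)
    if np.all(dy >= -1e-12):
        trend = "increasing"
    elif np.all(dy <= 1e-12):
        trend = "decreasing"
    else:
        trend = "nonmonotone"

    def smooth(x_new):
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        return res.predict(np.ones((len(x_new), 1)), exog_smooth=x_new[:, None])

    return GAMResult(
        variable=variable, smooth=smooth, r2_adj=float(r2_adj),
        p_value=p_value, trend=trend, edf=edf,
    )


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel-adjusted R²: 1 - (1-R²)(n-1)/(n-p-1)."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must be in [0, 1]")
    if n <= p + 1:
        raise ValueError(f"adjusted R² undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _ols_r2(X: np.ndarray, y: np.ndarray, names: list[str]) -> float:
    Xd = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError(f"rank-deficient design over columns {names}")
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / sst


def variation_partition(table: VariableTable, sets: dict[str, list[str]]) -> PartitionResult:
    """Unique and shared adjusted-R² fractions for three explanatory sets.

    ``sets`` maps 'C', 'T', 'A' to disjoint variable-name lists.  Seven OLS
    models (each set union) give seven R² values; after Ezekiel adjustment
    the unique and shared fractions follow by inclusion-exclusion, e.g.
    unique(T) = R²adj(CTA) - R²adj(CA).  Fractions sum to R²adj(CTA)
    exactly; individual shared fractions may be slightly negative, a known
    artifact of adjusted R².
    """
    for key in ("C", "T", "A"):
        if key not in sets or not sets[key]:
            raise ValueError(f"set {key!r} missing or empty")
    all_names = sets["C"] + sets["T"] + sets["A"]
    if len(set(all_names)) != len(all_names):
        raise ValueError("explanatory sets must be disjoint")

    y = table.data["response"].to_numpy(dtype=float)
    n = len(y)

    def model(keys: str) -> float:
        names = sum((sets[k] for k in keys), [])
        r2 = _ols_r2(table.data[names].to_numpy(dtype=float), y, names)
        return adjusted_r2(min(max(r2, 0.0), 1.0), n, len(names))

    adj = {keys: model(keys) for keys in ("C", "T", "A", "CT", "CA", "TA", "CTA")}

    a = adj["CTA"] - adj["TA"]  # unique C
    b = adj["CTA"] - adj["CA"]  # unique T
    c = adj["CTA"] - adj["CT"]  # unique A
    g = adj["C"] + adj["T"] + adj["A"] - adj["CT"] - adj["CA"] - adj["TA"] + adj["CTA"]
    d = adj["C"] + adj["T"] - adj["CT"] - g  # C&T only
    e = adj["T"] + adj["A"] - adj["TA"] - g  # T&A only
    f = adj["C"] + adj["A"] - adj["CA"] - g  # C&A only

    fractions = {"C": a, "T": b, "A": c, "C&T": d, "T&A": e, "C&A": f, "C&T&A": g}
    return PartitionResult(adj_r2=adj, fractions=fractions, residual=1.0 - adj["CTA"])
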