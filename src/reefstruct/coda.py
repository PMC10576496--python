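"""Compositional robust regression of structural metrics on benthic cover.

The benthic data are three-part compositions (Live / Dead / Other areas in
m²) whose parts vary independently — the totals differ between colonies —
so the analysis works on log-ratios rather than raw areas:

1. zeros are treated as *rounded* zeros (cover present but below the DEM's
   detection limit, one native pixel = GSD²) and replaced multiplicatively
   at a fraction alpha (default 0.05) of that limit;
2. each composition is expressed in pivot (isometric log-ratio) coordinates,
   once per part so every part takes the pivot role in turn;
3. each structural metric is regressed on the two coordinates with least
   trimmed squares (LTS), a high-breakdown estimator that minimises the sum
   of the h smallest squared residuals;
4. the pivot coefficient is converted to a predicted change in the metric
   per additional m² of that part, evaluated at the mean composition.

The three pivot coordinate systems are orthogonal rotations of one another,
so the three fits share fitted values and LTS objective; only the reported
coefficient changes meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SingularDesignError

PARTS = ("live", "dead", "other")
PART_LABELS = {"live": "Live", "dead": "Dead", "other": "Other"}
AREA_COLUMNS = ("live_m2", "dead_m2", "other_m2")

EXACT_LTS_MAX_N = 15


@dataclass
class ZeroReplacementConfig:
    """How rounded zeros are imputed before log-ratio transformation.

    ``simple_substitution`` (default) replaces each zero part with
    alpha·detection_limit and leaves nonzero parts untouched — appropriate
    here because the compositions are not closed to a constant total.
    ``closed_multiplicative`` additionally rescales the nonzero parts to
    preserve each record's total.
    """

    alpha: float = 0.05
    mode: str = "simple_substitution"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.mode not in {"simple_substitution", "closed_multiplicative"}:
            raise ValueError(f"unknown zero-replacement mode {self.mode!r}")


@dataclass
class LtsFit:
    """A least-trimmed-squares fit with reweighted classical inference."""

    coefficients: np.ndarray
    h: int
    objective: float
    subset: np.ndarray
    scale: float
    weights: np.ndarray
    reweighted_se: np.ndarray
    p_values: np.ndarray
    n_retained: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients


def replace_rounded_zeros(
    records: pd.DataFrame, config: ZeroReplacementConfig | None = None
) -> pd.DataFrame:
    """Impute zero parts at alpha × the record's detection limit.

    ``records`` must carry columns live_m2, dead_m2, other_m2 and
    detection_limit_m2.  Records without zeros pass through unchanged.
    """
    config = config or ZeroReplacementConfig()
    out = records.copy()
    parts = out.loc[:, list(AREA_COLUMNS)].to_numpy(dtype=float)
    if (parts < 0).any():
        raise ValueError("areas must be non-negative")
    dl = out["detection_limit_m2"].to_numpy(dtype=float)
    if (dl <= 0).any():
        raise ValueError("detection limits must be positive")
    zero = parts == 0.0
    repl = config.alpha * dl[:, None]
    if config.mode == "closed_multiplicative":
        totals = parts.sum(axis=1)
        added = (zero * repl).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(totals > 0, 1.0 - added / totals, 1.0)
        parts = np.where(zero, repl, parts * shrink[:, None])
    else:
        parts = np.where(zero, repl, parts)
    out.loc[:, list(AREA_COLUMNS)] = parts
    return out


def pivot_coordinates(x: np.ndarray, pivot_part: int = 0) -> np.ndarray:
    """Pivot (ilr) coordinates of 3-part compositions, pivot part first.

    z1 = √(2/3)·ln(x_j / √(x_k·x_l)) isolates part j's relative dominance;
    z2 = √(1/2)·ln(x_k / x_l) with (k, l) the remaining parts in fixed
    category order.  Scale-invariant: pivot(λx) = pivot(x).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != 3:
        raise ValueError("compositions must have exactly 3 parts")
    if (x <= 0).any():
        raise ValueError("all parts must be strictly positive (replace zeros first)")
    rest = [k for k in range(3) if k != pivot_part]
    xj, xk, xl = x[:, pivot_part], x[:, rest[0]], x[:, rest[1]]
    z1 = np.sqrt(2.0 / 3.0) * np.log(xj / np.sqrt(xk * xl))
    z2 = np.sqrt(0.5) * np.log(xk / xl)
    return np.column_stack([z1, z2])


# ---------------------------------------------------------------------------
# Least trimmed squares
# ---------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def default_h(n: int, p: int) -> int:
    """Maximum-breakdown trimming count ⌊(n + p + 1)/2⌋."""
    return (n + p + 1) // 2


def _c_steps(X, y, beta, h, max_iter=50):
    """Concentration steps: refit on the h smallest absolute residuals."""
    subset = None
    for _ in range(max_iter):
        resid = y - X @ beta
        new = np.argpartition(np.abs(resid), h - 1)[:h]
        new.sort()
        if subset is not None and np.array_equal(new, subset):
            break
        subset = new
        beta = _ols(X[subset], y[subset])
    resid = y - X @ beta
    obj = float(np.sort(resid**2)[:h].sum())
    return beta, subset, obj


def _lts_consistency_factor(h: int, n: int) -> float:
    """Fisher consistency of the raw LTS scale at the normal model."""
    alpha = h / n
    if alpha >= 1.0:
        return 1.0
    q = stats.norm.ppf((1.0 + alpha) / 2.0)
    trunc_var = 1.0 - 2.0 * q * stats.norm.pdf(q) / alpha
    return 1.0 / np.sqrt(trunc_var)


def lts_fit(
    X: np.ndarray,
    y: np.ndarray,
    h: int | None = None,
    trim_fraction: float | None = None,
    n_starts: int = 500,
    seed: int = 0,
    reweight_cutoff: float = 2.5,
    algorithm: str = "auto",
) -> LtsFit:
    """Least trimmed squares regression with reweighted inference.

    Minimises the sum of the ``h`` smallest squared residuals over the
    coefficients.  For n ≤ 15 the optimum is found exactly by enumerating
    all h-subsets; larger problems use seeded FAST-LTS (random elemental
    starts followed by concentration steps).  ``h = n`` reduces to OLS.

    Standard errors and p-values come from the reweighted step: classical
    OLS inference on the observations whose standardised LTS residuals are
    within ``reweight_cutoff`` of zero, using the consistency-corrected
    LTS scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need at least p + 2 observations")
    if h is None:
        if trim_fraction is not None:
            h = int(np.ceil(n * (1.0 - trim_fraction)))
        else:
            h = default_h(n, p)
    h_min = -(-(n + p + 1) // 2)  # ceil
    h = int(np.clip(h, min(h_min, n), n))

    if algorithm not in {"auto", "exact", "fast"}:
        raise ValueError(f"unknown LTS algorithm {algorithm!r}")
    if algorithm == "auto":
        algorithm = "exact" if n <= EXACT_LTS_MAX_N else "fast"

    if h == n:
        beta = _ols(X, y)
        resid = y - X @ beta
        best = (beta, np.arange(n), float(np.sum(resid**2)))
    elif algorithm == "exact":
        if n > EXACT_LTS_MAX_N:
            raise ValueError(f"exact enumeration is limited to n <= {EXACT_LTS_MAX_N}")
        best = None
        for idx in combinations(range(n), h):
            idx_arr = np.array(idx)
            Xs = X[idx_arr]
            if np.linalg.matrix_rank(Xs) < p:
                continue
            beta = _ols(Xs, y[idx_arr])
            obj = float(np.sum((y[idx_arr] - Xs @ beta) ** 2))
            if best is None or obj < best[2]:
                best = (beta, idx_arr, obj)
        if best is None:
            raise SingularDesignError("design rank deficient on every h-subset")
    else:
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_starts):
            idx = rng.choice(n, size=p + 1, replace=False)
            Xs = X[idx]
            if np.linalg.matrix_rank(Xs) < p:
                continue
            beta0 = _ols(Xs, y[idx])
            beta, subset, obj = _c_steps(X, y, beta0, h)
            if best is None or obj < best[2]:
                best = (beta, subset, obj)
        if best is None:
            raise SingularDesignError("design rank deficient on every elemental start")

    beta, subset, objective = best

    # ----- reweighted step -----------------------------------------------
    raw_scale = np.sqrt(objective / h) * _lts_consistency_factor(h, n)
    resid = y - X @ beta
    if h == n:
        # untrimmed fit IS ordinary least squares; keep every observation
        weights = np.ones(n)
    elif raw_scale < 1e-12:
        weights = (np.abs(resid) <= 1e-12).astype(float)
    else:
        weights = (np.abs(resid) / raw_scale <= reweight_cutoff).astype(float)
    keep = weights > 0
    n_keep = int(keep.sum())
    if n_keep >= p + 1 and np.linalg.matrix_rank(X[keep]) == p:
        beta_rw = _ols(X[keep], y[keep])
        resid_rw = y[keep] - X[keep] @ beta_rw
        dof = n_keep - p
        sigma2 = float(resid_rw @ resid_rw) / dof if dof > 0 else 0.0
        XtX_inv = np.linalg.inv(X[keep].T @ X[keep])
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta_rw / se, 0.0)
        if dof > 0 and sigma2 > 0:
            pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        else:
            # perfect fit: no evidence against any coefficient being noise-free
            pvals = np.where(np.abs(beta_rw) > 0, 0.0, 1.0)
        scale = np.sqrt(sigma2)
    else:
        beta_rw, se = beta, np.full(p, np.nan)
        pvals = np.full(p, np.nan)
        scale = raw_scale

    return LtsFit(
        coefficients=beta_rw,
        h=h,
        objective=objective,
        subset=np.asarray(subset),
        scale=float(scale),
        weights=weights,
        reweighted_se=se,
        p_values=pvals,
        n_retained=n_keep,
    )


# ---------------------------------------------------------------------------
# Per-component effects
# ---------------------------------------------------------------------------

def coda_metric_regression(
    records: pd.DataFrame,
    y: np.ndarray,
    trim_fraction: float | None = None,
    seed: int = 0,
    n_starts: int = 500,
) -> pd.DataFrame:
    """Regress one structural metric on the composition, per component.

    ``records`` must already be zero-replaced.  For each part j the model is
    refit in the pivot coordinate system that puts j first, and the z1
    coefficient (j's relative dominance) is reported with its reweighted SE
    and p-value.  ``delta_y_per_m2`` translates the fit to an area-scale
    effect: predicted metric change when 1 m² of part j is added to the mean
    composition, all other parts fixed.

    Returns a ComponentEffectTable: one row per part with columns
    part, coef_z1, se, p_value, delta_y_per_m2.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(records) != n or n < 6:
        raise ValueError("need matching records and responses, at least 6 rows")
    comp = records.loc[:, list(AREA_COLUMNS)].to_numpy(dtype=float)
    if (comp <= 0).any():
        raise ValueError("compositions contain non-positive parts; replace zeros first")

    xbar = comp.mean(axis=0)
    if np.ptp(y) == 0.0:
        # constant response: nothing to explain, effects are null by contract
        return pd.DataFrame(
            {
                "part": [PART_LABELS[p] for p in PARTS],
                "coef_z1": 0.0,
                "se": np.nan,
                "p_value": 1.0,
                "delta_y_per_m2": 0.0,
                "n_retained": n,
            }
        )
    rows = []
    objectives, fitted_all = [], []
    for j, part in enumerate(PARTS):
        Z = pivot_coordinates(comp, pivot_part=j)
        X = np.column_stack([np.ones(n), Z])
        fit = lts_fit(X, y, trim_fraction=trim_fraction, seed=seed, n_starts=n_starts)
        objectives.append(fit.objective)
        fitted_all.append(fit.predict(X))

        z_bar = pivot_coordinates(xbar[None, :], pivot_part=j)
        bumped = xbar.copy()
        bumped[j] += 1.0
        z_bump = pivot_coordinates(bumped[None, :], pivot_part=j)
        delta = float(
            fit.predict(np.column_stack([np.ones(1), z_bump]))[0]
            - fit.predict(np.column_stack([np.ones(1), z_bar]))[0]
        )
        rows.append(
            {
                "part": PART_LABELS[part],
                "coef_z1": float(fit.coefficients[1]),
                "se": float(fit.reweighted_se[1]),
                "p_value": float(fit.p_values[1]),
                "delta_y_per_m2": delta,
                "n_retained": fit.n_retained,
            }
        )

    # the three pivot systems are rotations of one another
    obj_scale = max(max(objectives), 1.0)
    if max(objectives) - min(objectives) > 1e-9 * obj_scale:
        raise AssertionError("pivot rotations disagree on the LTS objective")
    for fv in fitted_all[1:]:
        if not np.allclose(fv, fitted_all[0], atol=1e-9 * max(1.0, np.abs(y).max())):
            raise AssertionError("pivot rotations disagree on fitted values")

    return pd.DataFrame(rows)


def _sig_mark(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "."
    return ""


def effects_report(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-metric ComponentEffectTables into one results table.

    Columns mirror the regression summary layout: metric, part, Δŷ/m²,
    SEM, p, and a significance mark ('*' at alpha 0.05, '.' at 0.10).
    """
    if not tables:
        raise ValueError("no effect tables to report")
    blocks = []
    for metric, table in tables.items():
        if len(table) == 0:
            raise ValueError(f"empty effect table for {metric!r}")
        block = table.copy()
        block.insert(0, "metric", metric)
        block["signif"] = [_sig_mark(p) for p in block["p_value"]]
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def effects_markdown(report: pd.DataFrame) -> str:
    """Markdown rendering of an effects report."""
    lines = [
        "| Metric | Benthos | dy/m2 | SEM | p | |",
        "|---|---|---|---|---|---|",
    ]
    for _, r in report.iterrows():
        lines.append(
            f"| {r['metric']} | {r['part']} | {r['delta_y_per_m2']:.4g} "
            f"| {r['se']:.4g} | {r['p_value']:.4g} | {r['signif']} |"
        )
    lines.append("")
    lines.append("Significance: '*' p < 0.05, '.' p < 0.10.")
    return "\n".join(lines)
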