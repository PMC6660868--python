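"""Data-driven weight estimation.

Two estimators feed the model configuration:

* :func:`catpca_weights` — per-variable weights from a historical panel of
  ordinal scores, via single-component categorical PCA with optimal scaling
  (PRINCALS-style alternating least squares).  Each variable's 1..5
  categories are re-quantified monotonically so that a single latent
  component explains as much of the panel as possible; the variable weight
  is its squared component loading normalized to sum 1 — a
  variance-contribution reading of the loadings.

* :func:`component_betas` — the (b1, b2, b3) component weights from a panel
  of continuous (VT, VP, SOA) component scores, via a one-factor model
  fitted by principal-axis iteration; betas are squared loadings normalized
  to sum 1, with a configurable fallback when the fit is degenerate.

Both are deterministic: the ALS starts from the raw numeric scores, never
from a random configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "ConvergenceError",
    "DegenerateFactorWarning",
    "EstimationError",
    "OrdinalPanel",
    "catpca_weights",
    "component_betas",
]


class EstimationError(ValueError):
    """Panel violates estimation preconditions."""


class ConvergenceError(RuntimeError):
    """ALS failed to converge; carries the final loss value."""

    def __init__(self, message: str, loss: float):
        super().__init__(message)
        self.loss = loss


class DegenerateFactorWarning(UserWarning):
    """One-factor fit was degenerate; default betas were returned."""


@dataclass
class OrdinalPanel:
    """Historical panel of ordinal scores: rows = establishments, columns =
    variables of one (scope, product_line) group, values integer 1..5."""

    data: pd.DataFrame
    scope: str = "transversal"
    product_line: str = "all"

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[1] < 3:
            raise EstimationError("panel needs at least 3 variables for estimation")
        if df.shape[0] <= df.shape[1]:
            raise EstimationError(
                f"panel needs more rows than columns ({df.shape[0]} rows, {df.shape[1]} cols)"
            )
        arr = df.to_numpy()
        if not np.isin(arr, [1, 2, 3, 4, 5]).all():
            raise EstimationError("panel scores must be integers in 1..5")
        for col in df.columns:
            if df[col].nunique() < 2:
                raise EstimationError(f"variable {col!r} is constant in the panel")


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _monotone_fit(categories: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, float]:
    """Best category-wise monotone approximation of z, either direction.

    Returns the fitted values (same length as z) and the SSE.  Fitting both
    an increasing and a decreasing quantification and keeping the better one
    lets a variable load negatively on the component while its category
    quantifications stay ordered.
    """
    best: tuple[np.ndarray, float] | None = None
    for increasing in (True, False):
        iso = IsotonicRegression(increasing=increasing)
        fit = iso.fit_transform(categories, z)
        sse = float(((z - fit) ** 2).sum())
        if best is None or sse < best[1]:
            best = (np.asarray(fit, dtype=float), sse)
    return best


def catpca_weights(
    panel: OrdinalPanel, tol: float = 1e-6, max_iter: int = 500
) -> dict[str, float]:
    """Estimate variable weights by single-component optimal-scaling PCA.

    Alternates (a) monotone re-quantification of each variable's category
    values against the current object scores and (b) component extraction on
    the quantified, standardized matrix, until the relative loss improvement
    drops below ``tol`` or ``max_iter`` is reached.  The loss is the mean
    squared distance between object scores and each variable's loading-scaled
    quantified scores; it is non-increasing across iterations by
    construction (asserted).

    Returns ``{variable_id: weight}`` with nonnegative weights summing to 1:
    weight_j = loading_j**2 / sum_k loading_k**2.
    """
    X = panel.data.to_numpy(dtype=float)
    n, m = X.shape

    # deterministic start: standardized raw scores, unit loadings
    Q = np.column_stack([_standardize(X[:, j]) for j in range(m)])
    a = np.ones(m)

    def object_scores(Q: np.ndarray, a: np.ndarray) -> np.ndarray:
        zbar = Q @ a
        norm = np.linalg.norm(zbar)
        if norm < 1e-12:
            raise ConvergenceError("object scores collapsed to zero", loss=np.inf)
        return zbar / norm * np.sqrt(n)

    def loss_value(z: np.ndarray, Q: np.ndarray, a: np.ndarray) -> float:
        return float(((z[:, None] - Q * a) ** 2).sum()) / (n * m)

    z = object_scores(Q, a)
    a = Q.T @ z / n
    prev = loss_value(z, Q, a)

    for _ in range(max_iter):
        # (a) optimal monotone quantification per variable
        for j in range(m):
            fit, _ = _monotone_fit(X[:, j], z)
            sd = fit.std()
            if sd < 1e-12:  # all categories pooled: variable unrelated to z
                a[j] = 0.0
                continue
            Q[:, j] = (fit - fit.mean()) / sd
            a[j] = float(Q[:, j] @ z) / n
        # (b) component extraction: object scores for fixed quantifications
        z = object_scores(Q, a)
        a = Q.T @ z / n
        cur = loss_value(z, Q, a)
        assert cur <= prev + 1e-9, "ALS loss increased"
        # relative improvement below tol (absolute floor covers loss ~ 0)
        if prev - cur <= tol * max(prev, 1e-12):
            weights = a**2 / float((a**2).sum())
            return dict(zip(panel.data.columns, weights.tolist()))
        prev = cur

    raise ConvergenceError(
        f"optimal-scaling PCA did not converge in {max_iter} iterations", loss=prev
    )


# ---------------------------------------------------------------------------
# Component betas: one-factor model on (VT, VP, SOA)
# ---------------------------------------------------------------------------


def _principal_axis_loadings(R: np.ndarray, max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """One-factor principal-axis loadings from a correlation matrix.

    Initial communalities are the max absolute off-diagonal correlation per
    variable; iterate reduced-correlation eigen-decomposition until the
    communalities stabilize.  Heywood communalities are clipped to 1.
    """
    m = R.shape[0]
    off = R - np.eye(m)
    h2 = np.abs(off).max(axis=0)
    loadings = np.sqrt(h2)
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        lam, v = vals[-1], vecs[:, -1]
        if lam <= 0:
            raise np.linalg.LinAlgError("no positive leading eigenvalue")
        loadings = np.sqrt(lam) * v
        if loadings.sum() < 0:
            loadings = -loadings
        new_h2 = np.clip(loadings**2, 0.0, 1.0)
        if np.max(np.abs(new_h2 - h2)) < tol:
            return loadings
        h2 = new_h2
    return loadings


def component_betas(
    component_panel: pd.DataFrame,
    default_betas: tuple[float, float, float] = (0.45, 0.25, 0.30),
) -> tuple[float, float, float]:
    """Estimate (b1, b2, b3) from a panel of (vt, vp, soa) component scores.

    Fits a one-factor model to the three standardized columns and returns
    squared loadings normalized to sum 1.  When the fit is degenerate
    (no positive leading eigenvalue, invalid loadings, zero variance
    structure) the configured ``default_betas`` are returned with a
    :class:`DegenerateFactorWarning`.
    """
    df = component_panel
    if df.shape[1] != 3:
        raise EstimationError(f"component panel must have 3 columns, got {df.shape[1]}")
    if df.shape[0] < 10:
        raise EstimationError(f"component panel needs >= 10 rows, got {df.shape[0]}")
    X = df.to_numpy(dtype=float)
    if np.any(X.std(axis=0) < 1e-12):
        raise EstimationError("component panel has a zero-variance column")
    R = np.corrcoef(X, rowvar=False)
    try:
        loadings = _principal_axis_loadings(R)
        ss = float((loadings**2).sum())
        if not np.isfinite(ss) or ss < 1e-12:
            raise np.linalg.LinAlgError("degenerate loadings")
    except np.linalg.LinAlgError as e:
        warnings.warn(
            f"one-factor fit degenerate ({e}); falling back to default betas",
            DegenerateFactorWarning,
            stacklevel=2,
        )
        s = sum(default_betas)
        return tuple(b / s for b in default_betas)
    betas = loadings**2 / ss
    return tuple(float(b) for b in betas)
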