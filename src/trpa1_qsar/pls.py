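"""Partial least squares engine for field-matrix QSAR.

Implements the classic CoMFA-style modelling chain: column filtering
(minimum-sigma), block scaling, NIPALS PLS1, leave-one-out cross-validation
with optimum-component selection, and the internal model diagnostics
(r-squared, SEE, F, per-field contributions).

Notation: n samples, c latent components.  r2 = 1 - SSres/SStot;
SEE = sqrt(SSres / (n - c - 1)); F = (r2/c) / ((1 - r2)/(n - c - 1));
r2cv (Q2) = 1 - PRESS/SStot with PRESS accumulated over leave-one-out
predictions and SStot about the full training mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSModel",
    "CVResult",
    "InternalStats",
    "filter_columns",
    "block_scales",
    "fit_pls",
    "loo_q2",
    "internal_stats",
    "regression_stats",
]

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_FILTER = 2.0     # kcal/mol, SYBYL-style minimum sigma
DEFAULT_MAX_COMPONENTS = 10


def filter_columns(X: np.ndarray, threshold: float = DEFAULT_COLUMN_FILTER) -> np.ndarray:
    """Boolean mask of columns whose sample std across compounds >= threshold.

    A zero threshold keeps every column. Raises if nothing survives.
    """
    if threshold < 0:
        raise ValueError("column-filter threshold must be >= 0")
    X = np.asarray(X, float)
    if threshold == 0:
        return np.ones(X.shape[1], dtype=bool)
    sigma = X.std(axis=0, ddof=1)
    mask = sigma >= threshold
    if not mask.any():
        raise ValueError(
            f"column filter at {threshold} dropped every column; lower the threshold"
        )
    return mask


def block_scales(
    X: np.ndarray, channel_of_column: np.ndarray, mode: str = "comfa_std"
) -> np.ndarray:
    """Per-column divisors implementing the chosen scaling mode.

    ``comfa_std`` gives every field block (channel) equal overall variance:
    one common divisor per block, the pooled std of its centered entries.
    ``autoscale`` is per-column unit variance; ``none`` leaves units alone.
    """
    X = np.asarray(X, float)
    scales = np.ones(X.shape[1])
    if mode == "none":
        return scales
    if mode == "autoscale":
        s = X.std(axis=0, ddof=1)
        return np.where(s > 0, s, 1.0)
    if mode != "comfa_std":
        raise ValueError(f"unknown scaling mode {mode!r}")
    if channel_of_column is None:  # one block: a single pooled divisor
        channel_of_column = np.zeros(X.shape[1], dtype=int)
    channel_of_column = np.asarray(channel_of_column)
    for ch in np.unique(channel_of_column):
        cols = channel_of_column == ch
        centered = X[:, cols] - X[:, cols].mean(axis=0)
        s = centered.std(ddof=0)
        scales[cols] = s if s > 0 else 1.0
    return scales


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS regression in original column units."""

    n_components: int
    column_mask: np.ndarray         # over the pre-filter columns
    column_means: np.ndarray        # per retained column
    column_scales: np.ndarray       # per retained column
    coefficients: np.ndarray        # per retained column, original units
    coefficients_scaled: np.ndarray  # in the centered/scaled space
    intercept: float
    fitted: np.ndarray
    channel_of_column: np.ndarray | None = None  # per PRE-filter column

    def retained_channels(self) -> np.ndarray | None:
        """Channel label of each retained column."""
        if self.channel_of_column is None:
            return None
        return np.asarray(self.channel_of_column)[self.column_mask]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] == self.column_mask.size:
            X = X[:, self.column_mask]
        return X @ self.coefficients + self.intercept


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int) -> np.ndarray:
    """NIPALS PLS1 on centered data; returns coefficients in that space."""
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    Xk, yk = Xc.copy(), yc.copy()
    a = 0
    for a in range(n_components):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = Xk @ w
        tt = t @ t
        if tt < 1e-14:
            break
        W[:, a] = w
        P[:, a] = Xk.T @ t / tt
        q[a] = (yk @ t) / tt
        Xk = Xk - np.outer(t, P[:, a])
        yk = yk - q[a] * t
    else:
        a = n_components
    if a < n_components:
        W, P, q = W[:, :a], P[:, :a], q[:a]
    if W.shape[1] == 0:
        return np.zeros(p)
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    column_mask: np.ndarray | None = None,
    scaling: str = "none",
    channel_of_column: np.ndarray | None = None,
) -> PLSModel:
    """Fit a NIPALS PLS1 model of ``y`` on ``X``.

    ``column_mask`` (e.g. from :func:`filter_columns`) restricts the columns
    used; coefficients are mapped back to the original column units so that
    ``predict`` works on raw matrices.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if column_mask is None:
        column_mask = np.ones(X.shape[1], dtype=bool)
    Xr = X[:, column_mask]
    ch_full = None if channel_of_column is None else np.asarray(channel_of_column)
    ch = None if ch_full is None else ch_full[column_mask]
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    max_c = min(n - 1, Xr.shape[1])
    if not (1 <= n_components <= max_c):
        raise ValueError(f"n_components must be in [1, {max_c}], got {n_components}")
    means = Xr.mean(axis=0)
    scales = block_scales(Xr, ch, scaling) if scaling != "none" else np.ones(Xr.shape[1])
    Xc = (Xr - means) / scales
    ymean = y.mean()
    b_scaled = _nipals(Xc, y - ymean, n_components)
    coef = b_scaled / scales
    intercept = ymean - means @ coef
    fitted = Xr @ coef + intercept
    return PLSModel(
        n_components=n_components,
        column_mask=np.asarray(column_mask, bool),
        column_means=means,
        column_scales=scales,
        coefficients=coef,
        coefficients_scaled=b_scaled,
        intercept=float(intercept),
        fitted=fitted,
        channel_of_column=ch_full,
    )


@dataclass(frozen=True)
class CVResult:
    """Leave-one-out cross-validation curve and the selected ONC."""

    q2_by_ncomp: np.ndarray     # index a -> r2cv with a+1 components
    press_by_ncomp: np.ndarray
    onc: int

    @property
    def q2(self) -> float:
        return float(self.q2_by_ncomp[self.onc - 1])


def loo_q2(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    *,
    column_mask: np.ndarray | None = None,
    scaling: str = "none",
    channel_of_column: np.ndarray | None = None,
) -> CVResult:
    """Leave-one-out PRESS and r2cv for 1..max_components components.

    Each fold refits the NIPALS model without one sample and predicts it;
    r2cv = 1 - PRESS/SStot with SStot about the full-training mean. The ONC
    is the smallest component count attaining the maximal r2cv.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        raise ValueError("LOO needs at least 3 samples")
    if column_mask is None:
        column_mask = np.ones(X.shape[1], dtype=bool)
    Xr = X[:, column_mask]
    ch = None if channel_of_column is None else np.asarray(channel_of_column)[column_mask]
    bound = min(n - 2, Xr.shape[1])  # n-1 training samples per fold
    if max_components > bound:
        logger.warning("max_components clipped from %d to %d", max_components, bound)
        max_components = bound
    preds = np.zeros((n, max_components))
    for i in range(n):
        keep = np.arange(n) != i
        for a in range(1, max_components + 1):
            m = fit_pls(Xr[keep], y[keep], a, scaling=scaling, channel_of_column=ch)
            preds[i, a - 1] = m.predict(Xr[i : i + 1])[0]
    press = ((preds - y[:, None]) ** 2).sum(axis=0)
    sstot = ((y - y.mean()) ** 2).sum()
    q2 = 1.0 - press / sstot
    onc = int(np.argmax(q2)) + 1   # argmax returns the first (smallest) maximizer
    return CVResult(q2_by_ncomp=q2, press_by_ncomp=press, onc=onc)


@dataclass(frozen=True)
class InternalStats:
    """Non-cross-validated training diagnostics."""

    r2: float
    see: float
    f_value: float
    field_contributions: dict[str, float]


def regression_stats(actual: np.ndarray, predicted: np.ndarray, n_components: int) -> tuple[float, float, float]:
    """(r2, SEE, F) of fitted values against actuals for a c-component model.

    This is plain arithmetic on (actual, predicted) pairs, so it applies
    equally to a refit model and to a published prediction table.
    """
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    n, c = len(actual), n_components
    if n <= c + 1:
        raise ValueError(f"need n > c + 1 (n={n}, c={c})")
    ssres = ((actual - predicted) ** 2).sum()
    sstot = ((actual - actual.mean()) ** 2).sum()
    r2 = 1.0 - ssres / sstot
    see = float(np.sqrt(ssres / (n - c - 1)))
    if r2 >= 1.0:  # perfect fit: F diverges
        f = float("inf")
    else:
        f = float((r2 / c) / ((1.0 - r2) / (n - c - 1)))
    return float(r2), see, f


def internal_stats(model: PLSModel, X: np.ndarray, y: np.ndarray) -> InternalStats:
    """r2, SEE, F and normalized per-field contributions of a fitted model.

    Contributions follow the conventional definition: per channel,
    sum_j |coef_j| * sigma_j over its columns (in the scaled space the model
    was fitted in), normalized across channels to sum to 1.
    """
    y = np.asarray(y, float)
    r2, see, f = regression_stats(y, model.predict(X), model.n_components)
    contributions: dict[str, float] = {}
    retained = model.retained_channels()
    if retained is not None:
        X = np.asarray(X, float)
        Xr = X[:, model.column_mask] if X.shape[1] == model.column_mask.size else X
        sigma = ((Xr - model.column_means) / model.column_scales).std(axis=0, ddof=1)
        raw = {}
        for ch in dict.fromkeys(model.channel_of_column):
            cols = retained == ch
            raw[str(ch)] = float(np.abs(model.coefficients_scaled[cols]) @ sigma[cols])
        total = sum(raw.values())
        contributions = {k: (v / total if total > 0 else 0.0) for k, v in raw.items()}
    return InternalStats(r2=r2, see=see, f_value=f, field_contributions=contributions)
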